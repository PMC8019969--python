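"""End-to-end orchestration: preprocess, phase, classify, filter, summarize."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from .background import GeneBackgroundTable, build_background, filter_by_background
from .engine import (
    identify_ch,
    identify_ch_unrelated,
    identify_ha,
    identify_ha_unrelated,
)
from .model import (
    ChCall,
    FilterThresholds,
    HaCall,
    Pedigree,
    TrioSite,
    VariantCohort,
)
from .phasing import cohort_phasing_stats, phase_trio
from .preprocess import AttritionLedger, run_preprocess
from .summary import DiseaseSummary, summarize_disease


@dataclass
class TrioSurveyResult:
    ch_calls: list[ChCall] = field(default_factory=list)
    ha_calls: list[HaCall] = field(default_factory=list)
    phased_sites: dict[str, list[TrioSite]] = field(default_factory=dict)
    ledger: AttritionLedger = field(default_factory=AttritionLedger)

    def phasing_stats(self) -> pd.DataFrame:
        return cohort_phasing_stats(self.phased_sites)


def run_trio_survey(
    cohort: VariantCohort,
    pedigree: Pedigree,
    thresholds: FilterThresholds = FilterThresholds(),
) -> TrioSurveyResult:
    """Preprocess, phase and classify every complete trio in a cohort."""
    result = TrioSurveyResult()
    for trio in pedigree.trios:
        sites, _ = run_preprocess(cohort, trio, result.ledger)
        phased = phase_trio(sites)
        result.phased_sites[trio.child] = phased
        result.ch_calls += identify_ch(phased, trio.child, thresholds)
        result.ha_calls += identify_ha(phased, trio.child, thresholds)
    return result


def run_control_survey(
    cohort: VariantCohort,
    thresholds: FilterThresholds = FilterThresholds(),
) -> tuple[list[ChCall], list[HaCall]]:
    """Parent-free CH/HA classification of a phased unrelated cohort.

    Non-autosomal and duplicated positions are dropped first, mirroring the
    trio preprocessing scope.
    """
    from collections import Counter

    position_counts = Counter(record.position_key for record, _ in cohort.sites)
    clean = [
        (record, genotypes)
        for record, genotypes in cohort.sites
        if record.is_autosomal
        and position_counts[record.position_key] == 1
        and record.position_key not in cohort.multiallelic_positions
    ]
    ch_calls: list[ChCall] = []
    ha_calls: list[HaCall] = []
    for sample in cohort.samples:
        sample_sites = [
            (record, genotypes[sample])
            for record, genotypes in clean
            if genotypes.get(sample) is not None
        ]
        ch_calls += identify_ch_unrelated(sample_sites, sample, thresholds)
        ha_calls += identify_ha_unrelated(sample_sites, sample, thresholds)
    return ch_calls, ha_calls


@dataclass
class SurveyResult:
    """Full survey output for one disease cohort against one control cohort."""

    disease: str
    trio_result: TrioSurveyResult
    ch_background: GeneBackgroundTable
    ha_background: GeneBackgroundTable
    ch_filtered: list[ChCall]
    ha_filtered: list[HaCall]
    summary: DiseaseSummary


def run_survey(
    trio_cohort: VariantCohort,
    pedigree: Pedigree,
    control_cohort: VariantCohort,
    thresholds: FilterThresholds = FilterThresholds(),
    disease: str = "disease",
    denominator_mode: str = "calling_samples",
    cohort_size: Optional[int] = None,
) -> SurveyResult:
    """The complete survey: trio classification, control background, filtering
    and the per-disease summary."""
    trio_result = run_trio_survey(trio_cohort, pedigree, thresholds)
    control_ch, control_ha = run_control_survey(control_cohort, thresholds)
    ch_background = build_background(
        control_ch, "CH", denominator_mode, len(control_cohort.samples)
    )
    ha_background = build_background(
        control_ha, "HA", denominator_mode, len(control_cohort.samples)
    )
    ch_filtered = filter_by_background(
        trio_result.ch_calls, ch_background, thresholds.background_prevalence_max
    )
    ha_filtered = filter_by_background(
        trio_result.ha_calls, ha_background, thresholds.background_prevalence_max
    )
    if cohort_size is None:
        cohort_size = len(pedigree.trios)
    summary = summarize_disease(
        disease,
        cohort_size,
        trio_result.ch_calls,
        ch_filtered,
        trio_result.ha_calls,
        ha_filtered,
    )
    return SurveyResult(
        disease=disease,
        trio_result=trio_result,
        ch_background=ch_background,
        ha_background=ha_background,
        ch_filtered=ch_filtered,
        ha_filtered=ha_filtered,
        summary=summary,
    )
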