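"""Cohort-level summary statistics for CH/HA survey results.

Produces per-disease gene and sample counts before and after background
filtering, the "unique CH" increments (samples and genes with a CH call but
no HA call, expressed as a percent increase over the HA counts), pooled
cross-disease statistics, and attrition step summaries.  All counting is
over distinct (sample, gene) pairs, and every printed percent or mean is
rounded half-up to one decimal.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Optional, Sequence

import pandas as pd

from .model import sample_gene_pairs
from .preprocess import AttritionLedger


def round_half_up(value: float, decimals: int = 1) -> float:
    """Round half away from zero (the convention used for all printed values)."""
    quantum = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(quantum, rounding=ROUND_HALF_UP))


def percent(count: int, total: int, decimals: int = 1) -> float:
    if total <= 0:
        raise ValueError("total must be positive")
    return round_half_up(100.0 * count / total, decimals)


def percent_increase(unique_count: int, base_count: int) -> Optional[float]:
    """Percent increase of unique CH carriers over the HA count (1 decimal).

    Undefined (``None``) when the HA baseline is zero.
    """
    if base_count == 0:
        return None
    return round_half_up(100.0 * unique_count / base_count)


@dataclass
class DiseaseSummary:
    """Gene/sample counts for one disease cohort, before and after filtering."""

    disease: str
    cohort_size: int
    n_genes_ch_initial: int
    n_genes_ch_filtered: int
    n_samples_ch_initial: int
    n_samples_ch_filtered: int
    n_genes_ha_initial: int
    n_genes_ha_filtered: int
    n_samples_ha_initial: int
    n_samples_ha_filtered: int
    n_unique_ch_samples: int = 0
    n_unique_ch_genes: int = 0

    def __post_init__(self) -> None:
        if self.cohort_size <= 0:
            raise ValueError("cohort_size must be positive")
        for prefix in ("n_genes_ch", "n_samples_ch", "n_genes_ha", "n_samples_ha"):
            initial = getattr(self, f"{prefix}_initial")
            filtered = getattr(self, f"{prefix}_filtered")
            if filtered > initial:
                raise ValueError(
                    f"{prefix}: filtered count {filtered} exceeds initial {initial}"
                )

    # -- unrounded percents (used for pooling) --------------------------------
    def _raw_percent(self, count: int) -> float:
        return 100.0 * count / self.cohort_size

    # -- printed values -------------------------------------------------------
    @property
    def percent_samples_ch_initial(self) -> float:
        return percent(self.n_samples_ch_initial, self.cohort_size)

    @property
    def percent_samples_ch_filtered(self) -> float:
        return percent(self.n_samples_ch_filtered, self.cohort_size)

    @property
    def percent_samples_ha_initial(self) -> float:
        return percent(self.n_samples_ha_initial, self.cohort_size)

    @property
    def percent_samples_ha_filtered(self) -> float:
        return percent(self.n_samples_ha_filtered, self.cohort_size)

    @property
    def percent_increase_samples(self) -> Optional[float]:
        return percent_increase(self.n_unique_ch_samples, self.n_samples_ha_filtered)

    @property
    def percent_increase_genes(self) -> Optional[float]:
        return percent_increase(self.n_unique_ch_genes, self.n_genes_ha_filtered)


def summarize_disease(
    disease: str,
    cohort_size: int,
    ch_initial: Iterable,
    ch_filtered: Iterable,
    ha_initial: Iterable,
    ha_filtered: Iterable,
) -> DiseaseSummary:
    """Count distinct genes and samples in each call set for one disease."""
    sets = {
        name: sample_gene_pairs(calls)
        for name, calls in (
            ("ch_initial", ch_initial),
            ("ch_filtered", ch_filtered),
            ("ha_initial", ha_initial),
            ("ha_filtered", ha_filtered),
        )
    }
    ch_samples = {s for s, _ in sets["ch_filtered"]}
    ha_samples = {s for s, _ in sets["ha_filtered"]}
    ch_genes = {g for _, g in sets["ch_filtered"]}
    ha_genes = {g for _, g in sets["ha_filtered"]}
    return DiseaseSummary(
        disease=disease,
        cohort_size=cohort_size,
        n_genes_ch_initial=len({g for _, g in sets["ch_initial"]}),
        n_genes_ch_filtered=len(ch_genes),
        n_samples_ch_initial=len({s for s, _ in sets["ch_initial"]}),
        n_samples_ch_filtered=len(ch_samples),
        n_genes_ha_initial=len({g for _, g in sets["ha_initial"]}),
        n_genes_ha_filtered=len(ha_genes),
        n_samples_ha_initial=len({s for s, _ in sets["ha_initial"]}),
        n_samples_ha_filtered=len(ha_samples),
        n_unique_ch_samples=len(ch_samples - ha_samples),
        n_unique_ch_genes=len(ch_genes - ha_genes),
    )


def unique_ch_increment(
    ch_filtered: Iterable, ha_filtered: Iterable
) -> tuple[int, int, tuple[Optional[float], Optional[float]]]:
    """Samples and genes with a CH call but no HA call, after filtering.

    Returns (n_unique_samples, n_unique_genes, (percent increase in samples,
    percent increase in genes)); the percent increases are relative to the
    filtered HA sample/gene counts and are ``None`` when that baseline is 0.
    """
    ch_pairs = sample_gene_pairs(ch_filtered)
    ha_pairs = sample_gene_pairs(ha_filtered)
    ch_samples = {s for s, _ in ch_pairs}
    ha_samples = {s for s, _ in ha_pairs}
    ch_genes = {g for _, g in ch_pairs}
    ha_genes = {g for _, g in ha_pairs}
    n_unique_samples = len(ch_samples - ha_samples)
    n_unique_genes = len(ch_genes - ha_genes)
    return (
        n_unique_samples,
        n_unique_genes,
        (
            percent_increase(n_unique_samples, len(ha_samples)),
            percent_increase(n_unique_genes, len(ha_genes)),
        ),
    )


@dataclass
class PooledSummary:
    """Cross-disease means and size-weighted pooled percents (1 decimal)."""

    n_diseases: int
    mean_genes_ch_initial: float
    mean_genes_ch_filtered: float
    mean_genes_ha_initial: float
    mean_genes_ha_filtered: float
    mean_percent_samples_ch_initial: float
    mean_percent_samples_ch_filtered: float
    mean_percent_samples_ha_initial: float
    mean_percent_samples_ha_filtered: float
    pooled_percent_samples_ch_initial: float
    pooled_percent_samples_ch_filtered: float
    pooled_percent_samples_ha_initial: float
    pooled_percent_samples_ha_filtered: float


def pool_summaries(summaries: Sequence[DiseaseSummary]) -> PooledSummary:
    """Unweighted means of per-disease statistics plus pooled percents.

    The pooled percent divides the total number of carrier samples by the
    total cohort size, which equals the cohort-size-weighted mean of the
    unrounded per-disease percents.
    """
    if not summaries:
        raise ValueError("need at least one disease summary")
    n = len(summaries)
    total_size = sum(s.cohort_size for s in summaries)

    def mean_count(attr: str) -> float:
        return round_half_up(sum(getattr(s, attr) for s in summaries) / n)

    def mean_percent(attr: str) -> float:
        return round_half_up(sum(s._raw_percent(getattr(s, attr)) for s in summaries) / n)

    def pooled(attr: str) -> float:
        return round_half_up(100.0 * sum(getattr(s, attr) for s in summaries) / total_size)

    return PooledSummary(
        n_diseases=n,
        mean_genes_ch_initial=mean_count("n_genes_ch_initial"),
        mean_genes_ch_filtered=mean_count("n_genes_ch_filtered"),
        mean_genes_ha_initial=mean_count("n_genes_ha_initial"),
        mean_genes_ha_filtered=mean_count("n_genes_ha_filtered"),
        mean_percent_samples_ch_initial=mean_percent("n_samples_ch_initial"),
        mean_percent_samples_ch_filtered=mean_percent("n_samples_ch_filtered"),
        mean_percent_samples_ha_initial=mean_percent("n_samples_ha_initial"),
        mean_percent_samples_ha_filtered=mean_percent("n_samples_ha_filtered"),
        pooled_percent_samples_ch_initial=pooled("n_samples_ch_initial"),
        pooled_percent_samples_ch_filtered=pooled("n_samples_ch_filtered"),
        pooled_percent_samples_ha_initial=pooled("n_samples_ha_initial"),
        pooled_percent_samples_ha_filtered=pooled("n_samples_ha_filtered"),
    )


def genes_per_affected_sample(calls: Iterable) -> Optional[float]:
    """Mean number of distinct called genes among samples with >= 1 call.

    ``None`` when no sample carries a call; at least 1.0 otherwise.
    """
    genes_by_sample: dict[str, set[str]] = {}
    for sample, gene in sample_gene_pairs(calls):
        genes_by_sample.setdefault(sample, set()).add(gene)
    if not genes_by_sample:
        return None
    return sum(len(g) for g in genes_by_sample.values()) / len(genes_by_sample)


def attrition_summary(
    ledgers: AttritionLedger | Sequence[AttritionLedger],
) -> pd.DataFrame:
    """Per-step cohort medians with the percent retained relative to input.

    Accepts one cohort-wide ledger or a sequence of per-trio ledgers.  The
    returned frame has one row per step with columns ``step``, ``median``
    and ``retained_percent`` (median at that step over the input median,
    rounded to 1 decimal).
    """
    if isinstance(ledgers, AttritionLedger):
        entries = list(ledgers.entries)
    else:
        entries = [e for ledger in ledgers for e in ledger.entries]
    if not entries:
        return pd.DataFrame(columns=["step", "median", "retained_percent"])
    frame = pd.DataFrame(entries, columns=["step", "sample", "count"])
    rows = []
    initial_median: Optional[float] = None
    for step in dict.fromkeys(frame["step"]):
        median = float(statistics.median(frame.loc[frame["step"] == step, "count"]))
        if initial_median is None:
            initial_median = median
        retained = (
            round_half_up(100.0 * median / initial_median) if initial_median else None
        )
        rows.append({"step": step, "median": median, "retained_percent": retained})
    return pd.DataFrame(rows)


def mean_retained_fraction(ledgers: Sequence[AttritionLedger]) -> Optional[float]:
    """Mean over samples of final/initial variant counts."""
    fractions = []
    for ledger in ledgers:
        for sample in {smp for _, smp, _ in ledger.entries}:
            fraction = ledger.retained_fraction(sample)
            if fraction is not None:
                fractions.append(fraction)
    return sum(fractions) / len(fractions) if fractions else None
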