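"""Site-level preprocessing applied to each trio before phasing.

Steps, in fixed order: retain sites where the proband carries an alternate
allele, drop multiallelic/duplicate positions and non-autosomes, drop sites
where both parents' genotypes are fully missing, and (after phasing) drop
Mendelian-inconsistent sites.  Each step is idempotent and deletes sites for
the trio at hand only.  An :class:`AttritionLedger` records the per-sample
variant count after every step.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from itertools import product
from typing import Iterable, Optional

import pandas as pd

from .model import Genotype, Trio, TrioSite, VariantCohort

PREPROCESS_STEPS = (
    "input",
    "retain_proband_variant_sites",
    "drop_multiallelic_and_duplicates",
    "drop_missing_both_parents",
    "drop_mendelian_errors",
)


class MendelianStatus(str, Enum):
    CONSISTENT = "consistent"
    ERROR = "error"
    UNDETERMINED = "undetermined"


@dataclass
class AttritionLedger:
    """Ordered per-sample variant counts after each processing step."""

    entries: list[tuple[str, str, int]] = field(default_factory=list)

    def record(self, step: str, sample: str, count: int) -> None:
        previous = [c for s, smp, c in self.entries if smp == sample]
        if previous and count > previous[-1]:
            raise ValueError(
                f"count for {sample!r} increased from {previous[-1]} to {count} at step {step!r}"
            )
        self.entries.append((step, sample, count))

    def counts_for(self, sample: str) -> list[tuple[str, int]]:
        return [(step, count) for step, smp, count in self.entries if smp == sample]

    def retained_fraction(self, sample: str) -> Optional[float]:
        counts = [count for _, count in self.counts_for(sample)]
        if not counts or counts[0] == 0:
            return None
        return counts[-1] / counts[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries, columns=["step", "sample", "count"])

    def step_medians(self) -> list[tuple[str, float]]:
        frame = self.to_frame()
        out = []
        for step in dict.fromkeys(frame["step"]):
            out.append((step, float(frame.loc[frame["step"] == step, "count"].median())))
        return out


def extract_trio(cohort: VariantCohort, trio: Trio) -> list[TrioSite]:
    """Restrict a cohort to one trio's child/mother/father genotypes."""
    for member in (trio.child, trio.mother, trio.father):
        if member not in cohort.samples:
            raise KeyError(f"trio member {member!r} absent from the genotype map")
    sites = []
    for record, genotypes in cohort.sites:
        sites.append(
            TrioSite(
                record=record,
                child=genotypes[trio.child],
                mother=genotypes[trio.mother],
                father=genotypes[trio.father],
            )
        )
    return sites


def retain_proband_variant_sites(sites: Iterable[TrioSite]) -> list[TrioSite]:
    """Keep exactly the sites where the proband carries >= 1 alternate allele.

    Parents' genotypes at those sites are retained regardless of their value.
    """
    return [s for s in sites if s.child.has_alt]


def drop_multiallelic_and_duplicates(
    sites: Iterable[TrioSite],
    multiallelic_positions: Iterable[tuple[str, int]] = (),
) -> list[TrioSite]:
    """Remove duplicated (chrom, pos) keys, known multiallelic positions and
    non-autosomal records.

    Any position occurring more than once is removed entirely — downstream
    phasing tools cannot handle duplicate or multiallelic sites.
    """
    sites = list(sites)
    position_counts = Counter(s.record.position_key for s in sites)
    bad = {key for key, n in position_counts.items() if n > 1}
    bad |= set(multiallelic_positions)
    return [
        s
        for s in sites
        if s.record.position_key not in bad and s.record.is_autosomal
    ]


def drop_missing_both_parents(sites: Iterable[TrioSite]) -> list[TrioSite]:
    """Remove sites where BOTH parents' genotypes are fully missing."""
    return [
        s for s in sites if not (s.mother.fully_missing and s.father.fully_missing)
    ]


def _allele_options(allele: Optional[int]) -> tuple[int, ...]:
    return (0, 1) if allele is None else (allele,)


def _completions(genotype: Genotype):
    yield from product(_allele_options(genotype.a), _allele_options(genotype.b))


def detect_mendelian_error(
    child: Genotype, mother: Genotype, father: Genotype
) -> MendelianStatus:
    """Classify a genotype triplet against Mendelian transmission.

    A triplet is consistent when one transmitted allele per parent can
    produce the child genotype.  Missing alleles are enumerated over both
    completions: if every completion is consistent the triplet is
    consistent, if none is it is an error, otherwise it is undetermined.
    """
    verdicts = set()
    for (ca, cb), mom, dad in product(
        _completions(child), _completions(mother), _completions(father)
    ):
        ok = any(
            sorted((gm, gf)) == sorted((ca, cb))
            for gm in set(mom)
            for gf in set(dad)
        )
        verdicts.add(ok)
        if len(verdicts) == 2:
            return MendelianStatus.UNDETERMINED
    return MendelianStatus.CONSISTENT if True in verdicts else MendelianStatus.ERROR


def drop_mendelian_errors(sites: Iterable[TrioSite]) -> list[TrioSite]:
    """Remove sites whose triplet is Mendelian-inconsistent.

    Undetermined sites (missing data compatible with both outcomes) are kept.
    """
    return [
        s
        for s in sites
        if detect_mendelian_error(s.child, s.mother, s.father) is not MendelianStatus.ERROR
    ]


def run_preprocess(
    cohort: VariantCohort,
    trio: Trio,
    ledger: Optional[AttritionLedger] = None,
) -> tuple[list[TrioSite], AttritionLedger]:
    """Apply all preprocessing steps to one trio, recording attrition.

    The ledger is keyed by the proband sample id and gains one count per
    step, including the raw input count.
    """
    if ledger is None:
        ledger = AttritionLedger()
    sites = extract_trio(cohort, trio)
    ledger.record("input", trio.child, len(sites))
    sites = retain_proband_variant_sites(sites)
    ledger.record("retain_proband_variant_sites", trio.child, len(sites))
    sites = drop_multiallelic_and_duplicates(sites, cohort.multiallelic_positions)
    ledger.record("drop_multiallelic_and_duplicates", trio.child, len(sites))
    sites = drop_missing_both_parents(sites)
    ledger.record("drop_missing_both_parents", trio.child, len(sites))
    sites = drop_mendelian_errors(sites)
    ledger.record("drop_mendelian_errors", trio.child, len(sites))
    return sites, ledger
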