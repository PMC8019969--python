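"""Core data model for trio-based compound-heterozygous variant analysis.

The pipeline represents a cohort as a list of biallelic sites, each pairing a
:class:`VariantRecord` (position, alleles, functional annotations) with one
:class:`Genotype` per sample.  Trio-level views (:class:`TrioSite`) are built
from a :class:`Pedigree` and carry the transmission-phasing state used by the
compound-heterozygous (CH) classifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Optional

AUTOSOMES = frozenset(str(c) for c in range(1, 23))

IMPACT_CLASSES = ("HIGH", "MODERATE", "LOW", "MODIFIER")


def normalize_chrom(chrom: str) -> str:
    """Strip a leading ``chr`` prefix so both chromosome dialects compare equal."""
    return chrom[3:] if chrom.lower().startswith("chr") else chrom


@dataclass(frozen=True)
class VariantRecord:
    """One normalized biallelic site with its annotation bundle.

    ``gene`` may hold several comma-separated symbols when a variant overlaps
    more than one gene; :attr:`genes` splits them.  Absent annotations are
    ``None`` — the distinction between "absent" and zero is resolved by the
    classifier, not at the I/O layer.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: Optional[str] = None
    impact: Optional[str] = None
    cadd: Optional[float] = None
    maf_gnomad: Optional[float] = None
    maf_1kg: Optional[float] = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"REF and ALT must differ at {self.chrom}:{self.pos}")
        if self.impact is not None and self.impact not in IMPACT_CLASSES:
            raise ValueError(f"unknown impact class {self.impact!r}")
        for label, value in (("maf_gnomad", self.maf_gnomad), ("maf_1kg", self.maf_1kg)):
            if value is not None and not (0.0 <= value <= 1.0):
                raise ValueError(f"{label} must lie in [0,1], got {value}")
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))

    @property
    def site_id(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def position_key(self) -> tuple[str, int]:
        return (self.chrom, self.pos)

    @property
    def genes(self) -> tuple[str, ...]:
        """Gene symbols the site is annotated with (possibly several)."""
        if not self.gene:
            return ()
        return tuple(g for g in (s.strip() for s in self.gene.split(",")) if g)

    @property
    def is_autosomal(self) -> bool:
        return self.chrom in AUTOSOMES

    def swapped(self) -> "VariantRecord":
        """The same site with REF and ALT exchanged."""
        return replace(self, ref=self.alt, alt=self.ref)


@dataclass(frozen=True)
class Genotype:
    """A diploid genotype at a biallelic site.

    Alleles are 0 (REF), 1 (ALT) or ``None`` (missing).  For phased proband
    genotypes the order convention is (maternal, paternal); for phased
    unrelated samples it is (haplotype 1, haplotype 2).  Unphased genotypes
    are order-insensitive.
    """

    a: Optional[int]
    b: Optional[int]
    phased: bool = False

    def __post_init__(self) -> None:
        for allele in (self.a, self.b):
            if allele not in (0, 1, None):
                raise ValueError(f"allele must be 0, 1 or missing, got {allele!r}")
        if self.phased and (self.a is None or self.b is None):
            raise ValueError("a phased genotype cannot carry missing alleles")

    @property
    def alleles(self) -> tuple[Optional[int], Optional[int]]:
        return (self.a, self.b)

    @property
    def has_missing(self) -> bool:
        return self.a is None or self.b is None

    @property
    def fully_missing(self) -> bool:
        return self.a is None and self.b is None

    @property
    def is_het(self) -> bool:
        return {self.a, self.b} == {0, 1}

    @property
    def is_hom_alt(self) -> bool:
        return self.a == 1 and self.b == 1

    @property
    def is_hom_ref(self) -> bool:
        return self.a == 0 and self.b == 0

    @property
    def has_alt(self) -> bool:
        return self.a == 1 or self.b == 1

    def unphased(self) -> "Genotype":
        return Genotype(self.a, self.b, phased=False)

    def complemented(self) -> "Genotype":
        """Flip 0 <-> 1 (missing stays missing); used when REF/ALT are swapped back."""
        flip = {0: 1, 1: 0, None: None}
        return Genotype(flip[self.a], flip[self.b], phased=self.phased)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Genotype):
            return NotImplemented
        if self.phased != other.phased:
            return False
        if self.phased:
            return self.alleles == other.alleles
        return sorted(self.alleles, key=_allele_sort_key) == sorted(
            other.alleles, key=_allele_sort_key
        )

    def __hash__(self) -> int:
        if self.phased:
            return hash((self.a, self.b, True))
        return hash((frozenset((self.alleles, self.alleles[::-1])), False))


def _allele_sort_key(allele: Optional[int]) -> int:
    return -1 if allele is None else allele


MISSING_GENOTYPE = Genotype(None, None, phased=False)


@dataclass(frozen=True)
class Trio:
    family_id: str
    child: str
    mother: str
    father: str
    affected: bool = True


@dataclass
class Pedigree:
    """Families parsed from a 6-column FAM file.

    ``trios`` lists complete trios (both parent ids present and distinct);
    ``non_trio_samples`` lists sample ids with at least one unknown parent.
    """

    trios: list[Trio] = field(default_factory=list)
    non_trio_samples: list[str] = field(default_factory=list)

    def trio_for_child(self, child: str) -> Trio:
        for trio in self.trios:
            if trio.child == child:
                return trio
        raise KeyError(f"no complete trio with proband {child!r}")


class PhaseStatus(str, Enum):
    PHASED = "phased"
    UNPHASED_AMBIGUOUS = "unphased_ambiguous"
    UNPHASED_MISSING = "unphased_missing"
    MENDELIAN_ERROR = "mendelian_error"


@dataclass
class TrioSite:
    """One site restricted to a single trio, annotated with its phase state.

    After transmission phasing, a phased child genotype follows the
    (maternal, paternal) order convention.
    """

    record: VariantRecord
    child: Genotype
    mother: Genotype
    father: Genotype
    phase_status: Optional[PhaseStatus] = None


@dataclass(frozen=True)
class FilterThresholds:
    """Classification thresholds for "potentially damaging" calls.

    Defaults: impact HIGH, CADD >= 15, pair-level MAF <= 5% (at least one
    allele of a CH pair must be rare), gene background prevalence < 1% in the
    control cohort, gene/variant-disease association score >= 0.5, and
    over-representation cutoffs adjusted-p <= 0.05 and q <= 0.2.  Boundary
    semantics are inclusive exactly as written.
    """

    cadd_min: float = 15.0
    maf_max: float = 0.05
    impact_required: str = "HIGH"
    background_prevalence_max: float = 0.01
    gda_min: float = 0.5
    ora_padj_max: float = 0.05
    ora_q_max: float = 0.2

    def __post_init__(self) -> None:
        if self.cadd_min < 0:
            raise ValueError("cadd_min must be non-negative")
        for label, value in (
            ("maf_max", self.maf_max),
            ("background_prevalence_max", self.background_prevalence_max),
            ("gda_min", self.gda_min),
            ("ora_padj_max", self.ora_padj_max),
            ("ora_q_max", self.ora_q_max),
        ):
            if not (0.0 <= value <= 1.0):
                raise ValueError(f"{label} must lie in [0,1], got {value}")
        if self.impact_required not in IMPACT_CLASSES:
            raise ValueError(f"unknown impact class {self.impact_required!r}")


SiteKey = tuple[str, int, str, str]


@dataclass(frozen=True)
class ChCall:
    """A compound-heterozygous call: two qualifying ALT alleles in trans.

    ``site_maternal`` carries the ALT on the maternal haplotype and
    ``site_paternal`` the ALT on the paternal haplotype (haplotype 1/2 for
    unrelated samples).  ``criteria`` audits the five classification rules:
    both alleles HIGH impact, both CADD above threshold, no parent
    homozygous-alternate at either site, no parent carrying the same pair in
    trans, and at least one allele rare.  ``parent_phase_ambiguous`` is set
    when the trans-pair check in a parent could not be evaluated because of
    missing parental alleles.
    """

    sample: str
    gene: str
    site_maternal: SiteKey
    site_paternal: SiteKey
    criteria: tuple[bool, bool, bool, bool, bool] = (True,) * 5
    parent_phase_ambiguous: bool = False

    def __post_init__(self) -> None:
        if self.site_maternal == self.site_paternal:
            raise ValueError("a CH pair needs two distinct sites")

    @property
    def site_pair(self) -> frozenset[SiteKey]:
        """Order-insensitive identity of the pair."""
        return frozenset((self.site_maternal, self.site_paternal))

    @property
    def passes_all(self) -> bool:
        return all(self.criteria)


@dataclass(frozen=True)
class HaCall:
    """A homozygous-alternate call at a single qualifying site."""

    sample: str
    gene: str
    site: SiteKey


@dataclass
class VariantCohort:
    """A set of samples genotyped at a shared list of biallelic sites.

    ``multiallelic_positions`` records (chrom, pos) keys of input lines that
    carried more than one ALT allele; the preprocessing step removes every
    record at those positions.
    """

    samples: list[str]
    sites: list[tuple[VariantRecord, dict[str, Optional[Genotype]]]]
    multiallelic_positions: set[tuple[str, int]] = field(default_factory=set)

    def __len__(self) -> int:
        return len(self.sites)


@dataclass
class PathwayCollection:
    """Named gene sets (GMT-style) plus the union universe."""

    pathways: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        for name, genes in self.pathways.items():
            if not genes:
                raise ValueError(f"pathway {name!r} has an empty gene set")

    @property
    def universe(self) -> frozenset[str]:
        out: set[str] = set()
        for genes in self.pathways.values():
            out |= genes
        return frozenset(out)

    def __len__(self) -> int:
        return len(self.pathways)


@dataclass(frozen=True)
class AssociationRow:
    """One gene- or variant-disease association score in [0, 1]."""

    entity: str
    disease: str
    score: float
    kind: str  # GDA (gene-disease) or VDA (variant-disease)

    def __post_init__(self) -> None:
        if not (0.0 <= self.score <= 1.0):
            raise ValueError(f"association score must lie in [0,1], got {self.score}")
        if self.kind not in ("GDA", "VDA"):
            raise ValueError(f"score kind must be GDA or VDA, got {self.kind!r}")


def sample_gene_pairs(calls: Iterable) -> set[tuple[str, str]]:
    """Distinct (sample, gene) pairs covered by a collection of calls.

    Accepts CH/HA call objects or plain (sample, gene) tuples; all cohort
    counting downstream is over these deduplicated pairs.
    """
    pairs: set[tuple[str, str]] = set()
    for call in calls:
        if isinstance(call, (ChCall, HaCall)):
            pairs.add((call.sample, call.gene))
        else:
            sample, gene = call[0], call[1]
            pairs.add((str(sample), str(gene)))
    return pairs
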