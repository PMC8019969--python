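"""Synthetic trio cohorts with planted compound-heterozygous events.

The generator emulates the statistical structure the survey pipeline
assumes: non-overlapping autosomal genes, per-site minor allele frequencies
drawn from a Beta spectrum, parental haplotypes drawn per site, children
formed by Mendelian transmission of one whole parental haplotype per gene
(no recombination within a gene), site-level functional annotations (impact
class, a CADD mixture straddling the damaging threshold, two population
frequencies that may disagree), genotyping error and missingness, and an
unrelated phased control cohort.

Planted events come with a truth table for recovery testing: trans CH pairs
built to be phaseable by transmission, deliberately unphaseable variants
(all three members heterozygous), cis decoys (both ALTs on one haplotype),
and homozygous-alternate events.  Planted sites are exempt from the noise
model so that the expected-detectable flag is exact.

One global seed drives independent sub-streams for gene models, trio
haplotypes, planting, controls and noise.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import asdict, dataclass, field
from typing import Optional

import numpy as np
import yaml

from .model import (
    Genotype,
    Pedigree,
    SiteKey,
    Trio,
    VariantCohort,
    VariantRecord,
)
from . import variant_io

_BASES = ("A", "C", "G", "T")
_OTHER_IMPACTS = ("MODERATE", "LOW", "MODIFIER")


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic cohort.

    Rates are probabilities per trio (planting) or per genotype call
    (noise).  The CADD mixture places mass on both sides of the damaging
    threshold of 15 so that threshold behaviour is exercised; the MAF
    spectrum Beta(0.2, 2) truncated to (0, 0.5] is strongly rare-shifted,
    as in real site-frequency spectra.
    """

    seed: int = 0
    n_trios: int = 30
    n_controls: int = 200
    n_genes: int = 80
    mean_sites_per_gene: float = 6.0
    maf_beta_a: float = 0.2
    maf_beta_b: float = 2.0
    maf_ceiling: float = 0.5
    frac_high_impact: float = 0.15
    frac_damaging_cadd: float = 0.4
    cadd_benign_mean: float = 8.0
    cadd_benign_sd: float = 3.0
    cadd_damaging_mean: float = 25.0
    cadd_damaging_sd: float = 6.0
    frac_missing_annotation: float = 0.05
    p_planted_ch: float = 0.3
    p_planted_cis: float = 0.2
    p_planted_ha: float = 0.3
    p_planted_unphaseable: float = 0.15
    genotyping_error_rate: float = 0.001
    missingness_rate: float = 0.002
    background_gene_control_fraction: float = 0.0

    def __post_init__(self) -> None:
        for label in (
            "maf_ceiling",
            "frac_high_impact",
            "frac_damaging_cadd",
            "frac_missing_annotation",
            "p_planted_ch",
            "p_planted_cis",
            "p_planted_ha",
            "p_planted_unphaseable",
            "genotyping_error_rate",
            "missingness_rate",
            "background_gene_control_fraction",
        ):
            value = getattr(self, label)
            if not (0.0 <= value <= 1.0):
                raise ValueError(f"{label} must lie in [0,1], got {value}")
        if self.n_genes < 0 or self.n_trios < 0 or self.n_controls < 0:
            raise ValueError("cohort sizes must be non-negative")

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "SimulationConfig":
        with open(path) as handle:
            data = yaml.safe_load(handle) or {}
        return cls(**data)

    def to_yaml(self, path: str | os.PathLike) -> None:
        with open(path, "w") as handle:
            yaml.safe_dump(asdict(self), handle, sort_keys=False)


@dataclass
class SiteModel:
    """Ground-truth description of one simulated site."""

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    maf: float  # generating ALT frequency
    impact: str
    cadd: Optional[float]
    maf_gnomad: Optional[float]
    maf_1kg: Optional[float]

    def to_record(self) -> VariantRecord:
        return VariantRecord(
            chrom=self.chrom,
            pos=self.pos,
            ref=self.ref,
            alt=self.alt,
            gene=self.gene,
            impact=self.impact,
            cadd=self.cadd,
            maf_gnomad=self.maf_gnomad,
            maf_1kg=self.maf_1kg,
        )

    @property
    def site_id(self) -> SiteKey:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class GeneModel:
    name: str
    chrom: str
    start: int
    end: int
    sites: list[SiteModel] = field(default_factory=list)


@dataclass(frozen=True)
class TruthRecord:
    """One planted event and whether the pipeline is expected to find it."""

    sample: str
    gene: str
    kind: str  # CH_trans, cis_decoy or HA
    sites: tuple[SiteKey, ...]
    expected_detectable: bool


@dataclass
class TrioHaplotypes:
    """True per-gene haplotypes for one trio; index order matches gene sites."""

    child_sample: str
    mother_sample: str
    father_sample: str
    # gene name -> 2 x n_sites arrays; row 0 transmitted to the child
    mother: dict[str, np.ndarray] = field(default_factory=dict)
    father: dict[str, np.ndarray] = field(default_factory=dict)

    def child_alleles(self, gene: str) -> tuple[np.ndarray, np.ndarray]:
        return self.mother[gene][0], self.father[gene][0]


@dataclass
class SimulatedCohort:
    config: SimulationConfig
    gene_models: list[GeneModel]
    trio_cohort: VariantCohort
    pedigree: Pedigree
    control_cohort: VariantCohort
    truth: list[TruthRecord]
    child_haplotypes: dict[str, dict[SiteKey, tuple[int, int]]]
    background_gene: Optional[str] = None


# --------------------------------------------------------------------------
# gene models


def simulate_gene_models(
    config: SimulationConfig, rng: Optional[np.random.Generator] = None
) -> list[GeneModel]:
    """Draw non-overlapping autosomal genes with annotated sites."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    gene_length = 50_000
    spacing = 100_000
    models: list[GeneModel] = []
    per_chrom_index: dict[str, int] = {}
    for i in range(config.n_genes):
        chrom = str(1 + i % 22)
        slot = per_chrom_index.get(chrom, 0)
        per_chrom_index[chrom] = slot + 1
        start = 1_000_000 + slot * spacing
        end = start + gene_length - 1
        n_sites = max(2, int(rng.poisson(config.mean_sites_per_gene)))
        if n_sites > gene_length:
            raise ValueError(f"site density infeasible: {n_sites} sites in {gene_length} bp")
        positions = np.sort(rng.choice(np.arange(start, end + 1), size=n_sites, replace=False))
        gene = GeneModel(name=f"GENE{i:04d}", chrom=chrom, start=start, end=end)
        for pos in positions:
            ref, alt = rng.choice(len(_BASES), size=2, replace=False)
            maf = float(
                np.clip(
                    rng.beta(config.maf_beta_a, config.maf_beta_b) * config.maf_ceiling,
                    1e-4,
                    config.maf_ceiling,
                )
            )
            impact = (
                "HIGH"
                if rng.random() < config.frac_high_impact
                else str(rng.choice(_OTHER_IMPACTS))
            )
            if rng.random() < config.frac_damaging_cadd:
                cadd = rng.normal(config.cadd_damaging_mean, config.cadd_damaging_sd)
            else:
                cadd = rng.normal(config.cadd_benign_mean, config.cadd_benign_sd)
            cadd = round(float(max(cadd, 0.0)), 3)
            maf_gnomad: Optional[float] = round(maf, 6)
            # the second frequency source may disagree with the first
            maf_1kg: Optional[float] = round(
                float(np.clip(maf * rng.uniform(0.5, 1.5), 1e-6, config.maf_ceiling)), 6
            )
            cadd_out: Optional[float] = cadd
            if rng.random() < config.frac_missing_annotation:
                maf_gnomad = None
            if rng.random() < config.frac_missing_annotation:
                maf_1kg = None
            if rng.random() < config.frac_missing_annotation:
                cadd_out = None
            gene.sites.append(
                SiteModel(
                    chrom=chrom,
                    pos=int(pos),
                    ref=_BASES[ref],
                    alt=_BASES[alt],
                    gene=gene.name,
                    maf=maf,
                    impact=impact,
                    cadd=cadd_out,
                    maf_gnomad=maf_gnomad,
                    maf_1kg=maf_1kg,
                )
            )
        models.append(gene)
    return models


# --------------------------------------------------------------------------
# trios


def simulate_trio(
    config: SimulationConfig,
    gene_models: list[GeneModel],
    index: int,
    rng: np.random.Generator,
) -> TrioHaplotypes:
    """Draw parental haplotypes and transmit one per parent per gene.

    Haplotype row 0 of each parent is the transmitted one, so the child's
    maternal/paternal alleles are ``mother[gene][0]`` / ``father[gene][0]``.
    """
    trio = TrioHaplotypes(
        child_sample=f"trio{index:03d}_child",
        mother_sample=f"trio{index:03d}_mother",
        father_sample=f"trio{index:03d}_father",
    )
    for gene in gene_models:
        mafs = np.array([s.maf for s in gene.sites])
        mother = (rng.random((2, len(gene.sites))) < mafs).astype(np.int8)
        father = (rng.random((2, len(gene.sites))) < mafs).astype(np.int8)
        # put the transmitted haplotype in row 0
        if rng.random() < 0.5:
            mother = mother[::-1]
        if rng.random() < 0.5:
            father = father[::-1]
        trio.mother[gene.name] = mother
        trio.father[gene.name] = father
    return trio


# --------------------------------------------------------------------------
# planting


def _make_rare(site: SiteModel, rng: np.random.Generator) -> None:
    value = round(float(rng.uniform(0.0005, 0.03)), 6)
    site.maf_gnomad = value
    site.maf_1kg = value


def _make_common(site: SiteModel, rng: np.random.Generator) -> None:
    value = round(float(rng.uniform(0.06, 0.2)), 6)
    site.maf_gnomad = value
    site.maf_1kg = value


def _make_qualifying(site: SiteModel, rng: np.random.Generator) -> None:
    site.impact = "HIGH"
    site.cadd = round(float(rng.uniform(18.0, 30.0)), 3)


def plant_events(
    config: SimulationConfig,
    gene_models: list[GeneModel],
    trios: list[TrioHaplotypes],
    rng: np.random.Generator,
) -> tuple[list[TruthRecord], set[tuple[str, SiteKey]], Optional[str]]:
    """Plant CH, cis-decoy and HA events; returns truth, protected sites and
    the designated control-background gene (if any).

    Each planted event claims a gene not used by any other event so that
    truth records stay independent.  Protected (sample, site) pairs are
    exempted from the noise model.
    """
    truth: list[TruthRecord] = []
    protected: set[tuple[str, SiteKey]] = set()
    pool = [g for g in gene_models if len(g.sites) >= 2]
    rng.shuffle(pool)
    pool = list(pool)

    def claim_gene() -> Optional[GeneModel]:
        if not pool:
            warnings.warn("gene pool exhausted; skipping a planted event")
            return None
        return pool.pop()

    def protect(trio: TrioHaplotypes, sites: list[SiteModel]) -> None:
        for member in (trio.child_sample, trio.mother_sample, trio.father_sample):
            for site in sites:
                protected.add((member, site.site_id))

    def plant_trans_pair(
        trio: TrioHaplotypes, gene: GeneModel, a: int, b: int
    ) -> None:
        """Force a phaseable trans pair: each parent het at one site only."""
        mother = trio.mother[gene.name]
        father = trio.father[gene.name]
        mother[0, a], mother[1, a] = 1, 0
        mother[0, b], mother[1, b] = 0, 0
        father[0, a], father[1, a] = 0, 0
        father[0, b], father[1, b] = 1, 0

    background_gene: Optional[str] = None
    if config.background_gene_control_fraction > 0 and pool:
        bg_model = pool.pop()
        background_gene = bg_model.name
        # the background gene carries a qualifying rare pair that is common
        # in controls; one trio gets a genuine CH event there so that the
        # background filter has something to remove from the disease cohort
        for site in (bg_model.sites[0], bg_model.sites[1]):
            _make_qualifying(site, rng)
            _make_rare(site, rng)
        if trios:
            bg_trio = trios[0]
            plant_trans_pair(bg_trio, bg_model, 0, 1)
            protect(bg_trio, [bg_model.sites[0], bg_model.sites[1]])
            truth.append(
                TruthRecord(
                    sample=bg_trio.child_sample,
                    gene=background_gene,
                    kind="CH_trans",
                    sites=(bg_model.sites[0].site_id, bg_model.sites[1].site_id),
                    expected_detectable=True,
                )
            )

    for trio in trios:
        if rng.random() < config.p_planted_ch:
            gene = claim_gene()
            if gene is not None:
                a, b = rng.choice(len(gene.sites), size=2, replace=False)
                site_a, site_b = gene.sites[int(a)], gene.sites[int(b)]
                _make_qualifying(site_a, rng)
                _make_qualifying(site_b, rng)
                _make_rare(site_a, rng)
                # one allele of the pair may be common: the pair-level
                # frequency rule only needs one rare allele
                if rng.random() < 0.3:
                    _make_common(site_b, rng)
                else:
                    _make_rare(site_b, rng)
                mother = trio.mother[gene.name]
                father = trio.father[gene.name]
                unphaseable = rng.random() < config.p_planted_unphaseable
                if unphaseable:
                    # all three members heterozygous at both sites: the
                    # orientation cannot be recovered by transmission
                    mother[0, a], mother[1, a] = 1, 0
                    mother[0, b], mother[1, b] = 0, 1
                    father[0, a], father[1, a] = 0, 1
                    father[0, b], father[1, b] = 1, 0
                else:
                    plant_trans_pair(trio, gene, int(a), int(b))
                protect(trio, [site_a, site_b])
                truth.append(
                    TruthRecord(
                        sample=trio.child_sample,
                        gene=gene.name,
                        kind="CH_trans",
                        sites=(site_a.site_id, site_b.site_id),
                        expected_detectable=not unphaseable,
                    )
                )
        if rng.random() < config.p_planted_cis:
            gene = claim_gene()
            if gene is not None:
                a, b = rng.choice(len(gene.sites), size=2, replace=False)
                site_a, site_b = gene.sites[int(a)], gene.sites[int(b)]
                for site in (site_a, site_b):
                    _make_qualifying(site, rng)
                    _make_rare(site, rng)
                mother = trio.mother[gene.name]
                father = trio.father[gene.name]
                # both ALTs ride the transmitted maternal haplotype (cis)
                mother[0, a], mother[1, a] = 1, 0
                mother[0, b], mother[1, b] = 1, 0
                father[:, a] = 0
                father[:, b] = 0
                protect(trio, [site_a, site_b])
                truth.append(
                    TruthRecord(
                        sample=trio.child_sample,
                        gene=gene.name,
                        kind="cis_decoy",
                        sites=(site_a.site_id, site_b.site_id),
                        expected_detectable=False,
                    )
                )
        if rng.random() < config.p_planted_ha:
            gene = claim_gene()
            if gene is not None:
                a = int(rng.integers(len(gene.sites)))
                site_a = gene.sites[a]
                _make_qualifying(site_a, rng)
                _make_rare(site_a, rng)
                mother = trio.mother[gene.name]
                father = trio.father[gene.name]
                # both parents transmit the ALT but stay heterozygous
                mother[0, a], mother[1, a] = 1, 0
                father[0, a], father[1, a] = 1, 0
                protect(trio, [site_a])
                truth.append(
                    TruthRecord(
                        sample=trio.child_sample,
                        gene=gene.name,
                        kind="HA",
                        sites=(site_a.site_id,),
                        expected_detectable=True,
                    )
                )
    return truth, protected, background_gene


# --------------------------------------------------------------------------
# assembly


def _apply_noise(
    genotype: Genotype,
    sample: str,
    site_id: SiteKey,
    protected: set[tuple[str, SiteKey]],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> Genotype:
    if (sample, site_id) in protected:
        return genotype
    if rng.random() < config.missingness_rate:
        return Genotype(None, None)
    if rng.random() < config.genotyping_error_rate:
        flip = {0: 1, 1: 0}
        if rng.random() < 0.5:
            return Genotype(flip[genotype.a], genotype.b)
        return Genotype(genotype.a, flip[genotype.b])
    return genotype


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Generate the full study: trio cohort, pedigree, controls and truth."""
    streams = np.random.default_rng(config.seed).spawn(5)
    gene_rng, trio_rng, plant_rng, control_rng, noise_rng = streams
    gene_models = simulate_gene_models(config, gene_rng)
    trios = [
        simulate_trio(config, gene_models, i, trio_rng) for i in range(config.n_trios)
    ]
    truth, protected, background_gene = plant_events(
        config, gene_models, trios, plant_rng
    )

    all_sites = [site for gene in gene_models for site in gene.sites]
    all_sites.sort(key=lambda s: (int(s.chrom), s.pos))

    site_index: dict[str, dict[SiteKey, int]] = {}
    for gene in gene_models:
        site_index[gene.name] = {s.site_id: i for i, s in enumerate(gene.sites)}

    # trio cohort (children written unphased: phasing is the pipeline's job)
    trio_samples: list[str] = []
    pedigree = Pedigree()
    for i, trio in enumerate(trios):
        trio_samples += [trio.child_sample, trio.mother_sample, trio.father_sample]
        pedigree.trios.append(
            Trio(
                family_id=f"F{i:03d}",
                child=trio.child_sample,
                mother=trio.mother_sample,
                father=trio.father_sample,
            )
        )

    child_haplotypes: dict[str, dict[SiteKey, tuple[int, int]]] = {
        t.child_sample: {} for t in trios
    }
    genotype_rows: list[dict[str, Genotype]] = []
    for site in all_sites:
        row: dict[str, Genotype] = {}
        for trio in trios:
            gene = site.gene
            idx = site_index[gene][site.site_id]
            mother = trio.mother[gene]
            father = trio.father[gene]
            mat, pat = int(mother[0, idx]), int(father[0, idx])
            child_haplotypes[trio.child_sample][site.site_id] = (mat, pat)
            members = {
                trio.child_sample: Genotype(mat, pat),
                trio.mother_sample: Genotype(int(mother[0, idx]), int(mother[1, idx])),
                trio.father_sample: Genotype(int(father[0, idx]), int(father[1, idx])),
            }
            for sample, genotype in members.items():
                row[sample] = _apply_noise(
                    genotype, sample, site.site_id, protected, config, noise_rng
                )
        genotype_rows.append(row)

    trio_cohort = VariantCohort(
        samples=trio_samples,
        sites=[
            (site.to_record(), genotype_rows[i]) for i, site in enumerate(all_sites)
        ],
    )

    # unrelated phased controls
    control_samples = [f"control{i:04d}" for i in range(config.n_controls)]
    control_haps: dict[str, dict[str, np.ndarray]] = {s: {} for s in control_samples}
    for gene in gene_models:
        mafs = np.array([s.maf for s in gene.sites])
        for sample in control_samples:
            control_haps[sample][gene.name] = (
                control_rng.random((2, len(gene.sites))) < mafs
            ).astype(np.int8)
    if background_gene is not None:
        a, b = 0, 1
        n_planted = int(round(config.background_gene_control_fraction * config.n_controls))
        for sample in control_samples[:n_planted]:
            haps = control_haps[sample][background_gene]
            haps[0, a], haps[1, a] = 1, 0
            haps[0, b], haps[1, b] = 0, 1
    control_sites = []
    for site in all_sites:
        idx = site_index[site.gene][site.site_id]
        row = {
            sample: Genotype(
                int(control_haps[sample][site.gene][0, idx]),
                int(control_haps[sample][site.gene][1, idx]),
                phased=True,
            )
            for sample in control_samples
        }
        control_sites.append((site.to_record(), row))
    control_cohort = VariantCohort(samples=control_samples, sites=control_sites)

    return SimulatedCohort(
        config=config,
        gene_models=gene_models,
        trio_cohort=trio_cohort,
        pedigree=pedigree,
        control_cohort=control_cohort,
        truth=truth,
        child_haplotypes=child_haplotypes,
        background_gene=background_gene,
    )


# --------------------------------------------------------------------------
# output


def write_cohort(cohort: SimulatedCohort, out_dir: str | os.PathLike) -> dict[str, str]:
    """Write VCF/FAM/truth/config files; returns the path of each artifact."""
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "trios_vcf": os.path.join(out_dir, "trios.vcf"),
        "trios_fam": os.path.join(out_dir, "trios.fam"),
        "controls_vcf": os.path.join(out_dir, "controls.vcf"),
        "truth_tsv": os.path.join(out_dir, "truth.tsv"),
        "haplotypes_tsv": os.path.join(out_dir, "child_haplotypes.tsv"),
        "config_yaml": os.path.join(out_dir, "config.yaml"),
    }
    variant_io.write_vcf(paths["trios_vcf"], cohort.trio_cohort)
    variant_io.write_fam(paths["trios_fam"], cohort.pedigree)
    variant_io.write_vcf(paths["controls_vcf"], cohort.control_cohort)
    with open(paths["truth_tsv"], "w") as handle:
        handle.write("sample\tgene\tkind\texpected_detectable\tsites\n")
        for record in cohort.truth:
            sites = ";".join("{}:{}:{}:{}".format(*s) for s in record.sites)
            handle.write(
                f"{record.sample}\t{record.gene}\t{record.kind}\t"
                f"{int(record.expected_detectable)}\t{sites}\n"
            )
    with open(paths["haplotypes_tsv"], "w") as handle:
        handle.write("sample\tchrom\tpos\tref\talt\tmaternal\tpaternal\n")
        for sample in sorted(cohort.child_haplotypes):
            for (chrom, pos, ref, alt), (mat, pat) in sorted(
                cohort.child_haplotypes[sample].items(), key=lambda kv: (int(kv[0][0]), kv[0][1])
            ):
                handle.write(f"{sample}\t{chrom}\t{pos}\t{ref}\t{alt}\t{mat}\t{pat}\n")
    cohort.config.to_yaml(paths["config_yaml"])
    return paths
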