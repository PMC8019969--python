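"""The compound-heterozygous (CH) and homozygous-alternate (HA) classifier.

A CH call is a pair of alternate alleles at different sites of the same gene
carried on opposite child haplotypes (in trans), where

1. both alleles are annotated with HIGH impact severity,
2. both alleles have a scaled CADD score at or above the threshold (15),
3. neither parent is homozygous-alternate at either site,
4. neither parent carries the same two alternate alleles in trans, and
5. at least one allele of the pair has a minor allele frequency at or below
   the cutoff (5%; gnomAD takes priority over 1000 Genomes).

Criteria 3-4 require parents and are skipped for unrelated control samples.
An HA call is a single child 1/1 site passing impact, CADD and MAF cutoffs
where neither parent is also homozygous-alternate.

Absent MAF annotations are treated as frequency 0 (absence from population
databases implies rarity); an absent CADD score fails criterion 2 (positive
deleteriousness evidence is required).  All threshold comparisons are
inclusive.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Iterable, Optional, Sequence

from .model import (
    ChCall,
    FilterThresholds,
    Genotype,
    HaCall,
    TrioSite,
    PhaseStatus,
    VariantRecord,
)

DEFAULT_THRESHOLDS = FilterThresholds()


def effective_maf(record: VariantRecord) -> float:
    """Population frequency used for filtering: gnomAD, else 1000GP, else 0."""
    if record.maf_gnomad is not None:
        return record.maf_gnomad
    if record.maf_1kg is not None:
        return record.maf_1kg
    return 0.0


def allele_qualifies(
    record: VariantRecord, thresholds: FilterThresholds = DEFAULT_THRESHOLDS
) -> bool:
    """Criteria 1-2: required impact class and CADD at or above the cutoff.

    The per-allele MAF is deliberately NOT checked here — for CH pairs the
    frequency rule is pair-level (criterion 5).
    """
    return (
        record.impact == thresholds.impact_required
        and record.cadd is not None
        and record.cadd >= thresholds.cadd_min
    )


def pair_maf_rule(
    record_a: VariantRecord,
    record_b: VariantRecord,
    thresholds: FilterThresholds = DEFAULT_THRESHOLDS,
) -> bool:
    """Criterion 5: at least one allele of the pair is rare.

    One common allele is tolerated: a damaging common allele that is
    harmless when heterozygous may matter when paired in trans with a rare
    damaging allele.
    """
    return min(effective_maf(record_a), effective_maf(record_b)) <= thresholds.maf_max


def enumerate_trans_pairs(
    sites: Sequence[TrioSite],
) -> list[tuple[TrioSite, TrioSite]]:
    """All (maternal-ALT site, paternal-ALT site) pairs among phased child hets.

    Only sites with a phased heterozygous child genotype can be oriented;
    two ALTs on the same haplotype (cis) never form a pair.
    """
    maternal_alt = []
    paternal_alt = []
    for site in sites:
        if site.phase_status is not PhaseStatus.PHASED or not site.child.is_het:
            continue
        if site.child.a == 1:
            maternal_alt.append(site)
        else:
            paternal_alt.append(site)
    return [
        (m, p)
        for m in maternal_alt
        for p in paternal_alt
        if m.record.site_id != p.record.site_id
    ]


def _transmitted_untransmitted(
    parent: Genotype, transmitted_allele: int
) -> tuple[int, Optional[int]]:
    """Split a parent genotype into (transmitted, untransmitted) alleles.

    Returns ``None`` for the untransmitted allele when missing parental data
    make it undeterminable.
    """
    alleles = list(parent.alleles)
    if transmitted_allele in alleles:
        alleles.remove(transmitted_allele)
        return transmitted_allele, alleles[0]
    # the transmitted allele is not visible in the parent genotype: some
    # allele must be missing (a fully observed, Mendelian-consistent parent
    # always carries it)
    return transmitted_allele, None


def parent_exclusions(
    site_maternal: TrioSite, site_paternal: TrioSite
) -> tuple[bool, bool]:
    """Criteria 3-4 for one candidate pair; returns (excluded, ambiguous).

    Excluded when any parent is homozygous-alternate at either site
    (criterion 3) or carries the two ALT alleles in trans on its own
    haplotypes (criterion 4).  Parental haplotypes are reconstructed from
    transmission: the transmitted haplotype carries the alleles the child
    inherited at both sites, assuming no recombination within the gene.
    ``ambiguous`` flags pairs where missing parental alleles prevented the
    trans check; such pairs are NOT excluded.
    """
    ambiguous = False
    for which in ("mother", "father"):
        gt_m: Genotype = getattr(site_maternal, which)
        gt_p: Genotype = getattr(site_paternal, which)
        if gt_m.is_hom_alt or gt_p.is_hom_alt:
            return True, ambiguous
        # transmitted child alleles: the maternal-ALT site contributes the
        # maternal allele from the mother (1) and paternal allele from the
        # father (0); the paternal-ALT site vice versa.
        if which == "mother":
            trans_m, trans_p = site_maternal.child.a, site_paternal.child.a
        else:
            trans_m, trans_p = site_maternal.child.b, site_paternal.child.b
        t_m, u_m = _transmitted_untransmitted(gt_m, trans_m)
        t_p, u_p = _transmitted_untransmitted(gt_p, trans_p)
        if u_m is None or u_p is None:
            ambiguous = True
            continue
        if (t_m == 1 and u_p == 1) or (u_m == 1 and t_p == 1):
            return True, ambiguous
    return False, ambiguous


def _sites_by_gene(sites: Iterable[TrioSite]) -> dict[str, list[TrioSite]]:
    by_gene: dict[str, list[TrioSite]] = defaultdict(list)
    for site in sites:
        for gene in site.record.genes:
            by_gene[gene].append(site)
    return by_gene


def identify_ch(
    sites: Iterable[TrioSite],
    sample: str,
    thresholds: FilterThresholds = DEFAULT_THRESHOLDS,
    check_parents: bool = True,
) -> list[ChCall]:
    """All five-criteria CH calls for one phased proband.

    A site annotated with several gene symbols participates independently in
    each gene.  Calls are reported per (sample, gene, site pair), already
    deduplicated; downstream counting reduces them to distinct (sample,
    gene) pairs.
    """
    calls: list[ChCall] = []
    seen: set[tuple[str, frozenset]] = set()
    for gene, gene_sites in sorted(_sites_by_gene(sites).items()):
        qualifying = [s for s in gene_sites if allele_qualifies(s.record, thresholds)]
        for site_m, site_p in enumerate_trans_pairs(qualifying):
            if not pair_maf_rule(site_m.record, site_p.record, thresholds):
                continue
            ambiguous = False
            if check_parents:
                excluded, ambiguous = parent_exclusions(site_m, site_p)
                if excluded:
                    continue
            key = (gene, frozenset((site_m.record.site_id, site_p.record.site_id)))
            if key in seen:
                continue
            seen.add(key)
            calls.append(
                ChCall(
                    sample=sample,
                    gene=gene,
                    site_maternal=site_m.record.site_id,
                    site_paternal=site_p.record.site_id,
                    criteria=(True, True, True, True, True),
                    parent_phase_ambiguous=ambiguous,
                )
            )
    return calls


def identify_ha(
    sites: Iterable[TrioSite],
    sample: str,
    thresholds: FilterThresholds = DEFAULT_THRESHOLDS,
    check_parents: bool = True,
) -> list[HaCall]:
    """Homozygous-alternate calls for one proband; phase is not required.

    A site qualifies when the child is 1/1, the allele passes impact, CADD
    and MAF cutoffs, and (for trios) neither parent is also 1/1.
    """
    calls: list[HaCall] = []
    for site in sites:
        if not site.child.is_hom_alt:
            continue
        record = site.record
        if not allele_qualifies(record, thresholds):
            continue
        if effective_maf(record) > thresholds.maf_max:
            continue
        if check_parents and (site.mother.is_hom_alt or site.father.is_hom_alt):
            continue
        for gene in record.genes:
            calls.append(HaCall(sample=sample, gene=gene, site=record.site_id))
    return calls


def _unrelated_trio_view(
    sites: Iterable[tuple[VariantRecord, Genotype]],
) -> list[TrioSite]:
    """Wrap phased unrelated-sample genotypes as parentless trio sites."""
    missing = Genotype(None, None)
    view = []
    for record, genotype in sites:
        status = PhaseStatus.PHASED if genotype.phased else PhaseStatus.UNPHASED_MISSING
        view.append(
            TrioSite(
                record=record,
                child=genotype,
                mother=missing,
                father=missing,
                phase_status=status,
            )
        )
    return view


def identify_ch_unrelated(
    sites: Iterable[tuple[VariantRecord, Genotype]],
    sample: str,
    thresholds: FilterThresholds = DEFAULT_THRESHOLDS,
) -> list[ChCall]:
    """CH classification for a phased unrelated sample (control cohorts).

    Identical to :func:`identify_ch` with the parental exclusions skipped —
    without parents only impact, CADD and frequency criteria apply.  The
    call's haplotype fields follow the sample's haplotype-1/2 order.
    """
    return identify_ch(
        _unrelated_trio_view(sites), sample, thresholds, check_parents=False
    )


def identify_ha_unrelated(
    sites: Iterable[tuple[VariantRecord, Genotype]],
    sample: str,
    thresholds: FilterThresholds = DEFAULT_THRESHOLDS,
) -> list[HaCall]:
    """HA classification for an unrelated sample (no parental exclusion)."""
    return identify_ha(
        _unrelated_trio_view(sites), sample, thresholds, check_parents=False
    )
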