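"""Deterministic phasing of trio genotypes by Mendelian transmission.

A child genotype is phased when the parental genotypes force the parental
origin of both alleles.  Homozygous children phase trivially; a heterozygous
child phases exactly when only one orientation (maternal ALT vs paternal
ALT) is transmissible.  When both parents and the child are heterozygous the
orientation is ambiguous and the site stays unphased — such sites are
invisible to compound-heterozygous detection, a deliberately conservative
behaviour compared with statistical reference-panel phasing.

Phased proband genotypes follow the (maternal, paternal) order convention.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Iterable, Mapping, Optional

import pandas as pd

from .model import Genotype, PhaseStatus, TrioSite, VariantRecord
from .preprocess import MendelianStatus, _allele_options, detect_mendelian_error


def phase_by_transmission(site: TrioSite) -> TrioSite:
    """Phase one trio site; returns a copy with ``phase_status`` set.

    Outcomes: ``phased`` (child genotype rewritten in maternal/paternal
    order), ``unphased_ambiguous`` (complete data, both orientations
    transmissible), ``unphased_missing`` (missing data leave the orientation
    unforced), ``mendelian_error`` (no transmission can produce the child).
    """
    child, mother, father = site.child, site.mother, site.father
    if detect_mendelian_error(child, mother, father) is MendelianStatus.ERROR:
        return replace(site, phase_status=PhaseStatus.MENDELIAN_ERROR)
    if child.has_missing:
        return replace(site, phase_status=PhaseStatus.UNPHASED_MISSING)
    if not child.is_het:
        phased_child = Genotype(child.a, child.a, phased=True)
        return replace(site, child=phased_child, phase_status=PhaseStatus.PHASED)
    # heterozygous child: enumerate transmissible (maternal, paternal) orientations
    maternal_gametes = set(_allele_options(mother.a)) | set(_allele_options(mother.b))
    paternal_gametes = set(_allele_options(father.a)) | set(_allele_options(father.b))
    orientations = {
        (gm, gf)
        for gm in maternal_gametes
        for gf in paternal_gametes
        if {gm, gf} == {0, 1}
    }
    if len(orientations) == 1:
        maternal, paternal = orientations.pop()
        phased_child = Genotype(maternal, paternal, phased=True)
        return replace(site, child=phased_child, phase_status=PhaseStatus.PHASED)
    if mother.has_missing or father.has_missing:
        return replace(site, phase_status=PhaseStatus.UNPHASED_MISSING)
    return replace(site, phase_status=PhaseStatus.UNPHASED_AMBIGUOUS)


def phase_trio(sites: Iterable[TrioSite]) -> list[TrioSite]:
    """Phase every site of one trio."""
    return [phase_by_transmission(s) for s in sites]


class OrientationError(KeyError):
    """A site is absent from, or incompatible with, the orientation table."""


def restore_ref_alt_orientation(
    record: VariantRecord,
    genotypes: Mapping[str, Optional[Genotype]],
    reference_alleles: Mapping[tuple[str, int], tuple[str, str]],
) -> tuple[VariantRecord, dict[str, Optional[Genotype]]]:
    """Undo a REF/ALT swap introduced by an upstream phasing tool.

    ``reference_alleles`` maps (chrom, pos) to the (REF, ALT) orientation of
    the reference genome.  A swapped record is reverted and every genotype
    code complemented (0 <-> 1); an already-congruent record is returned
    unchanged.  The operation is idempotent.
    """
    key = record.position_key
    if key not in reference_alleles:
        raise OrientationError(f"site {key} absent from the orientation table")
    ref, alt = reference_alleles[key]
    if (record.ref, record.alt) == (ref, alt):
        return record, dict(genotypes)
    if (record.ref, record.alt) == (alt, ref):
        flipped = {
            sample: (gt.complemented() if gt is not None else None)
            for sample, gt in genotypes.items()
        }
        return record.swapped(), flipped
    raise OrientationError(
        f"alleles {record.ref}/{record.alt} at {key} are incongruent with the "
        f"reference orientation {ref}/{alt}"
    )


def phasing_stats(sites: Iterable[TrioSite]) -> dict[str, float]:
    """Fractions of sites per phase status; the four fractions sum to 1."""
    sites = list(sites)
    n = len(sites)
    counts = {status: 0 for status in PhaseStatus}
    for site in sites:
        if site.phase_status is None:
            raise ValueError("site has not been phased yet")
        counts[site.phase_status] += 1
    out = {"n_sites": float(n)}
    for status in PhaseStatus:
        out[f"fraction_{status.value}"] = counts[status] / n if n else 0.0
    return out


def cohort_phasing_stats(sites_by_sample: Mapping[str, Iterable[TrioSite]]) -> pd.DataFrame:
    """Per-sample phased/unphased fractions plus a cohort-mean row."""
    rows = []
    for sample, sites in sites_by_sample.items():
        stats = phasing_stats(sites)
        stats["sample"] = sample
        rows.append(stats)
    frame = pd.DataFrame(rows)
    if not frame.empty:
        mean_row = frame.drop(columns="sample").mean().to_dict()
        mean_row["sample"] = "__cohort_mean__"
        frame = pd.concat([frame, pd.DataFrame([mean_row])], ignore_index=True)
    return frame
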