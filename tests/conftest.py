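"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately re-derive expected behaviour from first
principles (exhaustive gamete enumeration, brute-force pair enumeration,
combinatorial tail counting) so that they stay independent of the package
code paths they check.
"""

from __future__ import annotations

from itertools import combinations, product

import numpy as np
import pytest

from chtrio.engine import effective_maf
from chtrio.model import Genotype, PhaseStatus, TrioSite, VariantRecord


# ---------------------------------------------------------------------------
# oracle: Mendelian consistency by exhaustive gamete enumeration


def oracle_mendelian(child: Genotype, mother: Genotype, father: Genotype) -> str:
    """'consistent' / 'error' / 'undetermined' over all missing completions."""

    def completions(g: Genotype):
        opts = lambda a: (0, 1) if a is None else (a,)
        return [(x, y) for x in opts(g.a) for y in opts(g.b)]

    verdicts = set()
    for (ca, cb), mom, dad in product(
        completions(child), completions(mother), completions(father)
    ):
        ok = False
        for gm in mom:
            for gf in dad:
                if sorted((gm, gf)) == sorted((ca, cb)):
                    ok = True
        verdicts.add(ok)
    if verdicts == {True}:
        return "consistent"
    if verdicts == {False}:
        return "error"
    return "undetermined"


def oracle_phase_orientation(child: Genotype, mother: Genotype, father: Genotype):
    """All (maternal, paternal) assignments consistent with transmission.

    Returns the set of orientations for a complete heterozygous child; phase
    is determined iff the set is a singleton.
    """
    orientations = set()
    for gm in set(mother.alleles):
        for gf in set(father.alleles):
            if sorted((gm, gf)) == sorted(child.alleles):
                orientations.add((gm, gf))
    return orientations


ALL_COMPLETE_GENOTYPES = [Genotype(0, 0), Genotype(0, 1), Genotype(1, 1)]


# ---------------------------------------------------------------------------
# oracle: brute-force CH classification within one gene


def oracle_ch_pairs(sites: list[TrioSite], thresholds) -> set[frozenset]:
    """Site-id pairs satisfying all five criteria, by naive enumeration."""
    calls = set()
    usable = [
        s
        for s in sites
        if s.phase_status is PhaseStatus.PHASED and s.child.is_het
    ]
    for s1, s2 in combinations(usable, 2):
        # criterion 1-2 per allele
        ok = True
        for s in (s1, s2):
            if s.record.impact != thresholds.impact_required:
                ok = False
            if s.record.cadd is None or s.record.cadd < thresholds.cadd_min:
                ok = False
        # in trans: maternal ALT at one site, paternal at the other
        trans = (s1.child.a == 1 and s2.child.b == 1) or (
            s1.child.b == 1 and s2.child.a == 1
        )
        if not trans:
            ok = False
        # criterion 3: neither parent HA at either site
        for s in (s1, s2):
            if s.mother.is_hom_alt or s.father.is_hom_alt:
                ok = False
        # criterion 4: parent carries the same pair in trans (transmitted
        # haplotype = alleles the child inherited, untransmitted = the rest)
        for which in ("mother", "father"):
            child_idx = 0 if which == "mother" else 1
            t1 = s1.child.alleles[child_idx]
            t2 = s2.child.alleles[child_idx]
            u = []
            for s, t in ((s1, t1), (s2, t2)):
                alleles = list(getattr(s, which).alleles)
                if t in alleles:
                    alleles.remove(t)
                    u.append(alleles[0])
                else:
                    u.append(None)
            if None in u:
                continue
            if (t1 == 1 and u[1] == 1) or (u[0] == 1 and t2 == 1):
                ok = False
        # criterion 5: at least one rare allele
        if min(effective_maf(s1.record), effective_maf(s2.record)) > thresholds.maf_max:
            ok = False
        if ok:
            calls.add(frozenset((s1.record.site_id, s2.record.site_id)))
    return calls


# ---------------------------------------------------------------------------
# random trio-gene fixtures


def random_gene_sites(
    rng: np.random.Generator, n_sites: int, gene: str = "G1"
) -> list[TrioSite]:
    """Random annotated trio sites in one gene, phased by transmission.

    Parental genotypes are drawn first, children by random transmission, so
    every site is Mendelian-consistent; phasing is then done by the package.
    """
    from chtrio.phasing import phase_by_transmission

    sites = []
    for i in range(n_sites):
        maf = float(rng.uniform(0.0, 0.4))
        mother_h = (rng.random(2) < 0.5).astype(int)
        father_h = (rng.random(2) < 0.5).astype(int)
        child = Genotype(int(mother_h[0]), int(father_h[0]))
        record = VariantRecord(
            chrom="1",
            pos=1000 + i,
            ref="A",
            alt="C",
            gene=gene,
            impact="HIGH" if rng.random() < 0.6 else "MODERATE",
            cadd=None if rng.random() < 0.1 else float(rng.uniform(5, 30)),
            maf_gnomad=None if rng.random() < 0.2 else round(maf, 4),
            maf_1kg=None if rng.random() < 0.2 else round(maf * 1.2, 4),
        )
        site = TrioSite(
            record=record,
            child=child,
            mother=Genotype(int(mother_h[0]), int(mother_h[1])),
            father=Genotype(int(father_h[0]), int(father_h[1])),
        )
        sites.append(phase_by_transmission(site))
    return sites


@pytest.fixture(scope="session")
def small_cohort():
    """One small simulated cohort shared across read-only tests."""
    from chtrio.simulate import SimulationConfig, simulate_cohort

    config = SimulationConfig(
        seed=7,
        n_trios=12,
        n_controls=60,
        n_genes=40,
        background_gene_control_fraction=0.05,
    )
    return simulate_cohort(config)
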