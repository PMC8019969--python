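"""The five-criterion CH classifier and its HA counterpart."""

from __future__ import annotations

import numpy as np
import pytest

from conftest import oracle_ch_pairs, random_gene_sites
from chtrio.engine import (
    allele_qualifies,
    effective_maf,
    enumerate_trans_pairs,
    identify_ch,
    identify_ch_unrelated,
    identify_ha,
    pair_maf_rule,
    parent_exclusions,
)
from chtrio.model import (
    FilterThresholds,
    Genotype,
    PhaseStatus,
    TrioSite,
    VariantRecord,
)

THRESHOLDS = FilterThresholds()


def qualifying_record(pos, gene="G1", impact="HIGH", cadd=25.0, maf=0.01, maf_1kg=None):
    return VariantRecord(
        "1", pos, "A", "C", gene=gene, impact=impact, cadd=cadd,
        maf_gnomad=maf, maf_1kg=maf_1kg,
    )


def phased_site(record, child, mother=(0, 1), father=(0, 1), status=PhaseStatus.PHASED):
    return TrioSite(
        record=record,
        child=Genotype(child[0], child[1], phased=status is PhaseStatus.PHASED),
        mother=Genotype(*mother),
        father=Genotype(*father),
        phase_status=status,
    )


class TestEffectiveMaf:
    def test_gnomad_priority(self):
        record = qualifying_record(100, maf=0.02, maf_1kg=0.10)
        assert effective_maf(record) == 0.02

    def test_fallback_to_1kg(self):
        record = qualifying_record(100, maf=None, maf_1kg=0.03)
        assert effective_maf(record) == 0.03

    def test_both_absent_is_zero(self):
        record = qualifying_record(100, maf=None, maf_1kg=None)
        assert effective_maf(record) == 0.0


class TestAlleleQualifies:
    @pytest.mark.parametrize(
        "impact, cadd, expected",
        [
            ("HIGH", 15.0, True),  # boundary inclusive
            ("MODERATE", 40.0, False),
            ("HIGH", 14.99, False),
            ("HIGH", None, False),  # absent CADD fails
        ],
    )
    def test_cases(self, impact, cadd, expected):
        record = qualifying_record(100, impact=impact, cadd=cadd)
        assert allele_qualifies(record, THRESHOLDS) is expected


class TestPairMafRule:
    @pytest.mark.parametrize(
        "maf_a, maf_b, expected",
        [
            (0.20, 0.01, True),  # one common allele tolerated
            (0.20, 0.20, False),
            (0.05, 0.05, True),  # boundary inclusive
        ],
    )
    def test_cases(self, maf_a, maf_b, expected):
        a = qualifying_record(100, maf=maf_a)
        b = qualifying_record(200, maf=maf_b)
        assert pair_maf_rule(a, b, THRESHOLDS) is expected


class TestEnumerateTransPairs:
    def test_opposite_haplotypes_pair(self):
        s1 = phased_site(qualifying_record(100), (1, 0))
        s2 = phased_site(qualifying_record(200), (0, 1))
        pairs = enumerate_trans_pairs([s1, s2])
        assert [(a.record.pos, b.record.pos) for a, b in pairs] == [(100, 200)]

    def test_cis_sites_do_not_pair(self):
        s1 = phased_site(qualifying_record(100), (1, 0))
        s2 = phased_site(qualifying_record(200), (1, 0))
        assert enumerate_trans_pairs([s1, s2]) == []

    def test_matches_brute_force_on_random_genes(self):
        rng = np.random.default_rng(17)
        for _ in range(200):
            sites = random_gene_sites(rng, int(rng.integers(2, 13)))
            pairs = enumerate_trans_pairs(sites)
            got = {frozenset((a.record.site_id, b.record.site_id)) for a, b in pairs}
            usable = [
                s for s in sites if s.phase_status is PhaseStatus.PHASED and s.child.is_het
            ]
            expected = set()
            for i in range(len(usable)):
                for j in range(i + 1, len(usable)):
                    a, b = usable[i], usable[j]
                    if (a.child.a == 1 and b.child.b == 1) or (
                        a.child.b == 1 and b.child.a == 1
                    ):
                        expected.add(frozenset((a.record.site_id, b.record.site_id)))
            assert got == expected


class TestParentExclusions:
    def test_parent_hom_alt_excludes(self):
        s1 = phased_site(qualifying_record(100), (1, 0), mother=(1, 1), father=(0, 0))
        s2 = phased_site(qualifying_record(200), (0, 1), mother=(0, 0), father=(0, 1))
        excluded, _ = parent_exclusions(s1, s2)
        assert excluded

    def test_parent_trans_pair_excludes(self):
        # father transmitted ALT at the paternal site and carries the ALT of
        # the maternal site on his untransmitted haplotype: same pair in trans
        s1 = phased_site(qualifying_record(100), (1, 0), mother=(0, 1), father=(0, 1))
        s2 = phased_site(qualifying_record(200), (0, 1), mother=(0, 0), father=(0, 1))
        excluded, _ = parent_exclusions(s1, s2)
        assert excluded

    def test_single_het_per_parent_not_excluded(self):
        s1 = phased_site(qualifying_record(100), (1, 0), mother=(0, 1), father=(0, 0))
        s2 = phased_site(qualifying_record(200), (0, 1), mother=(0, 0), father=(0, 1))
        excluded, ambiguous = parent_exclusions(s1, s2)
        assert not excluded and not ambiguous

    def test_missing_parent_allele_flags_ambiguous_without_excluding(self):
        s1 = phased_site(qualifying_record(100), (1, 0), mother=(1, None), father=(0, 0))
        s2 = phased_site(qualifying_record(200), (0, 1), mother=(0, 1), father=(0, 1))
        excluded, ambiguous = parent_exclusions(s1, s2)
        assert not excluded and ambiguous


def planted_gene_sites(trans=True):
    """A minimal gene with one qualifying pair, in trans or in cis."""
    s1 = phased_site(qualifying_record(100), (1, 0), mother=(0, 1), father=(0, 0))
    child2 = (0, 1) if trans else (1, 0)
    mother2 = (0, 0) if trans else (0, 1)
    father2 = (0, 1) if trans else (0, 0)
    s2 = phased_site(qualifying_record(200), child2, mother=mother2, father=father2)
    return [s1, s2]


class TestIdentifyCh:
    def test_planted_trans_pair_called(self):
        calls = identify_ch(planted_gene_sites(trans=True), "s1", THRESHOLDS)
        assert len(calls) == 1
        call = calls[0]
        assert call.gene == "G1"
        assert call.site_pair == frozenset(
            {("1", 100, "A", "C"), ("1", 200, "A", "C")}
        )
        assert call.passes_all

    def test_cis_pair_not_called(self):
        assert identify_ch(planted_gene_sites(trans=False), "s1", THRESHOLDS) == []

    def test_matches_brute_force_oracle_on_random_trios(self):
        rng = np.random.default_rng(23)
        for _ in range(300):
            sites = random_gene_sites(rng, int(rng.integers(2, 13)))
            calls = identify_ch(sites, "s", THRESHOLDS)
            assert {c.site_pair for c in calls} == oracle_ch_pairs(sites, THRESHOLDS)

    def test_multi_gene_site_participates_in_each_gene(self):
        from dataclasses import replace

        sites = planted_gene_sites(trans=True)
        for site in sites:
            site.record = replace(site.record, gene="G1,G2")
        calls = identify_ch(sites, "s1", THRESHOLDS)
        assert {c.gene for c in calls} == {"G1", "G2"}

    def test_monotone_in_thresholds(self):
        rng = np.random.default_rng(31)
        fixtures = [random_gene_sites(rng, 10) for _ in range(30)]
        base = FilterThresholds(cadd_min=10, maf_max=0.2)
        stricter_cadd = FilterThresholds(cadd_min=20, maf_max=0.2)
        stricter_maf = FilterThresholds(cadd_min=10, maf_max=0.01)
        for sites in fixtures:
            base_pairs = {c.site_pair for c in identify_ch(sites, "s", base)}
            for stricter in (stricter_cadd, stricter_maf):
                pairs = {c.site_pair for c in identify_ch(sites, "s", stricter)}
                assert pairs <= base_pairs

    def test_unrelated_mode_is_superset_of_trio_mode(self):
        rng = np.random.default_rng(37)
        for _ in range(100):
            sites = random_gene_sites(rng, 8)
            trio_calls = {c.site_pair for c in identify_ch(sites, "s", THRESHOLDS)}
            unrelated_sites = [
                (s.record, s.child)
                for s in sites
                if s.phase_status is PhaseStatus.PHASED
            ]
            unrelated_calls = {
                c.site_pair
                for c in identify_ch_unrelated(unrelated_sites, "s", THRESHOLDS)
            }
            assert trio_calls <= unrelated_calls


class TestIdentifyHa:
    def _site(self, child=(1, 1), mother=(0, 1), father=(0, 1), maf=0.01, **kwargs):
        return TrioSite(
            record=qualifying_record(100, maf=maf, **kwargs),
            child=Genotype(*child),
            mother=Genotype(*mother),
            father=Genotype(*father),
        )

    def test_qualifying_site_called(self):
        calls = identify_ha([self._site()], "s1", THRESHOLDS)
        assert len(calls) == 1
        assert calls[0].gene == "G1"

    def test_parent_hom_alt_excluded(self):
        assert identify_ha([self._site(mother=(1, 1))], "s1", THRESHOLDS) == []

    def test_common_allele_excluded(self):
        assert identify_ha([self._site(maf=0.10)], "s1", THRESHOLDS) == []

    def test_het_child_not_called(self):
        assert identify_ha([self._site(child=(0, 1))], "s1", THRESHOLDS) == []
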