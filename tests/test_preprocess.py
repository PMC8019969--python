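"""Trio preprocessing: site retention, removals, Mendelian classification."""

from __future__ import annotations

from itertools import product

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import ALL_COMPLETE_GENOTYPES, oracle_mendelian
from chtrio.model import Genotype, Trio, TrioSite, VariantCohort, VariantRecord
from chtrio.preprocess import (
    AttritionLedger,
    MendelianStatus,
    detect_mendelian_error,
    drop_mendelian_errors,
    drop_missing_both_parents,
    drop_multiallelic_and_duplicates,
    extract_trio,
    retain_proband_variant_sites,
    run_preprocess,
)


def make_site(pos=100, chrom="1", child=(0, 1), mother=(0, 1), father=(0, 0)):
    return TrioSite(
        record=VariantRecord(chrom, pos, "A", "C"),
        child=Genotype(*child),
        mother=Genotype(*mother),
        father=Genotype(*father),
    )


class TestRetainProbandVariantSites:
    def test_non_variant_proband_removed(self):
        assert retain_proband_variant_sites([make_site(child=(0, 0))]) == []

    def test_variant_proband_kept_regardless_of_parents(self):
        site = make_site(child=(0, 1), mother=(0, 0), father=(0, 0))
        assert retain_proband_variant_sites([site]) == [site]

    def test_matches_exhaustive_scan_on_random_fixture(self):
        rng = np.random.default_rng(11)
        sites = [
            make_site(
                pos=int(p),
                child=(int(rng.integers(2)), int(rng.integers(2))),
            )
            for p in rng.choice(100_000, size=200, replace=False)
        ]
        kept = retain_proband_variant_sites(sites)
        expected = {s.record.site_id for s in sites if 1 in s.child.alleles}
        assert {s.record.site_id for s in kept} == expected


class TestDropMultiallelicAndDuplicates:
    def test_duplicate_position_removes_both(self):
        s1 = make_site(pos=100)
        s2 = TrioSite(
            record=VariantRecord("1", 100, "A", "G"),
            child=Genotype(0, 1),
            mother=Genotype(0, 1),
            father=Genotype(0, 0),
        )
        assert drop_multiallelic_and_duplicates([s1, s2]) == []

    def test_non_autosome_removed(self):
        assert drop_multiallelic_and_duplicates([make_site(chrom="X")]) == []

    def test_unique_autosomal_kept(self):
        site = make_site()
        assert drop_multiallelic_and_duplicates([site]) == [site]

    def test_known_multiallelic_positions_removed(self):
        site = make_site(pos=100)
        assert drop_multiallelic_and_duplicates([site], {("1", 100)}) == []


class TestDropMissingBothParents:
    @pytest.mark.parametrize(
        "mother, father, kept",
        [
            ((None, None), (0, 1), True),
            ((None, None), (None, None), False),
            ((0, 1), (0, 0), True),
        ],
    )
    def test_cases(self, mother, father, kept):
        site = make_site(mother=mother, father=father)
        result = drop_missing_both_parents([site])
        assert (result == [site]) is kept


class TestMendelianClassifier:
    def test_alt_absent_from_both_parents_is_error(self):
        status = detect_mendelian_error(Genotype(0, 1), Genotype(0, 0), Genotype(0, 0))
        assert status is MendelianStatus.ERROR

    def test_transmissible_hom_alt_is_consistent(self):
        status = detect_mendelian_error(Genotype(1, 1), Genotype(1, 1), Genotype(0, 1))
        assert status is MendelianStatus.CONSISTENT

    def test_all_27_complete_triplets_match_gamete_oracle(self):
        for child, mother, father in product(ALL_COMPLETE_GENOTYPES, repeat=3):
            expected = oracle_mendelian(child, mother, father)
            got = detect_mendelian_error(child, mother, father).value
            assert got == expected, (child, mother, father)

    def test_one_missing_member_matches_completion_oracle(self):
        missing = Genotype(None, None)
        for where in range(3):
            for g1, g2 in product(ALL_COMPLETE_GENOTYPES, repeat=2):
                triplet = [g1, g2]
                triplet.insert(where, missing)
                expected = oracle_mendelian(*triplet)
                assert detect_mendelian_error(*triplet).value == expected

    @settings(max_examples=300, derandomize=True)
    @given(
        st.tuples(
            *(
                st.tuples(
                    st.sampled_from([0, 1, None]), st.sampled_from([0, 1, None])
                )
                for _ in range(3)
            )
        )
    )
    def test_arbitrary_triplets_match_oracle(self, alleles):
        child, mother, father = (Genotype(a, b) for a, b in alleles)
        expected = oracle_mendelian(child, mother, father)
        assert detect_mendelian_error(child, mother, father).value == expected

    def test_half_missing_alleles_match_oracle(self):
        genotypes = ALL_COMPLETE_GENOTYPES + [
            Genotype(0, None),
            Genotype(1, None),
            Genotype(None, None),
        ]
        for child, mother, father in product(genotypes, repeat=3):
            expected = oracle_mendelian(child, mother, father)
            assert detect_mendelian_error(child, mother, father).value == expected


class TestStepProperties:
    def test_each_step_is_idempotent(self):
        rng = np.random.default_rng(5)
        sites = []
        for i in range(100):
            draw = lambda: tuple(
                None if rng.random() < 0.1 else int(rng.integers(2)) for _ in range(2)
            )
            sites.append(
                make_site(
                    pos=100 + i,
                    chrom=str(rng.choice(["1", "2", "X"])),
                    child=draw(),
                    mother=draw(),
                    father=draw(),
                )
            )
        for step in (
            retain_proband_variant_sites,
            drop_multiallelic_and_duplicates,
            drop_missing_both_parents,
            drop_mendelian_errors,
        ):
            once = step(sites)
            assert step(once) == once


class TestLedgerAndRunPreprocess:
    def _clean_cohort(self):
        records = [VariantRecord("1", 100 + i, "A", "C") for i in range(4)]
        genotypes = [
            {"c": Genotype(0, 1), "m": Genotype(0, 1), "f": Genotype(0, 0)}
            for _ in records
        ]
        return VariantCohort(samples=["c", "m", "f"], sites=list(zip(records, genotypes)))

    def test_clean_input_keeps_all_counts_equal(self):
        cohort = self._clean_cohort()
        trio = Trio("F", "c", "m", "f")
        sites, ledger = run_preprocess(cohort, trio)
        counts = [count for _, count in ledger.counts_for("c")]
        assert counts == [4] * 5
        assert len(sites) == 4

    def test_counts_monotone_non_increasing(self, small_cohort):
        trio = small_cohort.pedigree.trios[0]
        _, ledger = run_preprocess(small_cohort.trio_cohort, trio)
        counts = [count for _, count in ledger.counts_for(trio.child)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_ledger_rejects_increase(self):
        ledger = AttritionLedger()
        ledger.record("input", "s", 10)
        with pytest.raises(ValueError):
            ledger.record("later", "s", 11)

    def test_missing_trio_member_raises(self):
        cohort = self._clean_cohort()
        with pytest.raises(KeyError):
            extract_trio(cohort, Trio("F", "c", "m", "absent"))

    def test_zero_error_synthetic_trios_have_no_mendelian_errors(self):
        from chtrio.simulate import SimulationConfig, simulate_cohort

        sim = simulate_cohort(
            SimulationConfig(
                seed=3,
                n_trios=5,
                n_genes=20,
                n_controls=0,
                genotyping_error_rate=0.0,
                missingness_rate=0.0,
            )
        )
        for trio in sim.pedigree.trios:
            sites = extract_trio(sim.trio_cohort, trio)
            statuses = {
                detect_mendelian_error(s.child, s.mother, s.father) for s in sites
            }
            assert MendelianStatus.ERROR not in statuses
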