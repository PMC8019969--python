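"""Transmission phasing, REF/ALT orientation restoration, phasing stats."""

from __future__ import annotations

from itertools import product

import numpy as np
import pytest

from conftest import ALL_COMPLETE_GENOTYPES, oracle_mendelian, oracle_phase_orientation
from chtrio.model import Genotype, PhaseStatus, TrioSite, VariantRecord
from chtrio.phasing import (
    OrientationError,
    phase_by_transmission,
    phase_trio,
    phasing_stats,
    restore_ref_alt_orientation,
)
from chtrio.preprocess import extract_trio


def make_site(child, mother, father, pos=100):
    return TrioSite(
        record=VariantRecord("1", pos, "A", "C"),
        child=Genotype(*child),
        mother=Genotype(*mother),
        father=Genotype(*father),
    )


class TestPhaseByTransmission:
    def test_single_possible_donor_forces_orientation(self):
        phased = phase_by_transmission(make_site((0, 1), (0, 0), (0, 1)))
        assert phased.phase_status is PhaseStatus.PHASED
        assert phased.child.alleles == (0, 1)  # maternal REF, paternal ALT

    def test_triple_het_is_ambiguous(self):
        phased = phase_by_transmission(make_site((0, 1), (0, 1), (0, 1)))
        assert phased.phase_status is PhaseStatus.UNPHASED_AMBIGUOUS
        assert not phased.child.phased

    def test_homozygous_child_phases_trivially(self):
        phased = phase_by_transmission(make_site((1, 1), (0, 1), (0, 1)))
        assert phased.phase_status is PhaseStatus.PHASED
        assert phased.child == Genotype(1, 1, phased=True)

    def test_inconsistent_triplet_flagged_error(self):
        phased = phase_by_transmission(make_site((0, 1), (0, 0), (0, 0)))
        assert phased.phase_status is PhaseStatus.MENDELIAN_ERROR

    def test_missing_parent_forced_vs_unforced(self):
        forced = phase_by_transmission(make_site((0, 1), (0, 0), (None, None)))
        assert forced.phase_status is PhaseStatus.PHASED
        assert forced.child.alleles == (0, 1)
        unforced = phase_by_transmission(make_site((0, 1), (0, 1), (None, None)))
        assert unforced.phase_status is PhaseStatus.UNPHASED_MISSING

    def test_all_27_complete_triplets_match_orientation_oracle(self):
        for child, mother, father in product(ALL_COMPLETE_GENOTYPES, repeat=3):
            phased = phase_by_transmission(make_site(child.alleles, mother.alleles, father.alleles))
            mendel = oracle_mendelian(child, mother, father)
            if mendel == "error":
                assert phased.phase_status is PhaseStatus.MENDELIAN_ERROR
                continue
            if not child.is_het:
                assert phased.phase_status is PhaseStatus.PHASED
                continue
            orientations = oracle_phase_orientation(child, mother, father)
            if len(orientations) == 1:
                assert phased.phase_status is PhaseStatus.PHASED
                assert phased.child.alleles == next(iter(orientations))
            else:
                assert phased.phase_status is PhaseStatus.UNPHASED_AMBIGUOUS

    def test_error_set_matches_mendelian_classifier(self):
        genotypes = ALL_COMPLETE_GENOTYPES + [Genotype(None, None), Genotype(0, None)]
        for child, mother, father in product(genotypes, repeat=3):
            phased = phase_by_transmission(make_site(child.alleles, mother.alleles, father.alleles))
            is_error = oracle_mendelian(child, mother, father) == "error"
            assert (phased.phase_status is PhaseStatus.MENDELIAN_ERROR) == is_error

    def test_phased_alleles_always_transmissible(self):
        rng = np.random.default_rng(21)
        for _ in range(500):
            draw = lambda: tuple(
                None if rng.random() < 0.15 else int(rng.integers(2)) for _ in range(2)
            )
            site = make_site(draw(), draw(), draw())
            phased = phase_by_transmission(site)
            if phased.phase_status is not PhaseStatus.PHASED:
                continue
            maternal, paternal = phased.child.alleles

            def transmissible(parent):
                opts = {a for a in parent.alleles if a is not None}
                if parent.has_missing:  # an unseen allele can be either code
                    opts |= {0, 1}
                return opts

            mother_opts = transmissible(site.mother)
            father_opts = transmissible(site.father)
            assert maternal in mother_opts
            assert paternal in father_opts

    def test_truth_haplotypes_recovered_on_noise_free_cohort(self):
        """With no genotyping noise, every phased orientation equals the truth."""
        from chtrio.simulate import SimulationConfig, simulate_cohort

        sim = simulate_cohort(
            SimulationConfig(
                seed=13,
                n_trios=8,
                n_genes=30,
                n_controls=0,
                genotyping_error_rate=0.0,
                missingness_rate=0.0,
            )
        )
        checked = 0
        for trio in sim.pedigree.trios:
            sites = extract_trio(sim.trio_cohort, trio)
            truth = sim.child_haplotypes[trio.child]
            for phased in phase_trio(sites):
                if phased.phase_status is not PhaseStatus.PHASED:
                    continue
                checked += 1
                assert phased.child.alleles == truth[phased.record.site_id]
        assert checked > 100


class TestRestoreOrientation:
    reference = {("1", 100): ("A", "C")}

    def test_swapped_record_restored_and_genotypes_complemented(self):
        record = VariantRecord("1", 100, "C", "A")
        genotypes = {"s": Genotype(0, 1, phased=True)}
        restored, flipped = restore_ref_alt_orientation(record, genotypes, self.reference)
        assert (restored.ref, restored.alt) == ("A", "C")
        assert flipped["s"] == Genotype(1, 0, phased=True)

    def test_congruent_record_unchanged(self):
        record = VariantRecord("1", 100, "A", "C")
        genotypes = {"s": Genotype(0, 1)}
        restored, out = restore_ref_alt_orientation(record, genotypes, self.reference)
        assert restored == record
        assert out == genotypes

    def test_idempotent_on_random_fixtures(self):
        rng = np.random.default_rng(9)
        for i in range(50):
            ref, alt = ("A", "C") if rng.random() < 0.5 else ("C", "A")
            record = VariantRecord("1", 100, ref, alt)
            genotypes = {
                "s": Genotype(
                    None if rng.random() < 0.2 else int(rng.integers(2)),
                    None if rng.random() < 0.2 else int(rng.integers(2)),
                )
            }
            once = restore_ref_alt_orientation(record, genotypes, self.reference)
            twice = restore_ref_alt_orientation(once[0], once[1], self.reference)
            assert twice == once

    def test_unknown_site_raises(self):
        with pytest.raises(OrientationError):
            restore_ref_alt_orientation(
                VariantRecord("1", 999, "A", "C"), {}, self.reference
            )


class TestPhasingStats:
    def test_all_homozygous_fully_phased(self):
        sites = [make_site((1, 1), (0, 1), (0, 1), pos=100 + i) for i in range(5)]
        stats = phasing_stats(phase_trio(sites))
        assert stats["fraction_phased"] == 1.0

    def test_all_triple_het_unphased(self):
        sites = [make_site((0, 1), (0, 1), (0, 1), pos=100 + i) for i in range(5)]
        stats = phasing_stats(phase_trio(sites))
        assert stats["fraction_phased"] == 0.0
        assert stats["fraction_unphased_ambiguous"] == 1.0

    def test_fractions_partition_to_one(self):
        rng = np.random.default_rng(2)
        draw = lambda: tuple(
            None if rng.random() < 0.2 else int(rng.integers(2)) for _ in range(2)
        )
        sites = [make_site(draw(), draw(), draw(), pos=100 + i) for i in range(200)]
        stats = phasing_stats(phase_trio(sites))
        total = sum(value for key, value in stats.items() if key.startswith("fraction_"))
        assert total == pytest.approx(1.0)
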