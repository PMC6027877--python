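"""Simulator tests: marker panels, pedigrees, gametes, cohorts, corruption."""

import numpy as np
import pytest
from scipy import stats

from hsmap import simhs
from hsmap.types import HsmapError, TrueRecombinationMap
from hsmap._refdata import rat_true_map_lengths_cm

from conftest import make_panel


class TestMarkerPanel:
    def test_bounds_order_and_determinism(self):
        p1 = simhs.make_marker_panel({"c": 10_000}, 1000, seed=5)
        p2 = simhs.make_marker_panel({"c": 10_000}, 1000, seed=5)
        assert 5 <= p1.n_markers <= 15
        assert p1.position_bp.min() >= 1 and p1.position_bp.max() <= 10_000
        assert np.all(np.diff(p1.position_bp) > 0)
        assert np.array_equal(p1.position_bp, p2.position_bp)

    def test_median_spacing_matches_request(self):
        # dense SNP panel on a chr1-sized chromosome
        p = simhs.make_marker_panel({"chr1": 282_800_000}, 3470, seed=1)
        med = np.median(np.diff(p.position_bp))
        assert abs(med - 3470) / 3470 < 0.10

    def test_rejects_bad_inputs(self):
        with pytest.raises(HsmapError):
            simhs.make_marker_panel({"c": 500}, 1000, seed=0)
        with pytest.raises(HsmapError):
            simhs.make_marker_panel({"c": 1000}, 0, seed=0)


class TestPedigree:
    def test_meiosis_counts(self):
        ped = simhs.build_hs_pedigree(65, 870 / 2 / 65, 8, seed=3)
        assert ped.n_informative_meioses() == 870
        tiny = simhs.build_hs_pedigree(1, 1, 8, seed=3)
        assert tiny.n_informative_meioses() == 2

    def test_parent_sexes_and_structure(self):
        ped = simhs.build_hs_pedigree(5, 4, 8, seed=0)
        df = ped.table.set_index("individual_id")
        kids = df[df["sire_id"].notna()]
        assert (df.loc[kids["sire_id"], "sex"] == "male").all()
        assert (df.loc[kids["dam_id"], "sex"] == "female").all()

    def test_empty_pedigree_rejected(self):
        with pytest.raises(HsmapError):
            simhs.build_hs_pedigree(0, 5, 8, seed=0)


class TestFounderHaplotypes:
    def test_polymorphic_fraction_and_inbreeding(self):
        panel = simhs.make_marker_panel({"c": 10_000_000}, 10_000, seed=1)
        fh = simhs.simulate_founder_haplotypes(panel, 8, polymorphic_fraction=0.5, seed=2)
        poly = (fh.haplotypes.min(axis=0) != fh.haplotypes.max(axis=0)).sum()
        n = panel.n_markers
        # binomial(n, 0.5) within 4 sigma
        assert abs(poly - 0.5 * n) < 4 * np.sqrt(n * 0.25)
        full = simhs.simulate_founder_haplotypes(panel, 8, polymorphic_fraction=1.0, seed=2)
        assert (full.haplotypes.min(axis=0) != full.haplotypes.max(axis=0)).all()

    def test_rejects_single_strain(self):
        panel = simhs.make_marker_panel({"c": 100_000}, 10_000, seed=1)
        with pytest.raises(HsmapError):
            simhs.simulate_founder_haplotypes(panel, 1, 0.5, seed=0)


class TestGametes:
    def test_zero_length_map_gives_no_crossovers(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            assert simhs._draw_crossover_bps(0.0, rng, None).size == 0

    def test_poisson_crossover_counts(self):
        # 100 cM chromosome: mean crossover count 1.00 within 3 SE over 10,000 draws
        rng = np.random.default_rng(1)
        counts = np.array([simhs._draw_crossover_bps(100.0, rng, None).size for _ in range(10_000)])
        se = np.sqrt(1.0 / 10_000)
        assert abs(counts.mean() - 1.0) < 3 * se
        # chi-square goodness of fit against Poisson(1), alpha = 0.01
        kmax = 6
        obs = np.bincount(np.minimum(counts, kmax), minlength=kmax + 1)
        exp = stats.poisson.pmf(np.arange(kmax + 1), 1.0)
        exp[kmax] = stats.poisson.sf(kmax - 1, 1.0)
        chi2 = ((obs - exp * counts.size) ** 2 / (exp * counts.size)).sum()
        assert stats.chi2.sf(chi2, df=kmax) > 0.01

    def test_sexes_use_their_own_map_lengths(self):
        # genome totals from the bundled rat map imply ~15.9 male and ~18.3
        # female crossovers per meiosis; expected counts are exact sums
        cms = rat_true_map_lengths_cm()
        male = sum(v[0] for v in cms.values()) / 100
        female = sum(v[1] for v in cms.values()) / 100
        assert abs(male - 15.89) < 0.02
        assert abs(female - 18.26) < 0.02
        rng = np.random.default_rng(2)
        n = 3000
        cnt_m = sum(rng.poisson(v[0] / 100, n).sum() for v in cms.values()) / n
        assert abs(cnt_m - male) < 3 * np.sqrt(male / n)

    def test_crossovers_respected_in_transmitted_alleles(self, hs_cohort):
        # faithful transmission: with no corruption, offspring dosages are the
        # sum of one gamete from each parent (checked via Mendel consistency)
        from hsmap.genoqc import mendel_rates

        gt, truth = simhs.simulate_cohort(
            hs_cohort["ped"], hs_cohort["founders"], hs_cohort["true_map"],
            error_rate=0, missing_rate=0, mendel_bad_marker_fraction=0, seed=99,
        )
        errors, complete = mendel_rates(gt, hs_cohort["ped"])
        assert errors.sum() == 0
        assert complete.sum() > 0


class TestCohort:
    def test_missing_fraction(self, hs_cohort):
        gt, _ = simhs.simulate_cohort(
            hs_cohort["ped"], hs_cohort["founders"], hs_cohort["true_map"],
            error_rate=0, missing_rate=0.1, mendel_bad_marker_fraction=0, seed=7,
        )
        frac = (gt.dosage < 0).mean()
        n = gt.dosage.size
        assert abs(frac - 0.1) < 4 * np.sqrt(0.1 * 0.9 / n)

    def test_planted_bad_markers_exceed_mendel_threshold(self, hs_cohort):
        from hsmap.genoqc import mendel_rates

        gt, truth = simhs.simulate_cohort(
            hs_cohort["ped"], hs_cohort["founders"], hs_cohort["true_map"],
            error_rate=0.0, missing_rate=0.0, mendel_bad_marker_fraction=0.05, seed=8,
        )
        errors, complete = mendel_rates(gt, hs_cohort["ped"])
        rate = errors / np.maximum(complete, 1)
        bad = gt.panel.index_of(truth.bad_markers)
        poly = gt.maf() > 0  # monomorphic markers cannot show Mendel errors
        bad = bad[poly[bad]]
        assert (rate[bad] > 0.02).mean() > 0.9

    def test_fixed_seed_bit_identical(self, hs_cohort):
        a, _ = simhs.simulate_cohort(hs_cohort["ped"], hs_cohort["founders"], hs_cohort["true_map"], seed=5)
        b, _ = simhs.simulate_cohort(hs_cohort["ped"], hs_cohort["founders"], hs_cohort["true_map"], seed=5)
        assert np.array_equal(a.dosage, b.dosage)

    def test_unknown_founder_rejected(self, hs_cohort):
        import pandas as pd

        bad = hs_cohort["ped"].table.copy()
        bad.loc[bad["strain"].notna(), "strain"] = 99
        from hsmap.types import Pedigree

        with pytest.raises(HsmapError):
            simhs.simulate_cohort(Pedigree(bad), hs_cohort["founders"], hs_cohort["true_map"], seed=0)


class TestCorruptPositions:
    def test_zero_fraction_is_identity(self):
        panel = simhs.make_marker_panel({"c": 50_000_000}, 500_000, seed=1)
        out, ids = simhs.corrupt_marker_positions(panel, 0.0, 1_000_000, seed=2)
        assert ids == []
        assert np.array_equal(out.position_bp, panel.position_bp)

    def test_displacement_count_and_magnitude(self):
        panel = simhs.make_marker_panel({"c": 200_000_000}, 2_000_000, seed=1)
        out, ids = simhs.corrupt_marker_positions(panel, 0.05, 20_000_000, seed=2)
        assert len(ids) == round(0.05 * panel.n_markers)
        old = dict(zip(panel.marker_id, panel.position_bp))
        new = dict(zip(out.marker_id, out.position_bp))
        for m in ids:
            assert abs(new[m] - old[m]) >= 20_000_000
        for m in set(panel.marker_id) - set(ids):
            assert new[m] == old[m]
        # panel invariants still hold after re-sorting
        assert np.all(np.diff(out.position_bp[out.chrom_slice("c")]) > 0)

    def test_majority_constraint(self):
        panel = simhs.make_marker_panel({"c": 50_000_000}, 500_000, seed=1)
        with pytest.raises(HsmapError):
            simhs.corrupt_marker_positions(panel, 0.5, 1_000_000, seed=0)


class TestOptionalModels:
    def test_gamma_renewal_interference_underdisperses(self):
        # strong interference (nu = 10): crossover counts on a 200 cM
        # chromosome have variance well below the Poisson variance
        rng = np.random.default_rng(3)
        counts = np.array([simhs._draw_crossover_bps(200.0, rng, 10.0).size for _ in range(4000)])
        assert abs(counts.mean() - 2.0) < 0.15
        assert counts.var() < 0.7 * counts.mean()

    def test_hemizygous_x_mode_silences_male_x_recombination(self, hs_cohort):
        gt, truth = simhs.simulate_cohort(
            hs_cohort["ped"], hs_cohort["founders"], hs_cohort["true_map"],
            error_rate=0, missing_rate=0, mendel_bad_marker_fraction=0,
            seed=6, x_chromosome="chr2",
        )
        male_x = sum(len(v) for (i, r, c), v in truth.crossovers.items() if r == "sire" and c == "chr2")
        male_auto = sum(len(v) for (i, r, c), v in truth.crossovers.items() if r == "sire" and c == "chr1")
        female_x = sum(len(v) for (i, r, c), v in truth.crossovers.items() if r == "dam" and c == "chr2")
        assert male_x == 0
        assert male_auto > 0
        assert female_x > 0
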