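"""QTL-scan tests: imputation, LOD, permutations, intervals, comparisons."""

import numpy as np
import pandas as pd
import pytest

from hsmap import qtlscan as q
from hsmap import _refdata
from hsmap.types import HsmapError


@pytest.fixture(scope="module")
def small_cross():
    cross, truth = q.simulate_f2_cross(220, {"1": 100.0, "2": 60.0}, 10.0,
                                       qtl=("1", 44.0, 0.6, 0.0), seed=3)
    return cross, truth


class TestCrossIO:
    def test_roundtrip(self, tmp_path, small_cross):
        cross, _ = small_cross
        path = tmp_path / "cross.csv"
        q.write_cross(cross, path)
        back = q.read_cross(path)
        assert np.array_equal(back.genotypes, cross.genotypes)
        assert list(back.marker_map["name"]) == list(cross.marker_map["name"])
        assert np.allclose(back.phenotypes["pheno"], cross.phenotypes["pheno"])

    def test_missing_codes(self, tmp_path):
        cross, _ = q.simulate_f2_cross(30, {"1": 20.0}, 10.0, missing_rate=0.3, seed=9)
        path = tmp_path / "m.csv"
        q.write_cross(cross, path)
        back = q.read_cross(path)
        assert np.array_equal(back.genotypes, cross.genotypes)
        assert (back.genotypes == -1).any()


class TestImputation:
    def test_typed_markers_reproduced_and_deterministic(self, small_cross):
        cross, _ = small_cross
        a = q.impute_genotypes(cross, step_cm=2.0, n_imputations=4, seed=5)
        b = q.impute_genotypes(cross, step_cm=2.0, n_imputations=4, seed=5)
        for chrom in a.positions:
            assert np.array_equal(a.draws[chrom], b.draws[chrom])
            mi = np.nonzero(a.is_marker[chrom])[0]
            sel = (cross.marker_map["chromosome"] == chrom).to_numpy()
            for m in range(4):
                assert np.array_equal(a.draws[chrom][:, m, mi], cross.genotypes[:, sel])

    def test_midpoint_conditional_distribution(self):
        # one individual typed AA at two markers 20 cM apart; the midpoint
        # genotype distribution must match the two-locus conditional
        mm = pd.DataFrame({"name": ["m0", "m1"], "chromosome": ["1", "1"], "cm": [0.0, 20.0]})
        cross = q.F2Cross(pd.DataFrame({"pheno": [0.0]}), np.array([[0, 0]], np.int8), mm)
        imps = q.impute_genotypes(cross, step_cm=10.0, n_imputations=20_000, seed=11)
        grid = imps.positions["1"]
        mid = int(np.argmin(np.abs(grid - 10.0)))
        draws = imps.draws["1"][0, :, mid]
        r = q._haldane_r(10.0)
        T = q._transition(float(r))
        probs = T[0, :] * T[:, 0]
        probs = probs / probs.sum()
        freqs = np.bincount(draws, minlength=3) / draws.size
        for g in range(3):
            se = np.sqrt(probs[g] * (1 - probs[g]) / draws.size)
            assert abs(freqs[g] - probs[g]) < 3 * se + 1e-9

    def test_invalid_parameters_rejected(self, small_cross):
        cross, _ = small_cross
        with pytest.raises(HsmapError):
            q.impute_genotypes(cross, step_cm=0)
        with pytest.raises(HsmapError):
            q.impute_genotypes(cross, n_imputations=0)


class TestLodScan:
    def test_matches_direct_regression_at_typed_marker(self):
        cross, _ = q.simulate_f2_cross(200, {"1": 40.0}, 10.0, qtl=("1", 20.0, 0.8, 0.2), seed=6)
        imps = q.impute_genotypes(cross, step_cm=2.0, n_imputations=1, seed=7)
        scan = q.lod_scan(imps, "pheno")
        y = cross.phenotypes["pheno"].to_numpy()
        g = cross.genotypes[:, (cross.marker_map["cm"] == 20.0).to_numpy()].ravel().astype(float)
        X = np.column_stack([np.ones_like(y), g - 1, (g == 1).astype(float)])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        rss1 = ((y - X @ beta) ** 2).sum()
        rss0 = ((y - y.mean()) ** 2).sum()
        want = len(y) / 2 * np.log10(rss0 / rss1)
        got = scan.frame.loc[scan.frame["cm"] == 20.0, "lod"].iloc[0]
        assert got == pytest.approx(want, abs=1e-9)

    def test_affine_phenotype_invariance(self, small_cross):
        cross, _ = small_cross
        imps = q.impute_genotypes(cross, step_cm=4.0, n_imputations=4, seed=8)
        s1 = q.lod_scan(imps, "pheno")
        shifted = q.F2Cross(cross.phenotypes * 3.0 + 7.0, cross.genotypes, cross.marker_map)
        imps2 = q.ImputationSet(shifted, imps.step_cm, imps.positions, imps.is_marker, imps.draws, imps.n_imputations)
        s2 = q.lod_scan(imps2, "pheno")
        assert np.allclose(s1.frame["lod"], s2.frame["lod"], atol=1e-9)

    def test_null_scan_stays_low(self):
        cross, _ = q.simulate_f2_cross(200, {"1": 100.0}, 10.0, qtl=None, seed=12)
        imps = q.impute_genotypes(cross, step_cm=4.0, n_imputations=8, seed=13)
        scan = q.lod_scan(imps, "pheno")
        assert scan.max_lod() < 4.0  # genome-wide max under the null

    def test_lod_non_negative(self, small_cross):
        cross, _ = small_cross
        imps = q.impute_genotypes(cross, step_cm=4.0, n_imputations=4, seed=8)
        scan = q.lod_scan(imps, "pheno")
        assert (scan.frame["lod"] >= 0).all()


class TestThresholdsAndIntervals:
    def test_threshold_ordering_and_alpha_one(self, small_cross):
        cross, _ = small_cross
        imps = q.impute_genotypes(cross, step_cm=8.0, n_imputations=2, seed=20)
        thr = q.permutation_thresholds(imps, "pheno", n_perm=120, alphas=(0.05, 0.63, 1.0), seed=21)
        assert thr[0.05] >= thr[0.63] >= thr[1.0]

    def test_constant_phenotype_rejected(self, small_cross):
        cross, _ = small_cross
        flat = q.F2Cross(pd.DataFrame({"pheno": np.zeros(len(cross.phenotypes))}),
                         cross.genotypes, cross.marker_map)
        imps = q.impute_genotypes(flat, step_cm=8.0, n_imputations=2, seed=20)
        with pytest.raises(HsmapError):
            q.permutation_thresholds(imps, "pheno", n_perm=120, seed=0)

    def test_bayes_interval_spike_and_flat(self):
        frame = pd.DataFrame({"chromosome": "1", "cm": np.arange(0, 22, 2.0),
                              "lod": 0.0, "is_marker": True, "flagged": False})
        frame.loc[5, "lod"] = 12.0
        scan = q.QtlScan(frame, 2.0, "p")
        assert q.bayes_interval(scan, "1") == (10.0, 10.0)
        flat = q.QtlScan(frame.assign(lod=1.0), 2.0, "p")
        assert q.bayes_interval(flat, "1") == (0.0, 20.0)

    def test_bayes_interval_matches_enumeration(self):
        # triangular LOD on 11 points against brute-force window enumeration
        cm = np.arange(0, 22, 2.0)
        lod = 3.0 - np.abs(cm - 10.0) / 4.0
        frame = pd.DataFrame({"chromosome": "1", "cm": cm, "lod": lod,
                              "is_marker": True, "flagged": False})
        scan = q.QtlScan(frame, 2.0, "p")
        got = q.bayes_interval(scan, "1", coverage=0.95)
        w = 10.0 ** (lod - lod.max())
        w = w / w.sum()
        peak = int(np.argmax(lod))
        best = None
        for i in range(peak + 1):
            for j in range(peak, cm.size):
                if w[i:j + 1].sum() >= 0.95 - 1e-12:
                    cand = (j - i, i, j)
                    if best is None or cand < best:
                        best = cand
        assert got == (cm[best[1]], cm[best[2]])


class TestComparisons:
    def test_identical_scans_have_no_shifts(self):
        peaks = pd.DataFrame({
            "phenotype": ["p"] * 3, "model": ["A"] * 3, "chromosome": [1, 2, 3],
            "peak_cm": [10.0, 30.0, np.nan],
        })
        merged, summary = q.compare_peaks(peaks, peaks.copy())
        assert summary["n_shifted"] == 0
        assert summary["n_qtl"] == 2

    def test_duplicate_rows_rejected(self):
        peaks = pd.DataFrame({
            "phenotype": ["p", "p"], "model": ["A", "A"], "chromosome": [1, 1],
            "peak_cm": [10.0, 12.0],
        })
        with pytest.raises(HsmapError):
            q.compare_peaks(peaks, peaks)

    def test_published_peak_table_gives_nine_of_thirtytwo(self):
        tab = _refdata.qtl_peak_table()
        old = tab.rename(columns={"old_peak_cm": "peak_cm"})[["phenotype", "model", "chromosome", "peak_cm"]]
        new = tab.rename(columns={"new_peak_cm": "peak_cm"})[["phenotype", "model", "chromosome", "peak_cm"]]
        merged, summary = q.compare_peaks(old, new, shift_threshold_cm=10.0)
        assert summary["n_qtl"] == 32
        assert summary["n_shifted"] == 9

    def test_repositioned_markers_change_lod_only_through_the_map(self):
        # complete data, one imputation: single-marker LODs at typed markers
        # are invariant to re-positioning the markers on the cM scale
        cross, _ = q.simulate_f2_cross(150, {"1": 60.0}, 10.0, qtl=("1", 30.0, 0.7, 0.0), seed=30)
        imps_a = q.impute_genotypes(cross, step_cm=2.0, n_imputations=1, seed=31)
        scan_a = q.lod_scan(imps_a, "pheno")
        new_cm = {n: c * 1.5 + 4.0 for n, c in zip(cross.marker_map["name"], cross.marker_map["cm"])}
        moved = cross.with_map(new_cm)
        imps_b = q.impute_genotypes(moved, step_cm=2.0, n_imputations=1, seed=32)
        scan_b = q.lod_scan(imps_b, "pheno")
        for name, old_cm in zip(cross.marker_map["name"], cross.marker_map["cm"]):
            la = scan_a.frame.loc[np.isclose(scan_a.frame["cm"], old_cm), "lod"].iloc[0]
            lb = scan_b.frame.loc[np.isclose(scan_b.frame["cm"], new_cm[name]), "lod"].iloc[0]
            assert la == pytest.approx(lb, abs=1e-9)


class TestPlantedQtl:
    def test_peak_near_truth_and_interval_contains_it(self, small_cross):
        cross, truth = small_cross
        imps = q.impute_genotypes(cross, step_cm=2.0, n_imputations=16, seed=40)
        scan = q.lod_scan(imps, "pheno")
        peaks = q.find_peaks(scan, suggestive=2.0)
        row = peaks.loc[peaks["chromosome"] == "1"].iloc[0]
        assert row["detected"]
        assert abs(row["peak_cm"] - 44.0) < 15.0
        assert row["ci_lo"] <= row["peak_cm"] <= row["ci_hi"]
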