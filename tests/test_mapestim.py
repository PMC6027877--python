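"""Estimation tests: mapping functions, parent calling, phasing, intervals."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from hsmap import mapestim as me
from hsmap.types import GenotypeTable, HsmapError

from conftest import make_panel, nuclear_family, table


class TestMappingFunctions:
    def test_closed_forms(self):
        assert me.map_distance(0.0) == 0.0
        assert me.map_distance(0.1, "haldane") == pytest.approx(11.157, abs=1e-3)
        assert me.map_distance(0.1, "kosambi") == pytest.approx(10.137, abs=1e-3)

    def test_invalid_fraction_rejected(self):
        for bad in (-0.01, 0.5, 0.7):
            with pytest.raises(HsmapError):
                me.map_distance(bad)

    @given(st.floats(min_value=0.0, max_value=0.499))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_inverse_is_identity_and_kosambi_below_haldane(self, r):
        for fn in ("haldane", "kosambi"):
            assert me.inverse_map_distance(me.map_distance(r, fn), fn) == pytest.approx(r, abs=1e-12)
        if r > 1e-4:  # the difference is O(r^3), below float noise for tiny r
            assert me.map_distance(r, "kosambi") < me.map_distance(r, "haldane")

    def test_strictly_increasing(self):
        r = np.linspace(0, 0.49, 100)
        for fn in ("haldane", "kosambi"):
            assert np.all(np.diff(me.map_distance(r, fn)) > 0)


class TestCallParents:
    def test_offspring_force_missing_sire_allele(self):
        panel = make_panel({"c": [1000]})
        ped = nuclear_family(2)
        gt = table(ped, panel, {"f0_s": [-1], "f0_d": [0], "f0_o0": [0], "f0_o1": [1]})
        out = me.call_parents(gt, ped)
        # offspring AB forces a B from the sire; offspring AA forces an A: AB
        assert out.row("f0_s")[0] == 1

    def test_unforced_call_stays_missing(self):
        panel = make_panel({"c": [1000]})
        ped = nuclear_family(2)
        gt = table(ped, panel, {"f0_s": [-1], "f0_d": [0], "f0_o0": [0], "f0_o1": [0]})
        out = me.call_parents(gt, ped)
        assert out.row("f0_s")[0] == -1  # AA and AB both compatible

    def test_contradiction_flagged_not_imputed(self):
        panel = make_panel({"c": [1000]})
        ped = nuclear_family(2)
        # dam AA; offspring AB needs sire B, offspring BB needs dam B too: impossible
        gt = table(ped, panel, {"f0_s": [-1], "f0_d": [0], "f0_o0": [1], "f0_o1": [2]})
        out = me.call_parents(gt, ped)
        assert out.contradicted == ["c_m000"]
        assert out.row("f0_s")[0] == -1

    def test_complete_input_unchanged(self, hs_cohort):
        from hsmap import simhs

        gt, _ = simhs.simulate_cohort(
            hs_cohort["ped"], hs_cohort["founders"], hs_cohort["true_map"],
            error_rate=0, missing_rate=0, mendel_bad_marker_fraction=0, seed=1,
        )
        out = me.call_parents(gt, hs_cohort["ped"])
        assert np.array_equal(out.dosage, gt.dosage)


class TestDistortionFilter:
    def _family(self, counts):
        # AB x AB families with pooled offspring genotype counts
        panel = make_panel({"c": [1000]})
        n = sum(counts)
        ped = nuclear_family(n)
        dos = {"f0_s": [1], "f0_d": [1]}
        j = 0
        for g, c in enumerate(counts):
            for _ in range(c):
                dos[f"f0_o{j}"] = [g]
                j += 1
        return ped, table(ped, panel, dos)

    def test_perfect_segregation_retained(self):
        ped, gt = self._family([25, 50, 25])
        out, removed = me.distortion_filter(gt, ped)
        assert removed == []
        assert out.distortion_stat["chi2"].iloc[0] == pytest.approx(0.0)

    def test_distorted_marker_removed_with_exact_statistic(self):
        # 80/15/5 against expected 25/50/25: chi2 = 55^2/25 + 35^2/50 + 20^2/25
        ped, gt = self._family([80, 15, 5])
        out, removed = me.distortion_filter(gt, ped)
        assert removed == ["c_m000"]
        assert gt.panel.n_markers - out.panel.n_markers == 1
        expected_chi2 = 55**2 / 25 + 35**2 / 50 + 20**2 / 25
        got = None
        # statistic recorded on the pre-filter table
        got = out.distortion_stat.loc[out.distortion_stat["marker_id"] == "c_m000", "chi2"].iloc[0]
        assert got == pytest.approx(expected_chi2)
        assert stats.chi2.sf(expected_chi2, 2) < 1e-10

    def test_uninformative_families_retained(self):
        panel = make_panel({"c": [1000]})
        ped = nuclear_family(20)
        dos = {"f0_s": [0], "f0_d": [0]}
        for j in range(20):
            dos[f"f0_o{j}"] = [0]
        gt = table(ped, panel, dos)
        out, removed = me.distortion_filter(gt, ped)
        assert removed == []


def _min_recombination_oracle(S, D, O):
    """Exhaustive minimum-recombination phasing for one parent (oracle).

    Enumerates every phase assignment of the parent's heterozygous markers
    and counts recombination events between consecutive resolved markers per
    offspring; returns the minimum total.
    """
    T = me._resolve_transmissions(np.asarray(S, np.int8), np.asarray(D, np.int8), np.asarray(O, np.int8))
    cols = np.nonzero(np.asarray(S) == 1)[0]
    if cols.size == 0:
        return 0
    Th = T[:, cols]
    best = None
    for bits in itertools.product((0, 1), repeat=cols.size):
        o = np.asarray(bits, np.int8)
        total = 0
        for i in range(Th.shape[0]):
            r = np.nonzero(Th[i] >= 0)[0]
            if r.size < 2:
                continue
            x = Th[i, r] ^ o[r]
            total += int((x[1:] != x[:-1]).sum())
        best = total if best is None else min(best, total)
    return best


class TestPhasing:
    def test_unanimous_transmissions_mean_zero_recombinants(self):
        panel = make_panel({"c": [1000, 2000]})
        ped = nuclear_family(10)
        dos = {"f0_s": [1, 1], "f0_d": [0, 0]}
        for j in range(10):
            g = [0, 0] if j % 2 == 0 else [1, 1]
            dos[f"f0_o{j}"] = g
        gt = table(ped, panel, dos)
        mset = me.phase_and_extract(gt, ped, min_parent_het_fraction=0)
        assert mset.count_events("male") == 0

    def test_single_discordant_offspring_is_recombinant(self):
        panel = make_panel({"c": [1000, 2000]})
        ped = nuclear_family(11)
        dos = {"f0_s": [1, 1], "f0_d": [0, 0]}
        for j in range(10):
            dos[f"f0_o{j}"] = [0, 0] if j % 2 == 0 else [1, 1]
        dos["f0_o10"] = [0, 1]
        gt = table(ped, panel, dos)
        mset = me.phase_and_extract(gt, ped, min_run_support=1, min_parent_het_fraction=0)
        assert mset.count_events("male") == 1

    def test_homozygous_parent_uninformative(self):
        panel = make_panel({"c": [1000, 2000]})
        ped = nuclear_family(4)
        dos = {"f0_s": [0, 2], "f0_d": [1, 1]}
        for j in range(4):
            dos[f"f0_o{j}"] = [1, 1]
        gt = table(ped, panel, dos)
        mset = me.phase_and_extract(gt, ped, min_parent_het_fraction=0)
        idx = [i for i, s in enumerate(mset.parent_sex) if s == "male"]
        assert all(mset.data["c"][i] is None for i in idx)

    def test_matches_exhaustive_minimum_recombination(self):
        # random small families (<= 4 offspring, <= 6 markers) against the
        # brute-force oracle
        rng = np.random.default_rng(0)
        for case in range(30):
            n_mark = int(rng.integers(2, 7))
            n_off = int(rng.integers(1, 5))
            panel = make_panel({"c": [1000 * (j + 1) for j in range(n_mark)]})
            ped = nuclear_family(n_off)
            S = rng.integers(0, 3, n_mark)
            D = rng.integers(0, 3, n_mark)
            O = np.empty((n_off, n_mark), dtype=np.int8)
            for i in range(n_off):
                a_s = np.where(S == 1, rng.integers(0, 2, n_mark), S // 2)
                a_d = np.where(D == 1, rng.integers(0, 2, n_mark), D // 2)
                O[i] = a_s + a_d
            dos = {"f0_s": list(S), "f0_d": list(D)}
            for i in range(n_off):
                dos[f"f0_o{i}"] = list(O[i])
            gt = table(ped, panel, dos)
            mset = me.phase_and_extract(gt, ped, min_run_support=1, min_parent_het_fraction=0)
            got = mset.count_events("male")
            want = _min_recombination_oracle(S, D, O)
            assert got == want, f"case {case}: {got} != {want}"


class TestIntervals:
    def _mset_from_spans(self, panel, entries, sex="male"):
        mset = me.MeiosisSet(panel=panel, min_run_support=1)
        mset.data = {"c": []}
        for k, ent in enumerate(entries):
            mset.offspring.append(f"o{k}")
            mset.parent.append("p")
            mset.parent_sex.append(sex)
            if ent is None:
                mset.data["c"].append(None)
            else:
                idx, org = ent
                mset.data["c"].append(
                    (np.asarray(idx, np.int32), np.asarray(org, np.uint8), np.zeros(len(idx), np.int32))
                )
        mset.mismatch = np.zeros(panel.n_markers, dtype=np.int64)
        mset.core = np.zeros(panel.n_markers, dtype=np.int64)
        return mset

    def test_recombination_fraction_counts(self):
        panel = make_panel({"c": [1000, 2000]})
        entries = [([0, 1], [0, 1])] * 2 + [([0, 1], [0, 0])] * 8
        mset = self._mset_from_spans(panel, entries)
        iv = me.interval_recfrac(mset, "male", support_correction=False)
        t = iv.tables["c"]
        assert t["n"].iloc[0] == 10
        assert t["k"].iloc[0] == pytest.approx(2.0)
        assert t["r"].iloc[0] == pytest.approx(0.2)

    def test_uninformative_interval_flagged(self):
        panel = make_panel({"c": [1000, 2000, 3000]})
        entries = [([0, 1], [0, 0])]
        mset = self._mset_from_spans(panel, entries)
        iv = me.interval_recfrac(mset, "male", support_correction=False)
        t = iv.tables["c"]
        assert not t["uninformative"].iloc[0]
        assert t["uninformative"].iloc[1]
        assert t["cm"].iloc[1] == 0.0

    def test_order_invariance(self):
        panel = make_panel({"c": [1000, 2000]})
        entries = [([0, 1], [0, 1]), ([0, 1], [0, 0]), ([0, 1], [1, 1])]
        a = me.interval_recfrac(self._mset_from_spans(panel, entries), "male", support_correction=False)
        b = me.interval_recfrac(self._mset_from_spans(panel, entries[::-1]), "male", support_correction=False)
        assert a.tables["c"]["r"].tolist() == b.tables["c"]["r"].tolist()

    def test_sex_separation(self):
        panel = make_panel({"c": [1000, 2000]})
        male_entries = [([0, 1], [0, 1]), ([0, 1], [0, 0])]
        mset = self._mset_from_spans(panel, male_entries, sex="male")
        # adding female meioses must not change the male estimate
        mset.offspring += ["fo1", "fo2"]
        mset.parent += ["q", "q"]
        mset.parent_sex += ["female", "female"]
        mset.data["c"] += [
            (np.array([0, 1], np.int32), np.array([1, 0], np.uint8), np.zeros(2, np.int32)),
            (np.array([0, 1], np.int32), np.array([1, 1], np.uint8), np.zeros(2, np.int32)),
        ]
        iv = me.interval_recfrac(mset, "male", support_correction=False)
        assert iv.tables["c"]["n"].iloc[0] == 2
        assert iv.tables["c"]["k"].iloc[0] == pytest.approx(1.0)


class TestAssembleAndConsensus:
    def test_average_track_is_mean_and_starts_at_zero(self, hs_cohort):
        from hsmap import genoqc

        gtq, _ = genoqc.apply_qc(hs_cohort["gt"], hs_cohort["ped"])
        mset = me.phase_and_extract(gtq, hs_cohort["ped"])
        iv_m = me.interval_recfrac(mset, "male")
        iv_f = me.interval_recfrac(mset, "female")
        gmap = me.assemble_map(iv_m, iv_f, gtq.panel, mset)
        for chrom in gmap.chromosomes:
            sub = gmap.chrom(chrom)
            assert sub["cm_male"].iloc[0] == 0.0
            assert np.allclose(sub["cm_avg"], (sub["cm_male"] + sub["cm_female"]) / 2)
            for col in ("cm_male", "cm_female", "cm_avg"):
                assert np.all(np.diff(sub[col].to_numpy()) >= 0)

    def test_consensus_identity_and_mean(self, hs_cohort):
        from hsmap import genoqc

        gtq, _ = genoqc.apply_qc(hs_cohort["gt"], hs_cohort["ped"])
        gmap, _ = me.estimate_map(gtq, hs_cohort["ped"])
        same = me.replicate_consensus([gmap] * 10)
        assert np.allclose(same.frame["cm_male"], gmap.frame["cm_male"])
        shifted = gmap.frame.copy()
        j = len(shifted) // 2
        shifted.loc[j, "cm_male"] += 1.0
        from hsmap.types import GeneticMap

        mean = me.replicate_consensus([gmap, GeneticMap(shifted)])
        assert mean.frame["cm_male"].iloc[j] >= gmap.frame["cm_male"].iloc[j]

    def test_consensus_rejects_mismatched_marker_sets(self, hs_cohort):
        from hsmap import genoqc
        from hsmap.types import GeneticMap

        gtq, _ = genoqc.apply_qc(hs_cohort["gt"], hs_cohort["ped"])
        gmap, _ = me.estimate_map(gtq, hs_cohort["ped"])
        with pytest.raises(HsmapError):
            me.replicate_consensus([gmap, GeneticMap(gmap.frame.iloc[:-1])])


class TestEstimatorAccuracy:
    def test_totals_converge_to_truth(self, hs_cohort):
        # mid-sized cohort: both sex totals within 10% of simulated truth
        from hsmap import genoqc

        gtq, _ = genoqc.apply_qc(hs_cohort["gt"], hs_cohort["ped"])
        gmap, diag = me.estimate_map(gtq, hs_cohort["ped"])
        cms = hs_cohort["cms"]
        want_m = sum(v[0] for v in cms.values())
        want_f = sum(v[1] for v in cms.values())
        assert gmap.total_cm("male") == pytest.approx(want_m, rel=0.10)
        assert gmap.total_cm("female") == pytest.approx(want_f, rel=0.10)


class TestHemizygousX:
    def test_only_female_track_estimated_on_x(self, hs_cohort):
        from hsmap import genoqc

        gtq, _ = genoqc.apply_qc(hs_cohort["gt"], hs_cohort["ped"])
        gmap, diag = me.estimate_map(gtq, hs_cohort["ped"], x_chromosome="chr2")
        sub = gmap.chrom("chr2")
        assert (sub["cm_male"] == 0).all()
        assert np.allclose(sub["cm_avg"], sub["cm_female"])
        assert gmap.chrom("chr1")["cm_male"].iloc[-1] > 0
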