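"""ΔCT computation, QC, 1-D k-means, and genotype-call mapping."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from culexkdr import calling, synthetic
from culexkdr.calling import (
    FLAG_GAP,
    FLAG_NO_AMP,
    FLAG_TTA_SUB,
    FLAG_TTT_SUB,
    ThresholdBands,
    WellReading,
    anova_delta_by_genotype,
    calls_from_clusters,
    calls_from_thresholds,
    compute_delta_ct,
    ct_from_curve,
    kmeans_1d,
    qc_filter,
    species_bands,
)


class TestDeltaCt:
    def test_absent_mutant_probe_substitutes_40(self):
        d, flags = compute_delta_ct(WellReading("s", ct_tta=20.0, ct_ttt=None))
        assert d == 20.0
        assert flags == {FLAG_TTT_SUB}

    def test_equal_cts_give_zero(self):
        d, flags = compute_delta_ct(WellReading("s", ct_tta=25.0, ct_ttt=25.0))
        assert d == 0.0 and flags == frozenset()

    def test_absent_wildtype_probe_is_symmetric(self):
        d, flags = compute_delta_ct(WellReading("s", ct_tta=None, ct_ttt=22.0))
        assert d == -18.0
        assert flags == {FLAG_TTA_SUB}

    def test_both_absent_flags_no_amplification(self):
        d, flags = compute_delta_ct(WellReading("s"))
        assert np.isnan(d) and flags == {FLAG_NO_AMP}

    @given(st.floats(1.0, 39.0), st.floats(1.0, 39.0), st.floats(-5.0, 5.0))
    def test_shifting_one_probe_shifts_delta_exactly(self, a, b, c):
        if not (0 < a + c <= 40):
            return
        d0, _ = compute_delta_ct(WellReading("s", ct_tta=a, ct_ttt=b))
        d1, _ = compute_delta_ct(WellReading("s", ct_tta=a + c, ct_ttt=b))
        assert d1 == pytest.approx(d0 - c, abs=1e-9)

    def test_ct_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            WellReading("s", ct_tta=41.0)

    def test_ct_recovered_from_curve_when_cts_absent(self):
        # sigmoid-ish ΔRn curve crossing 10% of plateau around cycle 21
        cycles = np.arange(1, 41)
        curve = 1.0 / (1.0 + np.exp(-(cycles - 24) / 1.5))
        ct = ct_from_curve(curve)
        assert 20.0 < ct < 22.0
        d, flags = compute_delta_ct(
            WellReading("s", curve_tta=list(curve), curve_ttt=list(np.zeros(40)))
        )
        assert flags == {FLAG_TTT_SUB}
        assert d == pytest.approx(40.0 - ct, abs=1e-6)

    def test_flat_curve_yields_no_ct(self):
        assert ct_from_curve(np.zeros(40)) is None


class TestQcFilter:
    def test_all_late_cts_excluded(self):
        kept, excl = qc_filter([WellReading("s", ct_tta=35.0, ct_ttt=None)])
        assert not kept and len(excl) == 1

    def test_one_early_ct_keeps_specimen(self):
        kept, excl = qc_filter([WellReading("s", ct_tta=20.0, ct_ttt=None)])
        assert len(kept) == 1 and not excl

    def test_survey_scale_exclusion_fraction(self):
        """75 specimens with 3 constructed failures: 72 kept, 4% excluded."""
        readings = [WellReading(f"s{i}", ct_tta=22.0, ct_ttt=23.0) for i in range(72)]
        readings += [WellReading(f"f{i}") for i in range(3)]
        kept, excl = qc_filter(readings)
        assert len(kept) == 72
        assert len(excl) / len(readings) == pytest.approx(0.04)


def contiguous_partition_oracle(values, k):
    """Exhaustive 1-D k-means oracle: the optimal partition is contiguous in
    sorted order, so enumerate all contiguous 3-splits."""
    v = np.sort(np.asarray(values, dtype=float))
    n = v.size
    best = (np.inf, None)
    for cuts in itertools.combinations(range(1, n), k - 1):
        bounds = (0, *cuts, n)
        groups = [v[bounds[i]: bounds[i + 1]] for i in range(k)]
        wcss = sum(((g - g.mean()) ** 2).sum() for g in groups)
        if wcss < best[0]:
            best = (wcss, [g.mean() for g in groups])
    return best


class TestKmeans1d:
    def test_three_point_masses_recovered_exactly(self):
        vals = np.repeat([-10.0, 0.0, 10.0], 3)
        m = kmeans_1d(vals, seed=0)
        assert np.allclose(m.centers, [-10, 0, 10])
        assert m.converged

    def test_k1_is_the_mean(self):
        vals = np.array([1.0, 2.0, 4.0, 9.0])
        m = kmeans_1d(vals, k=1, seed=0)
        assert m.centers[0] == pytest.approx(vals.mean())

    def test_too_few_distinct_values_rejected(self):
        with pytest.raises(ValueError):
            kmeans_1d([1.0, 1.0, 2.0], k=3)

    @pytest.mark.parametrize("seed", range(10))
    def test_equals_exhaustive_contiguous_partition_oracle(self, seed):
        rng = np.random.default_rng(seed)
        vals = rng.normal(0, 5, size=12)
        m = kmeans_1d(vals, k=3, seed=seed, restarts=16, max_iter=50)
        wcss, centers = contiguous_partition_oracle(vals, 3)
        assert m.inertia == pytest.approx(wcss, rel=1e-9)
        assert np.allclose(np.sort(m.centers), np.sort(centers))

    def test_assignments_match_center_order(self):
        vals = np.array([-9.0, -11.0, 0.5, -0.5, 10.0, 12.0])
        m = kmeans_1d(vals, seed=0)
        assert list(m.assignments) == [0, 0, 1, 1, 2, 2]


class TestClusterCalls:
    def test_published_pipiens_centers_map_ff_lf_ll(self):
        m = kmeans_1d(np.repeat([-13.212, -0.871, 12.691], 4), seed=0)
        calls = calls_from_clusters(m, [-13.0, -1.0, 12.5])
        assert [c.genotype for c in calls] == ["FF", "LF", "LL"]

    def test_published_tarsalis_centers_map_ff_lf_ll(self):
        m = kmeans_1d(np.repeat([-2.944, -0.089, 3.107], 4), seed=0)
        calls = calls_from_clusters(m, [-2.9, 0.0, 3.0])
        assert [c.genotype for c in calls] == ["FF", "LF", "LL"]

    def test_midway_value_goes_to_lower_cluster_and_is_flagged(self):
        m = kmeans_1d(np.repeat([-10.0, 0.0, 10.0], 3), seed=0)
        calls = calls_from_clusters(m, [-5.0])
        assert calls[0].genotype == "FF"
        assert calling.FLAG_TIE in calls[0].flags

    def test_non_three_centers_rejected(self):
        m = kmeans_1d([1.0, 2.0, 5.0, 9.0], k=2, seed=0)
        with pytest.raises(ValueError):
            calls_from_clusters(m, [1.0])


class TestThresholdCalls:
    def test_pipiens_bands(self):
        bands = species_bands("Cx. pipiens")
        calls = calls_from_thresholds([12.7, 0.0, -13.0], bands)
        assert [c.genotype for c in calls] == ["LL", "LF", "FF"]

    def test_tarsalis_zero_is_heterozygote(self):
        calls = calls_from_thresholds([0.0], species_bands("Cx. tarsalis"))
        assert calls[0].genotype == "LF"

    def test_band_gap_is_undetermined_and_flagged(self):
        calls = calls_from_thresholds([-3.0], species_bands("Cx. pipiens"))
        assert calls[0].genotype == "UNDETERMINED"
        assert FLAG_GAP in calls[0].flags

    def test_exact_band_edges(self):
        bands = species_bands("Cx. pipiens")
        # 5.0 is not "> 5.0": falls into the 4.9..5.0 gap
        calls = calls_from_thresholds([5.0, 4.9, -2.0, -4.0], bands)
        assert [c.genotype for c in calls] == ["UNDETERMINED", "LF", "LF", "UNDETERMINED"]

    def test_inverted_bands_rejected(self):
        with pytest.raises(ValueError):
            ThresholdBands("x", ff_max=1.0, lf_low=0.0, lf_high=2.0, ll_min=3.0)

    def test_unknown_species_has_no_bands(self):
        assert species_bands("Cx. apicalis") is None


class TestAntisymmetry:
    @pytest.mark.parametrize("species", ["Cx. pipiens", "Cx. tarsalis"])
    def test_probe_swap_negates_delta_and_mirrors_calls(self, species):
        """Swapping the two probes' CTs negates ΔCT and exchanges LL and FF
        under both calling methods."""
        rng = np.random.default_rng(7)
        model = synthetic.default_noise_model(species)
        readings, swapped = [], []
        for i, g in enumerate(["LL", "LF", "FF"] * 40):
            tta, ttt = synthetic.simulate_ct_pair(g, model, rng)
            if tta is None and ttt is None:
                continue
            readings.append(WellReading(f"s{i}", ct_tta=tta, ct_ttt=ttt))
            swapped.append(WellReading(f"s{i}", ct_tta=ttt, ct_ttt=tta))
        d = np.array([compute_delta_ct(r)[0] for r in readings])
        d_sw = np.array([compute_delta_ct(r)[0] for r in swapped])
        assert np.allclose(d_sw, -d)

        mirror = {"LL": "FF", "FF": "LL", "LF": "LF", "UNDETERMINED": "UNDETERMINED"}
        # the printed bands are asymmetric, so the mirror image of a call set
        # is produced by the sign-mirrored bands
        bands = species_bands(species)
        mirrored = ThresholdBands(
            species=bands.species, ff_max=-bands.ll_min, lf_low=-bands.lf_high,
            lf_high=-bands.lf_low, ll_min=-bands.ff_max,
        )
        thr = [c.genotype for c in calls_from_thresholds(d, bands)]
        thr_sw = [c.genotype for c in calls_from_thresholds(d_sw, mirrored)]
        assert thr_sw == [mirror[g] for g in thr]

        cl = [c.genotype for c in calls_from_clusters(kmeans_1d(d, seed=1), d)]
        cl_sw = [c.genotype for c in calls_from_clusters(kmeans_1d(d_sw, seed=1), d_sw)]
        assert cl_sw == [mirror[g] for g in cl]

    def test_cluster_and_threshold_calls_agree_on_well_separated_data(self):
        rng = np.random.default_rng(11)
        model = synthetic.default_noise_model("Cx. pipiens")
        d = []
        for g in ["LL", "LF", "FF"] * 120:
            tta, ttt = synthetic.simulate_ct_pair(g, model, rng)
            if tta is None and ttt is None:
                continue
            di, _ = compute_delta_ct(WellReading("s", ct_tta=tta, ct_ttt=ttt))
            d.append(di)
        d = np.array(d)
        cl = np.array([c.genotype for c in calls_from_clusters(kmeans_1d(d, seed=3), d)])
        th = np.array([c.genotype for c in calls_from_thresholds(d, species_bands("Cx. pipiens"))])
        non_gap = th != "UNDETERMINED"
        agree = np.mean(cl[non_gap] == th[non_gap])
        assert agree >= 0.99


class TestAnova:
    def test_equal_groups_give_zero_f(self):
        f, dfb, dfw, p = anova_delta_by_genotype(
            [1.0, 2.0, 3.0, 1.0, 2.0, 3.0], ["LL"] * 3 + ["FF"] * 3
        )
        assert f == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_hand_computed_two_group_f(self):
        """Groups {1,2,3} and {7,8,9}: MSB = 54/1, MSW = 4/4, so F = 54 on (1, 4)."""
        f, dfb, dfw, p = anova_delta_by_genotype(
            [1, 2, 3, 7, 8, 9], ["LL"] * 3 + ["FF"] * 3
        )
        assert f == pytest.approx(54.0)
        assert (dfb, dfw) == (1, 4)

    def test_separated_clusters_give_huge_f(self):
        rng = np.random.default_rng(2)
        model = synthetic.default_noise_model("Cx. pipiens")
        d, g = [], []
        for geno in ["LL", "LF", "FF"] * 120:
            tta, ttt = synthetic.simulate_ct_pair(geno, model, rng)
            if tta is None and ttt is None:
                continue
            di, _ = compute_delta_ct(WellReading("s", ct_tta=tta, ct_ttt=ttt))
            d.append(di)
            g.append(geno)
        f, _, _, p = anova_delta_by_genotype(d, g)
        assert f > 1000
        assert p < 1e-3

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            anova_delta_by_genotype([1.0, 2.0], ["LL", "LL"])
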