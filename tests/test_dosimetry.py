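"""DVH, Dx%, homogeneity, percent error, and paired comparison oracles."""

import itertools

import numpy as np
import pytest
from scipy import stats

from adaptdose.dosimetry import (
    DVHCurve,
    compare_plans,
    dose_at_volume,
    dvh,
    homogeneity,
    metrics_report,
    percent_error,
    structure_metrics,
    wilcoxon_signed_rank,
)


class TestDVH:
    def test_uniform_dose_is_a_step_function(self):
        dose = np.full((5, 5, 5), 50.0)
        mask = np.ones((5, 5, 5), dtype=np.uint8)
        curve = dvh(dose, mask, n_bins=100)
        assert np.all(curve.volume_fraction[curve.dose_grid <= 50.0] == 1.0)
        assert curve.volume_fraction[-1] == 0.0

    def test_two_level_dose_gives_half_fraction_between_levels(self):
        dose = np.concatenate([np.full(50, 20.0), np.full(50, 60.0)]).reshape(10, 10)
        mask = np.ones((10, 10), dtype=np.uint8)
        curve = dvh(dose, mask, n_bins=200)
        mid = (curve.dose_grid > 20.0) & (curve.dose_grid <= 60.0)
        np.testing.assert_allclose(curve.volume_fraction[mid], 0.5)

    def test_curve_matches_brute_force_counting_oracle(self, rng):
        dose = rng.gamma(3.0, 8.0, size=(8, 8, 8))
        mask = (rng.random((8, 8, 8)) < 0.5).astype(np.uint8)
        mask[0, 0, 0] = 1
        curve = dvh(dose, mask, n_bins=137)
        d = dose[mask > 0]
        for t, frac in zip(curve.dose_grid, curve.volume_fraction):
            assert frac == pytest.approx((d >= t).mean(), abs=1e-12)

    def test_curve_is_monotone_non_increasing_from_one(self, rng):
        dose = rng.random((6, 6, 6)) * 70
        mask = np.ones((6, 6, 6), dtype=np.uint8)
        curve = dvh(dose, mask)
        assert curve.volume_fraction[0] == 1.0
        assert np.all(np.diff(curve.volume_fraction) <= 0)

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError, match="empty"):
            dvh(np.ones((3, 3, 3)), np.zeros((3, 3, 3), dtype=np.uint8))


class TestDoseAtVolume:
    def test_uniform_structure(self):
        assert dose_at_volume(np.full(200, 60.0), 95.0) == 60.0

    def test_sorted_voxel_oracle_one_to_hundred(self):
        doses = np.arange(1.0, 101.0)
        d95 = dose_at_volume(doses, 95.0)
        assert 5.0 <= d95 <= 6.0  # any order-statistic convention lands here

    def test_d100_is_the_minimum_dose(self, rng):
        doses = rng.random(321) * 70
        assert dose_at_volume(doses, 100.0) == pytest.approx(doses.min())

    def test_out_of_range_percent_rejected(self):
        with pytest.raises(ValueError):
            dose_at_volume(np.ones(5), 0.0)
        with pytest.raises(ValueError):
            dose_at_volume(np.ones(5), 101.0)

    def test_curve_and_voxel_paths_agree_within_one_bin(self, rng):
        # dense voxel sampling keeps adjacent order statistics within a bin,
        # so the two conventions must coincide to grid resolution
        dose = rng.random((20, 20, 20)) * 70.0
        mask = np.ones((20, 20, 20), dtype=np.uint8)
        curve = dvh(dose, mask, n_bins=1000)
        bin_width = curve.dose_grid[1] - curve.dose_grid[0]
        for x in (2.0, 50.0, 95.0, 98.0, 99.0):
            assert dose_at_volume(curve, x) == pytest.approx(
                dose_at_volume(dose.ravel(), x), abs=2 * bin_width
            )


class TestScalarMetrics:
    def test_homogeneity_hand_example(self):
        assert homogeneity(63.0, 57.0, 60.0) == pytest.approx(0.1)

    def test_homogeneity_zero_for_uniform_and_scale_invariant(self, rng):
        assert homogeneity(60.0, 60.0, 60.0) == 0.0
        d2, d98, d50 = 70.0, 61.0, 66.0
        assert homogeneity(2 * d2, 2 * d98, 2 * d50) == pytest.approx(
            homogeneity(d2, d98, d50)
        )
        with pytest.raises(ValueError):
            homogeneity(1.0, 1.0, 0.0)

    def test_percent_error_hand_example_and_symmetry(self):
        assert percent_error(72.0, 68.4, 72.0) == pytest.approx(5.0)
        assert percent_error(68.4, 72.0, 72.0) == pytest.approx(5.0)
        assert percent_error(50.0, 50.0, 72.0) == 0.0
        with pytest.raises(ValueError):
            percent_error(1.0, 1.0, 0.0)

    def test_metric_ordering_invariants_on_random_fixtures(self, rng):
        for _ in range(200):
            dose = rng.gamma(2.0, 15.0, size=(6, 6, 6))
            mask = (rng.random((6, 6, 6)) < 0.4).astype(np.uint8)
            if not mask.any():
                continue
            m = structure_metrics(dose, mask)
            assert m["Dmax"] >= m["D2%"] >= m["D50%"] >= m["D98%"] >= m["D99%"] >= 0.0
            assert m["Dmax"] >= m["Dmean"] >= 0.0


def _exact_wilcoxon_p(diffs):
    """Two-sided signed-rank p by full enumeration of the 2^n sign null."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = d.size
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    mean = n * (n + 1) / 4
    count = 0
    total = 0
    for signs in itertools.product((0, 1), repeat=n):
        w = ranks[np.array(signs, dtype=bool)].sum()
        total += 1
        if abs(w - mean) >= abs(w_obs - mean) - 1e-12:
            count += 1
    return count / total


class TestWilcoxon:
    def test_all_one_sign_n6_matches_enumeration(self):
        diffs = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        p, degenerate = wilcoxon_signed_rank(diffs)
        assert not degenerate
        assert p == pytest.approx(2 / 64)  # statistic 0 for the opposing side
        assert p == pytest.approx(_exact_wilcoxon_p(diffs))

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_exact_enumeration_for_small_samples(self, seed):
        r = np.random.default_rng(seed)
        n = int(r.integers(5, 11))
        diffs = np.round(r.normal(0, 1, n), 3)
        diffs = diffs[diffs != 0]
        if len(np.unique(np.abs(diffs))) != len(diffs):
            diffs = diffs + np.linspace(0, 1e-4, len(diffs))  # break ties
        p, _ = wilcoxon_signed_rank(diffs)
        assert p == pytest.approx(_exact_wilcoxon_p(diffs), abs=1e-10)

    def test_all_zero_differences_is_degenerate(self):
        p, degenerate = wilcoxon_signed_rank(np.zeros(8))
        assert p == 1.0 and degenerate


class TestComparePlans:
    def _fixture(self):
        rng = np.random.default_rng(0)
        shape = (6, 6, 6)
        masks = {"spinal_cord": np.zeros(shape, dtype=np.uint8)}
        masks["spinal_cord"][2:4, 2:4, 2:4] = 1
        gt, pa, pb, mlist, rx = [], [], [], [], []
        for _ in range(5):
            g = rng.random(shape) * 60
            gt.append(g)
            pa.append(g + rng.normal(0, 1.0, shape))
            pb.append(g + rng.normal(0, 3.0, shape))
            mlist.append(masks)
            rx.append(70.0)
        return gt, pa, pb, mlist, rx

    def test_identical_predictions_give_degenerate_p_one(self):
        gt, pa, _, masks, rx = self._fixture()
        table = compare_plans(gt, pa, pa, masks, ["spinal_cord"], rx)
        assert (table["p_value"] == 1.0).all()
        assert table["degenerate"].all()
        assert not table["significant"].any()

    def test_means_match_hand_computed_averages(self):
        gt, pa, pb, masks, rx = self._fixture()
        table = compare_plans(gt, pa, pb, masks, ["spinal_cord"], rx)
        row = table[(table.structure == "spinal_cord") & (table.metric == "Dmean")].iloc[0]
        sel = masks[0]["spinal_cord"] > 0
        errs = [
            abs(g[sel].mean() - p[sel].mean()) / 70.0 * 100.0 for g, p in zip(gt, pa)
        ]
        assert row.mean_err_a_pct == pytest.approx(np.mean(errs))
        assert row.n_pairs == 5

    def test_unpaired_inputs_rejected(self):
        gt, pa, pb, masks, rx = self._fixture()
        with pytest.raises(ValueError, match="paired"):
            compare_plans(gt[:-1], pa, pb, masks, ["spinal_cord"], rx)


def test_metrics_report_contains_errors_vs_ground_truth(rng):
    shape = (8, 8, 8)
    gt = rng.random(shape) * 60
    pred = gt * 1.05
    masks = {"body": np.ones(shape, dtype=np.uint8)}
    frame = metrics_report(gt, pred, masks, highest_prescription=70.0)
    row = frame.iloc[0]
    assert row["structure"] == "body"
    assert row["err_Dmean_pct"] == pytest.approx(
        abs(gt.mean() - pred.mean()) / 70.0 * 100.0
    )
    assert row["gt_Dmax"] == pytest.approx(gt.max())
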