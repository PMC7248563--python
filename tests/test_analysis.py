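"""Regional statistics, agreement analytics and nonparametric tests."""

import numpy as np
import pandas as pd
import pytest

import relaxo as rx
from relaxo.fitting import ParameterMap
from relaxo.volume_io import Modality


def _pm_from(values, valid=None):
    arr = np.asarray(values, dtype=float).reshape(-1, 1, 1)
    v = (
        np.ones(arr.shape, dtype=bool)
        if valid is None
        else np.asarray(valid, dtype=bool).reshape(arr.shape)
    )
    return ParameterMap(
        value_ms=arr,
        amplitude=np.ones_like(arr),
        secondary=None,
        residual_rms=np.zeros_like(arr),
        valid=v,
        modality=Modality.IR_T1,
    )


def _lv_single(n, label=1):
    lut = pd.DataFrame(
        [
            {"label_id": 1, "region_name": "A", "hemisphere": "none"},
            {"label_id": 2, "region_name": "B", "hemisphere": "none"},
        ]
    )
    labels = np.full((n, 1, 1), label, dtype=np.uint16)
    return rx.LabelVolume(labels=labels, lut=lut)


class TestRegionMeans:
    def test_uniform_region(self):
        stats = rx.region_means(_pm_from([1200.0] * 5), _lv_single(5))
        row = stats.set_index("label_id").loc[1]
        assert row.mean_ms == 1200.0 and row.sd_ms == 0.0 and row.n_valid_voxels == 5

    def test_sample_sd_convention(self):
        stats = rx.region_means(_pm_from([10.0, 20.0, 30.0]), _lv_single(3))
        row = stats.set_index("label_id").loc[1]
        assert row.mean_ms == pytest.approx(20.0)
        assert row.sd_ms == pytest.approx(10.0)  # n-1 denominator

    def test_invalid_voxels_excluded(self):
        stats = rx.region_means(
            _pm_from([100.0, 999.0, 300.0], valid=[True, False, True]), _lv_single(3)
        )
        row = stats.set_index("label_id").loc[1]
        assert row.n_valid_voxels == 2 and row.mean_ms == pytest.approx(200.0)

    def test_absent_region_flagged_not_dropped(self):
        stats = rx.region_means(_pm_from([5.0, 5.0]), _lv_single(2, label=1))
        row = stats.set_index("label_id").loc[2]
        assert row.absent and row.n_valid_voxels == 0 and np.isnan(row.mean_ms)

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            rx.region_means(_pm_from([1.0, 2.0]), _lv_single(3))


class TestBlandAltman:
    def test_identical_pairs(self):
        mean, sd, (lo, hi) = rx.bland_altman([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert mean == 0.0 and sd == 0.0 and lo == 0.0 and hi == 0.0

    def test_hand_computed_example(self):
        mean, sd, (lo, hi) = rx.bland_altman([100.0, 200.0], [110.0, 190.0])
        assert mean == pytest.approx(0.0)
        assert sd == pytest.approx(14.142, abs=1e-3)
        assert lo == pytest.approx(-28.284, abs=1e-3)
        assert hi == pytest.approx(28.284, abs=1e-3)

    def test_translation_shifts_mean_only(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=20), rng.normal(size=20)
        m0, s0, _ = rx.bland_altman(x, y)
        m1, s1, _ = rx.bland_altman(x, y + 5.0)
        assert m1 == pytest.approx(m0 - 5.0)
        assert s1 == pytest.approx(s0)

    def test_two_sd_limits_cover_sim_normal(self):
        # ±2 SD spans ~95.4% of i.i.d. normal differences
        rng = np.random.default_rng(42)
        d = rng.normal(0.0, 3.0, size=1000)
        _, _, (lo, hi) = rx.bland_altman(d, np.zeros_like(d))
        coverage = np.mean((d >= lo) & (d <= hi))
        assert coverage >= 0.93


class TestRegression:
    def test_exact_line(self):
        slope, intercept, r2, _ = rx.regression_to_identity(
            [0.0, 1.0, 2.0], [1.0, 3.0, 5.0]
        )
        assert slope == pytest.approx(2.0)
        assert intercept == pytest.approx(1.0)
        assert r2 == pytest.approx(1.0)

    def test_identity_input(self):
        x = np.array([1.0, 2.0, 4.0])
        slope, intercept, r2, mpe = rx.regression_to_identity(x, x)
        assert slope == pytest.approx(1.0) and intercept == pytest.approx(0.0)
        assert r2 == pytest.approx(1.0) and mpe == pytest.approx(0.0)

    def test_symmetric_percent_error_formula(self):
        # |x-y| / ((x+y)/2) * 100 for the single pair (100, 102)
        assert rx.mean_percent_error([100.0], [102.0]) == pytest.approx(
            2.0 / 101.0 * 100.0
        )

    def test_constant_x_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            rx.regression_to_identity([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])


class TestMannWhitney:
    def test_exact_small_sample(self):
        u, p = rx.mann_whitney_u([1.0, 2.0], [3.0, 4.0])
        assert u == 0.0
        assert p == pytest.approx(1.0 / 3.0)  # 2 of C(4,2)=6 splits as extreme

    def test_identical_multisets(self):
        _, p = rx.mann_whitney_u([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == pytest.approx(1.0)

    def test_swap_symmetry(self):
        x, y = [1.0, 5.0, 2.0], [4.0, 7.0]
        _, p1 = rx.mann_whitney_u(x, y)
        _, p2 = rx.mann_whitney_u(y, x)
        assert p1 == pytest.approx(p2)

    def test_large_sample_delegates_to_approximation(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, 40)
        y = rng.normal(1.5, 1, 40)
        _, p = rx.mann_whitney_u(x, y)
        assert p < 1e-6

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError, match="nonempty"):
            rx.mann_whitney_u([], [1.0])


class TestWilcoxon:
    def test_exact_small_sample(self):
        w, p = rx.wilcoxon_signed_rank([1.0, 2.0, 3.0])
        assert w == 0.0
        assert p == pytest.approx(0.25)  # 2 of 2^3 = 8 sign patterns

    def test_sign_flip_symmetry(self):
        d = np.array([1.0, -2.0, 3.5, 0.5])
        _, p1 = rx.wilcoxon_signed_rank(d)
        _, p2 = rx.wilcoxon_signed_rank(-d)
        assert p1 == pytest.approx(p2)

    def test_single_nonzero_difference(self):
        _, p = rx.wilcoxon_signed_rank([0.0, 0.0, 2.5])
        assert p == pytest.approx(1.0)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            rx.wilcoxon_signed_rank([0.0, 0.0])


class TestShapiroGate:
    def test_two_point_distribution_flagged_non_normal(self):
        rng = np.random.default_rng(2)
        x = rng.choice([0.0, 1.0], size=200)
        assert rx.shapiro_wilk(x) < 0.05

    def test_null_calibration_p_uniform(self):
        # under normal data the p-value should be ~Uniform(0,1)
        rng = np.random.default_rng(3)
        ps = np.array([rx.shapiro_wilk(rng.normal(size=100)) for _ in range(200)])
        grid = np.linspace(0, 1, 101)
        ecdf = np.array([(ps <= g).mean() for g in grid])
        assert np.max(np.abs(ecdf - grid)) < 0.1

    def test_constant_sample_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            rx.shapiro_wilk([5.0, 5.0, 5.0, 5.0])

    def test_size_limits(self):
        with pytest.raises(ValueError):
            rx.shapiro_wilk([1.0, 2.0])


class TestScanRescan:
    def _stats(self, means, sds):
        return pd.DataFrame(
            {
                "label_id": np.arange(1, len(means) + 1),
                "region_name": [f"R{i}" for i in range(len(means))],
                "n_valid_voxels": 10,
                "mean_ms": means,
                "sd_ms": sds,
                "absent": False,
            }
        )

    def test_identical_scans(self):
        s = self._stats([1000.0, 1200.0, 1500.0, 900.0], [30.0, 40.0, 50.0, 20.0])
        rep = rx.scan_rescan_report(s, s.copy())
        assert rep.all_within_2sd
        assert rep.wilcoxon_p is None  # all-zero differences: "no difference"
        assert rep.slope == pytest.approx(1.0) and rep.r_squared == pytest.approx(1.0)

    def test_three_sd_deviation_flagged(self):
        s1 = self._stats([1000.0, 1200.0, 1500.0], [30.0, 40.0, 50.0])
        s2 = s1.copy()
        s2.loc[0, "mean_ms"] += 3 * 30.0
        rep = rx.scan_rescan_report(s1, s2)
        assert not rep.table["within_2sd"].iloc[0]
        assert rep.table["within_2sd"].iloc[1:].all()

    def test_lut_mismatch_rejected(self):
        s1 = self._stats([1.0, 2.0, 3.0], [0.1, 0.1, 0.1])
        s2 = s1.copy()
        s2["label_id"] = [4, 5, 6]
        with pytest.raises(ValueError, match="lut"):
            rx.scan_rescan_report(s1, s2)


class TestCompareRegions:
    def test_near_identical_pipelines_report(self):
        rng = np.random.default_rng(4)
        x = rng.uniform(900, 2000, size=29)
        y = x * (1 + rng.normal(0, 0.002, size=29))
        rep = rx.compare_regions(x, y)
        assert rep.n_pairs == 29
        assert rep.mean_percent_error < 1.0
        assert rep.slope == pytest.approx(1.0, abs=0.05)
        assert rep.r_squared > 0.99
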