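"""Phantom generation, signal simulation and perturbation properties."""

import numpy as np
import pytest

import relaxo as rx
from relaxo.phantom import VENTRICLE_REGIONS, _brain_envelope


class TestLabelPhantom:
    def test_29_distinct_regions_on_default_grid(self):
        lv = rx.make_label_phantom(rx.PhantomSpec(grid_shape=(64, 64, 32), seed=0))
        present = set(np.unique(lv.labels)) - {0}
        assert present == set(range(1, 30))

    def test_deterministic_given_seed(self, std_spec, std_labels):
        again = rx.make_label_phantom(rx.PhantomSpec(grid_shape=(32, 32, 16), seed=1))
        np.testing.assert_array_equal(again.labels, std_labels.labels)

    def test_ventricles_smaller_than_every_cortex_region(self, std_labels):
        ids, counts = np.unique(std_labels.labels, return_counts=True)
        size = dict(zip(ids.tolist(), counts.tolist()))
        names = std_labels.lut.set_index("region_name")["label_id"]
        vent = [size[names[n]] for n in VENTRICLE_REGIONS]
        cortex = [
            size[int(lid)]
            for name, lid in names.items()
            if "cortex" in name.lower() and name not in VENTRICLE_REGIONS
        ]
        assert max(vent) < min(cortex)

    def test_region_sizes_track_target_ratios(self, std_labels, std_spec):
        ids, counts = np.unique(std_labels.labels, return_counts=True)
        realized = dict(zip(ids.tolist(), counts.tolist()))
        n_fg = sum(v for k, v in realized.items() if k > 0)
        total_w = sum(std_spec.target_size_ratios.values())
        for lid, w in std_spec.target_size_ratios.items():
            target = max(8, n_fg * w / total_w)
            assert 0.5 * target <= realized[lid] <= 1.5 * target

    def test_too_small_grid_raises(self):
        with pytest.raises(ValueError, match="too small"):
            rx.make_label_phantom(rx.PhantomSpec(grid_shape=(6, 6, 4), seed=0))


class TestTruthMaps:
    def test_piecewise_constant_and_background_zero(self, std_labels, std_spec):
        t1, t2, pd_map = rx.truth_maps(std_labels, std_spec)
        bg = std_labels.labels == 0
        assert np.all(t1[bg] == 0) and np.all(t2[bg] == 0) and np.all(pd_map[bg] == 0)
        lid = int(std_labels.lut["label_id"].iloc[0])
        truth = std_spec.region_truth[lid]
        mask = std_labels.labels == lid
        assert np.all(t1[mask] == truth.t1_ms)
        assert np.all(t2[mask] == truth.t2_ms)
        # at most one distinct value per region
        assert len(np.unique(t1[t1 > 0])) <= 29
        assert len(np.unique(t2[t2 > 0])) <= 29

    def test_missing_truth_entry_raises(self, std_labels, std_spec):
        truth = dict(std_spec.region_truth)
        # spec validation forbids dropping a label, so bypass via direct call
        incomplete = rx.PhantomSpec(grid_shape=std_spec.grid_shape, seed=1)
        incomplete.region_truth = {
            k: v for k, v in truth.items() if k != 1
        }
        with pytest.raises(ValueError, match=r"\b1\b"):
            rx.truth_maps(std_labels, incomplete)


class TestSimulation:
    def test_ir_null_point(self):
        t1 = np.full((1, 1, 1), 1000.0)
        pd_map = np.full((1, 1, 1), 1000.0)
        prot = rx.AcquisitionProtocol(
            modality=rx.Modality.IR_T1,
            times_ms=(100.0, 1000.0 * np.log(2.0), 5000.0),
            tr_ms=6500.0,
        )
        s = rx.simulate_ir_series(t1, pd_map, prot, noise_sigma=0.0)
        assert abs(s.data[0, 0, 0, 1]) < 1e-3  # null point at TI = T1 ln 2

    def test_zero_noise_ir_equals_model(self, std_truth, noiseless_ir_series):
        t1, _, pd_map = std_truth
        prot = rx.default_ir_protocol()
        fg = np.argwhere(pd_map > 0)[::97]
        for i, j, k in fg:
            expected = rx.ir_model(prot.times, pd_map[i, j, k], 2.0, t1[i, j, k])
            np.testing.assert_allclose(
                noiseless_ir_series.data[i, j, k], expected, rtol=1e-5
            )

    def test_me_single_decay_value(self):
        t2 = np.full((1, 1, 1), 50.0)
        pd_map = np.full((1, 1, 1), 100.0)
        prot = rx.AcquisitionProtocol(
            modality=rx.Modality.MULTIECHO_T2, times_ms=(10.0, 50.0, 100.0), tr_ms=600.0
        )
        s = rx.simulate_multiecho_series(t2, pd_map, prot, noise_sigma=0.0)
        assert s.data[0, 0, 0, 1] == pytest.approx(100.0 / np.e, rel=1e-5)

    def test_rician_floor_mean_at_zero_signal(self):
        # mean of the magnitude of pure complex noise is sigma * sqrt(pi/2)
        sigma = 25.0
        pd_map = np.zeros((40, 40, 10))
        t2 = np.zeros_like(pd_map)
        s = rx.simulate_multiecho_series(
            t2, pd_map, rx.default_multiecho_protocol(), noise_sigma=sigma, seed=11
        )
        samples = s.data.ravel()  # 16000 voxels x 28 echoes
        expected = sigma * np.sqrt(np.pi / 2)
        se = sigma * np.sqrt(2 - np.pi / 2) / np.sqrt(samples.size)
        assert abs(samples.mean() - expected) < 3 * se

    def test_modality_mismatch_rejected(self, std_truth):
        t1, t2, pd_map = std_truth
        with pytest.raises(ValueError, match="IR_T1"):
            rx.simulate_ir_series(t1, pd_map, rx.default_multiecho_protocol())
        with pytest.raises(ValueError, match="MULTIECHO_T2"):
            rx.simulate_multiecho_series(t2, pd_map, rx.default_ir_protocol())

    def test_negative_sigma_rejected(self, std_truth):
        t1, _, pd_map = std_truth
        with pytest.raises(ValueError, match="noise_sigma"):
            rx.simulate_ir_series(
                t1, pd_map, rx.default_ir_protocol(), noise_sigma=-1.0
            )


class TestCenterEffect:
    def test_identity_effect_bit_exact(self, noiseless_ir_series):
        out = rx.apply_center_effect(noiseless_ir_series, rx.CenterEffect())
        np.testing.assert_array_equal(out.data, noiseless_ir_series.data)

    def test_gain_doubles_every_voxel(self, noiseless_ir_series):
        out = rx.apply_center_effect(noiseless_ir_series, rx.CenterEffect(gain=2.0))
        np.testing.assert_allclose(out.data, 2.0 * noiseless_ir_series.data, rtol=1e-6)

    def test_fitted_t1_invariant_under_gain(self, std_truth):
        # the amplitude parameter absorbs any global scaling
        t1, _, pd_map = std_truth
        block = (slice(10, 14), slice(10, 14), slice(6, 8))
        s = rx.simulate_ir_series(
            t1[block], pd_map[block], rx.default_ir_protocol(), noise_sigma=0.0
        )
        scaled = rx.apply_center_effect(s, rx.CenterEffect(gain=3.0))
        opts = rx.FitOptions(min_signal=1.0)
        pm1, pm2 = rx.fit_t1_map(s, opts), rx.fit_t1_map(scaled, opts)
        m = pm1.valid & pm2.valid
        assert m.any()
        np.testing.assert_allclose(pm1.value_ms[m], pm2.value_ms[m], rtol=1e-4)
        np.testing.assert_allclose(pm2.amplitude[m], 3.0 * pm1.amplitude[m], rtol=1e-3)

    def test_invalid_effect_rejected(self):
        with pytest.raises(ValueError):
            rx.CenterEffect(gain=0.0)
        with pytest.raises(ValueError):
            rx.CenterEffect(bias_field_amplitude=1.0)


class TestPerturbLabels:
    def test_zero_magnitude_is_identity(self, std_labels):
        out = rx.perturb_labels(std_labels, 0.0, seed=3)
        np.testing.assert_array_equal(out.labels, std_labels.labels)

    def test_negative_magnitude_rejected(self, std_labels):
        with pytest.raises(ValueError, match="magnitude"):
            rx.perturb_labels(std_labels, -0.5)

    def test_labels_stay_within_lut(self, std_labels):
        out = rx.perturb_labels(std_labels, 2.0, seed=4)
        present = set(np.unique(out.labels)) - {0}
        assert present <= set(std_labels.lut["label_id"])

    def test_dice_decreases_with_magnitude(self, std_labels):
        # mean per-region overlap with the original parcellation must fall
        # monotonically as the displacement amplitude grows
        ids = std_labels.lut["label_id"].tolist()
        mags = [0.5, 1.0, 2.0, 4.0]
        mean_dice = []
        for mag in mags:
            vals = []
            for seed in range(10):
                pert = rx.perturb_labels(std_labels, mag, seed=seed)
                vals.extend(rx.dice_score(std_labels, pert, l) for l in ids)
            mean_dice.append(np.mean(vals))
        assert all(a > b for a, b in zip(mean_dice, mean_dice[1:]))


def test_envelope_fills_reasonable_fraction():
    env = _brain_envelope((32, 32, 16))
    frac = env.mean()
    assert 0.3 < frac < 0.5  # ellipsoid of semi-axes 0.45 per extent
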