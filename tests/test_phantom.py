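"""Synthetic phantom cohort: determinism, geometry, and dose-model properties."""

import numpy as np
import pytest

from adaptdose.phantom import (
    PhantomConfig,
    SparingProfile,
    _rasterize_session,
    _sample_geometry,
    generate_anatomy,
    generate_cohort,
    generate_plan_pair,
    load_cohort,
    sample_sparing_profile,
    synthesize_dose,
)

CFG = PhantomConfig(grid_shape=(32, 32, 24))


class TestAnatomy:
    def test_fixed_seed_regenerates_bit_identical_session(self):
        a = generate_anatomy(CFG, np.random.default_rng(11))
        b = generate_anatomy(CFG, np.random.default_rng(11))
        np.testing.assert_array_equal(a.ct, b.ct)
        np.testing.assert_array_equal(a.ptv_map, b.ptv_map)
        for name in a.oar_masks:
            np.testing.assert_array_equal(a.oar_masks[name], b.oar_masks[name])

    def test_ptv_count_stays_within_configured_range(self):
        cfg = PhantomConfig(grid_shape=(32, 32, 24), n_ptvs_range=(2, 3))
        rng = np.random.default_rng(0)
        for _ in range(20):
            geom = _sample_geometry(cfg, rng)
            assert 2 <= len(geom.ptvs) <= 3

    def test_masks_are_binary_and_inside_the_body(self):
        s = generate_anatomy(CFG, np.random.default_rng(2))
        body = s.oar_masks["body"]
        for name, mask in s.oar_masks.items():
            assert set(np.unique(mask)) <= {0, 1}
            assert not np.any((mask > 0) & (body == 0)), name
        assert not np.any((s.ptv_map > 0) & (body == 0))

    def test_prescriptions_stay_in_configured_range(self):
        s = generate_anatomy(CFG, np.random.default_rng(3))
        rx = s.ptv_map[s.ptv_map > 0]
        assert rx.min() >= CFG.prescription_range_gy[0]
        assert rx.max() <= CFG.prescription_range_gy[1]

    def test_too_small_grid_is_rejected(self):
        with pytest.raises(ValueError, match="grid too small"):
            PhantomConfig(grid_shape=(8, 8, 8))


class TestDoseModel:
    def _anatomy(self, seed=4):
        return generate_anatomy(CFG, np.random.default_rng(seed))

    def test_ptv_voxels_receive_their_prescription_without_noise(self):
        anat = self._anatomy()
        dose = synthesize_dose(anat, SparingProfile({}), CFG, noise_rng=None)
        sel = anat.ptv_map > 0
        np.testing.assert_allclose(dose[sel], anat.ptv_map[sel], rtol=1e-6)

    def test_unspared_falloff_is_monotone_along_rays(self):
        anat = self._anatomy()
        dose = synthesize_dose(anat, SparingProfile({}), CFG, noise_rng=None)
        ptv = anat.ptv_map > 0
        com = np.round(np.mean(np.argwhere(ptv), axis=0)).astype(int)
        for axis in range(3):
            idx = [com[0], com[1], com[2]]
            line = []
            while 0 <= idx[axis] < dose.shape[axis]:
                if not ptv[tuple(idx)]:
                    line.append(dose[tuple(idx)])
                idx[axis] += 1
            diffs = np.diff(line)
            assert np.all(diffs <= 1e-5), f"axis {axis} not non-increasing"

    def test_doubling_sparing_strictly_decreases_oar_mean_dose(self):
        anat = self._anatomy()
        name = "parotid_l"
        d1 = synthesize_dose(anat, SparingProfile({name: 0.3}), CFG, noise_rng=None)
        d2 = synthesize_dose(anat, SparingProfile({name: 0.6}), CFG, noise_rng=None)
        sel = anat.oar_masks[name] > 0
        assert sel.any()
        assert d2[sel].mean() < d1[sel].mean()

    def test_spared_oar_dose_below_unspared_counterfactual(self):
        anat = self._anatomy()
        profile = sample_sparing_profile(CFG, np.random.default_rng(8))
        spared = synthesize_dose(anat, profile, CFG, noise_rng=None)
        baseline = synthesize_dose(anat, SparingProfile({}), CFG, noise_rng=None)
        for name, sigma in profile.strengths.items():
            sel = anat.oar_masks[name] > 0
            if sigma > 0.05 and sel.any():
                assert spared[sel].mean() < baseline[sel].mean()

    def test_ptv_d95_within_noise_of_prescription(self):
        from adaptdose.dosimetry import dose_at_volume

        pair = generate_plan_pair(CFG, np.random.default_rng(21), "P")
        for s in (pair.pre, pair.adaptive):
            top = s.ptv_map.max()
            sel = s.ptv_map >= top
            d95 = dose_at_volume(s.dose[sel], 95.0)
            assert abs(d95 - top) < 4 * CFG.noise_amplitude_gy

    def test_empty_ptv_rejected(self):
        anat = self._anatomy()
        anat.ptv_map = np.zeros_like(anat.ptv_map)
        with pytest.raises(ValueError, match="PTV"):
            synthesize_dose(anat, SparingProfile({}), CFG)


class TestPlanPairs:
    def test_zero_deformation_reproduces_the_pretreatment_session(self):
        cfg = PhantomConfig(
            grid_shape=(32, 32, 24),
            ptv_shrink_range=(1.0, 1.0),
            structure_shift_sigma_mm=0.0,
            gland_shrink_range=(1.0, 1.0),
            noise_amplitude_gy=0.0,
        )
        pair = generate_plan_pair(cfg, np.random.default_rng(5), "P")
        np.testing.assert_array_equal(pair.pre.ptv_map, pair.adaptive.ptv_map)
        np.testing.assert_array_equal(pair.pre.dose, pair.adaptive.dose)
        for name in pair.pre.oar_masks:
            np.testing.assert_array_equal(
                pair.pre.oar_masks[name], pair.adaptive.oar_masks[name]
            )

    def test_fixed_shrink_factor_scales_ptv_voxel_count(self):
        cfg = PhantomConfig(
            grid_shape=(48, 48, 32),
            ptv_shrink_range=(0.8, 0.8),
            structure_shift_sigma_mm=0.0,
            noise_amplitude_gy=0.0,
        )
        ratios = []
        for seed in range(5):
            pair = generate_plan_pair(cfg, np.random.default_rng(seed), "P")
            ratios.append(
                (pair.adaptive.ptv_map > 0).sum() / (pair.pre.ptv_map > 0).sum()
            )
        # the shrink factor is a volume factor, so counts scale by ~0.8
        assert abs(np.mean(ratios) - 0.8) < 0.1

    def test_sessions_share_patient_and_grid(self):
        pair = generate_plan_pair(CFG, np.random.default_rng(6), "P042")
        assert pair.pre.patient_id == pair.adaptive.patient_id == "P042"
        assert pair.pre.shape == pair.adaptive.shape
        assert pair.pre.session_kind == "pretreatment"
        assert pair.adaptive.session_kind == "adaptive"


class TestCohort:
    def test_patients_are_seed_independent_and_reproducible(self, tmp_path):
        pairs = generate_cohort(3, CFG, seed=77)
        again = generate_cohort(3, CFG, seed=77)
        for a, b in zip(pairs, again):
            np.testing.assert_array_equal(a.pre.dose, b.pre.dose)
        assert not np.array_equal(pairs[0].pre.dose, pairs[1].pre.dose)

    def test_cohort_round_trips_through_disk(self, tmp_path):
        pairs = generate_cohort(2, CFG, seed=5, out_dir=tmp_path)
        loaded = load_cohort(tmp_path)
        assert [p.patient_id for p in loaded] == [p.patient_id for p in pairs]
        np.testing.assert_array_equal(loaded[1].adaptive.dose, pairs[1].adaptive.dose)

    def test_sparing_intent_is_recoverable_from_the_preplan(self):
        """Across a cohort the pre-plan OAR dose ratio predicts the adaptive
        one — the learning signal the secondary head is meant to exploit."""
        cfg = PhantomConfig(grid_shape=(32, 32, 24))
        pre_ratio, ad_ratio = [], []
        for seed in range(10):
            pair = generate_plan_pair(cfg, np.random.default_rng(1000 + seed), "P")
            for name in ("parotid_l", "parotid_r", "oral_cavity"):
                for session, out in ((pair.pre, pre_ratio), (pair.adaptive, ad_ratio)):
                    sel = session.oar_masks[name] > 0
                    baseline = synthesize_dose(
                        session, SparingProfile({}), cfg, noise_rng=None
                    )
                    if sel.any() and baseline[sel].mean() > 1.0:
                        out.append(session.dose[sel].mean() / baseline[sel].mean())
                    else:
                        out.append(np.nan)
        pre_ratio, ad_ratio = np.asarray(pre_ratio), np.asarray(ad_ratio)
        ok = np.isfinite(pre_ratio) & np.isfinite(ad_ratio)
        assert ok.sum() >= 15
        r = np.corrcoef(pre_ratio[ok], ad_ratio[ok])[0, 1]
        assert r > 0.7
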