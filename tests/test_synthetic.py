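"""Phantom generator, perturbation operators and cohort simulation."""

import numpy as np
import pandas as pd
import pytest
from dataclasses import replace

from radpipe.preprocessing import resample_mask
from radpipe.synthetic import (DEFAULT_PHANTOM, SMALL_PHANTOM, CohortSpec,
                               PhantomSpec, attenuation_variant,
                               delineation_variants, generate_cohort,
                               generate_phantom, motion_variant,
                               pairwise_design_auc, simulate_feature_table)
from radpipe.volumes import ImageVolume, ROIMask


def _dice(a, b):
    return 2.0 * (a & b).sum() / (a.sum() + b.sum())


class TestGeneratePhantom:
    def test_mask_matches_analytic_ellipsoid_enumeration(self, default_phantom):
        _, _, mask, _ = default_phantom
        spec = DEFAULT_PHANTOM
        count = 0
        for i in range(spec.grid_shape[0]):
            for j in range(spec.grid_shape[1]):
                for k in range(spec.grid_shape[2]):
                    p = (i * spec.voxel_spacing_mm[0], j * spec.voxel_spacing_mm[1],
                         k * spec.voxel_spacing_mm[2])
                    s = sum(((p[a] - spec.tumour_centre_mm[a]) / spec.tumour_radii_mm[a]) ** 2
                            for a in range(3))
                    count += s <= 1.0
        assert mask.voxel_count() == count

    def test_zero_heterogeneity_gives_exactly_uniform_tumour(self):
        spec = replace(DEFAULT_PHANTOM, heterogeneity_amplitude=0.0)
        pet, _, mask, _ = generate_phantom(spec)
        assert np.all(pet.values[mask.values] == spec.suv_tumour_mean)

    def test_same_seed_is_bit_identical(self):
        a = generate_phantom(DEFAULT_PHANTOM)
        b = generate_phantom(DEFAULT_PHANTOM)
        assert np.array_equal(a[0].values, b[0].values)
        assert np.array_equal(a[1].values, b[1].values)
        assert np.array_equal(a[2].values, b[2].values)

    def test_size_gate_presets(self):
        _, _, big, _ = generate_phantom(DEFAULT_PHANTOM)
        _, _, small, _ = generate_phantom(SMALL_PHANTOM)
        assert resample_mask(big).voxel_count() >= 72
        assert resample_mask(small).voxel_count() < 72

    def test_tumour_outside_grid_rejected(self):
        with pytest.raises(ValueError, match="outside grid"):
            PhantomSpec(tumour_centre_mm=(5.0, 86.0, 77.0))

    def test_ct_exercises_hu_exclusion(self, default_phantom):
        _, ct, mask, _ = default_phantom
        inside = ct.values[mask.values]
        assert (inside == 40.0).any() and (inside == 700.0).any()


class TestDelineationVariants:
    def test_step_edge_threshold_recovers_true_mask(self):
        spec = replace(DEFAULT_PHANTOM, heterogeneity_amplitude=0.0,
                       suv_background=0.1)
        pet, _, mask, _ = generate_phantom(spec)
        _, thr, _ = delineation_variants(pet, mask, threshold_pct=0.40, seed=0)
        assert np.array_equal(thr.values, mask.values)

    def test_default_variants_overlap_but_differ(self, default_phantom):
        pet, _, mask, _ = default_phantom
        variants = delineation_variants(pet, mask, threshold_pct=0.34, seed=3)
        arrs = [v.values for v in variants]
        for i in range(3):
            for j in range(i + 1, 3):
                d = _dice(arrs[i], arrs[j])
                assert 0.6 < d < 1.0

    def test_threshold_out_of_range_rejected(self, default_phantom):
        pet, _, mask, _ = default_phantom
        with pytest.raises(ValueError, match="0.27"):
            delineation_variants(pet, mask, threshold_pct=0.5)


class TestAttenuationVariant:
    def test_zero_strength_is_identity(self, default_phantom):
        pet = default_phantom[0]
        out = attenuation_variant(pet, 0.0, seed=1)
        assert np.array_equal(out.values, pet.values)

    def test_roi_mean_ratio_preserved(self, default_phantom):
        pet, _, mask, _ = default_phantom
        out = attenuation_variant(pet, 0.25, seed=5, roi=mask)
        ratio = out.values[mask.values] / pet.values[mask.values]
        assert abs(ratio.mean() - 1.0) < 0.02

    def test_negative_strength_rejected(self, default_phantom):
        with pytest.raises(ValueError):
            attenuation_variant(default_phantom[0], -0.1)


class TestMotionVariant:
    def test_zero_blur_is_identity(self, default_phantom):
        pet = default_phantom[0]
        out = motion_variant(pet, (0.0, 0.0, 0.0))
        assert np.array_equal(out.values, pet.values)

    def test_blur_cannot_raise_suvmax(self, default_phantom):
        pet = default_phantom[0]
        out = motion_variant(pet, (3.0, 3.0, 12.0))
        assert out.values.max() <= pet.values.max() + 1e-12

    def test_mass_conserved_on_padded_grid(self, default_phantom):
        pet = default_phantom[0]
        padded = ImageVolume(np.pad(pet.values, 12), pet.spacing_mm)
        out = motion_variant(padded, (3.0, 3.0, 12.0))
        rel = abs(out.values.sum() - padded.values.sum()) / padded.values.sum()
        assert rel < 1e-3

    def test_negative_fwhm_rejected(self, default_phantom):
        with pytest.raises(ValueError):
            motion_variant(default_phantom[0], (-1.0, 0.0, 0.0))


class TestCohorts:
    def test_null_design_has_half_events_and_censoring_zero(self):
        spec = CohortSpec(n_patients=24, seed=11, outcome_coefficients=(0.0,),
                          intercept=0.0, censoring_rate=0.0)
        features, outcomes, truth = generate_cohort(spec)
        assert len(features) == 24
        assert (outcomes["efs_event"] == 1).all()  # no censoring -> all events observed
        latent = (outcomes["efs_months"] <= spec.horizon_months).mean()
        # binomial 3-sigma band around 0.5 at n=24
        assert abs(latent - 0.5) <= 3 * np.sqrt(0.25 / 24)

    def test_unknown_outcome_feature_rejected(self):
        spec = CohortSpec(outcome_feature_names=("nope/feature",),
                          outcome_coefficients=(1.0,))
        with pytest.raises(ValueError, match="unknown outcome feature"):
            generate_cohort(spec)

    def test_design_auc_matches_brute_force_pairs(self, rng):
        lp = rng.normal(size=40)
        labels = rng.random(40) < 0.5
        labels[0], labels[1] = True, False  # both classes present
        expected = np.mean([
            1.0 if a > b else (0.5 if a == b else 0.0)
            for a in lp[labels] for b in lp[~labels]])
        assert pairwise_design_auc(lp, labels) == pytest.approx(expected, abs=1e-12)


class TestSimulateFeatureTable:
    def test_deterministic_and_design_auc_near_calibration(self):
        X1, y1, i1 = simulate_feature_table(2000, seed=3)
        X2, y2, i2 = simulate_feature_table(2000, seed=3)
        pd.testing.assert_frame_equal(X1, X2)
        assert i1["design_auc"] == i2["design_auc"]
        # the preset effect size targets a design AUC of 0.75
        assert abs(i1["design_auc"] - 0.75) < 0.03

    def test_informative_blocks_are_correlated(self):
        X, _, info = simulate_feature_table(500, seed=4)
        c = X[["factor0_copy0", "factor0_copy1"]].corr().iloc[0, 1]
        assert c > 0.8
        cn = X[["noise0", "noise1"]].corr().iloc[0, 1]
        assert abs(cn) < 0.2
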