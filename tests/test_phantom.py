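"""Phantom generator: anatomy, plans, planted response, cohort draws."""

import numpy as np
import pytest

from hepajac.eqd2 import FractionationScheme, eqd2_map
from hepajac.grids import Grid3D
from hepajac.jacobian import jacobian_determinant
from hepajac.phantom import (
    CANCER_PROBS,
    CANCER_TYPES,
    FRACTION_NUMBERS,
    PRESCRIPTIONS_GY,
    CohortConfig,
    ResponseParams,
    generate_anatomy,
    generate_cohort,
    generate_plan,
    generate_response,
    load_case,
)

SHAPE, SPACING = (48, 48, 36), (4.0, 4.0, 5.0)


class TestAnatomy:
    def test_deterministic_given_seed(self):
        a = generate_anatomy(9, SHAPE, SPACING)
        b = generate_anatomy(9, SHAPE, SPACING)
        np.testing.assert_array_equal(a[0].values, b[0].values)
        np.testing.assert_array_equal(a[1].labels, b[1].labels)
        np.testing.assert_array_equal(a[2].labels, b[2].labels)

    def test_all_segments_present_and_disjoint(self, small_anatomy):
        _, labels, vessels = small_anatomy
        present = set(np.unique(labels.labels))
        assert {1, 2, 3, 4, 5} <= present
        assert (vessels.labels > 0).sum() > 0
        # segments partition the liver: every liver voxel has exactly one label
        assert np.array_equal(labels.liver_mask(), labels.labels > 0)

    def test_vessels_inside_liver(self, small_anatomy):
        _, labels, vessels = small_anatomy
        assert np.all(labels.liver_mask()[vessels.labels > 0])

    def test_liver_fraction_in_range(self, small_anatomy):
        _, labels, _ = small_anatomy
        assert 0.10 <= labels.liver_mask().mean() <= 0.40

    def test_too_small_volume_rejected(self):
        with pytest.raises(ValueError):
            generate_anatomy(0, (16, 16, 16), (4, 4, 4))


class TestPlan:
    def test_max_dose_within_prescription_band(self, small_anatomy):
        _, labels, _ = small_anatomy
        dose = generate_plan(labels, 5, 67.5, 15, seed=2)
        assert 67.5 <= dose.values.max() <= 1.1 * 67.5

    def test_far_field_below_bath(self, small_anatomy):
        _, labels, _ = small_anatomy
        dose = generate_plan(labels, 5, 100.0, 10, seed=2)
        hot = np.unravel_index(np.argmax(dose.values), dose.shape)
        pt = np.stack(
            np.meshgrid(*(np.arange(n) * s for n, s in zip(dose.shape, dose.spacing)),
                        indexing="ij"), axis=-1,
        )
        d = np.linalg.norm(pt - pt[hot], axis=-1)
        far = dose.values[d > 120.0]
        # beyond the falloff, only the (corridor) bath remains: < 15 Gy
        assert far.max() < 15.0 + 1e-6

    @pytest.mark.parametrize("target", [2, 3, 4, 5])
    def test_target_region_is_hottest(self, small_anatomy, target):
        # among the targetable regions; the central caudate-like segment 1
        # legitimately catches dose from any nearby focus
        _, labels, _ = small_anatomy
        dose = generate_plan(labels, target, 60.0, 15, seed=4)
        means = {k: dose.values[labels.labels == k].mean() for k in (2, 3, 4, 5)}
        assert means[target] == max(means.values())


class TestResponse:
    def _base(self, small_anatomy, params, eqd2_vals, t=147.0, seed=5):
        pre, labels, vessels = small_anatomy
        eqd2 = Grid3D(eqd2_vals, labels.spacing, labels.origin)
        return generate_response(labels, eqd2, t, params, seed, pre, vessels)

    def test_zero_dose_no_noise_is_identity(self, small_anatomy):
        # bare dose-only configuration: no noise, no compensation and no
        # dose-independent remodeling
        params = ResponseParams(patient_sd=0, voxel_noise_sd=0, compensation_gain=0,
                                baseline_remodeling=0)
        dv, dvf, post_ct, post_labels, _ = self._base(
            small_anatomy, params, np.zeros(SHAPE)
        )
        assert np.abs(dvf.u).max() < 0.1
        assert np.all(dv.values == 0)

    def test_uniform_dose_mean_matches_linear_formula(self, small_anatomy):
        # linear configuration: saturation and vascular modulation disabled
        params = ResponseParams(
            slope_per_gy=0.005, patient_sd=0, voxel_noise_sd=0, compensation_gain=0,
            max_atrophy=np.inf, vessel_sparing=0, vascular_hypertrophy=0,
            capsule_enhancement=0, baseline_remodeling=0,
        )
        _, labels, _ = small_anatomy
        liver = labels.liver_mask()
        dv, *_ = self._base(small_anatomy, params, np.full(SHAPE, 60.0))
        assert dv.values[liver].mean() == pytest.approx(-0.30, abs=0.02)

    def test_planted_jacobian_consistency(self, small_anatomy):
        """The constructed field's finite-difference Jacobian reproduces the
        planted 1 + dv within 0.02 on average over the liver."""
        pre, labels, vessels = small_anatomy
        dose = generate_plan(labels, 5, 67.5, 15, seed=2)
        eqd2 = eqd2_map(dose, FractionationScheme(67.5, 15))
        dv, dvf, *_ = generate_response(
            labels, eqd2, 147.0, ResponseParams(), 6, pre, vessels
        )
        liver = labels.liver_mask()
        jac = jacobian_determinant(dvf).values
        err = np.abs(jac - (1.0 + dv.values))[liver]
        assert err.mean() < 0.02

    def test_warped_mask_volume_matches_planted_change(self, small_anatomy):
        pre, labels, vessels = small_anatomy
        dose = generate_plan(labels, 5, 75.0, 15, seed=3)
        eqd2 = eqd2_map(dose, FractionationScheme(75.0, 15))
        dv, dvf, post_ct, post_labels, _ = generate_response(
            labels, eqd2, 147.0, ResponseParams(voxel_noise_sd=0), 7, pre, vessels
        )
        liver = labels.liver_mask()
        vv = labels.geometry.voxel_volume
        planted = (1.0 + dv.values[liver]).sum() * vv
        warped = post_labels.liver_mask().sum() * vv
        assert warped == pytest.approx(planted, rel=0.03)


class TestCohort:
    @pytest.fixture(scope="class")
    def cohort(self, tmp_path_factory):
        out = tmp_path_factory.mktemp("cohort")
        cases = generate_cohort(
            10, 21, CohortConfig(shape=(40, 40, 32), spacing=(4.5, 4.5, 5.5)), out_dir=out
        )
        return cases, out

    def test_metadata_within_study_ranges(self, cohort):
        cases, _ = cohort
        for c in cases:
            assert 79 <= c.t_days <= 257
            assert c.prescription_gy in PRESCRIPTIONS_GY
            assert c.n_fractions in FRACTION_NUMBERS
            assert c.cancer_type in CANCER_TYPES

    def test_deterministic_cohort(self):
        cfg = CohortConfig(shape=(40, 40, 32), spacing=(4.5, 4.5, 5.5))
        a = generate_cohort(10, 33, cfg)
        b = generate_cohort(10, 33, cfg)
        for ca, cb in zip(a, b):
            np.testing.assert_array_equal(ca.truth_dv.values, cb.truth_dv.values)
            assert ca.t_days == cb.t_days and ca.prescription_gy == cb.prescription_gy

    def test_cancer_type_proportions(self):
        # multinomial check on the metadata draw alone (no volumes needed)
        rng = np.random.default_rng(77)
        draws = rng.choice(len(CANCER_TYPES), size=1000, p=CANCER_PROBS)
        props = np.bincount(draws, minlength=3) / 1000
        np.testing.assert_allclose(props, CANCER_PROBS, atol=0.03)

    def test_round_trip_case_directory(self, cohort):
        cases, out = cohort
        back = load_case(out / cases[0].case_id)
        np.testing.assert_allclose(back.truth_dv.values, cases[0].truth_dv.values, atol=1e-6)
        np.testing.assert_array_equal(back.labels.labels, cases[0].labels.labels)
        assert back.t_days == pytest.approx(cases[0].t_days)
        assert (out / "manifest.json").exists()

    def test_minimum_cohort_size_enforced(self):
        with pytest.raises(ValueError):
            generate_cohort(5, 1)
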