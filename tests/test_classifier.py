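import numpy as np
import pytest

from lggspat import (
    AnalysisConfig,
    DegenerateInputError,
    ValidationError,
    classify_case,
    classify_clinical,
    classify_overlay,
    count_foci,
    residual_volume_flag,
)
from lggspat.classify import COMBINED, DISTANT, LOCAL, NOT_EVALUABLE, OUTSIDE, WITHIN
from lggspat.synthetic import FocusSpec, SyntheticCaseSpec, generate_case

from .conftest import digitized_sphere, vol_from_indices

NO_FLOOR = AnalysisConfig(min_component_ml=0.0)


def _pair(trans_indices, pre_indices, shape=(40, 40, 40)):
    return (
        vol_from_indices(trans_indices, shape=shape),
        vol_from_indices(pre_indices, shape=shape),
    )


class TestClinicalRule:
    def test_overlapping_focus_is_local(self):
        trans, pre = _pair([(5, 5, 5)], [(5, 5, 5), (6, 5, 5)])
        category, foci = classify_clinical(trans, pre, NO_FLOOR)
        assert category == LOCAL
        assert foci[0].min_distance_mm == 0.0 and foci[0].label == LOCAL

    def test_focus_beyond_threshold_is_distant(self):
        trans, pre = _pair([(30, 5, 5)], [(5, 5, 5)])  # 25 mm away
        category, foci = classify_clinical(trans, pre, NO_FLOOR)
        assert category == DISTANT and foci[0].min_distance_mm == 25.0

    def test_exactly_threshold_is_distant(self):
        # the rule is strict: local means strictly below the threshold
        trans, pre = _pair([(25, 5, 5)], [(5, 5, 5)])
        category, foci = classify_clinical(trans, pre, NO_FLOOR)
        assert foci[0].min_distance_mm == 20.0
        assert category == DISTANT

    def test_just_below_threshold_is_local(self):
        trans, pre = _pair([(24, 5, 5)], [(5, 5, 5)])
        category, _ = classify_clinical(trans, pre, NO_FLOOR)
        assert category == LOCAL

    def test_mixed_foci_are_combined(self):
        trans, pre = _pair([(5, 5, 5), (35, 5, 5)], [(5, 5, 5)])
        category, foci = classify_clinical(trans, pre, NO_FLOOR)
        assert category == COMBINED
        assert sorted(f.label for f in foci) == [DISTANT, LOCAL]

    def test_all_components_below_floor_is_degenerate(self):
        trans, pre = _pair([(5, 5, 5)], [(6, 5, 5)])
        with pytest.raises(DegenerateInputError):
            classify_clinical(trans, pre, AnalysisConfig(min_component_ml=0.01))

    def test_raising_threshold_never_makes_a_focus_distant(self, rng):
        for _ in range(10):
            n = int(rng.integers(1, 20))
            trans = vol_from_indices(rng.integers(0, 40, size=(n, 3)), shape=(40, 40, 40))
            pre = vol_from_indices(rng.integers(0, 40, size=(5, 3)), shape=(40, 40, 40))
            local_sets = []
            for t in (5.0, 15.0, 40.0):
                cfg = AnalysisConfig(local_threshold_mm=t, min_component_ml=0.0)
                _, foci = classify_clinical(trans, pre, cfg)
                local_sets.append({f.focus_index for f in foci if f.label == LOCAL})
            assert local_sets[0] <= local_sets[1] <= local_sets[2]


class TestOverlayModel:
    def test_single_voxel_overlap_counts_as_within(self):
        trans, ref = _pair([(5, 5, 5), (20, 20, 20)], [(5, 5, 5)])
        category, overlap_ml = classify_overlay(trans, ref)
        assert category == WITHIN and overlap_ml == pytest.approx(0.001)

    def test_disjoint_masks_are_outside(self):
        trans, ref = _pair([(10, 5, 5)], [(5, 5, 5)])
        category, overlap_ml = classify_overlay(trans, ref)
        assert category == OUTSIDE and overlap_ml == 0.0

    def test_absent_reference_is_not_evaluable(self):
        trans = vol_from_indices([(5, 5, 5)])
        assert classify_overlay(trans, None) == (NOT_EVALUABLE, 0.0)

    def test_min_overlap_voxels_is_respected(self):
        trans, ref = _pair([(5, 5, 5)], [(5, 5, 5)])
        assert classify_overlay(trans, ref, AnalysisConfig(min_overlap_voxels=2))[0] == OUTSIDE


class TestFociAndResidual:
    def test_single_sphere_is_unifocal(self):
        sphere = digitized_sphere(5.0)
        assert count_foci(sphere) == (1, False)

    def test_two_separated_spheres_are_multifocal(self):
        s = digitized_sphere(4.0, center_mm=(-8, 0, 0), pad_voxels=14)
        s2 = digitized_sphere(4.0, center_mm=(7, 0, 0), pad_voxels=14)
        both = s.with_voxels(s.voxels | s2.voxels)
        assert count_foci(both) == (2, True)

    def test_speck_below_floor_not_counted(self):
        sphere = digitized_sphere(5.0, pad_voxels=6)
        vox = sphere.voxels.copy()
        vox[0, 0, 0] = True  # 1 voxel = 0.001 ml, below the 0.01 ml floor
        assert count_foci(sphere.with_voxels(vox)) == (1, False)

    @pytest.mark.parametrize("n_vox,expected", [(9900, True), (10000, False), (40000, False)])
    def test_residual_flag_is_strict_at_10_ml(self, n_vox, expected, rng):
        shape = (40, 40, 40)
        flat = rng.choice(np.prod(shape), size=n_vox, replace=False)
        vol = vol_from_indices(np.column_stack(np.unravel_index(flat, shape)), shape=shape)
        assert residual_volume_flag(vol) is expected


def _synthetic_case(foci, include_preop=True, seed=5):
    spec = SyntheticCaseSpec(
        case_id="t", preop_center_mm=(0, 0, 0), preop_semiaxes_mm=(16, 14, 12),
        foci=tuple(foci), shape=(72, 72, 72), include_preoperative=include_preop, seed=seed,
    )
    return generate_case(spec)


class TestClassifyCase:
    def test_focus_inside_preop_is_local_within(self):
        case, truth = _synthetic_case([FocusSpec(radius_mm=5, mode="inside")])
        cls = classify_case(case)
        assert cls.clinical_category == LOCAL and cls.overlay_category == WITHIN
        assert cls.n_foci == 1 and not cls.multifocal
        assert cls.foci[0].min_distance_mm == 0.0

    def test_far_focus_is_distant_outside(self):
        case, truth = _synthetic_case([FocusSpec(radius_mm=5, mode="far", target_distance_mm=30)])
        cls = classify_case(case)
        assert cls.clinical_category == DISTANT and cls.overlay_category == OUTSIDE

    def test_inside_plus_far_is_combined_but_within(self):
        # overlap precedence: a clinically combined case with one overlapping
        # focus still counts as within in the overlay model
        case, truth = _synthetic_case([
            FocusSpec(radius_mm=4.5, mode="inside"),
            FocusSpec(radius_mm=4.5, mode="far", target_distance_mm=30),
        ])
        cls = classify_case(case)
        assert cls.clinical_category == COMBINED
        assert cls.overlay_category == WITHIN
        assert cls.multifocal and cls.n_foci == 2

    def test_missing_preop_clinical_only(self):
        case, truth = _synthetic_case([FocusSpec(radius_mm=5, mode="inside")],
                                      include_preop=False)
        cls = classify_case(case)
        assert cls.clinical_category == LOCAL
        assert cls.overlay_category == NOT_EVALUABLE
        assert cls.preoperative_volume_ml is None

    def test_overlay_reference_switch_to_pre_transformation(self):
        case, _ = _synthetic_case([FocusSpec(radius_mm=5, mode="near", target_distance_mm=10)])
        default = classify_case(case)
        sensitivity = classify_case(case, AnalysisConfig(overlay_reference="pre_transformation"))
        assert default.overlay_category == OUTSIDE  # near focus does not touch preop
        assert sensitivity.overlay_category == OUTSIDE  # nor the pre-transformation tumor
        inside_case, _ = _synthetic_case([FocusSpec(radius_mm=5, mode="inside")])
        assert classify_case(
            inside_case, AnalysisConfig(overlay_reference="pre_transformation")
        ).overlay_category == WITHIN


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"local_threshold_mm": 0},
            {"min_overlap_voxels": 0},
            {"min_component_ml": -1},
            {"connectivity": 4},
            {"overlay_reference": "followup"},
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValidationError):
            AnalysisConfig(**kwargs)
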