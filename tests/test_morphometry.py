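"""Morphometry pipeline: projection, thresholding, cleanup, measurement, QC."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from skimage import draw

from isletquant.morphometry import (
    BinaryMask,
    ImageStack,
    ParticleMeasurement,
    apply_qc,
    binarize,
    circularity,
    ellipsoid_volume,
    equivalent_diameter,
    max_project,
    measure_particles,
    measure_stack,
    morphological_clean,
    summarize_morphometry,
)
from isletquant.synthetic import generate_phantom_stack


def _particle(area=0.03, a=0.2, b=0.2, circ=0.9, frac=0.1, label=1):
    return ParticleMeasurement(
        label=label, area_mm2=area, major_axis_mm=a, minor_axis_mm=b,
        perimeter_mm=0.6, circularity=circ, area_fraction=frac,
    )


class TestMaxProject:
    def test_single_plane_identity(self):
        img = np.random.default_rng(0).random((1, 8, 8))
        stack = ImageStack(img, 1.0)
        np.testing.assert_array_equal(max_project(stack), img[0])

    def test_zero_plane_ignored(self):
        plane = np.random.default_rng(1).random((8, 8))
        stack = ImageStack(np.stack([np.zeros((8, 8)), plane]), 1.0)
        np.testing.assert_array_equal(max_project(stack), plane)

    def test_projection_equals_mid_plane_for_parabolic_phantom(
        self, phantom_spec_factory
    ):
        stack, _ = generate_phantom_stack(phantom_spec_factory())
        mid = stack.voxels.shape[0] // 2
        np.testing.assert_array_equal(max_project(stack), stack.voxels[mid])

    def test_invalid_stack_rejected(self):
        with pytest.raises(ValueError):
            ImageStack(np.zeros((8, 8)), 1.0)  # not 3-D
        with pytest.raises(ValueError):
            ImageStack(np.zeros((1, 8, 8)), -1.0)


class TestBinarize:
    def test_two_level_image_any_method(self):
        img = np.zeros((10, 10))
        img[3:7, 3:7] = 100.0
        for kwargs in ({"method": "auto"},
                       {"method": "manual", "manual_threshold": 50.0}):
            res = binarize(img, **kwargs)
            np.testing.assert_array_equal(res.mask, img == 100.0)

    def test_manual_threshold_above_max_gives_empty_mask(self):
        img = np.arange(16.0).reshape(4, 4)
        res = binarize(img, method="manual", manual_threshold=img.max() + 1)
        assert not res.mask.any()

    def test_constant_image_auto_raises(self):
        with pytest.raises(ValueError, match="manual"):
            binarize(np.full((5, 5), 7.0), method="auto")

    def test_threshold_recorded_in_provenance(self):
        img = np.zeros((10, 10))
        img[2:5, 2:5] = 10.0
        res = binarize(img, method="manual", manual_threshold=4.2)
        assert res.threshold == 4.2 and res.method == "manual"
        auto = binarize(img, method="auto")
        assert 0.0 < auto.threshold < 10.0 and auto.method == "auto"

    def test_phantom_mask_area_close_to_truth(self, phantom_spec_factory):
        stack, gt = generate_phantom_stack(phantom_spec_factory(200.0, 200.0))
        res = binarize(max_project(stack))
        area_mm2 = res.mask.sum() * (stack.pixel_size_um**2) / 1e6
        assert area_mm2 == pytest.approx(gt.areas_mm2[0], rel=0.02)


class TestMorphologicalClean:
    def test_zero_iterations_is_identity(self):
        mask = np.random.default_rng(0).random((20, 20)) > 0.5
        out = morphological_clean(mask, 0, 0, 1)
        np.testing.assert_array_equal(out.mask, mask)

    def test_single_pixel_speck_removed(self):
        mask = np.zeros((20, 20), bool)
        mask[10, 10] = True
        out = morphological_clean(mask, 1, 1, 1)
        assert not out.mask.any()

    def test_large_disk_nearly_unchanged(self):
        mask = np.zeros((300, 300), bool)
        rr, cc = draw.disk((150, 150), 100)
        mask[rr, cc] = True
        out = morphological_clean(mask, 2, 2, 1)
        change = abs(int(out.mask.sum()) - int(mask.sum())) / mask.sum()
        assert change < 0.01

    def test_provenance_preserved(self):
        bm = BinaryMask(np.ones((5, 5), bool), threshold=3.0, method="manual")
        out = morphological_clean(bm, 1, 1, 1)
        assert out.threshold == 3.0 and out.method == "manual"


class TestMeasureParticles:
    def test_circle_area_axes_circularity(self):
        mask = np.zeros((300, 300), bool)
        rr, cc = draw.disk((150, 150), 100)
        mask[rr, cc] = True
        (p,) = measure_particles(mask, 1.0)
        assert p.area_mm2 == pytest.approx(np.pi * 0.1**2, rel=0.02)
        assert p.major_axis_mm == pytest.approx(0.2, rel=0.02)
        assert p.minor_axis_mm == pytest.approx(0.2, rel=0.02)
        assert p.circularity == pytest.approx(1.0, abs=0.02)

    def test_square_circularity_formula(self):
        # exact arithmetic of 4*pi*A/P^2 at the formula level
        s = 200.0
        assert circularity(s * s, 4 * s) == pytest.approx(np.pi / 4)
        # the digitized square's estimate stays within the QC-relevant band
        mask = np.zeros((300, 300), bool)
        mask[50:250, 50:250] = True
        (p,) = measure_particles(mask, 1.0)
        assert 0.5 <= p.circularity <= 1.0

    def test_ellipse_phantom_axes_recovered(self, phantom_spec_factory):
        stack, gt = generate_phantom_stack(phantom_spec_factory(300.0, 150.0, 0.7))
        particles, _ = measure_stack(stack)
        best = max(particles, key=lambda p: p.area_mm2)
        assert best.major_axis_mm == pytest.approx(gt.major_axes_mm[0], rel=0.02)
        assert best.minor_axis_mm == pytest.approx(gt.minor_axes_mm[0], rel=0.02)
        assert best.area_mm2 == pytest.approx(gt.areas_mm2[0], rel=0.02)

    def test_empty_mask_gives_empty_list(self):
        assert measure_particles(np.zeros((10, 10), bool), 1.0) == []

    def test_scale_equivariance(self):
        mask = np.zeros((300, 300), bool)
        rr, cc = draw.disk((150, 150), 80)
        mask[rr, cc] = True
        (p1,) = measure_particles(mask, 1.0)
        (p2,) = measure_particles(mask, 2.0)
        assert p2.major_axis_mm == pytest.approx(2 * p1.major_axis_mm)
        assert p2.area_mm2 == pytest.approx(4 * p1.area_mm2)
        assert p2.circularity == pytest.approx(p1.circularity)


class TestQC:
    def test_low_circularity_flagged(self):
        accepted, flagged = apply_qc([_particle(circ=0.4)])
        assert not accepted and flagged[0].flag_reason.startswith("circularity")

    def test_large_area_fraction_flagged(self):
        accepted, flagged = apply_qc([_particle(frac=0.20)])
        assert not accepted and "area fraction" in flagged[0].flag_reason

    def test_interior_point_accepted(self):
        accepted, flagged = apply_qc([_particle(circ=1.0, frac=0.10)])
        assert accepted and not flagged

    def test_boundary_conditions(self):
        # circularity bounds inclusive; area bound strict
        acc, _ = apply_qc([_particle(circ=0.5), _particle(circ=1.0, label=2)])
        assert len(acc) == 2
        _, flg = apply_qc([_particle(frac=0.18)])
        assert len(flg) == 1

    @given(
        st.lists(
            st.tuples(
                st.floats(0.0, 1.0),  # circularity
                st.floats(0.001, 0.99),  # area fraction
            ),
            min_size=1,
            max_size=20,
        )
    )
    @settings(deadline=None, derandomize=True)
    def test_every_particle_appears_exactly_once(self, params):
        particles = [
            _particle(circ=c, frac=f, label=i) for i, (c, f) in enumerate(params)
        ]
        accepted, flagged = apply_qc(particles)
        assert len(accepted) + len(flagged) == len(particles)
        assert {p.label for p in accepted} | {p.label for p in flagged} == {
            p.label for p in particles
        }


class TestFormulas:
    @pytest.mark.parametrize(
        "a,b,expected",
        [(1.0, 1.0, 4 * np.pi / 3), (2.0, 1.0, 8 * np.pi / 3)],
    )
    def test_ellipsoid_volume_unit_cases(self, a, b, expected):
        assert ellipsoid_volume(a, b) == pytest.approx(expected)

    def test_pseudoislet_scale_volume(self):
        assert ellipsoid_volume(0.208, 0.208) == pytest.approx(0.0377, rel=0.01)

    def test_semi_axis_convention_is_one_eighth(self):
        assert ellipsoid_volume(0.3, 0.2, semi_axes=True) == pytest.approx(
            ellipsoid_volume(0.3, 0.2) / 8.0
        )

    def test_volume_errors(self):
        with pytest.raises(ValueError):
            ellipsoid_volume(0.0, 0.0)
        with pytest.raises(ValueError):
            ellipsoid_volume(0.1, 0.2)  # b > a

    @given(
        st.floats(0.01, 10.0), st.floats(0.01, 10.0), st.floats(1.001, 2.0)
    )
    @settings(deadline=None, derandomize=True)
    def test_volume_strictly_increasing_in_each_axis(self, a, b, factor):
        a, b = max(a, b), min(a, b)
        assert ellipsoid_volume(a * factor, b) > ellipsoid_volume(a, b)
        bigger_b = min(b * factor, a)
        if bigger_b > b:
            assert ellipsoid_volume(a, bigger_b) > ellipsoid_volume(a, b)

    def test_equivalent_diameter_unit_circle(self):
        assert equivalent_diameter(np.pi) == pytest.approx(2000.0)

    def test_equivalent_diameter_zero_and_negative(self):
        assert equivalent_diameter(0.0) == 0.0
        with pytest.raises(ValueError):
            equivalent_diameter(-1.0)

    def test_equivalent_diameter_pseudoislet_mean_area(self):
        assert equivalent_diameter(0.034) == pytest.approx(208.06, abs=0.5)


class TestSummary:
    def test_hand_computed_mean_sd_cv(self):
        parts = [_particle(area=v, a=0.2, b=0.2, label=i) for i, v in enumerate([1.0, 2.0, 3.0])]
        s = summarize_morphometry(parts)
        area = s.metrics["area_mm2"]
        assert area.mean == pytest.approx(2.0)
        assert area.sd == pytest.approx(1.0)
        assert area.cv_percent == pytest.approx(50.0)

    def test_identical_values_zero_cv(self):
        parts = [_particle(label=i) for i in range(4)]
        s = summarize_morphometry(parts)
        assert all(m.cv_percent == pytest.approx(0.0) for m in s.metrics.values())

    def test_too_few_measurements_rejected(self):
        with pytest.raises(ValueError):
            summarize_morphometry([_particle()])

    def test_cv_scale_invariant(self):
        vals = [0.8, 1.1, 1.7, 2.3]
        base = summarize_morphometry([_particle(area=v, label=i) for i, v in enumerate(vals)])
        scaled = summarize_morphometry(
            [_particle(area=7.3 * v, label=i) for i, v in enumerate(vals)]
        )
        assert scaled.metrics["area_mm2"].cv_percent == pytest.approx(
            base.metrics["area_mm2"].cv_percent
        )


class TestPipelineRecovery:
    def test_noise_free_phantom_within_two_percent(self, phantom_spec_factory):
        rng = np.random.default_rng(21)
        for _ in range(5):
            major = float(rng.uniform(100, 400))
            minor = major * float(rng.uniform(0.6, 1.0))
            spec = phantom_spec_factory(major, minor, float(rng.uniform(0, np.pi)))
            stack, gt = generate_phantom_stack(spec)
            particles, _ = measure_stack(stack)
            best = max(particles, key=lambda p: p.area_mm2)
            assert best.area_mm2 == pytest.approx(gt.areas_mm2[0], rel=0.02)
            assert best.major_axis_mm == pytest.approx(gt.major_axes_mm[0], rel=0.02)
            assert best.minor_axis_mm == pytest.approx(gt.minor_axes_mm[0], rel=0.02)

    def test_noisy_phantom_within_five_percent(self, phantom_spec_factory):
        spec = phantom_spec_factory(250.0, 180.0, 0.4, noise_sd=100.0, n_debris=4,
                                    seed=8)
        stack, gt = generate_phantom_stack(spec)
        particles, _ = measure_stack(stack)
        best = max(particles, key=lambda p: p.area_mm2)
        assert best.area_mm2 == pytest.approx(gt.areas_mm2[0], rel=0.05)
        assert best.major_axis_mm == pytest.approx(gt.major_axes_mm[0], rel=0.05)
        assert best.minor_axis_mm == pytest.approx(gt.minor_axes_mm[0], rel=0.05)
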