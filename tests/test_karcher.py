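"""Mean-shape machinery: arc-length resampling, rigid alignment without
reflection, Karcher iteration invariants and landmark widths."""

import math

import numpy as np
import pytest

from cryptomorph import (GeneratorConfig, Outline, karcher_mean, align_set,
                         resample_outline, landmark_widths, clade_contrast,
                         normalize_outline, generate_keyhole_outline)
from cryptomorph.karcher import MeanShapeReport


def circle(n=720, r=1.0):
    th = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return Outline(np.column_stack([r * np.cos(th), r * np.sin(th)]))


def ellipse(a, b, n=1440):
    th = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return Outline(np.column_stack([a * np.cos(th), b * np.sin(th)]))


class TestResample:
    def test_circle_to_regular_16gon(self):
        r16 = resample_outline(circle(), 16)
        sides = np.hypot(*np.diff(np.vstack([r16.points, r16.points[:1]]),
                                  axis=0).T)
        assert np.allclose(sides, sides[0], atol=1e-9)
        assert np.allclose(np.hypot(*r16.points.T), 1.0, atol=1e-6)

    def test_idempotent_on_equal_arc_outline(self):
        # 640 source points resample exactly onto every 10th vertex, so the
        # 64-point result is itself an equal-arc polygon
        first = resample_outline(circle(640), 64)
        again = resample_outline(first, 64)
        assert np.abs(again.points - first.points).max() < 1e-9

    def test_arc_length_preserved_on_smooth_outline(self):
        a, b = 1.0, 0.6
        res = resample_outline(ellipse(a, b), 200)
        # Ramanujan's approximation for the ellipse perimeter
        perim = math.pi * (3 * (a + b) - math.sqrt((3 * a + b) * (a + 3 * b)))
        assert res.perimeter() == pytest.approx(perim, rel=0.005)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            resample_outline(circle(), 8)


class TestAlignment:
    def test_self_alignment_is_identity(self):
        shape = resample_outline(ellipse(1.0, 0.5), 100)
        aligned, resid = align_set([shape], shape)
        assert resid[0] < 1e-12

    def test_rotated_copy_recovered(self):
        shape = resample_outline(ellipse(1.0, 0.5), 100)
        rotated = Outline(shape.points @ np.array(
            [[np.cos(0.4), -np.sin(0.4)], [np.sin(0.4), np.cos(0.4)]]).T)
        _, resid = align_set([rotated], shape)
        assert resid[0] < 1e-6

    def test_reflection_not_recoverable(self):
        """No reflection allowed: a mirrored asymmetric outline keeps a
        strictly positive residual."""
        rng = np.random.default_rng(0)
        cfg = GeneratorConfig.preset("keyhole_like")
        scalene = resample_outline(normalize_outline(
            generate_keyhole_outline(cfg, "Northern", rng)), 100)
        mirrored = Outline(scalene.points * np.array([-1.0, 1.0]))
        _, resid = align_set([mirrored.ensure_ccw()], scalene)
        assert resid[0] > 1e-4

    def test_mismatched_point_counts_rejected(self):
        with pytest.raises(ValueError, match="points"):
            align_set([resample_outline(circle(), 64)],
                      resample_outline(circle(), 100))


class TestKarcherMean:
    def test_identical_inputs_return_that_shape(self):
        # input already in the mean's canonical form (200 equal-arc points,
        # normalized as that polygon) so the mean must reproduce it exactly
        shape = normalize_outline(resample_outline(ellipse(1.0, 0.5), 200))
        rep = karcher_mean([shape, shape, shape], tol=1e-8)
        target = resample_outline(shape, 200)
        aligned, resid = align_set([rep.mean_outline], target)
        assert np.sqrt(resid[0] / 200) < 1e-6

    def test_symmetric_rotations_recover_template(self):
        cfg = GeneratorConfig.preset("keyhole_like", fourier_noise_sd=0.0,
                                     shape_noise_sd=0.0)
        template = resample_outline(normalize_outline(
            generate_keyhole_outline(cfg, "Northern",
                                     np.random.default_rng(0))), 200)
        copies = [template.rotated(np.deg2rad(s)).translated(0.3, -0.2)
                  for s in (-10, 10)]
        rep = karcher_mean(copies)
        aligned, _ = align_set([rep.mean_outline], template)
        rms = np.sqrt(np.mean(
            (aligned[0].points
             - (template.points - template.points.mean(0))) ** 2))
        assert rms < 1e-4

    def test_objective_non_increasing(self):
        rng = np.random.default_rng(7)
        cfg = GeneratorConfig.preset("keyhole_like")
        outs = [normalize_outline(generate_keyhole_outline(cfg, "Northern",
                                                           rng))
                for _ in range(40)]
        rep = karcher_mean(outs)
        h = np.asarray(rep.objective_history)
        assert np.all(np.diff(h) <= 1e-9 * (1 + h[:-1]))
        assert rep.converged and rep.convergence_iterations < 50

    def test_invariant_to_input_order_and_rigid_motion(self):
        """Reordering inputs and moving them rigidly changes the mean only
        within the iteration's own resolution (the cyclic correspondence is
        discrete and the stopping rule is a tolerance, so fixed points from
        different initializations agree approximately, not exactly)."""
        rng = np.random.default_rng(3)
        cfg = GeneratorConfig.preset("keyhole_like")
        outs = [normalize_outline(generate_keyhole_outline(cfg, "Southern",
                                                           rng))
                for _ in range(12)]
        rep1 = karcher_mean(outs)
        moved = [o.rotated(0.5).translated(2.0, -1.0) for o in reversed(outs)]
        rep2 = karcher_mean(moved)
        aligned, resid = align_set([rep2.mean_outline],
                                   rep1.mean_outline)
        assert np.sqrt(resid[0] / 200) < 0.01

    def test_fewer_than_two_outlines_rejected(self):
        with pytest.raises(ValueError):
            karcher_mean([circle()])


class TestLandmarks:
    def test_ellipse_quartile_widths(self):
        """Cross-sections of an ellipse at 25/75% height are sqrt(3)/2 of
        the central width, for any eccentricity."""
        for a, b in ((1.0, 0.5), (1.0, 0.9), (2.0, 0.4)):
            out = normalize_outline(ellipse(b, a))  # major axis vertical
            lms, w25, w50, w75, minor = landmark_widths(out)
            assert w25 / w50 == pytest.approx(math.sqrt(3) / 2, abs=1e-4)
            assert w75 / w50 == pytest.approx(math.sqrt(3) / 2, abs=1e-4)
            assert lms.shape == (6, 2)

    def test_circle_central_width_is_diameter(self):
        out = normalize_outline(circle())
        _, w25, w50, w75, minor = landmark_widths(out)
        assert w50 == pytest.approx(1.0, abs=1e-4)
        assert minor == pytest.approx(1.0, abs=1e-4)

    def test_planted_pinch_produces_target_ratio(self):
        """Noise-free pinched profile: quartile/central ratio 1.425."""
        cfg = GeneratorConfig.preset("keyhole_like", fourier_noise_sd=0.0,
                                     shape_noise_sd=0.0)
        out = normalize_outline(generate_keyhole_outline(
            cfg, "Northern", np.random.default_rng(0), n_points=1024))
        _, w25, w50, w75, _ = landmark_widths(out)
        assert 0.5 * (w25 + w75) / w50 == pytest.approx(1.425, abs=0.01)

    def test_landmarks_lie_on_the_outline(self):
        out = resample_outline(normalize_outline(ellipse(1.0, 0.5)), 400)
        lms, *_ = landmark_widths(out)
        for x, y in lms:
            d = np.min(np.hypot(out.points[:, 0] - x, out.points[:, 1] - y))
            assert d < 0.02  # within interpolation tolerance


class TestCladeContrast:
    def _report(self, minor, ratio_shape):
        lms, w25, w50, w75, _ = landmark_widths(ratio_shape)
        return MeanShapeReport(
            mean_outline=ratio_shape, n_shapes=1, convergence_iterations=1,
            converged=True, final_objective=0.0, objective_history=(0.0,),
            landmarks=lms, width_25=w25, width_50=w50, width_75=w75,
            minor_axis_width=minor)

    def test_identical_reports_zero_contrast(self):
        shape = normalize_outline(ellipse(1.0, 0.5))
        r = self._report(0.5, shape)
        c = clade_contrast(r, r)
        assert c.pct_minor_axis_narrower == 0.0
        assert c.quartile_over_central_ratio_N == \
            c.quartile_over_central_ratio_S

    def test_planted_recovery_case(self):
        shape = normalize_outline(ellipse(1.0, 0.5))
        c = clade_contrast(self._report(0.88 * 0.5, shape),
                           self._report(0.5, shape))
        assert c.pct_minor_axis_narrower == pytest.approx(12.0, abs=1e-9)

    def test_pinched_north_has_higher_ratio_than_ellipse_south(self):
        cfg = GeneratorConfig.preset("keyhole_like", fourier_noise_sd=0.0,
                                     shape_noise_sd=0.0)
        rng = np.random.default_rng(0)
        north = normalize_outline(generate_keyhole_outline(cfg, "Northern",
                                                           rng))
        south = normalize_outline(generate_keyhole_outline(cfg, "Southern",
                                                           rng))
        c = clade_contrast(self._report(0.4, north), self._report(0.5, south))
        assert c.quartile_over_central_ratio_N > \
            c.quartile_over_central_ratio_S
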