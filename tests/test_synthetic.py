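"""Generator contracts: planted clade effects, determinism, geometric
validity and the pinch-ratio inverse solver."""

import hashlib
import math
from dataclasses import replace
from pathlib import Path

import numpy as np
import pytest
from scipy.stats import mannwhitneyu
from shapely.geometry import Polygon

from cryptomorph import (GeneratorConfig, RejectedConfigurationError,
                         generate_keyhole_outline, generate_shell_outline,
                         generate_dataset, render_specimen,
                         solve_pinch_for_ratio, read_metadata, Outline)
from cryptomorph.synthetic import keyhole_halfwidth, draw_major_axes

NOISE_FREE = dict(fourier_noise_sd=0.0, shape_noise_sd=0.0)


def quartile_ratio_numeric(p, sigma=0.15, n=200001):
    """Independent oracle: evaluate the half-width profile on a fine grid."""
    h = np.linspace(0.0, 1.0, n)
    w = keyhole_halfwidth(h, W=1.0, H=1.0, p=p, sigma_frac=sigma)
    w25 = np.interp(0.25, h, w)
    w50 = np.interp(0.50, h, w)
    w75 = np.interp(0.75, h, w)
    return 0.5 * (w25 + w75) / w50


class TestPinchSolver:
    def test_pure_ellipse_ratio_gives_zero_pinch(self):
        assert solve_pinch_for_ratio(math.sqrt(3) / 2) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("target,expected", [
        (1.425, 0.46232),   # the planted quartile/central contrast
        (1.0, 0.17087),
    ])
    def test_solved_pinch_reproduces_ratio(self, target, expected):
        p = solve_pinch_for_ratio(target, 0.15)
        assert p == pytest.approx(expected, abs=1e-4)
        assert quartile_ratio_numeric(p) == pytest.approx(target, abs=1e-4)

    def test_unreachable_ratio_rejected(self):
        with pytest.raises(ValueError, match="unreachable"):
            solve_pinch_for_ratio(0.5)


class TestKeyholeOutline:
    def test_pinch_free_equal_axes_is_circle(self):
        cfg = GeneratorConfig.preset("keyhole_like", keyhole_width_S=0.2,
                                     **NOISE_FREE)
        out = generate_keyhole_outline(cfg, "Southern",
                                       np.random.default_rng(0))
        # W = 0.2, H = 2W = 0.4: pure ellipse with b/a = 0.5; force W = H
        # through the profile directly
        h = np.linspace(0, 1, 1001)
        w = keyhole_halfwidth(h, W=1.0, H=1.0, p=0.0, sigma_frac=0.15)
        assert np.allclose(w, 0.5 * np.sqrt(np.clip(1 - (2 * h - 1)**2, 0, 1)))
        assert out.is_simple() and out.is_ccw()

    def test_planted_width_narrowing_is_twelve_percent(self):
        """Noise-free Northern width is exactly 0.88 x Southern width."""
        cfg = GeneratorConfig.preset("keyhole_like", pinch_N=0.0, pinch_S=0.0,
                                     **NOISE_FREE)
        rng = np.random.default_rng(0)
        north = generate_keyhole_outline(cfg, "Northern", rng)
        south = generate_keyhole_outline(cfg, "Southern", rng)
        w_n = np.ptp(north.points[:, 0])
        w_s = np.ptp(south.points[:, 0])
        assert w_n / w_s == pytest.approx(0.88, abs=1e-9)

    def test_pinch_monotonically_increases_quartile_ratio(self):
        ratios = [quartile_ratio_numeric(p) for p in np.linspace(0, 0.8, 9)]
        assert np.all(np.diff(ratios) > 0)

    def test_same_seed_same_points(self):
        cfg = GeneratorConfig.preset("keyhole_like")
        a = generate_keyhole_outline(cfg, "Northern", np.random.default_rng(5))
        b = generate_keyhole_outline(cfg, "Northern", np.random.default_rng(5))
        assert np.array_equal(a.points, b.points)

    def test_invalid_pinch_rejected(self):
        with pytest.raises(RejectedConfigurationError, match="pinch_N"):
            GeneratorConfig.preset("keyhole_like", pinch_N=1.2)


class TestShellOutline:
    def test_zero_amplitude_is_circle(self):
        cfg = GeneratorConfig.preset("keyhole_like", ridge_amp_N=0.0,
                                     ridge_amp_S=0.0, **NOISE_FREE)
        out = generate_shell_outline(cfg, "Southern", np.random.default_rng(0))
        r = np.hypot(*out.points.T)
        assert np.allclose(r, 1.0, atol=1e-12)

    def test_higher_ridge_amplitude_lowers_solidity(self):
        """Monte-Carlo over the generator with a convex-hull oracle."""
        cfg = GeneratorConfig.preset("ridge_like")
        rng = np.random.default_rng(11)

        def mean_solidity(clade):
            vals = []
            for _ in range(100):
                poly = Polygon(generate_shell_outline(cfg, clade, rng).points)
                vals.append(poly.area / poly.convex_hull.area)
            return np.mean(vals)

        assert cfg.ridge_amp_N > cfg.ridge_amp_S
        assert mean_solidity("Northern") < mean_solidity("Southern")

    def test_same_seed_determinism(self):
        cfg = GeneratorConfig.preset("ridge_like")
        a = generate_shell_outline(cfg, "Northern", np.random.default_rng(3))
        b = generate_shell_outline(cfg, "Northern", np.random.default_rng(3))
        assert np.array_equal(a.points, b.points)

    def test_excessive_amplitude_rejected(self):
        cfg = GeneratorConfig.preset("keyhole_like", fourier_noise_sd=0.5)
        with pytest.raises(RejectedConfigurationError):
            for seed in range(30):
                generate_shell_outline(cfg, "Northern",
                                       np.random.default_rng(seed))


class TestRendering:
    def test_mask_area_matches_shoelace_within_two_percent(self):
        cfg = GeneratorConfig.preset("keyhole_like", **NOISE_FREE)
        rng = np.random.default_rng(5)
        shell = generate_shell_outline(cfg, "Southern", rng)
        placed = Outline(shell.points * 40 + 64)
        _, mask, _ = render_specimen(placed, None, cfg, rng)
        assert mask.sum() / placed.area() == pytest.approx(1.0, abs=0.02)

    def test_render_deterministic(self):
        cfg = GeneratorConfig.preset("keyhole_like", **NOISE_FREE)
        shell = generate_shell_outline(cfg, "Southern",
                                       np.random.default_rng(1))
        placed = Outline(shell.points * 40 + 64)
        img1, m1, _ = render_specimen(placed, None, cfg,
                                      np.random.default_rng(9))
        img2, m2, _ = render_specimen(placed, None, cfg,
                                      np.random.default_rng(9))
        assert np.array_equal(img1, img2) and np.array_equal(m1, m2)

    def test_keyhole_mask_inside_shell_mask(self, tiny_dataset):
        _, records, ds = tiny_dataset
        for rec in records[:10]:
            shell = ds.mask(rec.specimen_id, "shell")
            keyhole = ds.mask(rec.specimen_id, "keyhole")
            assert not np.any(keyhole & ~shell)


class TestDatasetGeneration:
    def test_counts_and_files(self, tiny_dataset):
        cfg, records, ds = tiny_dataset
        assert len(records) == 2 * cfg.n_per_clade
        for rec in records:
            assert (ds.root / rec.image_path).exists()
            assert (ds.root / rec.mask_path).exists()
            assert (ds.root / rec.keyhole_mask_path).exists()
        clades = {r.clade for r in records}
        assert clades == {"Northern", "Southern"}

    def test_metadata_roundtrip(self, tiny_dataset):
        cfg, records, ds = tiny_dataset
        loaded = read_metadata(ds.root / "metadata.csv")
        assert [r.specimen_id for r in loaded] == \
            [r.specimen_id for r in records]
        assert loaded[0].major_axis_mm == pytest.approx(
            records[0].major_axis_mm, abs=1e-3)

    def test_same_seed_identical_metadata_bytes(self, tmp_path):
        cfg = GeneratorConfig.preset("keyhole_like", n_per_clade=6,
                                     n_locations_per_clade=2, seed=77)
        h = []
        for sub in ("a", "b"):
            generate_dataset(cfg, tmp_path / sub)
            h.append(hashlib.sha256(
                (tmp_path / sub / "metadata.csv").read_bytes()).hexdigest())
        assert h[0] == h[1]

    def test_clade_sizes_overlap_and_are_not_significantly_different(self):
        """Sizes must be statistically indistinguishable between clades
        (Mann-Whitney P > 0.05 in at least 90% of seeded replicates)."""
        cfg = GeneratorConfig.preset("keyhole_like")
        non_sig = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            north = draw_major_axes(cfg, 200, rng)
            south = draw_major_axes(cfg, 200, rng)
            assert max(north.min(), south.min()) < min(north.max(), south.max())
            if mannwhitneyu(north, south).pvalue > 0.05:
                non_sig += 1
        assert non_sig >= 45

    def test_every_outline_satisfies_invariants(self):
        cfg = GeneratorConfig.preset("keyhole_like")
        rng = np.random.default_rng(2)
        for clade in ("Northern", "Southern"):
            for _ in range(25):
                for out in (generate_keyhole_outline(cfg, clade, rng),
                            generate_shell_outline(cfg, clade, rng)):
                    assert out.n_points >= 3
                    assert out.is_ccw()
                    assert out.is_simple()

    def test_weak_preset_scales_contrasts_to_quarter(self):
        base = GeneratorConfig.preset("keyhole_like")
        weak = GeneratorConfig.preset("weak_signal_like")
        assert weak.keyhole_narrowing == pytest.approx(0.25 * base.keyhole_narrowing)
        assert weak.pinch_N == pytest.approx(0.25 * base.pinch_N)
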