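"""Synthetic limpet-shell image generator with plantable clade effects.

Real studies of cryptic divergence photograph shells under standardized
conditions; here we emulate such a dataset with a parametric generator so the
whole analysis pipeline (classification, saliency, shape metrics, mean-shape
comparison) can be exercised against known ground truth.

Two clades ("Northern" and "Southern") are generated per species preset:

``keyhole_like``
    Keyhole-limpet style: an elongated apical aperture whose Northern form is
    narrower (width reduced by ``keyhole_narrowing``, default 12%) and
    centrally pinched so its upper/lower-quartile widths exceed the central
    width (default pinch solves a quartile/central ratio of 1.425).
``ridge_like``
    True-limpet style: no keyhole; the Northern clade has higher-amplitude
    marginal ridge bumps, lowering solidity and extent.
``weak_signal_like``
    As ``keyhole_like`` but with every clade contrast scaled to 25%,
    emulating a weakly diverged species.
``band_like``
    No outline contrast; clades differ only in concentric band contrast,
    a non-geometric cue.

The keyhole boundary is built from the half-width profile

    halfwidth(h) = (W/2) * sqrt(1 - (2h/H - 1)^2)
                   * (1 - p * exp(-(h - H/2)^2 / (2 sigma^2)))

for heights h in [0, H], mirrored about the vertical axis: an ellipse of
width W and height H carrying a Gaussian waist of amplitude p and width
sigma = pinch_sigma * H.  Within-clade variability comes from multiplicative
lognormal noise on W and H, additive jitter on p, and low-order Fourier
boundary perturbation.  Everything is driven by a single seed, and identical
configurations produce byte-identical datasets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace, field
from pathlib import Path

import numpy as np
from PIL import Image
from scipy.ndimage import gaussian_filter
from skimage.draw import polygon2mask

from .outline import Outline, GeometryError
from .records import SpecimenRecord, write_metadata

PRESETS = ("keyhole_like", "ridge_like", "weak_signal_like", "band_like")

#: additive Gaussian jitter on per-specimen pinch amplitude
PINCH_JITTER_SD = 0.05
#: keyhole height/width aspect of the Southern base form
KEYHOLE_ASPECT = 2.0
#: angular width (radians) of a ridge bump
RIDGE_THETA_SD = 0.06
#: shell diameter as a fraction of the frame for a mean-size specimen
SHELL_FRAME_FRACTION = 0.62


class RejectedConfigurationError(ValueError):
    """Configuration produces degenerate geometry; names the offending field."""


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic dataset; defaults are the keyhole preset."""

    species_preset: str = "keyhole_like"
    n_per_clade: int = 200
    n_locations_per_clade: int = 4
    # 256 px keeps the ~28-px keyhole wide enough for faithful sub-pixel
    # contour morphometry; classifier inputs are downsampled separately
    image_size: int = 256
    keyhole_width_S: float = 0.11
    keyhole_narrowing: float = 0.12
    pinch_N: float = 0.46233  # solves quartile/central ratio 1.425 at sigma 0.15
    pinch_S: float = 0.0
    pinch_sigma: float = 0.15
    ridge_count: int = 9
    ridge_amp_N: float = 0.04
    ridge_amp_S: float = 0.04
    band_amp_N: float = 0.0
    band_amp_S: float = 0.0
    fourier_noise_sd: float = 0.012
    shape_noise_sd: float = 0.10
    size_mean_mm: float = 18.3
    size_sd_mm: float = 2.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.species_preset not in PRESETS:
            raise RejectedConfigurationError(
                f"species_preset must be one of {PRESETS}, got {self.species_preset!r}"
            )
        for name in ("pinch_N", "pinch_S"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise RejectedConfigurationError(f"{name} must be in [0, 1), got {v}")
        for name in ("keyhole_width_S", "pinch_sigma", "image_size",
                     "size_mean_mm", "size_sd_mm"):
            if not getattr(self, name) > 0:
                raise RejectedConfigurationError(f"{name} must be strictly positive")
        for name in ("keyhole_narrowing", "ridge_amp_N", "ridge_amp_S",
                     "band_amp_N", "band_amp_S", "fourier_noise_sd",
                     "shape_noise_sd"):
            if getattr(self, name) < 0:
                raise RejectedConfigurationError(f"{name} must be non-negative")
        if not 0.0 <= self.keyhole_narrowing < 1.0:
            raise RejectedConfigurationError("keyhole_narrowing must be in [0, 1)")
        if self.n_per_clade < self.n_locations_per_clade:
            raise RejectedConfigurationError(
                "n_per_clade must be >= n_locations_per_clade"
            )

    @property
    def has_keyhole(self) -> bool:
        return self.species_preset in ("keyhole_like", "weak_signal_like")

    @classmethod
    def preset(cls, name: str, **overrides) -> "GeneratorConfig":
        """Build the named species preset, optionally overriding fields."""
        base = cls(species_preset="keyhole_like")
        if name == "keyhole_like":
            cfg = base
        elif name == "weak_signal_like":
            # every clade contrast at 25% of the keyhole preset
            cfg = replace(
                base,
                species_preset="weak_signal_like",
                keyhole_narrowing=0.25 * base.keyhole_narrowing,
                pinch_N=0.25 * base.pinch_N,
            )
        elif name == "ridge_like":
            cfg = replace(
                base,
                species_preset="ridge_like",
                ridge_amp_N=0.08,
                ridge_amp_S=0.04,
            )
        elif name == "band_like":
            cfg = replace(
                base,
                species_preset="band_like",
                band_amp_N=0.22,
                band_amp_S=0.10,
            )
        else:
            raise RejectedConfigurationError(f"unknown preset {name!r}")
        return replace(cfg, **overrides)


def solve_pinch_for_ratio(target_ratio: float, pinch_sigma: float = 0.15) -> float:
    """Pinch amplitude p whose noise-free quartile/central width ratio is given.

    For the half-width profile the widths at the 25/50/75% height levels are
    ``c*(1 - q*p)`` (quartiles) and ``1 - p`` (centre) in units of W/2, with
    ``c = sqrt(3)/2`` and ``q = exp(-1 / (32 sigma^2))``, so the ratio
    ``R = c (1 - q p) / (1 - p)`` is solved linearly for p.
    """
    c = math.sqrt(3.0) / 2.0
    q = math.exp(-1.0 / (32.0 * pinch_sigma**2))
    if target_ratio < c - 1e-12:
        raise ValueError(
            f"target ratio {target_ratio} unreachable: minimum is {c:.4f} at p = 0"
        )
    p = (target_ratio - c) / (target_ratio - c * q)
    if not 0.0 <= p < 1.0:
        raise ValueError(f"target ratio {target_ratio} maps outside p in [0, 1)")
    return p


def keyhole_halfwidth(h: np.ndarray, W: float, H: float, p: float,
                      sigma_frac: float) -> np.ndarray:
    """Evaluate the keyhole half-width profile at heights ``h`` in [0, H]."""
    sigma = sigma_frac * H
    ell = np.sqrt(np.clip(1.0 - (2.0 * h / H - 1.0) ** 2, 0.0, None))
    pinch = 1.0 - p * np.exp(-((h - H / 2.0) ** 2) / (2.0 * sigma**2))
    return (W / 2.0) * ell * pinch


def _fourier_perturb(points: np.ndarray, sd: float, rng: np.random.Generator,
                     orders=(2, 3, 4, 5)) -> np.ndarray:
    """Low-order radial Fourier jitter about the centroid (in place safe)."""
    if sd == 0:
        return points
    c = points.mean(axis=0)
    rel = points - c
    phi = np.arctan2(rel[:, 1], rel[:, 0])
    factor = np.ones(len(points))
    for k in orders:
        a = rng.normal(0.0, sd)
        ph = rng.uniform(0, 2 * np.pi)
        factor += a * np.cos(k * phi + ph)
    return c + rel * factor[:, None]


def generate_keyhole_outline(config: GeneratorConfig, clade: str,
                             rng: np.random.Generator,
                             n_points: int = 256) -> Outline:
    """One specimen's keyhole boundary in local coordinates (y up, origin centre).

    W, H and p are drawn from clade-specific distributions: the Northern
    population mean width is ``(1 - keyhole_narrowing)`` times the Southern,
    and the Northern pinch amplitude is ``pinch_N`` (Southern ``pinch_S``).
    """
    if clade not in ("Northern", "Southern"):
        raise ValueError(f"clade must be Northern or Southern, got {clade!r}")
    w_base = config.keyhole_width_S
    if clade == "Northern":
        w_base *= 1.0 - config.keyhole_narrowing
        p_base = config.pinch_N
    else:
        p_base = config.pinch_S
    h_base = KEYHOLE_ASPECT * config.keyhole_width_S

    W = w_base * math.exp(rng.normal(0.0, config.shape_noise_sd))
    H = h_base * math.exp(rng.normal(0.0, config.shape_noise_sd))
    jitter = rng.normal(0.0, PINCH_JITTER_SD) if config.shape_noise_sd > 0 else 0.0
    p = float(np.clip(p_base + jitter, 0.0, 0.95))

    theta = np.linspace(0.0, 2.0 * np.pi, n_points, endpoint=False)
    h = H * (1.0 - np.cos(theta)) / 2.0
    pinch = 1.0 - p * np.exp(-((h - H / 2.0) ** 2) / (2.0 * (config.pinch_sigma * H) ** 2))
    x = (W / 2.0) * np.sin(theta) * pinch
    y = h - H / 2.0
    pts = np.column_stack([x, y])
    pts = _fourier_perturb(pts, config.fourier_noise_sd, rng)
    outline = Outline(pts).ensure_ccw()
    if not outline.is_simple():
        raise RejectedConfigurationError(
            "keyhole outline self-intersects; reduce pinch_N/pinch_S or "
            "fourier_noise_sd"
        )
    return outline


def generate_shell_outline(config: GeneratorConfig, clade: str,
                           rng: np.random.Generator,
                           n_points: int = 256) -> Outline:
    """One specimen's shell boundary: r(theta) = R (1 + harmonics + ridge bumps)."""
    if clade not in ("Northern", "Southern"):
        raise ValueError(f"clade must be Northern or Southern, got {clade!r}")
    amp = config.ridge_amp_N if clade == "Northern" else config.ridge_amp_S
    theta = np.linspace(0.0, 2.0 * np.pi, max(n_points, 180), endpoint=False)
    r = np.ones_like(theta)
    for k in (2, 3, 4):
        a = rng.normal(0.0, config.fourier_noise_sd)
        ph = rng.uniform(0, 2 * np.pi)
        r += a * np.cos(k * theta + ph)
    if config.ridge_count > 0 and amp > 0:
        amp_i = amp * math.exp(rng.normal(0.0, 0.2))
        centers = (np.arange(config.ridge_count) / config.ridge_count) * 2 * np.pi
        centers = centers + rng.normal(0.0, 0.02, size=config.ridge_count)
        for c in centers:
            d = np.angle(np.exp(1j * (theta - c)))  # wrapped difference
            r += amp_i * np.exp(-0.5 * (d / RIDGE_THETA_SD) ** 2)
    if np.any(r <= 0):
        raise RejectedConfigurationError(
            "shell radius non-positive; reduce fourier_noise_sd or ridge amplitudes"
        )
    pts = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
    outline = Outline(pts).ensure_ccw()
    if not outline.is_simple():
        raise RejectedConfigurationError("shell outline self-intersects")
    return outline


# ---------------------------------------------------------------------------
# rendering


def _fill_fraction(outline: Outline, size: int, supersample: int = 4) -> np.ndarray:
    """Anti-aliased coverage of the outline's interior on a size x size grid.

    Rasterized at ``supersample`` x resolution with PIL's scanline fill and
    block-averaged down, giving (supersample^2 + 1) coverage levels.
    """
    from PIL import ImageDraw

    ss = supersample
    pts = outline.points * ss + (ss - 1) / 2.0
    im = Image.new("L", (size * ss, size * ss), 0)
    ImageDraw.Draw(im).polygon([(float(x), float(y)) for x, y in pts], fill=255)
    big = np.asarray(im, dtype=np.float32) / 255.0
    return big.reshape(size, ss, size, ss).mean(axis=(1, 3))


def _binary_mask(outline: Outline, size: int) -> np.ndarray:
    pts = outline.points
    rc = np.column_stack([pts[:, 1], pts[:, 0]])
    return polygon2mask((size, size), rc)


def render_specimen(shell: Outline, keyhole: Outline | None,
                    config: GeneratorConfig, rng: np.random.Generator,
                    band_amp: float = 0.0):
    """Render one specimen on a black background.

    ``shell`` and ``keyhole`` are in image pixel coordinates (x = column,
    y = row).  Returns ``(image, shell_mask, keyhole_mask)`` with a float
    image in [0, 1] and boolean masks that exactly match the rasterized
    outlines.  Outlines exceeding the frame are uniformly rescaled toward the
    image centre (with a logged warning).
    """
    import warnings

    size = config.image_size
    for name, ol in (("shell", shell), ("keyhole", keyhole)):
        if ol is None:
            continue
        lo, hi = ol.points.min(), ol.points.max()
        if lo < 0 or hi > size - 1:
            center = np.array([size / 2.0, size / 2.0])
            span = np.abs(ol.points - center).max()
            factor = (size / 2.0 - 1.0) / span
            warnings.warn(f"{name} outline exceeds frame; rescaling by {factor:.3f}")
            shrunk = Outline(center + (shell.points - center) * factor)
            shell = shrunk
            if keyhole is not None:
                keyhole = Outline(center + (keyhole.points - center) * factor)

    shell_cov = _fill_fraction(shell, size)
    shell_mask = _binary_mask(shell, size)
    key_cov = None
    keyhole_mask = None
    if keyhole is not None:
        key_cov = _fill_fraction(keyhole, size)
        keyhole_mask = _binary_mask(keyhole, size) & shell_mask

    img = rng.normal(0.03, 0.012, size=(size, size)).astype(np.float32)
    texture = gaussian_filter(rng.normal(0.0, 1.0, size=(size, size)), 2.0)
    texture = 0.07 * texture / max(texture.std(), 1e-9)

    yy, xx = np.mgrid[0:size, 0:size]
    cx, cy = shell.centroid()
    rad = np.hypot(xx - cx, yy - cy)
    shading = 0.82 - 0.18 * (rad / (size / 2.0))

    body = shading + texture
    if band_amp > 0:
        body = body * (1.0 + band_amp * np.sin(2.0 * np.pi * rad / (size * 0.07)))
    img = img * (1.0 - shell_cov) + body.astype(np.float32) * shell_cov
    if key_cov is not None:
        hole = 0.07 + rng.normal(0.0, 0.01, size=(size, size)).astype(np.float32)
        img = img * (1.0 - key_cov) + hole * key_cov
    img = np.clip(img, 0.0, 1.0)
    return img, shell_mask, keyhole_mask


# ---------------------------------------------------------------------------
# dataset assembly


def draw_major_axes(config: GeneratorConfig, n: int,
                    rng: np.random.Generator) -> np.ndarray:
    """Caliper sizes (mm); both clades share one overlapping distribution."""
    return np.clip(rng.normal(config.size_mean_mm, config.size_sd_mm, size=n),
                   config.size_mean_mm * 0.4, None)


def _save_png(path: Path, arr: np.ndarray) -> None:
    if arr.dtype == bool:
        Image.fromarray((arr * 255).astype(np.uint8), mode="L").save(path)
    else:
        Image.fromarray(
            np.round(np.clip(arr, 0, 1) * 255).astype(np.uint8), mode="L"
        ).save(path)


def generate_dataset(config: GeneratorConfig, out_dir: str | Path
                     ) -> list[SpecimenRecord]:
    """Write images, masks and metadata for ``2 * n_per_clade`` specimens.

    Fully reproducible: the same config (including seed) produces
    byte-identical PNGs and metadata CSV.  Returns the specimen records; the
    metadata table is written to ``<out_dir>/metadata.csv``.
    """
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "masks").mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    size = config.image_size
    records: list[SpecimenRecord] = []
    for clade in ("Northern", "Southern"):
        prefix = clade[0]
        locations = [f"{prefix}{i + 1}" for i in range(config.n_locations_per_clade)]
        sizes_mm = draw_major_axes(config, config.n_per_clade, rng)
        loc_idx = rng.integers(0, len(locations), size=config.n_per_clade)
        band_amp = config.band_amp_N if clade == "Northern" else config.band_amp_S
        for i in range(config.n_per_clade):
            sid = f"{config.species_preset}-{prefix}{i:04d}"
            size_factor = float(np.clip(sizes_mm[i] / config.size_mean_mm, 0.7, 1.3))
            shell = generate_shell_outline(config, clade, rng)
            radius_px = SHELL_FRAME_FRACTION * size * size_factor / 2.0
            center = size / 2.0 + rng.uniform(-2.0, 2.0, size=2)
            shell_px = Outline(shell.points * radius_px + center).ensure_ccw()
            keyhole_px = None
            if config.has_keyhole:
                key = generate_keyhole_outline(config, clade, rng)
                key_px = key.points * (size * size_factor) + center
                keyhole_px = Outline(key_px).ensure_ccw()
            img, smask, kmask = render_specimen(
                shell_px, keyhole_px, config, rng, band_amp=band_amp
            )
            img_path = f"images/{sid}.png"
            mask_path = f"masks/{sid}_shell.png"
            _save_png(out_dir / img_path, img)
            _save_png(out_dir / mask_path, smask)
            kmask_path = None
            if kmask is not None:
                kmask_path = f"masks/{sid}_keyhole.png"
                _save_png(out_dir / kmask_path, kmask)
            records.append(
                SpecimenRecord(
                    specimen_id=sid,
                    species=config.species_preset,
                    clade=clade,
                    location=locations[loc_idx[i]],
                    orientation="dorsal",
                    image_path=img_path,
                    mask_path=mask_path,
                    keyhole_mask_path=kmask_path,
                    major_axis_mm=round(float(sizes_mm[i]), 3),
                )
            )
    write_metadata(records, out_dir / "metadata.csv")
    return records
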