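"""Seeded resampling protocol: location capping, split assignment,
mixed-group relabeling and image augmentation.

Each resampling iteration draws, per class, a fixed number of training and
validation specimens from the pool; everything left over (plus any
per-location overflow) forms the Full-test pool, from which a class-balanced
Even-test subset is drawn.  The whole split is a pure function of
``(records, config, iteration_id)`` via ``seed = base_seed + iteration_id``.

The mixed-group control replaces the two clade labels by two synthetic
classes each containing equal numbers of true-Northern and true-Southern
specimens, destroying any clade signal while leaving every other property of
the experiment untouched; a classifier trained on such labels can only reach
chance-level test performance if it was previously exploiting genuine
clade-specific features.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage

from .records import SpecimenRecord

logger = logging.getLogger(__name__)

MIXED_CLASSES = ("mix_A", "mix_B")


class SizingError(ValueError):
    """Pool too small for the requested split sizes."""


@dataclass(frozen=True)
class AugmentationConfig:
    rotation_degrees: tuple[float, float] = (-30.0, 30.0)
    flip_horizontal: bool = True
    flip_vertical: bool = True
    flip_probability: float = 0.5
    scale: tuple[float, float] = (0.9, 1.1)


@dataclass(frozen=True)
class ProtocolConfig:
    n_train_per_class: int = 120
    n_val_per_class: int = 30
    n_even_test_per_class: int = 20
    location_cap: int = 100
    n_iterations: int = 100
    base_seed: int = 0
    augmentation: AugmentationConfig = field(default_factory=AugmentationConfig)

    def __post_init__(self) -> None:
        for name in ("n_train_per_class", "n_val_per_class",
                     "n_even_test_per_class", "location_cap", "n_iterations"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")


def desk_scale_protocol(base_seed: int = 0, n_iterations: int = 20
                        ) -> ProtocolConfig:
    """Reduced-size protocol (60 train / 15 val / 20 even-test per class)
    for laptop-scale experiments; the full-scale numbers stay the defaults."""
    return ProtocolConfig(
        n_train_per_class=60,
        n_val_per_class=15,
        n_even_test_per_class=20,
        n_iterations=n_iterations,
        base_seed=base_seed,
    )


@dataclass(frozen=True)
class SplitPlan:
    """One iteration's specimen assignment.

    ``train_ids``, ``val_ids``, ``even_test_ids`` and ``full_test_ids`` are
    pairwise disjoint; the test pool is ``even_test_ids + full_test_ids``
    (the Even-test is drawn from the pool and reported separately).
    """

    iteration_id: int
    seed: int
    train_ids: tuple[str, ...]
    val_ids: tuple[str, ...]
    even_test_ids: tuple[str, ...]
    full_test_ids: tuple[str, ...]
    label_map: dict[str, str]
    mixed: bool

    @property
    def test_pool_ids(self) -> tuple[str, ...]:
        return self.even_test_ids + self.full_test_ids

    def to_json(self, path: str | Path) -> None:
        d = asdict(self)
        Path(path).write_text(json.dumps(d, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "SplitPlan":
        d = json.loads(Path(path).read_text())
        for k in ("train_ids", "val_ids", "even_test_ids", "full_test_ids"):
            d[k] = tuple(d[k])
        return cls(**d)


def cap_locations(records: list[SpecimenRecord], cap: int,
                  rng: np.random.Generator
                  ) -> tuple[list[SpecimenRecord], list[SpecimenRecord]]:
    """Retain at most ``cap`` specimens per location for the train/val pool;
    the randomly chosen remainder is routed to the test pool."""
    if cap < 1:
        raise ValueError("cap must be >= 1")
    by_loc: dict[str, list[SpecimenRecord]] = {}
    for r in records:
        by_loc.setdefault(r.location, []).append(r)
    kept, overflow = [], []
    for loc in sorted(by_loc):
        group = by_loc[loc]
        if len(group) <= cap:
            kept.extend(group)
        else:
            idx = rng.permutation(len(group))
            kept.extend(group[i] for i in idx[:cap])
            overflow.extend(group[i] for i in idx[cap:])
    return kept, overflow


def make_mixed_groups(records: list[SpecimenRecord], rng: np.random.Generator
                      ) -> dict[str, str]:
    """Random relabeling into two synthetic classes, each with equal numbers
    of true-Northern and true-Southern specimens.

    Odd per-clade counts drop one specimen at random (logged).  The true
    labels stay on the records themselves, which is the audit channel.
    """
    by_clade: dict[str, list[str]] = {"Northern": [], "Southern": []}
    for r in records:
        by_clade[r.clade].append(r.specimen_id)
    label_map: dict[str, str] = {}
    for clade, ids in by_clade.items():
        ids = sorted(ids)
        perm = rng.permutation(len(ids))
        if len(ids) % 2 == 1:
            dropped = ids[perm[-1]]
            logger.info("odd %s count; dropping %s for parity", clade, dropped)
            perm = perm[:-1]
        half = len(perm) // 2
        for i in perm[:half]:
            label_map[ids[i]] = MIXED_CLASSES[0]
        for i in perm[half:]:
            label_map[ids[i]] = MIXED_CLASSES[1]
    return label_map


def make_split(records: list[SpecimenRecord], config: ProtocolConfig,
               iteration_id: int, mixed: bool = False) -> SplitPlan:
    """Build one iteration's SplitPlan (pure function of its arguments)."""
    seed = config.base_seed + iteration_id
    rng = np.random.default_rng(seed)
    kept, overflow = cap_locations(records, config.location_cap, rng)
    if mixed:
        label_map = make_mixed_groups(records, rng)
    else:
        label_map = {r.specimen_id: r.clade for r in records}
    classes = sorted(set(label_map.values()))

    kept_by_class: dict[str, list[str]] = {c: [] for c in classes}
    for r in kept:
        if r.specimen_id in label_map:
            kept_by_class[label_map[r.specimen_id]].append(r.specimen_id)
    test_pool_by_class: dict[str, list[str]] = {c: [] for c in classes}
    for r in overflow:
        if r.specimen_id in label_map:
            test_pool_by_class[label_map[r.specimen_id]].append(r.specimen_id)

    train, val = [], []
    n_needed = config.n_train_per_class + config.n_val_per_class
    for c in classes:
        ids = sorted(kept_by_class[c])
        if len(ids) < n_needed:
            raise SizingError(
                f"class {c!r}: pool of {len(ids)} < train+val {n_needed} "
                f"(shortfall {n_needed - len(ids)})"
            )
        perm = rng.permutation(len(ids))
        train.extend(ids[i] for i in perm[:config.n_train_per_class])
        val.extend(ids[i] for i in perm[config.n_train_per_class:n_needed])
        test_pool_by_class[c].extend(ids[i] for i in perm[n_needed:])

    even, full = [], []
    for c in classes:
        pool = sorted(test_pool_by_class[c])
        if len(pool) < config.n_even_test_per_class:
            raise SizingError(
                f"class {c!r}: test pool of {len(pool)} < even-test "
                f"{config.n_even_test_per_class} "
                f"(shortfall {config.n_even_test_per_class - len(pool)})"
            )
        perm = rng.permutation(len(pool))
        even.extend(pool[i] for i in perm[:config.n_even_test_per_class])
        full.extend(pool[i] for i in perm[config.n_even_test_per_class:])

    return SplitPlan(
        iteration_id=iteration_id,
        seed=seed,
        train_ids=tuple(train),
        val_ids=tuple(val),
        even_test_ids=tuple(even),
        full_test_ids=tuple(full),
        label_map=label_map,
        mixed=mixed,
    )


# ---------------------------------------------------------------------------
# augmentation


def sample_augment_params(aug: AugmentationConfig,
                          rng: np.random.Generator) -> dict:
    angle = float(rng.uniform(*aug.rotation_degrees))
    flip_h = bool(aug.flip_horizontal and rng.random() < aug.flip_probability)
    flip_v = bool(aug.flip_vertical and rng.random() < aug.flip_probability)
    scale = float(rng.uniform(*aug.scale))
    return {"angle": angle, "flip_h": flip_h, "flip_v": flip_v, "scale": scale}


def _rescale_keep_shape(image: np.ndarray, scale: float) -> np.ndarray:
    h, w = image.shape
    zoomed = ndimage.zoom(image, scale, order=1, mode="constant", cval=0.0,
                          grid_mode=False)
    out = np.zeros_like(image)
    zh, zw = zoomed.shape
    if zh >= h:
        r0, c0 = (zh - h) // 2, (zw - w) // 2
        out[...] = zoomed[r0:r0 + h, c0:c0 + w]
    else:
        r0, c0 = (h - zh) // 2, (w - zw) // 2
        out[r0:r0 + zh, c0:c0 + zw] = zoomed
    return out


def apply_augmentation(image: np.ndarray, params: dict) -> np.ndarray:
    """Apply sampled augmentation; identity parameters return the image
    bit-identically.  Output shape always equals input shape."""
    out = np.asarray(image, dtype=np.float32)
    if params["flip_h"]:
        out = out[:, ::-1]
    if params["flip_v"]:
        out = out[::-1, :]
    if params["angle"] != 0.0:
        out = ndimage.rotate(out, params["angle"], reshape=False, order=1,
                             mode="constant", cval=0.0)
    if params["scale"] != 1.0:
        out = _rescale_keep_shape(out, params["scale"])
    return np.ascontiguousarray(out)


def augment_image(image: np.ndarray, aug: AugmentationConfig,
                  rng: np.random.Generator) -> np.ndarray:
    """Seeded rotation / flip / rescale with unchanged output dimensions."""
    if image.size == 0:
        raise ValueError("empty image")
    return apply_augmentation(image, sample_augment_params(aug, rng))
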