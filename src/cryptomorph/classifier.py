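"""Two-class shell classifier: training, F1 evaluation and the repeated
resampling experiment.

A lightweight NumPy CNN (see :mod:`cryptomorph.nn`) is trained per split;
training and validation batches are augmented on the fly, test images never
are.  Performance is summarized as macro-F1 (mean over classes of
``2 P R / (P + R)``, with a class lacking predicted positives scoring
precision 0 and F1 0); per-class precision/recall/F1 are always carried
along for audit.  ``run_iterations`` repeats split -> train -> evaluate over
seeded iterations, for either genuine clade labels or the mixed-group
control.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from skimage.transform import resize

from .nn import SmallCNN, Adam, cross_entropy
from .records import SpecimenRecord
from .sampling import (ProtocolConfig, SplitPlan, make_split,
                       sample_augment_params, apply_augmentation)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ModelConfig:
    backbone: str = "small_cnn"
    conv_channels: tuple[int, ...] = (16, 32, 64)
    dense_units: int = 64
    input_size: int = 128
    epochs: int = 20
    batch_size: int = 16
    learning_rate: float = 1e-3
    early_stop_patience: int = 5
    # warmup: early stopping neither restores nor halts before this epoch,
    # so a model whose validation loss never improves (e.g. trained on
    # randomized labels) is still a *trained* network rather than a
    # near-initialization one that predicts a single class everywhere
    min_epochs: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.input_size % (2 ** len(self.conv_channels)) != 0:
            raise ValueError("input_size must halve evenly through the blocks")


def desk_scale_model_config(seed: int = 0) -> ModelConfig:
    """Small configuration for laptop-scale runs.

    48-px inputs: the input resolution must still resolve the keyhole
    aperture (~5 px wide after downsampling); coarser inputs blur away
    exactly the feature under study.  The backbone keeps the full default
    capacity (16/32/64 channels): the mixed-group control is only a valid
    chance-level benchmark if the network has enough capacity to fit
    random labels, and under-sized models collapse to constant predictions
    instead.
    """
    return ModelConfig(conv_channels=(16, 32, 64), dense_units=64,
                       input_size=48, epochs=15, batch_size=16,
                       early_stop_patience=4, seed=seed)


@dataclass(frozen=True)
class F1Result:
    classes: tuple[str, ...]
    precision_per_class: tuple[float, ...]
    recall_per_class: tuple[float, ...]
    f1_per_class: tuple[float, ...]
    macro_f1: float
    n_test: int
    test_kind: str


@dataclass
class IterationResults:
    """F1 results across resampling iterations, serializable to a flat table."""

    rows: list[dict] = field(default_factory=list)
    mixed: bool = False
    config_fingerprint: str = ""
    n_failures: int = 0

    def add(self, iteration: int, seed: int, result: F1Result) -> None:
        for cls, p, r, f in zip(result.classes, result.precision_per_class,
                                result.recall_per_class, result.f1_per_class):
            self.rows.append({
                "iteration": iteration, "seed": seed, "mixed": self.mixed,
                "test_kind": result.test_kind, "class": cls,
                "precision": p, "recall": r, "f1": f,
                "macro_f1": result.macro_f1,
            })

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)

    def macro_f1_values(self, test_kind: str = "even") -> np.ndarray:
        df = self.to_frame()
        df = df[df.test_kind == test_kind]
        return df.groupby("iteration")["macro_f1"].first().to_numpy()

    @property
    def n_iterations(self) -> int:
        return len({r["iteration"] for r in self.rows})

    def summary(self, test_kind: str = "even") -> dict:
        v = self.macro_f1_values(test_kind)
        return {
            "n_iterations": len(v), "median": float(np.median(v)),
            "min": float(v.min()), "max": float(v.max()),
            "iqr": float(np.percentile(v, 75) - np.percentile(v, 25)),
            "mixed": self.mixed, "test_kind": test_kind,
        }


class ImageDataset:
    """Images + records of one generated (or user-supplied) dataset.

    Loads grayscale PNGs as float arrays in [0, 1] and caches per-size
    resampled copies so repeated iterations do not re-read the disk.
    """

    def __init__(self, records: list[SpecimenRecord], root: str | Path):
        self.records = list(records)
        self.root = Path(root)
        self.by_id = {r.specimen_id: r for r in self.records}
        self._raw: dict[str, np.ndarray] = {}
        self._resized: dict[tuple[str, int], np.ndarray] = {}

    def raw_image(self, specimen_id: str) -> np.ndarray:
        if specimen_id not in self._raw:
            rec = self.by_id[specimen_id]
            arr = np.asarray(Image.open(self.root / rec.image_path),
                             dtype=np.float32) / 255.0
            self._raw[specimen_id] = arr
        return self._raw[specimen_id]

    def mask(self, specimen_id: str, region: str = "shell") -> np.ndarray:
        rec = self.by_id[specimen_id]
        path = rec.mask_path if region == "shell" else rec.keyhole_mask_path
        if path is None:
            raise ValueError(f"{specimen_id} has no {region} mask")
        return np.asarray(Image.open(self.root / path)) > 127

    def image(self, specimen_id: str, size: int) -> np.ndarray:
        key = (specimen_id, size)
        if key not in self._resized:
            raw = self.raw_image(specimen_id)
            if raw.shape[0] == size:
                self._resized[key] = raw
            else:
                self._resized[key] = resize(
                    raw, (size, size), order=1, anti_aliasing=True,
                    preserve_range=True,
                ).astype(np.float32)
        return self._resized[key]

    def stack(self, ids, size: int) -> np.ndarray:
        return np.stack([self.image(i, size) for i in ids])


# ---------------------------------------------------------------------------


def compute_f1(y_true: np.ndarray, y_pred: np.ndarray,
               classes: tuple[str, ...], test_kind: str) -> F1Result:
    """Per-class precision/recall/F1 and macro-F1 from label arrays.

    Zero-division convention: a class never predicted has precision 0 and
    hence F1 0; a class absent from the truth has recall 0.
    """
    known = set(classes)
    for arr in (y_true, y_pred):
        unknown = set(arr) - known
        if unknown:
            raise ValueError(f"unknown labels {sorted(unknown)}")
    ps, rs, fs = [], [], []
    for c in classes:
        tp = int(np.sum((y_pred == c) & (y_true == c)))
        fp = int(np.sum((y_pred == c) & (y_true != c)))
        fn = int(np.sum((y_pred != c) & (y_true == c)))
        p = tp / (tp + fp) if tp + fp > 0 else 0.0
        r = tp / (tp + fn) if tp + fn > 0 else 0.0
        f = 2 * p * r / (p + r) if p + r > 0 else 0.0
        ps.append(p)
        rs.append(r)
        fs.append(f)
    return F1Result(
        classes=tuple(classes),
        precision_per_class=tuple(ps),
        recall_per_class=tuple(rs),
        f1_per_class=tuple(fs),
        macro_f1=float(np.mean(fs)),
        n_test=len(y_true),
        test_kind=test_kind,
    )


class TrainedModel:
    """A trained network plus its class vocabulary."""

    def __init__(self, net: SmallCNN, classes: tuple[str, ...],
                 input_size: int):
        self.net = net
        self.classes = classes
        self.input_size = input_size
        self.gradient_capable = True

    def predict_labels(self, images: np.ndarray) -> np.ndarray:
        idx = self.net.predict(images)
        return np.asarray([self.classes[i] for i in idx])

    def predict_scores(self, images: np.ndarray) -> np.ndarray:
        return self.net.predict_proba(images)

    def input_gradient(self, images: np.ndarray, target_class) -> np.ndarray:
        return self.net.input_gradient(images, target_class)


def train_classifier(split: SplitPlan, dataset: ImageDataset,
                     model_config: ModelConfig,
                     protocol: ProtocolConfig | None = None) -> TrainedModel:
    """Train the small CNN on one split.

    Training and validation batches are augmented on the fly (per the
    protocol's augmentation config); early stopping monitors validation loss
    and the best-epoch weights are restored.  Fully seeded via
    ``model_config.seed`` combined with the split seed.
    """
    if len(split.train_ids) == 0:
        raise ValueError("empty training set")
    aug = (protocol or ProtocolConfig()).augmentation
    classes = tuple(sorted(set(split.label_map.values())))
    cls_index = {c: i for i, c in enumerate(classes)}
    size = model_config.input_size
    seed = int((model_config.seed * 1_000_003 + split.seed) % (2**31))
    rng = np.random.default_rng(seed)

    net = SmallCNN(size, tuple(model_config.conv_channels),
                   model_config.dense_units, n_classes=len(classes),
                   seed=seed)
    opt = Adam(net.params, lr=model_config.learning_rate)

    x_train = dataset.stack(split.train_ids, size)
    y_train = np.array([cls_index[split.label_map[i]] for i in split.train_ids])
    x_val = dataset.stack(split.val_ids, size)
    y_val = np.array([cls_index[split.label_map[i]] for i in split.val_ids])

    def augment_batch(xb: np.ndarray) -> np.ndarray:
        return np.stack([
            apply_augmentation(im, sample_augment_params(aug, rng))
            for im in xb
        ])

    best_loss, best_state, best_epoch = np.inf, net.get_state(), 0
    n = len(x_train)
    bs = model_config.batch_size
    for epoch in range(model_config.epochs):
        order = rng.permutation(n)
        for start in range(0, n, bs):
            sel = order[start:start + bs]
            xb = augment_batch(x_train[sel])
            logits = net.forward(xb, store=True)
            loss, dl = cross_entropy(logits, y_train[sel])
            net.zero_grads()
            net.backward(dl)
            opt.step(net.grads)
        val_logits = net.forward(augment_batch(x_val))
        val_loss, _ = cross_entropy(val_logits, y_val)
        warm = epoch < model_config.min_epochs
        if val_loss < best_loss - 1e-5 or (warm and epoch >= best_epoch):
            best_loss = min(best_loss, val_loss)
            best_state, best_epoch = net.get_state(), epoch
        elif epoch - best_epoch >= model_config.early_stop_patience:
            logger.debug("early stop at epoch %d (best %d)", epoch, best_epoch)
            break
    net.set_state(best_state)
    return TrainedModel(net, classes, size)


def evaluate_f1(model: TrainedModel, dataset: ImageDataset, test_ids,
                label_map: dict[str, str], test_kind: str) -> F1Result:
    if len(test_ids) == 0:
        raise ValueError("empty test set")
    x = dataset.stack(test_ids, model.input_size)
    y_true = np.asarray([label_map[i] for i in test_ids])
    y_pred = model.predict_labels(x)
    return compute_f1(y_true, y_pred, model.classes, test_kind)


def run_iterations(dataset: ImageDataset, protocol: ProtocolConfig,
                   model_config: ModelConfig, mixed: bool = False
                   ) -> IterationResults:
    """Repeat split -> train -> Even/Full-test evaluation over iterations."""
    results = IterationResults(
        mixed=mixed,
        config_fingerprint=f"{protocol}|{model_config}|mixed={mixed}",
    )
    failures = 0
    for it in range(protocol.n_iterations):
        try:
            split = make_split(dataset.records, protocol, it, mixed=mixed)
            model = train_classifier(split, dataset, model_config, protocol)
            even = evaluate_f1(model, dataset, split.even_test_ids,
                               split.label_map, "even")
            full = evaluate_f1(model, dataset, split.test_pool_ids,
                               split.label_map, "full")
            results.add(it, split.seed, even)
            results.add(it, split.seed, full)
        except Exception:  # noqa: BLE001 - per-iteration failures are recorded
            failures += 1
            logger.exception("iteration %d failed; skipping", it)
            if failures > 0.2 * protocol.n_iterations:
                raise RuntimeError(
                    f"{failures} of {protocol.n_iterations} iterations failed"
                )
    results.n_failures = failures
    return results


class RegionCropDataset:
    """View of an :class:`ImageDataset` cropped to one region per specimen.

    Feeds the region (bounding box plus a margin, resized to the model
    input) to the classifier instead of the whole image — the re-submission
    experiment that asks how much of the discriminative signal lives in the
    highlighted structure alone.
    """

    def __init__(self, base: ImageDataset, region: str = "keyhole",
                 margin_fraction: float = 0.1):
        self.base = base
        self.records = base.records
        self.region = region
        self.margin_fraction = margin_fraction
        self._cache: dict[tuple[str, int], np.ndarray] = {}

    def image(self, specimen_id: str, size: int) -> np.ndarray:
        key = (specimen_id, size)
        if key not in self._cache:
            raw = self.base.raw_image(specimen_id)
            mask = self.base.mask(specimen_id, self.region)
            self._cache[key] = crop_to_region(
                raw, mask, self.margin_fraction, output_size=size)
        return self._cache[key]

    def stack(self, ids, size: int) -> np.ndarray:
        return np.stack([self.image(i, size) for i in ids])


def crop_to_region(image: np.ndarray, region_mask: np.ndarray,
                   margin_fraction: float = 0.1,
                   output_size: int | None = None) -> np.ndarray:
    """Crop to the region's bounding box expanded by ``margin_fraction`` per
    side (clipped to the image), optionally resized to ``output_size``."""
    mask = np.asarray(region_mask).astype(bool)
    if mask.sum() == 0:
        raise ValueError("empty region mask")
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    r0, r1 = rows[0], rows[-1] + 1
    c0, c1 = cols[0], cols[-1] + 1
    mr = int(round((r1 - r0) * margin_fraction))
    mc = int(round((c1 - c0) * margin_fraction))
    r0, r1 = max(0, r0 - mr), min(image.shape[0], r1 + mr)
    c0, c1 = max(0, c0 - mc), min(image.shape[1], c1 + mc)
    out = np.asarray(image, dtype=np.float32)[r0:r1, c0:c1]
    if output_size is not None:
        out = resize(out, (output_size, output_size), order=1,
                     anti_aliasing=True, preserve_range=True).astype(np.float32)
    return out
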