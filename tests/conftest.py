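"""Shared fixtures: session-scoped synthetic datasets and trained-model
experiment results, so the expensive pieces are built once."""

from __future__ import annotations

import numpy as np
import pytest

from cryptomorph import (GeneratorConfig, ImageDataset, generate_dataset,
                         desk_scale_model_config, desk_scale_protocol,
                         run_iterations, compute_metrics_table)

KEYHOLE_SEED = 42
WEAK_SEED = 43


@pytest.fixture(scope="session")
def keyhole_dataset(tmp_path_factory):
    """keyhole_like dataset, 200 specimens per clade (the study conditions)."""
    root = tmp_path_factory.mktemp("keyhole_data")
    cfg = GeneratorConfig.preset("keyhole_like", n_per_clade=200,
                                 seed=KEYHOLE_SEED)
    records = generate_dataset(cfg, root)
    return cfg, records, ImageDataset(records, root)


@pytest.fixture(scope="session")
def weak_dataset(tmp_path_factory):
    """weak_signal_like dataset: clade contrasts at 25% strength."""
    root = tmp_path_factory.mktemp("weak_data")
    cfg = GeneratorConfig.preset("weak_signal_like", n_per_clade=200,
                                 seed=WEAK_SEED)
    records = generate_dataset(cfg, root)
    return cfg, records, ImageDataset(records, root)


@pytest.fixture(scope="session")
def tiny_dataset(tmp_path_factory):
    """Small keyhole dataset for fast unit tests (30 per clade)."""
    root = tmp_path_factory.mktemp("tiny_data")
    cfg = GeneratorConfig.preset("keyhole_like", n_per_clade=30, seed=7,
                                 n_locations_per_clade=2)
    records = generate_dataset(cfg, root)
    return cfg, records, ImageDataset(records, root)


@pytest.fixture(scope="session")
def keyhole_metrics(keyhole_dataset):
    """Five-descriptor table for every keyhole mask of the main dataset."""
    cfg, records, ds = keyhole_dataset
    return compute_metrics_table(records, ds.root, region="keyhole")


@pytest.fixture(scope="session")
def keyhole_runs(keyhole_dataset):
    """20 clade-based and 20 mixed-group resampling iterations at desk scale
    (60 train / 15 val / 20 even-test per class) on the main dataset."""
    _, records, ds = keyhole_dataset
    proto = desk_scale_protocol(base_seed=100, n_iterations=20)
    mc = desk_scale_model_config(seed=0)
    clade = run_iterations(ds, proto, mc, mixed=False)
    mixed = run_iterations(ds, proto, mc, mixed=True)
    return clade, mixed


@pytest.fixture(scope="session")
def weak_runs(weak_dataset):
    """5 clade-based iterations on the weak-signal dataset (enough to rank
    its median F1 against the keyhole preset's)."""
    _, records, ds = weak_dataset
    proto = desk_scale_protocol(base_seed=100, n_iterations=5)
    mc = desk_scale_model_config(seed=0)
    return run_iterations(ds, proto, mc, mixed=False)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
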