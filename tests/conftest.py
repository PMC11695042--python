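"""Shared fixtures and dataset builders for the blockpls test suite."""

from __future__ import annotations

import numpy as np
import pytest

from blockpls import BlockPartition, Dataset, FitOptions, autoscale, fit_mbpls


def make_dataset(rng, n=12, p=8, signal=True):
    """Random Dataset with generic-position X and (optionally) a linear signal."""
    X = rng.standard_normal((n, p))
    if signal:
        beta = rng.standard_normal(p)
        y = X @ beta + 0.3 * rng.standard_normal(n)
    else:
        y = rng.standard_normal(n)
    return Dataset(
        X=X,
        sample_ids=[f"s{i}" for i in range(n)],
        variable_ids=[f"g{j}" for j in range(p)],
        y=y,
    )


def random_partition(rng, p, n_blocks):
    """Random partition of p variables into n_blocks non-empty blocks."""
    labels = np.concatenate(
        [np.arange(1, n_blocks + 1), rng.integers(1, n_blocks + 1, size=p - n_blocks)]
    )
    return BlockPartition(labels=rng.permutation(labels))


def random_fit(rng, n=None, p=None, n_blocks=None, n_components=None):
    """Random scaled fit with varied shape; returns (model, scaled_ds, partition)."""
    n = n or int(rng.integers(8, 40))
    p = p or int(rng.integers(5, 60))
    n_blocks = n_blocks or int(rng.integers(1, min(6, p) + 1))
    n_components = n_components or int(rng.integers(1, 5))
    ds = make_dataset(rng, n=n, p=p)
    scaled, params = autoscale(ds)
    partition = random_partition(rng, p, n_blocks)
    model = fit_mbpls(
        scaled, partition, FitOptions(n_components=n_components), scaling=params
    )
    return model, scaled, partition


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
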