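"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from betanet.betaseries import WeightedNetwork


def brute_force_qstar(w: np.ndarray, labels: np.ndarray, gamma: float) -> float:
    """Naive signed-modularity evaluation by explicit double loops.

    Independent oracle for Q*: positive and negative parts handled with
    their own configuration-model expectations, negative sum normalized
    by the total weight.
    """
    n = w.shape[0]
    wp = np.maximum(w, 0.0)
    wn = -np.minimum(w, 0.0)
    vp, vn = wp.sum(), wn.sum()
    sp, sn = wp.sum(axis=1), wn.sum(axis=1)
    q = 0.0
    for i in range(n):
        for j in range(n):
            if labels[i] != labels[j]:
                continue
            if vp > 0:
                q += (wp[i, j] - gamma * sp[i] * sp[j] / vp) / vp
            if vn > 0:
                q -= (wn[i, j] - gamma * sn[i] * sn[j] / vn) / (vp + vn)
    return q


def set_partitions(n: int):
    """All set partitions of range(n) as label lists (restricted growth strings)."""
    def rec(prefix):
        if len(prefix) == n:
            yield list(prefix)
            return
        m = max(prefix) + 1 if prefix else 0
        for k in range(m + 1):
            yield from rec(prefix + [k])
    yield from rec([])


def random_signed_network(n: int, rng: np.random.Generator) -> WeightedNetwork:
    w = rng.normal(size=(n, n))
    w = (w + w.T) / 2.0
    np.fill_diagonal(w, 0.0)
    return WeightedNetwork(w=w)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def planted_labels():
    """Four equal communities over 40 regions."""
    return np.sort(np.arange(40) % 4)
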