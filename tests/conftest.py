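"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the package's own neighbour machinery:
they enumerate the full distance matrix and apply the statistic definitions
directly, so agreement is a genuine cross-check rather than a tautology.
"""

from __future__ import annotations

import numpy as np
import pytest

import poicoloc as pc

TIE_EPS_REL = 1e-9
TIE_EPS_ABS = 1e-12


def brute_knn(coords: np.ndarray, i: int, k: int):
    """All-pairs k-nearest neighbours of point i, ties at rank k included."""
    d = np.sqrt(((coords - coords[i]) ** 2).sum(axis=1))
    d[i] = np.inf
    order = np.argsort(d, kind="stable")
    dk = d[order[k - 1]]
    cut = dk + TIE_EPS_REL * dk + TIE_EPS_ABS
    keep = order[d[order] <= cut]
    return keep, d[keep]


def brute_weighted_ab_count(coords, labels, a, b, k):
    """Direct per-point enumeration of the tie-weighted A→B neighbour count."""
    total = 0.0
    for i in np.flatnonzero(labels == a):
        nbr, _ = brute_knn(coords, i, k)
        total += (labels[nbr] == b).sum() / len(nbr)
    return total


def brute_lclq(coords, labels, i, b, k):
    """Direct evaluation of the kernel-weighted local quotient at focal i."""
    nbr, d = brute_knn(coords, i, k)
    d_ib = d[k - 1]
    w = np.exp(-0.5 * d**2 / d_ib**2)
    share = (w * (labels[nbr] == b)).sum() / w.sum()
    n = len(coords)
    n_b = (labels == b).sum() - (1 if labels[i] == b else 0)
    return share * (n - 1) / n_b, share, d_ib


def make_pattern(coords, labels, area=None, region=None):
    coords = np.asarray(coords, dtype=float)
    ids = [f"p{i}" for i in range(len(coords))]
    if region is None and area is None:
        area = 1.0
    return pc.CategoricalPointPattern(ids, coords, list(labels), region=region, area=area)


@pytest.fixture
def csr_two_cat():
    """Fixed 60-point CSR scene with three categories (brute-force scale)."""
    rng = np.random.default_rng(101)
    coords = rng.uniform(0, 1, size=(60, 2))
    labels = np.array(list("ABC") * 20)
    rng.shuffle(labels)
    return make_pattern(coords, labels)


@pytest.fixture
def attraction_scene():
    """Planted B→A attraction: B Gaussian-displaced from CSR A anchors, with
    an independent CSR background category C diluting the expected share."""
    a = pc.simulate_csr(100, (0, 0, 1, 1), 5)
    c = pc.simulate_csr(100, (0, 0, 1, 1), 55)
    b = pc.simulate_attracted(a, "B", 60, sigma=0.003, seed=6)
    return pc.merge_patterns([a, c, b], ["A", "C", "B"], (0, 0, 1, 1))


def asymmetric_scene():
    """Deterministic one-way colocation: each motif is a close B pair with an
    A satellite, so every A's nearest point is a B while every B's nearest is
    its sibling B; CSR-free by construction."""
    coords, labels = [], []
    for i in range(10):
        x = i * 10.0
        coords += [[x, 0.0], [x, 0.5], [x + 1.5, 0.0]]
        labels += ["B", "B", "A"]
    for j in range(20):
        coords.append([j * 5.0 + 2.5, 50.0])
        labels.append("C")
    return make_pattern(coords, labels, area=100.0 * 55.0)
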