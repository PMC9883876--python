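"""Geographically weighted local colocation quotient (LCLQ).

Where the global quotient summarises a whole study area, the local variant
asks the colocation question at each individual type-A point, weighting that
point's neighbours by a Gaussian kernel under an adaptive bandwidth:

    w_ij = exp(-0.5 * d_ij^2 / d_ib^2)
    N_{A_i→B} = sum_j w_ij f_ij / sum_j w_ij      (f_ij = 1 iff j is type B)
    LCLQ_{A_i→B} = N_{A_i→B} / (N_B' / (N - 1))

with d_ib the distance from focal i to its k-th nearest neighbour (the
adaptive bandwidth: dense and sparse areas see comparable neighbour counts),
and N_B' = N_B, or N_B - 1 for the same-category quotient.  The weighted
share N_{A_i→B} lies in [0, 1]; LCLQ is 1 in expectation under random
labelling, > 1 where B points crowd the focal's neighbourhood.

Per-point significance again comes from random labelling: each Monte-Carlo
iteration shuffles the full label vector over the fixed locations (category
counts preserved) and re-evaluates every focal point; the focal's own label
never enters its value (j ≠ i).  P-values are one-sided high by default,
since mapped results highlight colocation (LCLQ > 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .gclq import MonteCarloConfig, significance_label
from .pattern import BandwidthSpec, CategoricalPointPattern, knn_indices

logger = logging.getLogger("poicoloc")


@dataclass(frozen=True)
class LCLQResult:
    """Local colocation quotient of one focal type-A point towards type B."""

    focal_id: object
    a_category: str
    b_category: str
    bandwidth_distance: float
    weighted_b_share: float
    value: float
    p_value: float | None = None

    @property
    def significance(self) -> str:
        return significance_label(self.p_value)


def gaussian_weight(d_ij: float, d_ib: float):
    """Gaussian kernel weight exp(-0.5 d_ij^2 / d_ib^2); 1 at distance zero.

    Raises if the bandwidth is degenerate (d_ib = 0: every one of the focal's
    k nearest neighbours is coincident with it) — increase k in that case.
    """
    if d_ib <= 0:
        raise ValueError(
            "degenerate adaptive bandwidth d_ib = 0 (all k nearest neighbours "
            "coincide with the focal point); increase k"
        )
    return np.exp(-0.5 * np.square(np.asarray(d_ij, dtype=float)) / d_ib**2)


class _LocalCache:
    """Per-focal neighbour sets with kernel weights, reused across permutations.

    Neighbour universe per the bandwidth spec: the k nearest points (exact
    ties at k included) when truncated, else all other points; the bandwidth
    d_ib is the k-th neighbour distance either way.
    """

    def __init__(self, pattern: CategoricalPointPattern, spec: BandwidthSpec) -> None:
        n = pattern.n
        k = spec.k
        idx, dist, ptr = knn_indices(pattern, k)
        counts = np.diff(ptr)
        # bandwidth: k-th sorted neighbour distance of each focal
        bw = np.array([dist[ptr[i] + k - 1] for i in range(n)])
        if np.any(bw <= 0):
            bad = int(np.flatnonzero(bw <= 0)[0])
            raise ValueError(
                f"degenerate adaptive bandwidth d_ib = 0 at point "
                f"{pattern.ids[bad]!r} (all {k} nearest neighbours coincident); "
                "increase k"
            )
        if not spec.truncated:
            # full-sum universe: all other points, same per-focal bandwidth
            idx = np.concatenate(
                [np.delete(np.arange(n), i) for i in range(n)]
            )
            counts = np.full(n, n - 1, dtype=np.int64)
            ptr = np.zeros(n + 1, dtype=np.int64)
            np.cumsum(counts, out=ptr[1:])
            diffs = pattern.coords[idx] - np.repeat(pattern.coords, n - 1, axis=0)
            dist = np.hypot(diffs[:, 0], diffs[:, 1])
        if spec.kernel == "gaussian":
            w = np.exp(-0.5 * (dist / np.repeat(bw, counts)) ** 2)
        else:  # flat kernel: every in-bandwidth neighbour weighted equally
            w = np.ones_like(dist)
        wsum = np.add.reduceat(w, ptr[:-1])
        self.idx = idx
        self.ptr = ptr
        self.wnorm = w / np.repeat(wsum, counts)
        self.bandwidths = bw
        self.n = n

    def shares(self, is_b: np.ndarray) -> np.ndarray:
        """Kernel-weighted type-B share N_{A_i→B} for every point as focal."""
        contrib = np.where(is_b[self.idx], self.wnorm, 0.0)
        return np.add.reduceat(contrib, self.ptr[:-1])


def _n_b_effective(pattern: CategoricalPointPattern, a: str, b: str) -> int:
    n_b = int((pattern.categories == b).sum())
    return n_b - 1 if a == b else n_b


def local_b_share(
    pattern: CategoricalPointPattern, focal_id, b_category: str, spec: BandwidthSpec
) -> float:
    """Kernel-weighted share of type-B points in one focal's neighbour set."""
    if b_category not in pattern.category_set:
        raise KeyError(f"unknown category {b_category!r}")
    cache = _LocalCache(pattern, spec)
    i = pattern.index_of(focal_id)
    return float(cache.shares(pattern.categories == b_category)[i])


def lclq(
    pattern: CategoricalPointPattern, focal_id, b_category: str, spec: BandwidthSpec
) -> LCLQResult:
    """Local colocation quotient of one focal point towards type B (no test)."""
    if b_category not in pattern.category_set:
        raise KeyError(f"unknown category {b_category!r}")
    cache = _LocalCache(pattern, spec)
    i = pattern.index_of(focal_id)
    a = str(pattern.categories[i])
    share = float(cache.shares(pattern.categories == b_category)[i])
    n_b_eff = _n_b_effective(pattern, a, b_category)
    if n_b_eff <= 0:
        raise ValueError(f"category {b_category!r} too sparse for a quotient")
    value = share / (n_b_eff / (pattern.n - 1))
    return LCLQResult(
        focal_id=focal_id, a_category=a, b_category=b_category,
        bandwidth_distance=float(cache.bandwidths[i]),
        weighted_b_share=share, value=value,
    )


def lclq_all(
    pattern: CategoricalPointPattern,
    a_category: str,
    b_category: str,
    spec: BandwidthSpec,
    config: MonteCarloConfig | None = None,
) -> list[LCLQResult]:
    """LCLQ_{A_i→B} for every type-A focal, with per-point Monte-Carlo p-values.

    Each permutation shuffles the full label vector once and re-evaluates all
    focal points against it; each focal's p-value is the (r+1)/(M+1) rank of
    its observed value within its own permuted distribution.  Pass
    ``config=None`` to skip the test (p_value stays None).
    """
    for c in (a_category, b_category):
        if c not in pattern.category_set:
            raise KeyError(f"unknown category {c!r}")
    cache = _LocalCache(pattern, spec)
    labels = pattern.categories
    focal_idx = np.flatnonzero(labels == a_category)
    obs = cache.shares(labels == b_category)[focal_idx]
    n_b_eff = _n_b_effective(pattern, a_category, b_category)
    if n_b_eff <= 0:
        raise ValueError(f"category {b_category!r} too sparse for a quotient")
    scale = (pattern.n - 1) / n_b_eff
    values = obs * scale

    p = np.full(len(focal_idx), np.nan)
    if config is not None:
        rng = config.rng()
        eps = 1e-12
        hi = np.zeros(len(focal_idx), dtype=np.int64)
        lo = np.zeros(len(focal_idx), dtype=np.int64)
        for _ in range(config.n_permutations):
            perm = rng.permutation(labels)
            s = cache.shares(perm == b_category)[focal_idx]
            hi += s >= obs - eps
            lo += s <= obs + eps
        m = config.n_permutations
        p_hi = (1 + hi) / (1 + m)
        p_lo = (1 + lo) / (1 + m)
        alternative = config.alternative or "greater"
        if alternative == "greater":
            p = p_hi
        elif alternative == "less":
            p = p_lo
        else:
            p = np.minimum(1.0, 2.0 * np.minimum(p_hi, p_lo))
        logger.info(
            "lclq_all %s→%s: %d focals, k=%d, %d permutations",
            a_category, b_category, len(focal_idx), spec.k, m,
        )

    return [
        LCLQResult(
            focal_id=pattern.ids[i], a_category=a_category, b_category=b_category,
            bandwidth_distance=float(cache.bandwidths[i]),
            weighted_b_share=float(obs[t]), value=float(values[t]),
            p_value=None if np.isnan(p[t]) else float(p[t]),
        )
        for t, i in enumerate(focal_idx)
    ]


def significant_colocated(
    results: list[LCLQResult], alpha: float = 0.05, min_value: float = 1.0
) -> list[LCLQResult]:
    """Keep only significantly colocated points: p < alpha AND value > min_value.

    This is the standard map-layer filter for local colocation results.
    """
    return [
        r for r in results
        if r.p_value is not None and r.p_value < alpha and r.value > min_value
    ]
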