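"""Global colocation quotient (GCLQ) with Monte-Carlo significance.

For an ordered category pair A→B the GCLQ asks: among the nearest neighbours
of type-A points, are type-B points over- or under-represented relative to
random labelling?

    N_{A→B} = sum over A points i of (#type-B neighbours of i) / nn_i
    GCLQ_{A→B} = (N_{A→B} / N_A) / (N_B' / (N - 1))

where the neighbour set of i is its k nearest points (exact distance ties at
the k-th rank are all included, so nn_i may exceed k and each tied neighbour
carries equal weight 1/nn_i), N is the total point count, and N_B' is N_B,
or N_B - 1 for the same-category quotient A→A (a point cannot be its own
neighbour).  GCLQ = 1 signals random co-distribution, > 1 attraction of A to
B, < 1 avoidance; the statistic is directional (A→B need not equal B→A).

Significance comes from a random-labelling Monte-Carlo test: locations stay
fixed, the full label vector is permuted (all category counts preserved),
and the observed quotient is ranked among the permuted ones.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal

import numpy as np

from .pattern import CategoricalPointPattern, knn_indices

logger = logging.getLogger("poicoloc")


@dataclass(frozen=True)
class MonteCarloConfig:
    """Random-labelling permutation-test settings.

    n_permutations defaults to 1000; alternative is the tail used for the
    p-value ("two-sided" doubles the smaller tail and caps at 1).  When left
    None, each statistic applies its own convention: two-sided for the global
    quotient, one-sided high for the local (mapped) quotient.
    """

    n_permutations: int = 1000
    seed: int | None = None
    alternative: Literal["two-sided", "greater", "less"] | None = None

    def __post_init__(self) -> None:
        if self.n_permutations < 99:
            raise ValueError("n_permutations must be >= 99")
        if self.alternative not in (None, "two-sided", "greater", "less"):
            raise ValueError(f"unknown alternative {self.alternative!r}")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def significance_label(p: float | None) -> str:
    """Shared star convention: *** p<=0.01, ** p<=0.05, * p<=0.10, else ns."""
    if p is None:
        return ""
    if p <= 0.01:
        return "***"
    if p <= 0.05:
        return "**"
    if p <= 0.10:
        return "*"
    return "ns"


@dataclass(frozen=True)
class GCLQResult:
    """One directional global colocation quotient at one bandwidth."""

    a_category: str
    b_category: str
    k: int
    n_ab: float
    value: float
    p_value: float | None = None
    n_permutations: int | None = None

    @property
    def significance(self) -> str:
        return significance_label(self.p_value)


class _NeighbourCache:
    """Flat tie-complete kNN structure reused across label permutations."""

    def __init__(self, pattern: CategoricalPointPattern, k: int) -> None:
        idx, dist, ptr = knn_indices(pattern, k)
        counts = np.diff(ptr)
        self.idx = idx
        self.ptr = ptr
        # equivalent weight 1/nn_i per neighbour entry of focal i
        self.w = np.repeat(1.0 / counts, counts)
        self.n = pattern.n

    def per_focal_share(self, is_b: np.ndarray) -> np.ndarray:
        """For every point, the equal-weight share of type-B neighbours."""
        contrib = np.where(is_b[self.idx], self.w, 0.0)
        return np.add.reduceat(contrib, self.ptr[:-1])


def _value_from_labels(
    labels: np.ndarray, a: str, b: str, cache: _NeighbourCache
) -> tuple[float, float]:
    """(GCLQ value, weighted count N_{A→B}) for one label vector."""
    is_a = labels == a
    is_b = labels == b
    n_a = int(is_a.sum())
    n_b = int(is_b.sum())
    n_b_eff = n_b - 1 if a == b else n_b
    n_ab = float(cache.per_focal_share(is_b)[is_a].sum())
    if n_a == 0 or n_b_eff <= 0:
        raise ValueError(f"categories {a!r}/{b!r} too sparse for a quotient")
    value = (n_ab / n_a) / (n_b_eff / (cache.n - 1))
    return value, n_ab


def weighted_ab_count(
    pattern: CategoricalPointPattern, a_category: str, b_category: str, k: int = 1
) -> float:
    """N_{A→B}: tie-weighted count of type-B points among A points' k nearest.

    Each A point contributes (#B neighbours)/nn_i, where nn_i is its
    neighbour count after tie expansion at the k-th distance.
    """
    for c in (a_category, b_category):
        if c not in pattern.category_set:
            raise KeyError(f"unknown category {c!r}")
    cache = _NeighbourCache(pattern, k)
    is_b = pattern.categories == b_category
    is_a = pattern.categories == a_category
    return float(cache.per_focal_share(is_b)[is_a].sum())


def gclq(
    pattern: CategoricalPointPattern,
    a_category: str,
    b_category: str,
    k: int = 1,
    _cache: _NeighbourCache | None = None,
) -> GCLQResult:
    """Point estimate of GCLQ_{A→B} at neighbour-order bandwidth k (no test)."""
    for c in (a_category, b_category):
        if c not in pattern.category_set:
            raise KeyError(f"unknown category {c!r}")
    cache = _cache or _NeighbourCache(pattern, k)
    value, n_ab = _value_from_labels(
        pattern.categories, a_category, b_category, cache
    )
    return GCLQResult(a_category, b_category, k, n_ab, value)


def _mc_pvalue(observed: float, permuted: np.ndarray, alternative: str) -> float:
    """(r+1)/(M+1) permutation p-value; two-sided doubles the smaller tail."""
    m = len(permuted)
    eps = 1e-12
    p_hi = (1 + int((permuted >= observed - eps).sum())) / (1 + m)
    p_lo = (1 + int((permuted <= observed + eps).sum())) / (1 + m)
    if alternative == "greater":
        return p_hi
    if alternative == "less":
        return p_lo
    return min(1.0, 2.0 * min(p_hi, p_lo))


def gclq_mc_test(
    pattern: CategoricalPointPattern,
    a_category: str,
    b_category: str,
    k: int = 1,
    config: MonteCarloConfig = MonteCarloConfig(),
    _cache: _NeighbourCache | None = None,
    _rng: np.random.Generator | None = None,
) -> GCLQResult:
    """GCLQ_{A→B} with a random-labelling Monte-Carlo p-value.

    Point locations (and hence every neighbour set) are held fixed; only the
    label vector is permuted, preserving all category counts.
    """
    cache = _cache or _NeighbourCache(pattern, k)
    base = gclq(pattern, a_category, b_category, k, _cache=cache)
    rng = _rng if _rng is not None else config.rng()
    labels = pattern.categories.copy()
    permuted = np.empty(config.n_permutations)
    for t in range(config.n_permutations):
        permuted[t], _ = _value_from_labels(
            rng.permutation(labels), a_category, b_category, cache
        )
    p = _mc_pvalue(base.value, permuted, config.alternative or "two-sided")
    return GCLQResult(
        a_category, b_category, k, base.n_ab, base.value,
        p_value=p, n_permutations=config.n_permutations,
    )


def bandwidth_sweep(
    pattern: CategoricalPointPattern,
    a_category: str,
    b_category: str,
    k_max: int = 10,
    config: MonteCarloConfig = MonteCarloConfig(),
    alpha: float = 0.05,
) -> tuple[list[GCLQResult], int | None]:
    """GCLQ + Monte-Carlo p for k = 1..k_max; bandwidth chosen by significance.

    Starting from the first-order neighbour and increasing the neighbour
    count, the quotient and its permutation p-value are computed at every k.
    The selected bandwidth is the smallest k with p <= alpha (None if no k
    qualifies); the full sweep is always returned so other selection rules
    can be applied downstream.
    """
    if not (1 <= k_max <= pattern.n - 1):
        raise ValueError(f"k_max must be in [1, {pattern.n - 1}]")
    rng = config.rng()
    results = []
    for k in range(1, k_max + 1):
        results.append(
            gclq_mc_test(pattern, a_category, b_category, k, config, _rng=rng)
        )
    selected = next((r.k for r in results if r.p_value <= alpha), None)
    logger.info(
        "bandwidth sweep %s→%s: selected k=%s of 1..%d",
        a_category, b_category, selected, k_max,
    )
    return results, selected


def gclq_matrix(
    pattern: CategoricalPointPattern,
    config: MonteCarloConfig = MonteCarloConfig(),
    k_max: int = 10,
    alpha: float = 0.05,
):
    """Selected-bandwidth GCLQ for every ordered category pair.

    Runs :func:`bandwidth_sweep` per ordered pair (diagonal included, with
    the same-category N_B - 1 correction) and returns a tidy DataFrame with
    one row per pair at its selected bandwidth — or, when no bandwidth is
    significant, at k = 1 for reference.  Categories with fewer than two
    points are skipped with a warning.
    """
    import pandas as pd

    cats = sorted(pattern.category_set)
    counts = pattern.category_counts
    usable = [c for c in cats if counts[c] >= 2]
    for c in cats:
        if c not in usable:
            logger.warning("category %r has < 2 points; skipped in GCLQ matrix", c)

    rows = []
    for a in usable:
        for b in usable:
            results, selected = bandwidth_sweep(
                pattern, a, b, k_max=k_max, config=config, alpha=alpha
            )
            r = results[selected - 1] if selected is not None else results[0]
            rows.append(
                {
                    "a_category": a, "b_category": b, "k": r.k,
                    "value": r.value, "p": r.p_value,
                    "significance": r.significance,
                    "selected": selected is not None,
                }
            )
    return pd.DataFrame(rows)
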