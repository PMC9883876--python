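"""Categorical point-pattern data model and neighbour queries.

The central container is :class:`CategoricalPointPattern`: a set of labelled
points in a planar (projected, metre-like) coordinate system together with a
study region of known area.  All statistics in this package (nearest-neighbour
index, global/local colocation quotients, kernel densities) operate on this
container and on the tie-aware k-nearest-neighbour queries defined here.

Distances are Euclidean throughout.  Exact distance ties are never broken:
a query for the k nearest neighbours returns *every* point at the k-th
distance, so the result may hold more than k entries.  Coincident points
(distance 0 between distinct ids) are legal — co-addressed facilities are
common in real POI data — and such a point is always the other's first
neighbour.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy.spatial import cKDTree
from shapely.geometry import box
from shapely.geometry.base import BaseGeometry

logger = logging.getLogger("poicoloc")

#: relative tolerance for declaring two neighbour distances tied
TIE_RTOL = 1e-9
#: absolute tolerance (covers exact-zero distances)
TIE_ATOL = 1e-12


@dataclass(frozen=True)
class PointRecord:
    """One labelled point: unique id, planar coordinates, category label."""

    id: object
    x: float
    y: float
    category: str

    def __post_init__(self) -> None:
        if not (np.isfinite(self.x) and np.isfinite(self.y)):
            raise ValueError(f"point {self.id!r}: non-finite coordinates")


@dataclass(frozen=True)
class NeighbourQueryResult:
    """Neighbours of one focal point, sorted by non-decreasing distance.

    If several points tie exactly at the last retained distance, all of them
    are included, so ``len(neighbour_ids)`` may exceed the requested k.
    """

    focal_id: object
    neighbour_ids: tuple
    distances: tuple


@dataclass(frozen=True)
class BandwidthSpec:
    """Adaptive (fixed-k) kernel bandwidth: radius = distance to k-th neighbour.

    Parameters
    ----------
    k
        Neighbour order defining the per-point bandwidth; 1 <= k <= N - 1.
    kernel
        Weighting kernel applied within the bandwidth.  ``"gaussian"`` is the
        default; ``"flat"`` (all weights 1) is provided for sensitivity checks.
    truncated
        If True (default) the weighted sums run over the k nearest neighbours
        (ties included); if False they run over all other points, with the
        bandwidth still set by the k-th neighbour distance.
    """

    k: int
    kernel: Literal["gaussian", "flat"] = "gaussian"
    truncated: bool = True

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("bandwidth k must be >= 1")
        if self.kernel not in ("gaussian", "flat"):
            raise ValueError(f"unknown kernel {self.kernel!r}")


class CategoricalPointPattern:
    """A categorical point pattern: labelled points plus a study region.

    Parameters
    ----------
    ids, coords, categories
        Parallel arrays: unique identifiers, an (N, 2) float array of planar
        coordinates, and a label per point.
    region
        Study-region geometry (shapely polygon).  May be None if ``area`` is
        given explicitly.
    area
        Region area in squared coordinate units.  Defaults to ``region.area``.
    metadata
        Free-form provenance (e.g. the generating scene configuration).
    """

    def __init__(
        self,
        ids: Sequence,
        coords: np.ndarray,
        categories: Sequence[str],
        region: BaseGeometry | None = None,
        area: float | None = None,
        metadata: dict | None = None,
    ) -> None:
        coords = np.asarray(coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 2:
            raise ValueError("coords must be an (N, 2) array")
        n = coords.shape[0]
        if n < 1:
            raise ValueError("a pattern needs at least one point")
        if len(ids) != n or len(categories) != n:
            raise ValueError("ids, coords and categories must have equal length")
        if not np.all(np.isfinite(coords)):
            raise ValueError("coordinates must be finite")
        ids = np.asarray(ids, dtype=object)
        if len(set(ids.tolist())) != n:
            raise ValueError("point ids must be unique within a pattern")
        if area is None:
            if region is None:
                raise ValueError("either region or area must be given")
            area = float(region.area)
        if not (area > 0):
            raise ValueError("study-region area must be positive")

        self.ids = ids
        self.coords = coords
        self.categories = np.asarray(categories, dtype=object)
        self.region = region
        self.area = float(area)
        self.metadata = dict(metadata or {})
        self._id_index: dict = {pid: i for i, pid in enumerate(ids.tolist())}
        self._tree: cKDTree | None = None

    # -- basic queries ----------------------------------------------------

    @property
    def n(self) -> int:
        return self.coords.shape[0]

    @property
    def category_counts(self) -> dict[str, int]:
        labels, counts = np.unique(self.categories, return_counts=True)
        return dict(zip(labels.tolist(), counts.tolist()))

    @property
    def category_set(self) -> set[str]:
        return set(np.unique(self.categories).tolist())

    @property
    def tree(self) -> cKDTree:
        if self._tree is None:
            self._tree = cKDTree(self.coords)
        return self._tree

    def index_of(self, point_id) -> int:
        try:
            return self._id_index[point_id]
        except KeyError:
            raise KeyError(f"unknown point id {point_id!r}") from None

    def mask(self, category: str) -> np.ndarray:
        """Boolean mask over points for one category ('all' selects everything)."""
        if category == "all":
            return np.ones(self.n, dtype=bool)
        if category not in self.category_set:
            raise KeyError(f"unknown category {category!r}")
        return self.categories == category

    def subset(self, category: str) -> "CategoricalPointPattern":
        """Single-category sub-pattern sharing the full pattern's region/area."""
        m = self.mask(category)
        return CategoricalPointPattern(
            self.ids[m], self.coords[m], self.categories[m],
            region=self.region, area=self.area, metadata=self.metadata,
        )

    def records(self) -> list[PointRecord]:
        return [
            PointRecord(pid, float(x), float(y), str(c))
            for pid, (x, y), c in zip(self.ids, self.coords, self.categories)
        ]

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        counts = ", ".join(f"{k}:{v}" for k, v in sorted(self.category_counts.items()))
        return f"<CategoricalPointPattern N={self.n} area={self.area:g} [{counts}]>"


# -- construction ---------------------------------------------------------


def build_pattern(
    records: Iterable[PointRecord],
    region: BaseGeometry | tuple | None = None,
    area: float | None = None,
    containment: Literal["strict", "warn", "ignore"] = "warn",
) -> CategoricalPointPattern:
    """Validate records and assemble a :class:`CategoricalPointPattern`.

    ``region`` may be a shapely geometry or an ``(xmin, ymin, xmax, ymax)``
    tuple.  Points outside the region raise under ``containment="strict"``,
    are logged under ``"warn"`` (the default — crawled POI data are noisy),
    and pass silently under ``"ignore"``.
    """
    records = list(records)
    if not records:
        raise ValueError("cannot build a pattern from zero records")
    if isinstance(region, tuple):
        region = box(*region)
    ids = [r.id for r in records]
    coords = np.array([[r.x, r.y] for r in records], dtype=float)
    cats = [r.category for r in records]

    if region is not None and containment != "ignore":
        import shapely

        # covers = contains-or-on-boundary
        inside = shapely.covers(region, shapely.points(coords))
        n_out = int((~inside).sum())
        if n_out:
            bad = [ids[i] for i in np.flatnonzero(~inside)[:5]]
            msg = f"{n_out} point(s) outside study region (e.g. {bad})"
            if containment == "strict":
                raise ValueError(msg)
            logger.warning(msg)

    pat = CategoricalPointPattern(ids, coords, cats, region=region, area=area)
    logger.info(
        "built pattern: N=%d, categories=%s, area=%g",
        pat.n, pat.category_counts, pat.area,
    )
    return pat


# -- tie-aware k-nearest-neighbour machinery ------------------------------


def _tie_cutoff(dk: float) -> float:
    """Largest distance still counted as tied with the k-th distance dk."""
    return dk + TIE_RTOL * dk + TIE_ATOL


def _row_bruteforce(coords: np.ndarray, i: int, k: int) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs fallback for one focal row; exact and tie-complete."""
    d = np.hypot(coords[:, 0] - coords[i, 0], coords[:, 1] - coords[i, 1])
    d[i] = np.inf
    order = np.argsort(d, kind="stable")
    dk = d[order[k - 1]]
    keep = order[d[order] <= _tie_cutoff(dk)]
    return keep, d[keep]


def knn_indices(
    pattern: CategoricalPointPattern, k: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Tie-complete k-nearest neighbours of every point, in flat ragged form.

    Returns ``(idx, dist, ptr)`` where the neighbours of point ``i`` occupy
    ``idx[ptr[i]:ptr[i+1]]`` (point indices, distance-sorted) with matching
    ``dist`` entries.  Self is always excluded; every point at the k-th
    distance is included.
    """
    n = pattern.n
    if not (1 <= k <= n - 1):
        raise ValueError(f"k must be in [1, N-1] = [1, {n - 1}], got {k}")
    coords = pattern.coords
    kq = min(n, k + 2)
    dists, idxs = pattern.tree.query(coords, k=kq)
    if kq == 1:  # scipy squeezes the trailing axis for k=1
        dists = dists[:, None]
        idxs = idxs[:, None]

    out_idx: list[np.ndarray] = []
    out_dist: list[np.ndarray] = []
    counts = np.empty(n, dtype=np.int64)
    for i in range(n):
        row_i = idxs[i]
        row_d = dists[i]
        keep = row_i != i
        ri, rd = row_i[keep], row_d[keep]
        if len(ri) < k or (len(rd) > k and rd[-1] <= _tie_cutoff(rd[k - 1])):
            # candidate window too small, or ties may extend past it
            ri, rd = _row_bruteforce(coords, i, k)
        else:
            dk = rd[k - 1]
            cut = _tie_cutoff(dk)
            m = np.searchsorted(rd, cut, side="right")
            ri, rd = ri[:m], rd[:m]
        out_idx.append(ri)
        out_dist.append(rd)
        counts[i] = len(ri)

    ptr = np.zeros(n + 1, dtype=np.int64)
    np.cumsum(counts, out=ptr[1:])
    return np.concatenate(out_idx), np.concatenate(out_dist), ptr


def k_nearest(
    pattern: CategoricalPointPattern, focal_id, k: int
) -> NeighbourQueryResult:
    """The k nearest neighbours of one point, ties at the k-th distance included."""
    n = pattern.n
    if not (1 <= k <= n - 1):
        raise ValueError(f"k must be in [1, N-1] = [1, {n - 1}], got {k}")
    i = pattern.index_of(focal_id)
    ri, rd = _row_bruteforce(pattern.coords, i, k)
    return NeighbourQueryResult(
        focal_id=focal_id,
        neighbour_ids=tuple(pattern.ids[ri].tolist()),
        distances=tuple(rd.tolist()),
    )


def adaptive_bandwidth(pattern: CategoricalPointPattern, focal_id, k: int) -> float:
    """Distance from the focal point to its k-th nearest neighbour.

    This is the per-point adaptive bandwidth used by the kernel-weighted
    local colocation quotient; ties at k share the same distance.
    """
    res = k_nearest(pattern, focal_id, k)
    return float(res.distances[min(k, len(res.distances)) - 1])
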