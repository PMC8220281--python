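"""Vietoris-Rips persistent homology (H0, H1) of dissimilarity matrices.

The filtration connects pairs of points whose dissimilarity falls below a
growing radius; connected components (H0) and independent 1-cycles (H1)
are tracked as the radius grows. H0 is computed with a union-find over
edges sorted by length; H1 by column reduction of the triangle boundary
matrix over GF(2), with columns stored as Python integer bitmasks. The
filtration order is made deterministic by breaking ties lexicographically:
edges by (length, i, j), triangles by (max edge length, i, j, k).

Conventions:

- zero-persistence H1 pairs (a cycle filled the instant it is born) are
  dropped, as is standard;
- H0 intervals all have birth 0; every merge is recorded, including
  zero-length merges between duplicate points, so that the number of
  finite H0 intervals plus the number of components at ``max_radius``
  always equals the number of points;
- 1-cycles still open when the filtration is truncated at ``max_radius``
  are reported with ``death = max_radius`` and ``truncated=True`` rather
  than dropped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PersistenceInterval",
    "PersistenceDiagram",
    "BettiCurve",
    "rips_persistence",
    "betti_curve",
    "default_grid",
    "tda_summaries",
]

#: refuse clouds larger than this unless the caller raises the guard
MAX_POINTS_GUARD = 600


@dataclass(frozen=True)
class PersistenceInterval:
    """A homological feature alive on the radius interval [birth, death)."""

    dim: int
    birth: float
    death: float  # may be inf (essential H0 class) or max_radius if truncated
    truncated: bool = False

    @property
    def persistence(self) -> float:
        return self.death - self.birth


@dataclass
class PersistenceDiagram:
    intervals: list[PersistenceInterval] = field(default_factory=list)
    max_radius: float = np.inf

    def in_dim(self, dim: int) -> list[PersistenceInterval]:
        return [iv for iv in self.intervals if iv.dim == dim]

    def sort(self) -> None:
        self.intervals.sort(key=lambda iv: (iv.dim, iv.birth, iv.death))


@dataclass
class BettiCurve:
    """Feature count of one homology dimension over a radius grid."""

    grid: np.ndarray
    counts: np.ndarray
    dim: int


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        root = i
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[i] != root:
            self.parent[i], i = root, self.parent[i]
        return root

    def union(self, i: int, j: int) -> bool:
        """Merge; the smaller root index survives (elder rule proxy). Returns True if merged."""
        ri, rj = self.find(i), self.find(j)
        if ri == rj:
            return False
        if rj < ri:
            ri, rj = rj, ri
        self.parent[rj] = ri
        return True


def _validate_dm(dm: np.ndarray) -> np.ndarray:
    dm = np.asarray(dm, dtype=float)
    if dm.ndim != 2 or dm.shape[0] != dm.shape[1]:
        raise ValueError("dissimilarity matrix must be square")
    if not np.allclose(dm, dm.T, atol=1e-12):
        raise ValueError("dissimilarity matrix must be symmetric")
    if np.any(np.diag(dm) != 0):
        raise ValueError("dissimilarity matrix must have a zero diagonal")
    if np.any(dm < 0):
        raise ValueError("dissimilarities must be non-negative")
    return dm


def _sorted_edges(dm: np.ndarray) -> list[tuple[float, int, int]]:
    n = dm.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    order = np.lexsort((ju, iu, dm[iu, ju]))
    return [(float(dm[iu[k], ju[k]]), int(iu[k]), int(ju[k])) for k in order]


def rips_persistence(
    dm: np.ndarray,
    max_dim: int = 1,
    max_radius: float | None = None,
    radius_cap: float | None = None,
    max_points: int = MAX_POINTS_GUARD,
) -> PersistenceDiagram:
    """Persistence diagram (H0 and optionally H1) of a Rips filtration.

    Parameters
    ----------
    dm
        Symmetric non-negative dissimilarity matrix with zero diagonal.
    max_dim
        0 or 1; homology above dimension 1 is out of scope.
    max_radius
        Truncation radius of the filtration. If None, it defaults to 1.1x
        the connectivity radius (the edge that first makes the cloud a
        single component): cycles of interest close before full
        connectivity, and truncation bounds the triangle count.
    radius_cap
        Optional hard upper bound applied to the automatic ``max_radius``
        (e.g. 2.0 for cosine dissimilarity).
    max_points
        Guard against accidentally feeding full-length recordings; use
        landmark subsampling (:func:`statescape.epc.maxmin_landmarks`)
        for large clouds, or raise the guard deliberately.
    """
    dm = _validate_dm(dm)
    n = dm.shape[0]
    if n > max_points:
        raise ValueError(
            f"cloud has {n} points > guard {max_points}; subsample with maxmin_landmarks "
            "or pass a larger max_points explicitly"
        )
    if max_dim not in (0, 1):
        raise ValueError("max_dim must be 0 or 1")
    if max_radius is not None and max_radius <= 0:
        raise ValueError("max_radius must be > 0")

    edges = _sorted_edges(dm)

    # connectivity radius for the default truncation
    if max_radius is None:
        uf0 = _UnionFind(n)
        n_comp, r_conn = n, None
        for d, i, j in edges:
            if uf0.union(i, j):
                n_comp -= 1
                if n_comp == 1:
                    r_conn = d
                    break
        if r_conn is None:  # disconnected even at max edge (cannot happen for finite dm)
            r_conn = edges[-1][0] if edges else 1.0
        max_radius = 1.1 * r_conn if r_conn > 0 else (edges[-1][0] if edges else 1.0)
        if max_radius == 0:
            max_radius = 1.0
        if radius_cap is not None:
            max_radius = min(max_radius, radius_cap)

    if edges and max_radius < edges[0][0]:
        warnings.warn(
            f"max_radius={max_radius} is below the smallest dissimilarity {edges[0][0]}; "
            "all points remain isolated",
            stacklevel=2,
        )

    intervals: list[PersistenceInterval] = []

    # ---- H0 via union-find over edges within the radius -----------------
    uf = _UnionFind(n)
    kept_edges: list[tuple[float, int, int]] = []
    edge_positive: list[bool] = []
    for d, i, j in edges:
        if d > max_radius:
            break
        kept_edges.append((d, i, j))
        merged = uf.union(i, j)
        edge_positive.append(not merged)
        if merged:
            intervals.append(PersistenceInterval(dim=0, birth=0.0, death=d))
    n_components = len({uf.find(i) for i in range(n)})
    for _ in range(n_components):
        intervals.append(PersistenceInterval(dim=0, birth=0.0, death=np.inf))

    # ---- H1 via GF(2) reduction of the triangle boundary matrix ---------
    if max_dim >= 1 and n >= 3:
        e_index: dict[tuple[int, int], int] = {}
        edge_val: list[float] = []
        for k, (d, i, j) in enumerate(kept_edges):
            e_index[(i, j)] = k
            edge_val.append(d)

        adj = dm <= max_radius
        np.fill_diagonal(adj, False)
        triangles: list[tuple[float, int, int, int]] = []
        for i in range(n - 2):
            row_i = adj[i]
            for j in range(i + 1, n - 1):
                if not row_i[j]:
                    continue
                common = np.flatnonzero(row_i & adj[j])
                for k in common[common > j]:
                    k = int(k)
                    fval = max(dm[i, j], dm[i, k], dm[j, k])
                    triangles.append((float(fval), i, j, k))
        triangles.sort()

        low_to_col: dict[int, int] = {}
        for fval, i, j, k in triangles:
            col = (
                (1 << e_index[(i, j)])
                | (1 << e_index[(i, k)])
                | (1 << e_index[(j, k)])
            )
            while col:
                low = col.bit_length() - 1
                other = low_to_col.get(low)
                if other is None:
                    break
                col ^= other
            if col:
                low = col.bit_length() - 1
                low_to_col[low] = col
                birth = edge_val[low]
                if fval > birth:  # drop zero-persistence pairs
                    intervals.append(PersistenceInterval(dim=1, birth=birth, death=fval))

        # positive edges never paired by a triangle: cycles open at truncation
        for k, pos in enumerate(edge_positive):
            if pos and k not in low_to_col:
                intervals.append(
                    PersistenceInterval(dim=1, birth=edge_val[k], death=float(max_radius), truncated=True)
                )

    diag = PersistenceDiagram(intervals=intervals, max_radius=float(max_radius))
    diag.sort()
    return diag


def betti_curve(diag: PersistenceDiagram, dim: int, grid: np.ndarray) -> BettiCurve:
    """Count features of one dimension alive at each grid radius.

    ``counts[g] = #{intervals with birth <= g < death}``. Averaging curves
    from several diagrams is well defined whenever they share the grid.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("grid must be non-empty")
    if grid.size > 1 and np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be strictly increasing")
    counts = np.zeros(grid.size, dtype=int)
    for iv in diag.in_dim(dim):
        counts += (iv.birth <= grid) & (grid < iv.death)
    return BettiCurve(grid=grid, counts=counts, dim=dim)


def default_grid(diag: PersistenceDiagram, n_points: int = 100) -> np.ndarray:
    """Evenly spaced radius grid from 0 to the diagram's truncation radius."""
    hi = diag.max_radius
    if not np.isfinite(hi):
        deaths = [iv.death for iv in diag.intervals if np.isfinite(iv.death)]
        hi = max(deaths) if deaths else 1.0
    return np.linspace(0.0, hi, n_points)


def tda_summaries(diag: PersistenceDiagram, grid: np.ndarray | None = None) -> dict[str, float]:
    """The three scalar H1 summaries of a diagram.

    - ``max_persistence``: lifetime of the longest-lived closed cycle
      (truncated cycles excluded: their true death is unknown);
    - ``n_cycles``: total number of 1-cycles over the filtration;
    - ``max_cycles``: the maximum of the H1 Betti curve on the grid.
    """
    h1 = diag.in_dim(1)
    closed = [iv for iv in h1 if not iv.truncated]
    max_pers = max((iv.persistence for iv in closed), default=0.0)
    if grid is None:
        grid = default_grid(diag)
    max_cycles = int(betti_curve(diag, 1, grid).counts.max()) if h1 else 0
    return {
        "max_persistence": float(max_pers),
        "n_cycles": float(len(h1)),
        "max_cycles": float(max_cycles),
    }
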