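"""Embedded point clouds: per-timepoint channel vectors in state space.

A segment's C x T matrix is read column-wise: the brain (or surrogate)
state at sample t is the C-dimensional vector of simultaneous channel
values. The temporally ordered set of these vectors is the embedded point
cloud (EPC). Consecutive-state cosine dissimilarity acts as a state-space
"velocity"; the full pairwise dissimilarity matrix feeds the Rips
filtration in :mod:`statescape.tda`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .segment import RecordingSegment

__all__ = [
    "PointCloud",
    "build_epc",
    "state_velocity",
    "average_velocity",
    "pairwise_dissimilarity",
    "maxmin_landmarks",
]


@dataclass
class PointCloud:
    """Temporally ordered points (``(T, C)`` array) with a metric label."""

    points: np.ndarray
    metric: str = "cosine"

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2:
            raise ValueError("points must be a 2-D (T, C) array")
        if self.metric not in ("cosine", "euclidean"):
            raise ValueError(f"metric must be 'cosine' or 'euclidean', got {self.metric!r}")

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    @property
    def dim(self) -> int:
        return self.points.shape[1]


def build_epc(seg: RecordingSegment, metric: str = "cosine") -> PointCloud:
    """Embed a segment as T points in C-dimensional state space."""
    if metric == "cosine" and seg.n_channels < 2:
        raise ValueError("cosine dissimilarity is degenerate for C < 2 channels")
    return PointCloud(points=seg.data.T.copy(), metric=metric)


def state_velocity(cloud: PointCloud) -> np.ndarray:
    """Cosine dissimilarity between consecutive states, length T - 1.

    ``v[t] = 1 - cos(x_t, x_{t+1})`` lies in [0, 2]; with a fixed sampling
    interval it is proportional to a state-space velocity. Entries
    involving a zero-norm state are undefined and returned as NaN (with a
    warning naming the indices).
    """
    x = cloud.points
    if x.shape[0] < 2:
        raise ValueError("need at least 2 points for a velocity")
    norms = np.linalg.norm(x, axis=1)
    zero = norms == 0
    a, b = x[:-1], x[1:]
    with np.errstate(invalid="ignore", divide="ignore"):
        cos = np.einsum("ij,ij->i", a, b) / (norms[:-1] * norms[1:])
    v = 1.0 - np.clip(cos, -1.0, 1.0)
    bad = zero[:-1] | zero[1:]
    if bad.any():
        warnings.warn(
            f"zero-norm state vectors at indices {np.flatnonzero(zero).tolist()}; "
            "velocity undefined (NaN) at adjacent steps",
            stacklevel=2,
        )
        v[bad] = np.nan
    return v


def average_velocity(cloud: PointCloud) -> float:
    """Mean consecutive-state dissimilarity, ignoring undefined steps."""
    return float(np.nanmean(state_velocity(cloud)))


def pairwise_dissimilarity(cloud: PointCloud) -> np.ndarray:
    """Symmetric T x T dissimilarity matrix under the cloud's metric.

    Cosine dissimilarity (``1 - cos``) is bounded by [0, 2]; zero-norm
    points make it undefined and are rejected with their indices.
    """
    x = cloud.points
    if cloud.metric == "cosine":
        zero = np.flatnonzero(np.linalg.norm(x, axis=1) == 0)
        if zero.size:
            raise ValueError(f"zero-norm points at indices {zero.tolist()}: cosine dissimilarity undefined")
    dm = squareform(pdist(x, metric=cloud.metric))
    np.clip(dm, 0.0, None, out=dm)  # guard tiny negative rounding
    np.fill_diagonal(dm, 0.0)
    return dm


def maxmin_landmarks(dm: np.ndarray, n_landmarks: int, start: int = 0) -> np.ndarray:
    """Greedy farthest-point (maxmin) landmark selection.

    Deterministic given ``start``; returns indices into the cloud. The
    landmark set approximately covers the cloud, which keeps Rips
    filtrations of long recordings desk-scale while preserving large-scale
    cycles.
    """
    n = dm.shape[0]
    if n_landmarks >= n:
        return np.arange(n)
    chosen = [start]
    min_d = dm[start].copy()
    for _ in range(n_landmarks - 1):
        nxt = int(np.argmax(min_d))
        chosen.append(nxt)
        np.minimum(min_d, dm[nxt], out=min_d)
    return np.array(sorted(chosen))
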