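"""Ordinal partition networks from univariate series.

A series is delay-embedded with dimension ``d`` and lag ``tau``; each
window ``(x_i, x_{i+tau}, ..., x_{i+(d-1)tau})`` is mapped to its argsort
permutation (the positions of the values in ascending order, ties broken
toward the earlier window position via a stable sort). Distinct
permutations are the nodes of a weighted directed graph; consecutive
windows contribute directed edge counts (self-loops included). Node visit
counts and per-node normalized out-transition distributions are retained
for the information-theoretic measures.

Parameter heuristics follow common attractor-reconstruction practice:
``tau`` is the first zero crossing of the sample autocorrelation (per
channel), and ``d`` is the candidate maximizing the variance of the
network's total-degree distribution, aggregated across channels by the
mode.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "EmbeddingParams",
    "OrdinalSymbolSequence",
    "OrdinalPartitionNetwork",
    "autocorrelation",
    "select_tau",
    "select_dim",
    "select_dim_mode",
    "ordinal_symbols",
    "build_opn",
    "opn_counts",
]


@dataclass(frozen=True)
class EmbeddingParams:
    """Delay-embedding dimension ``d`` and lag ``tau`` (in samples)."""

    d: int
    tau: int

    def __post_init__(self) -> None:
        if self.d < 2:
            raise ValueError(f"embedding dimension d must be >= 2, got {self.d}")
        if self.tau < 1:
            raise ValueError(f"lag tau must be >= 1, got {self.tau}")

    def window_span(self) -> int:
        return (self.d - 1) * self.tau


@dataclass
class OrdinalSymbolSequence:
    """Ordered permutation symbols of the embedded windows."""

    symbols: list[tuple[int, ...]]
    params: EmbeddingParams

    @property
    def n_windows(self) -> int:
        return len(self.symbols)


@dataclass
class OrdinalPartitionNetwork:
    """Weighted directed transition graph over permutation symbols.

    ``node_weights[s]`` counts windows mapped to symbol ``s``;
    ``edge_counts[(a, b)]`` counts consecutive-window transitions a -> b
    (self-loops included). Out-transition distributions are normalized per
    node over nodes that have at least one outgoing transition.
    """

    node_weights: dict[tuple[int, ...], int]
    edge_counts: dict[tuple[tuple[int, ...], tuple[int, ...]], int]
    params: EmbeddingParams | None = None
    nodes: list[tuple[int, ...]] = field(init=False)

    def __post_init__(self) -> None:
        self.nodes = sorted(self.node_weights)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        """Number of distinct directed edges (not summed transition counts)."""
        return len(self.edge_counts)

    def out_distributions(self) -> tuple[np.ndarray, np.ndarray]:
        """(mask, W) where W[i] is node i's normalized out-distribution.

        Rows of ``W`` are indexed like :attr:`nodes`; rows of nodes with no
        outgoing transition (at most the final observed symbol) are zero
        and flagged False in ``mask``.
        """
        idx = {s: i for i, s in enumerate(self.nodes)}
        n = self.n_nodes
        w = np.zeros((n, n))
        for (a, b), c in self.edge_counts.items():
            w[idx[a], idx[b]] += c
        totals = w.sum(axis=1)
        mask = totals > 0
        w[mask] /= totals[mask, None]
        return mask, w

    @classmethod
    def from_edges(
        cls,
        edge_counts: dict[tuple, int] | list[tuple],
        node_weights: dict | None = None,
    ) -> "OrdinalPartitionNetwork":
        """Build a transition network directly from weighted directed edges.

        Convenience constructor for planted-structure fixtures; nodes may
        be arbitrary hashables. Node weights default to out-strengths.
        """
        if not isinstance(edge_counts, dict):
            edge_counts = dict(Counter(edge_counts))
        if node_weights is None:
            node_weights = Counter()
            for (a, b), c in edge_counts.items():
                node_weights[a] += c
                node_weights.setdefault(b, 0)
            node_weights = dict(node_weights)
        return cls(node_weights=dict(node_weights), edge_counts=dict(edge_counts))

    def to_networkx(self):
        """Export as a networkx DiGraph (edge attr ``count``, node attr ``weight``)."""
        import networkx as nx

        g = nx.DiGraph()
        for s, w in self.node_weights.items():
            g.add_node(str(s), weight=w)
        for (a, b), c in self.edge_counts.items():
            g.add_edge(str(a), str(b), count=c)
        return g


def autocorrelation(series: np.ndarray, max_lag: int) -> np.ndarray:
    """Biased (divide by n) sample autocorrelation of the mean-removed series."""
    x = np.asarray(series, dtype=float)
    x = x - x.mean()
    n = x.size
    var = np.dot(x, x) / n
    if var == 0:
        raise ValueError("autocorrelation undefined for a constant series")
    # FFT-based autocovariance
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(x, nfft)
    acov = np.fft.irfft(f * np.conj(f), nfft)[: max_lag + 1] / n
    return acov / var


def select_tau(series: np.ndarray, max_tau: int | None = None) -> int:
    """Lag of the first zero crossing of the sample autocorrelation.

    The crossing is located between the last positive lag and the first
    non-positive one by linear interpolation and rounded to the nearest
    integer lag (never below 1); the finite-sample bias of the estimator
    otherwise systematically overshoots analytic crossings such as the
    quarter period of a sinusoid. If the autocorrelation stays positive up
    to ``max_tau`` (default ``len(series) // 4``), the cap is returned
    with a warning.
    """
    x = np.asarray(series, dtype=float)
    if x.size < 10:
        raise ValueError("series too short for lag selection (need >= 10 samples)")
    if max_tau is None:
        max_tau = max(1, x.size // 4)
    acf = autocorrelation(x, max_tau)
    below = np.flatnonzero(acf[1:] <= 0)
    if below.size == 0:
        warnings.warn(
            f"autocorrelation has no zero crossing up to lag {max_tau}; returning the cap",
            stacklevel=2,
        )
        return int(max_tau)
    lag = int(below[0] + 1)  # first lag with acf <= 0
    prev, cur = acf[lag - 1], acf[lag]
    if cur == 0:
        return lag
    crossing = (lag - 1) + prev / (prev - cur)
    return max(1, int(round(crossing)))


def ordinal_symbols(series: np.ndarray, params: EmbeddingParams) -> OrdinalSymbolSequence:
    """Map each delay window to its argsort permutation.

    The symbol lists window positions in ascending order of value; equal
    values are ordered by earlier window position (stable sort), which
    makes symbolization deterministic on flat or quantized stretches.
    """
    x = np.asarray(series, dtype=float).ravel()
    span = params.window_span()
    if x.size < span + 1:
        raise ValueError(f"series of length {x.size} too short for d={params.d}, tau={params.tau} (needs >= {span + 1})")
    n_windows = x.size - span
    # windows as a strided (n_windows, d) view
    idx = np.arange(n_windows)[:, None] + np.arange(params.d)[None, :] * params.tau
    windows = x[idx]
    perms = np.argsort(windows, axis=1, kind="stable")
    symbols = [tuple(int(v) for v in row) for row in perms]
    return OrdinalSymbolSequence(symbols=symbols, params=params)


def build_opn(sym: OrdinalSymbolSequence) -> OrdinalPartitionNetwork:
    """Count nodes and consecutive-symbol transitions into a network."""
    if sym.n_windows < 2:
        raise ValueError("need at least 2 windows to build a transition network")
    node_weights = dict(Counter(sym.symbols))
    edge_counts = dict(Counter(zip(sym.symbols[:-1], sym.symbols[1:])))
    return OrdinalPartitionNetwork(node_weights=node_weights, edge_counts=edge_counts, params=sym.params)


def opn_counts(opn: OrdinalPartitionNetwork) -> dict[str, int]:
    """Repertoire size (distinct symbols) and distinct-transition count."""
    return {"n_nodes": opn.n_nodes, "n_edges": opn.n_edges}


def _degree_variance(opn: OrdinalPartitionNetwork, which: str = "total") -> float:
    """Variance of the unweighted degree distribution over distinct edges."""
    idx = {s: i for i, s in enumerate(opn.nodes)}
    deg = np.zeros(opn.n_nodes)
    for a, b in opn.edge_counts:
        if which in ("total", "out"):
            deg[idx[a]] += 1
        if which in ("total", "in"):
            deg[idx[b]] += 1
    return float(np.var(deg))


def select_dim(
    series: np.ndarray,
    tau: int,
    candidates: tuple[int, ...] = (3, 4, 5, 6, 7),
    degree: str = "total",
) -> int:
    """Embedding dimension maximizing the degree-distribution variance.

    For each candidate ``d`` the OPN is built at lag ``tau`` and the
    variance of its (by default total-) degree distribution computed; the
    argmax is returned, ties going to the smallest ``d``. Too large a
    ``d`` turns the network into a path graph with near-constant degrees,
    so such candidates are never preferred on structured input.
    """
    if not candidates:
        raise ValueError("candidates must be non-empty")
    x = np.asarray(series, dtype=float)
    variances = {}
    for d in sorted(candidates):
        p = EmbeddingParams(d=d, tau=tau)
        if x.size < p.window_span() + 2:
            raise ValueError(f"series too short for candidate d={d} at tau={tau}")
        variances[d] = _degree_variance(build_opn(ordinal_symbols(x, p)), which=degree)
    return max(variances, key=lambda d: (variances[d], -d))


def select_dim_mode(per_channel_dims: list[int]) -> int:
    """Aggregate per-channel selections to one shared ``d`` by the mode.

    Ties go to the smallest dimension, keeping the choice deterministic.
    """
    if not per_channel_dims:
        raise ValueError("no per-channel dimensions given")
    counts = Counter(per_channel_dims)
    return min(counts, key=lambda d: (-counts[d], d))
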