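"""Scalar dynamical measures: determinism, degeneracy, permutation
entropy and the largest Lyapunov exponent.

Determinism and degeneracy are normalized information-theoretic summaries
of a state-transition graph with ``N`` nodes and per-node out-transition
distributions ``W_i``:

    Det = (log2 N - <H(W_i)>) / log2 N
    Deg = (log2 N - H(<W_i>)) / log2 N

where ``<.>`` is the unweighted mean over nodes that have outgoing
transitions and ``H`` is Shannon entropy in bits. Det is 1 when every
state has a unique successor (perfectly predictable future) and 0 when
every state's future is uniform over all states; Deg is 0 when the
node-averaged out-distribution is uniform and approaches 1 as all states
funnel into one shared future (an unrecoverable past). The unweighted
mean corresponds to the maximum-entropy intervention convention of the
effective-information literature; a visit-weighted variant is available.

The largest Lyapunov exponent is estimated with the Rosenstein
nearest-neighbour divergence method and reported in nats per sample.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.spatial import cKDTree

from .opn import OrdinalPartitionNetwork, OrdinalSymbolSequence

__all__ = [
    "shannon_entropy",
    "determinism",
    "degeneracy",
    "permutation_entropy",
    "lyapunov_largest",
]


def shannon_entropy(p: np.ndarray) -> float:
    """Shannon entropy in bits of a probability vector (zeros ignored)."""
    p = np.asarray(p, dtype=float)
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def _out_stats(opn: OrdinalPartitionNetwork, weighted: bool):
    mask, w = opn.out_distributions()
    n = opn.n_nodes
    if n < 2:
        warnings.warn("determinism/degeneracy undefined for a single-node network (log2 1 = 0)", stacklevel=3)
        return None
    if not mask.any():
        raise ValueError("network has no transitions")
    if weighted:
        weights = np.array([opn.node_weights[s] for s in opn.nodes], dtype=float)[mask]
        weights = weights / weights.sum()
    else:
        weights = np.full(int(mask.sum()), 1.0 / mask.sum())
    return mask, w, weights


def determinism(opn: OrdinalPartitionNetwork, weighted: bool = False) -> float:
    """Normalized predictability of the future given the present state.

    Returns NaN (with a warning) for single-node networks, where the
    normalization ``log2 N`` vanishes.
    """
    stats = _out_stats(opn, weighted)
    if stats is None:
        return float("nan")
    mask, w, weights = stats
    h = np.array([shannon_entropy(row) for row in w[mask]])
    log_n = np.log2(opn.n_nodes)
    return float((log_n - float(h @ weights)) / log_n)


def degeneracy(opn: OrdinalPartitionNetwork, weighted: bool = False) -> float:
    """Normalized concentration of the node-averaged out-distribution."""
    stats = _out_stats(opn, weighted)
    if stats is None:
        return float("nan")
    mask, w, weights = stats
    avg = weights @ w[mask]
    log_n = np.log2(opn.n_nodes)
    return float((log_n - shannon_entropy(avg)) / log_n)


def permutation_entropy(sym: OrdinalSymbolSequence | list) -> float:
    """Shannon entropy (bits, unnormalized) of the ordinal symbol frequencies."""
    from collections import Counter

    symbols = sym.symbols if isinstance(sym, OrdinalSymbolSequence) else list(sym)
    if not symbols:
        raise ValueError("empty symbol sequence")
    freqs = np.array(list(Counter(symbols).values()), dtype=float)
    return shannon_entropy(freqs / freqs.sum())


def _delay_embed(x: np.ndarray, m: int, lag: int) -> np.ndarray:
    n_vec = x.size - (m - 1) * lag
    idx = np.arange(n_vec)[:, None] + np.arange(m)[None, :] * lag
    return x[idx]


def lyapunov_largest(
    series: np.ndarray,
    m: int = 5,
    lag: int = 1,
    theiler: int | None = None,
    fit_range: tuple[int, int] = (1, 10),
    min_length: int = 1000,
) -> float:
    """Largest Lyapunov exponent, Rosenstein estimate, in nats per sample.

    The series is delay-embedded (``m``, ``lag``); each point's nearest
    neighbour outside a Theiler exclusion window (default
    ``lag * (m - 1)``) is found with a k-d tree; the mean log distance
    between the two trajectories is tracked forward in time and the
    exponent read off as the slope of a least-squares line over
    ``fit_range`` (steps, inclusive).
    """
    x = np.asarray(series, dtype=float).ravel()
    if x.size < min_length:
        raise ValueError(f"series too short for Lyapunov estimation ({x.size} < {min_length})")
    if x.std() == 0:
        raise ValueError("constant series: Lyapunov exponent undefined")
    if theiler is None:
        theiler = max(1, lag * (m - 1))
    y = _delay_embed(x, m, lag)
    n_vec = y.shape[0]
    t_lo, t_hi = fit_range
    if not 1 <= t_lo < t_hi:
        raise ValueError("fit_range must satisfy 1 <= lo < hi")
    if n_vec <= t_hi + theiler + 1:
        raise ValueError("embedded trajectory too short for the requested fit range")

    tree = cKDTree(y)
    k = min(2 * theiler + 2, n_vec)
    dists, idxs = tree.query(y, k=k)
    neigh = np.full(n_vec, -1)
    for col in range(1, k):
        cand = idxs[:, col]
        ok = (neigh < 0) & (np.abs(cand - np.arange(n_vec)) > theiler) & (dists[:, col] > 0)
        neigh[ok] = cand[ok]
    valid = neigh >= 0
    if not valid.any():
        raise ValueError("no valid neighbour pairs outside the Theiler window")

    steps = np.arange(0, t_hi + 1)
    mean_log = np.full(steps.size, np.nan)
    base = np.flatnonzero(valid)
    for s in steps:
        ok = base[(base + s < n_vec) & (neigh[base] + s < n_vec)]
        if ok.size == 0:
            break
        d = np.linalg.norm(y[ok + s] - y[neigh[ok] + s], axis=1)
        d = d[d > 0]
        if d.size == 0:
            continue
        mean_log[s] = np.log(d).mean()
    fit_steps = steps[t_lo : t_hi + 1]
    fit_vals = mean_log[t_lo : t_hi + 1]
    good = np.isfinite(fit_vals)
    if good.sum() < 2:
        raise ValueError("divergence curve too short to fit a slope")
    slope = np.polyfit(fit_steps[good], fit_vals[good], 1)[0]
    return float(slope)
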