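"""Independent brute-force oracles used by the test suite.

These deliberately use the plainest possible algorithms — full boundary
matrix reduction for persistence, exhaustive set-partition enumeration
for the map equation, direct formula evaluation for the graph measures —
so they share no code path with the package implementations they check.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


# ---------------------------------------------------------------------------
# persistence: textbook reduction of the full boundary matrix over GF(2)
# ---------------------------------------------------------------------------

def brute_force_persistence(dm: np.ndarray) -> list[tuple[int, float, float]]:
    """Persistence pairs (dim, birth, death) of the full Rips filtration.

    Enumerates every vertex, edge and triangle, sorts them by
    (filtration value, dimension, lexicographic vertex tuple), builds the
    single global boundary matrix over GF(2) and runs the standard
    left-to-right column reduction. Zero-persistence pairs are kept for
    dimension 0 (duplicate-point merges) and dropped for dimension 1;
    unpaired vertices become essential H0 classes with death = inf.
    """
    n = dm.shape[0]
    simplices: list[tuple[float, int, tuple[int, ...]]] = [(0.0, 0, (i,)) for i in range(n)]
    for i, j in combinations(range(n), 2):
        simplices.append((float(dm[i, j]), 1, (i, j)))
    for i, j, k in combinations(range(n), 3):
        simplices.append((float(max(dm[i, j], dm[i, k], dm[j, k])), 2, (i, j, k)))
    simplices.sort()
    index = {s[2]: idx for idx, s in enumerate(simplices)}

    columns: list[int] = []
    for _, dim, verts in simplices:
        col = 0
        if dim >= 1:
            for face in combinations(verts, dim):
                col |= 1 << index[face]
        columns.append(col)

    low_to_col: dict[int, int] = {}
    pairs: list[tuple[int, int]] = []
    for j, col in enumerate(columns):
        while col:
            low = col.bit_length() - 1
            if low not in low_to_col:
                break
            col ^= columns[low_to_col[low]]
        columns[j] = col
        if col:
            low = col.bit_length() - 1
            low_to_col[low] = j
            pairs.append((low, j))

    paired = {i for pair in pairs for i in pair}
    out: list[tuple[int, float, float]] = []
    for i, j in pairs:
        fi, dim_i, _ = simplices[i]
        fj, _, _ = simplices[j]
        if dim_i == 0 or fj > fi:
            out.append((dim_i, fi, fj))
    for idx, (f, dim, _) in enumerate(simplices):
        if idx not in paired and dim < 2:
            out.append((dim, f, np.inf))
    return sorted(out)


def diagram_to_tuples(diag) -> list[tuple[int, float, float]]:
    """Package diagram as sortable (dim, birth, death) tuples (inf-safe)."""
    out = []
    for iv in diag.intervals:
        death = np.inf if iv.truncated and iv.death >= diag.max_radius else iv.death
        out.append((iv.dim, iv.birth, death))
    return sorted(out)


# ---------------------------------------------------------------------------
# map equation: direct formula + exhaustive search over set partitions
# ---------------------------------------------------------------------------

def codelength_direct(p: np.ndarray, f: np.ndarray, assignment: np.ndarray) -> float:
    """Two-level map-equation codelength from its defining entropies.

    L = q H(Q) + sum_m p_circ_m H(P_m), written out term by term rather
    than via the algebraic expansion the package uses.
    """

    def entropy(probs):
        probs = np.asarray([x for x in probs if x > 0], dtype=float)
        probs = probs / probs.sum()
        return float(-(probs * np.log2(probs)).sum())

    labels = np.unique(assignment)
    q_m = []
    terms = 0.0
    for c in labels:
        members = np.flatnonzero(assignment == c)
        outside = np.flatnonzero(assignment != c)
        q = f[np.ix_(members, outside)].sum()
        q_m.append(q)
        p_circ = q + p[members].sum()
        if p_circ > 0:
            terms += p_circ * entropy([q] + list(p[members]))
    q_total = float(np.sum(q_m))
    if q_total > 0:
        terms += q_total * entropy(q_m)
    return terms


def set_partitions(items: list[int]):
    """All set partitions of ``items`` (restricted-growth enumeration)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for smaller in set_partitions(rest):
        for k in range(len(smaller)):
            yield smaller[:k] + [[first] + smaller[k]] + smaller[k + 1 :]
        yield [[first]] + smaller


def exhaustive_min_codelength(p: np.ndarray, f: np.ndarray) -> tuple[float, np.ndarray]:
    """Global minimum of the map equation by exhaustive enumeration (n <= 10)."""
    n = p.size
    best_l, best_a = np.inf, None
    for part in set_partitions(list(range(n))):
        assignment = np.empty(n, dtype=int)
        for c, block in enumerate(part):
            assignment[block] = c
        l = codelength_direct(p, f, assignment)
        if l < best_l - 1e-15:
            best_l, best_a = l, assignment
    return float(best_l), best_a


# ---------------------------------------------------------------------------
# graph measures: direct dict-based evaluation
# ---------------------------------------------------------------------------

def det_deg_direct(edge_counts: dict) -> tuple[float, float]:
    """Determinism and degeneracy evaluated straight from the formulas."""
    nodes = sorted({a for a, _ in edge_counts} | {b for _, b in edge_counts})
    n = len(nodes)
    out: dict = {}
    for (a, b), c in edge_counts.items():
        out.setdefault(a, {})[b] = out.setdefault(a, {}).get(b, 0) + c
    dists = []
    for a in nodes:
        if a in out:
            tot = sum(out[a].values())
            dists.append({b: c / tot for b, c in out[a].items()})

    def h(dist):
        return -sum(v * np.log2(v) for v in dist.values() if v > 0)

    mean_h = float(np.mean([h(d) for d in dists]))
    avg: dict = {}
    for d in dists:
        for b, v in d.items():
            avg[b] = avg.get(b, 0.0) + v / len(dists)
    log_n = np.log2(n)
    return (log_n - mean_h) / log_n, (log_n - h(avg)) / log_n


def modularity_direct(edge_counts: dict, assignment: dict) -> float:
    """Directed weighted modularity by explicit double sum over node pairs."""
    nodes = sorted({a for a, _ in edge_counts} | {b for _, b in edge_counts})
    m = sum(edge_counts.values())
    k_out = {u: 0.0 for u in nodes}
    k_in = {u: 0.0 for u in nodes}
    for (a, b), c in edge_counts.items():
        k_out[a] += c
        k_in[b] += c
    q = 0.0
    for u in nodes:
        for v in nodes:
            if assignment[u] == assignment[v]:
                a_uv = edge_counts.get((u, v), 0.0)
                q += a_uv / m - k_out[u] * k_in[v] / m**2
    return q
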