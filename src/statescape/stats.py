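"""Nonparametric group comparisons and condition-level aggregation.

Group differences are tested with the Kruskal-Wallis rank ANOVA
(tie-corrected H, chi-squared approximation) and pairwise two-sided
Mann-Whitney U post hoc tests (exact null for small tie-free samples,
normal approximation otherwise), both via scipy. No multiple-comparison
correction is applied by default; Holm correction is available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["StatTestResult", "kruskal_wallis", "mann_whitney_posthoc", "aggregate", "holm_correct"]


@dataclass(frozen=True)
class StatTestResult:
    test: str
    statistic: float
    p_value: float
    groups: tuple[str, ...]


def kruskal_wallis(groups: dict[str, np.ndarray] | list[np.ndarray]) -> StatTestResult:
    """Kruskal-Wallis H over two or more samples.

    All-identical observations make every rank tie; H is then 0 and p is
    reported as 1 with a warning instead of scipy's error.
    """
    if isinstance(groups, dict):
        labels, samples = tuple(groups), [np.asarray(g, float) for g in groups.values()]
    else:
        samples = [np.asarray(g, float) for g in groups]
        labels = tuple(f"group{i}" for i in range(len(samples)))
    if len(samples) < 2:
        raise ValueError("need at least 2 groups")
    for lab, g in zip(labels, samples):
        if g.size == 0:
            raise ValueError(f"group {lab!r} is empty")
    pooled = np.concatenate(samples)
    if np.all(pooled == pooled[0]):
        warnings.warn("all observations identical; H = 0, p = 1", stacklevel=2)
        return StatTestResult("kruskal_wallis", 0.0, 1.0, labels)
    h, p = sps.kruskal(*samples)
    return StatTestResult("kruskal_wallis", float(h), float(p), labels)


def mann_whitney_posthoc(groups: dict[str, np.ndarray]) -> list[StatTestResult]:
    """Two-sided Mann-Whitney U for every unordered pair of groups.

    The exact null distribution is used when both samples have n <= 20 and
    no ties; otherwise the tie-corrected normal approximation. Pairs with
    an empty group are skipped with a warning.
    """
    labels = list(groups)
    results = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            a = np.asarray(groups[labels[i]], float)
            b = np.asarray(groups[labels[j]], float)
            if a.size == 0 or b.size == 0:
                warnings.warn(f"skipping pair ({labels[i]}, {labels[j]}): empty group", stacklevel=2)
                continue
            small = a.size <= 20 and b.size <= 20
            no_ties = np.unique(np.concatenate([a, b])).size == a.size + b.size
            method = "exact" if (small and no_ties) else "asymptotic"
            u, p = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
            results.append(StatTestResult("mann_whitney", float(u), float(p), (labels[i], labels[j])))
    return results


def holm_correct(results: list[StatTestResult]) -> list[StatTestResult]:
    """Holm step-down adjusted p-values, preserving input order."""
    ps = np.array([r.p_value for r in results])
    order = np.argsort(ps)
    m = len(ps)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * ps[idx])
        adj[idx] = min(1.0, running)
    return [
        StatTestResult(r.test + "_holm", r.statistic, float(a), r.groups)
        for r, a in zip(results, adj)
    ]


def aggregate(table: pd.DataFrame, level: str, measures: list[str] | None = None) -> pd.DataFrame:
    """Mean +/- sample SD of each measure per group of ``level``.

    Groups of size 1 report SD 0 and are flagged via the ``n`` column;
    rows with missing values are counted in ``n_missing`` rather than
    silently dropped.
    """
    if level not in table.columns:
        raise ValueError(f"level column {level!r} not in table")
    if measures is None:
        measures = [c for c in table.columns if pd.api.types.is_numeric_dtype(table[c])]
    rows = []
    for key, grp in table.groupby(level):
        for m in measures:
            vals = grp[m].to_numpy(dtype=float)
            ok = np.isfinite(vals)
            n = int(ok.sum())
            if n == 0:
                warnings.warn(f"group {key!r} has no finite values for {m!r}; excluded", stacklevel=2)
                continue
            sd = float(np.std(vals[ok], ddof=1)) if n > 1 else 0.0
            rows.append(
                {
                    level: key,
                    "measure": m,
                    "mean": float(vals[ok].mean()),
                    "sd": sd,
                    "n": n,
                    "n_missing": int((~ok).sum()),
                }
            )
    return pd.DataFrame(rows)
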