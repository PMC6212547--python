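"""SGoF sequential goodness-of-fit correction and the G test.

SGoF compares the observed count of nominally significant p-values (p <=
gamma) with its binomial expectation under the complete null and declares
as many features significant as the count exceeds the binomial critical
value: starting from the observed count c = F, while the one-sided exact
binomial test still rejects (P[X >= c] <= alpha under Bin(n, gamma)), one
more feature is declared and c decreases by one.  The declared features are
the n_declared smallest p-values (ties broken by stable input order).

This gains power when many tests are weakly significant, at the cost of
never declaring more than the excess over the binomial bound — a property
that matters when interpreting recovery rates downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats


@dataclass(frozen=True)
class SGoFResult:
    """Declared-significant set for one p-value vector."""

    n_tests: int
    alpha: float
    gamma: float
    F: int
    n_declared: int
    declared: tuple = ()

    @property
    def declared_set(self) -> set:
        return set(self.declared)


def sgof(
    pvalues,
    alpha: float = 0.05,
    gamma: float = 0.05,
    ids=None,
    method: str = "exact",
) -> SGoFResult:
    """Binomial sequential goodness-of-fit multiple-testing correction.

    Parameters
    ----------
    pvalues:
        p-values in [0, 1]; a pandas Series' index is used as feature ids
        unless ``ids`` is given.
    method:
        ``"exact"`` uses the exact binomial survival test; ``"chi2"`` the
        one-sided chi-square approximation (for cross-checking large-n
        behavior of the approximate variant).
    """
    if isinstance(pvalues, pd.Series) and ids is None:
        ids = list(pvalues.index)
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be one-dimensional")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if not (0 < alpha < 1) or not (0 < gamma < 1):
        raise ValueError("alpha and gamma must be in (0, 1)")
    if ids is None:
        ids = list(range(len(p)))
    n = len(p)
    F = int((p <= gamma).sum())

    def rejects(c: int) -> bool:
        if c <= 0:
            return False
        if method == "exact":
            return stats.binom.sf(c - 1, n, gamma) <= alpha
        if method == "chi2":
            expected = n * gamma
            if c <= expected:
                return False
            stat = (c - expected) ** 2 / (n * gamma * (1 - gamma))
            return stats.chi2.sf(stat, 1) / 2.0 <= alpha
        raise ValueError("method must be 'exact' or 'chi2'")

    c = F
    n_declared = 0
    while rejects(c):
        n_declared += 1
        c -= 1

    order = np.argsort(p, kind="stable")
    declared = tuple(ids[i] for i in order[:n_declared])
    return SGoFResult(
        n_tests=n, alpha=alpha, gamma=gamma, F=F, n_declared=n_declared, declared=declared
    )


def g_test_heterogeneity(count_table) -> dict:
    """Likelihood-ratio (G) test of independence on a count table.

    G = 2 sum O ln(O/E) with the independence-model expectations,
    df = (r-1)(c-1), p from the upper chi-square tail; empty cells
    contribute zero.
    """
    table = np.asarray(count_table, dtype=float)
    if table.ndim != 2:
        raise ValueError("count table must be two-dimensional")
    if np.any(table < 0) or np.any(table != np.floor(table)):
        raise ValueError("counts must be nonnegative integers")
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    if np.any(rows == 0) or np.any(cols == 0):
        raise ValueError("count table has a zero margin")
    expected = np.outer(rows, cols) / table.sum()
    g = 2.0 * special.xlogy(table, table / expected).sum()
    df = (table.shape[0] - 1) * (table.shape[1] - 1)
    p = float(stats.chi2.sf(g, df))
    return {"G": float(g), "df": int(df), "p": p}
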