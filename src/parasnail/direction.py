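"""Directionality of parallel changes and intrapopulation variance.

A parallel feature is *directional* (D) when the crab-minus-wave effect has
the same nonzero sign in all three localities, *nondirectional* (ND)
otherwise (a zero estimate counts as a sign mismatch).  The excess of D
over its chance expectation is tested by permuting, within each locality,
the signed estimates across the parallel features.  Repeated recruitment by
selection also predicts lower within-population variance for directional
features; that is tested by an unpaired t test and a label permutation on
the per-feature intrapopulation variances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .design import SampleDesign


@dataclass(frozen=True)
class DirectionResult:
    """D/ND classification and (optionally) its randomization null."""

    classes: pd.Series  # 'D' / 'ND' per feature
    signs: pd.DataFrame  # features x localities, entries in {-1, 0, +1}
    n_directional: int
    n_nondirectional: int
    expected_directional: float | None = None
    expected_nondirectional: float | None = None
    ci_directional: tuple[float, float] | None = None
    ci_nondirectional: tuple[float, float] | None = None
    p_value: float | None = None
    n_permutations: int | None = None
    seed: int | None = None


@dataclass(frozen=True)
class VarianceComparison:
    """Intrapopulation variance of D vs ND features."""

    mean_directional: float
    mean_nondirectional: float
    ratio: float  # nondirectional / directional
    t_statistic: float
    t_pvalue: float
    randomization_p: float | None = None
    n_permutations: int | None = None
    seed: int | None = None


def _sign_frame(effect_table: pd.DataFrame, features) -> pd.DataFrame:
    features = list(features)
    missing = [f for f in features if f not in effect_table.index]
    if missing:
        raise ValueError(f"effect estimates missing for {len(missing)} features")
    if effect_table.shape[1] != 3:
        raise ValueError("effect table must have one signed estimate per locality (3 columns)")
    sub = effect_table.loc[features]
    if sub.isna().any().any():
        raise ValueError("effect table contains missing locality estimates")
    return np.sign(sub).astype(int)


def _count_directional(signs: np.ndarray) -> int:
    nonzero = (signs != 0).all(axis=1)
    same = (signs == signs[:, [0]]).all(axis=1)
    return int((nonzero & same).sum())


def classify_directions(effect_table: pd.DataFrame, parallel_set) -> DirectionResult:
    """Label each parallel feature D or ND from its sign triple."""
    signs = _sign_frame(effect_table, parallel_set)
    arr = signs.to_numpy()
    nonzero = (arr != 0).all(axis=1)
    same = (arr == arr[:, [0]]).all(axis=1)
    classes = pd.Series(np.where(nonzero & same, "D", "ND"), index=signs.index)
    n_d = int((classes == "D").sum())
    return DirectionResult(
        classes=classes,
        signs=signs,
        n_directional=n_d,
        n_nondirectional=len(classes) - n_d,
    )


def direction_randomization(
    effect_table: pd.DataFrame,
    parallel_set,
    R: int = 10_000,
    seed: int = 0,
    pool=None,
) -> DirectionResult:
    """Null expectation of the D count by within-locality permutation.

    Each replicate independently permutes, within each locality, the signed
    estimates across the parallel features and recounts D.  The reported
    expectations are null means, the CIs the 2.5/97.5 percentiles, and the
    p-value the upper-tail probability of the observed D count.

    ``pool`` optionally widens the permutation pool (e.g. to all analyzed
    genes): each replicate then draws the parallel features' signs without
    replacement from the pool's per-locality sign vectors.
    """
    base = classify_directions(effect_table, parallel_set)
    signs = base.signs.to_numpy()
    n = signs.shape[0]
    if n < 2:
        raise ValueError("need at least two parallel features to permute")
    pool_signs = signs if pool is None else _sign_frame(effect_table, pool).to_numpy()
    if pool_signs.shape[0] < n:
        raise ValueError("permutation pool smaller than the parallel set")
    m = pool_signs.shape[0]
    rng = np.random.default_rng(seed)

    d_perm = np.empty(R, dtype=int)
    chunk = max(1, int(2e6 // max(m, 1)))
    done = 0
    while done < R:
        r = min(chunk, R - done)
        block = np.broadcast_to(pool_signs.T, (r, 3, m)).copy()  # r x loc x feature
        perm = rng.permuted(block, axis=2)[:, :, :n]
        nonzero = (perm != 0).all(axis=1)
        same = (perm == perm[:, [0], :]).all(axis=1)
        d_perm[done : done + r] = (nonzero & same).sum(axis=1)
        done += r

    p = (1 + int((d_perm >= base.n_directional).sum())) / (R + 1)
    lo_d, hi_d = np.percentile(d_perm, [2.5, 97.5])
    nd_perm = n - d_perm
    lo_n, hi_n = np.percentile(nd_perm, [2.5, 97.5])
    return DirectionResult(
        classes=base.classes,
        signs=base.signs,
        n_directional=base.n_directional,
        n_nondirectional=base.n_nondirectional,
        expected_directional=float(d_perm.mean()),
        expected_nondirectional=float(nd_perm.mean()),
        ci_directional=(float(lo_d), float(hi_d)),
        ci_nondirectional=(float(lo_n), float(hi_n)),
        p_value=float(p),
        n_permutations=R,
        seed=seed,
    )


def intrapopulation_variance(matrix, sample_design: SampleDesign, features=None) -> pd.Series:
    """Mean within-group sample variance over the ecotype x locality groups.

    Groups with fewer than two replicates are skipped; it is an error for a
    feature to have no usable group at all.
    """
    values = matrix if isinstance(matrix, pd.DataFrame) else matrix.values
    if features is not None:
        values = values.loc[list(features)]
    table = sample_design.table.set_index("sample_id")
    cols = [c for c in values.columns if c in table.index]
    if len(cols) != values.shape[1]:
        raise ValueError("matrix columns missing from sample design")
    meta = table.loc[cols]
    groups = []
    for (_, _), sub in meta.groupby(["ecotype", "locality"], sort=True):
        ids = list(sub.index)
        if len(ids) >= 2:
            groups.append(values[ids].var(axis=1, ddof=1))
    if not groups:
        raise ValueError("every ecotype x locality group has fewer than 2 replicates")
    return pd.concat(groups, axis=1).mean(axis=1)


def compare_variances(
    var_vector: pd.Series,
    classes: pd.Series,
    R: int = 10_000,
    seed: int = 0,
    welch: bool = False,
) -> VarianceComparison:
    """Unpaired t test and label-permutation test of D vs ND variances.

    The reported ratio is mean(ND) / mean(D); the permutation statistic is
    the absolute difference of class means (two-sided).
    """
    classes = classes.loc[var_vector.index]
    d_vals = var_vector[classes == "D"].to_numpy(float)
    nd_vals = var_vector[classes == "ND"].to_numpy(float)
    if len(d_vals) == 0 or len(nd_vals) == 0:
        raise ValueError("both the D and ND classes must be nonempty")
    mean_d = float(d_vals.mean())
    mean_nd = float(nd_vals.mean())
    if d_vals.var(ddof=0) == 0 and nd_vals.var(ddof=0) == 0:
        # degenerate: no within-class spread; equal means -> t = 0, p = 1
        if mean_d == mean_nd:
            t_res = type("T", (), {"statistic": 0.0, "pvalue": 1.0})
        else:
            t_res = type("T", (), {"statistic": np.inf * np.sign(mean_d - mean_nd), "pvalue": 0.0})
    else:
        t_res = stats.ttest_ind(d_vals, nd_vals, equal_var=not welch)
    ratio = mean_nd / mean_d if mean_d > 0 else float("nan")

    rng = np.random.default_rng(seed)
    pooled = np.concatenate([d_vals, nd_vals])
    n_d = len(d_vals)
    obs = abs(mean_d - mean_nd)
    count = 0
    for _ in range(R):
        perm = rng.permutation(pooled)
        diff = abs(perm[:n_d].mean() - perm[n_d:].mean())
        if diff >= obs - 1e-15:
            count += 1
    p_rand = (1 + count) / (R + 1)
    return VarianceComparison(
        mean_directional=mean_d,
        mean_nondirectional=mean_nd,
        ratio=float(ratio),
        t_statistic=float(t_res.statistic),
        t_pvalue=float(t_res.pvalue),
        randomization_p=float(p_rand),
        n_permutations=R,
        seed=seed,
    )
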