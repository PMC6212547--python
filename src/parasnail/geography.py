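"""Geographic differentiation and its enrichment among parallel features.

Within each ecotype, a feature is geographically differentiated when the
2-df moderated F for the among-locality contrast survives SGoF.  Whether
parallel features are enriched for such differentiation is judged against a
resampling null: B random feature sets of the same size drawn from the
analysis universe, recording the fraction significant in each.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import SampleDesign
from .linmod import ArrayLinearModel
from .multitest import sgof


@dataclass(frozen=True)
class GeographyResult:
    """Observed fraction of a set that is geographically differentiated."""

    set_name: str
    set_size: int
    n_significant_in_set: int
    observed_fraction: float
    null_mean: float
    null_ci: tuple[float, float]
    p_value: float
    n_resamples: int
    seed: int


def locality_differentiation(
    matrix,
    sample_design: SampleDesign,
    ecotype: str,
    alpha: float = 0.05,
    gamma: float = 0.05,
) -> set:
    """Features with a significant among-locality effect within one ecotype.

    Fits the 2-df moderated F restricted to that ecotype's samples and
    applies SGoF at ``alpha``; returns the declared feature set.
    """
    sub = sample_design.subset(ecotype=ecotype)
    if sub.table.empty:
        raise ValueError(f"no samples for ecotype {ecotype!r}")
    localities = set(sub.table["locality"])
    if len(localities) < 3:
        raise ValueError(f"ecotype {ecotype!r} lacks samples in all three localities")
    values = matrix if isinstance(matrix, pd.DataFrame) else matrix.values
    cols = [c for c in values.columns if c in set(sub.table["sample_id"])]
    res = ArrayLinearModel(
        values[cols], sub, analysis="locality_within_ecotype"
    ).fit()
    pcol = f"locality@{ecotype}"
    return sgof(res.pvalues[pcol], alpha=alpha, gamma=gamma).declared_set


def parallel_enrichment_resample(
    sig_set,
    feature_set,
    universe,
    B: int = 1000,
    seed: int = 0,
    set_name: str = "parallel",
) -> GeographyResult:
    """Observed significant fraction of a feature set vs same-size resamples.

    The null resamples B uniform subsets of ``universe`` with
    ``len(feature_set)`` members and records the fraction that is
    geographically significant; the p-value is the upper-tail probability of
    the observed fraction, CI the 2.5/97.5 percentiles.
    """
    universe = list(dict.fromkeys(universe))
    feature_set = set(feature_set)
    sig_set = set(sig_set)
    if not feature_set:
        raise ValueError("feature set is empty")
    extra = feature_set - set(universe)
    if extra:
        raise ValueError(f"{len(extra)} features outside the universe")
    n = len(feature_set)
    obs = len(sig_set & feature_set) / n

    rng = np.random.default_rng(seed)
    is_sig = np.array([u in sig_set for u in universe])
    N = len(universe)
    fracs = np.empty(B)
    for b in range(B):
        idx = rng.choice(N, size=n, replace=False)
        fracs[b] = is_sig[idx].mean()
    lo, hi = np.percentile(fracs, [2.5, 97.5])
    p = (1 + int((fracs >= obs - 1e-15).sum())) / (B + 1)
    return GeographyResult(
        set_name=set_name,
        set_size=n,
        n_significant_in_set=len(sig_set & feature_set),
        observed_fraction=float(obs),
        null_mean=float(fracs.mean()),
        null_ci=(float(lo), float(hi)),
        p_value=float(p),
        n_resamples=B,
        seed=seed,
    )
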