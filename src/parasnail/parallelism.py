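"""Three-way intersection of per-locality significant sets and its null.

A feature shows a *parallel change* when it is significantly divergent
between the ecotypes in all three localities.  Whether the observed
intersection size k exceeds chance is tested two ways:

* an exact null — the distribution of |A ∩ B ∩ C| for independent uniform
  random subsets of fixed sizes n1, n2, n3 from a universe of N features,
  computed by hypergeometric convolution (the three-locality extension of
  the two-group gene-list overlap null);
* a permutation test — re-drawing which features carry each locality's
  significant calls (``gene_shuffle``), or re-permuting ecotype labels and
  re-running the model + correction chain (``label``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .multitest import sgof


@dataclass(frozen=True)
class ParallelResult:
    """Observed intersection and its chance expectations."""

    universe_size: int
    set_sizes: tuple[int, int, int]
    intersection: tuple
    k: int
    expected: float
    exact_p: float | None = None
    permutation_p: float | None = None
    n_permutations: int | None = None
    seed: int | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "N": [self.universe_size],
                "n1": [self.set_sizes[0]],
                "n2": [self.set_sizes[1]],
                "n3": [self.set_sizes[2]],
                "k": [self.k],
                "expected_k": [self.expected],
                "exact_p": [self.exact_p],
                "permutation_p": [self.permutation_p],
                "R": [self.n_permutations],
                "seed": [self.seed],
            }
        )


def intersect_significant(sig_sets: dict, universe) -> ParallelResult:
    """Intersect exactly three per-locality significant sets.

    ``sig_sets`` maps locality -> iterable of feature ids; all must be
    subsets of ``universe``.
    """
    if len(sig_sets) != 3:
        raise ValueError("exactly three localities are required")
    universe = set(universe)
    sets = {loc: set(s) for loc, s in sig_sets.items()}
    for loc, s in sets.items():
        extra = s - universe
        if extra:
            raise ValueError(f"{loc}: {len(extra)} features outside the universe")
    localities = list(sets)
    inter = sets[localities[0]] & sets[localities[1]] & sets[localities[2]]
    sizes = tuple(len(sets[loc]) for loc in localities)
    N = len(universe)
    expected = N * np.prod([s / N for s in sizes]) if N else 0.0
    return ParallelResult(
        universe_size=N,
        set_sizes=sizes,  # type: ignore[arg-type]
        intersection=tuple(sorted(inter)),
        k=len(inter),
        expected=float(expected),
    )


def probes_to_genes(probe_set, design) -> set:
    """Gene-level calls from probe-level calls: any significant probe."""
    return set(design.genes_of(probe_set))


def derome3_null(N: int, n1: int, n2: int, n3: int, k: int | None = None) -> dict:
    """Exact null of the three-way overlap of fixed-size random subsets.

    |A ∩ B| is hypergeometric (population N, n1 marked, n2 drawn); given
    |A ∩ B| = m, the triple overlap is hypergeometric with m marked and n3
    drawn.  Convolving gives the pmf of K = |A ∩ B ∩ C|; the upper tail
    P(K >= k) is the parallelism p-value.
    """
    for ni in (n1, n2, n3):
        if ni < 0 or ni > N:
            raise ValueError("set sizes must satisfy 0 <= ni <= N")
    kmax = min(n1, n2, n3)
    if k is not None and (k < 0 or k > kmax):
        raise ValueError("k must satisfy 0 <= k <= min(n1, n2, n3)")
    m_lo = max(0, n1 + n2 - N)
    m_hi = min(n1, n2)
    m = np.arange(m_lo, m_hi + 1)
    w = stats.hypergeom.pmf(m, N, n1, n2)
    ks = np.arange(0, kmax + 1)
    # pmf[k] = sum_m w[m] * P(Hypergeom(N, m, n3) = k)
    pk = stats.hypergeom.pmf(ks[:, None], N, m[None, :], n3)
    pmf = (pk * w[None, :]).sum(axis=1)
    expected = N * (n1 / N) * (n2 / N) * (n3 / N) if N > 0 else 0.0
    out = {"expected": float(expected), "pmf": pmf, "support": ks}
    if k is not None:
        out["p_value"] = float(pmf[k:].sum())
        out["k"] = k
    return out


def _random_subset_members(rng, R: int, N: int, n: int) -> np.ndarray:
    """Boolean membership matrix (R x N) of uniform size-n subsets."""
    if n == 0:
        return np.zeros((R, N), dtype=bool)
    if n == N:
        return np.ones((R, N), dtype=bool)
    u = rng.random((R, N))
    kth = np.partition(u, n - 1, axis=1)[:, n - 1 : n]
    return u <= kth


def permutation_parallel(
    sig_sets: dict,
    universe,
    R: int = 10_000,
    seed: int = 0,
    mode: str = "gene_shuffle",
    refit: dict | None = None,
) -> ParallelResult:
    """Permutation p-value for the observed three-way intersection.

    ``gene_shuffle`` (default): each replicate independently re-draws, within
    each locality, which universe features carry that locality's significant
    calls (preserving the per-locality counts) and recounts the overlap.

    ``label``: each replicate permutes ecotype labels within each locality's
    samples, refits the ecotype contrasts, re-applies SGoF and recounts the
    overlap.  Requires ``refit`` with keys ``matrix``, ``sample_design``,
    ``alpha``, ``gamma`` (and is far more expensive; use a reduced R).
    """
    obs = intersect_significant(sig_sets, universe)
    N = obs.universe_size
    k_obs = obs.k
    rng = np.random.default_rng(seed)

    if mode == "gene_shuffle":
        n1, n2, n3 = obs.set_sizes
        count = 0
        chunk = max(1, min(R, int(2e6 // max(N, 1)) or 1))
        done = 0
        while done < R:
            r = min(chunk, R - done)
            a = _random_subset_members(rng, r, N, n1)
            b = _random_subset_members(rng, r, N, n2)
            c = _random_subset_members(rng, r, N, n3)
            k_perm = (a & b & c).sum(axis=1)
            count += int((k_perm >= k_obs).sum())
            done += r
    elif mode == "label":
        if refit is None:
            raise ValueError("label mode needs the data matrix and sample design")
        count = _label_permutation_count(
            refit, universe, k_obs, R, rng
        )
    else:
        raise ValueError("mode must be 'gene_shuffle' or 'label'")

    p = (1 + count) / (R + 1)
    return ParallelResult(
        universe_size=N,
        set_sizes=obs.set_sizes,
        intersection=obs.intersection,
        k=k_obs,
        expected=obs.expected,
        permutation_p=float(p),
        n_permutations=R,
        seed=seed,
    )


def _label_permutation_count(refit: dict, universe, k_obs: int, R: int, rng) -> int:
    from .design import SampleDesign
    from .linmod import ArrayLinearModel

    matrix = refit["matrix"]
    sample_design: SampleDesign = refit["sample_design"]
    alpha = refit.get("alpha", 0.05)
    gamma = refit.get("gamma", 0.05)
    table = sample_design.table
    count = 0
    for _ in range(R):
        perm = table.copy()
        for loc in pd.unique(table["locality"]):
            idx = perm.index[perm["locality"] == loc]
            perm.loc[idx, "ecotype"] = (
                perm.loc[idx, "ecotype"].to_numpy()[rng.permutation(len(idx))]
            )
        res = ArrayLinearModel(
            matrix, SampleDesign(perm), analysis="ecotype_within_locality"
        ).fit()
        sets = {}
        for con in res.pvalues.columns:
            loc = con.split("@", 1)[1]
            sets[loc] = sgof(res.pvalues[con], alpha=alpha, gamma=gamma).declared_set
        inter = set(universe)
        for s in sets.values():
            inter &= s
        if len(inter) >= k_obs:
            count += 1
    return count
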