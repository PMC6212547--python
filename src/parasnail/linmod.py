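"""Row-wise linear models with empirical-Bayes variance moderation.

The model is the limma-style workhorse of the pipeline: every feature (gene
or probe) gets an ordinary least-squares fit on a group-means design over
the six ecotype x locality cells, residual variances are shrunk toward a
common prior by an inverse-chi-square empirical-Bayes step, and contrasts
are tested with moderated t (single degree of freedom) or moderated F
(multi-df) statistics on ``d0 + d`` degrees of freedom.

Three named analyses cover the study's questions:

``ecotype_within_locality``
    the three crab-minus-wave differences, one per locality (moderated t).
``factorial_interaction``
    ecotype main effect (t), locality main effect (2-df F) and the
    ecotype x locality interaction (2-df F).
``locality_within_ecotype``
    the 2-df among-locality F within each ecotype.

Usage follows the Model -> Results convention::

    model = ArrayLinearModel(matrix, sample_design, analysis="ecotype_within_locality")
    res = model.fit()            # moderated by default
    res.pvalues                  # features x contrasts
    print(res.summary())
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .design import IntensityMatrix, SampleDesign

ANALYSES = ("factorial_interaction", "ecotype_within_locality", "locality_within_ecotype")


class ContrastError(ValueError):
    """A requested contrast is not estimable under the design."""


def trigamma_inverse(y: float, tol: float = 1e-10, max_iter: int = 100) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton iteration).

    trigamma is strictly decreasing on (0, inf), so the root is unique.
    """
    if y <= 0:
        raise ValueError("trigamma_inverse requires y > 0")
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = special.polygamma(1, x)
        step = (tri - y) / special.polygamma(2, x)
        x_new = x - step
        if x_new <= 0:
            x_new = x / 2.0
        if abs(x_new - x) < tol * (1.0 + abs(x)):
            return float(x_new)
        x = x_new
    return float(x)


def estimate_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments fit of the scaled inverse-chi-square variance prior.

    Assumes s2 | sigma2 ~ sigma2 * chi2_df / df and sigma2 ~ s0^2 d0 / chi2_d0,
    and matches the mean and variance of log(s2) via digamma/trigamma.
    Returns (d0, s0sq); d0 may be ``inf`` when the observed spread of log s2
    does not exceed its pure-sampling component.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 2:
        raise ValueError("need at least two rows with positive residual variance")
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) - special.polygamma(1, df / 2.0)
    if evar > 0:
        d0 = 2.0 * trigamma_inverse(evar)
        s0sq = np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    else:
        d0 = np.inf
        s0sq = float(np.mean(s2[ok]))
    return float(d0), float(s0sq)


def squeeze_variances(s2: np.ndarray, df: float, d0: float, s0sq: float) -> np.ndarray:
    """Posterior (moderated) variances s~2 = (d0 s0^2 + d s2) / (d0 + d)."""
    s2 = np.asarray(s2, dtype=float)
    if np.isinf(d0):
        return np.full_like(s2, s0sq)
    if d0 == 0:
        return s2.copy()
    return (d0 * s0sq + df * s2) / (d0 + df)


@dataclass(frozen=True)
class _Contrast:
    name: str
    matrix: np.ndarray  # q x n_cells
    df: int


def _cell_key(ecotype: str, locality: str) -> str:
    return f"{ecotype}:{locality}"


def _build_contrasts(analysis: str, ecotypes, localities, cells) -> list[_Contrast]:
    idx = {c: i for i, c in enumerate(cells)}
    k = len(cells)

    def vec(pairs) -> np.ndarray:
        v = np.zeros(k)
        for cell, w in pairs:
            if cell not in idx:
                raise ContrastError(f"cell {cell!r} absent from the design")
            v[idx[cell]] = w
        return v

    out: list[_Contrast] = []
    if analysis == "ecotype_within_locality":
        if len(ecotypes) != 2:
            raise ContrastError("ecotype contrasts need both ecotypes present")
        a, b = "crab", "wave"
        for loc in localities:
            v = vec([(_cell_key(a, loc), 1.0), (_cell_key(b, loc), -1.0)])
            out.append(_Contrast(f"ecotype@{loc}", v[None, :], 1))
    elif analysis == "factorial_interaction":
        if len(ecotypes) != 2 or len(localities) < 2:
            raise ContrastError("factorial analysis needs 2 ecotypes and >=2 localities")
        nl = len(localities)
        v = np.zeros(k)
        for loc in localities:
            v += vec([(_cell_key("crab", loc), 1.0 / nl), (_cell_key("wave", loc), -1.0 / nl)])
        out.append(_Contrast("ecotype", v[None, :], 1))
        rows = []
        base = localities[0]
        for loc in localities[1:]:
            r = np.zeros(k)
            for eco in ecotypes:
                r += vec([(_cell_key(eco, loc), 0.5), (_cell_key(eco, base), -0.5)])
            rows.append(r)
        out.append(_Contrast("locality", np.vstack(rows), len(rows)))
        rows = []
        for loc in localities[1:]:
            r = vec(
                [
                    (_cell_key("crab", loc), 1.0),
                    (_cell_key("wave", loc), -1.0),
                    (_cell_key("crab", base), -1.0),
                    (_cell_key("wave", base), 1.0),
                ]
            )
            rows.append(r)
        out.append(_Contrast("interaction", np.vstack(rows), len(rows)))
    elif analysis == "locality_within_ecotype":
        if len(localities) < 2:
            raise ContrastError("locality contrasts need >=2 localities")
        base = localities[0]
        for eco in ecotypes:
            rows = []
            for loc in localities[1:]:
                rows.append(
                    vec([(_cell_key(eco, loc), 1.0), (_cell_key(eco, base), -1.0)])
                )
            out.append(_Contrast(f"locality@{eco}", np.vstack(rows), len(rows)))
    else:
        raise ContrastError(f"unknown analysis {analysis!r}; choose one of {ANALYSES}")
    return out


class ArrayLinearModel:
    """Row-wise OLS on a group-means (ecotype x locality cells) design.

    Parameters
    ----------
    data:
        :class:`IntensityMatrix` (one-channel) or plain DataFrame, features
        in rows and sample ids in columns.
    sample_design:
        Sample sheet covering every data column.
    analysis:
        One of :data:`ANALYSES`.
    """

    def __init__(self, data, sample_design: SampleDesign, analysis: str = "ecotype_within_locality"):
        values = data.values if isinstance(data, IntensityMatrix) else data
        table = sample_design.table.set_index("sample_id")
        missing = [c for c in values.columns if c not in table.index]
        if missing:
            raise ValueError(f"samples not in design: {missing[:5]}")
        meta = table.loc[list(values.columns)]
        self.data = values
        self.sample_design = sample_design
        self.analysis = analysis
        # factor levels in sample-sheet order, so fits are invariant to the
        # column order of the data matrix
        used = table.loc[table.index.isin(values.columns)]
        self.ecotypes = tuple(pd.unique(used["ecotype"]))
        self.localities = tuple(pd.unique(used["locality"]))

        cell_labels = [
            _cell_key(e, l) for e, l in zip(meta["ecotype"], meta["locality"])
        ]
        self.cells = tuple(
            _cell_key(e, l)
            for e in self.ecotypes
            for l in self.localities
            if _cell_key(e, l) in set(cell_labels)
        )
        self.contrasts = _build_contrasts(
            analysis, self.ecotypes, self.localities, self.cells
        )

        cell_idx = {c: i for i, c in enumerate(self.cells)}
        X = np.zeros((len(cell_labels), len(self.cells)))
        for i, c in enumerate(cell_labels):
            X[i, cell_idx[c]] = 1.0
        counts = X.sum(axis=0)
        tested = np.zeros(len(self.cells), dtype=bool)
        for con in self.contrasts:
            tested |= np.abs(con.matrix).sum(axis=0) > 0
        low = [self.cells[i] for i in np.flatnonzero(tested & (counts < 2))]
        if low:
            raise ContrastError(
                f"groups with fewer than 2 replicates enter tested contrasts: {low}"
            )
        self.exog = X
        self.df_residual = X.shape[0] - X.shape[1]
        if self.df_residual <= 0:
            raise ContrastError("no residual degrees of freedom")

    def fit(self, moderate: bool = True) -> "ModeratedArrayResults":
        Y = self.data.to_numpy(float)
        X = self.exog
        xtx_inv = np.diag(1.0 / X.sum(axis=0))  # one-hot design
        beta = Y @ X @ xtx_inv
        resid = Y - beta @ X.T
        d = self.df_residual
        s2 = (resid**2).sum(axis=1) / d
        res = ModeratedArrayResults(
            model=self,
            coef_cells=pd.DataFrame(beta, index=self.data.index, columns=self.cells),
            sigma2=pd.Series(s2, index=self.data.index),
            df_residual=d,
            xtx_inv=xtx_inv,
        )
        if moderate:
            res = res.moderate()
        else:
            res._finalize(d0=0.0, s0sq=float("nan"))
        return res


class ModeratedArrayResults:
    """Per-feature estimates, (moderated) variances and contrast tests."""

    def __init__(self, model, coef_cells, sigma2, df_residual, xtx_inv):
        self.model = model
        self.coef_cells = coef_cells
        self.sigma2 = sigma2
        self.df_residual = df_residual
        self._xtx_inv = xtx_inv
        self.df_prior: float | None = None
        self.var_prior: float | None = None
        self.s2_post: pd.Series | None = None
        self.coef: pd.DataFrame | None = None
        self.tstats: pd.DataFrame | None = None
        self.fstats: pd.DataFrame | None = None
        self.pvalues: pd.DataFrame | None = None

    # -- moderation -------------------------------------------------------
    def moderate(self) -> "ModeratedArrayResults":
        d0, s0sq = estimate_variance_prior(self.sigma2.to_numpy(), self.df_residual)
        self._finalize(d0=d0, s0sq=s0sq)
        return self

    def _finalize(self, d0: float, s0sq: float) -> None:
        self.df_prior = d0
        self.var_prior = s0sq
        s2p = squeeze_variances(self.sigma2.to_numpy(), self.df_residual, d0, s0sq)
        self.s2_post = pd.Series(s2p, index=self.sigma2.index)
        self._test_contrasts()

    @property
    def df_total(self) -> float:
        return self.df_prior + self.df_residual

    def _test_contrasts(self) -> None:
        beta = self.coef_cells.to_numpy()
        s2p = self.s2_post.to_numpy()
        dft = self.df_total
        index = self.coef_cells.index
        coef, tstats, fstats, pvals = {}, {}, {}, {}
        with np.errstate(divide="ignore", invalid="ignore"):
            for con in self.model.contrasts:
                C = con.matrix
                est = beta @ C.T  # n x q
                V = C @ self._xtx_inv @ C.T
                if con.df == 1:
                    u = float(np.sqrt(V[0, 0]))
                    t = est[:, 0] / (u * np.sqrt(s2p))
                    t = np.where(est[:, 0] == 0, 0.0, t)
                    coef[con.name] = est[:, 0]
                    tstats[con.name] = t
                    if np.isinf(dft):
                        p = 2.0 * stats.norm.sf(np.abs(t))
                    else:
                        p = 2.0 * stats.t.sf(np.abs(t), dft)
                    pvals[con.name] = p
                else:
                    W = np.linalg.inv(V)
                    quad = np.einsum("nq,qr,nr->n", est, W, est)
                    F = quad / con.df / s2p
                    F = np.where(quad == 0, 0.0, F)
                    fstats[con.name] = F
                    if np.isinf(dft):
                        p = stats.chi2.sf(con.df * F, con.df)
                    else:
                        p = stats.f.sf(F, con.df, dft)
                    pvals[con.name] = p
        self.coef = pd.DataFrame(coef, index=index)
        self.tstats = pd.DataFrame(tstats, index=index)
        self.fstats = pd.DataFrame(fstats, index=index)
        self.pvalues = pd.DataFrame(
            {c.name: pvals[c.name] for c in self.model.contrasts}, index=index
        )

    # -- convenience ------------------------------------------------------
    def effect_table(self) -> pd.DataFrame:
        """Signed single-df contrast estimates (features x contrasts)."""
        if self.coef is None or self.coef.empty:
            raise ContrastError("analysis has no single-df contrasts")
        return self.coef.copy()

    def summary(self) -> str:
        n = len(self.sigma2)
        lines = [
            "Moderated array linear model",
            f"  analysis:        {self.model.analysis}",
            f"  features:        {n}",
            f"  samples:         {self.model.exog.shape[0]}",
            f"  cells:           {len(self.model.cells)}",
            f"  residual df:     {self.df_residual}",
            f"  prior df (d0):   {self.df_prior:.4g}",
            f"  prior var (s0^2):{self.var_prior:.4g}",
        ]
        lines.append("  contrasts:")
        for con in self.model.contrasts:
            p = self.pvalues[con.name]
            lines.append(
                f"    {con.name:<22s} df={con.df}  median p={np.median(p):.3g}  "
                f"#p<=0.05: {(p <= 0.05).sum()}"
            )
        return "\n".join(lines)

    def diagnostics(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sigma2": self.sigma2,
                "s2_post": self.s2_post,
                "df_residual": self.df_residual,
                "df_prior": self.df_prior,
                "var_prior": self.var_prior,
            }
        )


# -- functional wrappers matching the pipeline's stage vocabulary ----------

def fit_row_models(matrix, sample_design, analysis: str) -> ModeratedArrayResults:
    """OLS fits without moderation (d0 = 0)."""
    return ArrayLinearModel(matrix, sample_design, analysis).fit(moderate=False)


def moderate_variances(fit: ModeratedArrayResults) -> ModeratedArrayResults:
    """Apply the empirical-Bayes variance shrinkage to an existing fit."""
    return fit.moderate()


def contrast_pvalues(fit: ModeratedArrayResults) -> pd.DataFrame:
    """The per-contrast p-value table of a fit."""
    return fit.pvalues.copy()
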