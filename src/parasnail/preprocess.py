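"""Background thresholds, filters, normalization and gene summarization.

Expression (one-channel) path: quantile normalization across arrays, a
background threshold estimated from the array's empty spots, the
"more than 20% of probes below background" gene filter, and median-polish
summarization of each probe set to one value per gene and sample (the RMA
summarization step).

CGH (two-channel) path: normexp background correction with an offset on the
linear scale, log2 transform, two-channel quantile normalization (both
channels of all arrays pooled), per-channel background filtering of probes,
and M-value computation against the common reference channel.  The joint
filter finally intersects the two assays' kept sets so only genes measured
reliably in both are analyzed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .design import ArrayDesign, DesignError, IntensityMatrix, strip_channel


class ConfigurationError(ValueError):
    """User-facing configuration problem with an actionable message."""


class PipelineError(RuntimeError):
    """A pipeline stage failed in a way that invalidates downstream stages."""


@dataclass
class FilterReport:
    """Outcome of a background filter: thresholds used and what survived."""

    thresholds: dict[str, float]
    kept_genes: set[str] = field(default_factory=set)
    kept_probes: set[str] = field(default_factory=set)
    frac_below: pd.Series | None = None  # per gene (expression) or per probe flag

    def summary(self) -> str:
        lines = [f"threshold[{ch}] = {t:.4f}" for ch, t in self.thresholds.items()]
        lines.append(f"kept genes:  {len(self.kept_genes)}")
        lines.append(f"kept probes: {len(self.kept_probes)}")
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        rows = [("gene", g) for g in sorted(self.kept_genes)]
        rows += [("probe", p) for p in sorted(self.kept_probes)]
        pd.DataFrame(rows, columns=["level", "feature_id"]).to_csv(path, sep="\t", index=False)


def background_threshold(
    matrix: IntensityMatrix,
    design: ArrayDesign,
    channel: str = "single",
    override: float | None = None,
) -> float:
    """Mean log2 intensity of the empty spots for one channel.

    ``override`` short-circuits the estimate (for externally supplied
    thresholds such as a platform-specific background constant).
    """
    if override is not None:
        return float(override)
    empties = design.empty_probe_ids
    if len(empties) == 0:
        raise ConfigurationError(
            "array design has no empty spots; supply a background threshold manually"
        )
    if matrix.scale != "log2":
        raise ValueError("background_threshold expects a log2-scale matrix")
    if channel == "single":
        cols = list(matrix.values.columns)
    else:
        cols = matrix.channel_columns(channel)
    block = matrix.values.loc[matrix.values.index.intersection(empties), cols]
    if block.empty:
        raise ConfigurationError("no empty-spot rows present in the intensity matrix")
    return float(block.to_numpy().mean())


def filter_expression_genes(
    matrix: IntensityMatrix,
    design: ArrayDesign,
    threshold: float,
    max_frac_below: float = 0.20,
) -> FilterReport:
    """Drop genes with more than ``max_frac_below`` of probes below background.

    A probe is "below" when its mean log2 signal across all samples is below
    the threshold; the gene is dropped iff the below-fraction strictly
    exceeds ``max_frac_below`` (a gene at exactly the boundary is kept).
    """
    if matrix.channels != "single" or matrix.scale != "log2":
        raise ValueError("expression filter expects a one-channel log2 matrix")
    gp = design.gene_probe_table
    gp = gp.loc[gp["probe_id"].isin(matrix.values.index)]
    if gp.empty:
        raise DesignError("array design contains no gene probes present in the matrix")
    probe_means = matrix.values.loc[gp["probe_id"]].mean(axis=1)
    below = probe_means < threshold
    per_gene = below.groupby(gp["gene_id"].to_numpy()).mean()
    counts = gp.groupby("gene_id").size()
    if (counts < 1).any():
        raise DesignError("gene with zero probes in design")
    kept = set(per_gene.index[per_gene <= max_frac_below])
    kept_probes = set(gp.loc[gp["gene_id"].isin(kept), "probe_id"])
    return FilterReport(
        thresholds={"single": float(threshold)},
        kept_genes=kept,
        kept_probes=kept_probes,
        frac_below=per_gene,
    )


def _normexp_conditional_mean(x: np.ndarray, mu: float, sigma: float, theta: float) -> np.ndarray:
    """E[S | X = x] for X = S + B, S ~ Exp(theta), B ~ N(mu, sigma^2)."""
    a = x - mu - sigma**2 / theta
    z = a / sigma
    # log-scale Mills ratio for numerical stability at very negative z
    mills = np.exp(stats.norm.logpdf(z) - stats.norm.logcdf(z))
    return a + sigma * mills


def normexp_correct(
    matrix: IntensityMatrix,
    design: ArrayDesign,
    offset: float = 16.0,
) -> IntensityMatrix:
    """Normexp + offset background correction on linear-scale intensities.

    The background normal parameters (mu, sigma) are estimated per channel
    from the empty-spot intensities; the signal exponential mean theta from
    the excess of the gene-probe mean over mu.  Every intensity is replaced
    by the posterior mean of the true signal, which is strictly positive,
    and the offset is added.
    """
    if matrix.scale != "linear":
        raise ValueError("normexp_correct expects linear-scale intensities")
    if offset < 0:
        raise ValueError("offset must be >= 0")
    empties = design.empty_probe_ids
    if len(empties) == 0:
        raise ConfigurationError(
            "normexp background estimation needs empty spots; none present in design"
        )
    values = matrix.values.copy()
    gene_probes = design.gene_probe_table["probe_id"]

    if matrix.channels == "two":
        channel_groups = {
            "cy3": matrix.channel_columns("cy3"),
            "cy5": matrix.channel_columns("cy5"),
        }
    else:
        channel_groups = {"single": list(values.columns)}

    eps = 1e-8
    for cols in channel_groups.values():
        bg = values.loc[values.index.intersection(empties), cols].to_numpy().ravel()
        mu = float(bg.mean())
        sigma = float(bg.std(ddof=1)) if bg.size > 1 else 0.0
        x = values.loc[:, cols].to_numpy(float)
        if sigma <= 0:
            warnings.warn(
                "non-positive background sd estimate; falling back to subtract-and-floor",
                RuntimeWarning,
                stacklevel=2,
            )
            corrected = np.maximum(x - mu, eps)
        else:
            theta = max(float(values.loc[gene_probes, cols].to_numpy().mean()) - mu, eps)
            corrected = _normexp_conditional_mean(x, mu, sigma, theta)
            corrected = np.maximum(corrected, eps)
        values.loc[:, cols] = corrected + offset

    return matrix.copy_with(values, scale="linear")


def log2_transform(matrix: IntensityMatrix) -> IntensityMatrix:
    if matrix.scale != "linear":
        raise ValueError("matrix is already on the log2 scale")
    vals = matrix.values.to_numpy(float)
    if (vals <= 0).any():
        raise ValueError(
            "non-positive linear intensities; background-correct with an offset first"
        )
    return matrix.copy_with(np.log2(matrix.values), scale="log2")


def quantile_normalize(matrix: IntensityMatrix, mode: str = "single") -> IntensityMatrix:
    """Force all columns to share the mean quantile distribution.

    ``mode="single"`` treats each column as one array; ``mode="two_channel"``
    pools both channels of all arrays as columns and normalizes them jointly
    (the two-color variant).  Operationally both normalize every column of
    the matrix; the mode documents (and checks) the expected layout.  Ties
    receive the mean of their tied quantile values.
    """
    if mode not in ("single", "two_channel"):
        raise ValueError("mode must be 'single' or 'two_channel'")
    if mode == "two_channel" and matrix.channels != "two":
        raise ValueError("two_channel mode requires a two-channel matrix")
    X = matrix.values.to_numpy(float)
    n, m = X.shape
    if m < 2:
        warnings.warn("single column: quantile normalization is the identity", RuntimeWarning)
        return matrix.copy_with(matrix.values.copy())
    ref = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X)
    grid = np.arange(n, dtype=float)
    for j in range(m):
        r = stats.rankdata(X[:, j], method="average") - 1.0
        out[:, j] = np.interp(r, grid, ref)
    values = pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns)
    return matrix.copy_with(values)


def median_polish(block: np.ndarray, tol: float = 1e-4, max_iter: int = 10):
    """Tukey median polish on a stack of probe x sample blocks.

    ``block`` has shape (..., P, S).  Returns (overall, row_effects,
    col_effects, residuals); the summarized per-sample value is
    ``overall + col_effects``.  Sweeps start with rows and stop when the
    largest absolute adjustment falls below ``tol``.
    """
    resid = np.asarray(block, dtype=float).copy()
    *lead, P, S = resid.shape
    overall = np.zeros(lead)
    row = np.zeros((*lead, P))
    col = np.zeros((*lead, S))
    for _ in range(max_iter):
        rdelta = np.median(resid, axis=-1)
        resid -= rdelta[..., :, None]
        row += rdelta
        cmed = np.median(col, axis=-1)
        col -= cmed[..., None]
        overall += cmed

        cdelta = np.median(resid, axis=-2)
        resid -= cdelta[..., None, :]
        col += cdelta
        rmed = np.median(row, axis=-1)
        row -= rmed[..., None]
        overall += rmed

        change = max(np.abs(rdelta).max(), np.abs(cdelta).max())
        if change < tol:
            break
    return overall, row, col, resid


def summarize_genes(matrix: IntensityMatrix, design: ArrayDesign) -> IntensityMatrix:
    """Collapse each gene's probe block to one log2 value per sample.

    Median polish is applied to the probes x samples block; the summarized
    value is the overall effect plus the sample (column) effect.  Genes with
    a single probe pass through unchanged.
    """
    if matrix.scale != "log2" or matrix.channels != "single":
        raise ValueError("summarize_genes expects a one-channel log2 matrix")
    gp = design.gene_probe_table
    gp = gp.loc[gp["probe_id"].isin(matrix.values.index)]
    if gp.empty:
        raise DesignError("no gene probes present in matrix")
    cols = matrix.values.columns
    results: dict[str, np.ndarray] = {}

    # vectorize across genes sharing a probe count
    counts = gp.groupby("gene_id").size()
    for n_probes, genes in counts.groupby(counts).groups.items():
        genes = list(genes)
        sub = gp.loc[gp["gene_id"].isin(genes)].sort_values(["gene_id", "probe_index"])
        block = (
            matrix.values.loc[sub["probe_id"]]
            .to_numpy(float)
            .reshape(len(genes), n_probes, len(cols))
        )
        order = sorted(genes)
        if n_probes == 1:
            for g, rowvals in zip(order, block[:, 0, :]):
                results[g] = rowvals
            continue
        overall, _, col_eff, _ = median_polish(block)
        summarized = overall[:, None] + col_eff
        for g, rowvals in zip(order, summarized):
            results[g] = rowvals

    values = pd.DataFrame.from_dict(results, orient="index", columns=cols)
    values = values.sort_index()
    values.index.name = "gene_id"
    return IntensityMatrix(values, scale="log2", channels="single", level="gene")


def filter_cgh_probes(
    matrix: IntensityMatrix,
    design: ArrayDesign,
    thresholds: dict[str, float],
) -> FilterReport:
    """Keep probes whose mean log2 signal clears background in BOTH channels."""
    if matrix.channels != "two" or matrix.scale != "log2":
        raise ValueError("CGH filter expects a two-channel log2 matrix")
    for ch in ("cy3", "cy5"):
        if ch not in thresholds:
            raise DesignError(f"missing threshold for channel {ch}")
    gp = design.gene_probe_table
    gp = gp.loc[gp["probe_id"].isin(matrix.values.index)]
    keep = pd.Series(True, index=gp["probe_id"].to_numpy())
    for ch in ("cy3", "cy5"):
        cols = matrix.channel_columns(ch)
        means = matrix.values.loc[keep.index, cols].mean(axis=1)
        keep &= means >= thresholds[ch]
    kept_probes = set(keep.index[keep])
    kept_genes = set(design.genes_of(kept_probes))
    return FilterReport(
        thresholds={k: float(v) for k, v in thresholds.items()},
        kept_genes=kept_genes,
        kept_probes=kept_probes,
    )


def compute_log_ratios(matrix: IntensityMatrix) -> IntensityMatrix:
    """M-values: log2(sample channel) - log2(reference channel), per individual."""
    if matrix.channels != "two":
        raise ValueError("log ratios require a two-channel matrix")
    if matrix.scale == "linear":
        matrix = log2_transform(matrix)
    cy3 = matrix.channel_columns("cy3")
    samples = [strip_channel(c)[0] for c in cy3]
    m = {}
    for sid, c3 in zip(samples, cy3):
        c5 = f"{sid}__cy5"
        if c5 not in matrix.values.columns:
            raise DesignError(f"sample {sid} lacks a reference channel column")
        m[sid] = matrix.values[c3] - matrix.values[c5]
    values = pd.DataFrame(m, index=matrix.values.index)
    return IntensityMatrix(values, scale="log2", channels="single", level="probe")


@dataclass(frozen=True)
class AnalysisSets:
    """Features surviving the joint expression + CGH filter."""

    genes: tuple[str, ...]
    probes: tuple[str, ...]


def intersect_filters(
    expr_report: FilterReport, cgh_report: FilterReport, design: ArrayDesign
) -> AnalysisSets:
    """Genes kept by expression whose CGH-kept probe set is nonempty.

    The retained probe set is the CGH-kept probes of those retained genes, so
    both assays analyze exactly the jointly reliable portion of the array.
    """
    cgh_genes_with_probe = set(design.genes_of(cgh_report.kept_probes))
    genes = expr_report.kept_genes & cgh_genes_with_probe
    if not genes:
        raise PipelineError(
            "joint filter removed every gene "
            f"(expression kept {len(expr_report.kept_genes)}, "
            f"CGH kept probes for {len(cgh_genes_with_probe)} genes)"
        )
    gp = design.gene_probe_table
    probes = [
        p
        for p in gp.loc[gp["gene_id"].isin(genes), "probe_id"]
        if p in cgh_report.kept_probes
    ]
    return AnalysisSets(genes=tuple(sorted(genes)), probes=tuple(probes))
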