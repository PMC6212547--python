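"""End-to-end orchestration: simulate/load -> preprocess -> model -> tests.

`run_pipeline` executes the full analysis chain on one dataset and returns a
:class:`PipelineResult` carrying every stage's output, while writing TSV
artifacts and a log to the output directory.  Reruns with the same
configuration are bit-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import preprocess as pp
from .design import ArrayDesign, IntensityMatrix, SampleDesign
from .direction import (
    DirectionResult,
    VarianceComparison,
    classify_directions,
    compare_variances,
    direction_randomization,
    intrapopulation_variance,
)
from .geography import GeographyResult, locality_differentiation, parallel_enrichment_resample
from .linmod import ArrayLinearModel, ModeratedArrayResults
from .multitest import sgof
from .parallelism import ParallelResult, derome3_null, intersect_significant, permutation_parallel
from .report import SummaryReport, fraction_percent
from .simulate import SimulationConfig, SyntheticDataset, simulate_dataset

logger = logging.getLogger("parasnail")


@dataclass
class PipelineConfig:
    """Everything `run_pipeline` needs; YAML/JSON round-trippable."""

    outdir: str = "parasnail_out"
    seed: int = 0
    alpha: float = 0.05
    gamma: float = 0.05
    R_parallel: int = 10_000
    R_direction: int = 10_000
    B_geography: int = 1000
    max_probe_fraction_below: float = 0.20
    threshold_cgh: float | None = None  # e.g. 10.7 to override the empty-spot estimate
    normexp_offset: float = 16.0
    parallel_mode: str = "gene_shuffle"
    nonparallel_definition: str = "some_but_not_all"  # or "complement"
    sgof_pooled: bool = False  # pool the three locality contrasts into one SGoF run
    # either simulate...
    simulate: dict | None = None
    # ...or load TSVs
    expression_path: str | None = None
    cgh_path: str | None = None
    design_path: str | None = None
    samples_path: str | None = None

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1) or not (0 < self.gamma < 1):
            raise ValueError("alpha and gamma must lie in (0, 1)")
        for name in ("R_parallel", "R_direction", "B_geography"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        path = Path(path)
        with open(path) as fh:
            raw = json.load(fh) if path.suffix == ".json" else yaml.safe_load(fh)
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class PipelineResult:
    config: PipelineConfig
    dataset: SyntheticDataset | None
    analysis_genes: tuple[str, ...]
    analysis_probes: tuple[str, ...]
    expression_fit: ModeratedArrayResults
    cgh_fit: ModeratedArrayResults
    expr_sig_sets: dict
    cgh_probe_sig_sets: dict
    cgh_gene_sig_sets: dict
    parallel_expression: ParallelResult
    parallel_cgh_probes: ParallelResult
    parallel_cgh_genes: tuple[str, ...]
    derome_expression: dict
    derome_cgh: dict
    direction_expression: DirectionResult | None
    direction_cgh: DirectionResult | None
    variance_expression: VarianceComparison | None
    variance_cgh: VarianceComparison | None
    geography: dict
    report: SummaryReport
    expression_genes_matrix: pd.DataFrame = None
    cgh_m_matrix: pd.DataFrame = None


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                logger.info("stage %s", name)
                return fn(*args, **kwargs)
            except pp.PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - annotate and re-raise
                raise pp.PipelineError(f"stage {name!r} failed: {exc}") from exc

        return wrapper

    return deco


@_stage("load")
def _load_inputs(config: PipelineConfig):
    if config.simulate is not None:
        sim_cfg = SimulationConfig(**{**config.simulate, "seed": config.seed})
        ds = simulate_dataset(sim_cfg)
        return ds, ds.design, ds.sample_design, ds.expression, ds.cgh
    for name in ("expression_path", "cgh_path", "design_path", "samples_path"):
        p = getattr(config, name)
        if p is None or not Path(p).exists():
            raise FileNotFoundError(f"input {name} missing or not found: {p}")
    design = ArrayDesign.from_tsv(config.design_path)
    samples = SampleDesign.from_tsv(config.samples_path)
    expr = IntensityMatrix.from_tsv(config.expression_path, scale="log2", channels="single")
    cgh = IntensityMatrix.from_tsv(config.cgh_path, scale="log2", channels="two")
    return None, design, samples, expr, cgh


@_stage("preprocess_expression")
def _preprocess_expression(expr, design, config):
    if expr.scale == "linear":
        expr = pp.normexp_correct(expr, design, offset=config.normexp_offset)
        expr = pp.log2_transform(expr)
    expr_n = pp.quantile_normalize(expr, mode="single")
    thr = pp.background_threshold(expr_n, design, "single")
    report = pp.filter_expression_genes(
        expr_n, design, thr, max_frac_below=config.max_probe_fraction_below
    )
    kept = expr_n.copy_with(
        expr_n.values.loc[expr_n.values.index.isin(report.kept_probes)]
    )
    genes = pp.summarize_genes(kept, design)
    return expr_n, report, genes


@_stage("preprocess_cgh")
def _preprocess_cgh(cgh, design, config):
    if cgh.scale == "linear":
        cgh = pp.normexp_correct(cgh, design, offset=config.normexp_offset)
        cgh = pp.log2_transform(cgh)
    cgh_n = pp.quantile_normalize(cgh, mode="two_channel")
    thresholds = {
        ch: pp.background_threshold(cgh_n, design, ch, override=config.threshold_cgh)
        for ch in ("cy3", "cy5")
    }
    report = pp.filter_cgh_probes(cgh_n, design, thresholds)
    m = pp.compute_log_ratios(cgh_n)
    return cgh_n, report, m


def _significant_sets(fit: ModeratedArrayResults, alpha, gamma, pooled: bool = False) -> dict:
    locs = [col.split("@", 1)[1] for col in fit.pvalues.columns]
    if not pooled:
        return {
            loc: sgof(fit.pvalues[col], alpha=alpha, gamma=gamma).declared_set
            for loc, col in zip(locs, fit.pvalues.columns)
        }
    # pooled variant: one SGoF over all contrasts, declared ids split by locality
    stacked = pd.concat(
        {loc: fit.pvalues[col] for loc, col in zip(locs, fit.pvalues.columns)}
    )
    res = sgof(stacked, alpha=alpha, gamma=gamma, ids=list(stacked.index))
    sets: dict = {loc: set() for loc in locs}
    for loc, fid in res.declared:
        sets[loc].add(fid)
    return sets


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute every stage in order; see the module docstring."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "pipeline.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        return _run(config, outdir)
    finally:
        logger.removeHandler(handler)
        handler.close()


def _run(config: PipelineConfig, outdir: Path) -> PipelineResult:
    logger.info("seed=%s alpha=%s gamma=%s", config.seed, config.alpha, config.gamma)
    dataset, design, samples, expr_raw, cgh_raw = _load_inputs(config)
    expr_samples = samples.subset(assay="expression")
    cgh_samples = samples.subset(assay="cgh")

    expr_norm, expr_report, gene_matrix = _preprocess_expression(expr_raw, design, config)
    cgh_norm, cgh_report, m_matrix = _preprocess_cgh(cgh_raw, design, config)
    sets = pp.intersect_filters(expr_report, cgh_report, design)
    logger.info(
        "joint filter: %d genes, %d probes retained", len(sets.genes), len(sets.probes)
    )

    gene_values = gene_matrix.values.loc[list(sets.genes)]
    m_values = m_matrix.values.loc[list(sets.probes)]

    expr_fit = ArrayLinearModel(
        gene_values, expr_samples, analysis="ecotype_within_locality"
    ).fit()
    cgh_fit = ArrayLinearModel(
        m_values, cgh_samples, analysis="ecotype_within_locality"
    ).fit()

    expr_sig = _significant_sets(expr_fit, config.alpha, config.gamma, config.sgof_pooled)
    cgh_probe_sig = _significant_sets(cgh_fit, config.alpha, config.gamma, config.sgof_pooled)
    cgh_gene_sig = {loc: set(design.genes_of(s)) for loc, s in cgh_probe_sig.items()}
    for loc in expr_sig:
        logger.info(
            "significant @%s: %d genes (expr), %d probes (CGH)",
            loc,
            len(expr_sig[loc]),
            len(cgh_probe_sig[loc]),
        )

    # parallelism
    par_expr = intersect_significant(expr_sig, sets.genes)
    par_cgh_probes = intersect_significant(cgh_probe_sig, sets.probes)
    par_cgh_genes = tuple(sorted(design.genes_of(par_cgh_probes.intersection)))
    seed_seq = np.random.SeedSequence(config.seed)
    s_par_e, s_par_c, s_dir_e, s_dir_c, s_var_e, s_var_c, s_geo = [
        int(s.generate_state(1)[0] % (2**31)) for s in seed_seq.spawn(7)
    ]
    derome_e = derome3_null(
        par_expr.universe_size, *par_expr.set_sizes, k=par_expr.k
    )
    derome_c = derome3_null(
        par_cgh_probes.universe_size, *par_cgh_probes.set_sizes, k=par_cgh_probes.k
    )
    refit_e = {"matrix": gene_values, "sample_design": expr_samples,
               "alpha": config.alpha, "gamma": config.gamma}
    refit_c = {"matrix": m_values, "sample_design": cgh_samples,
               "alpha": config.alpha, "gamma": config.gamma}
    par_expr = permutation_parallel(
        expr_sig, sets.genes, R=config.R_parallel, seed=s_par_e,
        mode=config.parallel_mode, refit=refit_e,
    )
    par_cgh_probes = permutation_parallel(
        cgh_probe_sig, sets.probes, R=config.R_parallel, seed=s_par_c,
        mode=config.parallel_mode, refit=refit_c,
    )
    par_expr = dataclasses.replace(par_expr, exact_p=derome_e["p_value"])
    par_cgh_probes = dataclasses.replace(par_cgh_probes, exact_p=derome_c["p_value"])

    # directionality
    def _effects(fit):
        eff = fit.effect_table()
        eff.columns = [c.split("@", 1)[1] for c in eff.columns]
        return eff

    dir_expr = dir_cgh = None
    if len(par_expr.intersection) >= 2:
        dir_expr = direction_randomization(
            _effects(expr_fit), par_expr.intersection, R=config.R_direction, seed=s_dir_e
        )
    if len(par_cgh_probes.intersection) >= 2:
        dir_cgh = direction_randomization(
            _effects(cgh_fit), par_cgh_probes.intersection, R=config.R_direction, seed=s_dir_c
        )

    # intrapopulation variance, D vs ND
    var_expr = var_cgh = None
    if dir_expr is not None and dir_expr.classes.nunique() == 2:
        v = intrapopulation_variance(gene_values, expr_samples, par_expr.intersection)
        var_expr = compare_variances(v, dir_expr.classes, R=config.R_direction, seed=s_var_e)
    if dir_cgh is not None and dir_cgh.classes.nunique() == 2:
        v = intrapopulation_variance(m_values, cgh_samples, par_cgh_probes.intersection)
        var_cgh = compare_variances(v, dir_cgh.classes, R=config.R_direction, seed=s_var_c)

    # geography
    geography: dict[tuple[str, str, str], GeographyResult] = {}
    geo_rng = np.random.default_rng(s_geo)
    for assay, values, samp, par_res, universe in (
        ("expression", gene_values, expr_samples, par_expr, sets.genes),
        ("cgh", m_values, cgh_samples, par_cgh_probes, sets.probes),
    ):
        parallel = set(par_res.intersection)
        if not parallel:
            continue
        sig_by_loc = expr_sig if assay == "expression" else cgh_probe_sig
        in_any = set().union(*sig_by_loc.values())
        if config.nonparallel_definition == "some_but_not_all":
            nonparallel = in_any - parallel
        else:
            nonparallel = set(universe) - parallel
        for ecotype in ("crab", "wave"):
            geo_sig = locality_differentiation(
                values, samp, ecotype, alpha=config.alpha, gamma=config.gamma
            )
            for name, fset in (("parallel", parallel), ("nonparallel", nonparallel)):
                if not fset:
                    continue
                seed_b = int(geo_rng.integers(2**31))
                geography[(assay, ecotype, name)] = parallel_enrichment_resample(
                    geo_sig, fset, universe, B=config.B_geography, seed=seed_b,
                    set_name=name,
                )

    report = _build_report(
        design, sets, expr_sig, cgh_gene_sig, par_expr, par_cgh_probes,
        par_cgh_genes, dir_expr, dir_cgh, var_expr, var_cgh, geography,
    )

    result = PipelineResult(
        config=config,
        dataset=dataset,
        analysis_genes=sets.genes,
        analysis_probes=sets.probes,
        expression_fit=expr_fit,
        cgh_fit=cgh_fit,
        expr_sig_sets=expr_sig,
        cgh_probe_sig_sets=cgh_probe_sig,
        cgh_gene_sig_sets=cgh_gene_sig,
        parallel_expression=par_expr,
        parallel_cgh_probes=par_cgh_probes,
        parallel_cgh_genes=par_cgh_genes,
        derome_expression=derome_e,
        derome_cgh=derome_c,
        direction_expression=dir_expr,
        direction_cgh=dir_cgh,
        variance_expression=var_expr,
        variance_cgh=var_cgh,
        geography=geography,
        report=report,
        expression_genes_matrix=gene_values,
        cgh_m_matrix=m_values,
    )
    _write_artifacts(result, outdir)
    return result


def _build_report(
    design, sets, expr_sig, cgh_gene_sig, par_expr, par_cgh, par_cgh_genes,
    dir_expr, dir_cgh, var_expr, var_cgh, geography,
) -> SummaryReport:
    universe = len(sets.genes)
    rows = {}
    for loc in expr_sig:
        e = expr_sig[loc]
        c = cgh_gene_sig.get(loc, set())
        rows[loc] = {
            "expression": len(e),
            "cgh": len(c),
            "both": len(e & c),
        }
    per_locality = pd.DataFrame.from_dict(rows, orient="index")
    parallel_expr_genes = set(par_expr.intersection)
    both = parallel_expr_genes & set(par_cgh_genes)
    extras = {}
    if var_expr is not None:
        extras["variance_ratio_expression(ND/D)"] = round(var_expr.ratio, 3)
        extras["variance_t_p_expression"] = round(var_expr.t_pvalue, 6)
    if var_cgh is not None:
        extras["variance_ratio_cgh(ND/D)"] = round(var_cgh.ratio, 3)
        extras["variance_t_p_cgh"] = round(var_cgh.t_pvalue, 6)
    for key, res in geography.items():
        extras[f"geo_frac[{','.join(key)}]"] = round(res.observed_fraction, 4)
    return SummaryReport(
        universe=universe,
        per_locality=per_locality,
        parallel_expression=par_expr.k,
        parallel_cgh_genes=len(par_cgh_genes),
        parallel_cgh_probes=par_cgh.k,
        parallel_both=len(both),
        directional_expression=(
            (dir_expr.n_directional, len(dir_expr.classes)) if dir_expr else (0, 0)
        ),
        directional_cgh=((dir_cgh.n_directional, len(dir_cgh.classes)) if dir_cgh else (0, 0)),
        extras=extras,
    )


def _write_artifacts(result: PipelineResult, outdir: Path) -> None:
    cfg = result.config
    (outdir / "config.json").write_text(json.dumps(cfg.to_dict(), indent=2, default=str))
    if result.dataset is not None:
        result.dataset.write(outdir / "synthetic")
    result.expression_fit.pvalues.to_csv(outdir / "expression_pvalues.tsv", sep="\t")
    result.cgh_fit.pvalues.to_csv(outdir / "cgh_pvalues.tsv", sep="\t")
    result.expression_fit.diagnostics().to_csv(outdir / "expression_fit_diag.tsv", sep="\t")
    result.cgh_fit.diagnostics().to_csv(outdir / "cgh_fit_diag.tsv", sep="\t")
    for loc, s in result.expr_sig_sets.items():
        pd.Series(sorted(s), name="gene_id").to_csv(
            outdir / f"sig_expression_{loc}.tsv", sep="\t", index=False
        )
    for loc, s in result.cgh_probe_sig_sets.items():
        pd.Series(sorted(s), name="probe_id").to_csv(
            outdir / f"sig_cgh_probes_{loc}.tsv", sep="\t", index=False
        )
    pd.Series(result.parallel_expression.intersection, name="gene_id").to_csv(
        outdir / "parallel_expression_genes.tsv", sep="\t", index=False
    )
    pd.Series(result.parallel_cgh_probes.intersection, name="probe_id").to_csv(
        outdir / "parallel_cgh_probes.tsv", sep="\t", index=False
    )
    pd.Series(result.parallel_cgh_genes, name="gene_id").to_csv(
        outdir / "parallel_cgh_genes.tsv", sep="\t", index=False
    )
    pd.concat(
        [
            result.parallel_expression.to_frame().assign(assay="expression"),
            result.parallel_cgh_probes.to_frame().assign(assay="cgh_probes"),
        ]
    ).to_csv(outdir / "parallelism.tsv", sep="\t", index=False)
    for name, d in (("expression", result.direction_expression), ("cgh", result.direction_cgh)):
        if d is None:
            continue
        d.signs.to_csv(outdir / f"sign_matrix_{name}.tsv", sep="\t")
        pd.DataFrame(
            {
                "n_directional": [d.n_directional],
                "n_nondirectional": [d.n_nondirectional],
                "expected_directional": [d.expected_directional],
                "ci_low": [d.ci_directional[0] if d.ci_directional else None],
                "ci_high": [d.ci_directional[1] if d.ci_directional else None],
                "p": [d.p_value],
                "R": [d.n_permutations],
                "seed": [d.seed],
            }
        ).to_csv(outdir / f"direction_{name}.tsv", sep="\t", index=False)
    geo_rows = []
    for (assay, eco, name), res in result.geography.items():
        geo_rows.append(
            {
                "assay": assay,
                "ecotype": eco,
                "set": name,
                "size": res.set_size,
                "observed_fraction": res.observed_fraction,
                "null_mean": res.null_mean,
                "ci_low": res.null_ci[0],
                "ci_high": res.null_ci[1],
                "p": res.p_value,
                "B": res.n_resamples,
            }
        )
    if geo_rows:
        pd.DataFrame(geo_rows).to_csv(outdir / "geography.tsv", sep="\t", index=False)
    (outdir / "summary.txt").write_text(result.report.to_text() + "\n")


def summarize_counts(counts: dict, universe: int) -> SummaryReport:
    """Build a report directly from per-locality and parallel counts.

    ``counts`` maps locality -> {"expression": int, "cgh": int, "both": int}
    plus the special keys ``parallel_expression``, ``parallel_cgh_genes``,
    ``parallel_cgh_probes``, ``parallel_both``, ``directional_expression``,
    ``directional_cgh`` (the last two as (D, total) pairs).
    """
    special = {
        "parallel_expression",
        "parallel_cgh_genes",
        "parallel_cgh_probes",
        "parallel_both",
        "directional_expression",
        "directional_cgh",
    }
    rows = {k: v for k, v in counts.items() if k not in special}
    per_locality = pd.DataFrame.from_dict(rows, orient="index")
    for col in ("expression", "cgh", "both"):
        if (per_locality[col] > universe).any():
            raise ValueError(f"{col} count exceeds universe")
    return SummaryReport(
        universe=universe,
        per_locality=per_locality,
        parallel_expression=counts.get("parallel_expression", 0),
        parallel_cgh_genes=counts.get("parallel_cgh_genes", 0),
        parallel_cgh_probes=counts.get("parallel_cgh_probes", 0),
        parallel_both=counts.get("parallel_both", 0),
        directional_expression=counts.get("directional_expression", (0, 0)),
        directional_cgh=counts.get("directional_cgh", (0, 0)),
    )
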