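"""Synthetic probe-level data with the replicate ecotype-pair structure.

The generator emulates the study design the pipeline targets: three
localities, each hosting a sympatric "crab"/"wave" ecotype pair; gene
expression measured on four pooled samples per ecotype and locality
(one-channel), and coding-sequence divergence measured by CGH on twelve
individuals per ecotype and locality, each hybridized against a common
reference (two-channel).  Genes receive known injected ecotype effects so
every downstream stage has a recoverable ground truth.

Effect taxonomy
---------------
``null``
    no ecotype difference anywhere.
``parallel_directional``
    ecotype difference of the same sign in all three localities.
``parallel_nondirectional``
    ecotype difference in all three localities, signs not all equal.
``locality_specific``
    ecotype difference in exactly one locality.

All effects are injected on the log2 scale, the scale on which the pipeline
operates.  Per-gene within-group variances are drawn from the scaled
inverse chi-square prior the moderated-variance model assumes,
``sigma^2 ~ s0^2 * d0 / chi2(d0)``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .design import (
    DEFAULT_LOCALITIES,
    ECOTYPES,
    EMPTY,
    ArrayDesign,
    DesignError,
    IntensityMatrix,
    SampleDesign,
    two_channel_columns,
)

EXPR_CLASSES = ("parallel_directional", "parallel_nondirectional", "locality_specific")

# fixed per-operation stream keys so each stage has its own reproducible RNG
_K_DESIGN, _K_SAMPLES, _K_TRUTH, _K_EXPR, _K_CGH = 11, 13, 17, 19, 23


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic dataset.

    ``effect_size`` is interpreted according to ``effect_scale``: ``"sd"``
    means multiples of the gene's own within-group standard deviation
    (effects scale with noise, so per-gene power is homogeneous), ``"log2"``
    means absolute log2 units.
    """

    n_genes: int = 2000
    probes_per_gene: int = 5
    n_empty_spots: int = 200
    localities: tuple[str, ...] = DEFAULT_LOCALITIES

    # truth-class fractions (remainder of 1 is null)
    frac_parallel_directional: float = 0.0
    frac_parallel_nondirectional: float = 0.0
    frac_locality_specific: float = 0.0

    effect_size: float = 3.0
    effect_scale: str = "sd"
    cgh_probe_affected_frac: float = 0.6

    baseline_mean: float = 12.0
    baseline_sd: float = 1.0
    probe_affinity_sd: float = 0.5
    d0_true: float = 4.0
    s0sq_true: float = 0.05
    background_mean: float = 8.0
    background_sd: float = 0.5
    pool_size_effect: float = 1.0

    # within-group variance multiplier for parallel_directional genes
    directional_var_factor: float = 1.0
    # sd of per-locality offsets (geographic differentiation), applied to both
    # ecotypes; parallel classes vs all other genes
    geo_sd_parallel: float = 0.0
    geo_sd_nonparallel: float = 0.0

    n_pools: int = 4
    n_individuals: int = 12
    dropout_expression: int = 2
    dropout_cgh: int = 3

    seed: int = 0

    def __post_init__(self) -> None:
        total = (
            self.frac_parallel_directional
            + self.frac_parallel_nondirectional
            + self.frac_locality_specific
        )
        if min(
            self.frac_parallel_directional,
            self.frac_parallel_nondirectional,
            self.frac_locality_specific,
        ) < 0 or total > 1 + 1e-12:
            raise ValueError("truth-class fractions must be >= 0 and sum to <= 1")
        for name in ("baseline_sd", "probe_affinity_sd", "background_sd", "s0sq_true"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.effect_scale not in ("sd", "log2"):
            raise ValueError("effect_scale must be 'sd' or 'log2'")
        if len(self.localities) != 3:
            raise ValueError("the study design requires exactly 3 localities")

    def replace(self, **changes) -> "SimulationConfig":
        return dataclasses.replace(self, **changes)


@dataclass(frozen=True)
class TruthTable:
    """Ground truth: per-gene classes/effects and per-probe CGH effects.

    ``genes`` columns: gene_id, expr_class, expr_effect_<locality> (signed
    log2 crab-minus-wave shift), cgh_class, cgh_effect_<locality> (gene-level
    M shift), within_sd (expression), cgh_within_sd (M-value),
    geo_offset_<locality> (locality shift shared by both ecotypes).
    ``probes`` columns: probe_id, gene_id, cgh_affected plus
    cgh_effect_<locality> realized per probe.
    """

    genes: pd.DataFrame
    probes: pd.DataFrame
    localities: tuple[str, ...]

    def expr_effects(self) -> pd.DataFrame:
        cols = [f"expr_effect_{loc}" for loc in self.localities]
        out = self.genes.set_index("gene_id")[cols]
        out.columns = list(self.localities)
        return out

    def cgh_probe_effects(self) -> pd.DataFrame:
        cols = [f"cgh_effect_{loc}" for loc in self.localities]
        out = self.probes.set_index("probe_id")[cols]
        out.columns = list(self.localities)
        return out

    def genes_of_class(self, *classes: str, assay: str = "expression") -> pd.Index:
        col = "expr_class" if assay == "expression" else "cgh_class"
        sel = self.genes.loc[self.genes[col].isin(classes), "gene_id"]
        return pd.Index(sel)

    def to_tsv(self, path) -> None:
        path = Path(path)
        self.genes.to_csv(path, sep="\t", index=False)

    def probes_to_tsv(self, path) -> None:
        self.probes.to_csv(path, sep="\t", index=False)


def generate_design(
    n_genes: int, probes_per_gene: int = 5, n_empty_spots: int = 200, seed: int = 0
) -> ArrayDesign:
    """Array layout: ``n_genes * probes_per_gene`` gene probes + empty spots.

    The seed only fixes the interleaving of empty spots among gene probes
    (their array position is irrelevant downstream but kept reproducible).
    """
    if n_genes < 1 or probes_per_gene < 1:
        raise ValueError("n_genes and probes_per_gene must be >= 1")
    if n_empty_spots < 0:
        raise ValueError("n_empty_spots must be >= 0")
    width = len(str(n_genes))
    genes = [f"g{str(i + 1).zfill(width)}" for i in range(n_genes)]
    rows = []
    for g in genes:
        for j in range(1, probes_per_gene + 1):
            rows.append((f"{g}_p{j}", g, j, False))
    for e in range(1, n_empty_spots + 1):
        rows.append((f"EMPTY_{e:05d}", EMPTY, 0, True))
    table = pd.DataFrame(rows, columns=["probe_id", "gene_id", "probe_index", "is_empty"])
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), _K_DESIGN]))
    order = rng.permutation(len(table))
    table = table.iloc[order].reset_index(drop=True)
    return ArrayDesign(table)


def generate_sample_design(config: SimulationConfig) -> SampleDesign:
    """Sample sheet for both assays with QC dropout applied.

    Dropout removes uniformly random replicates (never leaving a group with
    fewer than two), emulating hybridizations lost to quality control.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), _K_SAMPLES]))
    rows = []
    for assay, n_rep in (("expression", config.n_pools), ("cgh", config.n_individuals)):
        for loc in config.localities:
            for eco in ECOTYPES:
                for rep in range(1, n_rep + 1):
                    sid = f"{assay[:4]}_{loc[:3]}_{eco}_{rep:02d}"
                    rows.append((sid, assay, eco, loc, rep))
    table = pd.DataFrame(
        rows, columns=["sample_id", "assay", "ecotype", "locality", "replicate"]
    )
    drop_ids: list[str] = []
    for assay, n_drop in (
        ("expression", config.dropout_expression),
        ("cgh", config.dropout_cgh),
    ):
        sub = table.loc[table["assay"] == assay]
        group_sizes = sub.groupby(["ecotype", "locality"]).size().to_dict()
        candidates = list(sub["sample_id"])
        dropped = 0
        while dropped < n_drop:
            sid = candidates[int(rng.integers(len(candidates)))]
            row = sub.loc[sub["sample_id"] == sid].iloc[0]
            key = (row["ecotype"], row["locality"])
            if group_sizes[key] <= 2:
                candidates.remove(sid)
                continue
            group_sizes[key] -= 1
            drop_ids.append(sid)
            candidates.remove(sid)
            dropped += 1
    table = table.loc[~table["sample_id"].isin(drop_ids)].reset_index(drop=True)
    return SampleDesign(table)


def _sign_patterns_nondirectional() -> np.ndarray:
    # all 3 signs nonzero but not all equal: 2^3 - 2 = 6 patterns
    pats = []
    for s1 in (-1, 1):
        for s2 in (-1, 1):
            for s3 in (-1, 1):
                if not (s1 == s2 == s3):
                    pats.append((s1, s2, s3))
    return np.array(pats, dtype=float)


def _assign_classes(n: int, config: SimulationConfig, rng) -> np.ndarray:
    counts = {
        "parallel_directional": int(round(config.frac_parallel_directional * n)),
        "parallel_nondirectional": int(round(config.frac_parallel_nondirectional * n)),
        "locality_specific": int(round(config.frac_locality_specific * n)),
    }
    if sum(counts.values()) > n:
        raise ValueError("class fractions allocate more genes than exist")
    labels = np.array(["null"] * n, dtype=object)
    pool = rng.permutation(n)
    start = 0
    for cls in EXPR_CLASSES:
        stop = start + counts[cls]
        labels[pool[start:stop]] = cls
        start = stop
    return labels


def _signed_effects(labels: np.ndarray, magnitudes: np.ndarray, rng) -> np.ndarray:
    """Per-gene signed effect triples honoring the class invariants."""
    n = len(labels)
    eff = np.zeros((n, 3))
    nd_pats = _sign_patterns_nondirectional()
    for i, cls in enumerate(labels):
        if cls == "parallel_directional":
            sign = 1.0 if rng.random() < 0.5 else -1.0
            eff[i] = sign * magnitudes[i]
        elif cls == "parallel_nondirectional":
            eff[i] = nd_pats[rng.integers(len(nd_pats))] * magnitudes[i]
        elif cls == "locality_specific":
            j = rng.integers(3)
            eff[i, j] = (1.0 if rng.random() < 0.5 else -1.0) * magnitudes[i]
    return eff


def generate_truth(design: ArrayDesign, config: SimulationConfig) -> TruthTable:
    """Sample gene classes, signed effect triples and variance draws."""
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), _K_TRUTH]))
    genes = list(design.gene_ids)
    n = len(genes)
    locs = config.localities

    expr_class = _assign_classes(n, config, rng)
    cgh_class = _assign_classes(n, config, rng)

    # scaled inverse chi-square prior draws
    def draw_sd(k: int) -> np.ndarray:
        chi2 = rng.chisquare(config.d0_true, size=k)
        return np.sqrt(config.s0sq_true * config.d0_true / chi2)

    within_sd = draw_sd(n)
    cgh_within_sd = draw_sd(n)
    dir_factor = np.sqrt(config.directional_var_factor)
    within_sd = np.where(expr_class == "parallel_directional", within_sd * dir_factor, within_sd)
    cgh_within_sd = np.where(
        cgh_class == "parallel_directional", cgh_within_sd * dir_factor, cgh_within_sd
    )

    if config.effect_scale == "sd":
        expr_mag = config.effect_size * within_sd
        cgh_mag = config.effect_size * cgh_within_sd
    else:
        expr_mag = np.full(n, config.effect_size)
        cgh_mag = np.full(n, config.effect_size)

    expr_eff = _signed_effects(expr_class, expr_mag, rng)
    cgh_eff = _signed_effects(cgh_class, cgh_mag, rng)

    parallel = np.isin(expr_class, ["parallel_directional", "parallel_nondirectional"])
    geo_sd = np.where(parallel, config.geo_sd_parallel, config.geo_sd_nonparallel)
    geo = rng.normal(0.0, 1.0, size=(n, 3)) * geo_sd[:, None]

    genes_df = pd.DataFrame({"gene_id": genes, "expr_class": expr_class})
    for j, loc in enumerate(locs):
        genes_df[f"expr_effect_{loc}"] = expr_eff[:, j]
    genes_df["cgh_class"] = cgh_class
    for j, loc in enumerate(locs):
        genes_df[f"cgh_effect_{loc}"] = cgh_eff[:, j]
    genes_df["within_sd"] = within_sd
    genes_df["cgh_within_sd"] = cgh_within_sd
    for j, loc in enumerate(locs):
        genes_df[f"geo_offset_{loc}"] = geo[:, j]

    # realize gene-level CGH effects on a subset of each gene's probes
    gp = design.gene_probe_table
    gene_index = {g: i for i, g in enumerate(genes)}
    gi = gp["gene_id"].map(gene_index).to_numpy()
    affected = rng.random(len(gp)) < config.cgh_probe_affected_frac
    has_effect = cgh_class[gi] != "null"
    # guarantee at least one affected probe per divergent gene
    probes_df = pd.DataFrame(
        {"probe_id": gp["probe_id"], "gene_id": gp["gene_id"], "_gi": gi}
    )
    aff = affected & has_effect
    by_gene = probes_df.groupby("_gi").indices
    for g_idx, probe_rows in by_gene.items():
        if cgh_class[g_idx] == "null":
            continue
        if not aff[probe_rows].any():
            aff[probe_rows[int(rng.integers(len(probe_rows)))]] = True
    probes_df["cgh_affected"] = aff
    for j, loc in enumerate(locs):
        probes_df[f"cgh_effect_{loc}"] = np.where(aff, cgh_eff[gi, j], 0.0)
    probes_df = probes_df.drop(columns="_gi")

    return TruthTable(genes=genes_df, probes=probes_df, localities=tuple(locs))


def _probe_baselines(design: ArrayDesign, config: SimulationConfig, rng) -> pd.Series:
    """Gene baseline + probe affinity, indexed by probe_id (gene probes only)."""
    genes = list(design.gene_ids)
    base = pd.Series(
        rng.normal(config.baseline_mean, config.baseline_sd, size=len(genes)), index=genes
    )
    gp = design.gene_probe_table
    affinity = rng.normal(0.0, config.probe_affinity_sd, size=len(gp))
    values = base.loc[gp["gene_id"]].to_numpy() + affinity
    return pd.Series(values, index=gp["probe_id"].to_numpy())


def simulate_expression(
    design: ArrayDesign,
    truth: TruthTable,
    sample_design: SampleDesign,
    config: SimulationConfig,
) -> IntensityMatrix:
    """One-channel log2 expression intensities for the pooled samples."""
    samples = sample_design.table
    if not (samples["assay"] == "expression").all():
        raise ValueError("sample design passed to simulate_expression must be expression-only")
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), _K_EXPR]))
    locs = list(config.localities)

    baselines = _probe_baselines(design, config, rng)
    gp = design.gene_probe_table
    gene_idx = {g: i for i, g in enumerate(truth.genes["gene_id"])}
    gi = gp["gene_id"].map(gene_idx).to_numpy()
    eff = truth.expr_effects().to_numpy()  # genes x 3, crab minus wave
    geo = truth.genes[[f"geo_offset_{loc}" for loc in locs]].to_numpy()
    sd = truth.genes["within_sd"].to_numpy() / np.sqrt(config.pool_size_effect)

    n_probes = len(gp)
    cols = {}
    for _, s in samples.iterrows():
        j = locs.index(s["locality"])
        shift = geo[gi, j] + (eff[gi, j] if s["ecotype"] == "crab" else 0.0)
        noise = rng.normal(0.0, 1.0, size=n_probes) * sd[gi]
        cols[s["sample_id"]] = baselines.to_numpy() + shift + noise

    values = pd.DataFrame(cols, index=gp["probe_id"].to_numpy())
    empties = design.empty_probe_ids
    bg = pd.DataFrame(
        rng.normal(config.background_mean, config.background_sd, size=(len(empties), len(cols))),
        index=empties,
        columns=values.columns,
    )
    values = pd.concat([values, bg]).loc[design.probe_ids]
    values.index.name = "probe_id"
    return IntensityMatrix(values, scale="log2", channels="single", level="probe")


def simulate_cgh(
    design: ArrayDesign,
    truth: TruthTable,
    sample_design: SampleDesign,
    config: SimulationConfig,
) -> IntensityMatrix:
    """Two-channel log2 CGH intensities: sample (cy3) vs common reference (cy5).

    Both channels share the per-probe baseline, so M = cy3 - cy5 isolates the
    injected divergence effect.  Each channel's noise sd is the gene's M-value
    within-group sd divided by sqrt(2).
    """
    samples = sample_design.table
    if not (samples["assay"] == "cgh").all():
        raise ValueError("sample design passed to simulate_cgh must be cgh-only")
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), _K_CGH]))
    locs = list(config.localities)

    baselines = _probe_baselines(design, config, rng)
    gp = design.gene_probe_table
    gene_idx = {g: i for i, g in enumerate(truth.genes["gene_id"])}
    gi = gp["gene_id"].map(gene_idx).to_numpy()
    probe_eff = truth.cgh_probe_effects().loc[gp["probe_id"]].to_numpy()
    geo = truth.genes[[f"geo_offset_{loc}" for loc in locs]].to_numpy()
    channel_sd = truth.genes["cgh_within_sd"].to_numpy()[gi] / np.sqrt(2.0)

    n_probes = len(gp)
    cols = {}
    for _, s in samples.iterrows():
        j = locs.index(s["locality"])
        shift = geo[gi, j] + (probe_eff[:, j] if s["ecotype"] == "crab" else 0.0)
        sample_ch = (
            baselines.to_numpy() + shift + rng.normal(0.0, 1.0, size=n_probes) * channel_sd
        )
        ref_ch = baselines.to_numpy() + rng.normal(0.0, 1.0, size=n_probes) * channel_sd
        cols[f"{s['sample_id']}__cy3"] = sample_ch
        cols[f"{s['sample_id']}__cy5"] = ref_ch

    values = pd.DataFrame(cols, index=gp["probe_id"].to_numpy())
    values = values[two_channel_columns(samples["sample_id"])]
    empties = design.empty_probe_ids
    bg = pd.DataFrame(
        rng.normal(
            config.background_mean, config.background_sd, size=(len(empties), values.shape[1])
        ),
        index=empties,
        columns=values.columns,
    )
    values = pd.concat([values, bg]).loc[design.probe_ids]
    values.index.name = "probe_id"
    return IntensityMatrix(values, scale="log2", channels="two", level="probe")


@dataclass(frozen=True)
class SyntheticDataset:
    """Bundle returned by :func:`simulate_dataset`."""

    design: ArrayDesign
    sample_design: SampleDesign
    truth: TruthTable
    expression: IntensityMatrix
    cgh: IntensityMatrix

    def write(self, outdir) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "design": outdir / "array_design.tsv",
            "samples": outdir / "sample_design.tsv",
            "truth_genes": outdir / "truth_genes.tsv",
            "truth_probes": outdir / "truth_probes.tsv",
            "expression": outdir / "expression_intensities.tsv",
            "cgh": outdir / "cgh_intensities.tsv",
        }
        self.design.to_tsv(paths["design"])
        self.sample_design.to_tsv(paths["samples"])
        self.truth.to_tsv(paths["truth_genes"])
        self.truth.probes_to_tsv(paths["truth_probes"])
        self.expression.to_tsv(paths["expression"])
        self.cgh.to_tsv(paths["cgh"])
        return paths


def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Generate design, truth and both assays under one configuration."""
    design = generate_design(
        config.n_genes, config.probes_per_gene, config.n_empty_spots, seed=config.seed
    )
    sample_design = generate_sample_design(config)
    truth = generate_truth(design, config)
    expression = simulate_expression(
        design, truth, sample_design.subset(assay="expression"), config
    )
    cgh = simulate_cgh(design, truth, sample_design.subset(assay="cgh"), config)
    return SyntheticDataset(design, sample_design, truth, expression, cgh)
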