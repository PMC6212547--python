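"""Core containers: array design, sample design and intensity matrices.

The array is a NimbleGen-style oligo array: each gene is represented by a
small probe set (typically five 60-mers) plus a number of empty spots that
carry no probe and report the background hybridization level.  Two assays
share the same design: a one-channel expression scan of pooled samples and
a two-channel comparative genomic hybridization (CGH) scan in which each
individual is hybridized against a common reference sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

EMPTY = "EMPTY"

CY3_SUFFIX = "__cy3"
CY5_SUFFIX = "__cy5"

ECOTYPES = ("crab", "wave")
DEFAULT_LOCALITIES = ("Burela", "Roncudo", "Silleiro")


class DesignError(ValueError):
    """The array or sample design is internally inconsistent."""


@dataclass(frozen=True)
class ArrayDesign:
    """Probe -> gene map with empty-spot flags.

    ``table`` columns: ``probe_id``, ``gene_id`` (the :data:`EMPTY` sentinel
    for empty spots), ``probe_index`` (1-based index within the gene, 0 for
    empty spots) and ``is_empty``.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"probe_id", "gene_id", "probe_index", "is_empty"}
        missing = required - set(self.table.columns)
        if missing:
            raise DesignError(f"array design missing columns: {sorted(missing)}")
        if self.table["probe_id"].duplicated().any():
            raise DesignError("duplicate probe_id in array design")
        gene_rows = self.table.loc[~self.table["is_empty"]]
        if (gene_rows["gene_id"] == EMPTY).any():
            raise DesignError("non-empty probe mapped to the EMPTY sentinel")

    @property
    def probe_ids(self) -> pd.Index:
        return pd.Index(self.table["probe_id"])

    @property
    def gene_ids(self) -> pd.Index:
        genes = self.table.loc[~self.table["is_empty"], "gene_id"]
        return pd.Index(pd.unique(genes))

    @property
    def empty_probe_ids(self) -> pd.Index:
        return pd.Index(self.table.loc[self.table["is_empty"], "probe_id"])

    @property
    def gene_probe_table(self) -> pd.DataFrame:
        """Rows for real probes only (probe_id, gene_id, probe_index)."""
        return self.table.loc[~self.table["is_empty"]].reset_index(drop=True)

    def probes_of(self, genes) -> pd.Index:
        gp = self.gene_probe_table
        return pd.Index(gp.loc[gp["gene_id"].isin(set(genes)), "probe_id"])

    def genes_of(self, probes) -> pd.Index:
        gp = self.gene_probe_table
        sel = gp.loc[gp["probe_id"].isin(set(probes)), "gene_id"]
        return pd.Index(pd.unique(sel))

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "ArrayDesign":
        table = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "gene_id": str})
        table["is_empty"] = table["is_empty"].astype(bool)
        return cls(table)


@dataclass(frozen=True)
class SampleDesign:
    """Sample sheet: one row per biological sample.

    Columns: ``sample_id``, ``assay`` (``expression`` | ``cgh``), ``ecotype``
    (``crab`` | ``wave``), ``locality``, ``replicate``.  For the CGH assay
    every sample has both a Cy3 (sample) and Cy5 (reference) channel column
    in the intensity matrix; the sheet carries one row per individual.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"sample_id", "assay", "ecotype", "locality", "replicate"}
        missing = required - set(self.table.columns)
        if missing:
            raise DesignError(f"sample design missing columns: {sorted(missing)}")
        if self.table["sample_id"].duplicated().any():
            raise DesignError("duplicate sample_id in sample design")
        bad = set(self.table["assay"]) - {"expression", "cgh"}
        if bad:
            raise DesignError(f"unknown assay labels: {sorted(bad)}")
        bad = set(self.table["ecotype"]) - set(ECOTYPES)
        if bad:
            raise DesignError(f"unknown ecotype labels: {sorted(bad)}")

    @property
    def sample_ids(self) -> pd.Index:
        return pd.Index(self.table["sample_id"])

    @property
    def localities(self) -> tuple[str, ...]:
        return tuple(pd.unique(self.table["locality"]))

    def subset(self, **criteria) -> "SampleDesign":
        mask = pd.Series(True, index=self.table.index)
        for key, value in criteria.items():
            mask &= self.table[key] == value
        return SampleDesign(self.table.loc[mask].reset_index(drop=True))

    def groups(self) -> pd.core.groupby.DataFrameGroupBy:
        return self.table.groupby(["ecotype", "locality"], sort=True)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "SampleDesign":
        return cls(pd.read_csv(path, sep="\t", dtype={"sample_id": str}))


@dataclass
class IntensityMatrix:
    """Probes (or genes) x sample-columns intensity matrix.

    ``values``: DataFrame indexed by probe/gene id.  One-channel matrices use
    plain sample ids as columns; two-channel matrices use
    ``<sample_id>__cy3`` (sample) and ``<sample_id>__cy5`` (reference).

    ``scale`` is ``"linear"`` or ``"log2"``; ``channels`` is ``"single"`` or
    ``"two"``.  ``level`` tags whether rows are probes or summarized genes.
    """

    values: pd.DataFrame
    scale: str = "log2"
    channels: str = "single"
    level: str = "probe"

    def __post_init__(self) -> None:
        if self.scale not in ("linear", "log2"):
            raise DesignError(f"unknown scale {self.scale!r}")
        if self.channels not in ("single", "two"):
            raise DesignError(f"unknown channel layout {self.channels!r}")
        if self.values.isna().any().any():
            raise DesignError("intensity matrix contains missing cells")
        if self.scale == "log2" and not np.isfinite(self.values.to_numpy()).all():
            raise DesignError("log2 intensity matrix contains non-finite values")

    def copy_with(self, values: pd.DataFrame, **tags) -> "IntensityMatrix":
        kwargs = dict(scale=self.scale, channels=self.channels, level=self.level)
        kwargs.update(tags)
        return IntensityMatrix(values, **kwargs)

    @property
    def sample_ids(self) -> list[str]:
        """Biological sample ids (channel suffixes stripped, deduplicated)."""
        if self.channels == "single":
            return list(self.values.columns)
        seen: dict[str, None] = {}
        for col in self.values.columns:
            base = strip_channel(col)[0]
            seen.setdefault(base, None)
        return list(seen)

    def channel_columns(self, channel: str) -> list[str]:
        """Columns belonging to one channel ('cy3' or 'cy5')."""
        if self.channels != "two":
            raise DesignError("channel_columns requires a two-channel matrix")
        suffix = CY3_SUFFIX if channel == "cy3" else CY5_SUFFIX
        cols = [c for c in self.values.columns if c.endswith(suffix)]
        if not cols:
            raise DesignError(f"no {channel} columns present")
        return cols

    def to_tsv(self, path) -> None:
        out = self.values.copy()
        out.index.name = out.index.name or "feature_id"
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path, **tags) -> "IntensityMatrix":
        values = pd.read_csv(path, sep="\t", index_col=0)
        return cls(values, **tags)


def strip_channel(column: str) -> tuple[str, str | None]:
    """Split a column name into (sample_id, channel) for two-channel layouts."""
    if column.endswith(CY3_SUFFIX):
        return column[: -len(CY3_SUFFIX)], "cy3"
    if column.endswith(CY5_SUFFIX):
        return column[: -len(CY5_SUFFIX)], "cy5"
    return column, None


def two_channel_columns(sample_ids) -> list[str]:
    cols: list[str] = []
    for sid in sample_ids:
        cols.append(f"{sid}{CY3_SUFFIX}")
        cols.append(f"{sid}{CY5_SUFFIX}")
    return cols
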