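"""Count/percentage reporting with the study's printed-precision rules.

Universe percentages are rounded half-up to one decimal with a trailing
``.0`` stripped ("13", "2"); percentages below 0.1 are truncated at two
decimals so very small fractions are not inflated ("0.08").  Fractions of
the parallel set are reported as integer percent ("90%").
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_DOWN, ROUND_HALF_UP, Decimal

import pandas as pd


def percentage_value(count: int, universe: int) -> float:
    """Numeric percentage at the printed precision."""
    if universe <= 0:
        raise ValueError("universe must be positive")
    if count < 0 or count > universe:
        raise ValueError("count must lie in [0, universe]")
    pct = Decimal(100 * count) / Decimal(universe)
    if pct >= Decimal("0.1") or count == 0:
        return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))
    return float(pct.quantize(Decimal("0.01"), rounding=ROUND_DOWN))


def format_percentage(count: int, universe: int) -> str:
    """'17.2% (2998)'-style cell; trailing '.0' stripped ('13% (2266)')."""
    value = percentage_value(count, universe)
    text = f"{value:.2f}" if value < 0.1 and count > 0 else f"{value:.1f}"
    if text.endswith(".0") and value >= 1:
        text = text[:-2]
    return f"{text}% ({count})"


def fraction_percent(count: int, total: int) -> int:
    """Integer percent, half-up ('132 of 146' -> 90)."""
    if total <= 0:
        raise ValueError("total must be positive")
    if count < 0 or count > total:
        raise ValueError("count must lie in [0, total]")
    pct = Decimal(100 * count) / Decimal(total)
    return int(pct.quantize(Decimal("1"), rounding=ROUND_HALF_UP))


@dataclass
class SummaryReport:
    """Tabular stand-in for the headline count table and derived fractions."""

    universe: int
    per_locality: pd.DataFrame  # rows: locality; columns: expression, cgh, both
    parallel_expression: int
    parallel_cgh_genes: int
    parallel_cgh_probes: int
    parallel_both: int
    directional_expression: tuple[int, int]  # (D count, parallel count)
    directional_cgh: tuple[int, int]
    extras: dict = field(default_factory=dict)

    def table_rows(self) -> pd.DataFrame:
        """Formatted per-locality and parallel rows."""
        rows = []
        for loc, r in self.per_locality.iterrows():
            if r[["expression", "cgh", "both"]].min() < 0 or r["both"] > min(
                r["expression"], r["cgh"]
            ):
                raise ValueError(f"inconsistent counts for locality {loc}")
            rows.append(
                {
                    "row": loc,
                    "transcriptomics": format_percentage(int(r["expression"]), self.universe),
                    "genomics": format_percentage(int(r["cgh"]), self.universe),
                    "both": format_percentage(int(r["both"]), self.universe),
                }
            )
        rows.append(
            {
                "row": "parallel",
                "transcriptomics": format_percentage(self.parallel_expression, self.universe),
                "genomics": format_percentage(self.parallel_cgh_genes, self.universe),
                "both": format_percentage(self.parallel_both, self.universe),
            }
        )
        return pd.DataFrame(rows)

    def directional_percents(self) -> dict[str, int]:
        out = {}
        d, n = self.directional_expression
        out["expression"] = fraction_percent(d, n) if n else 0
        d, n = self.directional_cgh
        out["cgh"] = fraction_percent(d, n) if n else 0
        return out

    def to_text(self) -> str:
        lines = ["Summary report", f"universe: {self.universe} genes", ""]
        lines.append(self.table_rows().to_string(index=False))
        dp = self.directional_percents()
        lines.append("")
        lines.append(
            f"directional expression: {self.directional_expression[0]} of "
            f"{self.directional_expression[1]} ({dp['expression']}%)"
        )
        lines.append(
            f"directional CGH probes: {self.directional_cgh[0]} of "
            f"{self.directional_cgh[1]} ({dp['cgh']}%)"
        )
        for key, value in self.extras.items():
            lines.append(f"{key}: {value}")
        return "\n".join(lines)
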