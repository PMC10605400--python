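"""Human-readable report formatting: integer-percent tables for selection
frequencies and model performance summaries."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .models import METRICS, ClassifierSpec, PerformanceSummary
from .selection import SelectionResult

_METRIC_HEADERS = {
    "sensitivity": "Sensitivity(% ± SD)",
    "specificity": "Specificity(% ± SD)",
    "ppv": "PPV(% ± SD)",
    "npv": "NPV(% ± SD)",
    "accuracy": "Accuracy(%)",
}


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def format_pct(fraction: float) -> str:
    """0.51 -> '51%' (integer rounding, halves up)."""
    return f"{_round_half_up(100 * fraction)}%"


def format_mean_sd(mean: float, sd: float) -> str:
    """0.785, 0.10 -> '79 ± 10'."""
    if pd.isna(mean):
        return "—"
    return f"{_round_half_up(100 * mean)} ± {_round_half_up(100 * sd)}"


def selection_table(result: SelectionResult, only_chosen: bool = True,
                    ) -> pd.DataFrame:
    """'Features | % Choices' table of the chosen (or all) features."""
    df = result.frequency_table()
    if only_chosen:
        df = df[df["Features"].isin(result.chosen)]
    df = df.copy()
    df["% Choices"] = df["% Choices"].map(lambda v: f"{v}%")
    return df.reset_index(drop=True)


def performance_row(name: str, summary: PerformanceSummary) -> dict[str, str]:
    row = {"Features": name}
    for metric in METRICS:
        if metric == "accuracy":
            row[_METRIC_HEADERS[metric]] = (
                format_pct(summary.mean[metric])
                if pd.notna(summary.mean[metric]) else "—").rstrip("%")
        else:
            row[_METRIC_HEADERS[metric]] = format_mean_sd(
                summary.mean[metric], summary.sd[metric])
    return row


def univariate_table(results: dict[str, PerformanceSummary]) -> pd.DataFrame:
    return pd.DataFrame([performance_row(k, v) for k, v in results.items()])


def multivariate_table(results: list[tuple[ClassifierSpec, PerformanceSummary]],
                       top: int | None = 10) -> pd.DataFrame:
    rows = []
    for spec, summary in results[:top]:
        name = f"{spec.family}: " + " + ".join(spec.features)
        rows.append(performance_row(name, summary))
    return pd.DataFrame(rows)


def render_report(selection_results: dict[str, SelectionResult],
                  univariate: dict[str, dict[str, PerformanceSummary]],
                  multivariate: dict[str, list],
                  ) -> str:
    lines = []
    for zone, res in selection_results.items():
        lines.append(f"== Selected features ({zone}) ==")
        tbl = selection_table(res)
        if tbl.empty:
            lines.append("no feature passed the selection-frequency threshold")
        else:
            lines.append(tbl.to_string(index=False))
        lines.append("")
    for zone, uni in univariate.items():
        if uni:
            lines.append(f"== Univariate models ({zone}) ==")
            lines.append(univariate_table(uni).to_string(index=False))
            lines.append("")
    for zone, multi in multivariate.items():
        if multi:
            lines.append(f"== Best multivariate models ({zone}) ==")
            lines.append(multivariate_table(multi, top=5).to_string(index=False))
            lines.append("")
    return "\n".join(lines)
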