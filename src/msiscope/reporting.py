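"""Human-readable renderings of score reports (TSV, JSON, Markdown)."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .errors import MsiscopeError

__all__ = ["render_report"]


def _call_columns(df: pd.DataFrame) -> tuple[str, str]:
    calls = [c for c in df.columns if c.startswith("call_")]
    if len(calls) != 2:
        raise MsiscopeError(f"score report must carry exactly two call columns, found {calls}")
    return tuple(sorted(calls, key=lambda c: float(c.split("_", 1)[1])))  # type: ignore[return-value]


def render_report(
    score_report: pd.DataFrame,
    out_format: str = "markdown",
    panel_size: int | None = None,
) -> str:
    """Render a score report; Markdown flags samples scored on a reduced marker set."""
    if out_format == "tsv":
        return score_report.to_csv(sep="\t", index=False)
    if out_format == "json":
        return json.dumps(score_report.to_dict(orient="records"), indent=2, default=str) + "\n"
    if out_format != "markdown":
        raise MsiscopeError(f"unknown report format {out_format!r} (tsv|json|markdown)")

    lines = ["# MSI score report", ""]
    if score_report.empty:
        lines += ["No samples scored.", ""]
        return "\n".join(lines)
    lenient_col, conservative_col = _call_columns(score_report)
    thr_lenient = lenient_col.split("_", 1)[1]
    thr_conservative = conservative_col.split("_", 1)[1]
    lines += [
        f"Score = -log10 of the Fisher-combined probability that the sample's "
        f"WT-read frequencies arose from the control population. Thresholds: "
        f"{thr_lenient} (5% control probability) and {thr_conservative} (1%).",
        "",
        f"| sample | k | score | call at {thr_lenient} | call at {thr_conservative} |",
        "|---|---|---|---|---|",
    ]
    caveats = []
    for _, row in score_report.iterrows():
        lines.append(
            f"| {row['sample_id']} | {int(row['k'])} | {float(row['score']):.2f} "
            f"| {'POSITIVE' if row[lenient_col] else 'negative'} "
            f"| {'POSITIVE' if row[conservative_col] else 'negative'} |"
        )
        if panel_size is not None and int(row["k"]) < panel_size:
            caveats.append(
                f"- {row['sample_id']}: scored on {int(row['k'])}/{panel_size} markers "
                "(remaining markers failed coverage QC or were unmodelled)."
            )
    if caveats:
        lines += ["", "**Caveats**", *caveats]
    lines.append("")
    return "\n".join(lines)


def write_report(score_report: pd.DataFrame, path: str | Path, out_format: str, panel_size: int | None = None) -> None:
    Path(path).write_text(render_report(score_report, out_format, panel_size))
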