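"""Report serialization: JSON for machine use, flat CSVs for tables."""

from __future__ import annotations

import dataclasses
import json
import math
from typing import Sequence

import pandas as pd

from .pipeline import CohortSummary, ParticipantResult, SCHEMA_VERSION

__all__ = [
    "results_to_json",
    "write_report",
    "gof_table",
    "render_report",
]


def _clean(obj):
    """Recursively convert dataclasses/tuples and make NaN JSON-safe."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _clean(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _clean(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_clean(v) for v in obj]
    if isinstance(obj, float) and not math.isfinite(obj):
        return None
    return obj


def results_to_json(
    results: Sequence[ParticipantResult],
    summary: CohortSummary | None = None,
    meta: dict | None = None,
) -> dict:
    doc = {
        "schema_version": SCHEMA_VERSION,
        "participants": {r.participant: _clean(r) for r in results},
    }
    if summary is not None:
        doc["summary"] = _clean(summary)
    if meta:
        doc["meta"] = _clean(meta)
    return doc


def write_report(doc: dict, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=2)
        fh.write("\n")


def gof_table(results: Sequence[ParticipantResult]) -> pd.DataFrame:
    """Per-participant goodness-of-fit listing (one row per leaking fit)."""
    rows = []
    for r in results:
        if r.leak_fit is None:
            continue
        lf = r.leak_fit
        rows.append(
            {
                "participant": r.participant,
                "variant": lf.variant,
                "k_hat": lf.k_hat,
                "loglik": lf.loglik,
                "chi2": lf.chi2,
                "df": lf.df,
                "p_value": lf.p_value,
                "converged": lf.converged,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "participant",
            "variant",
            "k_hat",
            "loglik",
            "chi2",
            "df",
            "p_value",
            "converged",
        ],
    )


def render_report(doc: dict) -> str:
    """Human-readable summary of a pipeline JSON report."""
    lines = []
    parts = doc.get("participants", {})
    lines.append(f"participants: {len(parts)}")
    summary = doc.get("summary")
    if summary:
        lines.append(
            "tendencies: central={n_central} repulsion={n_repulsion} "
            "null={n_null}".format(**summary)
        )
        if summary.get("k_values"):
            lines.append(
                f"leaking factor k (central, n={len(summary['k_values'])}): "
                f"mean={summary['k_mean']:.3f} sd={summary['k_sd']:.3f}"
            )
        if summary.get("correlation_r") is not None:
            lines.append(
                "variance-ratio vs k: r({df}) = {r:.3f}, p = {p:.4f}".format(
                    df=summary["correlation_df"],
                    r=summary["correlation_r"],
                    p=summary["correlation_p"],
                )
            )
    lines.append("")
    lines.append("participant tendency  variant      k      chi2  df  p")
    for pid, rec in sorted(parts.items()):
        lf = rec.get("leak_fit")
        if lf:
            lines.append(
                f"{pid:<11s} {rec['tendency'] or '-':<9s} {lf['variant']:<8s} "
                f"{lf['k_hat']:7.3f} {lf['chi2']:8.2f}  {lf['df']:2d}  "
                f"{lf['p_value']:.3f}"
            )
        else:
            lines.append(f"{pid:<11s} {rec['tendency'] or '-':<9s} -")
    return "\n".join(lines)
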