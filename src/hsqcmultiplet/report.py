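"""Analysis reports: machine-readable JSON and human-readable markdown.

The JSON report is the primary output — one record per requested resonance
with assigned shifts, library distance, per-component percentage
contributions, the coefficient of determination rho and the trust flag,
plus a configuration echo and library provenance.  The markdown report
renders the same records as a table with the trust colour-coding semantics
(trustworthy / borderline / not trustworthy).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import List, Optional, Sequence, Union

from .config import AnalysisConfig
from .matching import MultipletFit

REPORT_SCHEMA_VERSION = 1

_TRUST_BADGE = {
    "trustworthy": "GREEN",
    "borderline": "YELLOW",
    "not_trustworthy": "RED",
    "not_found": "RED",
}


def fit_to_record(fit: MultipletFit) -> dict:
    rec = {
        "metabolite": fit.entry.metabolite if fit.entry else None,
        "moiety": fit.entry.moiety if fit.entry else None,
        "trust": fit.trust,
        "rho_percent": round(float(fit.rho), 4),
        "assigned_h_ppm": None,
        "assigned_c_ppm": None,
        "delta_ppm": None,
        "library_h_ppm": fit.entry.delta_h_lib if fit.entry else None,
        "library_c_ppm": fit.entry.delta_c_lib if fit.entry else None,
        "components": [],
    }
    if fit.assignment is not None:
        rec["assigned_h_ppm"] = round(float(fit.assignment.x_h), 5)
        rec["assigned_c_ppm"] = round(float(fit.assignment.x_c), 5)
        rec["delta_ppm"] = round(float(fit.assignment.delta_ppm), 6)
    if fit.fractions is not None:
        rec["components"] = [
            {"isotopomer": label, "percent": round(100.0 * float(f), 4)}
            for label, f in zip(fit.component_labels, fit.fractions)
        ]
    return rec


def results_to_report(
    results: List[MultipletFit],
    config: AnalysisConfig,
    j_scaling_used: int,
    library_provenance: str = "",
    errors: Optional[List[str]] = None,
) -> dict:
    return {
        "schema_version": REPORT_SCHEMA_VERSION,
        "generator": "hsqcmultiplet",
        "j_scaling": int(j_scaling_used),
        "config": config.to_dict(),
        "library": library_provenance,
        "errors": errors or [],
        "resonances": [fit_to_record(f) for f in results],
    }


def write_report(report: dict, path: Union[str, Path], format: str = "json") -> Path:
    """Write *report* as JSON or markdown; returns the path written."""
    path = Path(path)
    if format == "json":
        path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    elif format == "markdown":
        path.write_text(_render_markdown(report))
    else:
        raise ValueError(f"unknown report format {format!r}")
    return path


def read_report(path: Union[str, Path]) -> dict:
    return json.loads(Path(path).read_text())


def _render_markdown(report: dict) -> str:
    lines = [
        "# HSQC multiplet analysis report",
        "",
        f"Apparent-J scaling: {report['j_scaling']}",
        "",
        "| metabolite | moiety | 1H (ppm) | 13C (ppm) | dist (ppm) | rho (%) | trust | composition |",
        "|---|---|---|---|---|---|---|---|",
    ]
    for r in report["resonances"]:
        comp = "; ".join(f"{c['isotopomer']} {c['percent']:.1f}%" for c in r["components"])
        badge = _TRUST_BADGE.get(r["trust"], "?")
        fmt = lambda v: f"{v:.4f}" if v is not None else "-"
        lines.append(
            f"| {r['metabolite']} | {r['moiety']} | {fmt(r['assigned_h_ppm'])} "
            f"| {fmt(r['assigned_c_ppm'])} | {fmt(r['delta_ppm'])} "
            f"| {r['rho_percent']:.2f} | {badge} {r['trust']} | {comp or '-'} |"
        )
    if report.get("errors"):
        lines += ["", "## Errors", ""] + [f"- {e}" for e in report["errors"]]
    lines.append("")
    return "\n".join(lines)
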