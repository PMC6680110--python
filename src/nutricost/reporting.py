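"""Report rendering: CSV and JSON writers mirroring the published layouts.

The CSV has one data row per intervention x region with a fixed column
order (intervention, category, region, target_population, unit_cost_usd_yr,
coverage, cost_usd_million, share_pct) and a final ``Total`` row.  Monetary
columns are labelled with explicit units to avoid the billion/million
ambiguity costing reports tend to invite.  Both writers are lossless: the
JSON carries the exact line values and :func:`read_report_json` reconstructs
an equal :class:`~nutricost.costing.CostReport`.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Iterable, List

import pandas as pd

from .costing import CostLine, CostReport
from .errors import InvalidInputError
from .unit_costs import round_money

__all__ = ["read_report_json", "write_report", "write_report_csv", "write_report_json"]

CSV_COLUMNS = (
    "intervention",
    "category",
    "region",
    "target_population",
    "unit_cost_usd_yr",
    "coverage",
    "cost_usd_million",
    "share_pct",
)


def write_report_csv(report: CostReport, path: str | Path) -> Path:
    path = Path(path)
    total = report.total
    rows = []
    for line in report.lines:
        rows.append(
            {
                "intervention": line.intervention_id,
                "category": line.category,
                "region": line.region_id,
                "target_population": line.target_population,
                "unit_cost_usd_yr": line.annual_unit_cost,
                "coverage": line.coverage,
                "cost_usd_million": round_money(line.cost, 2),
                "share_pct": round_money(100.0 * line.cost / total, 2)
                if total > 0
                else 0.0,
            }
        )
    rows.append(
        {
            "intervention": "Total",
            "category": "",
            "region": "",
            "target_population": "",
            "unit_cost_usd_yr": "",
            "coverage": "",
            "cost_usd_million": round_money(total, 2),
            "share_pct": 100.00 if total > 0 else 0.0,
        }
    )
    pd.DataFrame(rows, columns=CSV_COLUMNS).to_csv(path, index=False)
    return path


def write_report_json(report: CostReport, path: str | Path) -> Path:
    """Nested scenario -> category -> intervention JSON, plus the exact flat
    line list used for lossless round-tripping."""
    path = Path(path)
    categories: Dict[str, dict] = {}
    for line in report.lines:
        cat = categories.setdefault(
            line.category, {"total_usd_million": 0.0, "interventions": {}}
        )
        cat["total_usd_million"] += line.cost
        cat["interventions"].setdefault(line.intervention_id, 0.0)
        cat["interventions"][line.intervention_id] += line.cost
    payload = {
        "scenario": report.scenario,
        "total_usd_million": report.total,
        "categories": categories,
        "lines": [
            {
                "intervention_id": line.intervention_id,
                "category": line.category,
                "region_id": line.region_id,
                "target_population": line.target_population,
                "annual_unit_cost": line.annual_unit_cost,
                "coverage": line.coverage,
                "cost": line.cost,
            }
            for line in report.lines
        ],
    }
    path.write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")
    return path


def read_report_json(path: str | Path) -> CostReport:
    """Reconstruct a report written by :func:`write_report_json`."""
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    return CostReport(
        scenario=payload["scenario"],
        lines=[CostLine(**line) for line in payload["lines"]],
    )


def write_report(
    report: CostReport,
    out_dir: str | Path,
    formats: Iterable[str] = ("csv", "json"),
    stem: str | None = None,
) -> List[Path]:
    """Write the report in each requested format; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stem = stem or f"{report.scenario}_report"
    written = []
    for fmt in formats:
        if fmt == "csv":
            written.append(write_report_csv(report, out_dir / f"{stem}.csv"))
        elif fmt == "json":
            written.append(write_report_json(report, out_dir / f"{stem}.json"))
        else:
            raise InvalidInputError(f"unknown report format {fmt!r}")
    if not written:
        raise InvalidInputError("no output formats requested")
    return written
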