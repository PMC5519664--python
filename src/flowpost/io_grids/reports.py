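"""Machine-readable result reports (JSON / CSV).

Any object exposing ``to_dict()`` (nested JSON-safe dict) and
``to_records()`` (flat list of row dicts sharing one schema) can be written;
both :class:`flowpost.comparison.ComparisonReport` and
:class:`flowpost.hemodynamics.EnergyLossResult` do.
"""

from __future__ import annotations

import csv
import json
from typing import Optional

__all__ = ["write_report", "read_report_json", "read_report_csv"]


def _detect(path: str, fmt: Optional[str]) -> str:
    name = (fmt or path.rsplit(".", 1)[-1]).lower()
    if name not in ("json", "csv"):
        raise ValueError(f"unsupported report format {name!r}; expected json or csv")
    return name


def write_report(report, path: str, fmt: Optional[str] = None) -> None:
    name = _detect(path, fmt)
    if name == "json":
        with open(path, "w") as fh:
            json.dump(report.to_dict(), fh, indent=2, allow_nan=True)
            fh.write("\n")
        return
    records = report.to_records()
    if not records:
        raise ValueError("report has no rows to write")
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(records[0].keys()))
        writer.writeheader()
        writer.writerows(records)


def read_report_json(path: str) -> dict:
    with open(path) as fh:
        return json.load(fh)


def read_report_csv(path: str) -> list[dict]:
    with open(path, newline="") as fh:
        return list(csv.DictReader(fh))
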