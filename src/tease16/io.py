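"""CSV/JSON readers and writers for the scoring pipeline.

Interchange formats (UTF-8, comma-delimited, header required):

* policy observations: ``area,topic_id,stringency,enforcement`` — one row
  per (area, topic) pair;
* consumption inputs:
  ``area,volume_sold_million_litres,abv_fraction,population_millions,gdp_ppp_pc``;
* score reports mirror the published layout: area, rank, one column per
  domain, total; ranges are serialized as (min, max) column pairs to keep
  files machine-readable.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Sequence

import pandas as pd

from .codebook import (
    DOMAINS,
    AreaFramework,
    CodebookError,
    EnforcementLevel,
    PolicyCodebook,
    PolicyObservation,
    default_codebook,
    validate_framework,
)
from .consumption import ConsumptionRecord
from .scoring import ScoreReport, round_half_away
from .sensitivity import SensitivityResult

POLICY_COLUMNS = ("area", "topic_id", "stringency", "enforcement")
CONSUMPTION_COLUMNS = (
    "area",
    "volume_sold_million_litres",
    "abv_fraction",
    "population_millions",
    "gdp_ppp_pc",
)


class FormatError(ValueError):
    pass


def read_policies(
    path: str | Path, codebook: PolicyCodebook | None = None
) -> list[AreaFramework]:
    """Read and validate per-area policy codings from CSV.

    Rows are grouped by area (first-appearance order); duplicate
    (area, topic) rows and unknown labels are reported with line numbers.
    """
    cb = codebook if codebook is not None else default_codebook()
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not set(POLICY_COLUMNS) <= set(
            reader.fieldnames
        ):
            raise FormatError(
                f"{path}: expected columns {','.join(POLICY_COLUMNS)}, "
                f"got {reader.fieldnames}"
            )
        rows_by_area: dict[str, list[PolicyObservation]] = {}
        seen_lines: dict[tuple[str, str], int] = {}
        for row in reader:
            line = reader.line_num
            area = row["area"].strip()
            topic_id = row["topic_id"].strip()
            key = (area, topic_id)
            if key in seen_lines:
                raise FormatError(
                    f"{path}: duplicate row for ({area}, {topic_id}) at line "
                    f"{line} (first seen at line {seen_lines[key]})"
                )
            seen_lines[key] = line
            try:
                obs = PolicyObservation(
                    area=area,
                    topic_id=topic_id,
                    stringency_label=row["stringency"].strip(),
                    enforcement=EnforcementLevel(row["enforcement"].strip().lower()),
                )
            except CodebookError as exc:
                raise FormatError(f"{path}: line {line}: {exc}") from None
            rows_by_area.setdefault(area, []).append(obs)
    frameworks = []
    for area, obs in rows_by_area.items():
        frameworks.append(validate_framework(AreaFramework(area, tuple(obs)), cb))
    return frameworks


def write_policies(frameworks: Sequence[AreaFramework], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(POLICY_COLUMNS)
        for f in frameworks:
            for obs in f.observations:
                writer.writerow(
                    [f.area, obs.topic_id, obs.stringency_label, obs.enforcement.label]
                )


def read_consumption(path: str | Path) -> list[ConsumptionRecord]:
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not set(CONSUMPTION_COLUMNS) <= set(
            reader.fieldnames
        ):
            raise FormatError(
                f"{path}: expected columns {','.join(CONSUMPTION_COLUMNS)}, "
                f"got {reader.fieldnames}"
            )
        records = []
        for row in reader:
            records.append(
                ConsumptionRecord(
                    area=row["area"].strip(),
                    volume_sold=float(row["volume_sold_million_litres"]),
                    abv=float(row["abv_fraction"]),
                    population=float(row["population_millions"]),
                    gdp_ppp_pc=float(row["gdp_ppp_pc"]),
                )
            )
    return records


def write_consumption(records: Sequence[ConsumptionRecord], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(CONSUMPTION_COLUMNS)
        for r in records:
            writer.writerow(
                [r.area, repr(r.volume_sold), repr(r.abv), repr(r.population), repr(r.gdp_ppp_pc)]
            )


def reports_frame(reports: Sequence[ScoreReport], rounded: bool = True) -> pd.DataFrame:
    """Score reports as a table: area, rank, five domains, total."""
    rows = []
    for r in reports:
        row = {"area": r.area, "rank": r.rank}
        for d in DOMAINS:
            v = r.domain_points[d]
            row[d] = round_half_away(v, 1) if rounded else v
        row["total"] = round_half_away(r.total, 1) if rounded else r.total
        rows.append(row)
    return pd.DataFrame(rows, columns=["area", "rank", *DOMAINS, "total"])


def write_report(
    reports: Sequence[ScoreReport], path: str | Path, fmt: str = "csv"
) -> None:
    """Write ranked score reports as CSV (one-decimal display rounding) or
    JSON (full precision plus rounded display values)."""
    path = Path(path)
    if fmt == "csv":
        reports_frame(reports, rounded=True).to_csv(path, index=False)
    elif fmt == "json":
        payload = []
        for r in reports:
            payload.append(
                {
                    "area": r.area,
                    "rank": r.rank,
                    "assumption": r.assumption.label,
                    "domain_points": r.domain_points,
                    "topic_points": r.topic_points,
                    "total": r.total,
                    "display": {
                        "total": round_half_away(r.total, 1),
                        **{
                            d: round_half_away(v, 1)
                            for d, v in r.domain_points.items()
                        },
                    },
                }
            )
        path.write_text(json.dumps(payload, indent=2), encoding="utf-8")
    else:
        raise FormatError(f"unknown report format {fmt!r}")


def sensitivity_frame(result: SensitivityResult) -> pd.DataFrame:
    """Sensitivity summary mirroring the published layout: per-area
    baseline/median/range for rank and score."""
    rows = []
    for area, s in result.per_area.items():
        rows.append(
            {
                "area": area,
                "baseline_rank": s.baseline_rank,
                "median_rank": s.median_rank,
                "rank_min": s.rank_range[0],
                "rank_max": s.rank_range[1],
                "baseline_score": round_half_away(s.baseline_score, 1),
                "median_score": round_half_away(s.median_score, 1),
                "score_min": round_half_away(s.score_range[0], 1),
                "score_max": round_half_away(s.score_range[1], 1),
            }
        )
    return pd.DataFrame(rows)


def write_sensitivity(result: SensitivityResult, path: str | Path) -> None:
    sensitivity_frame(result).to_csv(Path(path), index=False)
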