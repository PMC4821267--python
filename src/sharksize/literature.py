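"""Synthesis of published whale-shark length records across aggregations.

The package ships a transcription of the published multi-site summary of
whale-shark total lengths (location, sample size, size range, mean, survey
period, measurement technique) as a schema-validated CSV.  Records whose
mean was only reported as the midpoint of the size range, or read off a
size-frequency graph, carry an explicit ``mean_method`` flag so consumers
can exclude them; technique flags distinguish photogrammetry-based rows
from visual estimates.

Each record's length statistics are assigned to the last year of the period
the study covers, and summarised per (location, report year) for trend
displays of maximum / mean / minimum length.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict
from importlib import resources
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)

MEAN_METHODS = frozenset({"reported", "mean_of_range", "from_size_frequency"})
TECHNIQUE_FLAGS = frozenset(
    {"visual", "photogrammetry", "aerial_vehicle_comparison", "vertebral_rings", "unspecified"}
)

_COLUMNS = [
    "location", "country", "n", "min_m", "max_m", "mean_m", "mean_method",
    "period_start", "period_end", "techniques", "notes",
]


@dataclass(frozen=True)
class LiteratureRecord:
    """One published length summary for one aggregation and period."""

    location: str
    country: str
    n: int | None
    min_m: float | None
    max_m: float | None
    mean_m: float | None
    mean_method: str
    period_start: int
    period_end: int
    technique_flags: tuple[str, ...]
    notes: str = ""

    def __post_init__(self) -> None:
        if self.mean_method not in MEAN_METHODS:
            raise ValueError(f"mean_method must be one of {sorted(MEAN_METHODS)}")
        unknown = set(self.technique_flags) - TECHNIQUE_FLAGS
        if unknown:
            raise ValueError(f"unknown technique flags {sorted(unknown)}")
        if self.min_m is not None and self.max_m is not None and self.min_m > self.max_m:
            raise ValueError(f"{self.location}: min_m {self.min_m} > max_m {self.max_m}")
        if self.period_start > self.period_end:
            raise ValueError(f"{self.location}: period_start > period_end")
        if self.n is not None and self.n < 1:
            raise ValueError("n must be >= 1 when present")


def mean_of_range(min_m: float, max_m: float) -> float:
    """Midpoint of a size range, the fallback mean when none was reported."""
    if min_m <= 0 or max_m <= 0:
        raise ValueError("range bounds must be positive")
    if min_m > max_m:
        raise ValueError(f"min {min_m} > max {max_m}")
    return (min_m + max_m) / 2.0


def assign_report_year(record: LiteratureRecord) -> int:
    """The year a record's statistics are plotted at: the last year of the
    period covered by the study."""
    if record.period_end is None:  # defensive: dataclass requires it
        raise ValueError("record has no period")
    return record.period_end


def _parse_row(row: pd.Series) -> LiteratureRecord:
    def opt_float(v):
        return None if pd.isna(v) else float(v)

    def opt_int(v):
        return None if pd.isna(v) else int(v)

    techniques = tuple(
        t.strip() for t in str(row["techniques"]).split(";") if t.strip()
    ) if not pd.isna(row["techniques"]) else ()
    return LiteratureRecord(
        location=str(row["location"]),
        country=str(row["country"]),
        n=opt_int(row["n"]),
        min_m=opt_float(row["min_m"]),
        max_m=opt_float(row["max_m"]),
        mean_m=opt_float(row["mean_m"]),
        mean_method=str(row["mean_method"]),
        period_start=int(row["period_start"]),
        period_end=int(row["period_end"]),
        technique_flags=techniques,
        notes="" if pd.isna(row["notes"]) else str(row["notes"]),
    )


def read_literature_csv(path: str | Path) -> list[LiteratureRecord]:
    """Read and validate a literature table CSV."""
    frame = pd.read_csv(path)
    missing = [c for c in _COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"literature CSV lacks columns {missing}")
    return [_parse_row(row) for _, row in frame.iterrows()]


def write_literature_csv(records: list[LiteratureRecord], path: str | Path) -> None:
    """Write records back to the CSV schema (round-trips with reading)."""
    rows = []
    for rec in records:
        d = asdict(rec)
        d["techniques"] = ";".join(d.pop("technique_flags"))
        rows.append(d)
    pd.DataFrame(rows, columns=_COLUMNS).to_csv(path, index=False)


def load_packaged_table() -> list[LiteratureRecord]:
    """The transcribed worldwide literature table shipped with the package."""
    with resources.as_file(
        resources.files("sharksize.data").joinpath("literature_table.csv")
    ) as path:
        return read_literature_csv(path)


def summarize_by_year(records: list[LiteratureRecord]) -> tuple[pd.DataFrame, list[str]]:
    """One row per (location, report year): max / mean / min lengths.

    Missing statistics propagate as missing.  Duplicate keys reporting
    conflicting values for the same statistic produce a warning listing both
    values; the first record's value is kept.
    """
    warnings: list[str] = []
    table: dict[tuple[str, int], dict] = {}
    for rec in records:
        key = (rec.location, assign_report_year(rec))
        row = table.setdefault(
            key,
            {
                "location": key[0],
                "report_year": key[1],
                "country": rec.country,
                "n": rec.n,
                "max_m": rec.max_m,
                "mean_m": rec.mean_m,
                "min_m": rec.min_m,
                "mean_method": rec.mean_method,
                "techniques": ";".join(rec.technique_flags),
            },
        )
        if row is not table[key]:  # pragma: no cover - defensive
            continue
        for stat in ("max_m", "mean_m", "min_m"):
            new = getattr(rec, stat)
            old = row[stat]
            if old is not None and new is not None and old != new:
                warnings.append(
                    f"{key[0]} {key[1]}: conflicting {stat} values {old} and {new}; kept {old}"
                )
            elif old is None and new is not None:
                row[stat] = new
    frame = pd.DataFrame(list(table.values())).sort_values(
        ["location", "report_year"], ignore_index=True
    )
    for w in warnings:
        logger.warning(w)
    return frame, warnings
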