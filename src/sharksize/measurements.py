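"""Reading, validation and QC preprocessing of whale-shark sighting data.

A *sighting* pairs a visual total-length estimate (judged against a 2 m
reference object, recorded at 0.5 m resolution) with a stereo-video
measurement of the same free-swimming shark.  Stereo-video triangulation is
treated as the accurate reference method; the software that produces it also
reports a per-measurement precision in metres.

This module turns a raw sightings table into the analysis-ready paired table:

1. :func:`read_sightings` parses and validates the CSV.
2. :func:`filter_by_precision` drops stereo measurements whose reported
   precision exceeds a fraction (default 5%) of the measured length.
3. :func:`collapse_repeats` averages stereo measurements over repeat
   sightings of the same individual within the same year, keeping every
   visual estimate, and computes the absolute error ``diff = |visual - TLN|``.

:func:`validate_calibration` implements the acceptance check for the stereo
camera calibration against targets of known length.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VALID_SEXES = frozenset({"M", "F", "U"})
VALID_MATURITY = frozenset({"mature", "immature", "unknown"})

#: canonical column order of the analysis-ready paired table
PAIRED_COLUMNS = [
    "individual_id",
    "year",
    "visual_m",
    "tln_m",
    "diff_m",
    "signed_diff_m",
    "day",
    "time_of_day",
    "previsual_m",
]


class SchemaError(ValueError):
    """A mandatory column is missing or the header cannot be interpreted."""


class RowParseError(ValueError):
    """One or more data rows could not be parsed; carries 1-based row numbers."""

    def __init__(self, problems: list[tuple[int, str]]):
        self.problems = problems
        msg = "; ".join(f"row {i}: {m}" for i, m in problems)
        super().__init__(f"unparseable sighting rows: {msg}")


@dataclass(frozen=True)
class SightingRecord:
    """One field observation of a whale shark.

    Optional measurements that were not taken are ``None``, never 0.
    """

    sighting_id: str
    individual_id: str
    year: int
    visual_m: float
    stereo_m: float | None = None
    stereo_precision_m: float | None = None
    previsual_m: float | None = None
    day: int | None = None
    time_of_day: float | None = None
    sex: str = "U"
    clasper_maturity: str = "unknown"

    def __post_init__(self) -> None:
        if self.visual_m is not None and not self.visual_m > 0:
            raise ValueError(f"visual_m must be > 0, got {self.visual_m}")
        if self.stereo_m is not None and not self.stereo_m > 0:
            raise ValueError(f"stereo_m must be > 0, got {self.stereo_m}")
        if self.stereo_precision_m is not None and self.stereo_precision_m < 0:
            raise ValueError("stereo_precision_m must be >= 0")
        if self.sex not in VALID_SEXES:
            raise ValueError(f"sex must be one of {sorted(VALID_SEXES)}, got {self.sex!r}")
        if self.clasper_maturity not in VALID_MATURITY:
            raise ValueError(f"clasper_maturity must be one of {sorted(VALID_MATURITY)}")
        if not (isinstance(self.year, (int, np.integer)) and 1000 <= self.year <= 9999):
            raise ValueError(f"year must be a 4-digit integer, got {self.year!r}")
        if self.time_of_day is not None and not (0 <= self.time_of_day < 24):
            raise ValueError("time_of_day must lie in [0, 24)")


@dataclass(frozen=True)
class CalibrationReport:
    """Result of checking stereo measurements of targets of known length."""

    nominal_m: tuple[float, ...]
    measured_m: tuple[float, ...]
    relative_error: tuple[float, ...]
    tolerance: float
    passed: bool


#: default mapping canonical field -> CSV column name (identity)
DEFAULT_SCHEMA: dict[str, str] = {
    "sighting_id": "sighting_id",
    "individual_id": "individual_id",
    "year": "year",
    "visual_m": "visual_m",
    "stereo_m": "stereo_m",
    "stereo_precision_m": "stereo_precision_m",
    "previsual_m": "previsual_m",
    "day": "day",
    "time_of_day": "time_of_day",
    "sex": "sex",
    "clasper_maturity": "clasper_maturity",
}

_MANDATORY = ("sighting_id", "individual_id", "year", "visual_m")
_FLOAT_FIELDS = ("visual_m", "stereo_m", "stereo_precision_m", "previsual_m", "time_of_day")
_INT_FIELDS = ("year", "day")


def read_sightings(
    path: str | Path,
    schema_options: Mapping[str, str] | None = None,
) -> list[SightingRecord]:
    """Read a sightings CSV into validated :class:`SightingRecord` objects.

    Parameters
    ----------
    path
        CSV file with a header row and one sighting per row; missing values
        are empty cells.
    schema_options
        Optional mapping of canonical field names to the column names used in
        the file; unmapped fields fall back to their canonical names.

    Raises
    ------
    SchemaError
        If a mandatory column (sighting_id, individual_id, year, visual_m)
        is absent.
    RowParseError
        If any row holds a non-numeric value in a numeric column or fails a
        record invariant; the error lists every offending 1-based data row.
    """
    schema = dict(DEFAULT_SCHEMA)
    if schema_options:
        schema.update(schema_options)

    frame = pd.read_csv(path, dtype=str, skipinitialspace=True)
    for canonical in _MANDATORY:
        if schema[canonical] not in frame.columns:
            raise SchemaError(
                f"mandatory column {schema[canonical]!r} (field {canonical}) missing from {path}"
            )

    records: list[SightingRecord] = []
    problems: list[tuple[int, str]] = []
    for pos, (_, row) in enumerate(frame.iterrows(), start=1):
        kwargs: dict[str, object] = {}
        try:
            for canonical, column in schema.items():
                raw = row.get(column)
                if raw is None or (isinstance(raw, float) and math.isnan(raw)) or str(raw).strip() == "":
                    value = None
                elif canonical in _FLOAT_FIELDS:
                    try:
                        value = float(raw)
                    except ValueError:
                        raise ValueError(f"non-numeric {canonical}={raw!r}") from None
                elif canonical in _INT_FIELDS:
                    try:
                        value = int(float(raw))
                    except ValueError:
                        raise ValueError(f"non-numeric {canonical}={raw!r}") from None
                else:
                    value = str(raw).strip()
                if value is not None:
                    kwargs[canonical] = value
            for canonical in _MANDATORY:
                if canonical not in kwargs:
                    raise ValueError(f"missing mandatory value for {canonical}")
            records.append(SightingRecord(**kwargs))  # type: ignore[arg-type]
        except ValueError as exc:
            problems.append((pos, str(exc)))
    if problems:
        raise RowParseError(problems)
    logger.info("read %d sightings from %s", len(records), path)
    return records


def write_sightings(records: Iterable[SightingRecord], path: str | Path) -> None:
    """Write records to CSV with canonical column names (inverse of reading)."""
    names = [f.name for f in fields(SightingRecord)]
    frame = pd.DataFrame([{n: getattr(r, n) for n in names} for r in records], columns=names)
    frame.to_csv(path, index=False)


def validate_calibration(
    nominal_m: Sequence[float],
    measured_m: Sequence[float],
    tolerance: float = 0.02,
) -> CalibrationReport:
    """Check stereo measurements of known-length targets against a tolerance.

    The calibration of the stereo camera pair is accepted when every target
    (e.g. test lengths of 1, 3 and 5 m) is measured with a relative error
    ``|measured - nominal| / nominal`` at or below ``tolerance``.
    """
    nominal = tuple(float(v) for v in nominal_m)
    measured = tuple(float(v) for v in measured_m)
    if len(nominal) != len(measured):
        raise ValueError(
            f"nominal ({len(nominal)}) and measured ({len(measured)}) lengths differ in count"
        )
    if not nominal:
        raise ValueError("calibration requires at least one test length")
    if any(v <= 0 for v in nominal):
        raise ValueError("nominal test lengths must be positive")
    rel = tuple(abs(m - n) / n for n, m in zip(nominal, measured))
    passed = all(e <= tolerance for e in rel)
    return CalibrationReport(nominal, measured, rel, float(tolerance), passed)


def filter_by_precision(
    records: Sequence[SightingRecord],
    max_rel_precision: float = 0.05,
) -> tuple[list[SightingRecord], list[SightingRecord]]:
    """Split records into (kept, dropped) by the stereo precision rule.

    A stereo measurement is retained when the software-reported precision is
    at most ``max_rel_precision`` of the measured length (inclusive at the
    boundary).  Records without a stereo measurement pass through to *kept*
    untouched.
    """
    kept: list[SightingRecord] = []
    dropped: list[SightingRecord] = []
    for rec in records:
        if rec.stereo_m is None:
            kept.append(rec)
            continue
        if rec.stereo_precision_m is None:
            raise ValueError(
                f"sighting {rec.sighting_id}: stereo_m present but stereo_precision_m missing"
            )
        if rec.stereo_precision_m < 0:
            raise ValueError(f"sighting {rec.sighting_id}: negative stereo precision")
        if rec.stereo_precision_m <= max_rel_precision * rec.stereo_m:
            kept.append(rec)
        else:
            dropped.append(rec)
    logger.info(
        "precision filter (<= %.1f%% of length): kept %d, dropped %d",
        100 * max_rel_precision, len(kept), len(dropped),
    )
    return kept, dropped


def collapse_repeats(
    records: Sequence[SightingRecord],
    max_rel_spread: float = 0.05,
) -> tuple[pd.DataFrame, list[str]]:
    """Build the paired analysis table, averaging repeat stereo measurements.

    Repeat sightings of the same individual within the same year share a
    single collapsed stereo length (TLN), the arithmetic mean of that
    individual-year's stereo measurements; every visual estimate is kept as
    its own row.  Stereo measurements of the same individual-year are
    expected to agree to within ``max_rel_spread`` (relative spread
    ``(max - min)/min``); a violation produces a warning but the measurements
    are still averaged, since dropping them would silently change the sample
    size.

    Returns
    -------
    (pairs, warnings)
        ``pairs`` is a DataFrame with one row per input sighting and columns
        ``individual_id, year, visual_m, tln_m, diff_m, signed_diff_m, day,
        time_of_day, previsual_m``.  ``diff_m = |visual_m - tln_m|`` is the
        response of the bias analysis; ``signed_diff_m = tln_m - visual_m``
        (positive when the observer underestimated) is kept for diagnostics.
    """
    for rec in records:
        if rec.stereo_m is None:
            raise ValueError(
                f"sighting {rec.sighting_id}: collapse_repeats requires stereo_m on every record"
            )
    warnings: list[str] = []
    tln_by_key: dict[tuple[str, int], float] = {}
    by_key: dict[tuple[str, int], list[SightingRecord]] = {}
    for rec in records:
        by_key.setdefault((rec.individual_id, rec.year), []).append(rec)
    for key in sorted(by_key):
        values = sorted(r.stereo_m for r in by_key[key])  # type: ignore[misc]
        tln_by_key[key] = float(np.mean(values))
        if len(values) > 1:
            spread = (values[-1] - values[0]) / values[0]
            if spread >= max_rel_spread:
                msg = (
                    f"individual {key[0]} year {key[1]}: stereo spread "
                    f"{100 * spread:.1f}% >= {100 * max_rel_spread:.1f}%; averaged anyway"
                )
                warnings.append(msg)
                logger.warning(msg)
    rows = []
    for rec in records:
        tln = tln_by_key[(rec.individual_id, rec.year)]
        rows.append(
            {
                "individual_id": rec.individual_id,
                "year": rec.year,
                "visual_m": rec.visual_m,
                "tln_m": tln,
                "diff_m": abs(rec.visual_m - tln),
                "signed_diff_m": tln - rec.visual_m,
                "day": rec.day,
                "time_of_day": rec.time_of_day,
                "previsual_m": rec.previsual_m,
            }
        )
    pairs = pd.DataFrame(rows, columns=PAIRED_COLUMNS)
    logger.info(
        "collapsed %d sightings over %d individual-years (%d spread warnings)",
        len(records), len(by_key), len(warnings),
    )
    return pairs, warnings


def write_paired_table(pairs: pd.DataFrame, path: str | Path) -> None:
    """Write the paired analysis table as CSV."""
    pairs.to_csv(path, index=False, columns=[c for c in PAIRED_COLUMNS if c in pairs.columns])
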