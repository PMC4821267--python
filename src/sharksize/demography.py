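"""Size structure and maturity demography of the sampled aggregation.

Whale sharks are generally mature above about 9 m total length (the L50 at
Ningaloo Reef) and "mature or close to maturity" above about 8 m.  Given one
(collapsed stereo) length per individual, the sampled proportions over those
thresholds are extrapolated to the aggregation's estimated population range
(300-500 individuals at Ningaloo).

Percent proportions are rounded to the nearest whole percent *before*
extrapolation, and extrapolated counts rounded to the nearest integer; this
is the arithmetic that maps 6/95 and 20/95 with a population of 300-500 onto
the ranges 18-30 and 63-105 mature / near-mature individuals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

DEFAULT_EDGES = (3.0, 5.0, 7.0, 9.0)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class SizeClassHistogram:
    """Counts of sightings per length class, with the boundary rule spelt out."""

    edges: tuple[float, ...]
    counts: tuple[int, ...]
    convention: str

    @property
    def n(self) -> int:
        return sum(self.counts)

    def to_frame(self) -> pd.DataFrame:
        labels = [f"<= {self.edges[0]}"]
        labels.append(f"({self.edges[0]}, {self.edges[1]})")
        for lo, hi in zip(self.edges[1:-1], self.edges[2:]):
            labels.append(f"[{lo}, {hi})")
        labels.append(f">= {self.edges[-1]}")
        return pd.DataFrame({"size_class_m": labels, "count": list(self.counts)})


@dataclass(frozen=True)
class MaturityConfig:
    """Thresholds and population range for the maturity extrapolation."""

    l50_m: float = 9.0
    near_mature_m: float = 8.0
    population_range: tuple[int, int] = (300, 500)

    def __post_init__(self) -> None:
        if self.near_mature_m > self.l50_m:
            raise ValueError("near_mature_m must not exceed l50_m")
        low, high = self.population_range
        if not 0 < low <= high:
            raise ValueError("population_range must satisfy 0 < low <= high")


@dataclass(frozen=True)
class MaturityAssessment:
    """Sampled maturity proportions extrapolated to the aggregation."""

    n_individuals: int
    n_over_near: int
    n_over_l50: int
    pct_over_near: int
    pct_over_l50: int
    extrapolated_near: tuple[int, int]
    extrapolated_l50: tuple[int, int]
    sampling_fraction_pct: tuple[int, int]
    config: MaturityConfig

    def report_block(self) -> str:
        c = self.config
        return "\n".join(
            [
                f"individuals sampled: {self.n_individuals} "
                f"({self.sampling_fraction_pct[0]}-{self.sampling_fraction_pct[1]}% of the "
                f"{c.population_range[0]}-{c.population_range[1]} aggregation)",
                f"> {c.l50_m} m (likely mature): {self.n_over_l50} "
                f"({self.pct_over_l50}%) -> {self.extrapolated_l50[0]}-{self.extrapolated_l50[1]} "
                "individuals in the aggregation",
                f"> {c.near_mature_m} m (mature or close): {self.n_over_near} "
                f"({self.pct_over_near}%) -> {self.extrapolated_near[0]}-{self.extrapolated_near[1]} "
                "individuals in the aggregation",
            ]
        )


@dataclass(frozen=True)
class MethodComparison:
    """Per-method length summaries and visual over-estimation cases."""

    n: int
    visual_mean: float
    visual_sd: float
    tln_mean: float
    tln_sd: float
    n_overestimated: int
    overestimation_fraction: float
    over_mean: float | None
    over_sd: float | None


def size_histogram(lengths: Sequence[float], edges: Sequence[float] = DEFAULT_EDGES) -> SizeClassHistogram:
    """Histogram of lengths over the survey size classes.

    With the default edges (3, 5, 7, 9) m the bins are (-inf, 3], (3, 5),
    [5, 7), [7, 9), [9, inf): the first class is closed above, the last
    closed below, and interior classes include their left edge (except the
    second, whose left edge belongs to the first class).
    """
    edges_t = tuple(float(e) for e in edges)
    if len(edges_t) < 2 or any(a >= b for a, b in zip(edges_t, edges_t[1:])):
        raise ValueError("edges must be strictly increasing with at least 2 values")
    arr = np.asarray(list(lengths), dtype=float)
    if arr.size and (not np.all(np.isfinite(arr)) or np.any(arr <= 0)):
        raise ValueError("lengths must be positive and finite")
    counts = [0] * (len(edges_t) + 1)
    for x in arr:
        if x <= edges_t[0]:
            counts[0] += 1
        elif x >= edges_t[-1]:
            counts[-1] += 1
        else:
            for i, (lo, hi) in enumerate(zip(edges_t, edges_t[1:]), start=1):
                inside = (lo < x < hi) if i == 1 else (lo <= x < hi)
                if inside:
                    counts[i] += 1
                    break
    convention = (
        f"first class (-inf, {edges_t[0]}]; second ({edges_t[0]}, {edges_t[1]}); "
        f"interior classes left-closed [lo, hi); last class [{edges_t[-1]}, inf)"
    )
    return SizeClassHistogram(edges=edges_t, counts=tuple(counts), convention=convention)


def assess_maturity(
    per_individual_lengths: Sequence[float],
    config: MaturityConfig | None = None,
) -> MaturityAssessment:
    """Extrapolate sampled maturity proportions to the aggregation.

    ``per_individual_lengths`` must hold one (repeat-collapsed) length per
    individual.  Counts are of individuals *strictly greater* than each
    threshold; proportions are rounded to whole percents before multiplying
    by the population bounds.
    """
    cfg = config or MaturityConfig()
    arr = np.asarray(list(per_individual_lengths), dtype=float)
    if arr.size == 0:
        raise ValueError("no individuals supplied")
    if not np.all(np.isfinite(arr)) or np.any(arr <= 0):
        raise ValueError("lengths must be positive and finite")
    n = int(arr.size)
    n_near = int(np.sum(arr > cfg.near_mature_m))
    n_l50 = int(np.sum(arr > cfg.l50_m))
    pct_near = _round_half_up(100.0 * n_near / n)
    pct_l50 = _round_half_up(100.0 * n_l50 / n)
    low, high = cfg.population_range
    return MaturityAssessment(
        n_individuals=n,
        n_over_near=n_near,
        n_over_l50=n_l50,
        pct_over_near=pct_near,
        pct_over_l50=pct_l50,
        extrapolated_near=(_round_half_up(pct_near / 100.0 * low), _round_half_up(pct_near / 100.0 * high)),
        extrapolated_l50=(_round_half_up(pct_l50 / 100.0 * low), _round_half_up(pct_l50 / 100.0 * high)),
        sampling_fraction_pct=(_round_half_up(100.0 * n / high), _round_half_up(100.0 * n / low)),
        config=cfg,
    )


def method_comparison_summary(pairs: pd.DataFrame) -> MethodComparison:
    """Per-method means/sds and the visual over-estimation cases.

    Over-estimation cases are rows where the visual estimate exceeds the
    collapsed stereo length; their magnitudes are ``visual - TLN``.
    """
    if len(pairs) == 0:
        raise ValueError("empty paired table")
    visual = pairs["visual_m"].to_numpy(dtype=float)
    tln = pairs["tln_m"].to_numpy(dtype=float)
    over = visual - tln
    over = over[over > 0]
    n_over = int(over.size)
    return MethodComparison(
        n=len(pairs),
        visual_mean=float(visual.mean()),
        visual_sd=float(visual.std(ddof=1)) if len(pairs) > 1 else 0.0,
        tln_mean=float(tln.mean()),
        tln_sd=float(tln.std(ddof=1)) if len(pairs) > 1 else 0.0,
        n_overestimated=n_over,
        overestimation_fraction=n_over / len(pairs),
        over_mean=float(over.mean()) if n_over else None,
        over_sd=float(over.std(ddof=1)) if n_over > 1 else (0.0 if n_over else None),
    )
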