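"""End-to-end analysis: sightings CSV in, full bias/demography report out.

Stages, in order: read -> stereo precision filter -> repeat collapse ->
collinearity screen -> mixed-model ranking -> bias regression -> bootstrap
method comparison and mean SE -> size histograms -> maturity extrapolation.
Every numeric in the report comes from exactly one upstream operation, and
the provenance block records seed, config hash and input path so a run can
be reproduced bit for bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import bias_model, demography, measurements, resampling
from .demography import MaturityConfig

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AnalysisOptions:
    """Tunable knobs of the pipeline (see the config file schema)."""

    max_rel_precision: float = 0.05
    max_rel_spread: float = 0.05
    filter_before_collapse: bool = True
    criterion_type: str = "ML"
    spearman_threshold: float = 0.7
    n_iter: int = 10_000
    level: float = 0.95
    seed: int = 0
    histogram_edges: tuple[float, ...] = (3.0, 5.0, 7.0, 9.0)


@dataclass
class AnalysisReport:
    """Everything the pipeline computed, JSON-serialisable."""

    preprocessing: dict[str, Any]
    method_summary: demography.MethodComparison
    spearman: bias_model.SpearmanScreen
    model_comparison: list[bias_model.ModelComparisonRow]
    bias_line: bias_model.BiasLine
    bias_line_signed: bias_model.BiasLine
    difference_resample: resampling.ResampleResult
    stereo_mean_bootstrap: resampling.ResampleResult
    visual_histogram: demography.SizeClassHistogram
    stereo_histogram: demography.SizeClassHistogram
    maturity: demography.MaturityAssessment
    provenance: dict[str, Any]


def load_config(path: str | Path | None) -> dict[str, Any]:
    """Read the YAML config file (empty dict when no path given)."""
    if path is None:
        return {}
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"config {path} must be a mapping")
    return data


def options_from_config(config: dict[str, Any]) -> AnalysisOptions:
    section = dict(config.get("analysis", {}))
    if "histogram_edges" in section:
        section["histogram_edges"] = tuple(section["histogram_edges"])
    return AnalysisOptions(**section)


def maturity_from_config(config: dict[str, Any]) -> MaturityConfig:
    section = dict(config.get("maturity", {}))
    if "population_range" in section:
        section["population_range"] = tuple(section["population_range"])
    return MaturityConfig(**section)


def _to_jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, np.ndarray):
        if obj.size > 100:  # keep the report light: draws live in their own CSVs
            return {"n": int(obj.size), "mean": float(obj.mean()), "sd": float(obj.std(ddof=1))}
        return [float(v) for v in obj]
    if isinstance(obj, pd.DataFrame):
        return obj.where(pd.notna(obj), None).to_dict(orient="records")
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    return obj


def run_full_analysis(
    sightings_path: str | Path,
    config_path: str | Path | None = None,
    out_dir: str | Path | None = None,
) -> AnalysisReport:
    """Run every analysis stage on a sightings CSV; optionally write outputs.

    Raises a stage-named RuntimeError if any stage fails, so callers (and the
    CLI) can report where the pipeline stopped.
    """
    config = load_config(config_path)
    opts = options_from_config(config)
    maturity_cfg = maturity_from_config(config)

    stage = "read_sightings"
    try:
        records = measurements.read_sightings(
            sightings_path, schema_options=config.get("columns")
        )
        stage = "filter_by_precision"
        kept, dropped = measurements.filter_by_precision(records, opts.max_rel_precision)
        with_stereo = [r for r in kept if r.stereo_m is not None]
        stage = "collapse_repeats"
        pairs, spread_warnings = measurements.collapse_repeats(with_stereo, opts.max_rel_spread)
        preprocessing = {
            "n_read": len(records),
            "n_dropped_precision": len(dropped),
            "n_without_stereo": len(kept) - len(with_stereo),
            "n_pairs": len(pairs),
            "n_individual_years": int(pairs.groupby(["individual_id", "year"]).ngroups),
            "spread_warnings": spread_warnings,
        }
        stage = "spearman_screen"
        screen = bias_model.spearman_screen(pairs, threshold=opts.spearman_threshold)
        stage = "rank_models"
        comparison = bias_model.rank_models(table=pairs, criterion_type=opts.criterion_type)
        stage = "ols_bias_line"
        line = bias_model.ols_bias_line(pairs)
        line_signed = bias_model.ols_bias_line(pairs, signed=True)
        stage = "resampling"
        visual = pairs["visual_m"].to_numpy(dtype=float)
        stereo = pairs["tln_m"].to_numpy(dtype=float)
        diff_res = resampling.resample_mean_difference(
            visual, stereo, n_iter=opts.n_iter, level=opts.level, seed=opts.seed
        )
        se_res = resampling.bootstrap_mean_se(
            stereo, n_iter=opts.n_iter, level=opts.level, seed=opts.seed + 1
        )
        stage = "size_histogram"
        hist_visual = demography.size_histogram(visual, opts.histogram_edges)
        hist_stereo = demography.size_histogram(stereo, opts.histogram_edges)
        stage = "assess_maturity"
        per_individual = pairs.groupby("individual_id")["tln_m"].first()
        maturity = demography.assess_maturity(per_individual.to_numpy(), maturity_cfg)
        stage = "method_comparison_summary"
        method_summary = demography.method_comparison_summary(pairs)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    provenance = {
        "sightings_path": str(sightings_path),
        "config_path": str(config_path) if config_path else None,
        "config_sha256": hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "seed": opts.seed,
        "options": dataclasses.asdict(opts),
        "maturity_config": dataclasses.asdict(maturity_cfg),
    }
    report = AnalysisReport(
        preprocessing=preprocessing,
        method_summary=method_summary,
        spearman=screen,
        model_comparison=comparison,
        bias_line=line,
        bias_line_signed=line_signed,
        difference_resample=diff_res,
        stereo_mean_bootstrap=se_res,
        visual_histogram=hist_visual,
        stereo_histogram=hist_stereo,
        maturity=maturity,
        provenance=provenance,
    )
    if out_dir is not None:
        write_report(report, pairs, Path(out_dir))
    return report


def render_report(report: AnalysisReport) -> str:
    """Human-readable report block."""
    m = report.method_summary
    lo, hi = report.difference_resample.interval
    lines = [
        "== preprocessing ==",
        json.dumps(_to_jsonable(report.preprocessing), indent=2),
        "",
        "== per-method lengths (m) ==",
        f"visual: {m.visual_mean:.3f} +/- {m.visual_sd:.3f} (n={m.n})",
        f"stereo: {m.tln_mean:.3f} +/- {m.tln_sd:.3f}",
        f"visual over-estimates: {m.n_overestimated} "
        f"({100 * m.overestimation_fraction:.1f}%)"
        + (f", magnitude {m.over_mean:.2f} +/- {m.over_sd:.2f} m" if m.over_mean else ""),
        "",
        "== model comparison ==",
        bias_model.comparison_frame(report.model_comparison).to_string(
            index=False, float_format=lambda v: f"{v:.3f}"
        ),
        "",
        "== bias regression (diff on stereo length) ==",
        f"diff = {report.bias_line.slope:.4f} * TLN + {report.bias_line.intercept:.4f} "
        f"(R2 = {report.bias_line.r2:.4f})",
        "",
        "== bootstrap ==",
        report.difference_resample.summary(),
        report.stereo_mean_bootstrap.summary(),
        f"95% of method differences between {lo:.2f} and {hi:.2f} m",
        "",
        "== size classes ==",
        "visual:\n" + report.visual_histogram.to_frame().to_string(index=False),
        "stereo:\n" + report.stereo_histogram.to_frame().to_string(index=False),
        "",
        "== maturity ==",
        report.maturity.report_block(),
    ]
    return "\n".join(lines) + "\n"


def write_report(report: AnalysisReport, pairs: pd.DataFrame, out_dir: Path) -> None:
    """Write the report (text + JSON) and every referenced table."""
    out_dir.mkdir(parents=True, exist_ok=True)
    measurements.write_paired_table(pairs, out_dir / "paired_table.csv")
    bias_model.comparison_frame(report.model_comparison).to_csv(
        out_dir / "model_comparison.tsv", sep="\t", index=False
    )
    report.visual_histogram.to_frame().to_csv(
        out_dir / "histogram_visual.tsv", sep="\t", index=False
    )
    report.stereo_histogram.to_frame().to_csv(
        out_dir / "histogram_stereo.tsv", sep="\t", index=False
    )
    (out_dir / "report.txt").write_text(render_report(report))
    (out_dir / "report.json").write_text(
        json.dumps(_to_jsonable(report), indent=2, sort_keys=True) + "\n"
    )
    logger.info("wrote analysis outputs to %s", out_dir)
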