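"""End-to-end analysis pipeline: screen -> impute/standardize -> EFA ->
prune -> CFA -> residual-driven modification -> second-order model ->
normalized severity scores.

Each stage's artifact is kept on the :class:`RunReport` so every reported
number can be recomputed from stored intermediates, and
:func:`write_report` serializes the tables that mirror the usual reporting
of a factor-analytic re-analysis (variance accounting, loadings with small
values blanked, fit statistics for base and final models, score summaries).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import cfa as cfa_mod
from . import efa as efa_mod
from . import synthetic
from .cfa import CfaFit, CfaModelSpec, FitSummary, SeverityScores
from .efa import EfaSolution, PruneReport, RetentionReport
from .table import (
    IndicatorTable,
    MissingnessReport,
    PreparedMatrix,
    impute_median,
    missingness_screen,
    read_table,
    schema_from_frame,
    standardize,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "RunReport", "run_pipeline", "write_report",
           "spec_to_dict", "spec_from_dict"]


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration of a full pipeline run.

    ``input_path`` points at a crisis-by-indicator CSV/XLSX (with an
    accompanying ``schema_path`` CSV of indicator metadata), or
    ``generator`` names a synthetic preset (``"paperlike"`` or
    ``"fullsize"``).  ``efa_factors`` is the range of factor counts to
    explore; ``efa_only`` stops the run after the pruning stage.
    """

    input_path: str | None = None
    schema_path: str | None = None
    generator: str | None = "paperlike"
    seed: int = 0
    screening_threshold: float = 0.25
    efa_factors: tuple[int, ...] = (3, 4, 5, 6)
    display_threshold: float = 0.30
    cross_loading_gap: float = 0.20
    cfa_budget: int = 10
    residual_threshold: float = 0.10
    second_order: bool = True
    efa_only: bool = False
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if not 0 < self.screening_threshold < 1:
            raise ValueError("screening_threshold must lie in (0, 1)")
        if self.input_path is None and self.generator is None:
            raise ValueError("either input_path or generator is required")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "PipelineConfig":
        d = dict(d)
        if "efa_factors" in d:
            d["efa_factors"] = tuple(d["efa_factors"])
        return cls(**d)


@dataclass
class RunReport:
    """Stage-by-stage record of one pipeline run."""

    config: PipelineConfig
    table: IndicatorTable | None = None
    missingness: MissingnessReport | None = None
    screened: IndicatorTable | None = None
    imputed: PreparedMatrix | None = None
    standardized: PreparedMatrix | None = None
    efa_solutions: dict[int, EfaSolution] = field(default_factory=dict)
    retention: RetentionReport | None = None
    prune: PruneReport | None = None
    base_spec: CfaModelSpec | None = None
    base_fit: CfaFit | None = None
    base_summary: FitSummary | None = None
    modification_log: list[dict] = field(default_factory=list)
    final_spec: CfaModelSpec | None = None
    final_fit: CfaFit | None = None
    final_summary: FitSummary | None = None
    second_order_fit: CfaFit | None = None
    second_order_summary: FitSummary | None = None
    scores: SeverityScores | None = None
    crisis_types: dict[str, str] = field(default_factory=dict)
    truth: synthetic.SyntheticDataset | None = None

    def fit_table(self) -> pd.DataFrame:
        rows = []
        for label, s in (("base", self.base_summary), ("final", self.final_summary)):
            if s is not None:
                rows.append({"model": label, "chi_square": s.chi_square, "df": s.df,
                             "cfi": s.cfi, "tli": s.tli, "rmsea": s.rmsea})
        return pd.DataFrame(rows)

    def score_summary(self) -> pd.DataFrame | None:
        if self.scores is None:
            return None
        overall = pd.DataFrame(
            {
                "group": ["all"],
                "mean": [float(np.nanmean(self.scores.normalized))],
                "median": [float(np.nanmedian(self.scores.normalized))],
                "min": [float(np.nanmin(self.scores.normalized))],
                "max": [float(np.nanmax(self.scores.normalized))],
                "count": [int(np.isfinite(self.scores.normalized).sum())],
            }
        )
        if self.crisis_types:
            by_type = self.scores.summarize_by(self.crisis_types)
            return pd.concat([overall, by_type], ignore_index=True)
        return overall


def _load_input(config: PipelineConfig) -> tuple[IndicatorTable, dict[str, str], synthetic.SyntheticDataset | None]:
    if config.input_path is not None:
        if config.schema_path is None:
            raise ValueError("schema_path is required with input_path")
        schema = schema_from_frame(pd.read_csv(config.schema_path))
        return read_table(config.input_path, schema), {}, None
    if config.generator == "paperlike":
        gen_cfg = synthetic.paperlike_preset(seed=config.seed)
    elif config.generator == "fullsize":
        gen_cfg = synthetic.gcsi_table_preset(seed=config.seed)
    else:
        raise ValueError(f"unknown generator preset {config.generator!r}")
    ds = synthetic.generate(gen_cfg)
    types = dict(zip(ds.table.crisis_ids, ds.crisis_types))
    return ds.table, types, ds


def _constructs_from_efa(solution: EfaSolution, retained: tuple[str, ...]) -> CfaModelSpec:
    """Assign each retained indicator to the factor carrying its largest
    absolute pattern loading — the construct structure the EFA identified."""
    groups: dict[str, list[str]] = {f"construct{j + 1}": [] for j in range(solution.k)}
    for row, ind in enumerate(solution.indicator_ids):
        if ind not in retained:
            continue
        j = int(np.argmax(np.abs(solution.pattern[row])))
        groups[f"construct{j + 1}"].append(ind)
    groups = {c: tuple(inds) for c, inds in groups.items() if len(inds) >= 2}
    if len(groups) < 2:
        raise RuntimeError("EFA grouping left fewer than 2 usable constructs")
    return CfaModelSpec(groups)


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute the full analysis; deterministic given the config seed."""
    report = RunReport(config=config)
    stage = "load"
    try:
        table, types, truth = _load_input(config)
        report.table, report.crisis_types, report.truth = table, types, truth

        stage = "screen"
        screened, miss = missingness_screen(table, config.screening_threshold)
        report.screened, report.missingness = screened, miss
        logger.info("screen: removed %s", list(miss.removed))

        stage = "prepare"
        report.imputed = impute_median(screened)
        report.standardized = standardize(screened)

        stage = "efa"
        for k in config.efa_factors:
            report.efa_solutions[k] = efa_mod.fit_efa(report.imputed, k)
        report.retention = efa_mod.evaluate_solutions(list(report.efa_solutions.values()))

        stage = "prune"
        ks = sorted(report.efa_solutions)
        report.prune = efa_mod.prune_indicators(
            report.efa_solutions[ks[0]],
            report.efa_solutions[ks[1] if len(ks) > 1 else ks[0]],
            config.display_threshold,
            config.cross_loading_gap,
        )
        if config.efa_only:
            return report

        stage = "cfa_base"
        report.base_spec = _constructs_from_efa(
            report.efa_solutions[ks[0]], report.prune.retained
        )
        report.base_fit = cfa_mod.fit_cfa(report.standardized, report.base_spec)
        report.base_summary = cfa_mod.fit_summary(report.base_fit, report.standardized)

        stage = "cfa_modify"
        spec, fit, log = cfa_mod.modify_model(
            report.standardized,
            report.base_spec,
            budget=config.cfa_budget,
            threshold=config.residual_threshold,
        )
        report.final_spec, report.final_fit, report.modification_log = spec, fit, log
        report.final_summary = cfa_mod.fit_summary(fit, report.standardized)

        if config.second_order and len(spec.constructs) >= 3:
            stage = "cfa_second_order"
            so_spec = cfa_mod.add_second_order(spec)
            report.second_order_fit = cfa_mod.fit_cfa(report.standardized, so_spec)
            report.second_order_summary = cfa_mod.fit_summary(
                report.second_order_fit, report.standardized
            )

            stage = "scores"
            report.scores = cfa_mod.severity_factor_scores(
                report.second_order_fit, report.standardized
            )
        return report
    except Exception as e:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {e}") from e


def write_report(report: RunReport, outdir: str | Path) -> list[Path]:
    """Write the run's tables as CSV/JSON files; returns the paths written.

    Display tables follow reporting precision (loadings blanked below the
    display threshold); machine-readable outputs keep full precision.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def save(df: pd.DataFrame, name: str, **kw) -> None:
        path = out / name
        df.to_csv(path, **kw)
        written.append(path)

    lines: list[str] = []
    if report.missingness is not None:
        save(report.missingness.to_frame(), "missingness.csv", index=False)
        lines.append(f"screened out: {list(report.missingness.removed)}")
    if report.efa_solutions:
        var_rows = []
        for k, sol in sorted(report.efa_solutions.items()):
            for j in range(sol.k):
                var_rows.append(
                    {"solution": k, "factor": f"factor{j + 1}",
                     "ss_loadings": sol.ss_loadings[j],
                     "proportion": sol.proportion_var[j],
                     "cumulative": sol.cumulative_var[j]}
                )
            save(
                sol.loadings_frame(report.config.display_threshold).round(2),
                f"loadings_k{k}.csv",
            )
        save(pd.DataFrame(var_rows), "efa_variance.csv", index=False)
    if report.retention is not None:
        save(report.retention.to_frame(), "efa_retention.csv", index=False)
    if report.prune is not None:
        save(report.prune.to_frame(), "prune.csv", index=False)
        lines.append(f"pruned: {dict(report.prune.removed)}")
    if report.final_summary is not None:
        save(report.fit_table().round(2), "fit_statistics.csv", index=False)
        summary_json = {
            "base": report.base_summary.to_dict() if report.base_summary else None,
            "final": report.final_summary.to_dict(),
            "second_order": (
                report.second_order_summary.to_dict() if report.second_order_summary else None
            ),
            "modification_log": report.modification_log,
        }
        p = out / "fit_summary.json"
        p.write_text(json.dumps(summary_json, indent=2, default=_jsonify))
        written.append(p)
    if report.second_order_fit is not None:
        gam = report.second_order_fit.second_order_loadings
        df = pd.DataFrame(
            {"construct": report.second_order_fit.spec.construct_names,
             "standardized_loading": gam}
        )
        save(df, "second_order_loadings.csv", index=False)
        save(report.second_order_fit.estimates_frame(), "cfa_estimates.csv", index=False)
    if report.scores is not None:
        save(report.scores.to_frame(), "severity_scores.csv")
        summary = report.score_summary()
        if summary is not None:
            save(summary, "score_summary.csv", index=False)
    else:
        lines.append("score stage not run; no score files written")
    log_path = out / "run_log.txt"
    log_path.write_text("\n".join(lines) + "\n")
    written.append(log_path)
    return written


def _jsonify(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, tuple):
        return list(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


# ---------------------------------------------------------------------------
# model-spec serialization


def spec_to_dict(spec: CfaModelSpec) -> dict:
    return {
        "constructs": {c: list(inds) for c, inds in spec.constructs.items()},
        "residual_covariances": [list(p) for p in spec.residual_covariances],
        "second_order": spec.second_order,
    }


def spec_from_dict(d: Mapping[str, Any]) -> CfaModelSpec:
    return CfaModelSpec(
        constructs={c: tuple(v) for c, v in d["constructs"].items()},
        residual_covariances=tuple(tuple(p) for p in d.get("residual_covariances", ())),
        second_order=d.get("second_order"),
    )


def load_spec(path: str | Path) -> CfaModelSpec:
    with open(path) as fh:
        return spec_from_dict(yaml.safe_load(fh))


def save_spec(spec: CfaModelSpec, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(spec_to_dict(spec), fh, sort_keys=False)
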