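"""End-to-end orchestration: documents -> scores -> daily/weekly indices
-> aligned panel -> correlations -> VAR -> stability -> Granger -> IRF.

Every stage's output is persisted next to the final report so stages
can be rerun or audited in isolation; reports are byte-identical when
regenerated from the same inputs and configuration.
"""
from __future__ import annotations

import dataclasses
import datetime as dt
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import panel as panel_mod
from . import scoring, var as var_mod, irf as irf_mod
from .documents import filter_documents, read_documents
from .errors import EmovarError, PipelineError, StabilityError
from .lexicon import compile_lexicon

log = logging.getLogger("emovar")

__all__ = ["PipelineConfig", "AnalysisReport", "run_pipeline", "write_report"]


@dataclass(frozen=True)
class PipelineConfig:
    """Inputs, filters, calendar, and analysis options for one run."""

    documents: Path
    lexicon: Path
    trends: Path
    out_dir: Path
    country: str | None = None
    lang: str | None = None
    date_from: dt.date | None = None
    date_to: dt.date | None = None
    start_date: dt.date = dt.date(2020, 1, 21)
    n_weeks: int = 50
    timezone: str = "UTC"
    standardize: bool = True
    lag: int | None = None        # fixed lag order; None -> select by BIC
    p_max: int = 8
    alpha: float = 0.05
    horizon: int = 10
    ordering: tuple[str, ...] | None = None
    bootstrap: int = 1000
    seed: int | None = None
    unit_shock: bool = False
    on_unstable: str = "abort"    # "abort" | "warn"
    bivariate: bool = False
    plots: bool = False

    def __post_init__(self):
        if self.n_weeks < 1:
            raise EmovarError("n_weeks must be >= 1")
        if self.lag is None and self.n_weeks < self.p_max + 10:
            raise EmovarError(
                f"n_weeks={self.n_weeks} too small for lag selection up to "
                f"p_max={self.p_max}; need at least {self.p_max + 10}")
        if self.on_unstable not in ("abort", "warn"):
            raise EmovarError("on_unstable must be 'abort' or 'warn'")
        if self.bootstrap and self.seed is None:
            raise EmovarError("a seed is required when bootstrap bands are requested")

    def to_jsonable(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, Path):
                d[k] = str(v)
            elif isinstance(v, dt.date):
                d[k] = v.isoformat()
            elif isinstance(v, tuple):
                d[k] = list(v)
        return d

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        for key in ("documents", "lexicon", "trends", "out_dir"):
            if key in raw:
                raw[key] = Path(raw[key])
        for key in ("date_from", "date_to", "start_date"):
            if key in raw and isinstance(raw[key], str):
                raw[key] = dt.date.fromisoformat(raw[key])
        if "ordering" in raw and raw["ordering"] is not None:
            raw["ordering"] = tuple(raw["ordering"])
        return cls(**raw)


@dataclass
class AnalysisReport:
    """All stage outputs of one pipeline run plus provenance."""

    descriptives: pd.DataFrame          # per-emotion min/max/mean/sd of doc scores
    n_documents: int
    n_skipped: int
    correlations: list[panel_mod.CorrelationResult]
    lag_selection: var_mod.LagSelection | None
    lag_used: int
    model: var_mod.VARModel
    stability: var_mod.StabilityReport
    granger: list[var_mod.GrangerResult]
    irf: irf_mod.IRFResult
    provenance: dict = field(default_factory=dict)


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(name, str(exc)) from exc
        return wrapped
    return deco


def run_pipeline(config: PipelineConfig) -> AnalysisReport:
    """Execute every stage in order and persist all intermediates."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    lexicon = _stage("lexicon")(compile_lexicon)(config.lexicon)

    @_stage("score")
    def _score():
        docs = filter_documents(
            read_documents(config.documents),
            country=config.country, lang=config.lang,
            date_from=config.date_from, date_to=config.date_to,
            tz=config.timezone,
        )
        return scoring.score_documents(docs, lexicon, tz=config.timezone)

    table, skipped = _score()
    log.info("scored %d documents (%d skipped as unscorable)", len(table), skipped)
    table_out = table.copy()
    table_out["date"] = table_out["date"].astype(str)
    table_out.to_csv(out / "scores.csv", index=False)

    daily = _stage("daily")(scoring.daily_index_from_scores)(
        table, lexicon, n_skipped=skipped)
    daily_out = daily.data.copy()
    daily_out.index = daily_out.index.astype(str)
    daily_out.to_csv(out / "daily.csv")

    weekly = _stage("weekly")(scoring.weekly_emotion_index)(
        daily, config.start_date, config.n_weeks)

    @_stage("panel")
    def _panel():
        behavior = panel_mod.read_trends_csv(config.trends)
        pnl = panel_mod.assemble_weekly_panel(
            weekly, behavior, config.start_date, config.n_weeks)
        return panel_mod.standardize_panel(pnl) if config.standardize else pnl

    pnl = _panel()
    log.info("panel: T=%d weeks, columns=%s", pnl.T, list(pnl.columns))
    pnl.data.to_csv(out / "panel.csv")
    (out / "panel_provenance.json").write_text(
        json.dumps(pnl.provenance, indent=2, sort_keys=True) + "\n")

    correlations = _stage("correlations")(panel_mod.correlation_screen)(pnl)

    lag_selection = None
    if config.lag is not None:
        lag_used = config.lag
    else:
        lag_selection = _stage("select_lag")(var_mod.select_lag)(pnl, config.p_max)
        lag_used = lag_selection.selected_bic
        lag_selection.to_frame().to_csv(out / "lag_selection.csv")
    log.info("lag order: %d%s", lag_used,
             "" if config.lag is not None else " (BIC)")

    model = _stage("fit")(var_mod.fit_var)(pnl, lag_used)
    (out / "model.json").write_text(
        json.dumps(model.to_dict(), indent=2, sort_keys=True) + "\n")

    stability = _stage("stability")(var_mod.check_stability)(model)
    if not stability.is_stable:
        msg = f"VAR point estimate unstable (max modulus {stability.max_modulus:.4f})"
        if config.on_unstable == "abort":
            (out / "FAILED").write_text(msg + "\n")
            raise PipelineError("stability", msg)
        log.warning(msg)

    granger = _stage("granger")(var_mod.granger_matrix)(
        pnl, lag_used, config.alpha, bivariate=config.bivariate)
    var_mod.granger_frame(granger).to_csv(out / "granger.csv", index=False)

    @_stage("irf")
    def _irf():
        if config.bootstrap:
            return irf_mod.bootstrap_irf_bands(
                pnl, lag_used, config.horizon, ordering=config.ordering,
                B=config.bootstrap, alpha=config.alpha, seed=config.seed,
                unit_shock=config.unit_shock)
        return irf_mod.orthogonalized_irf(
            model, config.horizon, ordering=config.ordering,
            unit_shock=config.unit_shock)

    irf_result = _irf()
    irf_mod.irf_frame(irf_result).to_csv(out / "irf.csv", index=False)
    if config.plots:
        irf_mod.plot_irf_grid(irf_result, str(out / "irf_grid.png"))

    desc = pd.DataFrame({
        "min": table[list(lexicon.emotions)].min(),
        "max": table[list(lexicon.emotions)].max(),
        "mean": table[list(lexicon.emotions)].mean(),
        "sd": table[list(lexicon.emotions)].std(ddof=1),
    })
    desc.index.name = "emotion"

    cfg_jsonable = config.to_jsonable()
    cfg_jsonable.pop("out_dir", None)  # keep reports relocatable
    cfg_json = json.dumps(cfg_jsonable, sort_keys=True)
    provenance = {
        "config": cfg_jsonable,
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "seed": config.seed,
        "n_documents": int(len(table)),
        "n_skipped": int(skipped),
    }
    report = AnalysisReport(
        descriptives=desc, n_documents=len(table), n_skipped=skipped,
        correlations=correlations, lag_selection=lag_selection,
        lag_used=lag_used, model=model, stability=stability,
        granger=granger, irf=irf_result, provenance=provenance,
    )
    write_report(report, out)
    return report


def _md_table(df: pd.DataFrame, floatfmt: str = "{:.4f}") -> str:
    def fmt(v):
        if isinstance(v, (float, np.floating)):
            return floatfmt.format(v)
        return str(v)
    cols = [df.index.name or ""] + list(df.columns)
    lines = ["| " + " | ".join(cols) + " |",
             "|" + "---|" * len(cols)]
    for idx, row in df.iterrows():
        lines.append("| " + " | ".join([str(idx)] + [fmt(v) for v in row]) + " |")
    return "\n".join(lines)


def write_report(report: AnalysisReport, out_dir: str | Path) -> None:
    """Persist the machine-readable JSON and human-readable markdown report."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    corr_df = pd.DataFrame(
        [{"emotion": c.col_a, "r": c.r, "p_value": c.p_value, "n": c.n}
         for c in report.correlations]).set_index("emotion")
    granger_df = var_mod.granger_frame(report.granger)

    payload = {
        "descriptives": {
            m: {k: float(v) for k, v in row.items()}
            for m, row in report.descriptives.iterrows()},
        "n_documents": report.n_documents,
        "n_skipped": report.n_skipped,
        "correlations": [dataclasses.asdict(c) for c in report.correlations],
        "lag_selection": (
            None if report.lag_selection is None else {
                "candidates": list(report.lag_selection.candidates),
                "aic": report.lag_selection.aic,
                "bic": report.lag_selection.bic,
                "selected_aic": report.lag_selection.selected_aic,
                "selected_bic": report.lag_selection.selected_bic,
            }),
        "lag_used": report.lag_used,
        "model": report.model.to_dict(),
        "stability": {
            "moduli": report.stability.moduli.tolist(),
            "is_stable": report.stability.is_stable,
            "tolerance": report.stability.tolerance,
        },
        "granger": granger_df.to_dict(orient="records"),
        "irf": {
            "names": list(report.irf.names),
            "horizon": report.irf.horizon,
            "shock": report.irf.shock,
            "ordering": list(report.irf.ordering),
            "band_method": report.irf.band_method,
            "n_boot": report.irf.n_boot,
            "seed": report.irf.seed,
            "theta": report.irf.theta.tolist(),
            "lower": None if report.irf.lower is None else report.irf.lower.tolist(),
            "upper": None if report.irf.upper is None else report.irf.upper.tolist(),
        },
        "provenance": report.provenance,
    }
    (out / "report.json").write_text(
        json.dumps(payload, indent=2, sort_keys=True) + "\n", encoding="utf-8")

    granger_md = granger_df.copy()
    granger_md["decision"] = np.where(granger_md["reject"], "reject", "accept")
    md = [
        "# Analysis report",
        "",
        f"Documents scored: {report.n_documents} "
        f"(skipped as unscorable: {report.n_skipped})",
        "",
        "## Descriptive statistics of per-document emotion scores",
        "",
        _md_table(report.descriptives),
        "",
        "## Correlation of each emotion index with the behavior index",
        "",
        _md_table(corr_df),
        "",
        f"## Lag order (used: {report.lag_used})",
        "",
        ("(fixed by configuration)" if report.lag_selection is None
         else _md_table(report.lag_selection.to_frame())),
        "",
        "## Stability",
        "",
        f"max companion-root modulus: {report.stability.max_modulus:.4f} "
        f"-> {'stable' if report.stability.is_stable else 'UNSTABLE'}",
        "",
        "## Granger causality tests",
        "",
        _md_table(granger_md[["cause", "effect", "lag", "F", "p_value",
                              "decision"]].set_index("cause")),
        "",
        "## Impulse responses",
        "",
        f"shock convention: {report.irf.shock}; "
        f"ordering: {', '.join(report.irf.ordering)}; "
        f"horizon: {report.irf.horizon}; "
        f"bands: {report.irf.band_method or 'none'}",
        "",
    ]
    (out / "report.md").write_text("\n".join(md), encoding="utf-8")
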