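"""End-to-end orchestration: tracks → FPT → behaviour → covariates → GLMM.

Stage order follows the analysis design: read and regularise tracks, remove
sitting fixes by the speed rule, sweep FPT radii per trip and take the median
peak as the working ARS scale, classify travel/search at that scale, annotate
classified fixes with ranked two-day-averaged covariates for each fix's own
UTC date, and fit the binomial random-intercept model.  Every stage logs the
fixes it drops, so the stage-count table reconciles exactly.
"""

from __future__ import annotations

import datetime as dt
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import behaviour, fpt, glmm, rasters, track_io
from .errors import FptrackError, PipelineStageError

logger = logging.getLogger(__name__)

STAGES = ("raw", "regularised", "non_sitting", "fpt_defined", "classified", "modelled")


@dataclass
class PipelineConfig:
    """All knobs of a run; loadable from YAML.

    Paths may stay None when the analysis is driven in memory via
    :func:`analyse_tracks`.
    """

    tracks_path: str | None = None
    raster_dir: str | None = None
    out_dir: str | None = None
    window: tuple[float, float, float, float] = (-33.6806, -5.1134, -31.1726, -2.6054)
    interval_s: float = 60.0
    speed_threshold_kmh: float = 10.0
    radius_min_m: float = 5.0
    radius_max_m: float = 1000.0
    n_radii: int = 40
    t_high_s: float = 300.0
    variance_statistic: str = "var_log"
    rank_after_average: bool = True
    target_cell_deg: float = 0.05
    quadrature_nodes: int = 25
    schema: dict = field(default_factory=dict)

    def grid_window(self) -> rasters.GridWindow:
        w, s, e, n = self.window
        return rasters.GridWindow(w, s, e, n)

    def radii(self) -> np.ndarray:
        return fpt.default_radii(self.radius_min_m, self.radius_max_m, self.n_radii)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "window" in raw:
            raw["window"] = tuple(raw["window"])
        return cls(**raw)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the whole analysis from files; returns the structured run report.

    The report carries the behaviour table, per-track ARS peaks, the working
    scale, covariate diagnostics, the fitted model and the stage counts.
    Outputs are also written to ``config.out_dir`` when set.
    """
    try:
        tracks = track_io.read_tracks(config.tracks_path, schema=config.schema or None)
    except FptrackError as e:
        raise PipelineStageError("read_tracks", str(e)) from e
    raw = rasters.load_raster_directory(config.raster_dir)
    stack = rasters.CovariateStack(raw, config.grid_window(), config.target_cell_deg,
                                   rank_after_average=config.rank_after_average)
    report = analyse_tracks(tracks, stack, config)
    if config.out_dir:
        _write_outputs(report, report["behaviour_table"], Path(config.out_dir))
    return report


def analyse_tracks(tracks: list[track_io.Track], stack: rasters.CovariateStack,
                   config: PipelineConfig | None = None) -> dict:
    """The analysis chain on in-memory tracks and a prepared covariate stack."""
    config = config or PipelineConfig()
    report: dict = {"stage_counts": {}}
    report["stage_counts"]["raw"] = int(sum(len(t) for t in tracks))

    regs: list[track_io.RegularisedTrack] = []
    for t in tracks:
        r = track_io.regularise(t, config.interval_s)
        if not r.usable:
            logger.warning("trip %s unusable after regularisation, dropped", t.trip_id)
            continue
        regs.append(track_io.flag_sitting(r, config.speed_threshold_kmh))
    report["stage_counts"]["regularised"] = int(sum(len(r) for r in regs))
    report["stage_counts"]["non_sitting"] = int(sum(len(r.retained()) for r in regs))

    # --- FPT and the working scale --------------------------------------
    profiles = []
    failed = []
    for r in regs:
        try:
            profiles.append(fpt.fpt_profile(r, config.radii(),
                                            statistic=config.variance_statistic))
        except FptrackError as e:
            failed.append(r.trip_id)
            logger.warning("trip %s: %s", r.trip_id, e)
    if not profiles:
        raise PipelineStageError("fpt", f"no usable FPT profile; failing trips: {failed}")
    scale = fpt.ars_scale(profiles)
    report["ars"] = {
        "per_track_peaks_m": scale.per_track_peaks,
        "global_scale_m": scale.global_scale,
        "failed_trips": failed,
    }

    # --- behaviour at the working scale ---------------------------------
    tables = []
    for r in regs:
        ret = r.retained().copy()
        ret["fpt_s"] = fpt.fpt_at_scale(r, scale.global_scale)
        sit = r.fixes.loc[r.fixes["sitting"]].copy()
        sit["fpt_s"] = np.nan
        both = pd.concat([ret, sit]).sort_values("timestamp")
        both.insert(0, "individual_id", r.individual_id)
        both.insert(1, "trip_id", r.trip_id)
        tables.append(both)
    table = pd.concat(tables, ignore_index=True)
    nonsit = ~table["sitting"].astype(bool)
    report["stage_counts"]["fpt_defined"] = int(np.isfinite(table.loc[nonsit, "fpt_s"]).sum())
    table = behaviour.build_behaviour_table(table, t_high=config.t_high_s)
    counts = table["label"].value_counts().to_dict()
    report["label_counts"] = {k: int(v) for k, v in counts.items()}
    report["stage_counts"]["classified"] = int(counts.get("travel", 0) + counts.get("search", 0))

    # --- covariates ------------------------------------------------------
    for var in rasters.VARIABLES:
        table[f"{var}_rank"] = np.nan
    modelled_mask = table["label"].isin(["travel", "search"])
    sub = table.loc[modelled_mask]
    for date, idx in sub.groupby(sub["timestamp"].dt.date).groups.items():
        for var in rasters.VARIABLES:
            try:
                ranked = stack.ranked(var, date)
            except KeyError as e:
                raise PipelineStageError("covariates", str(e)) from e
            vals = [rasters.sample_at(ranked, lo, la)
                    for lo, la in zip(table.loc[idx, "lon"], table.loc[idx, "lat"])]
            table.loc[idx, f"{var}_rank"] = vals

    report["temporal_predictability"] = {
        var: stack.predictability(var) for var in rasters.VARIABLES
        if len(stack.dates(var)) >= 2
    }
    try:
        corr = rasters.covariate_correlations(table.loc[modelled_mask])
        report["covariate_correlations"] = {f"{a}_vs_{b}": v for (a, b), v in corr.items()}
    except ValueError as e:
        logger.warning("covariate correlations unavailable: %s", e)

    # --- habitat model ---------------------------------------------------
    table["y"] = np.where(table["label"] == "search", 1.0,
                          np.where(table["label"] == "travel", 0.0, np.nan))
    data = glmm.ModelData.from_frame(table.loc[modelled_mask].dropna(subset=["y"]))
    report["stage_counts"]["modelled"] = int(len(data.y))
    fit = glmm.fit_binomial_glmm(data, quadrature_nodes=config.quadrature_nodes)
    report["fit"] = fit.to_dict()
    report["summary_table"] = fit.summary_table()
    report["behaviour_table"] = table
    return report


def _write_outputs(report: dict, table: pd.DataFrame, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    table.to_csv(out / "behaviour.csv", index=False)
    with open(out / "fit.json", "w") as fh:
        json.dump(report["fit"], fh, indent=2)
    with open(out / "summary.txt", "w") as fh:
        fh.write(report["summary_table"] + "\n")
    slim = {k: v for k, v in report.items() if k not in ("behaviour_table",)}
    with open(out / "report.json", "w") as fh:
        json.dump(slim, fh, indent=2, default=str)


def stage_counts(report: dict) -> pd.Series:
    """Ordered table of fixes surviving each filtering stage."""
    sc = report["stage_counts"]
    return pd.Series([sc[s] for s in STAGES], index=list(STAGES), name="n_fixes")
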