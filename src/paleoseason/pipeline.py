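"""End-to-end orchestration: read → fit → extract → correct → transfer → stats → screen.

Each stage writes its intermediate table to the output directory so that
every number in the final report is traceable, and stages can be re-run
from intermediates.  A machine-readable run summary records the package
version, configuration hash, seed and all exclusions.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .damping import DampingModel, correct_extremes
from .io import read_samples
from .provenance import SrBaseline, collagen_layer_trends, collagen_qc, sr_screen, sr_seasonal_homogeneity
from .seasonal import classify_series, extract_extremes, fit_sinusoid
from .stats import layer_report, season_collagen_correlation
from .transfer import TransferCalibration, reconstruct_temperature

logger = logging.getLogger("paleoseason")

__all__ = ["RunConfig", "StageError", "run_all"]


class StageError(RuntimeError):
    """A pipeline stage failed; message names the stage and offending records."""


@dataclass
class RunConfig:
    """Configuration for a full pipeline run (loadable from YAML)."""

    enamel_path: str
    output_dir: str
    sr_path: str | None = None
    collagen_path: str | None = None
    calibration_path: str | None = None
    extraction_method: str = "observed"
    apply_damping: bool = True
    maturation_length: float | None = None
    sample_length: float | None = None
    min_damping_f: float = 0.3
    amplitude_snr: float = 2.0
    flip_positions: bool = False
    measurement_sd: float = 0.2
    n_mc: int = 10_000
    seed: int = 0
    sr_baseline_mean: float | None = None
    sr_baseline_sd: float | None = None
    sr_k_sd: float = 3.0
    cn_low: float = 2.9
    cn_high: float = 3.6
    stats_seasons: tuple = ("summer", "winter", "mean_annual")
    modern_reference: dict = field(default_factory=dict)  # e.g. {"T_july": 20.5, "T_january": 4.9}

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        unknown = set(raw) - set(known)
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        if "stats_seasons" in known:
            known["stats_seasons"] = tuple(known["stats_seasons"])
        return cls(**known)

    def content_hash(self) -> str:
        payload = {k: getattr(self, k) for k in self.__dataclass_fields__}
        payload["stats_seasons"] = list(payload["stats_seasons"])
        return hashlib.sha256(json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()[:16]


def run_all(config: RunConfig) -> dict:
    """Execute every stage and return the run summary (also written to disk)."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {
        "version": __version__,
        "config_hash": config.content_hash(),
        "seed": config.seed,
        "tables": {},
        "exclusions": {},
    }

    # --- read -------------------------------------------------------------
    try:
        series = read_samples(config.enamel_path, "enamel_o", flip_positions=config.flip_positions)
    except Exception as exc:
        raise StageError(f"stage read: {exc}") from exc
    if not series:
        raise StageError("stage read: no enamel series loaded")

    # --- fit / classify ---------------------------------------------------
    fits, classes = {}, {}
    fit_rows = []
    for ts in series:
        try:
            fit = fit_sinusoid(ts)
        except Exception as exc:
            raise StageError(f"stage fit: tooth {ts.tooth_id}: {exc}") from exc
        cls_ = classify_series(fit, ts, k=config.amplitude_snr)
        fits[ts.tooth_id], classes[ts.tooth_id] = fit, cls_
        fit_rows.append(
            {
                "tooth_id": ts.tooth_id,
                "layer_id": ts.layer_id,
                "A": fit.A,
                "M": fit.M,
                "lam": fit.lam,
                "phi": fit.phi,
                "resid_sd": fit.resid_sd,
                "converged": fit.converged,
                "classification": cls_,
            }
        )
    fits_df = pd.DataFrame(fit_rows)
    _write(fits_df, out / "sinusoid_fits.csv", summary)
    excluded = sorted(t for t, c in classes.items() if c == "non_sinusoidal")
    summary["exclusions"]["non_sinusoidal"] = excluded
    if excluded:
        logger.info("excluded non-sinusoidal teeth: %s", ", ".join(excluded))

    kept = [ts for ts in series if classes[ts.tooth_id] == "sinusoidal"]
    if not kept:
        raise StageError("stage classify: every series was non-sinusoidal")

    # --- extract / damping correction ------------------------------------
    raw_estimates = [extract_extremes(ts, fits[ts.tooth_id], method=config.extraction_method) for ts in kept]
    estimates = raw_estimates
    damping_f = None
    if config.apply_damping:
        if config.maturation_length is None or config.sample_length is None:
            raise StageError(
                "stage damping: maturation_length and sample_length are config-required "
                "(no silent physiological defaults); set apply_damping: false to skip"
            )
        lam_med = float(np.median([fits[ts.tooth_id].lam for ts in kept]))
        model = DampingModel.from_geometry(config.maturation_length, config.sample_length, lam_med)
        damping_f = model.f
        estimates = [
            correct_extremes(est, fits[est.tooth_id], model, min_f=config.min_damping_f)
            for est in raw_estimates
        ]
    ext_rows = []
    for raw, corr in zip(raw_estimates, estimates):
        ext_rows.append(
            {
                "tooth_id": raw.tooth_id,
                "layer_id": raw.layer_id,
                "completeness": raw.completeness,
                "summer_peak_raw": raw.summer_peak,
                "winter_trough_raw": raw.winter_trough,
                "summer_peak": corr.summer_peak,
                "winter_trough": corr.winter_trough,
                "mean_annual": corr.mean_annual,
                "seasonality": corr.seasonality,
                "damping_f": damping_f,
                "method": raw.method,
            }
        )
    _write(pd.DataFrame(ext_rows), out / "seasonal_extremes.csv", summary)

    # --- transfer ---------------------------------------------------------
    temp_df = None
    if config.calibration_path:
        cal = TransferCalibration.from_yaml(config.calibration_path)
        complete = [e for e in estimates if e.completeness == "both_extremes"]
        temps = [
            reconstruct_temperature(
                e, cal, measurement_sd=config.measurement_sd, n_mc=config.n_mc, seed=config.seed
            )
            for e in complete
        ]
        rows = [
            {
                "tooth_id": t.label,
                "layer_id": e.layer_id,
                "T_warmest_month": t.T_warmest_month,
                "T_coldest_month": t.T_coldest_month,
                "MAT": t.MAT,
                "err_warm": t.err_warm,
                "err_cold": t.err_cold,
                "err_mat": t.err_mat,
            }
            for t, e in zip(temps, complete)
        ]
        temp_df = pd.DataFrame(rows)
        if temp_df.empty:
            raise StageError("stage transfer: no tooth has both extremes")
        layer_tbl = (
            temp_df.groupby("layer_id", sort=False)[["T_warmest_month", "T_coldest_month", "MAT"]]
            .mean()
            .reset_index()
        )
        for key, col in (("T_july", "T_warmest_month"), ("T_january", "T_coldest_month"), ("MAT", "MAT")):
            if key in config.modern_reference:
                layer_tbl[f"delta_vs_modern_{col}"] = layer_tbl[col] - float(config.modern_reference[key])
        _write(temp_df, out / "tooth_temperatures.csv", summary)
        _write(layer_tbl, out / "layer_temperatures.csv", summary)

    # --- stats ------------------------------------------------------------
    stats_blocks = {}
    for season in config.stats_seasons:
        try:
            rep = layer_report(estimates, season)
        except ValueError as exc:
            logger.warning("stats for %s skipped: %s", season, exc)
            continue
        _write(rep.summary, out / f"summary_{season}.csv", summary)
        _write(rep.tukey, out / f"tukey_{season}.csv", summary)
        _write(rep.effect_sizes, out / f"effect_sizes_{season}.csv", summary)
        stats_blocks[season] = {
            "anova_F": rep.anova_F,
            "anova_p": rep.anova_p,
            "levene_p": rep.levene_p,
            "shapiro_p": rep.shapiro_p,
        }
    summary["stats"] = stats_blocks

    # --- provenance screen ------------------------------------------------
    if config.sr_path:
        sr = read_samples(config.sr_path, "sr")
        if config.sr_baseline_mean is None or config.sr_baseline_sd is None:
            raise StageError("stage screen: sr_baseline_mean/sd are config-required")
        baseline = SrBaseline(config.sr_baseline_mean, config.sr_baseline_sd, source="config")
        screen_df, sr_summary = sr_screen(sr, baseline, k_sd=config.sr_k_sd)
        homog = sr_seasonal_homogeneity(sr)
        _write(screen_df, out / "sr_screen.csv", summary)
        _write(homog, out / "sr_homogeneity.csv", summary)
        summary["sr"] = sr_summary
        summary["exclusions"]["nonlocal_sr"] = screen_df.loc[
            screen_df["status"] == "nonlocal", "tooth_id"
        ].tolist()

    if config.collagen_path:
        collagen = read_samples(config.collagen_path, "collagen")
        passed, qc_log = collagen_qc(collagen, config.cn_low, config.cn_high)
        trends = collagen_layer_trends(passed)
        _write(qc_log, out / "collagen_qc_log.csv", summary)
        _write(trends, out / "collagen_layer_trends.csv", summary)
        summary["exclusions"]["collagen_qc"] = qc_log.loc[qc_log["rejected"], "specimen_id"].tolist()
        coll_df = pd.DataFrame([{"layer_id": s.layer_id, "d13C": s.d13C} for s in passed])
        try:
            summary["winter_collagen_correlation"] = season_collagen_correlation(estimates, coll_df)
        except ValueError as exc:
            logger.warning("correlation skipped: %s", exc)

    summary["n_layers"] = int(pd.Series([ts.layer_id for ts in series]).nunique())
    summary["n_teeth"] = len(series)
    summary["n_teeth_analyzed"] = len(kept)
    with open(out / "run_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=float)
    summary["tables"]["run_summary"] = str(out / "run_summary.json")
    return summary


def _write(df: pd.DataFrame, path: Path, summary: dict) -> None:
    df.to_csv(path, index=False)
    summary["tables"][path.stem] = str(path)
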