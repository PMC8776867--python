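"""End-to-end pipeline driver: calibrate, simulate the 36-combination grid and
the unisensory conditions, analyze response windows and Integration
Coefficients, fit inverse effectiveness, and run the delay-sweep experiment.

All stages draw their seeds from a single SeedSequence spawned off the
experiment seed, so re-running with an identical configuration reproduces
byte-identical CSV outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import msi
from .calibration import CalibrationTarget, calibrate_all, calibrate_intensity
from .config import ExperimentConfig
from .lif import (
    AuditoryInputSpec,
    ConditionSummary,
    TrialConfig,
    VisualInputSpec,
    run_condition,
)

__all__ = ["PipelineResult", "run_pipeline", "relative_difference", "msi_concentration"]

log = logging.getLogger("mauthner.pipeline")


def relative_difference(p_model: float, p_reference: float) -> float:
    """Symmetric relative difference (p_model - p_ref) / (p_model + p_ref)."""
    if not (0 <= p_model <= 1 and 0 <= p_reference <= 1):
        raise ValueError("probabilities must lie in [0, 1]")
    total = p_model + p_reference
    if total == 0:
        raise ValueError("relative difference undefined: both probabilities zero")
    return (p_model - p_reference) / total


def msi_concentration(
    multi_trials: pd.DataFrame, onset: float, msi_width: float = 40.0
) -> pd.DataFrame:
    """Per contrast level: share of post-auditory responses inside the MSI
    window (the model analogue of the 82-100% behavioral concentration)."""
    rows = []
    for level, grp in multi_trials.groupby("contrast_level"):
        t = grp.loc[grp["responded"], "response_time"].to_numpy(dtype=float)
        post = t[t >= onset]
        frac = float((post < onset + msi_width).mean()) if post.size else np.nan
        rows.append(
            {
                "contrast_level": int(level),
                "n_post_auditory": int(post.size),
                "msi_fraction": frac,
                "msi_pct": 100.0 * frac if np.isfinite(frac) else np.nan,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class PipelineResult:
    """Bundle of every pipeline stage's output."""

    config: ExperimentConfig
    config_hash: str
    calibration: pd.DataFrame
    unisensory_trials: pd.DataFrame
    grid_trials: pd.DataFrame
    delay_trials: pd.DataFrame
    unisensory_probs: pd.DataFrame
    windows: msi.ResponseWindows
    ic_msi: pd.DataFrame
    ic_uv: pd.DataFrame
    fits: dict
    delay_summary: pd.DataFrame
    concentration: pd.DataFrame
    report: dict


def _condition_frame(
    summary: ConditionSummary,
    condition_id: str,
    v_max: float,
    a_max: float,
    config: TrialConfig,
    seed_label: int,
    contrast_level: Optional[int],
    amplitude_level: Optional[int],
) -> pd.DataFrame:
    df = summary.to_frame(condition_id, v_max, a_max, config, seed=seed_label)
    df["contrast_level"] = contrast_level
    df["amplitude_level"] = amplitude_level
    return df


def _analysis_view(trials: pd.DataFrame) -> pd.DataFrame:
    out = trials.copy()
    out["responded"] = out["spiked"].astype(bool)
    out["response_time"] = out["spike_time_ms"]
    return out


def run_pipeline(
    config: Optional[ExperimentConfig] = None, outdir: Optional[str | Path] = None
) -> PipelineResult:
    """Run the full calibrate -> simulate -> analyze -> report pipeline.

    When ``outdir`` is given, writes trials.csv, calibration.csv,
    unisensory_probabilities.csv, ic_matrix.csv, delay_summary.csv, fits.json
    and report.json (deterministic, sorted rows).
    """
    config = config or ExperimentConfig()
    chash = config.config_hash()
    n_levels = config.n_levels
    ss = np.random.SeedSequence(config.seed)
    children = iter(ss.spawn(1 + 2 * n_levels + n_levels * n_levels + len(config.delays)))
    params, trial = config.params, config.trial

    # --- stage 1: calibration -------------------------------------------------
    log.info("stage=calibration seed=%s", config.seed)
    calib = calibrate_all(
        params,
        trial,
        visual=CalibrationTarget(
            "visual",
            target_probs=tuple(config.visual_targets),
            intensity_bounds=tuple(config.visual_bounds),
            tolerance=config.calibration_tolerance,
            n_eval=config.calibration_n_eval,
        ),
        auditory=CalibrationTarget(
            "auditory",
            target_probs=tuple(config.auditory_targets),
            intensity_bounds=tuple(config.auditory_bounds),
            tolerance=config.calibration_tolerance,
            n_eval=config.calibration_n_eval,
        ),
        seed=next(children),
    )
    v_int = calib.query("modality == 'visual'").sort_values("level")["intensity_nA"].to_numpy()
    a_int = calib.query("modality == 'auditory'").sort_values("level")["intensity_nA"].to_numpy()

    # --- stage 2: unisensory conditions --------------------------------------
    log.info("stage=unisensory n_trials=%d", config.n_trials)
    uni_frames = []
    for level in range(1, n_levels + 1):
        child = next(children)
        summ = run_condition(
            VisualInputSpec(v_max=v_int[level - 1]), None, trial, params,
            n_trials=config.n_trials, seed=child,
        )
        uni_frames.append(_condition_frame(
            summ, f"V{level}", v_int[level - 1], 0.0, trial, config.seed, level, None
        ))
    for level in range(1, n_levels + 1):
        child = next(children)
        summ = run_condition(
            None, AuditoryInputSpec(a_max=a_int[level - 1]), trial, params,
            n_trials=config.n_trials, seed=child,
        )
        uni_frames.append(_condition_frame(
            summ, f"A{level}", 0.0, a_int[level - 1], trial, config.seed, None, level
        ))
    uni_trials = pd.concat(uni_frames, ignore_index=True)

    # --- stage 3: the 36-combination multisensory grid ------------------------
    log.info("stage=grid combinations=%d", n_levels * n_levels)
    grid_frames = []
    for ci in range(1, n_levels + 1):
        for ai in range(1, n_levels + 1):
            child = next(children)
            summ = run_condition(
                VisualInputSpec(v_max=v_int[ci - 1]),
                AuditoryInputSpec(a_max=a_int[ai - 1]),
                trial, params, n_trials=config.n_trials, seed=child,
            )
            grid_frames.append(_condition_frame(
                summ, f"VA_{ci}_{ai}", v_int[ci - 1], a_int[ai - 1], trial,
                config.seed, ci, ai,
            ))
    grid_trials = pd.concat(grid_frames, ignore_index=True)

    # --- stage 4: response windows and ICs ------------------------------------
    onset = -trial.av_delay  # auditory onset relative to the end of expansion
    windows = msi.ResponseWindows(
        auditory_onset=onset,
        msi_width=config.msi_width,
        lp_uv_quantiles=tuple(config.lp_uv_quantiles),
    )
    grid_view = _analysis_view(grid_trials)
    responded_times = grid_view.loc[grid_view["responded"], "response_time"]
    windows = msi.fit_uv_boundaries(responded_times, windows)

    uni_view = _analysis_view(uni_trials)
    uni_view["modality"] = np.where(uni_view["condition_id"].str.startswith("V"), "V", "A")
    uni_view["level"] = np.where(
        uni_view["modality"] == "V",
        uni_view["contrast_level"],
        uni_view["amplitude_level"],
    ).astype(float)
    uni_probs = msi.unisensory_probabilities(uni_view, windows)

    ic_msi_df = msi.ic_matrix(grid_view, uni_probs, window="MSI", windows=windows)
    ic_uv_df = msi.ic_matrix(grid_view, uni_probs, window="UV", windows=windows)
    amplitude_map = {i + 1: float(a_int[i]) for i in range(n_levels)}
    contrast_map = {i + 1: float(v_int[i]) for i in range(n_levels)}
    fits = {}
    for name, table in (("MSI", ic_msi_df), ("UV", ic_uv_df)):
        try:
            fits[name] = msi.inverse_effectiveness_fit(
                table, amplitude_map, contrast_map
            )
        except ValueError as exc:  # too few defined cells on small grids
            log.warning("stage=fits window=%s skipped: %s", name, exc)
            fits[name] = None
    conc = msi_concentration(grid_view, onset, config.msi_width)

    # --- stage 5: delay sweep at mid salience ---------------------------------
    log.info("stage=delay_sweep delays=%s", list(config.delays))
    v_mid = float(0.5 * (v_int[n_levels // 2 - 1] + v_int[n_levels // 2]))
    a_mid = float(0.5 * (a_int[n_levels // 2 - 1] + a_int[n_levels // 2]))
    delay_frames, delay_rows = [], []
    for delay in config.delays:
        child = next(children)
        d_trial = dataclasses.replace(trial, av_delay=-float(delay))
        summ = run_condition(
            VisualInputSpec(v_max=v_mid), AuditoryInputSpec(a_max=a_mid),
            d_trial, params, n_trials=config.n_delay_trials, seed=child,
        )
        frame = _condition_frame(
            summ, f"DLY{int(delay)}", v_mid, a_mid, d_trial, config.seed, None, None
        )
        delay_frames.append(frame)
        d_windows = msi.ResponseWindows(
            auditory_onset=float(delay),
            msi_width=config.msi_width,
            lp_uv_quantiles=tuple(config.lp_uv_quantiles),
        )
        times = summ.valid_spike_times
        labels, d_windows = msi.classify_responses(times, d_windows)
        n = config.n_delay_trials
        delay_rows.append(
            {
                "delay_ms": float(delay),
                "orp": summ.p,
                "p_pre": float((labels == "PRE").sum()) / n,
                "p_msi": float((labels == "MSI").sum()) / n,
                "p_uv": float(np.isin(labels, ["LP", "UV"]).sum()) / n,
                "lp_length_ms": msi.lp_interval_length(d_windows),
                "n_responses": int(times.size),
            }
        )
    delay_trials = pd.concat(delay_frames, ignore_index=True)
    delay_summary = pd.DataFrame(delay_rows)

    # --- stage 6: report ------------------------------------------------------
    mean_msi, se_msi = msi.mean_ic(ic_msi_df)
    try:
        mean_uv, se_uv = msi.mean_ic(ic_uv_df)
    except ValueError:  # no UV responses anywhere (tiny configs)
        mean_uv, se_uv = float("nan"), float("nan")
    labels_all, _ = msi.classify_responses(
        responded_times.to_numpy(dtype=float), windows, fit=False
    )
    occupancy = {
        w: float((labels_all == w).mean()) for w in ("PRE", "MSI", "LP", "UV")
    }
    report = {
        "config_hash": chash,
        "seed": config.seed,
        "mean_ic_msi": mean_msi,
        "mean_ic_msi_se": se_msi,
        "mean_ic_uv": mean_uv,
        "mean_ic_uv_se": se_uv,
        "amplitude_slope_msi": fits["MSI"]["amplitude"]["slope"] if fits["MSI"] else None,
        "amplitude_slope_ci": [
            fits["MSI"]["amplitude"]["ci_low"],
            fits["MSI"]["amplitude"]["ci_high"],
        ] if fits["MSI"] else None,
        "contrast_slope_msi": fits["MSI"]["contrast"]["slope"] if fits["MSI"] else None,
        "window_occupancy": occupancy,
        "uv_window_ms": [windows.uv_start, windows.uv_end],
        "msi_concentration_pct_by_contrast": conc["msi_pct"].tolist(),
        "min_msi_concentration_pct": float(np.nanmin(conc["msi_pct"].to_numpy())),
        "lp_length_by_delay_ms": dict(
            zip(map(float, delay_summary["delay_ms"]), delay_summary["lp_length_ms"])
        ),
    }

    result = PipelineResult(
        config=config, config_hash=chash, calibration=calib,
        unisensory_trials=uni_trials, grid_trials=grid_trials,
        delay_trials=delay_trials, unisensory_probs=uni_probs, windows=windows,
        ic_msi=ic_msi_df, ic_uv=ic_uv_df, fits=fits, delay_summary=delay_summary,
        concentration=conc, report=report,
    )
    if outdir is not None:
        _write_bundle(result, Path(outdir))
    return result


def _write_bundle(result: PipelineResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    trials = pd.concat(
        [result.unisensory_trials, result.grid_trials, result.delay_trials],
        ignore_index=True,
    )
    trials = trials.sort_values(["condition_id", "trial_index"], kind="mergesort")
    trials["config_hash"] = result.config_hash
    trials.to_csv(outdir / "trials.csv", index=False)
    for name, df in (
        ("calibration", result.calibration),
        ("unisensory_probabilities", result.unisensory_probs),
        ("delay_summary", result.delay_summary),
        ("msi_concentration", result.concentration),
    ):
        out = df.copy()
        out["config_hash"] = result.config_hash
        out.to_csv(outdir / f"{name}.csv", index=False)
    ic = pd.concat([result.ic_msi, result.ic_uv], ignore_index=True)
    ic["config_hash"] = result.config_hash
    ic.to_csv(outdir / "ic_matrix.csv", index=False)
    (outdir / "fits.json").write_text(json.dumps(result.fits, indent=2))
    (outdir / "report.json").write_text(json.dumps(result.report, indent=2))
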