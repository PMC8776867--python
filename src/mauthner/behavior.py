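"""Synthetic behavioral-trial generator and parameter-recovery harness.

Generates trial tables with the statistical structure of the goldfish escape
study — prior motor state (freezing vs not), intensity-dependent C-start
probability, intensity-independent alarm probability, per-trial habituation,
modality-specific response-time distributions and auditory-locked multisensory
response times — so the analysis stack can be exercised end to end without the
original recordings, and so that known generator parameters can be recovered
from the generated tables.

Response-time conventions follow the study: times are milliseconds relative to
the end of visual expansion, except auditory-only trials, whose times are
relative to the auditory onset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "LogisticLink",
    "BehaviorConfig",
    "generate_trials",
    "as_analysis_tables",
    "recover_parameters",
]

N_LEVELS = 6


def _logit(p: float) -> float:
    return math.log(p / (1.0 - p))


def _expit(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


@dataclass
class LogisticLink:
    """Logistic curve through (level 1, p_lo) and (level 6, p_hi).

    Probabilities strictly inside (0, 1); a flat link (p_lo == p_hi) encodes
    an intensity-independent response.
    """

    p_lo: float
    p_hi: float

    def __post_init__(self) -> None:
        if not (0 < self.p_lo < 1 and 0 < self.p_hi < 1):
            raise ValueError("link probabilities must lie in (0, 1)")
        if self.p_hi < self.p_lo:
            raise ValueError("link must be non-decreasing in level")

    def probability(self, level: np.ndarray | int) -> np.ndarray | float:
        lo, hi = _logit(self.p_lo), _logit(self.p_hi)
        frac = (np.asarray(level, dtype=float) - 1.0) / (N_LEVELS - 1)
        out = 1.0 / (1.0 + np.exp(-(lo + (hi - lo) * frac)))
        return out if out.ndim else float(out)

    def table(self) -> np.ndarray:
        """Per-level probabilities for levels 1..6."""
        return self.probability(np.arange(1, N_LEVELS + 1))


@dataclass
class BehaviorConfig:
    """Generator configuration; defaults emulate the study conditions."""

    n_animals: int = 180
    trials_range: tuple[int, int] = (9, 13)
    p_freezing_prior: float = 0.367
    visual_link: LogisticLink = field(default_factory=lambda: LogisticLink(0.10, 0.71))
    auditory_link: LogisticLink = field(default_factory=lambda: LogisticLink(0.02, 0.76))
    freezing_scale: float = 1.0 / 3.0   # C-start probability ratio freezing/non-freezing
    p_alarm: float = 0.17               # intensity-independent, non-freezing
    p_alarm_freezing: float = 0.01
    habituation_slope: float = 0.0194   # per-trial fractional decay; (1-d)^12 ~ 0.79
    enhancement: float = 0.4            # super-additivity weight, scaled by (1-pV)(1-pA)
    msi_lock_weight: float = 0.85       # fraction of VA C-starts locked to the pip
    av_delay: float = 160.0             # ms, sound before end of expansion
    msi_width: float = 40.0             # ms
    lp_gap: float = 45.0                # ms kept empty after the MSI window
    rt_visual_mode: float = 130.0       # ms before the +100 ms late edge, at level 1
    rt_visual_sigma: float = 0.8        # log-scale spread
    rt_contrast_shift: float = 0.18     # log-scale left shift per contrast level
    rt_visual_support: tuple[float, float] = (-960.0, 100.0)
    rt_auditory_beta: tuple[float, float] = (2.2, 3.0)
    rt_auditory_base: tuple[float, float] = (4.0, 17.0)   # ms after onset, near speaker
    rt_auditory_support: tuple[float, float] = (4.0, 21.0)
    rt_distance_gain: float = 4.0 / 30.0  # ms extra latency per cm speaker distance
    speaker_distance_range: tuple[float, float] = (0.0, 60.0)
    loom_center_mean: float = 29.4      # cm, thigmotactic mean distance to center
    loom_center_sd: float = 4.8
    modality_weights: Optional[tuple[float, float, float]] = None  # (V, A, VA)
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.p_freezing_prior, self.p_alarm, self.p_alarm_freezing,
                  self.msi_lock_weight):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        if not 0 <= self.habituation_slope < 1:
            raise ValueError("habituation_slope must lie in [0, 1)")
        lo, hi = self.trials_range
        if lo < 1 or hi < lo:
            raise ValueError("invalid trials_range")

    def multisensory_probability(self, p_v: float, p_a: float) -> float:
        """Configured VA C-start probability: probability summation plus an
        inverse-effectiveness-shaped enhancement term."""
        erp = p_v + p_a - p_v * p_a
        boost = self.enhancement * (1.0 - erp) * (1.0 - p_v) * (1.0 - p_a)
        return min(1.0, erp + boost)


def _assign_modalities(
    rng: np.random.Generator, n_trials: int, weights
) -> list[str]:
    """Study protocol: at least one V and one A per animal, remainder VA
    (or drawn from explicit (V, A, VA) weights)."""
    if n_trials < 3:
        raise ValueError(
            "infeasible design: each animal needs at least one V, one A and "
            "one multisensory trial"
        )
    if weights is None:
        rest = ["VA"] * (n_trials - 2)
    else:
        w = np.asarray(weights, dtype=float)
        w = w / w.sum()
        rest = list(rng.choice(["V", "A", "VA"], size=n_trials - 2, p=w))
    mods = ["V", "A"] + rest
    rng.shuffle(mods)
    return mods


def _draw_visual_rt(
    rng: np.random.Generator, cfg: BehaviorConfig, level: int
) -> float:
    """Left-skewed response time tied to the end of expansion; higher contrast
    shifts the distribution earlier (time-mirrored shifted log-normal)."""
    lo, hi = cfg.rt_visual_support
    mode = cfg.rt_visual_mode * math.exp(cfg.rt_contrast_shift * (level - 1))
    mu = math.log(mode) + cfg.rt_visual_sigma**2
    for _ in range(20):
        rt = hi - rng.lognormal(mu, cfg.rt_visual_sigma)
        if rt >= lo:
            return rt
    return lo


def _draw_auditory_latency(
    rng: np.random.Generator, cfg: BehaviorConfig, d_speaker: float
) -> float:
    """Latency after the pip: narrow 4-21 ms with a distance-dependent shift."""
    a, b = cfg.rt_auditory_beta
    base_lo, base_hi = cfg.rt_auditory_base
    lat = base_lo + rng.beta(a, b) * (base_hi - base_lo)
    lat += cfg.rt_distance_gain * d_speaker
    return float(np.clip(lat, *cfg.rt_auditory_support))


def _draw_va_rt(
    rng: np.random.Generator, cfg: BehaviorConfig, level: int, d_speaker: float
) -> float:
    """Multisensory response time: locked to the pip with the configured
    weight, otherwise a visual draw resampled out of the LP gap."""
    onset = -cfg.av_delay
    if rng.random() < cfg.msi_lock_weight:
        return onset + _draw_auditory_latency(rng, cfg, d_speaker)
    gap_lo, gap_hi = onset + cfg.msi_width, onset + cfg.msi_width + cfg.lp_gap
    for _ in range(20):
        rt = _draw_visual_rt(rng, cfg, level)
        if not gap_lo <= rt < gap_hi:
            return rt
    return gap_hi


def generate_trials(
    config: BehaviorConfig, rng: Optional[np.random.Generator] = None
) -> pd.DataFrame:
    """Generate a behavioral trial table; reproducible given ``config.seed``."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    lo, hi = config.trials_range
    decay = 1.0 - config.habituation_slope
    p_v_table = config.visual_link.table()
    p_a_table = config.auditory_link.table()
    rows = []
    for animal in range(config.n_animals):
        n_trials = int(rng.integers(lo, hi + 1))
        mods = _assign_modalities(rng, n_trials, config.modality_weights)
        for trial_index, mod in enumerate(mods, start=1):
            freezing = rng.random() < config.p_freezing_prior
            c_level = int(rng.integers(1, N_LEVELS + 1)) if "V" in mod else None
            a_level = int(rng.integers(1, N_LEVELS + 1)) if "A" in mod else None
            d_loom = float(max(0.0, rng.normal(config.loom_center_mean,
                                               config.loom_center_sd)))
            d_speaker = float(rng.uniform(*config.speaker_distance_range))
            if mod == "V":
                p = float(p_v_table[c_level - 1])
            elif mod == "A":
                p = float(p_a_table[a_level - 1])
            else:
                p = config.multisensory_probability(
                    float(p_v_table[c_level - 1]), float(p_a_table[a_level - 1])
                )
            if freezing:
                p *= config.freezing_scale
            p *= decay ** (trial_index - 1)
            response, rt = "none", np.nan
            if rng.random() < p:
                response = "c_start"
                if mod == "V":
                    rt = _draw_visual_rt(rng, config, c_level)
                elif mod == "A":
                    rt = _draw_auditory_latency(rng, config, d_speaker)
                else:
                    rt = _draw_va_rt(rng, config, c_level, d_speaker)
            elif rng.random() < (
                config.p_alarm_freezing if freezing else config.p_alarm
            ):
                response = "alarm"
            rows.append(
                {
                    "animal_id": animal,
                    "trial_index": trial_index,
                    "prior_state": "freezing" if freezing else "not_freezing",
                    "modality": mod,
                    "contrast_level": c_level,
                    "amplitude_level": a_level,
                    "av_delay": config.av_delay if mod == "VA" else np.nan,
                    "response": response,
                    "response_time": rt,
                    "distance_to_loom_center": d_loom,
                    "distance_to_speaker": d_speaker,
                }
            )
    df = pd.DataFrame(rows)
    df["contrast_level"] = df["contrast_level"].astype("Float64")
    df["amplitude_level"] = df["amplitude_level"].astype("Float64")
    return df


def as_analysis_tables(trials: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a behavioral table into the (unisensory, multisensory) frames the
    msi module consumes.  Auditory-only times stay on the onset axis (pass
    ``auditory_time_base='onset'`` downstream)."""
    uni = trials[trials["modality"].isin(["V", "A"])].copy()
    uni["level"] = np.where(
        uni["modality"] == "V", uni["contrast_level"], uni["amplitude_level"]
    ).astype(float)
    uni["responded"] = uni["response"] == "c_start"
    uni = uni[["modality", "level", "responded", "response_time"]].reset_index(drop=True)
    multi = trials[trials["modality"] == "VA"].copy()
    multi["responded"] = multi["response"] == "c_start"
    multi = multi[
        ["contrast_level", "amplitude_level", "responded", "response_time"]
    ].astype({"contrast_level": float, "amplitude_level": float}).reset_index(drop=True)
    return uni, multi


def _fit_modality_glm(sub: pd.DataFrame) -> dict:
    """Binomial GLM of C-start on intensity level (and prior state when both
    states are present).  Per-level probabilities are model predictions for
    the non-freezing state."""
    y = (sub["response"] == "c_start").to_numpy(dtype=float)
    level = sub["level"].to_numpy(dtype=float)
    freezing = (sub["prior_state"] == "freezing").to_numpy(dtype=float)
    with_state = freezing.std() > 0
    cols = [level, freezing] if with_state else [level]
    X = sm.add_constant(np.column_stack(cols))
    separation = False
    try:
        fit = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        if np.any(np.abs(fit.params) > 15):
            separation = True
    except Exception:
        return {"separation": True}
    ci = fit.conf_int(alpha=0.05)
    levels = np.arange(1, N_LEVELS + 1, dtype=float)
    pred_cols = [levels, np.zeros(N_LEVELS)] if with_state else [levels]
    X_pred = sm.add_constant(np.column_stack(pred_cols), has_constant="add")
    frame = fit.get_prediction(X_pred).summary_frame(alpha=0.05)
    out = {
        "separation": separation,
        "slope": float(fit.params[1]),
        "slope_ci": (float(ci[1][0]), float(ci[1][1])),
        "predicted_p": frame["mean"].to_numpy(),
        "predicted_se": frame["mean_se"].to_numpy(),
    }
    if with_state:
        eta = fit.params[0] + fit.params[1] * 3.5
        out["freezing_coef"] = float(fit.params[2])
        out["freezing_ratio"] = float(_expit(eta + fit.params[2]) / _expit(eta))
    return out


def recover_parameters(trials: pd.DataFrame) -> dict:
    """Recover response-curve parameters from a generated (or real) table.

    Returns per-modality empirical per-level probabilities for non-freezing
    unisensory trials, plus binomial-GLM fits of C-start on level and prior
    state (model-based per-level probabilities with standard errors, slope CI,
    freezing probability ratio, separation flag).
    """
    out = {}
    for mod, key in (("V", "visual"), ("A", "auditory")):
        sub = trials[trials["modality"] == mod].copy()
        if len(sub) == 0:
            continue
        sub["level"] = (
            sub["contrast_level"] if mod == "V" else sub["amplitude_level"]
        ).astype(float)
        nf = sub[sub["prior_state"] == "not_freezing"]
        emp = (
            nf.assign(c=(nf["response"] == "c_start"))
            .groupby("level")["c"]
            .agg(["mean", "count"])
            .rename(columns={"mean": "p_hat", "count": "n"})
            .reset_index()
        )
        emp["se"] = np.sqrt(emp["p_hat"] * (1 - emp["p_hat"]) / emp["n"])
        out[key] = {"empirical": emp, "glm": _fit_modality_glm(sub)}
    out["freezing_fraction"] = float((trials["prior_state"] == "freezing").mean())
    frz = trials["prior_state"] == "freezing"
    c = trials["response"] == "c_start"
    if frz.any() and (~frz).any() and c[~frz].mean() > 0:
        # level assignment is independent of prior state, so the pooled rate
        # ratio estimates the configured multiplicative freezing effect
        out["empirical_freezing_ratio"] = float(c[frz].mean() / c[~frz].mean())
    out["n_trials"] = int(len(trials))
    return out
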