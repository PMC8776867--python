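"""Multisensory-integration statistics: ERP, Integration Coefficient,
response-time windows and inverse-effectiveness fits.

The framework compares the Observed Response Probability (ORP) of an
audiovisual combination with the Expected Response Probability (ERP) under
independent processing of the two channels,

    ERP = P(V) + P(A) - P(V) * P(A),
    IC  = (ORP - ERP) / (ORP + ERP)  in [-1, 1],

where IC > 0 means multisensory enhancement beyond probability summation and
IC < 0 means suppression.

Response times of audiovisual trials fall into four windows: PRE (before the
auditory onset), MSI (the 40 ms multisensory-integration window after onset),
LP (a low-probability gap) and UV (late unisensory-visual responses near the
end of the loom expansion).  The LP/UV boundary is empirical: the 5% and 95%
quantiles of the pooled post-MSI response times delimit the UV window.

Window-restricted ICs use window-restricted probabilities on both sides by
default: the ORP of a window counts trials responding *in that window* over
all trials of the combination (a trial that escaped during MSI cannot respond
again later — the fish performs a single C-start), and the unisensory
probabilities entering the ERP are restricted to the same window.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "IntegrationResult",
    "ResponseWindows",
    "ProportionEstimate",
    "expected_response_probability",
    "integration_coefficient",
    "classify_response",
    "classify_responses",
    "fit_uv_boundaries",
    "lp_interval_length",
    "proportion_estimate",
    "unisensory_probabilities",
    "ic_matrix",
    "mean_ic",
    "inverse_effectiveness_fit",
]


@dataclass
class ProportionEstimate:
    """A proportion with its binomial standard error."""

    p: float
    se: float
    n: int


def proportion_estimate(k: int, n: int) -> ProportionEstimate:
    if n < 1 or not 0 <= k <= n:
        raise ValueError("require 0 <= k <= n, n >= 1")
    p = k / n
    return ProportionEstimate(p=p, se=float(np.sqrt(p * (1 - p) / n)), n=n)


@dataclass
class IntegrationResult:
    """ORP/ERP/IC triple for one audiovisual combination and window."""

    p_visual: float
    p_auditory: float
    erp: float
    orp: float
    ic: float
    n_trials: int
    window: str = "all"


@dataclass
class ResponseWindows:
    """Window definitions on the response-time axis (ms, relative to the end
    of visual expansion unless stated otherwise).

    ``uv_start``/``uv_end`` are the empirical LP/UV boundaries; fit them with
    :func:`fit_uv_boundaries` before classifying LP vs UV.
    """

    auditory_onset: float
    msi_width: float = 40.0
    lp_uv_quantiles: tuple[float, float] = (0.05, 0.95)
    visual_end: float = 0.0
    uv_start: Optional[float] = None
    uv_end: Optional[float] = None

    def __post_init__(self) -> None:
        if self.msi_width <= 0:
            raise ValueError("msi_width must be positive")
        q0, q1 = self.lp_uv_quantiles
        if not 0 < q0 < q1 < 1:
            raise ValueError("quantiles must satisfy 0 < q0 < q1 < 1")

    @property
    def msi_end(self) -> float:
        return self.auditory_onset + self.msi_width


def expected_response_probability(p_v: float, p_a: float) -> float:
    """ERP under the addition rule for independent events."""
    if not (0 <= p_v <= 1 and 0 <= p_a <= 1):
        raise ValueError("probabilities must lie in [0, 1]")
    return p_v + p_a - p_v * p_a


def integration_coefficient(orp: float, erp: float) -> float:
    """Integration Coefficient (ORP - ERP) / (ORP + ERP)."""
    if not (0 <= orp <= 1 and 0 <= erp <= 1):
        raise ValueError("probabilities must lie in [0, 1]")
    if orp + erp == 0:
        raise ValueError("IC undefined: ORP + ERP = 0")
    return (orp - erp) / (orp + erp)


def fit_uv_boundaries(
    times: Iterable[float], windows: ResponseWindows
) -> ResponseWindows:
    """Set the LP/UV boundaries from the pooled post-MSI response times."""
    t = np.asarray(list(times), dtype=float)
    t = t[np.isfinite(t)]
    post = t[t >= windows.msi_end]
    if post.size == 0:
        # no late responses at all: UV window degenerates to the MSI end
        return replace(windows, uv_start=windows.msi_end, uv_end=windows.msi_end)
    q0, q1 = windows.lp_uv_quantiles
    lo, hi = np.quantile(post, [q0, q1])
    return replace(windows, uv_start=float(lo), uv_end=float(hi))


def lp_interval_length(windows: ResponseWindows) -> float:
    """Length (ms) of the low-probability gap between MSI end and first UV
    responses; 0 when no post-MSI responses were observed."""
    if windows.uv_start is None:
        raise ValueError("fit_uv_boundaries must be applied first")
    return max(0.0, windows.uv_start - windows.msi_end)


def classify_response(t_resp: float, windows: ResponseWindows) -> str:
    """Classify one response time into PRE | MSI | LP | UV."""
    if t_resp < windows.auditory_onset:
        return "PRE"
    if t_resp < windows.msi_end:
        return "MSI"
    if windows.uv_start is None:
        raise ValueError("LP/UV boundary not fitted; call fit_uv_boundaries")
    return "LP" if t_resp < windows.uv_start else "UV"


def classify_responses(
    times: Iterable[float], windows: ResponseWindows, fit: bool = True
) -> tuple[np.ndarray, ResponseWindows]:
    """Vectorized classification; optionally fits the LP/UV boundary on the
    pooled post-MSI times first.  Every time receives exactly one label."""
    t = np.asarray(list(times), dtype=float)
    if fit or windows.uv_start is None:
        windows = fit_uv_boundaries(t, windows)
    labels = np.where(
        t < windows.auditory_onset,
        "PRE",
        np.where(t < windows.msi_end, "MSI", np.where(t < windows.uv_start, "LP", "UV")),
    )
    return labels, windows


def _window_mask(t: np.ndarray, window: str, windows: ResponseWindows) -> np.ndarray:
    finite = np.isfinite(t)
    if window == "all":
        return finite
    if window == "MSI":
        return finite & (t >= windows.auditory_onset) & (t < windows.msi_end)
    if window == "UV":
        if windows.uv_start is None or windows.uv_end is None:
            raise ValueError("UV window requires fitted LP/UV boundaries")
        return finite & (t >= windows.uv_start) & (t <= windows.uv_end)
    raise ValueError(f"unknown window {window!r}")


def unisensory_probabilities(
    trials: pd.DataFrame,
    windows: Optional[ResponseWindows] = None,
    auditory_time_base: str = "visual_end",
) -> pd.DataFrame:
    """Per-level unisensory response probabilities, whole-trial and windowed.

    ``trials`` needs columns ``modality`` ('V' or 'A'), ``level``,
    ``responded`` and ``response_time``.  ``auditory_time_base`` says whether
    auditory-only response times are on the shared visual-end axis (simulator
    convention) or relative to the auditory onset (behavioral convention).
    """
    required = {"modality", "level", "responded", "response_time"}
    if not required.issubset(trials.columns):
        raise ValueError(f"trials table needs columns {sorted(required)}")
    rows = []
    for (mod, level), grp in trials.groupby(["modality", "level"], sort=True):
        n = len(grp)
        t = grp["response_time"].to_numpy(dtype=float)
        responded = grp["responded"].to_numpy(dtype=bool)
        t = np.where(responded, t, np.nan)
        if mod == "A" and auditory_time_base == "onset" and windows is not None:
            t = t + windows.auditory_onset
        row = {
            "modality": mod,
            "level": int(level),
            "n": n,
            "p": responded.mean(),
            "se": float(np.sqrt(responded.mean() * (1 - responded.mean()) / n)),
        }
        if windows is not None:
            row["p_msi"] = _window_mask(t, "MSI", windows).mean()
            if windows.uv_start is not None and windows.uv_end is not None:
                row["p_uv"] = _window_mask(t, "UV", windows).mean()
            else:
                row["p_uv"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def _unisensory_lookup(unisensory: pd.DataFrame, window: str, window_erp: bool):
    col = "p"
    if window_erp and window in ("MSI", "UV"):
        col = "p_msi" if window == "MSI" else "p_uv"
        if col not in unisensory.columns:
            raise ValueError(f"unisensory table lacks windowed column {col!r}")
    lut = {}
    for _, r in unisensory.iterrows():
        lut[(r["modality"], int(r["level"]))] = (float(r[col]), int(r["n"]))
    return lut


def ic_matrix(
    trials: pd.DataFrame,
    unisensory: pd.DataFrame,
    window: str = "MSI",
    windows: Optional[ResponseWindows] = None,
    window_erp: bool = True,
) -> pd.DataFrame:
    """Integration Coefficients for every audiovisual combination in ``trials``.

    ``trials`` needs columns ``contrast_level``, ``amplitude_level``,
    ``responded`` and ``response_time`` (visual-end axis).  The ORP of a window
    counts trials responding in that window over all trials of the
    combination.  Undefined ICs (ORP + ERP = 0, or an empty UV window) are
    reported as missing, never imputed.
    """
    required = {"contrast_level", "amplitude_level", "responded", "response_time"}
    if not required.issubset(trials.columns):
        raise ValueError(f"trials table needs columns {sorted(required)}")
    if window != "all" and windows is None:
        raise ValueError("windowed ICs require a ResponseWindows")
    lut = _unisensory_lookup(unisensory, window, window_erp)
    rows = []
    grouped = trials.groupby(["contrast_level", "amplitude_level"], sort=True)
    for (ci, ai), grp in grouped:
        ci, ai = int(ci), int(ai)
        try:
            p_v, n_v = lut[("V", ci)]
            p_a, n_a = lut[("A", ai)]
        except KeyError as exc:
            raise ValueError(f"missing unisensory probability for level {exc}") from exc
        n = len(grp)
        t = grp["response_time"].to_numpy(dtype=float)
        t = np.where(grp["responded"].to_numpy(dtype=bool), t, np.nan)
        orp = float(_window_mask(t, window, windows).mean()) if window != "all" else float(
            grp["responded"].mean()
        )
        erp = expected_response_probability(p_v, p_a)
        defined = (orp + erp) > 0 and not (window == "UV" and orp == 0)
        ic = (orp - erp) / (orp + erp) if defined else np.nan
        rows.append(
            {
                "contrast_level": ci,
                "amplitude_level": ai,
                "window": window,
                "p_v": p_v,
                "p_a": p_a,
                "n_v": n_v,
                "n_a": n_a,
                "erp": erp,
                "orp": orp,
                "n": n,
                "ic": ic,
                "defined": defined,
            }
        )
    return pd.DataFrame(rows)


def mean_ic(ic_table: pd.DataFrame) -> tuple[float, float]:
    """Mean IC over the defined cells with a delta-method standard error.

    The SE propagates the binomial noise of each cell's ORP (independent
    across cells) and of each unisensory level probability (shared across the
    six cells of its row or column).
    """
    d = ic_table.dropna(subset=["ic"]).reset_index(drop=True)
    if len(d) == 0:
        raise ValueError("no defined ICs")
    m = float(d["ic"].mean())
    k = len(d)
    denom = (d["orp"] + d["erp"]) ** 2
    w_o = 2.0 * d["erp"] / denom    # dIC/dORP
    w_e = -2.0 * d["orp"] / denom   # dIC/dERP
    var = float(((w_o**2) * d["orp"] * (1 - d["orp"]) / d["n"]).sum()) / k**2
    for levcol, pcol, ncol, other_p in (
        ("contrast_level", "p_v", "n_v", "p_a"),
        ("amplitude_level", "p_a", "n_a", "p_v"),
    ):
        dEdp = 1.0 - d[other_p]
        for _, idx in d.groupby(levcol).groups.items():
            coef = float((w_e.loc[idx] * dEdp.loc[idx]).sum())
            p_l = float(d.loc[idx, pcol].iloc[0])
            n_l = float(d.loc[idx, ncol].iloc[0])
            var += coef**2 * p_l * (1 - p_l) / n_l / k**2
    return m, float(np.sqrt(var))


def inverse_effectiveness_fit(
    ic_table: pd.DataFrame,
    amplitude_values: Optional[Mapping[int, float]] = None,
    contrast_values: Optional[Mapping[int, float]] = None,
) -> dict:
    """OLS slopes of IC on auditory amplitude and on visual contrast.

    Levels map to physical values through the optional dictionaries (defaults
    to the level rank 1..6).  Returns, per predictor, the slope, its 95%
    confidence interval and p-value.  Inverse effectiveness shows as a
    negative slope whose CI excludes zero.
    """
    d = ic_table.dropna(subset=["ic"])
    if len(d) < 3:
        raise ValueError("need at least 3 defined ICs")
    out = {}
    for name, levcol, mapping in (
        ("amplitude", "amplitude_level", amplitude_values),
        ("contrast", "contrast_level", contrast_values),
    ):
        x = d[levcol].astype(float)
        if mapping is not None:
            x = d[levcol].map(lambda l: mapping[int(l)]).astype(float)
        if np.ptp(x.to_numpy()) == 0:
            raise ValueError(f"rank-deficient design: {name} values are constant")
        X = sm.add_constant(x.to_numpy())
        fit = sm.OLS(d["ic"].to_numpy(), X).fit()
        ci = fit.conf_int(alpha=0.05)[1]
        out[name] = {
            "slope": float(fit.params[1]),
            "ci_low": float(ci[0]),
            "ci_high": float(ci[1]),
            "pvalue": float(fit.pvalues[1]),
            "n": int(len(d)),
        }
    return out
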