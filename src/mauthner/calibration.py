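"""Fit input-current intensities so that simulated unisensory response
probabilities match behavioral targets.

The model's response probability is monotone in stimulus intensity, so each of
the six per-modality intensities is found by bisection on Monte-Carlo
estimates.  All evaluations within one fit reuse a single frozen set of
per-trial random draws (common random numbers), which makes the estimated
probability exactly monotone in intensity and the bisection deterministic.

For the auditory pulse an analytic oracle exists: the pulse (20 ms) vastly
outlasts the membrane time constant (0.5 ms), so the membrane reaches its
steady state R_in * a_max * R2 and the cell fires iff
R2 > dV_th / (R_in * a_max), giving

    P(spike) = max(0, 1 - dV_th / (R_in * a_max)),  dV_th = 15 mV.

The analytic form seeds the auditory search and serves as an independent
cross-check of the simulator in the tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .lif import (
    AuditoryInputSpec,
    MauthnerParams,
    TrialConfig,
    VisualInputSpec,
    _draw_trial_randomness,
    _simulate_trials,
)

__all__ = [
    "CalibrationTarget",
    "CalibrationResult",
    "DEFAULT_VISUAL_TARGETS",
    "DEFAULT_AUDITORY_TARGETS",
    "AUDITORY_BOUNDS_NA",
    "VISUAL_BOUNDS_NA",
    "analytic_auditory_probability",
    "calibrate_intensity",
    "calibrate_all",
    "freezing_current_for_halving",
]

#: Behavioral unisensory C-start probability ranges, interpolated over the six
#: levels (visual 10-71%, auditory 0-76%).  Exact per-level values were not
#: reported, so these are configuration defaults, not measured values.
DEFAULT_VISUAL_TARGETS = tuple(np.round(np.linspace(0.10, 0.71, 6), 4))
DEFAULT_AUDITORY_TARGETS = tuple(np.round(np.linspace(0.0, 0.76, 6), 4))

AUDITORY_BOUNDS_NA = (75.0, 250.0)
VISUAL_BOUNDS_NA = (90.0, 220.0)


@dataclass
class CalibrationTarget:
    """Per-modality calibration problem: six target probabilities and bounds."""

    modality: str  # "visual" | "auditory"
    target_probs: Sequence[float] = ()
    intensity_bounds: tuple[float, float] = ()
    tolerance: float = 0.02
    n_eval: int = 2000

    def __post_init__(self) -> None:
        if self.modality not in ("visual", "auditory"):
            raise ValueError("modality must be 'visual' or 'auditory'")
        if not self.target_probs:
            self.target_probs = (
                DEFAULT_VISUAL_TARGETS
                if self.modality == "visual"
                else DEFAULT_AUDITORY_TARGETS
            )
        if not self.intensity_bounds:
            self.intensity_bounds = (
                VISUAL_BOUNDS_NA if self.modality == "visual" else AUDITORY_BOUNDS_NA
            )
        probs = np.asarray(self.target_probs, dtype=float)
        if np.any((probs < 0) | (probs >= 1)):
            raise ValueError("target probabilities must lie in [0, 1)")
        if np.any(np.diff(probs) < 0):
            raise ValueError("target probabilities must be non-decreasing")
        if self.intensity_bounds[0] <= 0 or self.intensity_bounds[1] <= self.intensity_bounds[0]:
            raise ValueError("bounds must be positive and increasing")


@dataclass
class CalibrationResult:
    """One fitted intensity with its achieved-probability diagnostics."""

    modality: str
    target_p: float
    intensity: float      # nA
    achieved_p: float
    se: float
    converged: bool
    clipped: bool         # target unreachable inside the bounds
    n_eval: int


def analytic_auditory_probability(a_max: float, params: MauthnerParams) -> float:
    """Closed-form auditory-only response probability (pulse >> tau_m)."""
    if a_max < 0:
        raise ValueError("a_max must be non-negative")
    if a_max == 0:
        return 0.0
    return float(max(0.0, 1.0 - params.threshold_gap / (params.r_in * a_max)))


def freezing_current_for_halving(
    params: MauthnerParams, p_baseline: float = 0.38
) -> float:
    """Constant inhibitory current (negative, nA) halving a mid-intensity
    auditory response probability ``p_baseline``; the TrialConfig default."""
    if not 0 < p_baseline < 1:
        raise ValueError("p_baseline must lie in (0, 1)")
    a_r = params.threshold_gap / (1.0 - p_baseline)  # drive (mV) giving p_baseline
    return -a_r * p_baseline / (2.0 * params.r_in)


class _FrozenEvaluator:
    """Monte-Carlo probability of a unisensory condition under frozen draws."""

    def __init__(
        self,
        modality: str,
        params: MauthnerParams,
        config: TrialConfig,
        n_eval: int,
        seed,
    ) -> None:
        self.modality = modality
        self.params = params
        self.config = config
        self.n_eval = n_eval
        rng = np.random.default_rng(seed)
        vproto = VisualInputSpec(v_max=1.0) if modality == "visual" else None
        self.r1, self.r2, self.s = _draw_trial_randomness(rng, n_eval, vproto)
        if vproto is None:
            self.s = np.full(n_eval, 100.0)

    def __call__(self, intensity: float) -> float:
        if self.modality == "visual":
            vspec, aspec = VisualInputSpec(v_max=intensity), None
        else:
            vspec, aspec = None, AuditoryInputSpec(a_max=intensity)
        spiked, _ = _simulate_trials(
            vspec, aspec, self.config, self.params, self.r1, self.r2, self.s
        )
        return float(spiked.mean())


def calibrate_intensity(
    target_p: float,
    modality: str,
    params: MauthnerParams,
    config: Optional[TrialConfig] = None,
    bounds: Optional[tuple[float, float]] = None,
    tolerance: float = 0.02,
    n_eval: int = 2000,
    seed=0,
    max_iter: int = 25,
    evaluator: Optional[_FrozenEvaluator] = None,
) -> CalibrationResult:
    """Find the intensity (nA) whose unisensory response probability matches
    ``target_p`` within ``tolerance``, by bisection inside ``bounds``.

    If the target is unreachable inside the bounds the nearest bound is
    returned with ``clipped=True``.
    """
    if not 0 <= target_p < 1:
        raise ValueError("target_p must lie in [0, 1)")
    if modality not in ("visual", "auditory"):
        raise ValueError("modality must be 'visual' or 'auditory'")
    if config is None:
        config = TrialConfig()
    if bounds is None:
        bounds = VISUAL_BOUNDS_NA if modality == "visual" else AUDITORY_BOUNDS_NA
    if evaluator is None:
        evaluator = _FrozenEvaluator(modality, params, config, n_eval, seed)

    lo, hi = bounds
    p_lo, p_hi = evaluator(lo), evaluator(hi)
    se = lambda p: float(np.sqrt(max(p * (1 - p), 1e-12) / n_eval))

    def _result(intensity, p, converged, clipped):
        return CalibrationResult(
            modality=modality, target_p=target_p, intensity=float(intensity),
            achieved_p=float(p), se=se(p), converged=converged, clipped=clipped,
            n_eval=n_eval,
        )

    if target_p <= p_lo:
        return _result(lo, p_lo, abs(p_lo - target_p) <= tolerance, target_p < p_lo - tolerance)
    if target_p >= p_hi:
        return _result(hi, p_hi, abs(p_hi - target_p) <= tolerance, target_p > p_hi + tolerance)

    # analytic seed narrows the auditory bracket before bisection
    if modality == "auditory" and target_p > 0:
        guess = params.threshold_gap / (params.r_in * (1.0 - target_p))
        if lo < guess < hi:
            p_guess = evaluator(guess)
            if p_guess < target_p:
                lo, p_lo = guess, p_guess
            else:
                hi, p_hi = guess, p_guess

    mid, p_mid = lo, p_lo
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        p_mid = evaluator(mid)
        if abs(p_mid - target_p) <= tolerance:
            return _result(mid, p_mid, True, False)
        if p_mid < target_p:
            lo = mid
        else:
            hi = mid
    return _result(mid, p_mid, abs(p_mid - target_p) <= tolerance, False)


def calibrate_all(
    params: MauthnerParams,
    config: Optional[TrialConfig] = None,
    visual: Optional[CalibrationTarget] = None,
    auditory: Optional[CalibrationTarget] = None,
    seed: int | np.random.SeedSequence = 0,
) -> pd.DataFrame:
    """Calibrate all six auditory and six visual intensities.

    Returns a table with one row per (modality, level) carrying the target,
    the fitted intensity (nA) and achieved-vs-target diagnostics.  Identical
    seeds give identical tables.
    """
    if config is None:
        config = TrialConfig()
    visual = visual or CalibrationTarget("visual")
    auditory = auditory or CalibrationTarget("auditory")
    ss = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    seed_v, seed_a = ss.spawn(2)
    rows = []
    for target, child in ((visual, seed_v), (auditory, seed_a)):
        evaluator = _FrozenEvaluator(
            target.modality, params, config, target.n_eval, child
        )
        for level, p in enumerate(target.target_probs, start=1):
            res = calibrate_intensity(
                p,
                target.modality,
                params,
                config,
                bounds=tuple(target.intensity_bounds),
                tolerance=target.tolerance,
                n_eval=target.n_eval,
                evaluator=evaluator,
            )
            rows.append(
                {
                    "modality": target.modality,
                    "level": level,
                    "target_p": res.target_p,
                    "intensity_nA": res.intensity,
                    "achieved_p": res.achieved_p,
                    "se": res.se,
                    "converged": res.converged,
                    "clipped": res.clipped,
                }
            )
    return pd.DataFrame(rows)
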