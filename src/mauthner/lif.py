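"""Single-compartment Mauthner-cell model driven by visual and auditory currents.

The Mauthner cell is modelled as a leaky integrate-and-fire (LIF) unit,

    tau_m * dV/dt = -(V - V_rest) + R_in * I_syn(t),

with a hard threshold and single-spike semantics: a trial ends (behaviourally,
a C-start is triggered) at the first threshold crossing.  The "visual" input is
a slow ramp that peaks at the end of the simulated loom expansion,

    v(t) = e * v_max * (s - t') / (s * exp((s - t') / s)),   t' = t - t_peak,

whose slope constant ``s`` is redrawn every trial from a Gamma distribution
(mean 200 ms, s.d. 150 ms); the "auditory" input is a 20 ms square current
pulse.  Both peak amplitudes are scaled per trial by independent multipliers
R1, R2 ~ Uniform(0, 1], which is the only other source of stochasticity.

Membrane integration uses the exact exponential update for piecewise-constant
current, so trajectories agree with the closed-form solution at every step
boundary regardless of the step size.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np
import pandas as pd
from scipy.signal import lfilter

__all__ = [
    "MauthnerParams",
    "VisualInputSpec",
    "AuditoryInputSpec",
    "TrialConfig",
    "TrialResult",
    "ConditionSummary",
    "visual_current",
    "auditory_current",
    "step_membrane",
    "run_trial",
    "run_condition",
]

InhibitionMode = Literal["none", "feedforward", "freezing"]

#: Latency of feedforward inhibition relative to the excitatory inputs, ms.
FEEDFORWARD_DELAY_MS = 7.0


@dataclass
class MauthnerParams:
    """Membrane constants of the model Mauthner cell.

    ``r_in`` sets the current-to-voltage scale and is a free calibration
    parameter; the default 0.2 MOhm places the 75 nA auditory floor exactly at
    the 15 mV threshold gap (weakest pulse never fires).
    """

    v_rest: float = -80.0       # mV
    v_reset: float = -80.0      # mV
    v_threshold: float = -65.0  # mV
    tau_m: float = 0.5          # ms
    r_in: float = 0.2           # MOhm; mV per nA
    dt: float = 0.1             # ms

    def __post_init__(self) -> None:
        if not self.v_threshold > self.v_rest:
            raise ValueError("v_threshold must exceed v_rest")
        if self.tau_m <= 0:
            raise ValueError("tau_m must be positive")
        if not 0 < self.dt <= self.tau_m:
            raise ValueError("dt must satisfy 0 < dt <= tau_m")

    @property
    def threshold_gap(self) -> float:
        """Voltage distance from rest to threshold, mV."""
        return self.v_threshold - self.v_rest


@dataclass
class VisualInputSpec:
    """Ramped 'visual' input current ending (peaking) at ``t_peak``.

    ``t_peak`` defaults to the trial's ``visual_end`` when left unset.
    """

    v_max: float                # nA, peak current at R1 = 1
    s_mean: float = 200.0       # ms, Gamma mean of the slope constant
    s_sd: float = 150.0         # ms, Gamma s.d. of the slope constant
    t_peak: Optional[float] = None  # ms within trial

    def __post_init__(self) -> None:
        if self.v_max < 0:
            raise ValueError("v_max must be non-negative")
        if self.s_mean <= 0 or self.s_sd <= 0:
            raise ValueError("slope parameters must be positive")

    @property
    def gamma_shape(self) -> float:
        return (self.s_mean / self.s_sd) ** 2

    @property
    def gamma_scale(self) -> float:
        return self.s_sd**2 / self.s_mean


@dataclass
class AuditoryInputSpec:
    """Square 'auditory' current pulse; half-open support [onset, onset+duration).

    ``onset`` defaults to ``visual_end - av_delay`` of the trial when unset.
    """

    a_max: float                # nA, pulse amplitude at R2 = 1
    duration: float = 20.0      # ms
    onset: Optional[float] = None  # ms within trial

    def __post_init__(self) -> None:
        if self.a_max < 0:
            raise ValueError("a_max must be non-negative")
        if self.duration <= 0:
            raise ValueError("duration must be positive")


@dataclass
class TrialConfig:
    """Timing and circuit-variant configuration of one simulated trial."""

    duration: float = 1300.0        # ms
    visual_end: float = 1000.0      # ms; end of loom expansion
    av_delay: float = 160.0         # ms; positive = sound leads the visual end
    inhibition_mode: InhibitionMode = "none"
    freezing_current: float = -23.0  # nA; constant inhibitory drive
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if not 0 < self.visual_end <= self.duration:
            raise ValueError("require 0 < visual_end <= duration")
        if self.inhibition_mode not in ("none", "feedforward", "freezing"):
            raise ValueError(f"unknown inhibition_mode {self.inhibition_mode!r}")


@dataclass
class TrialResult:
    """Outcome of a single trial.

    ``spike_time`` is measured relative to the end of visual expansion
    (negative = before the end); it is NaN when no spike occurred.
    """

    spiked: bool
    spike_time: float
    r1: float
    r2: float
    s_draw: float


@dataclass
class ConditionSummary:
    """Monte-Carlo summary of one stimulus condition."""

    p: float
    se: float
    n_trials: int
    spiked: np.ndarray
    spike_times: np.ndarray  # ms relative to visual_end; NaN where no spike
    r1: np.ndarray
    r2: np.ndarray
    s_draw: np.ndarray

    @property
    def valid_spike_times(self) -> np.ndarray:
        return self.spike_times[self.spiked]

    def to_frame(
        self,
        condition_id: str,
        v_max: float,
        a_max: float,
        config: TrialConfig,
        seed: Optional[int] = None,
    ) -> pd.DataFrame:
        """Per-trial table in the package's standard CSV schema."""
        return pd.DataFrame(
            {
                "condition_id": condition_id,
                "v_max_nA": v_max,
                "a_max_nA": a_max,
                "av_delay_ms": config.av_delay,
                "inhibition_mode": config.inhibition_mode,
                "seed": seed if seed is not None else config.seed,
                "trial_index": np.arange(self.n_trials),
                "r1": self.r1,
                "r2": self.r2,
                "s_ms": self.s_draw,
                "spiked": self.spiked,
                "spike_time_ms": self.spike_times,
            }
        )


def visual_current(
    t: np.ndarray | float,
    spec: VisualInputSpec,
    s_draw: Optional[float] = None,
    r1: float = 1.0,
    t_peak: Optional[float] = None,
) -> np.ndarray | float:
    """Ramped visual input current at time ``t`` (ms), in nA.

    With u = (s - t')/s + 1 measured from the peak, the ramp is
    ``r1 * v_max * u * exp(1 - u)``: zero far before the stimulus, rising
    monotonically to ``r1 * v_max`` at the peak, and truncated at zero where
    the printed form would turn negative (beyond one slope constant past the
    peak).
    """
    s = spec.s_mean if s_draw is None else s_draw
    if s <= 0:
        raise ValueError("slope draw must be positive")
    peak = t_peak if t_peak is not None else spec.t_peak
    if peak is None:
        raise ValueError("t_peak not set on spec and not provided")
    u = (s + peak - np.asarray(t, dtype=float)) / s
    u = np.maximum(u, 0.0)
    out = r1 * spec.v_max * u * np.exp(1.0 - u)
    return out if out.ndim else float(out)


def auditory_current(
    t: np.ndarray | float,
    spec: AuditoryInputSpec,
    r2: float = 1.0,
    onset: Optional[float] = None,
) -> np.ndarray | float:
    """Square auditory pulse current at time ``t`` (ms), in nA."""
    t0 = onset if onset is not None else spec.onset
    if t0 is None:
        raise ValueError("onset not set on spec and not provided")
    t = np.asarray(t, dtype=float)
    out = np.where((t >= t0) & (t < t0 + spec.duration), r2 * spec.a_max, 0.0)
    return out if out.ndim else float(out)


def step_membrane(v: float, i_total: float, params: MauthnerParams) -> float:
    """Advance the membrane one step ``dt`` under constant current (exact update)."""
    v_inf = params.v_rest + params.r_in * i_total
    return v_inf + (v - v_inf) * np.exp(-params.dt / params.tau_m)


def _effective_onset(aspec: AuditoryInputSpec, config: TrialConfig) -> float:
    if aspec.onset is not None:
        return aspec.onset
    return config.visual_end - config.av_delay


def _simulate_trials(
    vspec: Optional[VisualInputSpec],
    aspec: Optional[AuditoryInputSpec],
    config: TrialConfig,
    params: MauthnerParams,
    r1: np.ndarray,
    r2: np.ndarray,
    s_draw: np.ndarray,
    chunk: int = 256,
) -> tuple[np.ndarray, np.ndarray]:
    """Integrate a batch of trials with given per-trial random draws.

    Returns ``(spiked, spike_times)`` with spike times relative to
    ``config.visual_end``.  Current is held constant over each step (sampled at
    the left edge); threshold is checked at step boundaries and the spike time
    is the first boundary with V >= threshold.
    """
    if vspec is None and aspec is None:
        raise ValueError("at least one input (visual or auditory) is required")
    n = len(r1)
    dt = params.dt
    n_steps = int(round(config.duration / dt))
    t = np.arange(n_steps) * dt  # left edges
    decay = np.exp(-dt / params.tau_m)
    t_peak = None
    if vspec is not None:
        t_peak = vspec.t_peak if vspec.t_peak is not None else config.visual_end
    onset = _effective_onset(aspec, config) if aspec is not None else None
    shift = int(round(FEEDFORWARD_DELAY_MS / dt))

    spiked = np.zeros(n, dtype=bool)
    spike_times = np.full(n, np.nan)
    for lo in range(0, n, chunk):
        hi = min(lo + chunk, n)
        drive = np.zeros((hi - lo, n_steps))
        if vspec is not None and vspec.v_max > 0:
            s = s_draw[lo:hi, None]
            u = np.maximum((s + t_peak - t[None, :]) / s, 0.0)
            drive += r1[lo:hi, None] * vspec.v_max * u * np.exp(1.0 - u)
        if aspec is not None and aspec.a_max > 0:
            mask = (t >= onset) & (t < onset + aspec.duration)
            drive += r2[lo:hi, None] * aspec.a_max * mask[None, :]
        if config.inhibition_mode == "feedforward":
            # mirror of the excitatory inputs, negated and delayed
            drive[:, shift:] -= drive[:, : n_steps - shift].copy()
        elif config.inhibition_mode == "freezing":
            drive += config.freezing_current
        b = (params.v_rest + params.r_in * drive) * (1.0 - decay)
        zi = np.full((hi - lo, 1), decay * params.v_rest)
        v, _ = lfilter([1.0], [1.0, -decay], b, axis=1, zi=zi)
        crossed = v >= params.v_threshold
        any_cross = crossed.any(axis=1)
        first = crossed.argmax(axis=1)
        spiked[lo:hi] = any_cross
        spike_times[lo:hi] = np.where(
            any_cross, (first + 1) * dt - config.visual_end, np.nan
        )
    return spiked, spike_times


def _draw_trial_randomness(
    rng: np.random.Generator, n: int, vspec: Optional[VisualInputSpec]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-trial multipliers R1, R2 ~ U(0, 1] and slope draws s ~ Gamma."""
    r1 = 1.0 - rng.random(n)
    r2 = 1.0 - rng.random(n)
    if vspec is not None:
        s = rng.gamma(vspec.gamma_shape, vspec.gamma_scale, n)
        s = np.maximum(s, 1e-6)
    else:
        s = np.full(n, np.nan)
    return r1, r2, s


def run_trial(
    vspec: Optional[VisualInputSpec],
    aspec: Optional[AuditoryInputSpec],
    config: TrialConfig,
    params: MauthnerParams,
    rng: np.random.Generator,
) -> TrialResult:
    """Simulate a single trial, drawing R1, R2 and s from ``rng``."""
    if vspec is None and aspec is None:
        raise ValueError("at least one input (visual or auditory) is required")
    r1, r2, s = _draw_trial_randomness(rng, 1, vspec)
    if vspec is None:
        s = np.full(1, 100.0)  # placeholder; unused without a visual input
    spiked, times = _simulate_trials(vspec, aspec, config, params, r1, r2, s)
    return TrialResult(
        spiked=bool(spiked[0]),
        spike_time=float(times[0]),
        r1=float(r1[0]),
        r2=float(r2[0]),
        s_draw=float(s[0]),
    )


def run_condition(
    vspec: Optional[VisualInputSpec],
    aspec: Optional[AuditoryInputSpec],
    config: TrialConfig,
    params: MauthnerParams,
    n_trials: int = 200,
    seed: Optional[int | np.random.SeedSequence] = None,
    rng: Optional[np.random.Generator] = None,
) -> ConditionSummary:
    """Run ``n_trials`` independent trials of one stimulus condition.

    Reproducible given ``seed``; response probability is the fraction of
    spiking trials with a binomial standard error.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    r1, r2, s = _draw_trial_randomness(rng, n_trials, vspec)
    if vspec is None:
        s = np.full(n_trials, 100.0)
    spiked, times = _simulate_trials(vspec, aspec, config, params, r1, r2, s)
    p = float(spiked.mean())
    se = float(np.sqrt(p * (1.0 - p) / n_trials))
    return ConditionSummary(
        p=p, se=se, n_trials=n_trials, spiked=spiked, spike_times=times,
        r1=r1, r2=r2, s_draw=s,
    )
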