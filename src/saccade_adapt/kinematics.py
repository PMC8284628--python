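"""Synthesis and measurement of continuous saccade trajectories.

Traces are sampled at 1 kHz: horizontal/vertical position in degrees and
velocity in deg/s.  A saccade is segmented at the time of its peak speed
sqrt(Hdot^2 + Vdot^2) into an acceleration and a deceleration period, and
the horizontal displacement expressed in each period is the integral of
horizontal velocity over that window.

The synthetic saccade generator produces a 15-degree vertical movement with
an asymmetric unimodal speed profile (~20 ms acceleration, ~50 ms
deceleration, matching measured control saccades) and injects horizontal
velocity as three components: an "aim" component proportional to the whole
vertical profile, plus components confined to the acceleration or the
deceleration window.  Integrated horizontal displacement equals the sum of
the three components by construction, which makes the synthesis ->
segmentation -> integration loop testable to tight tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal
from scipy.integrate import cumulative_trapezoid

from .errors import KinematicsError


@dataclass
class SaccadeTrace:
    """1 kHz eye trace: time (ms), position (deg), velocity (deg/s)."""

    t: np.ndarray
    H: np.ndarray
    V: np.ndarray
    Hdot: np.ndarray
    Vdot: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.t)
        if not (len(self.H) == len(self.V) == len(self.Hdot) == len(self.Vdot) == n):
            raise KinematicsError("trace channels must have equal length")

    @property
    def speed(self) -> np.ndarray:
        return np.hypot(self.Hdot, self.Vdot)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "t_ms": self.t, "H_deg": self.H, "V_deg": self.V,
            "Hdot_dps": self.Hdot, "Vdot_dps": self.Vdot,
        })


@dataclass
class SaccadeSegments:
    """Peak-speed segmentation of a single saccade (sample indices)."""

    onset: int
    t_peak: int
    offset: int

    @property
    def accel_duration_ms(self) -> int:
        return self.t_peak - self.onset

    @property
    def decel_duration_ms(self) -> int:
        return self.offset - self.t_peak

    @property
    def duration_ms(self) -> int:
        return self.offset - self.onset


@dataclass
class TrialPairResponse:
    """Trial-to-trial change in horizontal velocity for one trial pair."""

    dHdot: np.ndarray
    error_class: str  # "Hplus" | "Hminus" | "excluded"
    truncated: bool = False


@dataclass
class ProfileConfig:
    """Shape of the synthetic velocity profile."""

    accel_ms: float = 20.0
    decel_ms: float = 50.0
    pad_ms: float = 30.0
    fs_hz: float = 1000.0

    def __post_init__(self) -> None:
        if self.accel_ms <= 0 or self.decel_ms <= 0 or self.pad_ms < 0:
            raise KinematicsError("profile durations must be positive")


def _unit_bumps(cfg: ProfileConfig):
    """Sampled velocity bumps, each numerically normalized to unit displacement.

    Returns (t_s, g, gA, gD): g spans the whole saccade (raised-cosine rise
    over the acceleration window, fall over deceleration); gA and gD are
    full-cycle raised cosines confined to one window each.
    """
    dt = 1.0 / cfg.fs_hz
    n_pad = int(round(cfg.pad_ms / 1000.0 / dt))
    n_a = int(round(cfg.accel_ms / 1000.0 / dt))
    n_d = int(round(cfg.decel_ms / 1000.0 / dt))
    n = 2 * n_pad + n_a + n_d + 1
    t = np.arange(n) * dt
    g = np.zeros(n)
    gA = np.zeros(n)
    gD = np.zeros(n)
    i0 = n_pad
    ip = n_pad + n_a          # sample of peak speed
    i1 = n_pad + n_a + n_d
    ta = (np.arange(n_a + 1)) / n_a
    td = (np.arange(n_d + 1)) / n_d
    g[i0:ip + 1] = 0.5 * (1.0 - np.cos(np.pi * ta))
    g[ip:i1 + 1] = 0.5 * (1.0 + np.cos(np.pi * td))
    gA[i0:ip + 1] = 0.5 * (1.0 - np.cos(2.0 * np.pi * ta))
    gD[ip:i1 + 1] = 0.5 * (1.0 - np.cos(2.0 * np.pi * td))
    for arr in (g, gA, gD):
        arr /= np.trapezoid(arr, t)
    return t, g, gA, gD, (i0, ip, i1)


def profile_accel_fraction(profile: ProfileConfig | None = None) -> float:
    """Fraction of the unit profile's displacement accrued before peak speed."""
    cfg = profile or ProfileConfig()
    t, g, _, _, (i0, ip, i1) = _unit_bumps(cfg)
    return float(np.trapezoid(g[i0:ip + 1], t[i0:ip + 1]))


def synthesize_saccade(amplitude_v: float, aim_component: float = 0.0,
                       acc_component: float = 0.0, dec_component: float = 0.0,
                       profile: ProfileConfig | None = None,
                       seed: int | None = None,
                       velocity_noise_sd: float = 0.0) -> SaccadeTrace:
    """Generate a synthetic vertical saccade with horizontal displacement
    components: ``aim_component`` spread over the whole movement in
    proportion to the speed profile, ``acc_component`` confined to the
    acceleration window, ``dec_component`` to the deceleration window (all
    degrees)."""
    if amplitude_v <= 0:
        raise KinematicsError("vertical amplitude must be positive")
    cfg = profile or ProfileConfig()
    t, g, gA, gD, _ = _unit_bumps(cfg)
    Vdot = amplitude_v * g
    Hdot = aim_component * g + acc_component * gA + dec_component * gD
    if velocity_noise_sd > 0.0:
        rng = np.random.default_rng(seed)
        Hdot = Hdot + rng.normal(0.0, velocity_noise_sd, len(t))
        Vdot = Vdot + rng.normal(0.0, velocity_noise_sd, len(t))
    H = cumulative_trapezoid(Hdot, t, initial=0.0)
    V = cumulative_trapezoid(Vdot, t, initial=0.0)
    return SaccadeTrace(t=t * 1000.0, H=H, V=V, Hdot=Hdot, Vdot=Vdot)


def lowpass_filter(trace: SaccadeTrace, cutoff_hz: float = 200.0,
                   order: int = 3) -> SaccadeTrace:
    """Zero-phase low-pass Butterworth filter of all channels (200 Hz default)."""
    fs = 1000.0
    b, a = signal.butter(order, cutoff_hz / (fs / 2.0))
    padlen = 3 * (max(len(a), len(b)) - 1)
    if len(trace.t) <= padlen:
        raise KinematicsError(
            f"trace of {len(trace.t)} samples too short for filtering"
        )
    f = lambda x: signal.filtfilt(b, a, x)
    return SaccadeTrace(t=trace.t, H=f(trace.H), V=f(trace.V),
                        Hdot=f(trace.Hdot), Vdot=f(trace.Vdot))


def segment_by_peak_speed(trace: SaccadeTrace, threshold_dps: float = 30.0,
                          floor_dps: float = 1.0) -> SaccadeSegments:
    """Locate the saccade by a speed threshold and split it at peak speed.

    Detection uses the conventional 30 deg/s criterion; onset and offset
    are then refined by walking each edge outward until speed drops to
    ``floor_dps``, so the slow tails of the velocity profile stay inside
    the integration windows.  Peak ties break to the earliest sample.
    """
    speed = trace.speed
    above = np.flatnonzero(speed > threshold_dps)
    if len(above) == 0:
        raise KinematicsError("no suprathreshold samples: saccade not detected")
    onset, offset = int(above[0]), int(above[-1])
    while onset > 0 and speed[onset - 1] > floor_dps:
        onset -= 1
    while offset < len(speed) - 1 and speed[offset + 1] > floor_dps:
        offset += 1
    t_peak = onset + int(np.argmax(speed[onset:offset + 1]))
    if not onset < t_peak < offset:
        # peak at the very edge: clamp strictly inside the saccade
        t_peak = min(max(t_peak, onset + 1), offset - 1)
    return SaccadeSegments(onset=onset, t_peak=t_peak, offset=offset)


def phase_displacements(trace: SaccadeTrace, segments: SaccadeSegments
                        ) -> tuple[float, float]:
    """Integrate horizontal velocity over the acceleration and deceleration
    windows (trapezoidal, seconds); returns (yA, yD) in degrees."""
    t_s = trace.t / 1000.0
    on, pk, off = segments.onset, segments.t_peak, segments.offset
    yA = float(np.trapezoid(trace.Hdot[on:pk + 1], t_s[on:pk + 1]))
    yD = float(np.trapezoid(trace.Hdot[pk:off + 1], t_s[pk:off + 1]))
    return yA, yD


def clamp_landing_prediction(position: float, velocity: float,
                             acceleration: float) -> float:
    """Predicted landing point from constant-deceleration extrapolation.

    Used to place the target on error-clamp trials: from the state sampled
    when speed falls below threshold, extrapolate to the time velocity
    crosses zero.  Exact for quadratic (constant-acceleration) trajectories.
    """
    if velocity == 0.0:
        return position
    if acceleration == 0.0 or np.sign(acceleration) == np.sign(velocity):
        raise KinematicsError(
            "extrapolation undefined: axis is not decelerating"
        )
    t_star = -velocity / acceleration
    return position + velocity * t_star + 0.5 * acceleration * t_star**2


def classify_pair_error(endpoint_error: float,
                        threshold: float = 2.5) -> str:
    """Classify the previous trial's horizontal endpoint error."""
    if endpoint_error > threshold:
        return "Hplus"
    if endpoint_error < -threshold:
        return "Hminus"
    return "excluded"


def chsp_filter(start_h_n: float, start_h_n1: float,
                max_change: float = 0.5) -> bool:
    """True (keep the pair) iff the change in horizontal starting position
    between consecutive saccades is within +/- max_change degrees."""
    return abs(start_h_n1 - start_h_n) <= max_change


def pair_response(trace_n: SaccadeTrace, trace_n1: SaccadeTrace,
                  endpoint_error_n: float) -> TrialPairResponse:
    """Sample-wise trial-to-trial change in horizontal velocity.

    Both traces must be time-aligned to saccade onset; unequal durations
    truncate to the shorter trace (flagged in the result).
    """
    n = min(len(trace_n.t), len(trace_n1.t))
    d = trace_n1.Hdot[:n] - trace_n.Hdot[:n]
    return TrialPairResponse(
        dHdot=d,
        error_class=classify_pair_error(endpoint_error_n),
        truncated=len(trace_n.t) != len(trace_n1.t),
    )


def compensation_onset(mean_response: np.ndarray, baseline_sd: float,
                       n_sd: float = 2.0, hold_ms: int = 10
                       ) -> int | None:
    """Onset (ms from saccade start) of error-compensating velocity change.

    Input is the pooled response-to-error trace (responses to negative
    errors sign-flipped before pooling, so compensation is positive).  The
    onset is the first sample from which the trace stays at or above
    ``n_sd * baseline_sd`` for at least ``hold_ms`` consecutive samples;
    returns None when no qualifying crossing exists.
    """
    x = np.asarray(mean_response, dtype=float)
    thresh = n_sd * baseline_sd
    ok = x >= thresh
    count = 0
    start = None
    for i, flag in enumerate(ok):
        if flag:
            if start is None:
                start = i
            count += 1
            if count >= hold_ms:
                return start
        else:
            start = None
            count = 0
    return None
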