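"""Membrane-recruitment kinetics: ratio traces and mono-exponential fits.

An optogenetic heterodimer pair recruits a cytosolic prey protein to the
plasma membrane while blue light is on and releases it in the dark. The
standard read-out is the membrane-mean over cytosol-mean intensity
ratio, normalized to its first frame. The ON phase is fitted with a
saturating exponential R(t) = baseline + A·(1 − exp(−(t−t0)/τ)) and the
OFF phase with a decaying one, giving the half-times t½ = ln(2)·τ that
characterize the tool. Recruitment efficiency is the plateau of the
normalized ratio during stimulation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.optimize

from .imaging import ImageStack, RoiSet

__all__ = [
    "RatioTrace",
    "MonoExpFit",
    "ratio_trace",
    "cytosol_change_percent",
    "relocation_change_percent",
    "fit_monoexp",
    "recruitment_efficiency",
]

LN2 = math.log(2.0)


@dataclass
class RatioTrace:
    """Normalized membrane/cytosol intensity-ratio time series."""

    time: np.ndarray  # s
    ratio: np.ndarray  # dimensionless
    normalized: bool = False
    stim_windows: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.ratio = np.asarray(self.ratio, dtype=float)
        if self.time.shape != self.ratio.shape:
            raise ValueError("time and ratio must have equal length")
        if len(self.time) >= 2 and np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        if self.normalized and not math.isclose(self.ratio[0], 1.0, rel_tol=1e-12):
            raise ValueError("normalized trace must start at exactly 1")


@dataclass
class MonoExpFit:
    """Result of a single-phase mono-exponential fit."""

    phase: str  # "ON" | "OFF"
    tau: float  # s
    amplitude: float
    baseline: float
    rss: float
    converged: bool
    t0: float = 0.0

    @property
    def t_half(self) -> float:
        return LN2 * self.tau

    def predict(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        if self.phase == "ON":
            return self.baseline + self.amplitude * (
                1.0 - np.exp(-(t - self.t0) / self.tau)
            )
        return self.baseline + self.amplitude * np.exp(-(t - self.t0) / self.tau)


def ratio_trace(
    stack: ImageStack,
    rois: RoiSet,
    channel: str | int = "prey",
    normalize: bool = True,
    stim_windows: list[tuple[float, float]] | None = None,
) -> RatioTrace:
    """Per-frame membrane-mean / cytosol-mean ratio of a channel.

    The stack should be background-corrected. With ``normalize`` each
    value is divided by the first-frame ratio, so the trace starts at
    exactly 1.
    """
    mem = rois["membrane"]
    cyt = rois["cytosol"]
    if not mem.any() or not cyt.any():
        raise ValueError("membrane and cytosol ROIs must be non-empty")
    sub = stack.channel(channel)
    mem_mean = sub[:, mem].mean(axis=1)
    cyt_mean = sub[:, cyt].mean(axis=1)
    if np.any(cyt_mean == 0) or np.any(~np.isfinite(cyt_mean)):
        raise ValueError("cytosol mean is zero or non-finite in some frame")
    ratio = mem_mean / cyt_mean
    if normalize:
        ratio = ratio / ratio[0]
    return RatioTrace(
        time=stack.times,
        ratio=ratio,
        normalized=normalize,
        stim_windows=list(stim_windows or []),
    )


def _frame_at(stack: ImageStack, t: float) -> int:
    k = int(round(t / stack.frame_interval))
    if not 0 <= k < stack.n_frames:
        raise ValueError(f"time {t} s outside the recording")
    return k


def cytosol_change_percent(
    stack: ImageStack,
    cytosol_roi: np.ndarray,
    t_pre: float,
    t_act: float,
    channel: str | int = "prey",
) -> float:
    """Percent depletion of cytosolic prey signal upon activation.

    Compares the cytosol-ROI mean just before photo-activation with the
    one during activation: (1 − I_act/I_pre)·100. Positive values mean
    signal left the cytosol (i.e. was recruited to the membrane).
    """
    roi = np.asarray(cytosol_roi, dtype=bool)
    if not roi.any():
        raise ValueError("cytosol ROI is empty")
    sub = stack.channel(channel)
    i_pre = sub[_frame_at(stack, t_pre)][roi].mean()
    i_act = sub[_frame_at(stack, t_act)][roi].mean()
    if i_pre == 0 or not np.isfinite(i_pre):
        raise ValueError("pre-activation cytosol mean is zero or non-finite")
    return float((1.0 - i_act / i_pre) * 100.0)


def relocation_change_percent(
    sensor_stack: ImageStack,
    rois: RoiSet,
    t_pre: float,
    t_act: float,
    channel: str | int = "prey",
) -> float:
    """Percent change of a location sensor's membrane/cytosol ratio.

    (R_act/R_pre − 1)·100 with R the membrane-mean over cytosol-mean
    ratio; a gain of membrane signal is reported as positive.
    """
    trace = ratio_trace(sensor_stack, rois, channel=channel, normalize=False)
    r_pre = trace.ratio[_frame_at(sensor_stack, t_pre)]
    r_act = trace.ratio[_frame_at(sensor_stack, t_act)]
    if r_pre == 0 or not np.isfinite(r_pre):
        raise ValueError("pre-activation ratio is zero or non-finite")
    return float((r_act / r_pre - 1.0) * 100.0)


def fit_monoexp(
    trace: RatioTrace,
    phase: str,
    window: tuple[float, float],
    t0: float | None = None,
) -> MonoExpFit:
    """Least-squares mono-exponential fit of one kinetic phase.

    ON model: R(t) = baseline + A·(1 − exp(−(t−t0)/τ));
    OFF model: R(t) = baseline + A·exp(−(t−t0)/τ).

    ``t0`` defaults to the first sample of (or after) the window start —
    the illumination transition. τ is initialized from the time to half
    the endpoint difference and bounded in (frame_interval/10,
    100·window length). A flat trace converges with a near-zero
    amplitude but its τ is unidentifiable; the ``converged`` flag stays
    honest in that the optimizer's status is reported, and callers should
    treat |A| ≈ 0 fits as kinetics-free.
    """
    phase = phase.upper()
    if phase not in {"ON", "OFF"}:
        raise ValueError("phase must be 'ON' or 'OFF'")
    a, b = window
    mask = (trace.time >= a) & (trace.time <= b)
    if mask.sum() < 5:
        raise ValueError("need at least 5 samples in the fit window")
    t = trace.time[mask]
    y = trace.ratio[mask]
    if t0 is None:
        t0 = float(t[0])
    dt = np.median(np.diff(t))
    span = float(t[-1] - t[0])

    # initial guesses from the endpoints
    if phase == "ON":
        base0 = float(y[0])
        amp0 = float(y[-1] - y[0])
    else:
        base0 = float(y[-1])
        amp0 = float(y[0] - y[-1])
    half_level = base0 + amp0 / 2.0 if phase == "ON" else base0 + amp0 / 2.0
    crossing = np.flatnonzero(
        (y - half_level) * np.sign(amp0 if amp0 != 0 else 1.0) >= 0
        if phase == "ON"
        else (y - half_level) * np.sign(amp0 if amp0 != 0 else 1.0) <= 0
    )
    tau0 = float(t[crossing[0]] - t0) / LN2 if len(crossing) else span / 3.0
    tau_lo, tau_hi = dt / 10.0, 100.0 * max(span, dt)
    tau0 = min(max(tau0, tau_lo * 1.01), tau_hi * 0.99)
    if tau0 <= 0 or not np.isfinite(tau0):
        tau0 = span / 3.0

    if phase == "ON":

        def model(tt, tau, amp, base):
            return base + amp * (1.0 - np.exp(-(tt - t0) / tau))

    else:

        def model(tt, tau, amp, base):
            return base + amp * np.exp(-(tt - t0) / tau)

    converged = True
    try:
        popt, _ = scipy.optimize.curve_fit(
            model,
            t,
            y,
            p0=[tau0, amp0, base0],
            bounds=([tau_lo, -np.inf, -np.inf], [tau_hi, np.inf, np.inf]),
            maxfev=20_000,
        )
    except RuntimeError:
        converged = False
        popt = [tau0, amp0, base0]
    tau, amp, base = (float(v) for v in popt)
    resid = y - model(t, tau, amp, base)
    return MonoExpFit(
        phase=phase,
        tau=tau,
        amplitude=amp,
        baseline=base,
        rss=float(np.dot(resid, resid)),
        converged=converged,
        t0=t0,
    )


def recruitment_efficiency(
    trace: RatioTrace, stim_window: tuple[float, float] | None = None
) -> float:
    """Plateau of the normalized ratio during stimulation.

    The mean over the last quartile of the stimulation window; without
    recruitment (and with normalization) this is 1.
    """
    if stim_window is None:
        if not trace.stim_windows:
            raise ValueError("no stimulation window available")
        stim_window = trace.stim_windows[0]
    a, b = stim_window
    lo = b - (b - a) / 4.0
    mask = (trace.time >= lo) & (trace.time <= b)
    if not mask.any():
        raise ValueError("no samples in the last quartile of the stim window")
    return float(trace.ratio[mask].mean())
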