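"""Resistance/permeability time-series utilities.

Impedance sensing reports monolayer resistance (Ω at 4 kHz, sampled
every 10 s) as a proxy for paracellular barrier strength. These helpers
normalize traces to a baseline window, extract stimulus-locked response
amplitudes (sign-preserving, so barrier drops come out negative), and
correlate morphology and resistance read-outs acquired on different time
grids. Permeability-assay plate readings (four positions per transwell)
are averaged per well.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

__all__ = [
    "ResistanceTrace",
    "normalize_trace",
    "response_amplitude",
    "area_resistance_correlation",
    "permeability_summary",
]


@dataclass
class ResistanceTrace:
    """A resistance time series with its stimulation windows."""

    time: np.ndarray  # s
    resistance: np.ndarray  # Ω
    stim_windows: list[tuple[float, float]] = field(default_factory=list)
    well_id: str = ""
    normalized: bool = False

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.resistance = np.asarray(self.resistance, dtype=float)
        if self.time.shape != self.resistance.shape:
            raise ValueError("time and resistance must have equal length")
        if len(self.time) >= 2 and np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")

    def window_mask(self, window: tuple[float, float]) -> np.ndarray:
        a, b = window
        return (self.time >= a) & (self.time < b)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_s": self.time, "value": self.resistance, "well_id": self.well_id}
        )


def normalize_trace(
    trace: ResistanceTrace, baseline_window: tuple[float, float]
) -> ResistanceTrace:
    """Divide by the baseline-window mean so the baseline sits at 1."""
    mask = trace.window_mask(baseline_window)
    if not mask.any():
        raise ValueError("baseline window contains no samples")
    base = trace.resistance[mask].mean()
    if base == 0 or not np.isfinite(base):
        raise ValueError("baseline mean is zero or non-finite")
    return ResistanceTrace(
        time=trace.time.copy(),
        resistance=trace.resistance / base,
        stim_windows=list(trace.stim_windows),
        well_id=trace.well_id,
        normalized=True,
    )


def response_amplitude(
    trace: ResistanceTrace,
    stim_window: tuple[float, float],
    baseline_window: tuple[float, float] | None = None,
) -> tuple[float, float]:
    """Signed extremum-vs-baseline response within a stimulus window.

    Returns (amplitude in trace units, amplitude as % of baseline). The
    extremum is the sample with the largest absolute deviation from the
    baseline mean, so both resistance increases (barrier strengthening)
    and dips (contraction) are captured with their sign. The baseline
    window defaults to everything before the stimulus.
    """
    if baseline_window is None:
        baseline_window = (float(trace.time[0]), stim_window[0])
    bmask = trace.window_mask(baseline_window)
    smask = trace.window_mask(stim_window)
    if not bmask.any():
        raise ValueError("baseline window contains no samples")
    if not smask.any():
        raise ValueError("stimulus window contains no samples")
    base = trace.resistance[bmask].mean()
    dev = trace.resistance[smask] - base
    amp = float(dev[np.argmax(np.abs(dev))])
    return amp, 100.0 * amp / base


def area_resistance_correlation(
    area_time: np.ndarray,
    area_values: np.ndarray,
    resistance_trace: ResistanceTrace,
) -> float:
    """Pearson correlation of an area trace with a resistance trace.

    The two series are resampled by linear interpolation onto the
    coarser of the two time grids, restricted to their common time span,
    before correlating.
    """
    at = np.asarray(area_time, dtype=float)
    av = np.asarray(area_values, dtype=float)
    rt, rv = resistance_trace.time, resistance_trace.resistance
    lo = max(at[0], rt[0])
    hi = min(at[-1], rt[-1])
    if hi <= lo:
        raise ValueError("traces do not overlap in time")
    dt_a = np.median(np.diff(at))
    dt_r = np.median(np.diff(rt))
    grid_src = at if dt_a >= dt_r else rt
    grid = grid_src[(grid_src >= lo) & (grid_src <= hi)]
    if len(grid) < 3:
        raise ValueError("fewer than 3 common samples")
    a_i = np.interp(grid, at, av)
    r_i = np.interp(grid, rt, rv)
    r, _ = scipy.stats.pearsonr(a_i, r_i)
    return float(r)


def permeability_summary(
    readings: pd.DataFrame,
    group_col: str = "group",
    well_col: str = "well_id",
    value_col: str = "fluorescence",
) -> pd.DataFrame:
    """Per-well means of four-position fluorescence readings, by group.

    Each transwell is read at four positions; the per-well value is
    their mean. Returns a tidy table (group, well_id, mean_fluorescence)
    plus group means in the attribute ``.attrs['group_means']``.
    """
    if readings[value_col].isna().any():
        raise ValueError("NaN fluorescence reading")
    per_well = (
        readings.groupby([group_col, well_col], sort=False)[value_col]
        .mean()
        .reset_index()
        .rename(columns={value_col: "mean_fluorescence"})
    )
    out = per_well
    out.attrs["group_means"] = (
        per_well.groupby(group_col, sort=False)["mean_fluorescence"].mean().to_dict()
    )
    return out
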