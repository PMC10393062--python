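"""Synthetic ground-truth scenes for every quantification stage.

Real optogenetic recruitment data are time-lapse confocal stacks of cells
expressing a membrane-anchored bait and a cytosolic prey that
redistributes to the membrane during blue-light illumination. Instead of
shipping microscopy data, this module generates small scenes whose every
measurable quantity is known by construction:

* a two-compartment recruitment movie with exact mono-exponential ON/OFF
  kinetics (:func:`simulate_recruitment_stack`),
* star-convex cells whose area follows a prescribed profile
  (:func:`simulate_morphology_sequence`),
* junction polylines of controlled tortuosity (:func:`simulate_junction`),
* two-channel mosaic monolayers with a controlled membrane-overlap
  fraction (:func:`simulate_mosaic_monolayer`),
* impedance (resistance) traces with stimulus-locked responses
  (:func:`simulate_resistance_trace`).

Each generator returns the data plus a :class:`SceneTruth` carrying the
true parameters; wherever digitization intervenes (areas, arc lengths)
the truth is re-measured from the emitted pixels, not just copied from
the generating parameters. All randomness flows from a single per-scene
``numpy`` generator seeded by the config; identical configs give
bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .imaging import ImageStack
from .junctions import JunctionPath
from .traces import ResistanceTrace

__all__ = [
    "SceneConfig",
    "SceneTruth",
    "simulate_recruitment_stack",
    "simulate_morphology_sequence",
    "simulate_junction",
    "simulate_mosaic_monolayer",
    "simulate_resistance_trace",
    "membrane_fraction_series",
    "ratio_excess_series",
    "ratio_from_fraction",
]

LN2 = math.log(2.0)


@dataclass
class SceneConfig:
    """Parameters for a recruitment scene.

    Defaults mirror the reference acquisition: 2.5-s frame interval, a
    2-minute illumination window, ON half-time of a few seconds and an
    OFF half-time of tens of seconds.
    """

    image_shape: tuple[int, int] = (96, 96)
    pixel_size: float = 0.2  # µm / px
    frame_interval: float = 2.5  # s
    n_frames: int = 96
    stim_windows: tuple[tuple[float, float], ...] = ((30.0, 150.0),)
    tau_on: float = 8.0  # s
    tau_off: float = 20.0  # s
    recruit_fraction: float = 0.15
    bleach_rate: float = 0.0  # 1/s
    noise_model: tuple = ("none",)  # ("none",) | ("gaussian", sigma) | ("poisson", gain)
    membrane_band_px: int = 3
    cell_radius_px: int = 36
    seed: int = 0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.tau_on) and self.tau_on > 0):
            raise ValueError("tau_on must be positive and finite")
        if not (np.isfinite(self.tau_off) and self.tau_off > 0):
            raise ValueError("tau_off must be positive and finite")
        if not 0.0 <= self.recruit_fraction <= 1.0:
            raise ValueError("recruit_fraction must be in [0, 1]")
        if self.bleach_rate < 0 or not np.isfinite(self.bleach_rate):
            raise ValueError("bleach_rate must be finite and >= 0")
        t_end = self.n_frames * self.frame_interval
        wins = sorted(self.stim_windows)
        for (a, b) in wins:
            if not (0.0 <= a < b <= t_end):
                raise ValueError(f"stim window ({a}, {b}) outside recording [0, {t_end})")
        for (_, b), (a2, _) in zip(wins, wins[1:]):
            if a2 < b:
                raise ValueError("stim windows must be non-overlapping")
        kind = self.noise_model[0]
        if kind not in {"none", "gaussian", "poisson"}:
            raise ValueError(f"unknown noise model {kind!r}")


@dataclass
class SceneTruth:
    """Ground truth accompanying a simulated scene."""

    true_tau_on: float | None = None
    true_tau_off: float | None = None
    membrane_mask: np.ndarray | None = None
    cytosol_mask: np.ndarray | None = None
    true_area_series: np.ndarray | None = None  # µm² per frame
    true_overlap_series: np.ndarray | None = None  # µm² per frame
    true_arc_length: float | None = None  # µm (or px when pixel_size = 1)
    true_chord_polygon_perimeter: float | None = None
    true_fraction_series: np.ndarray | None = None  # membrane-bound prey fraction
    true_ratio_series: np.ndarray | None = None  # noiseless membrane/cytosol ratio
    edge_touching: list[int] = field(default_factory=list)
    extras: dict = field(default_factory=dict)

    @property
    def true_t_half_on(self) -> float | None:
        return None if self.true_tau_on is None else LN2 * self.true_tau_on

    @property
    def true_t_half_off(self) -> float | None:
        return None if self.true_tau_off is None else LN2 * self.true_tau_off


# ---------------------------------------------------------------------------
# Recruitment kinetics scene

def _piecewise_exponential(
    times: np.ndarray,
    windows: list[tuple[float, float]],
    target_on: float,
    tau_on: float,
    tau_off: float,
) -> np.ndarray:
    """Exact solution of x' = (x_target − x)/τ with piecewise targets.

    x_target = ``target_on`` and τ = tau_on inside the windows, 0 and
    tau_off outside; x(0) = 0. The ODE is propagated analytically
    through every window boundary, so the returned samples carry no
    time-stepping error.
    """
    events = sorted(windows)

    def segment_params(t: float) -> tuple[float, float]:
        for a, b in events:
            if a <= t < b:
                return target_on, tau_on
        return 0.0, tau_off

    switch = sorted({0.0, *[a for a, _ in events], *[b for _, b in events]})
    x = 0.0
    t_last = 0.0
    out = np.empty(len(times))
    idx = 0
    checkpoints = sorted(set(switch) | set(float(t) for t in times))
    for t in checkpoints:
        if t > t_last:
            target, tau = segment_params(t_last)
            x = target + (x - target) * math.exp(-(t - t_last) / tau)
            t_last = t
        while idx < len(times) and math.isclose(times[idx], t, abs_tol=1e-12):
            out[idx] = x
            idx += 1
    assert idx == len(times)
    return out


def ratio_excess_series(config: SceneConfig, geometry_gain: float) -> np.ndarray:
    """Exact membrane/cytosol ratio excess R(t_k) − 1 at each frame.

    The observable the half-times are defined on is the normalized
    membrane-to-cytosol ratio; its excess over the resting value obeys
    x' = (x_target − x)/τ with τ = tau_on (target set by
    recruit_fraction and the cell geometry) during illumination and
    τ = tau_off (target 0) in the dark.

    ``geometry_gain`` is n_cell / n_membrane: the plateau excess for a
    membrane-bound pool fraction r is gain·r/(1−r).
    """
    times = np.arange(config.n_frames) * config.frame_interval
    r = config.recruit_fraction
    target = geometry_gain * r / (1.0 - r) if r < 1.0 else np.inf
    return _piecewise_exponential(
        times, list(config.stim_windows), target, config.tau_on, config.tau_off
    )


def membrane_fraction_series(config: SceneConfig, geometry_gain: float) -> np.ndarray:
    """Membrane-bound prey pool fraction f(t_k) implied by the ratio.

    Inverts R − 1 = gain·f/(1−f): f = (R−1) / (R−1+gain). Equals
    recruit_fraction at the ON plateau and 0 at rest.
    """
    g = ratio_excess_series(config, geometry_gain)
    return g / (g + geometry_gain)


def ratio_from_fraction(
    f: np.ndarray, n_membrane: int, n_cell: int
) -> np.ndarray:
    """Noiseless membrane-mean / cytosol-mean ratio implied by fraction f.

    The cytosolic pool fills the whole cell footprint (n_cell pixels,
    including under the membrane band), so cytosol pixels carry
    (1−f)/n_cell each while membrane pixels additionally carry f/n_mem
    of membrane-bound prey. The ratio of means is therefore
    1 + f·n_cell / ((1−f)·n_mem), equal to exactly 1 at rest (f = 0).
    """
    f = np.asarray(f, dtype=float)
    return 1.0 + (f * n_cell) / ((1.0 - f) * n_membrane)


def _disk_masks(
    shape: tuple[int, int], radius: int, band: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    cy, cx = (shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0
    r = np.hypot(yy - cy, xx - cx)
    cell = r <= radius
    interior = r <= radius - band
    membrane = cell & ~interior
    cytosol = r <= radius - band - 2  # 2-px guard ring, mirrors ROI construction
    return cell, membrane, cytosol


def simulate_recruitment_stack(config: SceneConfig) -> tuple[ImageStack, SceneTruth]:
    """Two-channel recruitment movie with exact mono-exponential kinetics.

    Channel 0 ("bait") is a static membrane marker; channel 1 ("prey") is
    a conserved pool redistributing between a thin membrane band and the
    cytosol interior. The kinetics live on the observable the half-times
    are defined on: the membrane/cytosol ratio excess follows the
    piecewise mono-exponential ON/OFF law exactly (see
    :func:`ratio_excess_series`), and the membrane-bound pool fraction is
    derived from it. Per-frame prey signal is conserved before bleaching
    and noise; bleaching multiplies all signal by exp(−bleach_rate·t);
    noise is applied last.
    """
    ny, nx = config.image_shape
    cell, membrane, cytosol = _disk_masks(
        (ny, nx), config.cell_radius_px, config.membrane_band_px
    )
    n_mem = int(membrane.sum())
    n_cyt = int(cytosol.sum())
    if n_mem == 0 or n_cyt == 0:
        raise ValueError("cell radius too small for the membrane band")

    n_cell = int(cell.sum())
    gain = n_cell / n_mem
    f = membrane_fraction_series(config, gain)
    times = np.arange(config.n_frames) * config.frame_interval

    prey_total = 1.0e4  # arbitrary-unit pool size, well above noise floor
    bait_level = 1000.0

    data = np.zeros((config.n_frames, 2, ny, nx), dtype=float)
    # prey: cytosolic pool fills the whole cell footprint (including under
    # the membrane band); membrane-bound prey adds on top of the band
    for k in range(config.n_frames):
        frame = np.zeros((ny, nx))
        frame[cell] = (1.0 - f[k]) * prey_total / n_cell
        frame[membrane] += f[k] * prey_total / n_mem
        data[k, 1] = frame
        data[k, 0] = np.where(membrane, bait_level, 0.0)

    if config.bleach_rate > 0:
        data *= np.exp(-config.bleach_rate * times)[:, None, None, None]

    rng = np.random.default_rng(config.seed)
    kind = config.noise_model[0]
    if kind == "gaussian":
        sigma = float(config.noise_model[1])
        data = data + rng.normal(0.0, sigma, size=data.shape)
    elif kind == "poisson":
        gain = float(config.noise_model[1])
        data = rng.poisson(np.clip(data / gain, 0, None)).astype(float) * gain

    stack = ImageStack(
        data=data,
        frame_interval=config.frame_interval,
        pixel_size=config.pixel_size,
        channel_roles={"bait": 0, "prey": 1},
    )
    ratio = ratio_from_fraction(f, n_mem, n_cell)
    truth = SceneTruth(
        true_tau_on=config.tau_on,
        true_tau_off=config.tau_off,
        membrane_mask=membrane,
        cytosol_mask=cytosol,
        true_fraction_series=f,
        true_ratio_series=ratio,
        extras={"n_membrane_px": n_mem, "n_cell_px": n_cell},
    )
    return stack, truth


# ---------------------------------------------------------------------------
# Morphology scene

def _star_convex_mask(
    shape: tuple[int, int],
    center: tuple[float, float],
    base_radius: float,
    harmonics: np.ndarray,
    phases: np.ndarray,
    scale: float,
) -> np.ndarray:
    """Binary mask of a star-convex cell with a radial-harmonic boundary."""
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    dy, dx = yy - center[0], xx - center[1]
    r = np.hypot(dy, dx)
    theta = np.arctan2(dy, dx)
    boundary = base_radius * np.ones_like(theta)
    for k, (a, ph) in enumerate(zip(harmonics, phases), start=2):
        boundary = boundary + base_radius * a * np.cos(k * theta + ph)
    return r <= boundary * scale


def simulate_morphology_sequence(
    area_profile: np.ndarray,
    n_cells: int = 2,
    image_shape: tuple[int, int] = (256, 256),
    base_radius: float = 50.0,
    pixel_size: float = 1.0,
    frame_interval: float = 15.0,
    seed: int = 0,
) -> tuple[ImageStack, SceneTruth]:
    """Label movie of star-convex cells following a relative area profile.

    ``area_profile`` gives the target area relative to frame 0 (e.g.
    ``linspace(1, 1.15, 40)`` for +15% growth). The boundary radius is
    scaled by sqrt(profile) so the continuous area tracks the profile;
    the recorded ``true_area_series`` is re-measured from the emitted
    masks (per cell, in µm²), so it carries the actual digitized areas.
    Cells touching the image border are flagged in ``edge_touching``.
    """
    area_profile = np.asarray(area_profile, dtype=float)
    if np.any(area_profile <= 0):
        raise ValueError("area profile must be positive")
    if base_radius * math.sqrt(area_profile.min()) < 1.0:
        raise ValueError("requested shrinkage below 1 px radius")
    rng = np.random.default_rng(seed)
    ny, nx = image_shape
    # place cells on a jittered grid, far enough apart not to merge
    n_frames = len(area_profile)
    max_scale = math.sqrt(area_profile.max())
    margin = base_radius * 1.35 * max_scale
    centers = []
    cols = int(math.ceil(math.sqrt(n_cells)))
    for i in range(n_cells):
        gy, gx = divmod(i, cols)
        cy = margin + gy * 2.05 * margin + rng.uniform(-3, 3)
        cx = margin + gx * 2.05 * margin + rng.uniform(-3, 3)
        centers.append((cy, cx))
    harmonics = rng.uniform(0.02, 0.08, size=(n_cells, 3))
    phases = rng.uniform(0, 2 * math.pi, size=(n_cells, 3))

    labels = np.zeros((n_frames, 1, ny, nx), dtype=np.uint16)
    areas = np.zeros((n_frames, n_cells))
    edge = set()
    for k in range(n_frames):
        scale = math.sqrt(area_profile[k])
        for c in range(n_cells):
            mask = _star_convex_mask(
                (ny, nx), centers[c], base_radius, harmonics[c], phases[c], scale
            )
            labels[k, 0][mask] = c + 1
            areas[k, c] = mask.sum() * pixel_size**2
            if (
                mask[0].any()
                or mask[-1].any()
                or mask[:, 0].any()
                or mask[:, -1].any()
            ):
                edge.add(c + 1)

    stack = ImageStack(
        data=labels,
        frame_interval=frame_interval,
        pixel_size=pixel_size,
        channel_roles={"labels": 0},
    )
    truth = SceneTruth(
        true_area_series=areas,
        edge_touching=sorted(edge),
        extras={"area_profile": area_profile, "centers": centers},
    )
    return stack, truth


# ---------------------------------------------------------------------------
# Junction scene

def _quadrature_length(points: np.ndarray) -> float:
    return float(np.sum(np.hypot(np.diff(points[:, 0]), np.diff(points[:, 1]))))


def simulate_junction(
    tortuosity: float = 0.0,
    n_corners: int = 2,
    length: float = 100.0,
    seed: int = 0,
    shape: str = "sine",
    n_points: int = 200,
    sine_period: float = 50.0,
) -> tuple[list[JunctionPath], SceneTruth]:
    """Junction polylines of controlled tortuosity between corner points.

    ``shape`` selects the generating curve between consecutive corners:

    * ``"sine"`` — chord perturbed perpendicular by a sine of amplitude
      ``tortuosity`` (px) and period ``sine_period``;
    * ``"semicircle"`` — half circle over the chord (arc/chord = π/2);
    * ``"straight"`` — the chord itself.

    ``true_arc_length`` is computed by dense quadrature (1e4+1 samples of
    the generating curve), independent of the emitted polyline sampling.
    """
    if tortuosity < 0:
        raise ValueError("tortuosity must be >= 0")
    if n_corners < 2:
        raise ValueError("need at least two corners")
    rng = np.random.default_rng(seed)
    # corner points along a rough line with jitter
    base = np.stack(
        [
            np.linspace(0, length * (n_corners - 1), n_corners),
            rng.uniform(-0.1 * length, 0.1 * length, size=n_corners),
        ],
        axis=1,
    )

    def curve(p0, p1, s):  # s in [0, 1]
        chord = p1 - p0
        t_hat = chord / np.linalg.norm(chord)
        n_hat = np.array([-t_hat[1], t_hat[0]])
        if shape == "straight" or tortuosity == 0 and shape == "sine":
            return p0 + np.outer(s, chord)
        if shape == "semicircle":
            mid = (p0 + p1) / 2.0
            r = np.linalg.norm(chord) / 2.0
            ang = np.pi * (1.0 - s)
            return (
                mid
                + np.outer(np.cos(ang) * r, t_hat)
                + np.outer(np.sin(ang) * r, n_hat)
            )
        if shape == "sine":
            clen = np.linalg.norm(chord)
            offset = tortuosity * np.sin(2 * np.pi * s * clen / sine_period)
            return p0 + np.outer(s, chord) + np.outer(offset, n_hat)
        raise ValueError(f"unknown junction shape {shape!r}")

    paths: list[JunctionPath] = []
    total_arc = 0.0
    total_poly = 0.0
    s_emit = np.linspace(0.0, 1.0, n_points)
    s_dense = np.linspace(0.0, 1.0, 10_001)
    for p0, p1 in zip(base[:-1], base[1:]):
        pts = curve(p0, p1, s_emit)
        paths.append(JunctionPath(points=pts, corners=[0, len(pts) - 1]))
        total_arc += _quadrature_length(curve(p0, p1, s_dense))
        total_poly += float(np.linalg.norm(p1 - p0))

    truth = SceneTruth(
        true_arc_length=total_arc,
        true_chord_polygon_perimeter=total_poly,
        extras={"corners": base},
    )
    return paths, truth


# ---------------------------------------------------------------------------
# Mosaic monolayer scene

def simulate_mosaic_monolayer(
    overlap_fraction: float = 0.3,
    image_shape: tuple[int, int] = (128, 256),
    growth_factor: float | None = None,
    n_frames: int = 1,
    pixel_size: float = 1.0,
    intensity: float = 1000.0,
    seed: int = 0,
) -> tuple[ImageStack, SceneTruth]:
    """Two-channel mosaic with a controlled membrane-overlap fraction.

    Two membrane fields occupy overlapping horizontal bands; the
    intersection-over-union of the two channels equals
    ``overlap_fraction`` up to integer-pixel rounding. With
    ``growth_factor`` and ``n_frames`` > 1 the intersection width grows
    linearly so the final overlap area is ``growth_factor`` times the
    initial one. ``true_overlap_series`` is counted from the emitted
    masks (µm²).
    """
    if not 0.0 <= overlap_fraction <= 1.0:
        raise ValueError("overlap_fraction must be in [0, 1]")
    ny, nx = image_shape
    union_w = nx
    # widths: A covers [0, wa), B covers [nx - wb, nx); overlap = wa + wb - nx
    inter_w0 = int(round(overlap_fraction * union_w))
    if growth_factor is not None and n_frames > 1:
        inter_end = int(round(inter_w0 * growth_factor))
        inter_ws = np.round(np.linspace(inter_w0, inter_end, n_frames)).astype(int)
    else:
        inter_ws = np.full(n_frames, inter_w0)
    if np.any(inter_ws > nx):
        raise ValueError("requested overlap exceeds the field width")

    data = np.zeros((n_frames, 2, ny, nx), dtype=float)
    overlap_area = np.zeros(n_frames)
    for k, iw in enumerate(inter_ws):
        wa = (nx + iw) // 2
        wb = nx - (wa - iw)
        data[k, 0, :, :wa] = intensity
        data[k, 1, :, nx - wb :] = intensity
        inter = (data[k, 0] > 0) & (data[k, 1] > 0)
        overlap_area[k] = inter.sum() * pixel_size**2

    stack = ImageStack(
        data=data,
        frame_interval=15.0,
        pixel_size=pixel_size,
        channel_roles={"cell_a": 0, "cell_b": 1},
    )
    union = (data[0, 0] > 0) | (data[0, 1] > 0)
    truth = SceneTruth(
        true_overlap_series=overlap_area,
        extras={
            "overlap_fraction_measured": overlap_area[0]
            / (union.sum() * pixel_size**2),
        },
    )
    return stack, truth


# ---------------------------------------------------------------------------
# Resistance trace scene

def simulate_resistance_trace(
    baseline: float = 1000.0,
    amplitude: float = 200.0,
    stim_windows: tuple[tuple[float, float], ...] = ((600.0, 1200.0),),
    relax_tau: float = 60.0,
    duration: float = 2400.0,
    sampling_interval: float = 10.0,
    noise_sigma: float = 0.0,
    rise_tau: float | None = None,
    seed: int = 0,
    well_id: str = "A1",
) -> ResistanceTrace:
    """Monolayer-resistance trace with stimulus-locked response.

    During each stimulus window the resistance steps to
    baseline + amplitude (optionally with a finite mono-exponential rise
    of time constant ``rise_tau``); after the window it relaxes back to
    baseline exponentially with ``relax_tau``. Default sampling every
    10 s matches impedance-sensing acquisition. Gaussian noise of
    ``noise_sigma`` is added when requested.
    """
    if relax_tau <= 0:
        raise ValueError("relax_tau must be positive")
    t = np.arange(0.0, duration, sampling_interval)
    wins = sorted(stim_windows)
    dev = np.zeros_like(t)  # deviation from baseline at each sample
    for i, tt in enumerate(t):
        d = 0.0
        for a, b in wins:
            if tt < a:
                break
            if a <= tt < b:
                if rise_tau is None:
                    d = amplitude
                else:
                    d = amplitude * (1.0 - math.exp(-(tt - a) / rise_tau))
            elif tt >= b:
                if rise_tau is None:
                    d_end = amplitude
                else:
                    d_end = amplitude * (1.0 - math.exp(-(b - a) / rise_tau))
                d = d_end * math.exp(-(tt - b) / relax_tau)
        dev[i] = d
    value = baseline + dev
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        value = value + rng.normal(0.0, noise_sigma, size=value.shape)
    return ResistanceTrace(
        time=t, resistance=value, stim_windows=list(wins), well_id=well_id
    )
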