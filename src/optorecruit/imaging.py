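"""Image I/O, thresholding, filtering and ROI construction.

This module is the shared substrate for all quantification stages: a
time-lapse container (:class:`ImageStack`), the three histogram
thresholders the original FIJI/CellProfiler workflows relied on (Huang
fuzzy-entropy, Otsu between-class variance, IsoData fixed point),
Gaussian filtering, background and photobleaching correction, and
automatic membrane/cytosol ROI construction from a membrane-marker
("bait") channel.

All thresholders operate on a 256-bin histogram spanning the per-image
min–max intensity range, which is the FIJI convention; thresholds are
returned as intensities (the upper edge of the last background bin), and
the "dark background" orientation is used throughout: pixels with
intensity strictly above the threshold are foreground.

All operations are pure: input arrays are never modified in place.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.ndimage as ndi
import scipy.optimize
import tifffile
from skimage.morphology import disk

__all__ = [
    "ImageStack",
    "RoiSet",
    "read_stack",
    "write_stack",
    "threshold_huang",
    "threshold_otsu",
    "threshold_isodata",
    "gaussian_blur",
    "background_correct",
    "bleach_correct_exponential",
    "make_membrane_cytosol_rois",
    "save_rois",
    "load_rois",
]

N_BINS = 256


@dataclass
class ImageStack:
    """A T×C×Y×X time-lapse with physical calibration.

    Parameters
    ----------
    data:
        Intensity array, axes (time, channel, row, column). Arbitrary
        units; float or integer dtype.
    frame_interval:
        Time between frames in seconds; must be positive.
    pixel_size:
        Pixel edge length in micrometres.
    channel_roles:
        Map from role name (``"bait"``, ``"prey"``, ``"junction_stain"``,
        ``"nucleus"``, ...) to channel index.

    Pixel coordinates are 0-based ``(row, column)`` with the pixel-center
    convention.
    """

    data: np.ndarray
    frame_interval: float = 1.0
    pixel_size: float = 1.0
    channel_roles: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(
                f"stack data must be 4-D (T, C, Y, X); got ndim={self.data.ndim}"
            )
        if min(self.data.shape) < 1:
            raise ValueError("all stack dimensions must be >= 1")
        if not (self.frame_interval > 0):
            raise ValueError("frame_interval must be positive")
        if not (self.pixel_size > 0):
            raise ValueError("pixel_size must be positive")
        for role, idx in self.channel_roles.items():
            if not 0 <= idx < self.data.shape[1]:
                raise ValueError(f"channel role {role!r} -> {idx} out of range")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def shape(self) -> tuple[int, int, int, int]:
        return self.data.shape

    @property
    def times(self) -> np.ndarray:
        """Frame acquisition times in seconds (frame 0 at t = 0)."""
        return np.arange(self.n_frames) * self.frame_interval

    def channel(self, role_or_index: str | int) -> np.ndarray:
        """Return the T×Y×X sub-stack for a channel role or index."""
        if isinstance(role_or_index, str):
            if role_or_index not in self.channel_roles:
                raise KeyError(f"unknown channel role {role_or_index!r}")
            idx = self.channel_roles[role_or_index]
        else:
            idx = int(role_or_index)
        return self.data[:, idx]

    def copy(self) -> "ImageStack":
        return ImageStack(
            data=self.data.copy(),
            frame_interval=self.frame_interval,
            pixel_size=self.pixel_size,
            channel_roles=dict(self.channel_roles),
        )


@dataclass
class RoiSet:
    """Named binary masks over the Y×X grid.

    Standard names: ``membrane``, ``cytosol``, ``background``,
    ``activation_roi``. Membrane and cytosol must be disjoint.
    """

    masks: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        self.masks = {k: np.asarray(v, dtype=bool) for k, v in self.masks.items()}
        shapes = {m.shape for m in self.masks.values()}
        if len(shapes) > 1:
            raise ValueError(f"ROI masks have inconsistent shapes: {shapes}")
        mem = self.masks.get("membrane")
        cyt = self.masks.get("cytosol")
        if mem is not None and cyt is not None and np.any(mem & cyt):
            raise ValueError("membrane and cytosol ROIs must be disjoint")

    def __getitem__(self, name: str) -> np.ndarray:
        return self.masks[name]

    def __contains__(self, name: str) -> bool:
        return name in self.masks


# ---------------------------------------------------------------------------
# I/O

def write_stack(stack: ImageStack, path: str | Path) -> None:
    """Write a stack as TIFF (axes TCYX) with a JSON metadata sidecar."""
    path = Path(path)
    tifffile.imwrite(path, stack.data, metadata={"axes": "TCYX"})
    meta = {
        "frame_interval": stack.frame_interval,
        "pixel_size": stack.pixel_size,
        "channel_roles": stack.channel_roles,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta))


def read_stack(path: str | Path, axes: str | None = None) -> ImageStack:
    """Read a TIFF into an :class:`ImageStack`.

    1-D to 4-D inputs are promoted to T×C×Y×X: a plain Y×X frame becomes
    T=1, C=1; a 3-D array is interpreted per ``axes`` ("TYX" or "CYX",
    default "TYX"). A sidecar JSON written by :func:`write_stack` restores
    calibration and channel roles.
    """
    path = Path(path)
    data = tifffile.imread(path)
    if data.ndim > 4:
        raise ValueError(f"cannot interpret {data.ndim}-D TIFF as T×C×Y×X")
    if data.ndim == 1:
        raise ValueError("1-D TIFF is not an image")
    if data.ndim == 2:
        data = data[None, None]
    elif data.ndim == 3:
        order = axes or "TYX"
        if order == "TYX":
            data = data[:, None]
        elif order == "CYX":
            data = data[None, :]
        else:
            raise ValueError(f"unsupported 3-D axis order {order!r}")
    kwargs: dict = {}
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        kwargs = {
            "frame_interval": meta["frame_interval"],
            "pixel_size": meta["pixel_size"],
            "channel_roles": {k: int(v) for k, v in meta["channel_roles"].items()},
        }
    return ImageStack(data=data, **kwargs)


def save_rois(rois: RoiSet, path: str | Path) -> None:
    """Write an ROI set as JSON with run-length-encoded masks."""
    payload = {}
    for name, mask in rois.masks.items():
        flat = mask.ravel()
        # RLE: alternating run lengths, starting with a False run
        change = np.flatnonzero(np.diff(flat)) + 1
        bounds = np.concatenate([[0], change, [flat.size]])
        runs = np.diff(bounds).tolist()
        if flat[0]:
            runs = [0] + runs
        payload[name] = {"shape": list(mask.shape), "runs": runs}
    Path(path).write_text(json.dumps(payload))


def load_rois(path: str | Path) -> RoiSet:
    """Read an ROI set written by :func:`save_rois`."""
    payload = json.loads(Path(path).read_text())
    masks = {}
    for name, entry in payload.items():
        size = int(np.prod(entry["shape"]))
        flat = np.zeros(size, dtype=bool)
        pos, value = 0, False
        for run in entry["runs"]:
            if value:
                flat[pos : pos + run] = True
            pos += run
            value = not value
        masks[name] = flat.reshape(entry["shape"])
    return RoiSet(masks=masks)


# ---------------------------------------------------------------------------
# Thresholding (256-bin FIJI-style histograms)

def _histogram(image: np.ndarray) -> tuple[np.ndarray, float, float]:
    """256-bin histogram over the image's min–max range.

    Returns (counts, lo, hi). Raises on a constant image, for which no
    threshold separates two classes.
    """
    img = np.asarray(image, dtype=float).ravel()
    lo, hi = float(img.min()), float(img.max())
    if not np.isfinite(lo) or not np.isfinite(hi):
        raise ValueError("image contains non-finite values")
    if lo == hi:
        raise ValueError("constant image: histogram is degenerate, no threshold exists")
    counts, _ = np.histogram(img, bins=N_BINS, range=(lo, hi))
    return counts.astype(float), lo, hi


def _bin_to_intensity(t_bin: int, lo: float, hi: float) -> float:
    """Upper edge of bin ``t_bin``; foreground is intensity > threshold."""
    return lo + (t_bin + 1) * (hi - lo) / N_BINS


def threshold_huang(image: np.ndarray) -> float:
    """Huang–Wang minimum-fuzzy-entropy threshold (dark background).

    For each candidate split the image is fuzzified: a pixel's membership
    to its class is u = 1 / (1 + |g − μ_class| / C) with C the intensity
    range, and the Shannon entropy of the membership map, weighted by the
    histogram, is minimized. Returns an intensity; pixels strictly above
    it are foreground.
    """
    counts, lo, hi = _histogram(image)
    levels = np.arange(N_BINS, dtype=float)
    total = counts.sum()
    # cumulative moments for class means below/above each candidate
    csum = np.cumsum(counts)
    cmom = np.cumsum(counts * levels)
    best_t, best_s = 0, np.inf
    c_norm = N_BINS - 1.0  # fuzzy range constant, in bin units
    for t in range(N_BINS - 1):
        w0 = csum[t]
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        mu0 = cmom[t] / w0
        mu1 = (cmom[-1] - cmom[t]) / w1
        u = np.empty(N_BINS)
        u[: t + 1] = 1.0 / (1.0 + np.abs(levels[: t + 1] - mu0) / c_norm)
        u[t + 1 :] = 1.0 / (1.0 + np.abs(levels[t + 1 :] - mu1) / c_norm)
        # Shannon fuzzy entropy; u is in (0.5, 1] so 1-u may be 0
        with np.errstate(divide="ignore", invalid="ignore"):
            h = -u * np.log(u) - (1.0 - u) * np.log(1.0 - u)
        h[~np.isfinite(h)] = 0.0
        s = float(np.dot(counts, h))
        if s < best_s:
            best_s, best_t = s, t
    return _bin_to_intensity(best_t, lo, hi)


def threshold_otsu(image: np.ndarray) -> float:
    """Otsu threshold maximizing between-class variance (two classes).

    The variance is piecewise constant across empty histogram gaps; the
    midpoint of the maximizing plateau is returned, so a balanced bimodal
    image thresholds at the midpoint between its modes.
    """
    counts, lo, hi = _histogram(image)
    levels = np.arange(N_BINS, dtype=float)
    total = counts.sum()
    csum = np.cumsum(counts)
    cmom = np.cumsum(counts * levels)
    w0 = csum[:-1] / total
    w1 = 1.0 - w0
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = cmom[:-1] / csum[:-1]
        mu1 = (cmom[-1] - cmom[:-1]) / (total - csum[:-1])
    sigma_b = np.where((w0 > 0) & (w1 > 0), w0 * w1 * (mu0 - mu1) ** 2, -np.inf)
    best = np.max(sigma_b)
    if not np.isfinite(best):
        raise ValueError("degenerate histogram: all pixels in one bin")
    plateau = np.flatnonzero(np.isclose(sigma_b, best, rtol=1e-12, atol=0.0))
    t_bin = int(round(plateau.mean()))
    return _bin_to_intensity(t_bin, lo, hi)


def threshold_isodata(image: np.ndarray) -> float:
    """IsoData (Ridler–Calvard) threshold — FIJI's "Default" method.

    Iterates t ← (mean below t + mean above t) / 2 on the 256-bin
    histogram until the fixed point is reached.
    """
    counts, lo, hi = _histogram(image)
    levels = np.arange(N_BINS, dtype=float)
    csum = np.cumsum(counts)
    cmom = np.cumsum(counts * levels)
    total, total_mom = csum[-1], cmom[-1]

    t = N_BINS // 2
    for _ in range(N_BINS):
        w0 = csum[t]
        if w0 == 0:
            t += 1
            continue
        if w0 == total:
            t -= 1
            continue
        mu0 = cmom[t] / w0
        mu1 = (total_mom - cmom[t]) / (total - w0)
        t_new = int(round((mu0 + mu1) / 2.0))
        if t_new == t:
            break
        t = t_new
    return _bin_to_intensity(t, lo, hi)


# ---------------------------------------------------------------------------
# Filtering and corrections

def gaussian_blur(image: np.ndarray, sigma: float) -> np.ndarray:
    """Gaussian filter with a normalized kernel and reflective boundary.

    ``sigma`` is in pixels; ``sigma=0`` returns an unchanged copy.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    img = np.asarray(image, dtype=float)
    if sigma == 0:
        return img.copy()
    return ndi.gaussian_filter(img, sigma=sigma, mode="reflect")


def background_correct(stack: ImageStack, background_roi: np.ndarray) -> ImageStack:
    """Subtract the per-frame mean of a background ROI; clip at zero.

    The ROI is applied per channel: each (frame, channel) plane has the
    mean of its own background pixels removed.
    """
    roi = np.asarray(background_roi, dtype=bool)
    if roi.shape != stack.data.shape[2:]:
        raise ValueError("background ROI shape does not match image planes")
    if not roi.any():
        raise ValueError("background ROI is empty")
    data = np.asarray(stack.data, dtype=float).copy()
    bg = data[:, :, roi].mean(axis=2)  # (T, C)
    data -= bg[:, :, None, None]
    np.clip(data, 0.0, None, out=data)
    out = stack.copy()
    out.data = data
    return out


def bleach_correct_exponential(
    stack: ImageStack, channel: str | int
) -> tuple[ImageStack, bool]:
    """Photobleaching correction by an exponential fit to frame means.

    Fits the frame-mean series of the given channel to a·exp(−b·t)
    (FIJI's "Exponential" bleach-correction model, no offset) and divides
    frame k of that channel by fit(t_k)/fit(t_0). Returns the corrected
    stack and a success flag; a non-decaying series or failed fit leaves
    the stack unchanged (flag False) with a warning.
    """
    ch = stack.channel_roles[channel] if isinstance(channel, str) else int(channel)
    data = np.asarray(stack.data, dtype=float).copy()
    means = data[:, ch].mean(axis=(1, 2))
    t = stack.times

    def model(tt, a, b):
        return a * np.exp(-b * tt)

    ok = True
    try:
        b0 = 1.0 / max(t[-1], 1e-9)
        popt, _ = scipy.optimize.curve_fit(
            model, t, means, p0=[means[0], b0], maxfev=10_000
        )
        a_fit, b_fit = popt
        if b_fit <= 0 or a_fit <= 0:
            raise RuntimeError("series does not decay")
        factor = model(t, a_fit, b_fit) / model(0.0, a_fit, b_fit)
        data[:, ch] /= factor[:, None, None]
    except (RuntimeError, scipy.optimize.OptimizeWarning):
        warnings.warn("bleach correction skipped: exponential fit failed", stacklevel=2)
        ok = False
    out = stack.copy()
    if ok:
        out.data = data
    return out, ok


# ---------------------------------------------------------------------------
# ROI construction

def make_membrane_cytosol_rois(
    bait_frame: np.ndarray, band_px: int = 3, erode_px: int = 2
) -> RoiSet:
    """Build membrane / cytosol / background ROIs from a bait frame.

    The cell mask is the IsoData foreground of the membrane-marker
    channel's first activation frame. The membrane ROI is the rim left by
    subtracting an erosion of the filled mask by ``band_px``; the cytosol
    ROI is the filled mask eroded by ``band_px + erode_px``, guaranteeing
    disjointness with a safety margin. Background is the complement of
    the filled mask.
    """
    frame = np.asarray(bait_frame, dtype=float)
    thr = threshold_isodata(frame)
    mask = frame > thr
    filled = ndi.binary_fill_holes(mask)
    inner = ndi.binary_erosion(filled, structure=disk(band_px))
    membrane = filled & ~inner
    cytosol = ndi.binary_erosion(filled, structure=disk(band_px + erode_px))
    if not membrane.any():
        raise ValueError("membrane ROI empty after erosion")
    if not cytosol.any():
        raise ValueError("cytosol ROI empty: cell too small for requested erosion")
    return RoiSet(
        masks={
            "membrane": membrane,
            "cytosol": cytosol,
            "background": ~filled,
        }
    )
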