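"""Independent brute-force reference implementations used by the tests.

These deliberately use plain Python loops and restate the definitions
from first principles, so they share no code path with the package's
vectorized implementations.
"""

import math

import numpy as np

N_BINS = 256


def histogram_256(image):
    img = np.asarray(image, dtype=float).ravel()
    lo, hi = float(img.min()), float(img.max())
    counts, _ = np.histogram(img, bins=N_BINS, range=(lo, hi))
    return counts.tolist(), lo, hi


def bin_upper_edge(t, lo, hi):
    return lo + (t + 1) * (hi - lo) / N_BINS


def huang_bruteforce(image):
    """Exhaustive minimization of Huang–Wang fuzzy entropy."""
    counts, lo, hi = histogram_256(image)
    total = sum(counts)
    c = N_BINS - 1.0
    best_t, best_s = 0, math.inf
    for t in range(N_BINS - 1):
        w0 = sum(counts[: t + 1])
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        mu0 = sum(g * counts[g] for g in range(t + 1)) / w0
        mu1 = sum(g * counts[g] for g in range(t + 1, N_BINS)) / w1
        s = 0.0
        for g in range(N_BINS):
            if counts[g] == 0:
                continue
            mu = mu0 if g <= t else mu1
            u = 1.0 / (1.0 + abs(g - mu) / c)
            h = 0.0
            if 0.0 < u < 1.0:
                h = -u * math.log(u) - (1.0 - u) * math.log(1.0 - u)
            s += counts[g] * h
        if s < best_s:
            best_s, best_t = s, t
    return bin_upper_edge(best_t, lo, hi)


def otsu_bruteforce(image):
    """Exhaustive between-class-variance search; plateau midpoint."""
    counts, lo, hi = histogram_256(image)
    total = sum(counts)
    best = -math.inf
    variances = []
    for t in range(N_BINS - 1):
        w0 = sum(counts[: t + 1])
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            variances.append(-math.inf)
            continue
        mu0 = sum(g * counts[g] for g in range(t + 1)) / w0
        mu1 = sum(g * counts[g] for g in range(t + 1, N_BINS)) / w1
        v = (w0 / total) * (w1 / total) * (mu0 - mu1) ** 2
        variances.append(v)
        best = max(best, v)
    plateau = [
        t
        for t, v in enumerate(variances)
        if v != -math.inf and math.isclose(v, best, rel_tol=1e-12)
    ]
    t_bin = round(sum(plateau) / len(plateau))
    return bin_upper_edge(t_bin, lo, hi)


def isodata_bruteforce(image):
    """Iterative Ridler–Calvard fixed point on the histogram."""
    counts, lo, hi = histogram_256(image)
    total = sum(counts)
    t = N_BINS // 2
    for _ in range(N_BINS):
        w0 = sum(counts[: t + 1])
        if w0 == 0:
            t += 1
            continue
        if w0 == total:
            t -= 1
            continue
        mu0 = sum(g * counts[g] for g in range(t + 1)) / w0
        mu1 = sum(g * counts[g] for g in range(t + 1, N_BINS)) / (total - w0)
        t_new = round((mu0 + mu1) / 2.0)
        if t_new == t:
            break
        t = t_new
    return bin_upper_edge(t, lo, hi)


def arc_length_quadrature(curve_fn, n=10_000):
    """Dense polyline quadrature of a parametric curve on [0, 1]."""
    s = np.linspace(0.0, 1.0, n + 1)
    pts = curve_fn(s)
    return float(np.sum(np.hypot(np.diff(pts[:, 0]), np.diff(pts[:, 1]))))
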