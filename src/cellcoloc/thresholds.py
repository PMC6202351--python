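"""Automatic intensity thresholding on a 256-bin histogram.

All algorithms operate on a 256-bin histogram of min–max scaled intensities
(the convention of ImageJ's threshold menu) and return a bin index ``t``:
bins ``0..t`` are background, ``t+1..255`` are foreground.  The public API
maps the bin boundary back to raw intensity units; foreground pixels are
those strictly above the cutoff on a dark background (strictly below on a
light background).

The registry is extensible: ``@register("Name")`` adds a method that takes a
256-element count vector and returns a bin index.
"""

from __future__ import annotations

from typing import Callable

import numpy as np

__all__ = ["auto_threshold", "foreground_mask", "threshold_bin", "register",
           "available_methods"]

_REGISTRY: dict[str, Callable[[np.ndarray], int]] = {}

_BINS = 256


def register(name: str) -> Callable:
    def deco(fn: Callable[[np.ndarray], int]) -> Callable[[np.ndarray], int]:
        _REGISTRY[name] = fn
        return fn
    return deco


def available_methods() -> list[str]:
    return sorted(_REGISTRY)


def _histogram(image: np.ndarray) -> tuple[np.ndarray, float, float]:
    flat = np.asarray(image, dtype=float).ravel()
    lo, hi = float(flat.min()), float(flat.max())
    if lo == hi:
        raise ValueError("cannot threshold a constant image")
    idx = np.floor((flat - lo) * (_BINS / (hi - lo))).astype(np.int64)
    np.clip(idx, 0, _BINS - 1, out=idx)
    hist = np.bincount(idx, minlength=_BINS).astype(float)
    return hist, lo, hi


@register("Default")
def _isodata(hist: np.ndarray) -> int:
    """Iterative intermeans (IsoData variant, ImageJ's 'Default')."""
    idx = np.arange(_BINS)
    t = int(round((idx * hist).sum() / hist.sum()))
    t = min(max(t, 0), _BINS - 2)
    for _ in range(_BINS):
        low, high = hist[: t + 1], hist[t + 1 :]
        mu1 = (idx[: t + 1] * low).sum() / low.sum() if low.sum() else 0.0
        mu2 = (idx[t + 1 :] * high).sum() / high.sum() if high.sum() else float(_BINS - 1)
        t_new = int((mu1 + mu2) / 2)
        if t_new == t:
            return t
        t = min(max(t_new, 0), _BINS - 2)
    return t


@register("Otsu")
def _otsu(hist: np.ndarray) -> int:
    """Maximize between-class variance; ties -> smallest index."""
    idx = np.arange(_BINS)
    total = hist.sum()
    w0 = np.cumsum(hist)
    w1 = total - w0
    csum = np.cumsum(hist * idx)
    mu0 = np.divide(csum, w0, out=np.zeros(_BINS), where=w0 > 0)
    mu1 = np.divide(csum[-1] - csum, w1, out=np.zeros(_BINS), where=w1 > 0)
    bcv = w0 * w1 * (mu0 - mu1) ** 2
    bcv[w1 == 0] = -1.0  # no foreground class
    return int(np.argmax(bcv))


@register("Mean")
def _mean(hist: np.ndarray) -> int:
    idx = np.arange(_BINS)
    return min(int((idx * hist).sum() / hist.sum()), _BINS - 2)


@register("MinError")
def _min_error(hist: np.ndarray) -> int:
    """Kittler–Illingworth minimum-error criterion.

    Class variances are floored at 1/12 (the quantization variance of one
    bin) to keep the criterion finite on spiky histograms.
    """
    idx = np.arange(_BINS, dtype=float)
    total = hist.sum()
    w0 = np.cumsum(hist)
    w1 = total - w0
    csum = np.cumsum(hist * idx)
    csq = np.cumsum(hist * idx**2)
    best_t, best_j = 0, np.inf
    for t in range(_BINS - 1):
        if w0[t] == 0 or w1[t] == 0:
            continue
        p0, p1 = w0[t] / total, w1[t] / total
        m0 = csum[t] / w0[t]
        m1 = (csum[-1] - csum[t]) / w1[t]
        v0 = max(csq[t] / w0[t] - m0**2, 1.0 / 12.0)
        v1 = max((csq[-1] - csq[t]) / w1[t] - m1**2, 1.0 / 12.0)
        j = 1 + p0 * np.log(v0) + p1 * np.log(v1) - 2 * (p0 * np.log(p0) + p1 * np.log(p1))
        if j < best_j:
            best_j, best_t = j, t
    return best_t


@register("Triangle")
def _triangle(hist: np.ndarray) -> int:
    """Triangle method: maximize distance from the peak-to-tail chord."""
    nz = np.nonzero(hist)[0]
    first, last = nz[0], nz[-1]
    peak = int(np.argmax(hist))
    # work on the longer tail; mirror so the tail is to the right of the peak
    flipped = (peak - first) > (last - peak)
    h = hist[::-1].copy() if flipped else hist.copy()
    peak_i = _BINS - 1 - peak if flipped else peak
    end_i = _BINS - 1 - first if flipped else last
    if end_i <= peak_i:
        return peak
    xs = np.arange(peak_i, end_i + 1, dtype=float)
    # distance from (x, h[x]) to the chord (peak_i, h[peak]) -> (end_i, 0)
    nx, ny = h[peak_i], float(end_i - peak_i)  # chord normal (unnormalized)
    d = nx * (xs - peak_i) - ny * (h[peak_i : end_i + 1] - h[peak_i])
    t = int(peak_i + np.argmax(d))
    if flipped:
        t = _BINS - 1 - t
    return min(max(t, 0), _BINS - 2)


def threshold_bin(image: np.ndarray, method: str = "Default") -> int:
    """Bin index of the background/foreground split (0..255)."""
    if method not in _REGISTRY:
        raise ValueError(
            f"unknown threshold method {method!r}; available: {available_methods()}"
        )
    hist, _, _ = _histogram(image)
    return _REGISTRY[method](hist)


def auto_threshold(image: np.ndarray, method: str = "Default",
                   polarity: object = None) -> float:
    """Automatic cutoff in raw intensity units.

    The cutoff sits on the boundary between the last background bin and the
    first foreground bin of the 256-bin scaled histogram.  ``polarity`` is
    accepted for interface symmetry; it does not change the cutoff, only how
    :func:`foreground_mask` interprets it.
    """
    hist, lo, hi = _histogram(image)
    t = threshold_bin(image, method)
    return lo + (t + 1) * (hi - lo) / _BINS


def foreground_mask(image: np.ndarray, cutoff: float,
                    polarity: str = "dark_background") -> np.ndarray:
    """Pixels above the cutoff (dark background) or below it (light)."""
    if polarity == "dark_background":
        return np.asarray(image) > cutoff
    return np.asarray(image) < cutoff
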