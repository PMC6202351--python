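"""Colocalization metrics on per-cell pixel intensity vectors.

A cell is a fixed set of ``N`` pixels with one intensity vector per reporter
channel (:class:`CellPixels`).  Thresholds are *top-percentile* selections:
``f_T = 0.1`` selects the 10% of in-cell pixels with the highest intensity in
a channel.  Selection is rank-based (exactly ``max(1, round(f_T * N))``
pixels, ties broken by pixel index), so overlap fractions are exact on a
threshold grid regardless of tied intensities.

Metrics
-------
``tos``
    Threshold overlap score.  With per-channel top fractions
    ``f_1, ..., f_k`` the observed overlap ``A_O`` (fraction of pixels
    selected in *every* channel) is rescaled against its independence
    expectation ``A_E = prod f_i`` and its attainable bounds
    ``A_max = min f_i`` and ``A_min = max(0, sum f_i - (k - 1))``::

        TOS = (A_O - A_E) / (A_max - A_E)   if A_O >= A_E   (colocalized)
        TOS = (A_O - A_E) / (A_E - A_min)   otherwise       (anticolocalized)

    giving +1 for maximal overlap, 0 for independence, -1 for minimal
    overlap.  Logarithmic scaling replaces the linear rescale with
    ``ln(A_O/A_E) / ln(A_max/A_E)`` (and its mirrored form below ``A_E``),
    emphasizing deviations at small fractions.  Undefined combinations
    (any ``f_T = 1``, zero denominators) are NaN.
``pcc`` / ``srcc``
    Pearson and Spearman (mid-rank) correlation of the channel vectors.
``icq``
    Intensity correlation quotient: the fraction of pixels whose demeaned
    intensities agree in sign, minus the chance expectation (1/2 for two
    channels, 1/4 for three).  Pixels with a zero sign product are excluded.
``manders``
    Intensity-weighted overlap: ``M1`` is the fraction of channel-1 total
    intensity that lies in pixels selected in the *other* channel(s);
    ``M2`` (and ``M3``) by symmetry.
``costes_thresholds``
    Costes' automatic threshold pair: descend along the least-squares
    regression line ``B = a + b A`` until the correlation of the
    below-threshold pixels is no longer positive.

When a :class:`ThresholdSpec` is passed to ``pcc``/``srcc``/``icq`` the
statistic is computed as if only the selected pixels existed; the restricted
set is the *intersection* of the per-channel selections.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "CellPixels",
    "ThresholdSpec",
    "TosTerms",
    "select_top_fraction",
    "tos",
    "tos_terms",
    "pcc",
    "srcc",
    "icq",
    "manders",
    "costes_thresholds",
]


@dataclass
class CellPixels:
    """Equal-length per-channel intensity vectors in one common pixel order."""

    channels: tuple[np.ndarray, ...]

    def __init__(self, *channels) -> None:
        if len(channels) == 1 and isinstance(channels[0], (list, tuple)):
            channels = tuple(channels[0])
        arrs = tuple(np.asarray(c, dtype=float).ravel() for c in channels)
        if not 2 <= len(arrs) <= 3:
            raise ValueError("a cell carries 2 or 3 reporter channels")
        n = arrs[0].size
        if n < 1 or any(a.size != n for a in arrs):
            raise ValueError("channel vectors must share one length >= 1")
        self.channels = arrs

    @property
    def n(self) -> int:
        return self.channels[0].size

    @property
    def k(self) -> int:
        return len(self.channels)


@dataclass(frozen=True)
class ThresholdSpec:
    """Top-percentile fraction per channel, each in (0, 1]."""

    fractions: tuple[float, ...]

    def __init__(self, *fractions) -> None:
        if len(fractions) == 1 and isinstance(fractions[0], (list, tuple)):
            fractions = tuple(fractions[0])
        for f in fractions:
            if not 0.0 < f <= 1.0:
                raise ValueError(f"f_T must be in (0, 1], got {f}")
        object.__setattr__(self, "fractions", tuple(float(f) for f in fractions))


@dataclass(frozen=True)
class TosTerms:
    a_o: float  # observed overlap fraction
    a_e: float  # expected overlap under independence
    a_max: float  # largest attainable overlap
    a_min: float  # smallest attainable overlap


def select_top_fraction(values: np.ndarray, f_t: float) -> np.ndarray:
    """Indices of the top ``max(1, round(f_t * N))`` pixels by intensity.

    Ranking is by descending intensity with ties broken by ascending pixel
    index; ``f_t = 1`` selects every pixel.
    """
    values = np.asarray(values, dtype=float).ravel()
    n = values.size
    if n < 1:
        raise ValueError("empty intensity vector")
    if not 0.0 < f_t <= 1.0:
        raise ValueError(f"f_T must be in (0, 1], got {f_t}")
    if f_t == 1.0:
        return np.arange(n)
    n_sel = max(1, int(np.floor(f_t * n + 0.5)))
    order = np.argsort(-values, kind="stable")  # stable: ties keep index order
    return np.sort(order[:n_sel])


def _selections(cell: CellPixels, spec: ThresholdSpec) -> list[np.ndarray]:
    if len(spec.fractions) != cell.k:
        raise ValueError(
            f"threshold spec has {len(spec.fractions)} fractions for "
            f"{cell.k} channels"
        )
    masks = []
    for vals, f in zip(cell.channels, spec.fractions):
        m = np.zeros(cell.n, dtype=bool)
        m[select_top_fraction(vals, f)] = True
        masks.append(m)
    return masks


def tos_terms(cell: CellPixels, spec: ThresholdSpec) -> TosTerms:
    """Overlap terms from the actual selected pixel counts."""
    masks = _selections(cell, spec)
    n = cell.n
    fs = [m.sum() / n for m in masks]
    inter = masks[0]
    for m in masks[1:]:
        inter = inter & m
    a_o = inter.sum() / n
    a_e = float(np.prod(fs))
    a_max = float(min(fs))
    a_min = max(0.0, sum(fs) - (cell.k - 1))
    return TosTerms(float(a_o), a_e, a_max, a_min)


def _tos_linear(t: TosTerms) -> float:
    if t.a_o >= t.a_e:
        denom = t.a_max - t.a_e
        return (t.a_o - t.a_e) / denom if denom > 0 else np.nan
    denom = t.a_e - t.a_min
    return (t.a_o - t.a_e) / denom if denom > 0 else np.nan


def tos(cell: CellPixels, spec: ThresholdSpec, scaling: str = "linear") -> float:
    """Threshold overlap score in ``[-1, 1]``, or NaN where undefined.

    Any channel at ``f_T = 1`` makes the score uninformative (overlap is
    forced) and yields NaN — the blacked-out row/column of a metric matrix.
    On the anticolocalization branch of the log scaling, ``A_min = 0`` makes
    the log rescale degenerate; the linear-branch value is returned there.
    """
    if scaling not in ("linear", "log"):
        raise ValueError(f"scaling must be 'linear' or 'log', got {scaling!r}")
    if spec is None:
        raise ValueError("TOS requires a threshold")
    t = tos_terms(cell, spec)
    if scaling == "linear":
        return _tos_linear(t)
    if t.a_o >= t.a_e:
        if t.a_max <= t.a_e or t.a_e <= 0:
            return np.nan
        return float(np.log(t.a_o / t.a_e) / np.log(t.a_max / t.a_e))
    # a_o >= a_min always (inclusion-exclusion), so a_o = 0 implies a_min = 0
    if t.a_min <= 0:
        return _tos_linear(t)
    return float(-np.log(t.a_o / t.a_e) / np.log(t.a_min / t.a_e))


def _restrict(cell: CellPixels, spec: ThresholdSpec | None) -> list[np.ndarray]:
    """Channel vectors restricted to the intersection of the selections."""
    if spec is None:
        return list(cell.channels)
    masks = _selections(cell, spec)
    keep = masks[0]
    for m in masks[1:]:
        keep = keep & m
    return [c[keep] for c in cell.channels]


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if a.size < 2:
        return np.nan
    da, db = a - a.mean(), b - b.mean()
    va, vb = (da**2).sum(), (db**2).sum()
    if va == 0 or vb == 0:
        return np.nan
    return float((da * db).sum() / np.sqrt(va * vb))


def _midranks(x: np.ndarray) -> np.ndarray:
    from scipy.stats import rankdata

    return rankdata(x, method="average")


def pcc(cell: CellPixels, spec: ThresholdSpec | None = None) -> float:
    """Pearson correlation of the two channels (optionally threshold-restricted)."""
    if cell.k != 2:
        raise ValueError("PCC is defined for two channels")
    a, b = _restrict(cell, spec)
    return _pearson(a, b)


def srcc(cell: CellPixels, spec: ThresholdSpec | None = None) -> float:
    """Spearman rank correlation (Pearson on mid-ranks)."""
    if cell.k != 2:
        raise ValueError("SRCC is defined for two channels")
    a, b = _restrict(cell, spec)
    if a.size < 2:
        return np.nan
    return _pearson(_midranks(a), _midranks(b))


def icq(cell: CellPixels, spec: ThresholdSpec | None = None) -> float:
    """Intensity correlation quotient.

    Two channels: fraction of pixels whose demeaned intensities share a sign,
    minus 1/2, over pixels with a nonzero product — range [-0.5, 0.5].
    Three channels: fraction of pixels where all three demeaned intensities
    share a sign, minus 1/4 (the chance level 2 * (1/2)^3) — range
    [-0.25, 0.75].  Means are taken on the restricted set.
    """
    vecs = _restrict(cell, spec)
    if vecs[0].size == 0:
        return np.nan
    dev = [v - v.mean() for v in vecs]
    if len(dev) == 2:
        prod = dev[0] * dev[1]
        valid = prod != 0
        if not valid.any():
            return np.nan
        return float((prod[valid] > 0).mean() - 0.5)
    nonzero = (dev[0] != 0) & (dev[1] != 0) & (dev[2] != 0)
    if not nonzero.any():
        return np.nan
    pos = (dev[0] > 0) & (dev[1] > 0) & (dev[2] > 0)
    neg = (dev[0] < 0) & (dev[1] < 0) & (dev[2] < 0)
    same = (pos | neg)[nonzero]
    return float(same.mean() - 0.25)


def manders(cell: CellPixels, spec: ThresholdSpec) -> tuple[float, ...]:
    """Manders coefficients ``(M1, ..., Mk)``.

    ``Mi`` is the fraction of channel-i total intensity residing in pixels
    selected in every *other* channel; NaN when channel i sums to zero.
    """
    if spec is None:
        raise ValueError("Manders coefficients require a threshold")
    masks = _selections(cell, spec)
    out = []
    for i, vals in enumerate(cell.channels):
        others = np.ones(cell.n, dtype=bool)
        for j, m in enumerate(masks):
            if j != i:
                others &= m
        total = vals.sum()
        out.append(float(vals[others].sum() / total) if total > 0 else np.nan)
    return tuple(out)


def costes_thresholds(
    cell: CellPixels, max_steps: int = 512
) -> tuple[float, float]:
    """Costes' automatic threshold pair ``(T_A, T_B)``.

    Fits ``B = a + b A`` by ordinary least squares on all in-cell pixels,
    then scans ``T_A`` downward over the sorted unique intensities of A (or
    ``max_steps`` evenly spaced quantiles when there are more), with
    ``T_B = a + b T_A``, returning the first (highest) pair at which the
    Pearson correlation of the strictly-below-threshold pixels is <= 0.
    Steps where that correlation is undefined are skipped.  If the
    correlation never drops to zero the scan exhausts to the minimum of A,
    which is returned with a warning.
    """
    if cell.k != 2:
        raise ValueError("Costes thresholds are defined for two channels")
    a_vals, b_vals = cell.channels
    if cell.n < 8:
        raise ValueError("Costes' method needs at least 8 pixels")
    va = np.var(a_vals)
    if va == 0 or np.var(b_vals) == 0:
        raise ValueError("degenerate regression: a channel is constant")
    b = float(np.cov(a_vals, b_vals, bias=True)[0, 1] / va)
    a = float(b_vals.mean() - b * a_vals.mean())

    uniq = np.unique(a_vals)[::-1]  # descending
    if uniq.size > max_steps:
        qs = np.linspace(1.0, 0.0, max_steps)
        uniq = np.quantile(a_vals, qs)
    for t_a in uniq:
        t_b = a + b * t_a
        below = (a_vals < t_a) & (b_vals < t_b)
        r = _pearson(a_vals[below], b_vals[below])
        if np.isfinite(r) and r <= 0:
            return float(t_a), float(t_b)
    t_a = float(a_vals.min())
    warnings.warn(
        "below-threshold correlation never reached zero; Costes scan "
        "descended to the minimum intensity",
        stacklevel=2,
    )
    return t_a, a + b * t_a
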