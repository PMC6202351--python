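"""Metric matrices over the F_T threshold grid, heat maps, scatter data.

A metric matrix evaluates one colocalization metric at every combination of
per-channel top-percentile thresholds.  The step ``F_T`` defines the grid
``{F_T, 2 F_T, ...}`` capped at 1; when ``F_T`` does not divide 1 evenly the
remainder is the last step (step 0.3 -> 0.3, 0.6, 0.9, 1.0).  Entries where
a metric's contract is undefined are NaN — for TOS that is the entire
``f_T = 1`` row/column, rendered black in the plugin-style display.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from .io import ChannelStack, LabelMap
from .metrics import CellPixels, ThresholdSpec, icq, manders, pcc, srcc, tos

__all__ = [
    "MetricMatrix",
    "threshold_grid",
    "metric_matrix",
    "aggregate_matrices",
    "heatmap",
    "scatterplot_data",
    "METRIC_FUNCTIONS",
    "register_metric",
]


def _make_builtin() -> dict[str, Callable[[CellPixels, ThresholdSpec], float]]:
    def m_i(i: int):
        def f(cell: CellPixels, spec: ThresholdSpec) -> float:
            vals = manders(cell, spec)
            if i >= len(vals):
                raise ValueError(f"M{i + 1} undefined for {len(vals)} channels")
            return vals[i]

        return f

    return {
        "TOS": lambda c, s: tos(c, s, "linear"),
        "TOS(log)": lambda c, s: tos(c, s, "log"),
        "PCC": pcc,
        "SRCC": srcc,
        "ICQ": icq,
        "M1": m_i(0),
        "M2": m_i(1),
        "M3": m_i(2),
    }


METRIC_FUNCTIONS = _make_builtin()


def register_metric(name: str, fn: Callable[[CellPixels, ThresholdSpec], float]) -> None:
    """Register a custom metric ``fn(cell, spec) -> float`` for matrices/tables."""
    METRIC_FUNCTIONS[name] = fn


@dataclass
class MetricMatrix:
    grid: np.ndarray  # shared f_T axis values
    values: np.ndarray  # 2-D or 3-D, NaN where undefined
    metric: str
    scaling: str = "none"

    @property
    def ndim(self) -> int:
        return self.values.ndim


def threshold_grid(step_ft: float) -> np.ndarray:
    """Grid ``{step, 2*step, ...}`` capped at 1.0 with a final partial step."""
    if not 0.0 < step_ft <= 1.0:
        raise ValueError(f"step F_T must be in (0, 1], got {step_ft}")
    n = math.ceil(round(1.0 / step_ft, 9))
    pts = [round(i * step_ft, 10) for i in range(1, n)]
    return np.array(pts + [1.0])


def metric_matrix(
    cell: CellPixels, metric: str, step_ft: float, scaling: str = "linear"
) -> MetricMatrix:
    """Evaluate ``metric`` at every grid combination of per-channel f_T."""
    name = metric
    if metric == "TOS" and scaling == "log":
        name = "TOS(log)"
    if name not in METRIC_FUNCTIONS:
        raise ValueError(f"unknown metric {metric!r}; known: {sorted(METRIC_FUNCTIONS)}")
    fn = METRIC_FUNCTIONS[name]
    grid = threshold_grid(step_ft)
    shape = (grid.size,) * cell.k
    values = np.full(shape, np.nan)
    for idx in np.ndindex(*shape):
        spec = ThresholdSpec(*(float(grid[i]) for i in idx))
        values[idx] = fn(cell, spec)
    return MetricMatrix(grid, values, metric, scaling if metric == "TOS" else "none")


def _mode_binned(vals: np.ndarray) -> float:
    """Mode on values binned to width 0.01 over [-1, 1]; ties -> lower bin."""
    edges = np.linspace(-1.0, 1.0, 201)
    idx = np.clip(np.searchsorted(edges, vals, side="right") - 1, 0, 199)
    counts = np.bincount(idx, minlength=200)
    best = int(np.argmax(counts))
    return float((edges[best] + edges[best + 1]) / 2)


def aggregate_matrices(matrices: list[MetricMatrix], stat: str = "median") -> MetricMatrix:
    """Element-wise mean/median/mode across cells, NaN entries excluded.

    An element is NaN only when it is NaN in every input matrix.
    """
    if not matrices:
        raise ValueError("no matrices to aggregate")
    first = matrices[0]
    for m in matrices[1:]:
        if m.values.shape != first.values.shape or not np.allclose(m.grid, first.grid):
            raise ValueError("matrices must share one grid")
        if m.metric != first.metric:
            raise ValueError("matrices must share one metric")
    stack = np.stack([m.values for m in matrices])
    out = np.full(first.values.shape, np.nan)
    flat = stack.reshape(stack.shape[0], -1)
    for j in range(flat.shape[1]):
        col = flat[:, j]
        col = col[np.isfinite(col)]
        if col.size == 0:
            continue
        if stat == "mean":
            v = float(col.mean())
        elif stat == "median":
            v = float(np.median(col))
        elif stat == "mode":
            v = _mode_binned(col)
        else:
            raise ValueError(f"stat must be mean/median/mode, got {stat!r}")
        out.ravel()[j] = v
    return MetricMatrix(first.grid.copy(), out, first.metric, first.scaling)


def heatmap(
    channel: ChannelStack, labelmaps: list[LabelMap], scope: str = "cell"
) -> list[np.ndarray]:
    """8-bit heat maps: in-cell intensities rescaled so min -> 0, max -> 255.

    ``scope`` picks the normalization window: each cell independently, all
    in-cell pixels of one image, or all in-cell pixels of the stack.
    Background pixels are 0; a constant scope maps to 0.
    """
    if scope not in ("cell", "image", "stack"):
        raise ValueError(f"scope must be cell/image/stack, got {scope!r}")
    if len(labelmaps) != len(channel):
        raise ValueError("one label map per image is required")

    def rescale(img: np.ndarray, mask: np.ndarray, lo: float, hi: float,
                out: np.ndarray) -> None:
        if hi > lo:
            out[mask] = np.round((img[mask] - lo) * (255.0 / (hi - lo)))

    outputs = [np.zeros(img.shape, dtype=np.uint8) for img in channel.images]
    if scope == "stack":
        pool = np.concatenate(
            [img[lm.labels > 0].astype(float)
             for img, lm in zip(channel.images, labelmaps)]
        )
        lo, hi = (pool.min(), pool.max()) if pool.size else (0.0, 0.0)
    for img, lm, out in zip(channel.images, labelmaps, outputs):
        incell = lm.labels > 0
        if not incell.any():
            continue
        if scope == "image":
            vals = img[incell].astype(float)
            lo, hi = vals.min(), vals.max()
        if scope == "cell":
            for k in range(1, lm.n_objects + 1):
                mask = lm.labels == k
                vals = img[mask].astype(float)
                rescale(img.astype(float), mask, vals.min(), vals.max(), out)
        else:
            rescale(img.astype(float), incell, lo, hi, out)
    return outputs


def scatterplot_data(cell: CellPixels) -> pd.DataFrame:
    """Long-format per-pixel intensity table for 2-D/3-D scatterplots."""
    data = {"pixel": np.arange(cell.n)}
    for i, vals in enumerate(cell.channels, start=1):
        data[f"channel{i}"] = vals
    return pd.DataFrame(data)
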