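"""Per-cell data tables, summaries, histograms and mask/ROI export.

The data table is the primary analysis output: one row per retained cell,
labeled ``image:cellnumber``, with physical features, per-channel mean
intensities, and one column per requested metric.  ``NaN`` (serialized
literally in CSV) marks a value the metric's contract could not produce.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from . import ijroi
from .io import LabelMap, labelmap_outlines

logger = logging.getLogger(__name__)

__all__ = ["SummaryReport", "HistogramReport", "build_cell_table", "summarize",
           "histogram", "export_masks_and_rois"]


@dataclass(frozen=True)
class SummaryReport:
    metric: str
    count: int
    mean: float
    median: float
    stddev: float  # sample (n-1); NaN for a single cell

    def __str__(self) -> str:
        return (
            f"{self.metric}: n={self.count} mean={self.mean:.6g} "
            f"median={self.median:.6g} stddev={self.stddev:.6g}"
        )


@dataclass(frozen=True)
class HistogramReport:
    counts: np.ndarray
    count: int
    mean: float
    stddev: float
    bins: int
    min: float
    max: float
    mode: float
    bin_width: float


def build_cell_table(
    features: pd.DataFrame,
    metric_values: dict[int, dict[str, float]],
    image_name: str | dict[int, str] = "1",
) -> pd.DataFrame:
    """One row per cell: ``Label`` = ``image:cellnumber``, features, metrics.

    ``metric_values`` maps cell label -> {metric name -> value}; a metric
    missing for a cell becomes NaN.
    """
    if features.empty:
        cols = ["Label"] + [c for c in features.columns if c != "label"]
        names = sorted({m for d in metric_values.values() for m in d})
        return pd.DataFrame(columns=cols + names)
    table = features.copy()
    if isinstance(image_name, dict):
        img_of = lambda k: image_name.get(k, "1")  # noqa: E731
    else:
        img_of = lambda k: image_name  # noqa: E731
    table.insert(0, "Label", [f"{img_of(int(k))}:{int(k)}" for k in table["label"]])
    table = table.drop(columns=["label"])
    names = sorted({m for d in metric_values.values() for m in d})
    for name in names:
        table[name] = [
            metric_values.get(int(k.split(":")[-1]), {}).get(name, np.nan)
            for k in table["Label"]
        ]
    return table.reset_index(drop=True)


def summarize(records: pd.DataFrame, metric: str) -> SummaryReport:
    """Count/mean/median/sample-stddev of a metric over its finite values."""
    if metric not in records.columns:
        raise ValueError(f"metric {metric!r} not in the table")
    vals = pd.to_numeric(records[metric], errors="coerce").to_numpy(dtype=float)
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError(f"no finite values for metric {metric!r}")
    sd = float(np.std(vals, ddof=1)) if vals.size > 1 else np.nan
    return SummaryReport(metric, int(vals.size), float(vals.mean()),
                         float(np.median(vals)), sd)


def histogram(values, bins: int = 50) -> HistogramReport:
    """Equal-width histogram over [min, max]; right-most bin closed.

    The mode is the midpoint of the most populated bin (ties -> lower bin).
    Constant input is a degenerate single-bin histogram with bin width 0.
    """
    if bins < 1:
        raise ValueError("bins must be >= 1")
    vals = np.asarray(values, dtype=float).ravel()
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("no finite values to histogram")
    lo, hi = float(vals.min()), float(vals.max())
    if lo == hi:
        counts = np.zeros(bins, dtype=int)
        counts[0] = vals.size
        return HistogramReport(counts, vals.size, lo,
                               float(np.std(vals, ddof=1)) if vals.size > 1 else np.nan,
                               bins, lo, hi, lo, 0.0)
    width = (hi - lo) / bins
    # bins closed on the right: value v lands in ceil((v - lo)/width) - 1
    idx = np.clip(np.ceil((vals - lo) / width).astype(int) - 1, 0, bins - 1)
    counts = np.bincount(idx, minlength=bins)
    edges = lo + width * np.arange(bins + 1)
    best = int(np.argmax(counts))
    mode = float((edges[best] + edges[best + 1]) / 2)
    return HistogramReport(
        counts, int(vals.size), float(vals.mean()),
        float(np.std(vals, ddof=1)) if vals.size > 1 else np.nan,
        bins, lo, hi, mode, float((hi - lo) / bins),
    )


def export_masks_and_rois(
    labelmaps: list[LabelMap], out_dir: str | Path
) -> dict[str, Path]:
    """Write, per image, an 8-bit binary mask TIFF and an ImageJ RoiSet.zip.

    Outlines are traced along pixel edges, so re-importing the zip with
    :func:`cellcoloc.io.load_roi_set` + ``rois_to_labelmap`` reproduces the
    original pixel sets (hole-free objects).  An empty label map produces a
    zero mask and an empty zip with a warning.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: dict[str, Path] = {}
    for i, lm in enumerate(labelmaps, start=1):
        mask = ((lm.labels > 0) * np.uint8(255))
        mask_path = out / f"mask_{i:03d}.tif"
        tifffile.imwrite(mask_path, mask)
        files[f"mask_{i:03d}"] = mask_path
        rois = labelmap_outlines(lm)
        if not rois.outlines:
            logger.warning("image %d: no objects; writing an empty ROI set", i)
        ij_rois = []
        for k, outline in enumerate(rois.outlines, start=1):
            # pixel-center coords -> ImageJ corner lattice
            ij_rois.append(
                ijroi.IJRoi(
                    x=list(outline[:, 0] + 0.5),
                    y=list(outline[:, 1] + 0.5),
                    roi_type=ijroi.TRACED,
                    name=f"{i:04d}-{k:04d}",
                )
            )
        zip_path = out / (f"RoiSet_{i:03d}.zip" if len(labelmaps) > 1 else "RoiSet.zip")
        ijroi.write_roi_zip(ij_rois, zip_path)
        files[f"rois_{i:03d}"] = zip_path
    return files
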