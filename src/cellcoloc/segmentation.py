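"""Cell identification and filtering on the cell-identification channel.

Pipeline: auto-threshold -> (optional pre-watershed area cut) -> (optional
watershed split of touching objects) -> 8-connected labeling in raster-scan
order -> border-object removal -> per-object feature table -> interval
filters on physical and signal-intensity features.

Filters exist instead of learned cell detectors on purpose: they make no
assumption about cell morphology and are easy to reason about, which matters
for heterogeneous samples.  Physical features come from the
cell-identification channel; intensity features are per reporter channel,
including the object-to-background ratios ``MeanBgndRatio`` and
``MedianBgndRatio`` (object mean/median divided by the mean/median of the
extracellular pixels of the same image).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.measure import regionprops
from skimage.segmentation import watershed

from .io import ChannelStack, LabelMap, labelmap_outlines

logger = logging.getLogger(__name__)

__all__ = [
    "FilterSpec",
    "segment_cells",
    "remove_border_objects",
    "compute_features",
    "apply_filters",
    "PHYSICAL_FEATURES",
    "INTENSITY_FEATURES",
]

_EIGHT = np.ones((3, 3), dtype=bool)

# canonical filter names -> feature-table columns
PHYSICAL_FEATURES = {
    "Area": "area",
    "Perimeter": "perimeter",
    "Circularity": "circularity",
    "AspectRatio": "aspect_ratio",
    "Roundness": "roundness",
    "Solidity": "solidity",
    "Feret": "feret",
}
INTENSITY_FEATURES = {
    "MeanIntensity": "mean_intensity",
    "MedianIntensity": "median_intensity",
    "MeanBgndRatio": "mean_bgnd_ratio",
    "MedianBgndRatio": "median_bgnd_ratio",
}


@dataclass(frozen=True)
class FilterSpec:
    """Inclusive interval test on one feature.

    Physical features carry no channel; intensity features name exactly one
    reporter channel role.
    """

    parameter: str
    min: float = -np.inf
    max: float = np.inf
    channel: str | None = None

    def __post_init__(self) -> None:
        if self.min > self.max:
            raise ValueError(f"filter {self.parameter}: min > max")
        if self.parameter in PHYSICAL_FEATURES:
            if self.channel is not None:
                raise ValueError(f"physical filter {self.parameter} takes no channel")
        elif self.parameter in INTENSITY_FEATURES:
            if self.channel is None:
                raise ValueError(f"intensity filter {self.parameter} needs a channel")
        else:
            known = sorted(PHYSICAL_FEATURES) + sorted(INTENSITY_FEATURES)
            raise ValueError(f"unknown filter parameter {self.parameter!r}; known: {known}")


def _raster_relabel(labels: np.ndarray) -> np.ndarray:
    """Renumber 1..K in raster-scan order of each object's first pixel."""
    out = np.zeros_like(labels, dtype=np.int32)
    flat = labels.ravel()
    order: dict[int, int] = {}
    for v in flat[flat > 0]:
        if v not in order:
            order[v] = len(order) + 1
    for old, new in order.items():
        out[labels == old] = new
    return out


def segment_cells(
    image: np.ndarray,
    cutoff: float,
    polarity: str = "dark_background",
    use_watershed: bool = False,
    prewatershed_max_area: int | None = None,
    source_image_index: int = 0,
) -> LabelMap:
    """Binarize at ``cutoff`` and label cells.

    Objects larger than ``prewatershed_max_area`` (typically extracellular
    aggregates that watershed would shred into cell-sized fragments) are
    removed *before* watershed.  Watershed markers are the local maxima of
    the Euclidean distance transform (minimum separation 2 px, plateaus
    merged); watershed lines become background so split objects stay
    disjoint.  Labels run 1..K in raster-scan order of each object's
    topmost-leftmost pixel.
    """
    from .thresholds import foreground_mask

    fg = foreground_mask(image, cutoff, polarity)
    labeled, _ = ndi.label(fg, structure=_EIGHT)
    if prewatershed_max_area is not None:
        areas = np.bincount(labeled.ravel())
        too_big = np.nonzero(areas > prewatershed_max_area)[0]
        too_big = too_big[too_big > 0]
        if too_big.size:
            logger.info("pre-watershed filter removed %d object(s)", too_big.size)
            fg &= ~np.isin(labeled, too_big)
            labeled, _ = ndi.label(fg, structure=_EIGHT)
    if use_watershed and fg.any():
        dist = ndi.distance_transform_edt(fg)
        coords = peak_local_max(dist, min_distance=2, labels=labeled, exclude_border=False)
        peak_mask = np.zeros_like(fg)
        peak_mask[tuple(coords.T)] = True
        markers, _ = ndi.label(peak_mask, structure=_EIGHT)
        # keep the watershed regions themselves as labels: the 1-px lines are
        # 4-connected, so 8-connected relabeling could fuse split objects back
        ws = watershed(-dist, markers, mask=fg, watershed_line=True)
        labeled = ws.astype(np.int32)
    return LabelMap(_raster_relabel(labeled), source_image_index)


def remove_border_objects(labelmap: LabelMap) -> LabelMap:
    """Drop objects with any pixel on the image border; renumber 1..K."""
    lab = labelmap.labels
    border = np.unique(
        np.concatenate([lab[0, :], lab[-1, :], lab[:, 0], lab[:, -1]])
    )
    border = border[border > 0]
    if border.size:
        lab = np.where(np.isin(lab, border), 0, lab)
        if lab.max() == 0:
            logger.warning("all objects touched the border; nothing remains")
    return LabelMap(_raster_relabel(lab), labelmap.source_image_index)


def compute_features(
    labelmap: LabelMap, reporter_stacks: list[ChannelStack] | None = None
) -> pd.DataFrame:
    """Per-object feature table, one row per label.

    Physical columns: ``area``, ``centroid_x``/``centroid_y`` (mean pixel
    coordinates), ``perimeter`` (length of the traced pixel-edge outline),
    ``circularity`` (``4 pi A / P^2`` clamped to [0, 1]), ``aspect_ratio``,
    ``roundness``, ``solidity``, ``feret``.  Per reporter channel:
    ``{mean,median}_intensity_<role>`` and ``{mean,median}_bgnd_ratio_<role>``
    using label-0 pixels of the same image as the extracellular reference
    (NaN when the background mean/median is zero).
    """
    lab = labelmap.labels
    props = regionprops(lab)
    outlines = labelmap_outlines(labelmap)
    rows = []
    for p, outline in zip(props, outlines.outlines):
        d = np.diff(np.vstack([outline, outline[:1]]), axis=0)
        perim = float(np.hypot(d[:, 0], d[:, 1]).sum())
        area = float(p.area)
        circ = min(1.0, 4 * np.pi * area / perim**2) if perim > 0 else np.nan
        major, minor = p.axis_major_length, p.axis_minor_length
        rows.append(
            {
                "label": p.label,
                "area": area,
                "centroid_x": float(p.centroid[1]),
                "centroid_y": float(p.centroid[0]),
                "perimeter": perim,
                "circularity": circ,
                "aspect_ratio": float(major / minor) if minor > 0 else np.nan,
                "roundness": float(4 * area / (np.pi * major**2)) if major > 0 else np.nan,
                "solidity": float(p.solidity),
                "feret": float(p.feret_diameter_max),
            }
        )
    table = pd.DataFrame(rows)
    if table.empty:
        table = pd.DataFrame(
            columns=["label", "area", "centroid_x", "centroid_y", "perimeter",
                     "circularity", "aspect_ratio", "roundness", "solidity", "feret"]
        )
    if reporter_stacks:
        bg = lab == 0
        for stack in reporter_stacks:
            img = stack.images[labelmap.source_image_index]
            if img.shape != lab.shape:
                raise ValueError("label map and reporter images must share shape")
            bg_vals = img[bg].astype(float)
            bg_mean = float(bg_vals.mean()) if bg_vals.size else 0.0
            bg_median = float(np.median(bg_vals)) if bg_vals.size else 0.0
            means, medians, mratio, dratio = [], [], [], []
            for k in table["label"]:
                vals = img[lab == k].astype(float)
                m, md = float(vals.mean()), float(np.median(vals))
                means.append(m)
                medians.append(md)
                mratio.append(m / bg_mean if bg_mean != 0 else np.nan)
                dratio.append(md / bg_median if bg_median != 0 else np.nan)
            role = stack.role
            table[f"mean_intensity_{role}"] = means
            table[f"median_intensity_{role}"] = medians
            table[f"mean_bgnd_ratio_{role}"] = mratio
            table[f"median_bgnd_ratio_{role}"] = dratio
    return table


def apply_filters(features: pd.DataFrame, specs: list[FilterSpec]) -> set[int]:
    """Labels retained by the conjunction of all interval filters.

    Bounds are inclusive.  An object with a NaN feature fails any filter on
    that feature.
    """
    retained = set(int(v) for v in features.get("label", pd.Series(dtype=int)))
    for spec in specs:
        if spec.parameter in PHYSICAL_FEATURES:
            col = PHYSICAL_FEATURES[spec.parameter]
        else:
            col = f"{INTENSITY_FEATURES[spec.parameter]}_{spec.channel}"
        if col not in features.columns:
            raise ValueError(f"feature column {col!r} not present in the table")
        ok = (features[col] >= spec.min) & (features[col] <= spec.max)
        keep = set(int(v) for v in features.loc[ok, "label"])
        dropped = retained - keep
        if dropped:
            logger.info("filter %s dropped labels %s", spec.parameter, sorted(dropped))
        retained &= keep
    return retained
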