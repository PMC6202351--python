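"""End-to-end analysis driver: inputs -> cell filters -> visualization -> analysis.

``run_analysis`` consumes a flat key/value configuration (the CLI and YAML
config files map straight onto it), executes the full workflow and writes an
output bundle: the per-cell table CSV, a summary, metric matrices, heat
maps, mask/ROI exports and a plain-text log of every decision (thresholds
chosen, cells dropped and by which filter).  Runs are deterministic for a
given configuration.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from . import alignment as al
from . import io as cio
from . import matrices as mx
from . import metrics as me
from . import reporting as rp
from . import segmentation as sg
from . import thresholds as th

logger = logging.getLogger(__name__)

__all__ = ["run_analysis", "parse_filter", "DEFAULTS"]

DEFAULTS: dict = {
    "threshold_method": "Default",
    "background": "auto",
    "align": False,
    "max_shift": 20,
    "watershed": False,
    "prewatershed_max_area": None,
    "manual_threshold": None,
    "filters": [],
    "metrics": None,  # channel-count dependent
    "ft": 0.1,
    "scaling": "linear",
    "threshold_mode": "ft",  # ft | costes | none
    "matrix": True,
    "matrix_stat": "median",
    "heatmap": False,
    "heatmap_scope": "cell",
    "export_rois": True,
    "histogram_bins": 50,
    "summary_metric": None,
}

_TWO_CH = ["TOS", "PCC", "SRCC", "ICQ", "M1", "M2"]
_THREE_CH = ["TOS", "ICQ", "M1", "M2", "M3"]


def parse_filter(text: str) -> sg.FilterSpec:
    """Parse ``"Name[:channel]=min,max"`` into a :class:`FilterSpec`."""
    name, _, bounds = text.partition("=")
    if not bounds:
        raise ValueError(f"filter {text!r} lacks '=min,max'")
    channel = None
    if ":" in name:
        name, channel = name.split(":", 1)
    lo_s, _, hi_s = bounds.partition(",")
    lo = float(lo_s) if lo_s.strip() else -np.inf
    hi = float(hi_s) if hi_s.strip() else np.inf
    return sg.FilterSpec(name.strip(), lo, hi, channel)


def _cell_pixels(labels: np.ndarray, label: int,
                 reporter_imgs: list[np.ndarray]) -> me.CellPixels:
    mask = labels == label
    return me.CellPixels(*[img[mask].astype(float) for img in reporter_imgs])


def _metrics_for_cell(cell: me.CellPixels, names: list[str], mode: str,
                      ft: float, scaling: str, log: list[str],
                      label: str) -> dict[str, float]:
    out: dict[str, float] = {}
    if mode == "costes":
        try:
            t_a, t_b = me.costes_thresholds(cell)
            log.append(f"{label}: Costes thresholds T_A={t_a:.6g} T_B={t_b:.6g}")
        except ValueError as exc:
            log.append(f"{label}: Costes failed ({exc}); metrics NaN")
            return {n: np.nan for n in names}
        above = [cell.channels[0] > t_a, cell.channels[1] > t_b]
        both = above[0] & above[1]
        for name in names:
            if name in ("M1", "M2"):
                i = 0 if name == "M1" else 1
                total = cell.channels[i].sum()
                sel = above[1 - i]
                out[name] = float(cell.channels[i][sel].sum() / total) if total > 0 else np.nan
            elif name in ("PCC", "SRCC", "ICQ"):
                sub = me.CellPixels(*[c[both] for c in cell.channels]) if both.sum() >= 1 \
                    else None
                if sub is None:
                    out[name] = np.nan
                else:
                    fn = {"PCC": me.pcc, "SRCC": me.srcc, "ICQ": me.icq}[name]
                    out[name] = fn(sub, None)
            else:
                # TOS needs fractional thresholds; use the fraction of pixels
                # above the Costes cutoffs in each channel
                fs = [max(1, int(a.sum())) / cell.n for a in above]
                out[name] = me.tos(cell, me.ThresholdSpec(*fs), scaling)
        return out
    spec = None if mode == "none" else me.ThresholdSpec(*([ft] * cell.k))
    for name in names:
        key = "TOS(log)" if (name == "TOS" and scaling == "log") else name
        fn = mx.METRIC_FUNCTIONS[key]
        try:
            out[name] = fn(cell, spec)
        except (ValueError, TypeError):
            if name in ("PCC", "SRCC", "ICQ") or spec is not None:
                raise
            out[name] = np.nan
    return out


def run_analysis(config: dict) -> dict:
    """Run the full pipeline from a configuration mapping.

    Required keys: ``cell_channel`` (TIFF path or list), ``reporters``
    (list of 2-3 TIFF paths), ``out`` (output directory).  Optional keys and
    their defaults are in :data:`DEFAULTS`; ``roi_set`` / ``mask`` switch
    cell identification from thresholding to an ROI list or binary mask.

    Returns a dict with the cell table, summaries, matrices and the paths of
    everything written.
    """
    cfg = {**DEFAULTS, **config}
    for key in ("cell_channel", "reporters", "out"):
        if key not in cfg:
            raise ValueError(f"config misses required key {key!r}")
    out_dir = Path(cfg["out"])
    out_dir.mkdir(parents=True, exist_ok=True)
    log: list[str] = []

    cell_stack = cio.load_channel_stack(cfg["cell_channel"], role="cell_id")
    reporters = [
        cio.load_channel_stack(p, role=f"reporter{i + 1}")
        for i, p in enumerate(cfg["reporters"])
    ]
    if not 2 <= len(reporters) <= 3:
        raise ValueError("2 or 3 reporter channels are required")
    for r in reporters:
        if r.shape != cell_stack.shape or len(r) != len(cell_stack):
            raise ValueError("all channels must share dimensions and stack length")
    k = len(reporters)
    metric_names = cfg["metrics"] or (_TWO_CH if k == 2 else _THREE_CH)
    if k == 3:
        bad = [m for m in metric_names if m in ("PCC", "SRCC")]
        if bad:
            raise ValueError(
                f"{bad} are two-channel metrics; with three reporters use "
                f"{_THREE_CH}"
            )

    if cfg["align"]:
        reporters = al.align_stacks(
            cell_stack, reporters, cfg["threshold_method"], cfg["max_shift"],
            cfg["background"],
        )
        log.append("alignment: reporter stacks registered to the cell channel")

    # --- cell identification per image ---
    labelmaps: list[cio.LabelMap] = []
    for i, img in enumerate(cell_stack.images):
        if "roi_set" in cfg and cfg["roi_set"]:
            rois = cio.load_roi_set(cfg["roi_set"], img.shape)
            lm = cio.rois_to_labelmap(rois, img.shape)
            lm.source_image_index = i
            log.append(f"image {i + 1}: {lm.n_objects} cell(s) from ROI set")
        else:
            if "mask" in cfg and cfg["mask"]:
                masks = cio.load_mask(cfg["mask"])
                fg_img = masks[i].astype(np.uint8) * 255
                cutoff, polarity = 127.0, "dark_background"
            else:
                fg_img = img
                if cfg["background"] == "auto":
                    polarity = al.detect_background_polarity(img).value
                else:
                    polarity = ("dark_background" if cfg["background"] == "dark"
                                else "light_background")
                cutoff = (float(cfg["manual_threshold"])
                          if cfg["manual_threshold"] is not None
                          else th.auto_threshold(img, cfg["threshold_method"]))
            lm = sg.segment_cells(
                fg_img, cutoff, polarity, cfg["watershed"],
                cfg["prewatershed_max_area"], source_image_index=i,
            )
            log.append(
                f"image {i + 1}: polarity={polarity} cutoff={cutoff:.6g} "
                f"objects={lm.n_objects}"
            )
        before = lm.n_objects
        lm = sg.remove_border_objects(lm)
        lm.source_image_index = i
        if lm.n_objects < before:
            log.append(f"image {i + 1}: removed {before - lm.n_objects} border object(s)")
        labelmaps.append(lm)

    # --- features + filters ---
    filter_specs = [
        f if isinstance(f, sg.FilterSpec) else parse_filter(f)
        for f in cfg["filters"]
    ]
    per_image_tables = []
    metric_values: dict[str, dict[str, float]] = {}
    matrices_per_cell: dict[str, list[mx.MetricMatrix]] = {m: [] for m in metric_names}
    records_rows = []
    for i, lm in enumerate(labelmaps):
        feats = sg.compute_features(lm, reporters)
        retained = sg.apply_filters(feats, filter_specs)
        dropped = sorted(set(feats["label"].astype(int)) - retained)
        for d in dropped:
            log.append(f"image {i + 1}: cell {d} dropped by filters")
        feats = feats[feats["label"].isin(retained)].reset_index(drop=True)
        reporter_imgs = [r.images[i] for r in reporters]
        mvals: dict[int, dict[str, float]] = {}
        for lbl in feats["label"].astype(int):
            cell = _cell_pixels(lm.labels, lbl, reporter_imgs)
            mvals[lbl] = _metrics_for_cell(
                cell, metric_names, cfg["threshold_mode"], cfg["ft"],
                cfg["scaling"], log, f"image {i + 1} cell {lbl}",
            )
            if cfg["matrix"]:
                for m in metric_names:
                    matrices_per_cell[m].append(
                        mx.metric_matrix(cell, m, cfg["ft"], cfg["scaling"])
                    )
        table = rp.build_cell_table(feats, mvals, image_name=str(i + 1))
        per_image_tables.append(table)

    cell_table = (
        pd.concat(per_image_tables, ignore_index=True)
        if per_image_tables else pd.DataFrame()
    )
    files: dict[str, Path] = {}
    p = out_dir / "cells.csv"
    cell_table.to_csv(p, index=False, na_rep="NaN")
    files["cells"] = p

    summary_metric = cfg["summary_metric"] or (metric_names[0] if metric_names else None)
    summaries = []
    if summary_metric and not cell_table.empty:
        try:
            s = rp.summarize(cell_table, summary_metric)
            summaries.append(str(s))
            hist = rp.histogram(cell_table[summary_metric], cfg["histogram_bins"])
            summaries.append(
                f"{summary_metric} histogram: bins={hist.bins} "
                f"min={hist.min:.6g} max={hist.max:.6g} mode={hist.mode:.6g} "
                f"bin_width={hist.bin_width:.6g}"
            )
        except ValueError as exc:
            log.append(f"summary skipped: {exc}")
    p = out_dir / "summary.txt"
    p.write_text("\n".join(summaries) + "\n")
    files["summary"] = p

    agg_matrices: dict[str, mx.MetricMatrix] = {}
    if cfg["matrix"]:
        for m in metric_names:
            mats = matrices_per_cell[m]
            if not mats:
                continue
            agg = mx.aggregate_matrices(mats, cfg["matrix_stat"])
            agg_matrices[m] = agg
            p = out_dir / f"matrix_{m.replace('(', '_').replace(')', '')}.csv"
            _write_matrix_csv(agg, p)
            files[f"matrix_{m}"] = p
            p = out_dir / f"matrix_{m.replace('(', '_').replace(')', '')}_raw.csv"
            _write_matrix_raw_csv(mats, cell_table, p)
            files[f"matrix_{m}_raw"] = p

    if cfg["heatmap"]:
        for r in reporters:
            hms = mx.heatmap(r, labelmaps, cfg["heatmap_scope"])
            p = out_dir / f"heatmap_{r.role}.tif"
            tifffile.imwrite(p, np.stack(hms), photometric="minisblack")
            files[f"heatmap_{r.role}"] = p

    if cfg["export_rois"]:
        files.update(rp.export_masks_and_rois(labelmaps, out_dir))

    p = out_dir / "log.txt"
    p.write_text("\n".join(log) + "\n")
    files["log"] = p

    return {
        "cell_table": cell_table,
        "summaries": summaries,
        "matrices": agg_matrices,
        "labelmaps": labelmaps,
        "files": files,
        "log": log,
    }


def _write_matrix_csv(matrix: mx.MetricMatrix, path: Path) -> None:
    """Aggregated matrix as CSV: grid header row/column, NaN as empty."""
    if matrix.ndim == 2:
        df = pd.DataFrame(matrix.values, index=matrix.grid, columns=matrix.grid)
        df.index.name = "fT1\\fT2"
        df.to_csv(path, na_rep="")
    else:
        rows = []
        g = matrix.grid
        for i, j, l in np.ndindex(*matrix.values.shape):
            rows.append({"fT1": g[i], "fT2": g[j], "fT3": g[l],
                         "value": matrix.values[i, j, l]})
        pd.DataFrame(rows).to_csv(path, index=False, na_rep="")


def _write_matrix_raw_csv(mats: list[mx.MetricMatrix],
                          cell_table: pd.DataFrame, path: Path) -> None:
    """Long-format per-cell values: cell_label, fT1, fT2[, fT3], value."""
    labels = list(cell_table["Label"]) if not cell_table.empty else []
    rows = []
    for lbl, m in zip(labels, mats):
        g = m.grid
        for idx in np.ndindex(*m.values.shape):
            row = {"cell_label": lbl}
            for ax, i in enumerate(idx, start=1):
                row[f"fT{ax}"] = g[i]
            row["value"] = m.values[idx]
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, na_rep="NaN")
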