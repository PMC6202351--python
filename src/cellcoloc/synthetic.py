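"""Seeded synthetic microscopy fixtures with known colocalization structure.

Generates label maps of non-overlapping elliptical cells plus 2-3 reporter
channels painted with a controlled localization pattern, and the matching
ground truth.  This emulates the situations the toolkit targets — low and
heterogeneous signal, per-cell localization differences — without modeling
optics (no PSF, no photobleaching): cells are hard-edged ellipses and noise
is i.i.d. Gaussian.

Patterns
--------
``correlated(rho)``
    Per-cell pixel pairs (triples) drawn from a (equi)correlated normal,
    shifted well above zero so clipping is negligible; per-cell PCC
    estimates recover rho.
``colocalized_foci`` / ``anticolocalized_foci``
    A bright focus covering the top ``focus_fraction`` of each cell's
    pixels, identical across channels (TOS -> +1 at matching f_T) or
    disjoint between channels (TOS -> -1).
``independent``
    I.i.d. noise per channel: no structure, metrics near 0.
``nested_organelles``
    Channel 1 bright in a central focus, channel 2 bright in a ring around
    it: overlap appears only at generous thresholds, so TOS flips sign as
    f_T grows.

All randomness flows from one integer seed through ``numpy``'s PCG64
generator; rasters are integer-valued 16-bit, so datasets are reproducible
bit-for-bit across platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .io import ChannelStack, LabelMap

__all__ = ["SynthConfig", "generate_cells", "paint_cell_channel",
           "paint_reporters", "write_dataset", "make_dataset"]

PATTERNS = ("correlated", "colocalized_foci", "anticolocalized_foci",
            "independent", "nested_organelles")


@dataclass
class SynthConfig:
    """Study conditions for one synthetic dataset."""

    size: tuple[int, int] = (256, 256)
    n_cells: int = 10
    semi_axes: tuple[float, float] = (5.0, 10.0)  # range for both ellipse axes, px
    background_level: float = 100.0
    noise_sd: float = 10.0
    pattern: str = "correlated"
    rho: float = 0.8
    channels: int = 2
    seed: int = 0
    border_cells: bool = False
    cell_level: float = 1000.0  # mean in-cell reporter intensity, a.u.
    cell_sd: float = 200.0
    focus_fraction: float = 0.1  # of cell pixels, for the foci patterns

    def __post_init__(self) -> None:
        if self.pattern not in PATTERNS:
            raise ValueError(f"pattern must be one of {PATTERNS}")
        if not -1.0 < self.rho < 1.0:
            raise ValueError("rho must be in (-1, 1)")
        if self.channels not in (2, 3):
            raise ValueError("channels must be 2 or 3")


def _ellipse_mask(shape, cy, cx, a, b, theta) -> np.ndarray:
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    ct, st = np.cos(theta), np.sin(theta)
    u = (xx - cx) * ct + (yy - cy) * st
    v = -(xx - cx) * st + (yy - cy) * ct
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def generate_cells(cfg: SynthConfig) -> LabelMap:
    """Pack seeded non-overlapping ellipses into the frame.

    Cells keep a 2-px margin from the border unless ``border_cells`` is set,
    in which case the first cell is deliberately placed across an edge (to
    exercise border-object removal).  Raises after bounded retries when the
    requested packing is infeasible.
    """
    h, w = cfg.size
    a_max = cfg.semi_axes[1]
    if cfg.n_cells * np.pi * a_max**2 >= 0.5 * h * w:
        raise ValueError("infeasible packing: cells would cover >= 50% of the frame")
    rng = np.random.default_rng(cfg.seed)
    labels = np.zeros((h, w), dtype=np.int32)
    placed = 0
    attempts = 0
    max_attempts = 400 * cfg.n_cells
    while placed < cfg.n_cells:
        if attempts > max_attempts:
            raise RuntimeError(f"packing failed after {max_attempts} attempts")
        attempts += 1
        a = rng.uniform(*cfg.semi_axes)
        b = rng.uniform(*cfg.semi_axes)
        theta = rng.uniform(0, np.pi)
        if cfg.border_cells and placed == 0:
            cy, cx = 0.0, rng.uniform(a_max, w - a_max)
        else:
            margin = max(a, b) + 2
            if 2 * margin >= min(h, w):
                raise ValueError("cells do not fit inside the frame")
            cy = rng.uniform(margin, h - margin)
            cx = rng.uniform(margin, w - margin)
        mask = _ellipse_mask((h, w), cy, cx, a, b, theta)
        if not mask.any():
            continue
        # require clear separation so labels stay distinct after any watershed
        grown = np.zeros_like(mask)
        rr, cc = np.nonzero(mask)
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                grown[np.clip(rr + dy, 0, h - 1), np.clip(cc + dx, 0, w - 1)] = True
        if (labels[grown] > 0).any():
            continue
        placed += 1
        labels[mask] = placed
    return LabelMap(labels)


def _background(rng: np.random.Generator, shape, cfg: SynthConfig) -> np.ndarray:
    return np.clip(
        rng.normal(cfg.background_level, cfg.noise_sd, shape), 0, None
    )


def _quantize(img: np.ndarray) -> np.ndarray:
    return np.clip(np.round(img), 0, 65535).astype(np.uint16)


def paint_cell_channel(labels: LabelMap, cfg: SynthConfig) -> ChannelStack:
    """Cell-identification channel: bright flat cells on noisy background."""
    rng = np.random.default_rng((cfg.seed, 0xC1D))
    img = _background(rng, labels.shape, cfg)
    img[labels.labels > 0] = cfg.cell_level * 5
    return ChannelStack([_quantize(img)], 16, "synthetic-cellid", "cell_id")


def paint_reporters(
    labels: LabelMap, cfg: SynthConfig
) -> tuple[list[ChannelStack], pd.DataFrame]:
    """Paint reporter channels over a label map per the configured pattern."""
    rng = np.random.default_rng((cfg.seed, 0x5EED))
    h, w = labels.shape
    k = cfg.channels
    imgs = [_background(rng, (h, w), cfg) for _ in range(k)]
    truth_rows = []
    for lbl in range(1, labels.n_objects + 1):
        mask = labels.labels == lbl
        n = int(mask.sum())
        rr, cc = np.nonzero(mask)
        if cfg.pattern == "correlated":
            cov = np.full((k, k), cfg.rho) + (1 - cfg.rho) * np.eye(k)
            z = rng.multivariate_normal(np.zeros(k), cov, size=n,
                                        method="cholesky")
            for i in range(k):
                imgs[i][mask] = np.clip(
                    cfg.cell_level + cfg.cell_sd * z[:, i], 0, None
                )
            truth_rows.append({"label": lbl, "pattern": cfg.pattern,
                               "target": cfg.rho, "area": n})
        elif cfg.pattern == "independent":
            for i in range(k):
                imgs[i][mask] = np.clip(
                    rng.normal(cfg.cell_level, cfg.cell_sd, n), 0, None
                )
            truth_rows.append({"label": lbl, "pattern": cfg.pattern,
                               "target": 0.0, "area": n})
        elif cfg.pattern in ("colocalized_foci", "anticolocalized_foci"):
            n_f = max(1, int(np.floor(cfg.focus_fraction * n + 0.5)))
            base = np.clip(rng.normal(cfg.cell_level * 0.3, cfg.cell_sd * 0.1,
                                      (k, n)), 0, None)
            # deterministic descending ramp so the top-f_T set is exact
            ramp = cfg.cell_level * 3 + np.arange(n_f, 0, -1, dtype=float)
            if cfg.pattern == "colocalized_foci":
                sel = np.arange(n_f)
                for i in range(k):
                    imgs[i][rr, cc] = base[i]
                    imgs[i][rr[sel], cc[sel]] = ramp
                overlap = 1.0
            else:
                if k * n_f > n:
                    raise ValueError("cell too small for disjoint foci")
                for i in range(k):
                    sel = np.arange(i * n_f, (i + 1) * n_f)
                    imgs[i][rr, cc] = base[i]
                    imgs[i][rr[sel], cc[sel]] = ramp
                overlap = 0.0
            truth_rows.append({"label": lbl, "pattern": cfg.pattern,
                               "target": overlap, "area": n})
        else:  # nested_organelles
            from scipy.stats import rankdata

            cy, cx = rr.mean(), cc.mean()
            r = np.hypot(rr - cy, cc - cx)
            # radial quantile per pixel, ties broken deterministically
            u = rankdata(r, method="ordinal") / n
            # channel 1 peaks at the center, channel 2 on a shell at u = 0.3:
            # the organelles are disjoint at tight thresholds but their edges
            # overlap once thresholds are generous
            profiles = [1.0 - u, 1.0 - np.abs(u - 0.3)]
            if k == 3:
                profiles.append(1.0 - np.abs(u - 0.5))
            for i in range(k):
                imgs[i][rr, cc] = cfg.cell_level * (0.2 + profiles[i])
            truth_rows.append({"label": lbl, "pattern": cfg.pattern,
                               "target": np.nan, "area": n})
    stacks = [
        ChannelStack([_quantize(imgs[i])], 16, f"synthetic-reporter{i + 1}",
                     f"reporter{i + 1}")
        for i in range(k)
    ]
    return stacks, pd.DataFrame(truth_rows)


def make_dataset(cfg: SynthConfig) -> tuple[ChannelStack, list[ChannelStack],
                                            LabelMap, pd.DataFrame]:
    """Convenience: label map + cell-id channel + reporters + ground truth."""
    labels = generate_cells(cfg)
    cell_stack = paint_cell_channel(labels, cfg)
    reporters, truth = paint_reporters(labels, cfg)
    return cell_stack, reporters, labels, truth


def write_dataset(
    stacks: list[ChannelStack],
    labels: LabelMap,
    truth: pd.DataFrame,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write TIFF stacks, a label TIFF, a RoiSet.zip and the truth CSV."""
    from .reporting import export_masks_and_rois

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: dict[str, Path] = {}
    for stack in stacks:
        p = out / f"{stack.role}.tif"
        tifffile.imwrite(p, np.stack(stack.images), photometric="minisblack")
        files[stack.role] = p
    p = out / "labels.tif"
    tifffile.imwrite(p, labels.labels.astype(np.uint16))
    files["labels"] = p
    exported = export_masks_and_rois([labels], out)
    files.update(exported)
    p = out / "truth.csv"
    truth.to_csv(p, index=False, na_rep="NaN")
    files["truth"] = p
    return files
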