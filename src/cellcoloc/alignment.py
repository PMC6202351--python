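"""Background polarity detection and threshold-mask image registration.

Reporter channels are aligned to the cell-identification channel by
thresholding each image into a binary foreground mask and finding the integer
translation that maximizes foreground overlap.  Only whole-pixel translation
is considered — interpolation would alter the original intensity values.
Pixels shifted out of the frame are discarded and vacated pixels are filled
with exact zeros, so all channels keep one common shape.

Polarity: assuming more background than cell pixels, an intensity histogram
skewed right (positive third standardized moment) means bright objects on a
dark background; skewed left means a light background.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io import ChannelStack
from .thresholds import auto_threshold, foreground_mask

logger = logging.getLogger(__name__)

__all__ = ["Polarity", "Shift", "detect_background_polarity", "estimate_shift",
           "translate_image", "align_stacks"]

DARK = "dark_background"
LIGHT = "light_background"


@dataclass(frozen=True)
class Polarity:
    value: str  # dark_background | light_background
    skewness: float


@dataclass(frozen=True)
class Shift:
    dy: int
    dx: int


def detect_background_polarity(image: np.ndarray) -> Polarity:
    """Classify an image as dark- or light-background from histogram skewness.

    Uses the sample third standardized moment with ``n`` normalization.
    A perfectly symmetric histogram (skewness 0) defaults to dark background
    with a warning; a constant image is an error.
    """
    flat = np.asarray(image, dtype=float).ravel()
    if np.all(flat == flat[0]):
        raise ValueError("polarity undeterminable: image is constant")
    skew = float(stats.skew(flat, bias=True))
    if skew == 0.0:
        logger.warning("zero skewness: defaulting to dark background")
        return Polarity(DARK, 0.0)
    return Polarity(DARK if skew > 0 else LIGHT, skew)


def estimate_shift(ref_mask: np.ndarray, mov_mask: np.ndarray, max_shift: int = 20) -> Shift:
    """Integer translation of ``mov_mask`` that best overlaps ``ref_mask``.

    Exhaustive search over the square window ``[-max_shift, max_shift]^2``
    counting overlapping foreground pixels.  Ties are broken by smallest
    ``|dy| + |dx|``, then smallest ``dy``, then smallest ``dx``.  If no
    translation produces any overlap, ``Shift(0, 0)`` is returned with a
    warning.
    """
    ref = np.asarray(ref_mask, dtype=bool)
    mov = np.asarray(mov_mask, dtype=bool)
    if ref.shape != mov.shape:
        raise ValueError("masks must share one shape")
    if not ref.any() or not mov.any():
        raise ValueError(
            "empty foreground mask: the threshold must select cell areas "
            "for alignment to work"
        )
    h, w = ref.shape
    best_score = -1
    best: tuple[int, int, int] | None = None
    for dy in range(-max_shift, max_shift + 1):
        for dx in range(-max_shift, max_shift + 1):
            # overlap of mov translated by (dy, dx) with ref
            ry0, ry1 = max(0, dy), min(h, h + dy)
            rx0, rx1 = max(0, dx), min(w, w + dx)
            if ry0 >= ry1 or rx0 >= rx1:
                continue
            my0, my1 = ry0 - dy, ry1 - dy
            mx0, mx1 = rx0 - dx, rx1 - dx
            score = int(np.count_nonzero(ref[ry0:ry1, rx0:rx1] & mov[my0:my1, mx0:mx1]))
            key = (abs(dy) + abs(dx), dy, dx)
            if score > best_score or (score == best_score and best is not None and key < best):
                best_score = score
                best = key
    if best_score <= 0:
        logger.warning("alignment not found: no overlap within the search window")
        return Shift(0, 0)
    assert best is not None
    return Shift(best[1], best[2])


def translate_image(image: np.ndarray, shift: Shift) -> np.ndarray:
    """Translate by whole pixels; overhang is dropped, gaps become zeros."""
    h, w = image.shape
    out = np.zeros_like(image)
    dy, dx = shift.dy, shift.dx
    ry0, ry1 = max(0, dy), min(h, h + dy)
    rx0, rx1 = max(0, dx), min(w, w + dx)
    if ry0 < ry1 and rx0 < rx1:
        out[ry0:ry1, rx0:rx1] = image[ry0 - dy : ry1 - dy, rx0 - dx : rx1 - dx]
    return out


def align_stacks(
    cell_stack: ChannelStack,
    reporter_stacks: list[ChannelStack],
    threshold_method: str = "Default",
    max_shift: int = 20,
    background: str = "auto",
) -> list[ChannelStack]:
    """Align each reporter image to the matching cell-identification image.

    Every stack slice is registered independently (fields of view drift
    independently).  Returns new reporter stacks; the cell stack is the
    reference and is never modified.  A slice whose mask is degenerate is
    left unshifted with a warning.
    """

    def _mask(img: np.ndarray) -> np.ndarray:
        if background == "auto":
            pol = detect_background_polarity(img)
        else:
            pol = Polarity(DARK if background == "dark" else LIGHT, np.nan)
        cutoff = auto_threshold(img, threshold_method)
        return foreground_mask(img, cutoff, pol.value)

    aligned: list[ChannelStack] = []
    for stack in reporter_stacks:
        if len(stack) != len(cell_stack):
            raise ValueError("all channel stacks must have equal length")
        new_images = []
        for i, (ref_img, mov_img) in enumerate(zip(cell_stack.images, stack.images)):
            try:
                shift = estimate_shift(_mask(ref_img), _mask(mov_img), max_shift)
            except ValueError as exc:
                logger.warning("image %d of %s: %s; alignment skipped", i, stack.name, exc)
                new_images.append(mov_img.copy())
                continue
            if shift != Shift(0, 0):
                logger.info("image %d of %s: shift dy=%d dx=%d", i, stack.name, shift.dy, shift.dx)
            new_images.append(translate_image(mov_img, shift))
        aligned.append(ChannelStack(new_images, stack.bit_depth, stack.name, stack.role))
    return aligned
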