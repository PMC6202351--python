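# Methods

This note records the models, conventions and numerical choices behind
`cellcoloc`, in the order the pipeline applies them, together with the
limitations a user should know before trusting numbers on real data.

## Input model and coordinates

Images are monochromatic rasters with one scalar sample per pixel; RGB,
CMYK and palette TIFFs are rejected rather than converted, because channel
mixing silently destroys intensity information. All measurements are in
pixels; physical calibration metadata is ignored.

Internally everything is 0-based `(row, col)` with pixel centers at integer
coordinates, so pixel `(r, c)` occupies `[r−0.5, r+0.5] × [c−0.5, c+0.5]`.
ImageJ ROI vertices live on the pixel-corner lattice; 0.5 is subtracted per
vertex on load and added back on export. A pixel belongs to an ROI when its
center is inside or on the polygon boundary — a deterministic rasterization
with no area bias for the rectangles and traced outlines that occur in
practice. Overlapping ROIs are resolved by "later ROI wins", a documented
choice; ROI order defines cell numbering. The bundled ImageJ ROI codec
reads/writes polygon, rectangle, freehand and traced ROIs with 16-bit
integer coordinates, which covers cell outlines; point/line/oval ROIs are
out of scope.

## Background polarity and alignment

Polarity is detected from the sample skewness (third standardized moment,
`n` normalization) of the intensity histogram: assuming more background
than cell pixels, positive skew means bright cells on a dark background.
Zero skew defaults to dark background with a warning; a manual override
exists because the assumption fails for densely packed fields.

Registration maximizes binary-mask overlap over integer translations in a
`[−max_shift, +max_shift]²` window (default 20 px, sized for chromatic and
stage offsets). Ties are broken by smallest `|dy|+|dx|`, then `dy`, then
`dx`, making the result unique. Each stack slice is aligned independently,
since fields of view drift independently. Only whole-pixel translation is
supported: subpixel registration would interpolate and alter the original
intensities. Shifted-out pixels are discarded and vacated pixels set to
exact zero, so all channels keep one common shape and the zero band marks
the unshared region. Alignment quality depends entirely on thresholding
selecting cell areas in both channels; empty or degenerate masks skip
alignment for that slice with a warning.

## Thresholding and segmentation

All auto-threshold algorithms run on a 256-bin histogram of min–max scaled
intensities and return the boundary between the last background and first
foreground bin, mapped back to raw units; foreground is strictly above the
cutoff on a dark background (below on a light one). Implemented methods:
iterative intermeans (IsoData variant, the default), Otsu (ties broken
toward the smallest index), Mean, Kittler–Illingworth MinError (class
variances floored at 1/12, the one-bin quantization variance, to keep the
criterion finite on spiky histograms), and Triangle. The registry is
extensible.

Foreground objects are 8-connected, the particle-analysis convention.
Watershed markers are the local maxima of the Euclidean distance transform
with minimum separation 2 px and connected plateaus merged to one marker;
watershed lines become background so split objects stay disjoint, and the
watershed regions are used directly as labels (an 8-connected relabel could
fuse them back across the 1-px line). Objects above the pre-watershed area
bound are removed *before* watershed, because watershed would otherwise
shred large debris into cell-sized fragments that pass downstream filters.
Labels are renumbered 1..K in raster-scan order of each object's first
pixel, making labeling deterministic. Any object touching the frame border
is removed — its features would be truncated.

Perimeter is the length of the outline traced along pixel edges (the union
of unit pixel squares), the same outline exported as the cell's ROI, so
perimeter, ROI export and re-import are mutually consistent; this crack
perimeter is slightly longer than ImageJ's corner-smoothed estimate (a 3×3
square measures 12, not ≈10.5). Circularity `4πA/P²` is clamped to [0, 1].
Filter bounds are inclusive; physical filters apply to the
cell-identification channel, intensity filters to exactly one named
reporter channel. `MeanBgndRatio`/`MedianBgndRatio` divide the object's
mean/median by that of the extracellular (label-0) pixels of the same
image and are NaN when the background statistic is zero.

## Metrics

Top-percentile selection keeps exactly `max(1, round(f·N))` pixels, ranked
by descending intensity with ties broken by ascending pixel index. Using
rank counts rather than intensity cutoffs makes overlap fractions exact on
the threshold grid even with heavily tied (quantized) intensities, and
makes every metric reproducible bit-for-bit.

TOS rescales the observed overlap fraction against its independence
expectation and its sharp bounds (`A_max = min f_i`,
`A_min = max(0, Σf_i − (k−1))`, the inclusion–exclusion bound, for k = 2 or
3 channels). The logarithmic scaling `ln(A_O/A_E)/ln(A_max/A_E)` (mirrored
below `A_E`) stretches resolution near small fractions. Undefined
combinations give NaN: any channel at `f = 1`, zero denominators, or a zero
log argument. One subtlety: `A_O ≥ A_min` always holds, so a zero log
argument on the anticolocalization branch can only occur when `A_min = 0`,
where the log rescale is degenerate anyway; the linear-branch value is used
there, keeping the −1 endpoint meaningful.

PCC and SRCC (Pearson on mid-ranks) return NaN for constant vectors or
fewer than two pixels. ICQ counts pixels whose demeaned intensities agree
in sign, minus chance (1/2 for two channels; 1/4 for three, since all three
signs agree with probability 2·(1/2)³); zero sign-products are excluded
from numerator and denominator, Li's convention, to avoid bias from flat
pixels. When a threshold is supplied to PCC/SRCC/ICQ the statistic is
computed on the *intersection* of the per-channel selections — one
deterministic reading of "only the pixels above the thresholds exist",
consistent with the three-channel ICQ failure mode (no pixels above all
three thresholds → NaN); union restriction is a trivial variant but is not
the default. Manders' `M_i` is channel-i intensity inside the joint
selection of the other channels over total channel-i intensity, NaN when
the channel sums to zero.

Costes thresholds use ordinary least squares of B on A (orthogonal
regression is a possible variant; OLS is the documented choice), then scan
`T_A` downward over the sorted unique A values, capped at 512 evenly
spaced quantiles, stopping at the first pair whose below-threshold PCC is
≤ 0. Scan steps where that PCC is undefined (fewer than 2 pixels, constant
vector) are skipped. On strongly correlated data the below-threshold
correlation never reaches zero and the scan exhausts to the minimum with a
warning — inherent Costes behavior, not an error. On pure noise the stop
position is itself a random variable with a heavy lower tail: consecutive
scan steps share almost all pixels, so an initial positive sample
correlation can persist deep into the scan. Median behavior places `T_A` in
the top decile; single draws occasionally stop much lower.

## Matrices, heat maps, aggregation

The threshold grid is `{F_T, 2F_T, …}` capped at 1.0, with the remainder as
the final step when `F_T` does not divide 1 (step 0.3 → 0.3, 0.6, 0.9,
1.0). Matrix axis order is reporter 1, reporter 2 (, reporter 3).
Aggregation across cells is element-wise with NaN entries excluded; an
element is NaN only when every cell is NaN there. The mode statistic bins
values to width 0.01 over [−1, 1] and reports the fullest bin's midpoint
(ties → lower bin) — binned because metric values on continuous data are
almost surely distinct.

Heat maps rescale in-cell intensities so the scope minimum maps to 0 and
the maximum to 255 (scope = each cell, one image, or the whole stack);
background is 0 and a constant scope maps to 0. Cell scaling shows where
each reporter peaks within a cell; image/stack scaling preserves relative
brightness across cells and slices. Rescaling an already cell-scaled raster
is the identity.

Histograms use equal-width bins over [min, max] *closed on the right*
(value `v` lands in bin `⌈(v−lo)/w⌉−1`), so the maximum falls in the last
bin and, e.g., {0, 0.5, 1} with two bins counts [2, 1]. Summary standard
deviation is the sample (n−1) estimator and NaN for a single cell.

## Synthetic data

The generator packs seeded non-overlapping ellipses (semi-axes uniform in
5–10 px by default, 2-px border margin, rejection sampling with bounded
retries) and paints reporters per pattern: `correlated(ρ)` draws per-cell
pixel tuples from an equicorrelated normal (mean 1000, sd 200 a.u.,
clipped at 0 — clipping is negligible five standard deviations above zero)
so per-cell PCC recovers ρ; the foci patterns place a deterministic
descending intensity ramp on the top `focus_fraction` (default 10%) of cell
pixels — identical across channels (TOS = +1 exactly at matching `F_T`) or
disjoint (TOS = −1); `nested_organelles` gives channel 1 a radial profile
peaking at the cell center and channel 2 a shell at radial quantile 0.3, so
the structures are disjoint at tight thresholds but overlap at their edges
once thresholds are generous, flipping the TOS sign with `F_T`.
Background is Gaussian (level 100, sd 10) and all rasters are quantized to
16-bit, so datasets are identical across platforms for a given seed
(PCG64). Correlation is imposed per cell, not globally: per-cell recovery
is the test surface.

What the generator does **not** emulate: point-spread blur, shot noise,
uneven illumination, autofluorescence gradients, or irregular cell shapes.
Passing tests therefore demonstrate the correctness of the computations and
contracts, not robustness to optical artifacts; on real data the cell
filters and visual checks of thresholds and alignment remain the user's
responsibility.

## Problem sizes and other choices

The self-check script and test suite use deliberately small problems — 200
random 10×10-pixel cells for the TOS oracle sweep, one 100-cell / ~200
pixels-per-cell dataset for correlation recovery, 160–320 px frames for
pipeline runs — sizes at which every expected value can be recomputed by
brute force while exercising the same code paths as full-size images.

CSV output serializes NaN literally as `NaN` (matrix CSVs use empty cells
for readability of the grid layout). Reruns of the pipeline with the same
configuration are byte-identical; logs carry no timestamps for that reason.
The default histogram bin count is 50. Three-reporter analyses restrict the
metric set to TOS, ICQ and Manders — PCC/SRCC have no three-way analogue
here. The "Custom" extension point is a registered Python callback with the
same `(cell, spec)` signature as the built-in metrics; it appears in tables
and matrices identically.
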