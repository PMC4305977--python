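# Methods

## Pixel classification model

The classifier reproduces the vendor-style positive-pixel-count rule set on
8-bit RGB scans. Color is decomposed as HSI with intensity the plain
channel mean `I = (R+G+B)/3` on `[0, 255]` (unrounded), saturation
`S = 1 − 3·min(R,G,B)/(R+G+B)` (0 for black), and hue the standard arccos
form normalized to the circular unit interval, reflected (`H → 1 − H`) when
`B > G`. Gray pixels (`R = G = B`) are achromatic: hue is undefined and
they can never be stained.

A pixel is stained when (i) it is chromatic, (ii) the circular distance
from its hue to `hue_value` is at most `hue_width / 2` — `hue_width` is the
*total* breadth of the window, giving the default brown window
`[−0.15, 0.35] mod 1` — and (iii) `S ≥ saturation_threshold` (inclusive).
Stained pixels bin by intensity with half-open `[low, high)` intervals:

| class | interval (defaults) |
|---|---|
| strong positive | `[isp_low, isp_high)` = `[0, 70)` |
| medium positive | `[isp_high, ip_high)` = `[70, 70)` (empty) |
| weak positive | `[ip_high, iwp_high)` = `[70, 230)` |
| background | `I ≥ iwp_high = 230` |

Half-open bins make boundary intensities unambiguous (`I = 70` is weak) and
the equal default middle cut points leave the medium bin empty by
construction — the shipped defaults are implemented literally. Unstained
pixels are negative (counterstained) tissue when `I` is below the negative
ceiling `inp_high`, background otherwise; the sentinel `inp_high = −1`
ties that ceiling to `iwp_high`, so by default every unstained non-bright
pixel counts as tissue. Stained pixels darker than `isp_low` (unreachable
under the defaults) fall back to negative.

The vectorized image path and the scalar per-pixel path share one formula
set; the test suite holds them to exact agreement against an independent
scalar re-implementation on random images.

## Whole-slide score and tiling

`NSR% = 100 · strong / (strong + medium + weak + negative)`. "Tissue" is
every non-background class; bright unstained pixels and anything under the
caller-supplied stroma/exclusion mask are background and never enter the
denominator. A region with zero tissue raises an explicit error rather
than reporting 0. Tiling (default 1000 px, zero overlap, 0-based row-major
half-open tiles, undersized edge tiles unpadded) exists purely to bound
memory: classification is per-pixel, so aggregated counts are provably
identical to a single-pass classification, and the suite asserts exact
equality across tile sizes. Automatic stroma segmentation is out of scope;
stroma handling is mask-driven throughout, mirroring workflows where a
pathologist outlines stroma on the mark-up image.

## Hot spot

The hot spot is the square window of fixed physical area (default 2 mm²;
side `round(√area · 1000 / mpp)` px, minimum 1) maximizing *window NSR* —
strong over tissue within the window — rather than the raw strong count,
so a maximum over a partition of the slide can never fall below the
whole-slide score (max ≥ tissue-weighted mean). Windows sit on a stride
grid (default stride = one window side, i.e. a tiling; flush bottom/right
positions are always added so the scan covers the raster even when the
stride does not divide it; small-raster tests use stride 1). Windows with
tissue fraction below `min_tissue_fraction` (default 0.5, preventing
mostly-background edge windows from winning on tiny denominators) or with
more than `max_stroma_fraction` (default 0.25) of their pixels in the
stroma mask are discarded; stroma pixels are excluded from numerator and
denominator in any case, so the tolerance only rejects stroma-dominated
windows. Ties break to the smallest `(row, col)` lexicographically, which
the row-major argmax provides for free. Counts come from summed-area
tables, so the scan is `O(H·W)` in the raster size, independent of window
size, and is tested for exact agreement with an exhaustive slicing scan.

## Cell counting

Connected components (8-connectivity, `skimage.measure.label`) of
strong-positive pixels whose physical area (`pixels · mpp²`) reaches
`min_cell_area_um2` (default 20 µm², a conservative lower bound for a
lymphocyte cross-section) count as cells. Densities divide by the tissue
area `tissue pixels · (mpp/1000)²` and convert to cells per high-power
field by multiplying with `hpf_area_mm2` (default 0.237 mm², a common 40×
field area; both constants are configurable because microscope field
sizes vary and no single value is canonical). Touching cells merge into
one component — watershed splitting is deliberately absent, a documented
limitation; the synthetic generator therefore guarantees planted cells a
two-pixel separation so recovery tests are exact.

## Statistics

All tests are two-sided with significance at p < 0.05. Mann–Whitney uses
the exact permutation distribution of U (rank-sum form over all
`C(n, n1)` group assignments of the pooled midranks, valid under ties)
when the combined sample is ≤ 12, and scipy's tie-corrected normal
approximation otherwise; the exact two-sided p is
`min(1, 2·min(P(U ≤ u), P(U ≥ u)))`. Kruskal–Wallis uses the chi-square
approximation, Student's t pools variances, and the chi-square test on
contingency tables applies no continuity correction (exposed as data:
integer counts are validated). Bonferroni adjustment is `min(1, m·p)`
with the family size `m` defaulting to the number of markers in the study
(six in a full panel). Pearson's r takes its p from the t transform with
n−2 df; zero-variance input is an error. The diagnostic rule predicts
disease when the per-subject score — the maximum whole-slide NSR over the
configured marker subset (default CD3 + CD8) — exceeds the threshold
(default 2 %); PPV/NPV are reported as undefined (None), never 0, when a
denominator is empty.

## Synthetic data

The generator renders what the classifier *measures*, not what tissue
looks like: a white background (I ≥ 230), a pale counterstained tissue
rectangle, dark-blue negative nuclei, and DAB-brown positive cells as
disks in the strong exemplar color, plus single-pixel strong/weak speckle
to top the rendered class fractions up to their designed targets. Disk
placement is rejection sampling with a carved dilated footprint
(radius + 2) so cells can never touch under 8-connectivity; an optional
planted hot spot multiplies the local probability of strong staining
inside a disk; an optional stroma band is rendered pale and reported as a
mask (never segmented). Ground truth records the realized fractions,
per-cell centroids and the intended per-pixel label map, all recomputable
bit-exactly from the spec and seed (one named generator per call, no
global state).

Noise is Gaussian per channel but *class-preserving*: after adding noise
and clipping to [0, 255], the raster is reclassified and any pixel whose
class flipped reverts to its class exemplar color. This is the clip that
keeps ground truth exact at every noise level — with an unconstrained
clip, ~24 % of strong-exemplar pixels (I ≈ 66.7) would cross the I = 70
boundary at noise sd 8, destroying the designed fractions. The cost is
realism: real DAB staining has soft class boundaries, stain gradients,
JPEG artifacts and out-of-focus regions that this generator does not
emulate, so passing tests demonstrate algorithmic correctness on
well-posed inputs, not robustness to real-slide variability.

Study simulation draws per-subject strong fractions from a lognormal
around `base_fraction · group_effect` (σ = 0.3 between biopsies), with
per-marker GERD baselines of roughly 0.05–1.35 % of tissue and a default
2× EoE pre-treatment effect — values typical of lymphocyte and
dendritic-cell loads in oesophageal biopsies. Default study slides are
512×512 px at 4 µm/px (≈ 4 mm² of tissue), the smallest geometry that
still fits a full 2 mm² hot-spot window; the calibration simulations
(type I error and power of the group comparison at n = 10/group over 100
replicates) run on the drawn fraction distributions directly, which is the
quantity the test consumes.

## Numerical and design notes

- Intensity stays real-valued (no rounding) end to end; comparisons are
  float with exact integer pixel counts underneath, so tiling invariance,
  fraction recovery and oracle agreement are exact, not approximate.
- The hot-spot NSR comparison uses the same `100·strong/tissue` float
  expression in scan and reporting, so the reported window reproduces its
  score from its own counts.
- `window_side_px` uses banker's rounding (Python `round`), floored at
  1 px for degenerate resolutions.
- CSV reports are written with full `repr` precision (lossless on
  re-parse with round-trip float parsing); the whole pipeline is a pure
  function of (inputs, config, seed) and reruns are byte-identical.
- Decoding vendor pyramidal formats (SVS/JPEG2000) is out of scope; inputs
  are flat TIFF/PNG with an explicit sidecar `mpp`, which keeps physical
  calibration testable and vendor-independent.
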