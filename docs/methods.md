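# Methods

`ecmlines` models planar fibrous extracellular matrix (ECM) as randomized
arrays of printed fibronectin line elements and quantifies how their
organization steers cell shape, adhesion architecture, polarity and
migration. This note documents the models, the parameters that matter, the
numerical choices, and what the synthetic validation does and does not
demonstrate.

## Pattern model

A pattern field is a `width × height` µm rectangle (default 700 × 700 µm)
seeded with `D` line elements. Each line has

- an initiation point drawn i.i.d. uniform over the field,
- an angle drawn uniform on `[−θ, +θ]` about the pattern axis, where θ is
  the angular dispersion (±5° = strongly aligned, ±90° = isotropic),
- a stroke width `w` (µm),

and extends bidirectionally from its initiation point to the field boundary
(a full chord, clipped with shapely). Lines may cross; rasterization takes
the union: a pixel is set iff its center — at `(i + 0.5, j + 0.5)·pixel
size`, top-left origin, x right, y down — lies within `w/2` of any line
segment. Angles are degrees from the +x axis toward +y; axial quantities
(orientations of lines, cells, adhesions) live in `(−90, 90]`.

The printed design space is the standard grid: dispersions ±5/15/30/45/60/
90°, densities 50/100/200/400/800 lines per field, photomask widths
2.5/3.5/5/10 µm demagnified 5× by the projection stepper to substrate
widths 0.5/0.7/1.0/2.0 µm. At 800 lines with 1–2 µm widths the summed line
area exceeds the field and the print is effectively uniform; the
`coverage_fraction` saturation flag (default threshold 0.99) marks that
regime.

Seeding: a layout has one root seed; per-field seeds derive from
`SeedSequence([root, field_index])`, so any field is reproducible in
isolation. Identical parameters + seed give byte-identical fields, masks
and exports.

Layout export is SVG 1.1 with µm user units (one group per field, one
stroked line per element) plus a per-field metadata CSV. The default
layout packs the requested θ×D×w grid into the smallest near-square grid
at 750 µm pitch; the published arrays' exact slot plan (how their 252
conditions were arranged on the 1.2 cm stamp) is not asserted anywhere —
layout shape and pitch are configurable.

## Synthetic microscopy

The generator exists so that every downstream stage can be validated by
parameter recovery without any external data. Per condition it renders
five channels — pattern, cytosol (cell body), nucleus, vinculin
(adhesions), MTOC — and writes a ground-truth table of every sampled value.

**Cell body.** A stadium (rectangle with semicircular caps, half-length
`a`, cap radius `r`). Its second central moments are closed-form
(`Ix = 4ar³/3 + πr⁴/4`, `Iy = 4a³r/3 + πr⁴/4 + 8ar³/3 + πa²r²`), and the
ratio `a/r` is solved (Brent) so the moment-equivalent aspect ratio equals
the sampled target exactly; `r` then follows from the sampled area
(`A = 4ar + πr²`). A moment-based measurement of the rendered mask should
therefore return the sampled aspect ratio up to rasterization error.
Aspect ratio and area are log-normal (defaults: median AR 2.5, log-sd
0.25; median area 1200 µm², log-sd 0.2); orientation is axial wrapped
normal about the pattern axis. Cells are placed with ≥2 µm capsule-to-
capsule clearance, because segmentation deliberately has no watershed
splitting; contact handling is out of scope and flagged as a limitation
for real images.

**Condition link functions.** The defaults tie morphology and migration to
the pattern dispersion θ by linear interpolation between the aligned (±5°)
and isotropic (±90°) regimes: orientation sd 5°→50°, median aspect ratio
3.5→1.6, adhesion angle sd σ_FA 8°→35°, speed 0.7→0.35 µm/min, persistence
weight 0.85→0.4, axis confinement 0.9→0. These encode the qualitative
biology — alignment elongates and orients cells, organizes adhesions, and
speeds up and straightens migration — with magnitudes chosen once as
plausible for fibroblasts on line patterns. No quantitative link between θ
and these parameters is claimed; all validation is parameter recovery, not
value matching against any measured dataset.

**Adhesions.** Poisson count per cell (default mean 20); elliptical blobs
(length 1.2–3 µm, width 0.5–0.8 µm) placed along the cell's long axis
offset toward the periphery, centers kept ≥2.2 µm apart (adhesions are
distinct puncta; without the spacing, blob merging biases orientation
statistics). Blob orientations are axial wrapped normal about the cell
axis with sd σ_FA.

**MTOC and polarity.** A leading-edge direction is sampled as ± the cell
axis; the MTOC class (front/middle/back of the nucleus along that
direction) is multinomial with configurable probabilities, and the point is
placed beyond/within the nucleus extent accordingly. The leading-edge
direction is recorded in ground truth — downstream classification consumes
annotation or ground truth, never inference.

**Migration.** A biased persistent random walk at the frame interval Δt
(default 10 min over 6 h → 37 frames): step length is gamma (shape 8, mean
speed·Δt); the new heading is the direction of
`p·u(heading) + c·u(nearest axis direction)` plus Gaussian heading noise
(default sd 20°), where `p` is the persistence weight and `c` the axis
confinement. With `c = 1` and zero noise the walk is exactly straight
along the axis (headings snapped to axial when within 1e−12, so the
persistence metric is exactly 1); with `p = c = 0` the heading resamples
uniformly — a pure random walk whose MSD is linear in lag. Walks reflect
at the field boundary. Nuclei render as Gaussian spots (sd 4 µm).

**Noise model.** analytic shapes → Gaussian blur (sd 1 px) → background
offset (100 counts) → Poisson shot noise (scale 0.12) → Gaussian read
noise (sd 3) → quantization (16-bit). Defaults give SNR ≈ 10 at the cell
interior. Not modelled: realistic PSFs, photobleaching, cell contact or
division dynamics, spectral bleed-through. Consequently, passing recovery
tests shows the measurement chain is unbiased under these conditions; it
does not certify segmentation thresholds or tracking gates for any real
microscope's data.

## Measurement chain

**Morphometrics.** Background filtering (Gaussian high-pass by default,
rolling-ball available), thresholding (manual fixed threshold takes
precedence; Otsu otherwise), 8-connected labelling, minimum-area gate
(default 50 µm²). Per cell: area, ellipse-equivalent aspect ratio and
axial orientation from second central moments (regionprops), outline
polygon, and orientation relative to the pattern axis folded into
[0, 90]°. Degenerate regions get the minor axis floored at one pixel and a
flag. Touching cells are not split.

**Adhesions.** Suprathreshold vinculin components inside each cell's
footprint (dilated 2 µm so edge adhesions are kept; components are assigned
to the nearest cell within that distance), gated to 0.25–15 µm² (typical
vinculin focal-adhesion sizes; configurable). Adhesion orientations are
re-expressed relative to the host cell's major axis, then summarized per
cell by the axial circular angular deviation — by default about the
circular mean of the relative angles; `center="cell_axis"` measures about
the axis itself. A cell with no adhesions reports a null deviation, not 0.

**Tracking.** Detection: 1-px Gaussian smooth, threshold, minimum area,
intensity-weighted sub-pixel centroid. Linking: per frame pair, the
globally optimal assignment minimizing total squared displacement
(Hungarian algorithm) with a hard displacement gate (default 30 µm per
10-min frame); unmatched detections start tracks, unmatched ends terminate
(no gap closing — a missed detection truncates). A new track appearing
within 20 µm of a live track flags that track as divided. Metrics: speed =
path length / duration (µm/h); persistence = net displacement / path
length ∈ [0, 1] (null for zero path; snapped to 1 within 1e−12 for
collinear same-direction steps). Exclusion rules (all switchable off for
perturbation experiments): tracked ≥90% of the session, not division-
flagged, path length ≥ 20 µm (about two nucleus diameters — a default
chosen here, since no canonical non-migratory threshold exists).

**Polarity.** MTOC orientation is the axial fold into [0, 90]° of the
nucleus→MTOC direction vs the pattern axis (aligned ⇔ ≤45°); position
class projects the MTOC onto the annotated leading-edge axis against the
nucleus extent. Protrusions: per frame pair, mask pixels gained adjacent
to the previous boundary are binned by angle about the centroid (36 bins
of 10°); a protrusion is a maximal contiguous (wrapping) run of bins
active in ≥3 frame pairs with summed gain ≥ the configured minimum, its
angle the gain-weighted circular mean. This is an algorithmic surrogate
for manual ruffling-edge identification; bin width, frame and gain
thresholds are logged with the outputs. Kymographs sample a fixed segment
per frame (bilinear interpolation, averaged across a configurable
perpendicular width). FRET ratio: background subtraction of both channels,
acceptor-threshold mask, pixelwise acceptor/donor inside the mask, 3×3
median filter computed over in-mask neighbours; non-positive donor pixels
become NaN and are counted in a warning.

## Statistics

Axial data are analyzed by angle doubling: resultant length R of the
doubled angles, axial mean = half the doubled-angle mean, angular
deviation `√(2(1−R))/2` rad (maximum ≈ 40.51° when the doubled angles
balance).

The two-response model treats cell orientation and aspect ratio jointly as
a general linear model in width, alignment, density and their products.
The published description of this analysis ("multinomial multivariate
linear regression" with one approximate F per term) is read here as a
MANOVA-style general linear model rather than a multinomial logit: the
reported layout — per-response coefficients plus a single multivariate F
per term — matches term tests on a multi-response GLM. Each term is tested
by the extra residual SSCP of the term-deleted fit via Pillai's trace with
Rao's F approximation (cross-checked in tests against an independent
projection-matrix oracle and statsmodels MANOVA). Model comparison uses
the Gaussian log-determinant AIC, `n·ln det(E/n) + 2k` with `k` = terms ×
responses; constants are dropped consistently, so only AIC differences are
meaningful. Dual-direction stepwise search evaluates single-term deletions
and re-additions of dropped terms, always respecting hierarchy
(interactions require their main effects), accepting the best
AIC-improving move; the step trace is non-increasing by construction.

A known property, verified by simulation in the test suite: AIC is not
selection-consistent. Dropping a zero-effect term with 2 response
dimensions trades a χ²(2)-distributed deviance gain against a penalty of
4, so such a term is eliminated with probability 1−e⁻² ≈ 0.865 no matter
how large n gets — roughly 87 of 100 seeded simulations, and no amount of
data raises it. A BIC-style penalty would eliminate such terms almost
surely at large n, but it would not be the Akaike criterion this package
implements; the selection-behavior simulation reports the rate as
measured.

Pearson correlation (p from the t transform on n−2 df), Levene's test
(mean-centered classic form by default, median/Brown–Forsythe available)
and one-way ANOVA with Bonferroni-adjusted pairwise t tests
(`p_adj = min(1, p·m)`) are thin validated wrappers over scipy.

## Validation experiments and problem sizes

`ecmlines.validation` holds the recovery loops used by both the test suite
and `scripts/acceptance.py`: morphology (200 cells/condition, 0.8 µm/px,
default noise), adhesion deviation (σ_FA 10° and 40°, ~12 cells × ~50
adhesions at 0.2 µm/px), MTOC class fractions (200 cells), tracking
(50 tracks × 37 frames at speeds 10/30/60 µm/h, noiseless and default
noise, 1 µm/px; cells whose ground-truth paths pass within 25 µm of
another cell are excluded from the comparison, since identity swaps at
crossings are a declared non-goal of the linker — the in-silico analogue
of excluding touching cells), dispersion trends (15 tracks/condition; 200
cells/condition for orientation variance), the adhesion–speed coupling
(4 conditions), and the selection simulation (100 seeds × n = 2000). These
sizes were chosen so the whole validation runs in minutes on one CPU while
keeping Monte-Carlo error well inside the stated tolerances; expected
values for wrapped-normal axial deviations use `E[cos 2Δ] = exp(−2σ²)`.

## Known limitations

- No contact handling (segmentation) and no gap closing or merge/split
  resolution beyond the division flag (tracking).
- Protrusion detection is a surrogate for a manual procedure; its
  thresholds have no calibrated correspondence to "ruffling".
- The condition link functions are modeling choices; absolute recovered
  values describe the synthetic model, not any cell line.
- Absolute AIC values are convention-dependent; only within-run
  comparisons are meaningful.
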