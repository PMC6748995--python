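# Methods

This note documents the models, parameter choices and numerical conventions
behind nephroquant, and what the synthetic-data validation does and does not
demonstrate about real data.

## Synthetic sphere images

The generator emulates a 2D optical section through a 3D culture of
kidney-mesenchyme spheres (3D stacks are supported behind the same
interface, but 2D sections are the default because the quantified
immunofluorescence images are thin physical sections).

Per image it renders, in order:

1. **Sphere placement.** `n_spheres` circular domains (default 6, radius
   58 px) dart-thrown into the image (default 384×384 px), preferring
   non-overlapping positions.
2. **Nucleus placement.** Each sphere receives `nuclei_per_sphere` nuclei
   (default 28–36, giving ≈200 per image) with radii drawn from
   N(4.5, 0.5²) px. Centers are placed by best-candidate (blue-noise)
   sampling with a minimum center-to-center distance of
   `min_separation × mean radius` (default 2.8, i.e. a sub-radius gap
   between adjacent nuclei). Best-candidate sampling degrades gracefully
   near the packing limit instead of jamming. A configurable
   `touching_fraction` deliberately places nuclei within touching range to
   exercise the watershed split.
3. **Classes and brightness.** Per marker channel, each nucleus is positive
   with probability `positive_fraction`; its brightness is drawn from the
   positive or negative intensity distribution (default log-normal with
   arithmetic mean/SD 400/80 AU vs 50/15 AU — fluorescence intensities are
   non-negative and right-skewed, and this ~8× separation reflects a clean
   nuclear transcription-factor stain). An optional EdU channel works the
   same way with `edu_fraction`.
4. **Rendering.** The nuclear channel renders soft-edged disks
   (error-function profile, edge σ 0.75 px, amplitude 300 AU ± 20%
   staining variability) on a 20 AU background; marker channels render hard
   disks at the drawn brightness, so that with blur and noise disabled the
   mean intensity over the true disk equals the drawn value exactly (the
   generator's separability control).
5. **Optics and noise.** Gaussian PSF blur (σ 1 px), then Poisson shot
   noise (gain 1 photon/AU) and Gaussian read noise (SD 4 AU).

**Ground truth is the realized sample**, not the nominal parameter: recovery
is scored against the classes actually drawn, since at ~200 nuclei a
binomial draw of a 48.56% fraction routinely lands a point away.

Defaults for per-image nucleus counts are engineering choices — the study
pools "no less than 10,000" cells across experiments without stating
per-section counts — and every one of them is exposed in the config.

What the generator does *not* emulate: real chromatin texture, intensity
gradients with depth, nuclear shape irregularity, segmentation-relevant
debris, autofluorescence, or spatial correlation of marker expression
within a sphere (classes are i.i.d.). Passing recovery tests therefore
validates the measurement chain's correctness and its behavior under blur,
noise and contact — not robustness to every artifact of real microscopy.

## Segmentation

- **Preprocessing:** morphological top-hat with a flat square structuring
  element (half-width `bg_radius`, default 40 px ≫ nucleus radius) removes
  slowly varying background exactly (it reconstructs any locally linear
  background); Gaussian smoothing (σ 1 px) suppresses shot noise. Only the
  nuclear channel is preprocessed — marker intensities are always measured
  on raw channels.
- **Intensity model:** two-component 1-D Gaussian mixture fitted by EM,
  initialized from moment estimates on either side of the Otsu split,
  ≤100 iterations, relative log-likelihood tolerance 1e-6; components
  ordered by mean (higher = foreground). Degenerate inputs (no spread,
  one-sided split, vanishing variance) fall back to a plain Otsu threshold
  with a warning.
- **Graph cut:** the binary MRF energy with unary terms
  −log(w_k N(x; μ_k, σ_k)) and Potts pairwise term λ (default 1.0,
  4-connectivity in 2D / 6 in 3D for an isotropic penalty) is minimized
  exactly by min-cut/max-flow (`scipy.sparse.csgraph.maximum_flow`).
  Capacities are normalized per pixel, clipped at a level (10⁴ energy
  units) far beyond any pairwise influence, and integer-scaled such that
  both the largest capacity and the attainable flow stay well inside int32
  — the solver's arithmetic range — while quantization error stays
  negligible. λ = 0 reduces to per-pixel maximum likelihood.
- **Splitting:** connected components are split by watershed on the negated
  Euclidean distance transform (smoothed with σ 0.5 px), seeded at regional
  maxima (minimum peak distance 3 px, at least one seed per component).
  Fragments under `min_nucleus_size` (default 20 px, ≈⅓ of a nominal
  nucleus) are removed and labels relabeled contiguously 1..L. Splitting is
  pluggable (`split_method="none"` keeps plain components).
- Coordinates are 0-based pixel indices in (z,)y,x order; masks share the
  image grid exactly.

Only two-label foreground extraction is implemented: nucleus binarization
is a binary problem and the two-label case is exactly solvable, which a
multi-label alpha-expansion is not.

## Marker quantification

- **Per-nucleus statistics:** mean and SD of raw marker intensity over each
  label's pixels. The SD uses the population (divisor n) convention — a
  descriptive spread over an enumerated pixel set, not a sample estimate.
- **Threshold model:** k-means (default k = 3: negative / low / high
  classes) on standardized (mean, SD) feature pairs; mean-only clustering is
  available and solved *exactly* by dynamic programming over sorted values
  (the 1-D optimal partition is contiguous), making it deterministic with
  no seed sensitivity. The joint 2-D mode uses Lloyd's algorithm with
  k-means++ and ≥10 restarts at a fixed seed. Whether intensity means and
  SDs should be clustered jointly or separately is ambiguous in the source
  description; both modes are implemented, joint is the default.
- **Negative threshold τ:** candidate cuts are midpoints between
  consecutive cluster centers (on the mean-intensity axis); each candidate
  snaps to the midpoint of the pooled-intensity gap containing it, and the
  candidate with the widest gap wins. For clean two-population data this is
  exactly "midpoint between the negative cluster's maximum and the next
  cluster's minimum"; the widest-gap selection additionally keeps a
  dominant unstained population that k-means split across two clusters from
  dragging τ into the negative mode — without it, a 5% positive fraction is
  over-reported by ten points or more.
- **Tie rule:** positive iff mean intensity > τ, strictly; a cell exactly
  at τ is negative. With a degenerate model (all intensities identical)
  every cell is negative and a warning is logged.
- **Scopes:** per-image ratios feed between-condition t-tests ("means of
  the ratios"); pooled ratios (concatenating nuclei across replicate images
  before dividing) are reported alongside.
- The classification is scale-equivariant: multiplying a channel by c > 0
  rescales τ by c and changes no call.

## Viability gating

Gating operates on log10 intensity because flow intensities span decades.
Default gate: Otsu's threshold (deterministic and parameter-free); 2-means
(gate at the midpoint of the two cluster centers) and fixed thresholds are
alternatives. Events strictly above the gate are dead; viability
= 100 − dead%, the inversion identity holding exactly by construction.
Degenerate (effectively unimodal) inputs produce a warning and require a
fixed threshold. Single-detector gating only; no scatter-based debris
gating or compensation is modeled.

## Group statistics

Pooled-variance Student t (df = nA + nB − 2) is the default independent
test, matching the named procedure; Welch is available by flag, and a
paired test (df = n − 1) covers matched designs. All tests are two-sided
(sidedness is unstated in the source; two-sided is conservative).
Comparisons accept raw per-experiment values or (mean, SD, n) summaries.
Conventions for degenerate dispersion: zero variance with equal means gives
t = 0, p = 1; with unequal means t = ±∞, p = 0, with a warning. A
single-value group reports SD 0 with a warning. Fold change (mean_B/mean_A)
is reported alongside. No multiple-testing correction is applied (none is
part of the emulated analysis).

## Pipeline and reproducibility

Every run derives all stage seeds deterministically from one master seed
(`stage_seed = (master · 1000003 + crc32(tag)) mod 2³¹−1`), decorrelating
stages and replicate images while keeping a single knob. The run report
embeds the resolved config, master seed and per-stage seeds; re-running
from the report reproduces every number exactly. Recovery experiments
default to 10 master seeds × 3 images (~200 nuclei each) per marker
quantity and 10,000 events per viability quantity — the scale of the
emulated study's per-condition data — which keeps the full validation run
around a minute on one CPU.

## Known limitations

- The watershed splitter resolves touching pairs but will merge deeply
  overlapping nuclei (center distance well under one diameter); at the
  default packing this costs ~1% of nuclei.
- τ selection assumes marker positivity is expressed as a gap in the
  per-nucleus mean-intensity distribution; a continuum of expression
  (no gap) has no well-defined negative threshold, and k-means will place
  one anyway.
- Otsu gating assumes both populations are represented; below ~2% minority
  fraction the gate drifts.
- The EM intensity model assumes approximately Gaussian foreground and
  background pixel-intensity modes after preprocessing; strongly textured
  nuclei would violate this.
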