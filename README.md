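# nephroquant

Quantification of nephron-progenitor maintenance and differentiation in 3D
kidney-mesenchyme (KM) sphere cultures from fluorescence microscopy and flow
cytometry. The package is written for developmental-biology and bioimage
analysts who need the complete measurement chain behind "X% of cells are
SIX2-positive" claims: nuclear segmentation, per-cell marker intensities,
automatic negative-staining thresholds, labeled-to-total cell ratios,
live/dead viability gating, and the group statistics that compare culture
conditions. Because such microscopy datasets are rarely deposited, the
package ships a first-class synthetic-data generator with full ground truth,
so every stage of the pipeline can be validated by parameter recovery.

## Method

**Segmentation.** The nuclear counterstain channel is background-subtracted
(morphological top-hat) and smoothed, then binarized by exact minimization of
a two-label Markov random field energy

```
E(l) = Σ_p U_p(l_p) + λ Σ_{(p,q) adjacent} [l_p ≠ l_q]
```

where the unary costs `U_p` are negative log-likelihoods under a
two-component Gaussian intensity model fitted by EM. For two labels this
energy is submodular, so a single min-cut/max-flow computation yields the
global optimum. Touching nuclei are separated by a distance-transform
watershed and fragments below a minimum size are discarded.

**Marker classification.** Per nucleus, the mean and SD of the raw marker
intensities are clustered by k-means (default k = 3: negative / low / high;
mean-only clustering is solved exactly by dynamic programming). The
negative-staining threshold τ is the midpoint of the widest intensity gap
between consecutive clusters; a cell is marker-positive iff its mean
intensity exceeds τ strictly. The labeled-to-total ratio
`r = positives / total` is reported per image (feeding t-tests) and pooled
across replicate images. The same machinery applied to an EdU channel yields
the proliferating-cell ratio.

**Viability.** Sytox (dead-cell stain) event tables are gated on log10
intensity, by Otsu's threshold by default; viability is the inverted
dead-stain positivity, `100 − dead%`.

**Statistics.** Conditions are compared on the means of per-experiment
ratios with a two-sided pooled-variance Student t-test (Welch and paired
variants available), significance at p < 0.05, fold change alongside.

## Worked example

A two-condition synthetic experiment (3 replicate images each, ~200 nuclei
per image, ground-truth SIX2-positive fractions 48.56% and 4.31%), plus one
viability run with 20.2% true dead fraction:

```
nephroquant run --config demo.yaml --out out/
```

with `demo.yaml`:

```yaml
seed: 7
conditions:
  - name: BM_FGF2
    n_images: 3
    image: {positive_fraction: 0.4856}
  - name: BIO_pulse
    n_images: 3
    image: {positive_fraction: 0.0431}
quantify:
  k: 3
  channels: [SIX2]
cytometry:
  - name: BM_FGF2_BIO
    events: {n_events: 10000, dead_fraction: 0.202}
comparisons:
  - {a: BM_FGF2, b: BIO_pulse, channel: SIX2, test: independent}
```

prints

```
master seed: 7
BM_FGF2 SIX2: 48.81% (SD 2.50, n=3)
BIO_pulse SIX2: 3.97% (SD 1.62, n=3)
BM_FGF2_BIO viability: 79.3%
BM_FGF2 vs BIO_pulse (SIX2): t=-26.082 p=0.0000 *
```

Reading: the full segment → threshold → classify → ratio pipeline recovers
the two planted positive fractions to within a point (48.81 vs 48.56; 3.97
vs 4.31), Otsu gating recovers the planted 79.8% viability, and the
condition difference is (unsurprisingly, at this effect size) significant.
`out/report.json` holds the same numbers in machine-readable form together
with the resolved per-stage configuration and seeds; re-running with the
same config reproduces every number exactly.

The stages are also available individually (`simulate-image`,
`simulate-events`, `segment`, `quantify`, `viability`, `compare`) and as
library functions (`nephroquant.generate_sphere_image`,
`segment_nuclei`, `measure_nuclei`, `fit_threshold`, `classify_cells`,
`positive_ratio`, `gate_viability`, `compare`, ...).

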