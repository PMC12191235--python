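# Methods

This note records the models, conventions and numerical choices behind
`radassay`, in the spirit of a statistical-software methods appendix. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Single-cell death model and survival analysis

**Biosensor model.** Each cell carries a constitutive red signal (mApple)
and a calcium-driven green signal (GC150). The GEDI ratio
`R = green/red` is taken over the red-channel cell mask, so it is invariant
to overall gain, to exposure changes affecting both channels equally, and
to per-cell expression level; it scales linearly with green-channel gain
(both properties are asserted in the invariance tests). Cells whose red
mean does not exceed a configurable floor are unmeasurable at that
timepoint and excluded there — never assigned `R = 0`, which would silently
count them as alive.

**Fate rule.** Death is called at the earlier of (a) the first scheduled
timepoint with `R > theta` and (b) the first scheduled timepoint at which a
previously present cell is absent (detachment; observation is
interval-censored, and the event is assigned to the right endpoint of the
interval because the product-limit estimator needs a time). Cells present
with `R <= theta` at the last timepoint are right-censored. Cells first
detected after baseline (drift-in, division) were not at risk at `t = 0`
and are excluded from survival; both death causes are recorded so either
convention (ratio-crossing or disappearance-only) can be reproduced with
the `events` flag.

**Threshold.** `calibrate_threshold` minimises total misclassification
between baseline and post-lethal-dose (25 Gy, 24 h) ratio samples by
scanning every cut between adjacent pooled sample values; ties are resolved
to the midpoint of the tied cuts, and calibration fails (rather than
returning a value) if no cut beats 50% misclassification. Without
calibration data the conventional `theta = 1` is used.

**Survival statistics.** Kaplan–Meier curves and log-rank tests are
computed with `lifelines` behind the `km_curve`/`logrank` interface; the
multi-group statistic uses pooled event times with exact hypergeometric
variance and ties pooled at identical times. Pairwise dose-versus-control
comparisons are reported with unadjusted and Bonferroni-adjusted p-values
side by side. The test suite checks the statistic against an independently
coded observed-minus-expected implementation and the p-value against the
exact label-permutation null at n = 6 per group. Two caveats are asserted
rather than assumed: the analytic p is a chi-square asymptotic
approximation, and at 12 cells the permutation null is discrete (C(12,6) =
924 atoms, with large point masses under tied event times), so agreement is
asserted against the permutation mid-p at the 0.05 scale of the
approximation error, not to resampling precision — closer agreement is not
achievable in principle at that sample size.

**Tracking.** Objects are linked across scheduled timepoints by greedy
nearest-centroid matching, accepting candidate links in order of increasing
displacement up to a cap (default 24 px ≈ 2× the default mean cell
diameter). Greedy matching is adequate for the sparse fields this package
targets (~2,500 cells seeded per well, tens of cells per field); no global
assignment or frame-rate tracking is attempted.

## Image operators

* **Background subtraction** (`rolling_ball`): the background is a
  morphological grey opening with a flat disk footprint (decomposed for
  speed). A flat opening maps constant images to exactly zero, preserves
  objects smaller than the footprint at full amplitude, and — unlike a
  curvature-coupled rolling-ball estimate — commutes with multiplicative
  gain, which keeps Otsu masks and ratio measurements gain-invariant.
* **PSF sharpening** (`sharpen_psf`): Gaussian unsharp masking,
  `img + strength * (img - G_sigma(img))`, clipped at zero; identity at
  `strength = 0`. This is a contrast-enhancing approximation to
  deconvolution, sufficient for feeding a threshold; no PSF measurement is
  assumed and no Richardson–Lucy iteration is attempted. Note that unsharp
  masking rings around very bright puncta; masks for punctate reporters
  (the 53BP1 path) should disable it and use a manual threshold.
* **Thresholding**: manual value (the original assays used manual,
  per-assay thresholds, which are kept as config values) or Otsu. In the
  automatic segmentation pipelines Otsu is guarded by a robust noise floor
  (median + 5 × 1.4826 × MAD of the preprocessed image): on a signal-free
  frame plain Otsu splits the noise and fabricates objects, while the floor
  yields zero objects without affecting frames with real signal.
* **Labeling**: 8-connected components, minimum area 20 px (configurable;
  unspecified in the original assays), labels renumbered consecutively.
  Segmented objects whose area exceeds mean + 3 SD are flagged as likely
  merged neighbours; no watershed splitting is attempted.

## Foci counting

A punctum must be at least `contrast_factor` (default 10, "an order of
magnitude") times the per-cell background — per-cell because reporter
expression varies between cells. Background is the median of in-mask
pixels after excluding the brightest 5%, which is robust to the puncta
themselves at realistic foci loads. Candidate regions are 8-connected
superlevel components; each contributes one punctum per local intensity
maximum above threshold (maxima closer than 2 px are merged). Counting
maxima rather than components resolves touching foci and makes counts
monotone when the contrast factor is lowered — a maximum above a high
threshold is also above every lower one, whereas component counts can drop
when regions merge. Area bounds (2–50 px by default) reject single hot
pixels and flat saturated patches; a perfectly flat region larger than the
maximum punctum area is treated as saturation and dropped. The γ-H2AX path
is identical to the 53BP1 path except compartments come from DAPI nuclear
masks instead of red-channel cell masks.

Group comparisons use one-way ANOVA (single timepoint) or two-way
group × timepoint ANOVA with Tukey HSD pairwise tests. When an effect's sum
of squares is numerically zero the 0/0 F ratio is reported as F = 0, p = 1.

## Plate assays

* **Viability**: `100 × (treated − blank) / (zero-dose control − blank)`,
  replicates averaged first; invariant to affine luminometer rescaling.
  A zero-dose control at or below blank invalidates the assay.
* **Colonies**: background subtraction → threshold → colony-scale labeling
  (min 100 px). Touching colonies are counted once and flagged via
  circularity (`4πA/P² < 0.8`); splitting is a documented non-goal.
* **Flow cytometry**: debris removed with a rectangular FSC/SSC gate;
  positive-uptake gate at the 99th percentile (configurable — the original
  protocol states only "above the unstained gate") of the unstained
  reference's fluorescence; MFI is arithmetic by default (geometric
  optional), reported for all events and positives (which population the
  original analysis used is unstated, so both are emitted). Optional
  division sub-gating assigns positives to generations by 2× dye dilution
  from the brightest histogram peak; it presumes resolvable peaks and is
  off by default. No compensation or FCS binary parsing (CSV exports only).
* **sEV dosing**: particles/cell = concentration × volume / cell count.
* **Stress-test metrics**: non-mitochondrial OCR = mean of the
  rotenone/antimycin phase; basal = last pre-injection reading minus
  non-mitochondrial (vendor convention for the basal reference; the source
  protocol is silent); maximal = FCCP-phase maximum minus non-mitochondrial;
  spare capacity = maximal − basal, also as % of basal. Because maximal
  takes a maximum of noisy readings, its sampling error is of order σ (an
  order statistic is biased upward by ~0.85σ at 3 readings), not σ/√n; the
  tests assert accordingly.

## Synthetic data: what it emulates, and what it does not

The generators reproduce the statistical structure the analysis relies on,
with defaults chosen to mirror the study conditions they stand in for:

* **Timelapse** (`gen_timelapse`): cells as isotropic Gaussian blobs
  (radius 6 ± 1 px, log-normal red amplitude with median ≈ 490 over
  background 100), observation schedule 0/6/12/18 h post-irradiation,
  ratio step `r_live = 0.5 → r_dead = 1.5` at an exponentially distributed
  death time (Weibull shape exposed), group hazards defaulting to 0.12/h
  (control) vs 0.04/h (high-dose sEV) — a 3:1 protection ratio; dead cells
  detach with probability 0.8 after a 6 h delay; Gaussian read noise
  (σ = 5) with optional Poisson shot noise; sub-pixel centroid jitter
  (0.7 px) per timepoint. The ratio transition is a step (a ramp duration
  is available but defaults to 0) because truth is then unambiguous.
* **Foci** (`gen_foci_stack`): nuclei as soft-edged flat disks (radius
  14 px, i.e. ~14 µm diameter at a 20× pixel scale of ~0.5 µm/px) rather
  than Gaussian blobs, so the in-mask background under the ×10 contrast
  rule is flat and per-cell truth is unambiguous; Poisson(λ) puncta per
  nucleus rendered as Gaussian PSF spots (σ = 1 px) with peak 20× the
  in-cell background, placed ≥ 4 px apart when possible.
* **Colonies**: soft-edged disks with the half-amplitude contour at the
  nominal radius, so thresholding recovers πr² areas.
* **Flow**: log-normal fluorescence, stained population shifted 100×
  (halved per division generation), debris cluster at ~10% of cell scatter.
* **OCR traces**: four labeled phases at the supplied plateau levels with
  Gaussian noise.

Not modelled: optics beyond a Gaussian PSF, photobleaching, cell division
and migration (beyond jitter), cell-shape realism, flow spillover, and
montage stitching (each field is analysed independently and pooled per
well). Consequently, passing tests demonstrate correctness of the
quantification logic under the assumed statistical structure — segmentation
robustness to real morphology, debris, focus drift and stitching artefacts
is out of scope and must be validated on real images. The imaging
magnification-to-pixel scale of the source assays is not stated anywhere;
the pixel defaults above are explicit, documented choices.

## Problem sizes and determinism

Every stochastic test and the acceptance script run from fixed seeds
through `numpy.random.default_rng`; identical seeds give byte-identical
images and tables. The test bench uses cohorts of 50–200 cells per field,
60–200 nuclei per foci field, 8–30 k flow events and 25-seed invariance
sweeps — sizes at which the suite completes in a few minutes on one CPU
while leaving the statistical assertions well-powered (e.g. the 3:1 hazard
contrast at n = 200/group yields log-rank p far below the 10⁻³ bound being
asserted).
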