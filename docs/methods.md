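# Methods

## Problem and model

A conditionally stabilized nuclear biosensor (nanobody–EGFP–NLS) is degraded
unless it binds its target protein in the cytosol; bound sensor accumulates
in the nucleus. An mCherry reporter, co-translated with the sensor, reads
out induction independently of target binding. A field of view therefore
contains three useful channels — nuclear stain, mCherry (expression), EGFP
(sensor) — and the analysis reduces each cell to a background-corrected mean
intensity per channel, a positive/negative call, and per-well / per-sample
fractions that feed group statistics.

The package implements that reduction as a deterministic operator chain with
no fitted components. Every stage is a pure function of its inputs and
parameters, so pipeline output equals stage-by-stage manual invocation, and
reruns are byte-identical.

## Segmentation

Cells are identified on the nuclear-stain channel (or on mCherry for
plate screens, so untransduced cells never enter the denominator):

1. maximum-intensity z-projection (identity for single-plane input);
2. global threshold — minimum cross-entropy (Li) by default, Otsu or a fixed
   value as alternatives;
3. `despeckle_rounds` passes of a 3×3 median filter on the binary mask;
4. connected components (8-connectivity by default);
5. inclusive area filter `min_area_px ≤ A ≤ max_area_px`;
6. dense relabeling in raster-scan order of each object's first pixel.

Numerical conventions, chosen once and asserted in tests:

* **Li threshold.** The criterion
  `η(t) = Σ_{g≤t} h(g)·g·log(g/μ_low) + Σ_{g>t} h(g)·g·log(g/μ_high)`
  is evaluated exhaustively at every occupied gray level (vectorized over
  cumulative histogram sums), and the exact discrete argmin is returned;
  ties break toward the smaller threshold. Bins with g = 0 contribute zero
  (the g·log g → 0 limit). This differs from iterative Li implementations,
  which converge to a fixed point that need not be the discrete argmin; the
  exhaustive form is cheap (≤ 65,536 candidates) and exactly testable
  against a brute-force oracle.
* **Binarization** is strict (`pixel > t`); a pixel at the threshold is
  background.
* **Despeckling** replicates edge pixels at the border (the convention of
  ImageJ rank filters). A median never introduces new values; idempotence is
  not assumed.
* **Area bounds are inclusive** — "between 20 and 150 px" is read as the
  closed interval, so 20 px and 150 px objects survive.
* **Border-touching objects are kept** by default (`border_policy="drop"`
  is available).
* **No watershed splitting** of touching nuclei is attempted. The synthetic
  generator avoids overlap by construction; on real data with confluent
  nuclei this chain undercounts, which is the main known limitation for
  transfer to real images.
* The monolayer (well) defaults use the same chain with lighter cleanup
  (1 despeckle round) and wider area bounds (20–200 px) than the in vivo
  defaults (4 rounds, 20–150 px), since cultured-cell nuclei rendered at
  radius 4–7 px cover ~50–155 px.

## Quantification

`raw_mean` is the arithmetic in-mask mean per channel. The background of a
channel is the mean over all pixels outside every object dilated by
`margin_px` (default 3 px, disk-shaped element); the dilation guards against
rim halos. `corr_mean = max(raw_mean − background, 0)`. The
sensor-to-expression ratio is `corr_sensor / corr_expression`, defined only
where the corrected expression mean exceeds 1e-9 (NaN otherwise); cells with
undefined ratio stay in fraction-positive counts but drop out of ratio
summaries. The background ROI definition (complement of dilated objects) is
this package's concretization of a "background region of interest"; nothing
in the upstream assay convention pins it down further.

## Classification

* **control_null**: positive iff `corr > mean + k·SD` of the control-cell
  values, with the sample SD (n−1). Controls are pooled across all control
  images of the experiment (maximizing the null sample; per-plate pooling is
  a caller choice). For a Gaussian null the expected positive rate is
  `1 − Φ(k)`, ≈ 2.28% at the default k = 2 — this calibration is asserted at
  n = 10,000 in the acceptance tests.
* **fixed**: positive iff `corr > 400 AU` (default), the convention used for
  plate screens on 16-bit data. Whether such a cutoff transfers to another
  camera scale is unknowable from the assay description, so it is a free
  parameter.

Both rules use strict `>`, so a cell exactly at the cutoff is negative.
Note the corrected means are floored at 0, so the empirical null among
measured control cells is a *censored* Gaussian; the pooled mean + 2 SD
threshold then yields control positive rates near, but not exactly at,
2.28%. The exact-tail calibration is tested on uncensored values.

## Aggregation

Fractions are computed per image, per well (cells pooled over the well's
fields), and per sample, where a sample's value is the **unweighted mean of
its replicate wells' fractions** — each technical replicate well is one data
point, and samples (e.g. patients) enter group statistics with one value
each. Wells with zero cells are flagged and excluded from the sample mean.

## Statistics

* `sem`: sample SD / √n.
* `one_way_anova`: F = MS_between / MS_within with (k−1, N−k) df; p from the
  F upper tail. All-identical data raises (0/0); zero within-group variance
  with distinct means reports F = ∞, p = 0 with a note.
* `tukey_hsd`: per pair, `q = |x̄_i − x̄_j| / sqrt(MS_within/2 · (1/n_i + 1/n_j))`
  (Tukey–Kramer, valid for unequal n); adjusted p from the
  studentized-range survival function with (k, N−k). At k = 2 this equals
  the pooled t-test exactly (q = √2·|t|).
* `t_test_unpaired`: pooled-variance Student's t (df = n_a + n_b − 2),
  two-tailed by default; "Student" is read as pooled, with Welch behind a
  flag.

The studentized-range distribution is evaluated by
`scipy.stats.studentized_range` (numerical double integration); its values
are cross-checked in tests against tabulated critical values (e.g.
q₀.₀₅(3, 12) = 3.773 → p = 0.05 within 1e-3) and against an independent
Tukey implementation. The replicate unit entering every test is the
per-sample (or per-experiment) mean, never the per-cell value — except in
the in vivo workflow, which pools per-nucleus intensities across animals
within a condition, matching how such cohorts are conventionally reported.

## Synthetic data: what it emulates, and what it does not

The generator's defaults define the study conditions for all recovery and
calibration tests: 512×512 px 16-bit fields, 150 cells (500 in the recovery
sweeps), nucleus radii 4–7 px, 30% positive cells, mCherry ~ lognormal
(median ≈ 2000 AU, log-SD 0.4), sensor = 100 AU baseline for negatives and
baseline + 1.0 × (own mCherry) for positives, background 100 AU, Poisson
shot noise plus Gaussian read noise (SD 20 AU). In vivo mode: 256×256×5
stacks, 40 nuclei of radius 2.8–6.5 px (disk areas inside the 20–150 px
band by construction), 15 autofluorescent blobs rendered identically in
both channels at ≈ 4000 AU. No intensity statistics for positive
vs. negative cells exist in the assay description, so these values are
chosen for comfortable separability — they are synthetic settings, not
measurements, and the positive/negative gap they create is wide.

Emulated: disk nuclei, per-cell expression spread, sensor–expression
coupling, additive background, shot + read noise, quantization and
clipping, channel co-localized autofluorescence. Deliberately not emulated:
optical PSF blur, photobleaching, uneven illumination, overlapping or
non-convex nuclei, 3-D structure beyond independent z-planes.
Consequently, passing tests demonstrate the *correctness of the operator
chain and its calibration*, not segmentation robustness on real tissue;
with the default gap, classification accuracy is essentially ceiling, so
recovery tests probe counting and measurement, not borderline
discrimination.

Nuclei are rendered as hard-edged uniform disks rather than with
anti-aliased rims: soft rims would make the in-mask mean differ from the
tabulated ground-truth mean by more than integer rounding and would break
the exact quantification oracle. Placement enforces centre distance ≥ sum
of radii + 2 px so that rendered masks stay disconnected under
8-connectivity (the per-cell averaging assumes resolvable cells); placement
is rejection sampling with a budget of 500 attempts per object, raising a
density error beyond it. Ground-truth `true_mcherry`/`true_sensor` are the
expected **raw** in-mask means (signal + background), so
background-corrected measurements should recover `true − background`.

Four RNG sub-streams (placement, expression, positivity, noise — in that
spawn order from the seed) make each randomness source independently
replayable, and guarantee that changing `p_positive` perturbs only the
sensor channel.

## Pipeline behavior

Per-field errors quarantine the field (logged with well/field identity);
a run aborts only when more than 50% of fields fail — the 50% is arbitrary
and exists to distinguish a bad plate from a bad run. In vivo stacks
missing a channel, or animals with zero surviving nuclei, are skipped with
a warning. Outputs are CSVs with fixed float formatting (`%.9g`), sorted by
(sample, well, field, cell), plus a serialized copy of the config — the
determinism contract is byte-level.

## Problem sizes in the test suite

The suite verifies oracle equivalence on 32×32–40×40 images (50 for the Li
threshold, 20 for despeckling), calibration at n = 10,000, fraction
recovery over 100 seeded 500-cell wells across five true fractions, ANOVA
type-I error over 2,000 null simulations, and the in vivo workflow over 8
stacks (320 nuclei, 120 blobs). These sizes give binomial/Monte-Carlo
standard errors comfortably inside the asserted tolerances while keeping
the whole suite around half a minute.
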