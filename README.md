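# fluorequant

Quantification of nuclear fluorescent-reporter signal in multi-channel
fluorescence microscopy.

The package re-implements, as a tested and reusable pipeline, the image
analysis behind conditionally stabilized biosensor assays: a
nanobody–EGFP–NLS fusion is degraded unless its target protein (here, human
α-synuclein) is present in the cytosol, so a cell's nuclear EGFP intensity
reports target entry. Reporter cells co-express mCherry as an induction
control. The analysis questions are always the same: *which cells are
reporter-positive, what fraction per well/sample, and do conditions differ?*

It is written for microscopy and screening labs who have multi-channel TIFF
fields (nuclear stain, mCherry expression reporter, EGFP sensor) or
two-channel in vivo z-stacks, and want per-cell numbers and group statistics
rather than hand-drawn ROIs.

## What it computes

**Segmentation.** Nuclei/cells are found on the nuclear-stain or mCherry
channel by a deterministic chain: optional maximum-intensity z-projection →
global threshold (minimum cross-entropy / Li by default) → iterated 3×3
median despeckling → connected components → inclusive area filter → dense
relabeling. The Li threshold minimizes, over every candidate gray level *t*,

    η(t) = Σ_{g≤t} h(g)·g·log(g/μ_low(t)) + Σ_{g>t} h(g)·g·log(g/μ_high(t))

by exhaustive search over the histogram, so the returned threshold is the
exact discrete argmin (verified against a brute-force oracle in the tests).

**Per-cell intensities.** For each cell and channel, the mean in-mask
intensity is corrected by subtracting the mean of the non-cell background
region: `corr = max(raw − background, 0)`. The sensor signal can be
normalized to the expression reporter (EGFP/mCherry ratio) to factor out
induction differences.

**Positive-cell classification.** Either a control-null rule — positive if
`corr > mean + k·SD` of negative-control cells (k = 2 by default; for a
Gaussian null the false-positive rate is 1 − Φ(2) ≈ 2.28%) — or a fixed
cutoff in camera units (400 AU by default). Both comparisons are strict.

**Aggregation and statistics.** Cells pool into per-well fractions; a
sample's value is the unweighted mean of its replicate wells. Groups are
compared with one-way ANOVA plus Tukey's HSD (Tukey–Kramer SE for unequal
n, studentized-range p-values), or an unpaired two-tailed Student's t-test;
spread is reported as SEM.

**In vivo workflow.** For two-channel z-stacks where autofluorescent blobs
appear in both channels: max-project both, subtract the autofluorescence
channel from the signal channel (clipped at 0), Li-threshold, despeckle ×4,
keep 20–150 px objects (nucleus size range), measure per-nucleus means, pool
per condition, t-test.

**Synthetic data.** `fluorequant.synth` generates fields and z-stacks with
exact ground truth (disk nuclei, lognormal mCherry, bimodal sensor signal
coupled to mCherry in positive cells, Poisson + Gaussian noise, co-localized
autofluorescent blobs), with documented RNG sub-streams so tests can replay
any stream independently.

## Worked example

```python
from fluorequant import (
    SynthParams, SegmentationParams, ClassificationRule,
    generate_well_field, segment_cells, measure_cells, compute_ratio,
    classify_cells,
)

# simulate one field: 150 reporter cells, 30% accumulate sensor signal
params = SynthParams(seed=1, n_cells=150, p_positive=0.3)
stack, truth_mask, truth = generate_well_field(params)

seg = SegmentationParams(despeckle_rounds=1, min_area_px=20, max_area_px=200)
labels = segment_cells(stack, "expression", seg)
cells = compute_ratio(measure_cells(stack, labels))

# negative-control cells from a matched field with p_positive = 0
ctrl_stack, _, _ = generate_well_field(SynthParams(seed=2, n_cells=150, p_positive=0.0))
ctrl = measure_cells(ctrl_stack, segment_cells(ctrl_stack, "expression", seg))
rule = ClassificationRule(kind="control_null", k_sd=2.0, channel_role="sensor")
cells = classify_cells(cells, rule, ctrl["corr_mean_sensor"])
```

Output of the accompanying print statements:

```
segmented cells:     150 (ground truth 150)
positivity cutoff:   104.7 AU (control mean + 2 SD)
fraction positive:   0.300 (ground truth 0.293)
mean EGFP/mCherry ratio of positives: 1.03
```

All 150 simulated cells are recovered; the control-derived cutoff sits just
above the noise floor of negative cells; the classified positive fraction
matches the generator's ground truth; and the EGFP/mCherry ratio of positive
cells is ~1 because the generator couples sensor accumulation 1:1 to each
cell's own mCherry level.

## Command line

```sh
fluorequant simulate --mode well --out sim/ --seed 1 --n-fields 3
fluorequant segment  --config cfg.yaml --in sim/field000.tif --out mask.tif
fluorequant run      --config cfg.yaml       # whole plate or in vivo workflow
```

`fluorequant run` reads one YAML config (paths, channel role map,
segmentation parameters, classification rule, stats plan) and writes
`per_cell.csv`, `per_well.csv`, `per_sample.csv`, `stats.csv`, a copy of the
config, and a log into the output directory. Reruns with the same config are
byte-identical.

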