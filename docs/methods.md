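# Methods

## Feature pipeline

For a 2D slice `I(x, y)` (x = column, y = row) the Gradient-DDP descriptor is
computed as follows.

**Gradient field.** `compute_gradient` uses the standard numerical gradient
(`np.gradient`, unit spacing): central differences at interior pixels,
one-sided first-order differences at the boundary. This operator is exact on
affine images and returns zero fields on constants. Magnitude is
`hypot(Gx, Gy)`; orientation is `atan2(Gy, Gx)` folded onto `(-π, π]`, with
`atan2(0, 0) = 0` defining the direction at zero-gradient pixels.

**Block statistics.** The slice is tiled into non-overlapping
`block_size × block_size` blocks (default 3), row-major, trailing rows and
columns that do not fill a block discarded. Each block contributes three
numbers, grouped by block in the output vector:

- mean of the gradient magnitude (intensity/pixel),
- population variance (denominator *N*) of the gradient magnitude — no
  sample-variance convention is implied by the descriptor, and population
  variance is the plain second moment of the block,
- circular mean `atan2(mean sin, mean cos)` of the orientation — arithmetic
  means of angles are discontinuous at ±π.

**Normalization.** The whole vector is min–max rescaled to [0, 1]. The
summary scalars `b_min`, `b_max`, `μ` in the coder are computed over the
entire vector, not per statistic channel; a per-channel variant is not the
default because the coder's anchors are defined on the single vector *b*.
A constant vector normalizes to all zeros by convention (every entry then
receives code 0, the `b_min` anchor).

**Quantization.** Eleven codes 0–10. Equality anchors (`b_min → 0`,
`b_max → 1`, `μ → 6`) are tested within a relative tolerance
`ε = 1e-12 · (b_max − b_min)`, since exact float equality is measure-zero.
Two modes:

- `literal` (default): the interval rules exactly as printed, evaluated
  top-to-bottom with first-match-wins. The printed upper-half cut points
  `(μ + b_max)·k/4` are not guaranteed to exceed `μ` (e.g. for vectors with
  negative mean), so the printed rule set is not a partition; entries matched
  by no rule receive the fallback code 10. Fidelity is preferred over
  aesthetics here — including code 1 for `b_max`, which breaks ordinal order.
- `monotone`: the defensible re-reading with cut points
  `b_min + k(μ − b_min)/4` and `μ + k(b_max − μ)/4`, k = 1, 2, 3, which is a
  proper ordered partition and is order-preserving between the anchors.

The mode is recorded in each feature's provenance. A scalar rule-by-rule
evaluator (`quantize_scalar_reference`) is kept in the package as the
independent oracle for the vectorized implementation; the test suite checks
their agreement on 10⁵ random values in both modes.

**Histogram.** Codes are counted into 16 equal-width bins spanning [0, 10]
(last bin right-inclusive) and divided by the count, so the descriptor sums
to 1. With 11 distinct codes and 16 bins, five bins are structurally empty;
binning the pre-quantization normalized values over [0, 1] instead is exposed
via `FeatureConfig(histogram_domain="normalized")` since either reading of
"aggregated into normalized histograms with 16 bins" is defensible. Codes are
the default because the coder's output *is* the descriptor.

**Intensity baseline.** The classical DDP path replaces the block statistics
with dense per-pixel (mean, max, min) over 3×3 neighborhoods, border pixels
excluded (no padding — padding fabricates intensities and no convention is
canonical). It shares the normalization/quantization/histogram stages and
defaults with the gradient variant so a comparison isolates the descriptor
change. The per-pixel window mean is clipped into [window min, window max]
to make the min ≤ mean ≤ max invariant exact under floating-point summation.

## Phantom

The generator emulates the data regime the descriptors are meant for without
any external data: per subject, an elliptical "brain" (semi-axes ≈ 42% of the
frame with ±3% subject-level jitter) partitioned into a CSF ring, a
gray-matter band and a white-matter core; elliptical lesions placed by
rejection sampling fully inside white matter (100 attempts per lesion, then a
placement error); per-modality tissue means encoding the standard contrasts
(T2/FLAIR lesions hyperintense vs. white matter, T1 hypointense, FLAIR CSF
suppressed below gray matter); a smooth multiplicative intensity
non-uniformity (INU) field from a random second-order polynomial rescaled to
`1 ± inu_amplitude`; additive Gaussian noise (Rician optional — magnitude MR
noise is Rician but reduces to Gaussian at high SNR), clipped at 0.

Defaults, chosen once as realistic desk-scale study conditions:

| parameter | default | rationale |
|---|---|---|
| image_size | 96 × 96 | large enough for ~1024 blocks per slice; fast |
| slices_per_subject | 30 | desk-scale stand-in for 120 (simulated) / 50 (clinical) slices per subject |
| noise_sigma | 3 intensity units | ≈3% of white matter, the standard simulated-MRI noise setting |
| inu_amplitude | 0.2 | the standard 20% INU knob of simulated brain databases |
| severity specs | mild 1–3 lesions, 1–3 px; moderate 4–8, 2–5 px; severe 9–15, 4–8 px | strictly increasing expected lesion load with overlapping ranges, so grades are separable but not trivially |
| binary MS grade | moderate | the single-grade lesion load typical of simulated MS brains |

Lesions are re-sampled per slice (count ~ uniform integer range, semi-axes ~
uniform, orientation ~ uniform), which models independent axial
cross-sections rather than a coherent 3D lesion; subjects keep a fixed
anatomy across their slices. Labels are derived from the generated masks
(`MS` ⇔ at least one lesion voxel), so label soundness holds by construction.

What the phantom does **not** model: real cortical anatomy (gyri,
ventricles), slice thickness / partial-volume effects, registration error,
longitudinal within-subject change, or realistic lesion intensity
distributions. Passing the end-to-end gates therefore shows the pipeline
recovers a known, clean lesion-load signal under noise and bias fields — not
clinical-grade performance; real-data claims require the NIfTI/PNG loaders
and real cohorts.

## Evaluation protocol

Whole subjects are dealt to 5 folds by a seeded greedy scheme: per class,
subjects are shuffled and assigned to the currently least-loaded fold (ties →
lowest fold index), so per-fold class counts deviate from balance by at most
one. In round *r*, fold *r* is the test set, fold *r+1 (mod K)* the
validation set, the rest training. The validation fold is reported but
nothing is selected on it — the protocol declares a dedicated validation set
without a tuning step, and rotation keeps all three roles subject-exclusive
in every round. Greedy assignment rather than exact optimization is adequate
at these cohort sizes and is deterministic given the seed.

Classifiers (scikit-learn): `SVC(C=10, kernel="rbf", gamma="scale")`,
`KNeighborsClassifier(n_neighbors=3, weights="distance", p=2)`,
`LinearDiscriminantAnalysis(solver="svd")` (no shrinkage), and
`LogisticRegression` with the default L2 penalty at C=1.0 — the "logistic"
arm is a proper classifier even though least-squares regression on class
labels would be a literal reading of some descriptions of it, because it is
used for classification throughout.

Metrics: accuracy, macro-averaged precision/recall/F1 (zero-division cells
contribute 0), confusion matrix, and MCC. MCC is implemented twice — the
binary closed form `(TP·TN − FP·FN)/√((TP+FP)(TP+FN)(TN+FP)(TN+FN))` and the
generalized correlation form `cov(t,p)/√(cov(t,t)·cov(p,p))` over the
confusion matrix — with a zero denominator yielding 0 by convention; the two
agree on all 2×2 matrices and the generalized form is the one used. Across
modalities, MCC values are aggregated as arithmetic mean ± population
(denominator *n*) standard deviation, reported to 3 decimals; population std
is the convention consistent with the published aggregation arithmetic.

## Problem sizes and numerical notes

The packaged experiments use 20 subjects per class × 30 slices at 96 × 96
(binary: 1200 slices; severity: 1800), which keeps a full multi-modality run
under a minute on one CPU while leaving the classification task non-trivial.
Determinism: every stochastic component (phantom, splits, solvers) is driven
by explicit integer seeds through `numpy.random.default_rng`; identical
configs give bitwise-identical cohorts (checked by SHA-256 checksum).

Known limitations: the 2D concentric-ellipse anatomy makes the brain
boundary the dominant gradient structure, so descriptors lean on
lesion-induced interior edges against a simple background; per-slice lesion
resampling inflates the effective information per subject relative to
coherent 3D lesions; and the `literal` quantizer intentionally reproduces a
non-monotone rule table, so its codes are categorical rather than ordinal —
the histogram stage treats them as such.
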