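# Methods

## Problem and pipeline

`octdr` implements a computer-aided diagnosis pipeline for early diabetic
retinopathy (DR) from macular 3D-OCT: a volume of K parallel grayscale
B-scans (K = 5 by default, the mid scan crossing the fovea) in which the
retina appears as 12 stacked layers (NFL innermost through RPE outermost,
bounded by 13 surfaces). The pipeline has three stages:

1. **Segmentation by label propagation** — a 12-layer segmentation of the
   foveal mid scan (supplied by the user, or ground truth when working with
   phantoms) is treated as a patient-specific atlas and propagated outward
   scan by scan.
2. **Second-order texture features** — each layer's reflectivity texture is
   summarised by a pairwise Markov–Gibbs random field (MGRF): gray-level
   co-occurrence statistics, analytical Gibbs potentials, per-pixel Gibbs
   energies, and the nine deciles of the energy CDF as a fixed-length
   descriptor.
3. **Classification** — twelve small feed-forward networks (one per layer)
   vote on the subject's diagnosis; the majority decides.

The mid-scan segmentation itself (an atlas/shape-database method) is out of
scope; the pipeline starts from a provided mid-slice label map.

## MGRF texture model

A B-scan is a map g : R → {0, …, Q−1} on the pixel lattice. The
neighborhood system N is the 8 in-plane offsets
(0,±1), (±1,0), (±1,±1); two through-plane offsets (±1 scan) can be added
by configuration, though the in-plane cliques dominate in anisotropic
5-scan volumes. For layer l and offset i:

- **F_i** — the co-occurrence matrix over pairs (g(v), g(v+offset)) with
  both endpoints inside the image and inside the layer, normalized to sum
  to 1. Tallied per scan and averaged (unweighted) over the scans in which
  the layer appears.
- **f_i(q) = Σ_s F_i(q,s)** — the gray marginal. This row-sum convention
  makes f a true distribution; a variant carrying an extra 1/Q factor is
  available as `marginal_convention="printed"` for auditability, but only
  the row-sum convention has the property that the potentials vanish for
  independent gray levels, which the feature relies on.
- **V_i(q,s) = ρ_i (F_i(q,s) − f_i(q) f_i(s))** — the analytical
  maximum-likelihood Gibbs potentials. ρ_i defaults to 1 for every offset:
  it scales all potentials (hence all features) linearly and the downstream
  classifier standardizes scales anyway, so discrimination is unaffected.
- **Layer energy** E_i = Σ_{q,s} F_i(q,s)(F_i(q,s) − f_i(q)f_i(s)) — a
  per-offset scalar, exposed as a diagnostic.
- **Per-pixel energy** e(v) = Σ_i V_i(g(v), g(v+offset_i)) over all offsets
  whose far endpoint is in-image and in-layer, with no normalization by
  neighbor count (a pixel's Gibbs energy is the plain sum of its clique
  potentials). Pixels with no in-layer neighbor get energy 0.

The per-layer descriptor U_l is the nine deciles E(10)…E(90) of the
per-pixel energies pooled over the whole volume, computed by linear
interpolation between closest order statistics (inclusive endpoints) — a
fixed, testable convention. A `per_scan` flag instead emits deciles per
scan (9·K values per layer) for the concatenated-feature variant; pooled
is the default. The partition function of the MGRF is never needed: only
potentials and energies enter the features.

**Quantization.** Q is a free parameter, default Q = 32 uniform bins over
the input dynamic range: small enough that Q×Q co-occurrence matrices stay
well populated inside single layers of a 5-scan volume, large enough to
retain texture contrast. Integer input already confined to [0, Q−1] passes
through unchanged, making volume round trips exact.

## Label propagation

For each unlabeled scan (processed outward from the mid scan), the scan is
densely registered to its already-labeled neighbor (iterative Lucas–Kanade
optical flow by default; TV-L1 available; any dense 2D registration can be
plugged in). For target pixel v with correspondence v′:

- collect the window (11×11 initially) around v′ and keep reference pixels
  whose gray level is within τ = 2 quantized levels of g(v);
- if none qualify, grow the window by 4 pixels per side and retry, up to
  31×31;
- the label posterior is each label's incidence among qualifying pixels;
  v takes the argmax.

Three deterministic rules complete the procedure:

- **center-match shortcut**: when g(v′) = g(v) exactly (common between
  neighboring scans at Q = 32), v′'s label is taken outright. This makes
  propagation across identical scans an exact fixed point for *any* label
  map — plain incidence voting cannot guarantee that (a constant-intensity
  region votes by label frequency regardless of correspondence) — and
  matches the intent that labels propagate onto regions of *similar
  appearance*.
- **ties** prefer the label of v′, then the smaller label index.
- **exhaustion fallback**: if the maximum window holds no qualifying pixel,
  v takes v′'s label with confidence 0, so no pixel is left unlabeled and
  low-confidence regions are flaggable downstream.

Background (label 0) participates like any label. Out-of-image
correspondences are clamped to the nearest valid pixel. Window sizes, τ
and the expansion schedule are configuration; the defaults were chosen on
phantoms before any classification experiments.

## Classifier ensemble

Per layer: input d = 9 deciles → 20 tanh → 10 tanh → 2 softmax, trained
from scratch with per-sample stochastic gradient descent on cross-entropy
(learning rate 0.01, epoch cap 500, stop early when the maximum absolute
weight change over an epoch falls below 1e-6), weights initialised from a
seeded normal distribution scaled by 1/√fan-in. Features are standardized
with training-fold statistics only, preventing test leakage. Training is
bit-reproducible given the seed, and the backprop gradients are verified
against central finite differences in the test suite.

Fusion: each layer votes argmax of its posterior; the majority of 12 votes
decides. A 6–6 tie goes to DR only when the mean DR posterior across the
12 networks exceeds 0.5, otherwise to healthy — deterministic and using
the available confidence. DR is the positive class throughout; outputs
order classes (healthy, DR).

Evaluation: subject-level stratified k-fold cross-validation (stratified so
small cohorts remain feasible; all rows of a subject stay in one fold),
pooled confusion counts, and per-layer ROC/AUC by threshold sweep with
trapezoidal integration. Sensitivity is TP/(TP+FN) and specificity
TN/(TN+FP); a `printed` convention reporting TP/(TP+FP) in the specificity
slot is exposed for auditability only. Zero-denominator rates are reported
as undefined, never as 0.

## Phantom generator

Clinical OCT cohorts for this task are private, so the package ships a
synthetic layered-retina phantom (default 128×256 pixels × 5 scans,
Q = 32) that emulates exactly the structure the pipeline exploits:

- 12 layers between dark vitreous and choroid, boundaries perturbed by a
  shared low-frequency wave, with a Gaussian foveal dip thinning the inner
  layers near the central column, strongest at the mid scan;
- per-layer correlated speckle texture (Gaussian-smoothed white noise with
  per-layer correlation lengths, multiplicative speckle modulation), layer
  means alternating bright/dark as in real OCT;
- a DR effect expressed purely as a change of texture correlation lengths
  and anisotropy in a configurable subset of layers (default OPL and ONL,
  layers 5–6), with the DR values rank-mapped onto a healthy-marginal
  sample so first-order histograms match between classes.

Histogram matching defaults on: it removes all first-order signal, so a
classifier can only succeed through second-order structure — precisely
what the Gibbs-energy features measure. Effect sizes are free parameters
of the phantom, not claims about retinal biology. The phantom does *not*
model physical OCT speckle statistics, attenuation, vascular shadowing, or
pathological morphology (no edema or drusen); passing tests therefore
demonstrate the correctness of the computational chain and its sensitivity
to second-order contrast, not clinical performance.

Determinism: geometry is seeded per volume, textures per (scan, layer);
identical (class, params, seed) reproduce volumes bit for bit, and cohort
subject i uses seed base+i.

## Problem sizes

The shipped experiments use 40-subject cohorts (20 healthy / 20 DR) at
128×256×5 with 5-fold cross-validation, 20 phantoms for segmentation
recovery, and 512×512 scans for the independence-limit checks — sizes at
which every stage's statistical behaviour is already stable.

## Known limitations

- With the default phantom, only 2 of the 12 layer classifiers carry
  signal. Hard majority voting with 10 chance-level voters then has a
  ceiling: even with perfect affected-layer classifiers the expected vote
  accuracy is P(Bin(10, ½) ≥ 5) + P(= 4)·P(tie broken correctly) ≈ 0.83.
  Measured end-to-end accuracy lands in the 0.72–0.88 range across seeds,
  consistent with that ceiling. This is a property of the fusion rule
  under a two-informative-layer regime, not a defect of the features (the
  affected-layer classifiers score ≥ 0.95); clinical cohorts, where all 12
  layers carry disease signal, do not sit in this regime. Configuring more
  `affected_layers` moves the phantom out of it as well.
- The center-match shortcut makes propagation between similar scans lean
  heavily on the registration; severely mis-registered volumes would
  propagate confident errors. Confidence maps expose this.
- The propagation assumes slowly varying anatomy between adjacent scans
  (2–2.5 mm slice spacing in the motivating acquisitions is coarse; the
  method transfers labels, it does not re-segment).
- Feature tables assume all 12 layers present in every volume; volumes
  missing a layer fail fast (or NaN-fill under a permissive flag).
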