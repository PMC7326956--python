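# Methods

## Scope and design

`nfdecode` is a desk-scale re-implementation of a closed-loop real-time
fMRI decoding pipeline for motor imagery neurofeedback.  The pipeline's
scientific claim is behavioural, not anatomical: under learning-driven
nonstationarity, a classifier trained once before feedback degrades
across feedback runs, and retraining it after every run on only the
newly acquired data removes that degradation.  Because the original
study's participant data are private, the pipeline is exercised on a
synthetic cohort whose generator builds in exactly the nonstationarity
the claim is about; the package therefore demonstrates *directional*
reproduction (which strategy wins, and why), not reproduction of any
human-data performance numbers.

## Experimental protocol

One run is 9 rest blocks bracketing 8 task blocks (4 imagined left-hand
gripping/opening, LGO; 4 right-hand, RGO), every block 30 s, sampled at
TR 2.0 s: 255 volumes, of which 135 rest, 60 LGO, 60 RGO.  Four runs
per subject: run 0 trains the initial models; runs 1–3 are feedback
runs.  Task-block ordering within a run is not constrained by the
protocol's bookkeeping; the builder defaults to strict alternation
starting with LGO and offers a seed-deterministic shuffle.  Volume
labels use 0-based indices and half-open block intervals.

Per-volume labels can be delayed by `label_shift_volumes` to account for
hemodynamic lag.  The schedule's own default is 0 (so task-volume counts
match the literal TPV definition); the *session* default is 2 volumes
(4 s ≈ the canonical HRF peak delay).  Without the shift, roughly the
first two volumes of every task block are labelled task while the BOLD
response is still at baseline — a systematic ~13 % label corruption that
depresses both training and measured TPV.  The cue timeline that selects
models and drives feedback is never shifted.

## Synthetic cohort generator

A subject is a set of spherical activation regions on a 24×24×12 grid of
3-mm voxels (a deliberately small stand-in for whole-brain data —
enough structure for the decoding problem, small enough to simulate 30
subjects in under a minute):

* two *relevant* hand-area regions (radius 3, amplitude 2 % of a
  baseline of 100), one LGO- and one RGO-selective, placed
  contralaterally;
* one *relevant* SMA-like midline region (radius 2, 1.5 %) responding to
  both tasks;
* four *transient* regions (radius 2–3, 1.5 %, mixed selectivity)
  representing early-training activity.

Voxel signal = baseline + Σ region amplitude × binary sphere profile ×
(condition boxcar ⊗ HRF) + linear drift + AR(1) Gaussian noise.  The HRF
is the canonical double-gamma (response gamma shape 6 minus undershoot
gamma shape 16 at 1:6 ratio, unit peak).  Defaults: noise sd 2 (so
contrast-to-noise ≈ 1 at region cores before smoothing), AR(1)
coefficient 0.3, drift 0.02·noise_sd per volume — a regime in which
detrending matters over a 255-volume run.  Spatial profiles are hard
spheres so truth masks stay well defined; spatial correlation comes from
the 8-mm smoothing in preprocessing.

Learning: with rate λ (default 0.4, jittered ±20 % per subject),
transient amplitudes scale by (1−λ)^run and relevant radii shrink by
(1−λ/2)^run toward a 1-voxel floor while relevant amplitudes rise by
15 %·λ per run.  Run 0 always uses the full widespread topography.  No
published effect sizes exist for these changes, so only directional
claims are recoverable; λ=0.4 yields transient-amplitude factors
0.6/0.36/0.22 over runs 1–3, enough for the static decoder's decline to
be unambiguous at n=30 without being instantaneous.

Everything is deterministic given (subject seed, run index); cohort
subject *s* uses seed base+*s*.  Data are stored float32.

What the generator does **not** emulate: head motion and realignment,
physiological (cardiac/respiratory) noise, anatomical variability and
MNI-space geometry, non-spherical activation shapes, and spatially
correlated scanner noise.  Passing tests therefore show the *pipeline*
behaves correctly under the modelled nonstationarity — not that the
effect sizes or TPV levels transfer to human data (synthetic TPVs sit
near ceiling; human ones do not).

## Preprocessing

Real-time path per volume: 8-mm FWHM separable Gaussian smoothing
(σ = FWHM/(2√(2 ln 2)·voxel); reflecting boundaries preserve mass on
small grids), masking to a fixed recorded voxel order (default: whole
grid), then streaming linear detrending.

The streaming detrender keeps running sums (n, Σt, Σt², Σy, Σty) per
voxel — constant memory — and emits at step n exactly the step-n
residual of an OLS line fitted to all n samples (0 during the n ≤ 2
warm-up, where a line fits the data exactly).  A sliding-window variant
is available.  In the closed loop the fit is *cue-aware*: only volumes
whose lag-shifted label is rest are ingested, and task volumes are
corrected against the current fit without updating it.  A line fitted to
all volumes indiscriminately absorbs the block structure into its slope
early in the run (there is nothing else to explain the first task
block's rise) and misclassifies task volumes wholesale; rest volumes are
task-signal-free by construction, so a rest-only fit tracks scanner
drift and nothing else.  The lag shift keeps the first volumes of each
rest block — which still carry the previous block's decaying response —
out of the fit.

Offline path (training-set preparation and offline metrics): batch OLS
detrend over the full run.  Offline metrics additionally discard the
first 5 volumes per run; the real-time path classifies every volume.
No per-feature standardisation is applied by default.

## Decoding

Linear soft-margin SVM, `½‖w‖² + c Σ hinge`, c = 1, via scikit-learn's
exact dual solver (tol 1e-8).  Three contrasts: R vs LGO and R vs RGO
(trained on rest plus that task's volumes), LGO vs RGO (task volumes
only).  Ties at decision value exactly 0 go to the negative (rest)
class — no undeserved feedback.  Weight maps scatter w back into image
space for group analysis.

The decision trace is drift-corrected by the same cumulative linear
detrend plus re-addition of the running mean, so the level information
separating the classes survives and only the linear drift component is
removed; labels are re-thresholded at 0.  In the closed loop this
corrector is likewise rest-fit/task-evaluate.  The standalone
`detrend_decisions` function applies the pure cumulative algorithm to a
finished trace.

## Closed loop and strategies

Per volume: preprocess → select the rest-vs-task model matching the
current block's cue → decision value → output drift correction →
threshold → feedback.  A correct task classification raises the cued arm
by 11° (LGO→left arm by default; the mirror convention is a flag);
incorrect leaves it stationary; arms reset to 0 at block ends; rest
volumes are classified and logged but never move the robot.  Retraining
labels come from the schedule (supervised, known block structure), not
from predictions.  All streaming state resets at run boundaries (runs
are separate scans).  Incremental: run r decoded by models trained on
run r−1 only.  Static: run-0 models throughout — which makes run-1
outputs bit-identical across strategies, a useful built-in control.

## Evaluation

TPV and pairwise accuracy as defined above (rest excluded).  One-way
repeated-measures ANOVA by direct sums-of-squares decomposition,
F = MS_condition/MS_error, df = (k−1, (k−1)(n−1)), sphericity assumed —
for 30 subjects × 3 runs this is the F(2,58) form.  Post-hoc paired
t-tests are two-sided and uncorrected.  GLM: per-voxel OLS on
[LGO regressor, RGO regressor, intercept, linear drift], t = cᵀβ̂ /
√(σ̂² cᵀ(XᵀX)⁻¹c), df = volumes − 4.  Group maps: voxelwise one-sample t
across subjects (df n−1), thresholded at two-sided p < 0.001 with an
optional cluster-extent filter — a deliberate, simple stand-in for
random-field-theory cluster correction, which is out of scope.

## Numerical choices and degenerate cases

Streaming/batch detrend agreement is exact to ~1e-13 in double
precision; tests assert 1e-8 relative.  SVM solver tolerance 1e-8;
analytic-toy agreement asserted at 1e-4.  Zero-variance cells: paired t
flags degenerate differences; group t-maps flag zero-variance voxels
invalid (±inf t when the mean is nonzero); rm-ANOVA returns F=0 for
identical columns.  Empty masks, single-class training sets, non-finite
features, rank-deficient GLM designs, non-divisible block durations and
missing runs are rejected with explicit errors.

On HRF-convolved data, block-transition volumes are intrinsically
ambiguous: at a 2-volume label shift the first labelled task volume
carries only ~half the plateau response, and the soft-margin SVM may
accept hinge losses there even at zero noise.  Perfect (100 %) TPV is
therefore only guaranteed — and only asserted — for instantaneous
(unconvolved) signal; the zero-noise HRF-convolved check asserts ≥90 %.

## Problem sizes

Defaults were chosen so the full pipeline is interactive on a laptop:
the 30-subject × 4-run × 2-strategy comparison at 24×24×12 (6 912
voxels × 255 volumes) takes about 45 s; the 10-subject high-SNR recovery
experiment (relevant-regions-only topography, λ=0, amplitude ×1.5 over
noise sd 1) about 10 s plus GLM time.  Cohort experiments simulate,
analyse and discard one subject at a time, so peak memory is a single
subject's four runs (~30 MB).

## Known limitations

Realignment, segmentation, normalisation, motion covariates and atlas
labelling are out of scope; the generator's realism limits are listed
above.  The rest-only drift fit assumes the schedule is known to the
real-time system (true in cue-driven neurofeedback).  The ANOVA applies
no sphericity correction, matching the reported F(2,58) form.  The
LGO-vs-RGO contrast is evaluated offline only, as in the original
design, where feedback was driven solely by the two rest-vs-task models.
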