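# nfdecode

Closed-loop motor-imagery fMRI decoding with incremental SVM retraining,
on synthetic nonstationary cohorts.

## The problem

In real-time fMRI neurofeedback, a classifier trained before the
feedback session decodes the participant's ongoing brain state — here,
imagined left- vs right-hand gripping/opening (LGO/RGO) vs rest — and
drives the feedback (a robot arm that rises 11° per correctly decoded
task volume).  But neurofeedback exists to make the participant *learn*,
and learning reshapes the activation pattern: early sessions show
widespread activity that later becomes focal and confined to
task-relevant regions.  A classifier trained once therefore goes stale
across feedback runs, while one retrained after every run on the newly
acquired data keeps up.

`nfdecode` implements this pipeline end to end for researchers studying
decoder stability under nonstationarity: a block-design protocol
(9 rest + 8 task blocks of 30 s at TR 2.0 s; 255 volumes/run; 4 runs per
subject), a seeded generator of 4D voxel-grid cohorts with
learning-driven topography changes, streaming preprocessing (8-mm FWHM
Gaussian smoothing, masking, constant-memory incremental linear
detrending), soft-margin linear SVM decoding (`c = 1`) with decision-
trace drift correction, a volume-by-volume feedback simulator, and the
evaluation statistics: task predictive value (TPV), LGO-vs-RGO accuracy,
one-way repeated-measures ANOVA with post-hoc paired t-tests, GLM
activation maps, and group t-maps of classifier weights.

## The model in brief

Each volume's masked, detrended pattern **x** is scored by a linear SVM,
`d = w·x + b`, trained by minimising `½‖w‖² + c Σᵢ max(0, 1 − yᵢ(w·xᵢ + b))`.
Three contrasts are decoded: R vs LGO, R vs RGO (these drive feedback)
and LGO vs RGO (offline separability of the two imageries).  Per run,
`TPV = 100 × (#task volumes predicted task) / (#task volumes)`, rest
volumes excluded.  Two training regimes are compared across feedback
runs 1–3:

* **incremental** — run *r* is decoded by the SVM trained on run *r−1*
  alone; after run *r* the SVMs are retrained on run *r*'s data only;
* **static** — the run-0 SVMs decode all three feedback runs unchanged.

The synthetic forward model per voxel is
`baseline + Σ regions amplitude · profile · (boxcar ⊗ HRF) + drift·t + AR(1) noise`,
with the canonical double-gamma HRF, and a learning rate that fades
transient regions by `(1−λ)^run` and shrinks relevant-region radii — the
widespread→focal trajectory.

## Worked example

`examples/05_cohort_comparison.py` runs both strategies over an 8-subject
seeded cohort and prints:

```
mean TPV (%) by strategy / contrast / run:
run                      1     2     3
strategy    contrast
incremental R_vs_LGO  99.6  98.3  98.1
            R_vs_RGO  99.4  98.3  99.2
static      R_vs_LGO  99.6  91.7  69.4
            R_vs_RGO  99.4  96.0  81.5

run effect (repeated-measures ANOVA, runs 1-3):
  incremental/realtime/R_vs_LGO: F(2,14) = 2.41, p = 0.1262
  incremental/realtime/R_vs_RGO: F(2,14) = 1.77, p = 0.2062
  static/realtime/R_vs_LGO: F(2,14) = 30.28, p = 0.0000
  static/realtime/R_vs_RGO: F(2,14) = 17.35, p = 0.0002

static R-vs-LGO run1 vs run3 paired t: t(7) = 5.86, p = 6.21e-04
```

Read: run 1 is identical under both strategies (both use the run-0
models).  As the cohort's activation focalises, the static decoder's TPV
collapses (99.6 → 69.4 %, a highly significant run effect), while the
incrementally retrained decoder stays near ceiling with no significant
run effect.  The other examples cover the schedule builder, the
nonstationary generator, streaming detrending, a single closed-loop
session, and GLM/weight-map recovery of the ground-truth regions.

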