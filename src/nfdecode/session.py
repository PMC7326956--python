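"""Closed-loop neurofeedback session simulation and training strategies.

The real-time loop processes each volume in acquisition order: smooth,
mask, incrementally detrend, compute the decision value of the SVM
matching the current block's cue (rest-vs-LGO during LGO blocks,
rest-vs-RGO during RGO blocks), drift-correct the classifier output,
threshold, and — during task blocks — drive the robot arm: a correct
"task" classification raises the cued arm by 11 degrees, an incorrect
one leaves it stationary, and the arm resets at the end of each block.

Two training strategies are compared:

* **incremental** — the initial SVMs are trained on run 0; after every
  feedback run the SVMs are retrained *on that run's data only* and used
  for the next run (run r is classified by the model trained on run r-1);
* **static** — the run-0 SVMs classify all three feedback runs with no
  update (the conventional approach, used here for validation).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .decode import (
    CONTRASTS,
    Contrast,
    DecisionDetrender,
    DecisionTrace,
    LinearModel,
    train_contrast,
)
from .preprocess import DetrendState, apply_mask, batch_detrend, smooth_run
from .protocol import BlockSchedule, Condition
from .simulate import Subject, SyntheticRun

__all__ = [
    "FeedbackState",
    "SessionConfig",
    "RunResult",
    "SessionResult",
    "feedback_step",
    "train_models_on_run",
    "run_realtime",
    "incremental_session",
    "static_session",
]

#: contrasts evaluated in real time (these drive feedback)
REALTIME_CONTRASTS = ("R_vs_LGO", "R_vs_RGO")
#: all contrasts, including the offline-only LGO-vs-RGO model
ALL_CONTRASTS = ("R_vs_LGO", "R_vs_RGO", "LGO_vs_RGO")


@dataclass
class FeedbackState:
    """Robot arm angles and the action history of one run.

    Angles only ever increase by ``increment_deg`` (correct task
    classification) or reset to 0 (block end); both arms start and end
    every block at 0.
    """

    increment_deg: float = 11.0
    left_arm_deg: float = 0.0
    right_arm_deg: float = 0.0
    history: list[tuple[int, str]] = field(default_factory=list)
    #: which cue raises the left arm (mirror convention is configurable)
    left_arm_cue: Condition = Condition.LGO

    def angle_for(self, cue: Condition) -> float:
        return self.left_arm_deg if cue == self.left_arm_cue else self.right_arm_deg


def feedback_step(
    state: FeedbackState,
    cue: Condition,
    predicted_task: bool,
    is_block_end: bool,
    volume: int = -1,
) -> FeedbackState:
    """Advance the feedback controller by one task-block volume.

    A correct classification (predicted task during a task block) raises
    the arm matching the cue by the increment; an incorrect one leaves
    both arms stationary.  At a block end the cued arm resets to 0
    *after* any raise from this volume.
    """
    if cue not in (Condition.LGO, Condition.RGO):
        raise ValueError(f"feedback cue must be a task condition, got {cue}")
    left = cue == state.left_arm_cue
    if predicted_task:
        if left:
            state.left_arm_deg += state.increment_deg
        else:
            state.right_arm_deg += state.increment_deg
        state.history.append((volume, f"raise_{'left' if left else 'right'}"))
    else:
        state.history.append((volume, "hold"))
    if is_block_end:
        if left:
            state.left_arm_deg = 0.0
        else:
            state.right_arm_deg = 0.0
        state.history.append((volume, f"reset_{'left' if left else 'right'}"))
    return state


@dataclass(frozen=True)
class SessionConfig:
    """Settings shared by the real-time loop and training preparation."""

    fwhm_mm: float = 8.0
    voxel_mm: float = 3.0
    mask: np.ndarray | None = None  # None -> whole grid
    increment_deg: float = 11.0
    left_arm_cue: Condition = Condition.LGO
    svm_c: float = 1.0
    #: volumes dropped at the start of a run when *training* (the
    #: real-time loop always classifies every volume)
    train_discard_volumes: int = 0
    #: hemodynamic-lag shift applied to training labels and metrics.
    #: 2 volumes = 4 s at TR 2.0 s, roughly the canonical HRF delay; the
    #: BOLD response to a cue arrives ~2 volumes late, so training labels
    #: and metric labels are delayed to match while the cue timeline that
    #: selects models and drives feedback stays unshifted.
    label_shift_volumes: int = 2
    #: sliding-window size for the streaming detrends (None = cumulative)
    detrend_window: int | None = None
    #: extra volumes during which decision values pass through raw
    #: before the output drift correction is trusted.  The streaming
    #: fits are updated on rest-cue volumes only (task signal never
    #: enters the drift line), so no warm-up beyond the fit's own
    #: 3-sample minimum is needed by default.
    detrend_warmup_volumes: int = 0

    def resolve_mask(self, run: SyntheticRun) -> np.ndarray:
        if self.mask is not None:
            if self.mask.shape != run.grid_dims:
                raise ValueError(
                    f"mask shape {self.mask.shape} does not match run grid "
                    f"{run.grid_dims}"
                )
            return np.asarray(self.mask, dtype=bool)
        return np.ones(run.grid_dims, dtype=bool)


@dataclass
class RunResult:
    """Real-time outputs for one run under one model generation."""

    run_index: int
    traces: dict[str, DecisionTrace]  # contrast name -> trace
    feedback: FeedbackState
    feedback_angles: np.ndarray  # cued-arm angle after each volume
    labels: np.ndarray  # metric labels (possibly lag-shifted)
    cues: np.ndarray  # unshifted cue timeline


@dataclass
class SessionResult:
    """One subject under one training strategy across runs 1-3."""

    strategy: str  # "incremental" | "static"
    subject_id: int
    run_results: dict[int, RunResult]
    #: contrast name -> list of model generations (index g trained on run g)
    models: dict[str, list[LinearModel]]
    mask: np.ndarray


def _preprocess_batch(run: SyntheticRun, config: SessionConfig) -> np.ndarray:
    """Offline feature preparation: smooth, mask, batch detrend."""
    smoothed = smooth_run(run.data, config.fwhm_mm, config.voxel_mm)
    X = apply_mask(smoothed, config.resolve_mask(run))
    return batch_detrend(X, axis=1)


def train_models_on_run(
    run: SyntheticRun,
    config: SessionConfig,
    contrasts: Sequence[str] = ALL_CONTRASTS,
) -> dict[str, LinearModel]:
    """Train the requested contrasts on one run's (batch-preprocessed) data.

    Labels come from the run's schedule (supervised retraining with the
    known block structure), optionally lag-shifted; the first
    ``train_discard_volumes`` volumes can be dropped.
    """
    X = _preprocess_batch(run, config)
    labels = run.schedule.with_shift(config.label_shift_volumes).labels()
    d = config.train_discard_volumes
    if d:
        X, labels = X[:, d:], labels[d:]
    return {
        name: train_contrast(X, labels, CONTRASTS[name], c=config.svm_c)
        for name in contrasts
    }


def run_realtime(
    run: SyntheticRun,
    models: dict[str, LinearModel],
    config: SessionConfig | None = None,
) -> RunResult:
    """Simulate the real-time loop over one run.

    Every volume (rest blocks included) is smoothed, masked, streamed
    through the incremental detrend and classified by both rest-vs-task
    models; rest-block volumes are logged but drive no feedback.  During
    task blocks the model matching the cue decides whether the cued arm
    rises.
    """
    config = config or SessionConfig()
    mask = config.resolve_mask(run)
    n_mask = int(mask.sum())
    for name in REALTIME_CONTRASTS:
        if name not in models:
            raise ValueError(f"missing model for contrast {name}")
        if models[name].weights.shape[0] != n_mask:
            raise ValueError(
                f"model {name} has {models[name].weights.shape[0]} weights "
                f"but the mask selects {n_mask} voxels"
            )

    schedule = run.schedule
    cues = schedule.cue_labels()
    block_end = schedule.is_block_end()
    nv = run.n_volumes
    # lag-shifted labels mark which volumes are hemodynamically at rest:
    # the first volumes of a rest block still carry the previous task
    # block's decaying response and must not enter the drift fits
    shifted_labels = schedule.with_shift(config.label_shift_volumes).labels()

    # spatial smoothing is per-volume, so the 4D pass is identical to
    # smoothing each incoming volume on arrival
    smoothed = smooth_run(run.data, config.fwhm_mm, config.voxel_mm)
    masked = apply_mask(smoothed, mask)

    detrend = DetrendState(n_mask, window=config.detrend_window)
    out_detrend = {
        name: DecisionDetrender(
            config.detrend_window, warmup=config.detrend_warmup_volumes
        )
        for name in REALTIME_CONTRASTS
    }
    raw = {name: np.empty(nv) for name in REALTIME_CONTRASTS}
    corrected = {name: np.empty(nv) for name in REALTIME_CONTRASTS}

    fb = FeedbackState(
        increment_deg=config.increment_deg, left_arm_cue=config.left_arm_cue
    )
    angles = np.zeros(nv)

    for v in range(nv):
        cue = cues[v]
        is_rest = shifted_labels[v] is Condition.REST
        # drift fits are updated on rest volumes only: rest data is
        # task-signal-free, so the line tracks scanner/classifier drift
        # without absorbing the block structure
        if is_rest:
            features = detrend.update(masked[:, v], t=v + 1)
        else:
            features = detrend.evaluate(masked[:, v], t=v + 1)
        for name in REALTIME_CONTRASTS:
            m = models[name]
            d_raw = float(m.weights @ features + m.bias)
            raw[name][v] = d_raw
            if is_rest:
                corrected[name][v] = out_detrend[name].step(d_raw, t=v + 1)
            else:
                corrected[name][v] = out_detrend[name].correct(d_raw, t=v + 1)
        if cue in (Condition.LGO, Condition.RGO):
            active = "R_vs_LGO" if cue == Condition.LGO else "R_vs_RGO"
            predicted_task = corrected[active][v] > 0
            before = fb.angle_for(cue)
            feedback_step(fb, cue, predicted_task, bool(block_end[v]), volume=v)
            # angle after any raise, before the block-end reset: equals
            # increment x (correct classifications so far in this block)
            angles[v] = before + (config.increment_deg if predicted_task else 0.0)

    traces = {}
    for name in REALTIME_CONTRASTS:
        m = models[name]
        traces[name] = DecisionTrace(
            raw=raw[name],
            corrected=corrected[name],
            predicted=m.predict(corrected[name]),
            volume_indices=np.arange(nv),
        )
    labels = schedule.with_shift(config.label_shift_volumes).labels()
    return RunResult(
        run_index=run.run_index,
        traces=traces,
        feedback=fb,
        feedback_angles=angles,
        labels=labels,
        cues=cues,
    )


def _session(
    subject: Subject, config: SessionConfig | None, strategy: str
) -> SessionResult:
    config = config or SessionConfig()
    if len(subject.runs) != 4:
        raise ValueError(f"subject must have 4 runs, got {len(subject.runs)}")
    mask = config.resolve_mask(subject.runs[0])

    models: dict[str, list[LinearModel]] = {name: [] for name in ALL_CONTRASTS}
    gen0 = train_models_on_run(subject.runs[0], config)
    for name in ALL_CONTRASTS:
        models[name].append(gen0[name])

    run_results: dict[int, RunResult] = {}
    for r in (1, 2, 3):
        generation = r - 1 if strategy == "incremental" else 0
        current = {name: models[name][generation] for name in ALL_CONTRASTS}
        run_results[r] = run_realtime(subject.runs[r], current, config)
        if strategy == "incremental":
            gen = train_models_on_run(subject.runs[r], config)
            for name in ALL_CONTRASTS:
                models[name].append(gen[name])

    return SessionResult(
        strategy=strategy,
        subject_id=subject.subject_id,
        run_results=run_results,
        models=models,
        mask=mask,
    )


def incremental_session(
    subject: Subject, config: SessionConfig | None = None
) -> SessionResult:
    """Run the incremental strategy: run r classified by the model trained
    on run r-1 alone; after each feedback run all three contrasts are
    retrained on the newly acquired data only."""
    return _session(subject, config, "incremental")


def static_session(
    subject: Subject, config: SessionConfig | None = None
) -> SessionResult:
    """Run the static (validation) strategy: the run-0 models classify all
    feedback runs with no update."""
    return _session(subject, config, "static")
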