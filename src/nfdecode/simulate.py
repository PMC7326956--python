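"""Synthetic nonstationary motor-imagery fMRI cohorts.

The study's real data are private, so the pipeline is exercised on a
forward model that reproduces the statistical structure the analysis
assumes: block-design BOLD activation (boxcar convolved with the
canonical double-gamma HRF), linear scanner drift, AR(1) temporal noise,
and — crucially — a *learning-driven nonstationarity*: activation that is
widespread in early feedback runs and progressively more focal in later
ones.  That nonstationarity is what makes a classifier trained once on
run 0 degrade over feedback runs while an incrementally retrained one
keeps up.

Topography model
----------------
A subject's activation is a set of spherical regions on a small voxel
grid (default 24 x 24 x 12 at 3-mm isotropic voxels):

* two *relevant* hand-area regions, one LGO-selective and one
  RGO-selective, placed contralaterally (left-hand imagery activates the
  right hemisphere);
* one *relevant* SMA-like region responding to BOTH tasks;
* four *transient* regions, active early in training and fading as the
  subject learns.

Across feedback runs, ``learning_rate`` scales transient amplitudes down
by ``(1 - learning_rate)**run_index`` and multiplicatively shrinks
relevant-region radii toward a one-voxel floor while slightly raising
their amplitude — the widespread-to-focal trajectory.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import signal as _signal
from scipy.stats import gamma as _gamma

from .protocol import BlockSchedule, Condition, build_schedule

__all__ = [
    "Region",
    "ActivationTopography",
    "SubjectConfig",
    "SyntheticRun",
    "Subject",
    "canonical_hrf",
    "condition_regressor",
    "default_topography",
    "recovery_topography",
    "topography_for_run",
    "simulate_run",
    "simulate_subject",
    "simulate_cohort",
    "run_to_nifti",
    "mask_to_nifti",
    "write_cohort_manifest",
]

#: amplitude (% of baseline) below which a region no longer counts as
#: active when building ground-truth masks
TRUTH_AMPLITUDE_FLOOR = 0.1


@dataclass(frozen=True)
class Region:
    """One spherical activation region.

    amplitude is the task-evoked signal change in percent of baseline.
    ``selectivity`` is LGO, RGO or BOTH; ``relevance`` is ``"relevant"``
    (stable task representation) or ``"transient"`` (early-training
    activity that decays with learning).
    """

    center: tuple[int, int, int]
    radius: float
    amplitude: float
    selectivity: str  # "LGO" | "RGO" | "BOTH"
    relevance: str = "relevant"  # "relevant" | "transient"

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("region amplitude must be >= 0")
        if self.radius < 1:
            raise ValueError("region radius must be >= 1 voxel")
        if self.selectivity not in ("LGO", "RGO", "BOTH"):
            raise ValueError(f"bad selectivity {self.selectivity!r}")
        if self.relevance not in ("relevant", "transient"):
            raise ValueError(f"bad relevance {self.relevance!r}")

    def mask(self, grid_dims: tuple[int, int, int]) -> np.ndarray:
        """Boolean sphere on the grid (voxels within ``radius`` of center)."""
        zz, yy, xx = np.ogrid[: grid_dims[0], : grid_dims[1], : grid_dims[2]]
        cx, cy, cz = self.center
        d2 = (zz - cx) ** 2 + (yy - cy) ** 2 + (xx - cz) ** 2
        return d2 <= self.radius**2

    def responds_to(self, condition: Condition) -> bool:
        return self.selectivity in ("BOTH", condition.value)


@dataclass(frozen=True)
class ActivationTopography:
    regions: tuple[Region, ...]

    def validate(self, grid_dims: tuple[int, int, int]) -> None:
        for r in self.regions:
            for c, n in zip(r.center, grid_dims):
                if c - r.radius < 0 or c + r.radius > n - 1:
                    raise ValueError(
                        f"region at {r.center} (radius {r.radius}) exceeds "
                        f"grid {grid_dims}"
                    )

    def truth_mask(
        self, condition: Condition, grid_dims: tuple[int, int, int]
    ) -> np.ndarray:
        """Voxels carrying task signal for ``condition`` in this topography."""
        mask = np.zeros(grid_dims, dtype=bool)
        for r in self.regions:
            if r.amplitude >= TRUTH_AMPLITUDE_FLOOR and r.responds_to(condition):
                mask |= r.mask(grid_dims)
        return mask


@dataclass(frozen=True)
class SubjectConfig:
    """Per-subject generator settings.

    noise_sd is the stationary standard deviation of the AR(1) noise in
    raw signal units; default amplitudes of 2% of a baseline of 100 give
    contrast-to-noise ~1 at region cores before smoothing.  drift_slope
    defaults to 0.02 * noise_sd per volume, a regime where detrending
    matters over a 255-volume run.
    """

    seed: int = 0
    grid_dims: tuple[int, int, int] = (24, 24, 12)
    baseline: float = 100.0
    noise_sd: float = 2.0
    ar1: float = 0.3
    drift_slope: float = 0.04
    learning_rate: float = 0.4

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if not 0 <= self.ar1 < 1:
            raise ValueError("ar1 must be in [0, 1)")
        if not 0 <= self.learning_rate <= 1:
            raise ValueError("learning_rate must be in [0, 1]")


@dataclass(frozen=True)
class SyntheticRun:
    """One simulated run: voxels-over-time data plus ground truth."""

    run_index: int
    data: np.ndarray  # 4D grid (x, y, z, volumes), float32
    schedule: BlockSchedule
    truth_masks: dict[Condition, np.ndarray]
    topography: ActivationTopography

    @property
    def grid_dims(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]


@dataclass(frozen=True)
class Subject:
    subject_id: int
    config: SubjectConfig
    runs: tuple[SyntheticRun, ...]


def canonical_hrf(tr_s: float, duration_s: float = 32.0) -> np.ndarray:
    """Canonical double-gamma hemodynamic impulse response.

    A response gamma (shape 6, scale 1; peak near 5-6 s) minus an
    undershoot gamma (shape 16; peak near 15-16 s) at 1:6 amplitude
    ratio, sampled every ``tr_s`` seconds over ``duration_s`` and scaled
    to unit peak.  Zero at t=0.
    """
    if tr_s <= 0:
        raise ValueError("tr_s must be > 0")
    if duration_s < 30:
        raise ValueError("duration_s must be >= 30 to cover the undershoot")
    t = np.arange(0.0, duration_s + tr_s / 2, tr_s)
    h = _gamma.pdf(t, a=6.0) - _gamma.pdf(t, a=16.0) / 6.0
    return h / h.max()


def condition_regressor(
    schedule: BlockSchedule, condition: Condition, tr_s: float | None = None
) -> np.ndarray:
    """Boxcar-convolved-with-HRF regressor for one condition, unit peak boxcar."""
    tr = schedule.tr_s if tr_s is None else tr_s
    boxcar = (schedule.cue_labels() == condition).astype(float)
    hrf = canonical_hrf(tr)
    return np.convolve(boxcar, hrf)[: schedule.n_volumes]


def default_topography() -> ActivationTopography:
    """Widespread (pre-learning) topography on the default 24x24x12 grid.

    Two contralateral hand-area regions, one SMA-like bilateral region,
    and four transient regions that fade with feedback training.
    """
    return ActivationTopography(
        regions=(
            # right-hemisphere hand area <- left-hand imagery
            Region((17, 12, 7), radius=3.0, amplitude=2.0, selectivity="LGO"),
            # left-hemisphere hand area <- right-hand imagery
            Region((7, 12, 7), radius=3.0, amplitude=2.0, selectivity="RGO"),
            # SMA-like midline region, task-general
            Region((12, 17, 8), radius=2.0, amplitude=1.5, selectivity="BOTH"),
            # transient early-training activity (prefrontal / parietal-like)
            Region((5, 6, 6), 3.0, 1.5, "BOTH", "transient"),
            Region((19, 6, 6), 3.0, 1.5, "BOTH", "transient"),
            Region((5, 18, 6), 2.0, 1.5, "LGO", "transient"),
            Region((19, 18, 6), 2.0, 1.5, "RGO", "transient"),
        )
    )


def recovery_topography() -> ActivationTopography:
    """Relevant-regions-only topography for parameter-recovery studies.

    No transient regions: every active voxel belongs to a stable,
    task-selective region, so recovered weight maps and GLM peaks can be
    scored directly against the ground truth.
    """
    return ActivationTopography(
        regions=tuple(
            r for r in default_topography().regions if r.relevance == "relevant"
        )
    )


def topography_for_run(
    base: ActivationTopography, run_index: int, learning_rate: float
) -> ActivationTopography:
    """Learning-adjusted topography for one run.

    Run 0 returns ``base`` unchanged.  For later runs, transient-region
    amplitudes decay by ``(1 - learning_rate)**run_index`` and
    relevant-region radii shrink multiplicatively (floor 1 voxel) while
    their amplitude rises slightly — focalisation with learning.
    """
    if run_index not in (0, 1, 2, 3):
        raise ValueError("run_index must be in 0..3")
    if run_index == 0 or learning_rate == 0:
        return base
    out = []
    for r in base.regions:
        if r.relevance == "transient":
            out.append(
                replace(r, amplitude=r.amplitude * (1 - learning_rate) ** run_index)
            )
        else:
            radius = max(1.0, r.radius * (1 - learning_rate / 2) ** run_index)
            amp = r.amplitude * (1 + 0.15 * learning_rate * run_index)
            out.append(replace(r, radius=radius, amplitude=amp))
    return ActivationTopography(regions=tuple(out))


def _ar1_noise(
    rng: np.random.Generator, shape: tuple[int, ...], sd: float, ar1: float
) -> np.ndarray:
    """Stationary AR(1) noise along the last axis with marginal sd ``sd``."""
    z = rng.standard_normal(shape)
    if ar1 == 0:
        return sd * z
    innov = sd * np.sqrt(1 - ar1**2) * z
    # stationary start: first sample at full marginal sd
    innov[..., 0] = sd * z[..., 0]
    return _signal.lfilter([1.0], [1.0, -ar1], innov, axis=-1)


def simulate_run(
    schedule: BlockSchedule,
    topography: ActivationTopography,
    config: SubjectConfig,
    run_index: int,
) -> SyntheticRun:
    """Generate one run: baseline + task activation + drift + AR(1) noise.

    Fully determined by ``(config.seed, run_index)``.  Task signal per
    region is amplitude (% of baseline) times the binary sphere profile
    times the condition's boxcar (x) HRF regressor.
    """
    topo = topography_for_run(topography, run_index, config.learning_rate)
    topo.validate(config.grid_dims)
    nv = schedule.n_volumes
    dims = config.grid_dims

    regressors = {
        c: condition_regressor(schedule, c) for c in (Condition.LGO, Condition.RGO)
    }
    expected = np.zeros(dims + (nv,), dtype=np.float64)
    for region in topo.regions:
        if region.amplitude < TRUTH_AMPLITUDE_FLOOR:
            continue
        course = np.zeros(nv)
        for c in (Condition.LGO, Condition.RGO):
            if region.responds_to(c):
                course = course + regressors[c]
        amp = region.amplitude / 100.0 * config.baseline
        expected[region.mask(dims)] += amp * course

    t = np.arange(nv, dtype=np.float64)
    expected += config.baseline + config.drift_slope * t

    rng = np.random.default_rng([config.seed, run_index, 0x5EED])
    noise = _ar1_noise(rng, dims + (nv,), config.noise_sd, config.ar1)

    data = (expected + noise).astype(np.float32)
    truth = {
        c: topo.truth_mask(c, dims) for c in (Condition.LGO, Condition.RGO)
    }
    return SyntheticRun(
        run_index=run_index,
        data=data,
        schedule=schedule,
        truth_masks=truth,
        topography=topo,
    )


def _jittered_config(
    template: SubjectConfig, subject_seed: int
) -> tuple[SubjectConfig, float]:
    """Deterministic per-subject variation of amplitude scale and learning rate."""
    rng = np.random.default_rng([subject_seed, 0xA11])
    amp_scale = rng.uniform(0.85, 1.15)
    lr = float(np.clip(template.learning_rate * rng.uniform(0.8, 1.2), 0.0, 1.0))
    return replace(template, seed=subject_seed, learning_rate=lr), amp_scale


def simulate_subject(
    subject_id: int,
    seed: int,
    template: SubjectConfig | None = None,
    topography: ActivationTopography | None = None,
    schedule: BlockSchedule | None = None,
    jitter: bool = True,
) -> Subject:
    """Simulate one subject's four runs (run 0 pre-feedback, runs 1-3 feedback)."""
    template = template or SubjectConfig()
    topo = topography or default_topography()
    schedule = schedule or build_schedule(9, 4, 4)
    if jitter:
        config, amp_scale = _jittered_config(template, seed)
        topo = ActivationTopography(
            regions=tuple(
                replace(r, amplitude=r.amplitude * amp_scale) for r in topo.regions
            )
        )
    else:
        config = replace(template, seed=seed)
    runs = tuple(
        simulate_run(schedule, topo, config, run_index) for run_index in range(4)
    )
    return Subject(subject_id=subject_id, config=config, runs=runs)


def simulate_cohort(
    n_subjects: int = 30,
    base_seed: int = 0,
    template: SubjectConfig | None = None,
    topography: ActivationTopography | None = None,
    schedule: BlockSchedule | None = None,
    jitter: bool = True,
) -> list[Subject]:
    """Simulate a cohort; subject ``s`` uses seed ``base_seed + s``.

    For large cohorts prefer looping over :func:`simulate_subject` so
    only one subject's runs are held in memory at a time.
    """
    if n_subjects < 2:
        raise ValueError("n_subjects must be >= 2")
    return [
        simulate_subject(s, base_seed + s, template, topography, schedule, jitter)
        for s in range(n_subjects)
    ]


# -- export -----------------------------------------------------------------


def _affine(voxel_mm: float = 3.0) -> np.ndarray:
    return np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])


def run_to_nifti(run: SyntheticRun, path: str | Path, voxel_mm: float = 3.0) -> None:
    """Write one run's 4D data as NIfTI (3-mm isotropic voxels by default)."""
    import nibabel as nib

    nib.save(nib.Nifti1Image(run.data, _affine(voxel_mm)), str(path))


def mask_to_nifti(mask: np.ndarray, path: str | Path, voxel_mm: float = 3.0) -> None:
    import nibabel as nib

    nib.save(nib.Nifti1Image(mask.astype(np.uint8), _affine(voxel_mm)), str(path))


def write_cohort_manifest(subjects: Sequence[Subject], path: str | Path) -> None:
    """JSON manifest of a cohort: per-subject seeds and generator settings."""
    manifest = {
        "n_subjects": len(subjects),
        "subjects": [
            {
                "subject_id": s.subject_id,
                "seed": s.config.seed,
                "learning_rate": s.config.learning_rate,
                "grid_dims": list(s.config.grid_dims),
                "n_runs": len(s.runs),
            }
            for s in subjects
        ],
    }
    Path(path).write_text(json.dumps(manifest, indent=2) + "\n")
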