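"""Classification metrics, group statistics, and GLM activation maps.

Performance of the rest-vs-task models is summarised by the task
predictive value (TPV): the percentage of task-labelled volumes
correctly classified as task, with rest volumes excluded from both
numerator and denominator.  The LGO-vs-RGO model uses plain accuracy
over task volumes.  Run effects are tested with a one-way
repeated-measures ANOVA (sphericity assumed) and post-hoc paired
t-tests, the same tests the study applies to its cohort tables.

Activation mapping follows the standard mass-univariate GLM: per voxel,
OLS on a design of one boxcar (x) HRF regressor per task, an intercept
and a linear drift term, with t-maps for each task and the LGO > RGO
contrast.  Group maps are voxelwise one-sample t-tests across subjects,
thresholded at p < 0.001 with an optional cluster-extent filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .decode import CONTRASTS, LinearModel, weight_map
from .preprocess import apply_mask, smooth_run
from .protocol import BlockSchedule, Condition
from .session import ALL_CONTRASTS, REALTIME_CONTRASTS, SessionConfig, SessionResult
from .simulate import SyntheticRun, condition_regressor

__all__ = [
    "StatResult",
    "TMap",
    "tpv",
    "pairwise_accuracy",
    "rm_anova",
    "paired_t",
    "glm_activation",
    "group_t_map",
    "suprathreshold",
    "dice",
    "session_metrics",
    "offline_session_metrics",
    "cohort_report",
]


@dataclass(frozen=True)
class StatResult:
    """A test statistic with its degrees of freedom and p-value."""

    statistic: float
    df: tuple[float, ...] | float
    p: float
    degenerate: bool = False


@dataclass
class TMap:
    """Voxelwise t statistics; ``valid`` flags voxels with defined variance."""

    t: np.ndarray
    df: int
    contrast: str
    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.valid is None:
            self.valid = np.isfinite(self.t)


# -- classification metrics -------------------------------------------------


def tpv(
    predictions: np.ndarray, labels: np.ndarray, task_condition: Condition
) -> float:
    """Task predictive value in percent.

    100 x (# task volumes predicted as the task) / (# task volumes),
    where "task volumes" are those labelled ``task_condition``.  Rest
    volumes do not enter the computation.
    """
    predictions = np.asarray(predictions, dtype=object)
    labels = np.asarray(labels, dtype=object)
    if predictions.shape != labels.shape:
        raise ValueError("predictions and labels must be aligned")
    task = labels == task_condition
    n_task = int(task.sum())
    if n_task == 0:
        raise ValueError(f"no volumes labelled {task_condition}")
    return 100.0 * float(np.sum(predictions[task] == task_condition)) / n_task


def pairwise_accuracy(predictions: np.ndarray, labels: np.ndarray) -> float:
    """Percent of LGO/RGO volumes classified correctly; rest volumes ignored."""
    predictions = np.asarray(predictions, dtype=object)
    labels = np.asarray(labels, dtype=object)
    if predictions.shape != labels.shape:
        raise ValueError("predictions and labels must be aligned")
    task = (labels == Condition.LGO) | (labels == Condition.RGO)
    n_task = int(task.sum())
    if n_task == 0:
        raise ValueError("no LGO/RGO volumes")
    return 100.0 * float(np.sum(predictions[task] == labels[task])) / n_task


# -- group statistics -------------------------------------------------------


def rm_anova(values: np.ndarray) -> StatResult:
    """One-way repeated-measures ANOVA on a subjects x conditions table.

    F = MS_condition / MS_error with df = (k-1, (k-1)(n-1)); sphericity
    is assumed (no correction), matching the F_{2,58} form reported for
    30 subjects across 3 feedback runs.
    """
    values = np.asarray(values, dtype=np.float64)
    if values.ndim != 2:
        raise ValueError("values must be a 2D subjects x conditions table")
    if not np.all(np.isfinite(values)):
        raise ValueError("missing cells in the repeated-measures table")
    n, k = values.shape
    if n < 2 or k < 2:
        raise ValueError("need >= 2 subjects and >= 2 conditions")
    grand = values.mean()
    ss_cond = n * np.sum((values.mean(axis=0) - grand) ** 2)
    ss_subj = k * np.sum((values.mean(axis=1) - grand) ** 2)
    ss_total = np.sum((values - grand) ** 2)
    ss_err = ss_total - ss_cond - ss_subj
    df_cond = k - 1
    df_err = (k - 1) * (n - 1)
    ms_err = ss_err / df_err
    if ms_err <= 0:
        f = 0.0 if ss_cond <= 1e-24 else np.inf
        return StatResult(f, (df_cond, df_err), 0.0 if np.isinf(f) else 1.0, True)
    f = (ss_cond / df_cond) / ms_err
    p = float(stats.f.sf(f, df_cond, df_err))
    return StatResult(float(f), (df_cond, df_err), p)


def paired_t(a: np.ndarray, b: np.ndarray) -> StatResult:
    """Two-sided paired-sample t-test; zero-variance differences flag degenerate."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("paired_t needs two equal-length 1D arrays, n >= 2")
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0):
        return StatResult(0.0 if np.allclose(d, 0) else np.inf, a.size - 1, np.nan, True)
    res = stats.ttest_rel(a, b)
    return StatResult(float(res.statistic), a.size - 1, float(res.pvalue))


# -- GLM activation mapping -------------------------------------------------


def glm_activation(
    run: SyntheticRun,
    config: SessionConfig | None = None,
    discard_volumes: int = 5,
) -> dict[str, TMap]:
    """Mass-univariate GLM t-maps for one run.

    Design: one boxcar (x) HRF regressor per task condition, an
    intercept, and a linear drift term.  Returns t-maps for "LGO",
    "RGO" (each regressor against 0) and the "LGO_gt_RGO" contrast.
    The first ``discard_volumes`` volumes are dropped, mirroring the
    offline analysis path.
    """
    config = config or SessionConfig()
    schedule = run.schedule
    nv = run.n_volumes
    x_lgo = condition_regressor(schedule, Condition.LGO)
    x_rgo = condition_regressor(schedule, Condition.RGO)
    drift = np.arange(nv, dtype=np.float64)
    X = np.column_stack([x_lgo, x_rgo, np.ones(nv), drift])

    d = discard_volumes
    X = X[d:]
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient GLM design matrix")

    smoothed = smooth_run(run.data, config.fwhm_mm, config.voxel_mm)
    Y = smoothed.reshape(-1, nv)[:, d:].T  # time x voxels

    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ X.T @ Y
    resid = Y - X @ beta
    df = X.shape[0] - X.shape[1]
    sigma2 = np.sum(resid**2, axis=0) / df

    dims = run.grid_dims
    out: dict[str, TMap] = {}
    for name, cvec in (
        ("LGO", np.array([1.0, 0.0, 0.0, 0.0])),
        ("RGO", np.array([0.0, 1.0, 0.0, 0.0])),
        ("LGO_gt_RGO", np.array([1.0, -1.0, 0.0, 0.0])),
    ):
        var = sigma2 * float(cvec @ XtX_inv @ cvec)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = (cvec @ beta) / np.sqrt(var)
        out[name] = TMap(t=t.reshape(dims), df=df, contrast=name)
    return out


def group_t_map(subject_maps: Sequence[np.ndarray], contrast: str = "") -> TMap:
    """Voxelwise one-sample t-test of subject maps against 0 (df = n-1).

    Voxels with zero across-subject variance are flagged invalid (their
    t is +/- inf when the mean is nonzero).
    """
    maps = np.asarray(subject_maps, dtype=np.float64)
    if maps.ndim < 2 or maps.shape[0] < 2:
        raise ValueError("need >= 2 subject maps on a common grid")
    n = maps.shape[0]
    mean = maps.mean(axis=0)
    sd = maps.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
        t = np.where(sd == 0, np.where(mean == 0, 0.0, np.sign(mean) * np.inf), t)
    return TMap(t=t, df=n - 1, contrast=contrast, valid=sd > 0)


def suprathreshold(
    tmap: TMap,
    p: float = 0.001,
    two_sided: bool = True,
    cluster_extent: int = 0,
) -> np.ndarray:
    """Boolean map of voxels exceeding the voxelwise threshold.

    ``p`` is the voxelwise significance level (two-sided by default);
    ``cluster_extent`` optionally removes connected components smaller
    than the given voxel count — a simple stand-in for cluster-level
    correction.
    """
    crit = stats.t.isf(p / 2 if two_sided else p, tmap.df)
    above = (np.abs(tmap.t) if two_sided else tmap.t) > crit
    above &= tmap.valid | np.isinf(tmap.t)
    if cluster_extent > 1:
        lab, n_lab = ndimage.label(above)
        keep = np.zeros_like(above)
        for i in range(1, n_lab + 1):
            comp = lab == i
            if comp.sum() >= cluster_extent:
                keep |= comp
        above = keep
    return above


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|) between two boolean masks."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 0.0
    return 2.0 * float(np.logical_and(a, b).sum()) / float(denom)


# -- cohort tables ----------------------------------------------------------

_METRIC_FOR_CONTRAST = {
    "R_vs_LGO": "TPV",
    "R_vs_RGO": "TPV",
    "LGO_vs_RGO": "accuracy",
}


def _metric(contrast_name: str, predictions: np.ndarray, labels: np.ndarray) -> float:
    if contrast_name == "LGO_vs_RGO":
        return pairwise_accuracy(predictions, labels)
    task = CONTRASTS[contrast_name].positive
    return tpv(predictions, labels, task)


def session_metrics(result: SessionResult) -> pd.DataFrame:
    """Real-time per-run metrics of one session (TPV per rest-vs-task model)."""
    rows = []
    for r, rr in sorted(result.run_results.items()):
        for name in REALTIME_CONTRASTS:
            rows.append(
                {
                    "subject": result.subject_id,
                    "strategy": result.strategy,
                    "run": r,
                    "contrast": name,
                    "metric": "TPV",
                    "path": "realtime",
                    "value": _metric(name, rr.traces[name].predicted, rr.labels),
                }
            )
    return pd.DataFrame(rows)


def offline_session_metrics(
    result: SessionResult,
    subject_runs: Sequence[SyntheticRun],
    config: SessionConfig | None = None,
    discard_volumes: int = 5,
) -> pd.DataFrame:
    """Offline re-analysis of a session: batch preprocessing, all 3 contrasts.

    Applies the model generation the strategy dictates for each run
    (incremental: trained on run r-1; static: run 0) to batch-detrended
    features, discarding the first ``discard_volumes`` volumes as the
    offline path does.
    """
    from .session import _preprocess_batch  # offline feature path

    config = config or SessionConfig()
    rows = []
    for r in sorted(result.run_results):
        X = _preprocess_batch(subject_runs[r], config)
        labels = (
            subject_runs[r]
            .schedule.with_shift(config.label_shift_volumes)
            .labels()[discard_volumes:]
        )
        X = X[:, discard_volumes:]
        generation = r - 1 if result.strategy == "incremental" else 0
        for name in ALL_CONTRASTS:
            model = result.models[name][generation]
            predicted = model.predict(model.decision_values(X))
            rows.append(
                {
                    "subject": result.subject_id,
                    "strategy": result.strategy,
                    "run": r,
                    "contrast": name,
                    "metric": _METRIC_FOR_CONTRAST[name],
                    "path": "offline",
                    "value": _metric(name, predicted, labels),
                }
            )
    return pd.DataFrame(rows)


def cohort_report(
    metrics: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, dict]]:
    """Summarise a cohort metrics table and run the study's tests.

    Parameters
    ----------
    metrics:
        Long-format table with columns subject/strategy/run/contrast/
        metric/path/value (concatenated :func:`session_metrics` /
        :func:`offline_session_metrics` output).

    Returns
    -------
    table:
        The input table, one row per (subject, run, contrast, strategy,
        path).
    summary:
        Mean (sd) per strategy/path/contrast/run — the study's Table-1
        shape.
    tests:
        Per (strategy, path, contrast): the repeated-measures ANOVA over
        runs 1-3 and post-hoc paired t-tests between run pairs.
    """
    required = {"subject", "strategy", "run", "contrast", "metric", "path", "value"}
    if not required.issubset(metrics.columns):
        raise ValueError(f"metrics table must have columns {sorted(required)}")

    summary = (
        metrics.groupby(["strategy", "path", "contrast", "run"])["value"]
        .agg(["mean", "std", "count"])
        .reset_index()
    )

    tests: dict[str, dict] = {}
    for (strategy, path, contrast), g in metrics.groupby(
        ["strategy", "path", "contrast"]
    ):
        wide = g.pivot(index="subject", columns="run", values="value").sort_index()
        runs = sorted(wide.columns)
        entry: dict = {}
        if len(runs) >= 2 and wide.notna().all().all() and len(wide) >= 2:
            entry["anova"] = rm_anova(wide[runs].to_numpy())
            entry["posthoc"] = {
                f"run{a}_vs_run{b}": paired_t(
                    wide[a].to_numpy(), wide[b].to_numpy()
                )
                for i, a in enumerate(runs)
                for b in runs[i + 1 :]
            }
        else:
            entry["anova"] = None
            entry["posthoc"] = {}
        tests[f"{strategy}/{path}/{contrast}"] = entry

    return metrics, summary, tests


def weight_maps_for_cohort(
    results: Sequence[SessionResult], contrast: str, generation: int = -1
) -> np.ndarray:
    """Stack one weight map per subject for a contrast and model generation."""
    maps = []
    for res in results:
        models = res.models[contrast]
        maps.append(weight_map(models[generation], res.mask))
    return np.asarray(maps)
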