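"""Metrics, repeated-measures statistics, GLM and group t-maps."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats as sps

from nfdecode import (
    ActivationTopography,
    Condition,
    SessionConfig,
    SubjectConfig,
    build_schedule,
    dice,
    glm_activation,
    group_t_map,
    paired_t,
    pairwise_accuracy,
    rm_anova,
    simulate_run,
    suprathreshold,
    tpv,
)
from nfdecode.evaluate import cohort_report

LGO, RGO, REST = Condition.LGO, Condition.RGO, Condition.REST
CONDS = np.array([REST, LGO, RGO], dtype=object)


def counting_oracle_tpv(pred, lab, task):
    num = den = 0
    for p, l in zip(pred, lab):
        if l == task:
            den += 1
            if p == task:
                num += 1
    return 100.0 * num / den


class TestTpv:
    def test_45_of_60(self):
        lab = np.array([LGO] * 60 + [REST] * 10, dtype=object)
        pred = np.array([LGO] * 45 + [REST] * 25, dtype=object)
        assert tpv(pred, lab, LGO) == 75.0

    def test_all_correct(self):
        lab = np.array([LGO] * 5, dtype=object)
        assert tpv(lab, lab, LGO) == 100.0

    def test_rest_volumes_do_not_count(self):
        lab = np.array([REST, REST, LGO], dtype=object)
        pred = np.array([LGO, LGO, LGO], dtype=object)  # false alarms on rest
        assert tpv(pred, lab, LGO) == 100.0

    @given(st.integers(0, 200))
    def test_matches_counting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        lab = CONDS[rng.integers(0, 3, 50)]
        pred = CONDS[rng.integers(0, 3, 50)]
        if not (lab == LGO).any():
            lab[0] = LGO
        assert tpv(pred, lab, LGO) == counting_oracle_tpv(pred, lab, LGO)

    def test_no_task_volumes_rejected(self):
        lab = np.array([REST, REST], dtype=object)
        with pytest.raises(ValueError):
            tpv(lab, lab, LGO)


class TestPairwiseAccuracy:
    def test_perfect(self):
        lab = np.array([LGO, RGO, LGO], dtype=object)
        assert pairwise_accuracy(lab, lab) == 100.0

    def test_constant_prediction_on_balanced_labels(self):
        lab = np.array([LGO, RGO] * 10, dtype=object)
        pred = np.array([LGO] * 20, dtype=object)
        assert pairwise_accuracy(pred, lab) == 50.0

    @given(st.integers(0, 100))
    def test_matches_counting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        lab = CONDS[rng.integers(0, 3, 60)]
        pred = CONDS[rng.integers(0, 3, 60)]
        lab[:2] = [LGO, RGO]
        task = (lab == LGO) | (lab == RGO)
        want = 100.0 * sum(
            p == l for p, l in zip(pred[task], lab[task])
        ) / task.sum()
        assert pairwise_accuracy(pred, lab) == pytest.approx(want)


def anova_ss_oracle(values):
    """From-scratch sums-of-squares decomposition with explicit loops."""
    n, k = values.shape
    grand = values.mean()
    ss_cond = sum(n * (values[:, j].mean() - grand) ** 2 for j in range(k))
    ss_subj = sum(k * (values[i].mean() - grand) ** 2 for i in range(n))
    ss_tot = sum(
        (values[i, j] - grand) ** 2 for i in range(n) for j in range(k)
    )
    ss_err = ss_tot - ss_cond - ss_subj
    return (ss_cond / (k - 1)) / (ss_err / ((k - 1) * (n - 1)))


class TestRmAnova:
    def test_df_shape_for_30_by_3(self):
        rng = np.random.default_rng(0)
        res = rm_anova(rng.standard_normal((30, 3)))
        assert res.df == (2, 58)

    def test_identical_columns_give_zero_f(self):
        col = np.arange(6.0)
        res = rm_anova(np.column_stack([col, col, col]))
        assert res.statistic == pytest.approx(0.0, abs=1e-12)

    def test_matches_ss_decomposition_oracle(self):
        rng = np.random.default_rng(1)
        values = rng.standard_normal((4, 3)) + np.array([0.0, 0.5, 1.0])
        res = rm_anova(values)
        assert res.statistic == pytest.approx(anova_ss_oracle(values), rel=1e-10)

    def test_matches_statsmodels_anova_rm(self):
        from statsmodels.stats.anova import AnovaRM

        rng = np.random.default_rng(2)
        values = rng.standard_normal((8, 3)) + np.array([0.0, 0.3, 0.9])
        long = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(8), 3),
                "cond": np.tile(np.arange(3), 8),
                "y": values.ravel(),
            }
        )
        sm_res = AnovaRM(long, "y", "subject", within=["cond"]).fit()
        f_sm = float(sm_res.anova_table["F Value"].iloc[0])
        p_sm = float(sm_res.anova_table["Pr > F"].iloc[0])
        res = rm_anova(values)
        assert res.statistic == pytest.approx(f_sm, rel=1e-8)
        assert res.p == pytest.approx(p_sm, rel=1e-8)

    def test_f_equals_t_squared_for_two_conditions(self):
        rng = np.random.default_rng(3)
        a, b = rng.standard_normal((2, 12))
        f = rm_anova(np.column_stack([a, b])).statistic
        t = paired_t(a, b).statistic
        assert f == pytest.approx(t**2, abs=1e-9)

    def test_missing_cells_rejected(self):
        bad = np.ones((4, 3))
        bad[0, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            rm_anova(bad)


class TestPairedT:
    def test_hand_computed_example(self):
        b = np.zeros(3)
        a = np.array([1.0, 2.0, 3.0])
        res = paired_t(a, b)
        assert res.statistic == pytest.approx(2.0 / (1.0 / np.sqrt(3)), rel=1e-9)
        assert res.df == 2

    def test_sign_flip_negates_t(self):
        rng = np.random.default_rng(4)
        a, b = rng.standard_normal((2, 10))
        assert paired_t(a, b).statistic == pytest.approx(
            -paired_t(b, a).statistic, rel=1e-12
        )

    def test_identical_inputs_degenerate(self):
        a = np.arange(5.0)
        res = paired_t(a, a.copy())
        assert res.degenerate


@pytest.fixture(scope="module")
def noise_schedule():
    return build_schedule(3, 1, 1, block_s=20.0, tr_s=2.0)


def _noise_run(seed, schedule):
    cfg = SubjectConfig(
        seed=seed, grid_dims=(12, 12, 8), noise_sd=1.0, ar1=0.0, drift_slope=0.0
    )
    return simulate_run(schedule, ActivationTopography(()), cfg, 0)


class TestGlm:
    def test_null_false_positive_rate_near_nominal(self, noise_schedule):
        """Monte-Carlo over seeded white-noise runs: two-sided 0.05 rate."""
        unsmoothed = SessionConfig(fwhm_mm=1e-6)
        rates = []
        for seed in (0, 1, 2):
            run = _noise_run(seed, noise_schedule)
            tmaps = glm_activation(run, unsmoothed, discard_volumes=0)
            crit = sps.t.isf(0.025, tmaps["LGO"].df)
            rates.append(np.mean(np.abs(tmaps["LGO"].t) > crit))
        assert 0.03 < np.mean(rates) < 0.07

    def test_null_t_distribution_ks(self, noise_schedule):
        unsmoothed = SessionConfig(fwhm_mm=1e-6)
        run = _noise_run(5, noise_schedule)
        tmaps = glm_activation(run, unsmoothed, discard_volumes=0)
        t = tmaps["RGO"]
        ks = sps.kstest(t.t.ravel(), sps.t(df=t.df).cdf)
        assert ks.pvalue > 0.01

    def test_high_snr_peak_inside_truth_mask(self, small_run):
        tmaps = glm_activation(small_run)
        for cond in (LGO, RGO):
            t = tmaps[cond.value].t
            peak = np.unravel_index(np.argmax(t), t.shape)
            assert small_run.truth_masks[cond][peak]

    def test_contrast_cancels_on_shared_region(self, quiet_run):
        """A BOTH-selective region responds equally to LGO and RGO, so the
        LGO>RGO contrast is ~0 there while each task map is strongly positive."""
        tmaps = glm_activation(quiet_run)
        both_center = (8, 12, 5)
        assert tmaps["LGO"].t[both_center] > 10
        ratio = abs(tmaps["LGO_gt_RGO"].t[both_center]) / tmaps["LGO"].t[both_center]
        assert ratio < 0.1

    def test_matches_statsmodels_ols_single_voxel(self, small_run):
        import statsmodels.api as sm

        from nfdecode.preprocess import smooth_run
        from nfdecode.simulate import condition_regressor

        d = 5
        sched = small_run.schedule
        nv = small_run.n_volumes
        X = np.column_stack(
            [
                condition_regressor(sched, LGO),
                condition_regressor(sched, RGO),
                np.ones(nv),
                np.arange(nv, dtype=float),
            ]
        )[d:]
        y = smooth_run(small_run.data)[11, 8, 5][d:]
        fit = sm.OLS(y, X).fit()
        tmaps = glm_activation(small_run)
        assert tmaps["LGO"].t[11, 8, 5] == pytest.approx(fit.tvalues[0], rel=1e-8)
        assert tmaps["LGO"].df == int(fit.df_resid)

    def test_rank_deficient_design_rejected(self, small_config, small_topography):
        rest_only = build_schedule(1, 0, 0, block_s=30.0, tr_s=2.0)
        run = simulate_run(rest_only, ActivationTopography(()), small_config, 0)
        with pytest.raises(ValueError, match="rank"):
            glm_activation(run, discard_volumes=0)


class TestGroupTMap:
    def test_identical_nonzero_maps_flagged(self):
        maps = [np.ones((3, 3, 3))] * 4
        res = group_t_map(maps)
        assert np.all(np.isinf(res.t))
        assert not res.valid.any()

    def test_per_voxel_matches_scalar_t_test(self):
        rng = np.random.default_rng(6)
        maps = rng.standard_normal((7, 4, 4, 2)) + 0.4
        res = group_t_map(maps)
        v = (2, 1, 1)
        want = sps.ttest_1samp(maps[:, v[0], v[1], v[2]], 0.0)
        assert res.t[v] == pytest.approx(want.statistic, rel=1e-10)
        assert res.df == 6

    def test_too_few_maps_rejected(self):
        with pytest.raises(ValueError):
            group_t_map([np.zeros((2, 2, 2))])

    def test_suprathreshold_cluster_extent(self):
        t = np.zeros((8, 8, 8))
        t[0:3, 0:3, 0:3] = 50.0  # 27-voxel cluster
        t[7, 7, 7] = 50.0  # isolated voxel
        tm = group_t_map([t, t + 0.1, t - 0.1])
        above = suprathreshold(tm, p=0.001, cluster_extent=5)
        assert above[1, 1, 1] and not above[7, 7, 7]

    def test_dice(self):
        a = np.zeros((4, 4), bool)
        b = np.zeros((4, 4), bool)
        a[:2] = True
        b[1:3] = True
        assert dice(a, b) == pytest.approx(0.5)
        assert dice(a, a) == 1.0


class TestCohortReport:
    def _metrics(self, values):
        rows = []
        for subj in range(values.shape[0]):
            for j, run in enumerate((1, 2, 3)):
                rows.append(
                    {
                        "subject": subj,
                        "strategy": "static",
                        "run": run,
                        "contrast": "R_vs_LGO",
                        "metric": "TPV",
                        "path": "realtime",
                        "value": values[subj, j],
                    }
                )
        return pd.DataFrame(rows)

    def test_perfect_decoder_means_100_f_zero(self):
        metrics = self._metrics(np.full((6, 3), 100.0))
        _, summary, tests = cohort_report(metrics)
        assert (summary["mean"] == 100.0).all()
        res = tests["static/realtime/R_vs_LGO"]["anova"]
        assert res.statistic == pytest.approx(0.0, abs=1e-12)

    def test_row_count_bookkeeping(self):
        metrics = self._metrics(np.random.default_rng(0).uniform(50, 90, (5, 3)))
        table, summary, _ = cohort_report(metrics)
        assert len(table) == 5 * 3
        assert len(summary) == 3

    def test_declining_trend_detected(self):
        rng = np.random.default_rng(1)
        values = np.array([80.0, 70.0, 60.0]) + rng.normal(0, 3, (10, 3))
        _, _, tests = cohort_report(self._metrics(values))
        entry = tests["static/realtime/R_vs_LGO"]
        assert entry["anova"].p < 0.05
        assert entry["posthoc"]["run1_vs_run3"].statistic > 0

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError, match="columns"):
            cohort_report(pd.DataFrame({"value": [1.0]}))
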