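"""Linear SVM training, decision values, drift correction, weight maps."""

import numpy as np
import pytest

from nfdecode import (
    Condition,
    detrend_decisions,
    decision_value,
    train_contrast,
    train_linear_svm,
    weight_map,
)
from nfdecode.decode import CONTRASTS, LinearModel, load_model, save_model
from nfdecode.preprocess import apply_mask, batch_detrend, smooth_run

LGO, RGO, REST = Condition.LGO, Condition.RGO, Condition.REST


def hinge_objective(w, b, X, signs, c):
    """Independent evaluation of 0.5||w||^2 + c * sum hinge."""
    margins = signs * (w @ X + b)
    return 0.5 * float(w @ w) + c * float(np.maximum(0, 1 - margins).sum())


def two_point_problem():
    X = np.array([[1.0, -1.0], [0.0, 0.0]])  # features x samples
    y = np.array([LGO, REST], dtype=object)
    return X, y


class TestTrainLinearSvm:
    def test_two_point_analytic_optimum(self):
        # minimising 0.5 a^2 + 2 max(0, 1-a) over w=(a,0) gives a=1, b=0
        X, y = two_point_problem()
        m = train_linear_svm(X, y, LGO, REST, c=1.0)
        assert m.weights == pytest.approx([1.0, 0.0], abs=1e-4)
        assert m.bias == pytest.approx(0.0, abs=1e-4)
        signs = np.array([1.0, -1.0])
        assert hinge_objective(m.weights, m.bias, X, signs, 1.0) == pytest.approx(
            0.5, abs=1e-4
        )

    def test_four_point_analytic_optimum(self):
        X = np.array([[1.0, 2.0, -1.0, -2.0], [0.0, 0.0, 0.0, 0.0]])
        y = np.array([LGO, LGO, REST, REST], dtype=object)
        m = train_linear_svm(X, y, LGO, REST, c=1.0)
        assert m.weights == pytest.approx([1.0, 0.0], abs=1e-4)
        assert m.bias == pytest.approx(0.0, abs=1e-4)

    def test_label_swap_negates_weights_and_bias(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((5, 20))
        y = np.array([LGO] * 10 + [REST] * 10, dtype=object)
        m1 = train_linear_svm(X, y, LGO, REST)
        m2 = train_linear_svm(X, y, REST, LGO)
        assert m1.weights == pytest.approx(-m2.weights, abs=1e-5)
        assert m1.bias == pytest.approx(-m2.bias, abs=1e-5)

    def test_duplicated_samples_with_halved_c_equivalent(self):
        """Objective equivalence: duplicating every sample doubles the hinge
        sum, so halving c recovers the same optimum."""
        rng = np.random.default_rng(1)
        X = rng.standard_normal((4, 12))
        y = np.array([LGO] * 6 + [REST] * 6, dtype=object)
        m1 = train_linear_svm(X, y, LGO, REST, c=1.0)
        X2 = np.concatenate([X, X], axis=1)
        y2 = np.concatenate([y, y])
        m2 = train_linear_svm(X2, y2, LGO, REST, c=0.5)
        signs = np.where(y == LGO, 1.0, -1.0)
        o1 = hinge_objective(m1.weights, m1.bias, X, signs, 1.0)
        o2 = hinge_objective(m2.weights, m2.bias, X, signs, 1.0)
        assert o2 == pytest.approx(o1, rel=1e-4)

    def test_sample_order_invariance(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((6, 30))
        y = np.array([LGO] * 15 + [REST] * 15, dtype=object)
        perm = rng.permutation(30)
        m1 = train_linear_svm(X, y, LGO, REST)
        m2 = train_linear_svm(X[:, perm], y[perm], LGO, REST)
        assert m1.weights == pytest.approx(m2.weights, abs=1e-6)
        assert m1.bias == pytest.approx(m2.bias, abs=1e-6)

    def test_single_class_rejected(self):
        X = np.zeros((3, 4))
        with pytest.raises(ValueError, match="both classes"):
            train_linear_svm(X, np.array([LGO] * 4, dtype=object), LGO, REST)

    def test_nan_features_rejected(self):
        X = np.zeros((2, 4))
        X[0, 0] = np.nan
        y = np.array([LGO, LGO, REST, REST], dtype=object)
        with pytest.raises(ValueError, match="non-finite"):
            train_linear_svm(X, y, LGO, REST)

    def test_foreign_labels_rejected(self):
        X = np.zeros((2, 3))
        y = np.array([LGO, REST, RGO], dtype=object)
        with pytest.raises(ValueError, match="neither class"):
            train_linear_svm(X, y, LGO, REST)


class TestDecisionValue:
    @pytest.fixture
    def model(self):
        return LinearModel(np.array([1.0, 0.0]), 0.0, LGO, REST)

    def test_dot_product(self, model):
        assert decision_value(model, np.array([0.5, 0.0])) == pytest.approx(0.5)

    def test_zero_input_gives_bias(self):
        m = LinearModel(np.array([1.0, 2.0]), -0.7, LGO, REST)
        assert decision_value(m, np.zeros(2)) == pytest.approx(-0.7)

    def test_negated_model_negates_value(self, model):
        neg = LinearModel(-model.weights, -model.bias, REST, LGO)
        x = np.array([0.3, -0.2])
        assert decision_value(model, x) == pytest.approx(-decision_value(neg, x))

    def test_length_mismatch_rejected(self, model):
        with pytest.raises(ValueError):
            decision_value(model, np.zeros(3))

    def test_tie_resolves_to_negative_class(self, model):
        assert model.predict(np.array([0.0]))[0] is REST
        assert model.predict(np.array([1e-12]))[0] is LGO


class TestDetrendDecisions:
    @pytest.fixture
    def model(self):
        return LinearModel(np.array([1.0]), 0.0, LGO, REST)

    def test_single_value_unchanged(self, model):
        corrected, labels = detrend_decisions(np.array([0.4]), model)
        assert corrected[0] == pytest.approx(0.4)
        assert labels[0] is LGO

    def test_drift_free_alternation_preserved(self, model):
        raw = np.tile([1.0, -1.0], 50).astype(float)
        corrected, _ = detrend_decisions(raw, model)
        # the correction converges back to the raw values as n grows
        assert np.allclose(corrected[-20:], raw[-20:], atol=0.05)
        late_err = np.abs(corrected[-20:] - raw[-20:]).max()
        early_err = np.abs(corrected[10:30] - raw[10:30]).max()
        assert late_err <= early_err

    def test_linear_drift_removed_signs_recovered(self, model):
        true = np.tile([1.0, -1.0], 40)
        raw = true + 0.01 * np.arange(80)  # slow classifier drift
        corrected, labels = detrend_decisions(raw, model)
        want = [LGO if v > 0 else REST for v in true[20:]]
        assert all(a is b for a, b in zip(labels[20:], want))
        # and the corrected trace is closer to the drift-free values
        assert (
            np.abs(corrected[20:] - true[20:]).mean()
            < np.abs(raw[20:] - true[20:]).mean()
        )

    def test_level_survives_correction(self, model):
        # a constant positive level must stay positive (mean re-added)
        raw = np.full(30, 2.0)
        corrected, labels = detrend_decisions(raw, model)
        assert np.allclose(corrected, 2.0, atol=1e-9)
        assert all(l is LGO for l in labels)


class TestWeightMap:
    def test_round_trip_and_conservation(self):
        rng = np.random.default_rng(3)
        mask = rng.random((4, 4, 3)) > 0.5
        w = rng.standard_normal(int(mask.sum()))
        m = LinearModel(w, 0.0, LGO, REST)
        grid = weight_map(m, mask)
        assert np.array_equal(apply_mask(grid, mask), w)
        assert grid.sum() == pytest.approx(w.sum())
        assert np.all(grid[~mask] == 0)

    def test_zero_weights_zero_grid(self):
        mask = np.ones((2, 2, 2), dtype=bool)
        m = LinearModel(np.zeros(8), 0.0, LGO, REST)
        assert not weight_map(m, mask).any()


def test_model_serialisation_round_trip(tmp_path):
    m = LinearModel(np.array([0.1, -0.2, 0.3]), 0.5, RGO, REST, c=1.0)
    save_model(m, tmp_path / "model")
    back = load_model(tmp_path / "model")
    assert np.array_equal(back.weights, m.weights)
    assert back.bias == m.bias
    assert back.positive_class is RGO and back.negative_class is REST


def test_informative_voxels_get_largest_weights(quiet_run):
    """On near-noiseless data the top-|w| voxels lie in the truth region."""
    mask = np.ones(quiet_run.grid_dims, dtype=bool)
    X = batch_detrend(apply_mask(smooth_run(quiet_run.data), mask), axis=1)
    labels = quiet_run.schedule.with_shift(2).labels()
    model = train_contrast(X, labels, CONTRASTS["R_vs_LGO"])
    truth = quiet_run.truth_masks[LGO]
    k = int(truth.sum())
    top_k = np.argsort(np.abs(model.weights))[-k:]
    truth_rows = set(np.flatnonzero(truth.ravel()))
    overlap = len(truth_rows & set(top_k)) / k
    assert overlap >= 0.5
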