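import numpy as np
import pandas as pd
import pytest

from mqtrans.io_cohort import Label, SampleAnnotation
from mqtrans.regression import (
    GeneModel,
    compute_mqtrans,
    filter_models,
    fit_gene_model,
    fit_gene_models,
    read_models,
    split_train_test,
    write_models,
)


def frame(values, features, samples):
    return pd.DataFrame(values, index=features, columns=samples)


def random_instance(rng, n_pred, n_samp):
    feats = [f"tf{i}" for i in range(n_pred)] + ["target"]
    X = rng.normal(size=(n_pred, n_samp))
    y = rng.normal(size=n_samp) + rng.normal(size=n_pred) @ X
    return frame(np.vstack([X, y]), feats, [f"s{j}" for j in range(n_samp)])


def normal_equations(X, y):
    """Independent closed-form oracle: solve (D'D)b = D'y with intercept."""
    D = np.hstack([np.ones((X.shape[0], 1)), X])
    return np.linalg.solve(D.T @ D, D.T @ y)


class TestSplitTrainTest:
    @staticmethod
    def annotations(n_primary, n_metastatic):
        out = [
            SampleAnnotation(f"P{i}", 0, label=Label.PRIMARY)
            for i in range(n_primary)
        ]
        out += [
            SampleAnnotation(f"M{i}", 1, label=Label.METASTATIC)
            for i in range(n_metastatic)
        ]
        return out

    def test_counts_follow_the_rule(self):
        train, test = split_train_test(self.annotations(10, 4), 0.6, seed=3)
        assert len(train) == 6
        assert len(test) == 8  # 4 remaining primary + all 4 metastatic
        assert set(train).isdisjoint(test)
        assert sorted(train + test) == sorted(
            a.sample_id for a in self.annotations(10, 4)
        )

    def test_deterministic_under_seed(self):
        ann = self.annotations(25, 5)
        assert split_train_test(ann, 0.6, 11) == split_train_test(ann, 0.6, 11)

    def test_excluded_samples_in_neither(self):
        ann = self.annotations(10, 4) + [SampleAnnotation("X", None)]
        train, test = split_train_test(ann, 0.6, 0)
        assert "X" not in train + test

    def test_fraction_one_rejected(self):
        with pytest.raises(ValueError, match="testing"):
            split_train_test(self.annotations(10, 4), 1.0, 0)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            split_train_test(self.annotations(10, 0), 0.6, 0)


class TestFitGeneModel:
    def test_target_equals_predictor_column(self):
        data = frame(
            [[1.0, 2.0, 3.0, 4.0], [0.5, 0.1, 0.9, 0.3], [1.0, 2.0, 3.0, 4.0]],
            ["tf1", "tf2", "g"],
            list("abcd"),
        )
        m = fit_gene_model(data, ["tf1", "tf2"], "g")
        assert m.weights == pytest.approx([1.0, 0.0], abs=1e-10)
        assert m.intercept == pytest.approx(0.0, abs=1e-10)
        assert m.training_pcc == pytest.approx(1.0)

    def test_affine_target_recovers_slope_and_intercept(self):
        tf = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        data = frame([tf, 2 * tf + 3], ["tf1", "g"], list("abcde"))
        m = fit_gene_model(data, ["tf1"], "g")
        assert m.weights == pytest.approx([2.0], abs=1e-10)
        assert m.intercept == pytest.approx(3.0, abs=1e-10)
        mq = compute_mqtrans([m], data)
        assert np.allclose(mq.to_numpy(), 0.0, atol=1e-10)

    def test_constant_target_is_unfittable_and_filtered(self):
        data = frame(
            [[1.0, 2.0, 3.0], [5.0, 5.0, 5.0]], ["tf1", "g"], list("abc")
        )
        m = fit_gene_model(data, ["tf1"], "g")
        assert not np.isfinite(m.training_pcc)
        assert filter_models([m]) == []

    def test_matches_normal_equations_oracle(self, rng):
        for _ in range(30):
            n_pred = int(rng.integers(1, 11))
            n_samp = int(rng.integers(n_pred + 2, 31))
            data = random_instance(rng, n_pred, n_samp)
            preds = [f"tf{i}" for i in range(n_pred)]
            m = fit_gene_model(data, preds, "target")
            oracle = normal_equations(
                data.loc[preds].to_numpy().T, data.loc["target"].to_numpy()
            )
            assert m.intercept == pytest.approx(oracle[0], abs=1e-8)
            assert m.weights == pytest.approx(oracle[1:], abs=1e-8)

    def test_rank_deficient_design_is_deterministic(self, rng):
        # more predictors than samples: minimum-norm solution, reproducible
        data = random_instance(rng, 12, 6)
        preds = [f"tf{i}" for i in range(12)]
        m1 = fit_gene_model(data, preds, "target")
        m2 = fit_gene_model(data, preds, "target")
        assert np.array_equal(m1.weights, m2.weights)
        mq = compute_mqtrans([m1], data)
        assert np.allclose(mq.to_numpy(), 0.0, atol=1e-8)  # interpolating fit

    def test_target_in_predictors_rejected(self, rng):
        data = random_instance(rng, 2, 8)
        with pytest.raises(ValueError, match="target"):
            fit_gene_models(data, ["tf0", "target"], ["target"])

    def test_noise_never_beats_exact_fit_pcc(self, rng):
        data = random_instance(rng, 3, 25)
        preds = ["tf0", "tf1", "tf2"]
        exact = fit_gene_model(data, preds, "target").training_pcc
        noisy = data.copy()
        noisy.loc["target"] += rng.normal(0, 2.0, size=25)
        assert fit_gene_model(noisy, preds, "target").training_pcc <= exact + 1e-12

    def test_predictor_screening_limits_model_size(self, rng):
        data = random_instance(rng, 10, 30)
        preds = [f"tf{i}" for i in range(10)]
        m = fit_gene_model(data, preds, "target")
        assert len(m.predictor_features) == 10
        (m_screened,) = fit_gene_models(
            data, preds, ["target"], n_predictors=4
        )
        assert len(m_screened.predictor_features) == 4
        assert set(m_screened.predictor_features) <= set(preds)

    def test_self_symbol_predictor_excluded(self, rng):
        data = random_instance(rng, 3, 20)
        symbols = {"tf0": ["SYM_A"], "tf1": ["SYM_B"], "tf2": ["SYM_C"],
                   "target": ["SYM_B"]}
        (m,) = fit_gene_models(
            data, ["tf0", "tf1", "tf2"], ["target"], probe_to_symbols=symbols
        )
        assert "tf1" not in m.predictor_features
        assert set(m.predictor_features) == {"tf0", "tf2"}

    def test_missing_values_drop_feature_from_modelling(self, rng):
        data = random_instance(rng, 3, 20)
        data.loc["target", data.columns[0]] = np.nan
        (m,) = fit_gene_models(data, ["tf0", "tf1", "tf2"], ["target"])
        assert not m.fittable


class TestFilterModels:
    @staticmethod
    def model(pcc, n_nonzero=2):
        return GeneModel("g", ["tf0", "tf1"], np.ones(2), 0.0, pcc, n_nonzero)

    def test_strictly_above_threshold_retained(self):
        assert filter_models([self.model(0.8275)]) != []

    def test_exactly_at_threshold_rejected(self):
        assert filter_models([self.model(0.5)]) == []

    def test_nan_pcc_rejected(self):
        assert filter_models([self.model(float("nan"))]) == []

    def test_zero_weight_model_rejected(self):
        assert filter_models([self.model(0.9, n_nonzero=0)]) == []

    def test_monotone_in_threshold(self, rng):
        models = [self.model(p) for p in rng.uniform(-1, 1, size=50)]
        kept = [len(filter_models(models, th)) for th in (0.1, 0.3, 0.5, 0.7, 0.9)]
        assert kept == sorted(kept, reverse=True)


class TestComputeMqtrans:
    def test_hand_arithmetic(self):
        m = GeneModel("g", ["tf1", "tf2"], np.array([1.0, -1.0]), 0.5, 0.9, 2)
        data = frame([[2.0], [1.0], [1.0]], ["tf1", "tf2", "g"], ["s1"])
        mq = compute_mqtrans([m], data)
        assert mq.loc["g", "s1"] == pytest.approx(0.5)  # predicted 1.5 − real 1.0

    def test_exact_prediction_gives_zero(self):
        m = GeneModel("g", ["tf1"], np.array([2.0]), 1.0, 1.0, 1)
        data = frame([[3.0], [7.0]], ["tf1", "g"], ["s1"])
        assert compute_mqtrans([m], data).loc["g", "s1"] == 0.0

    def test_training_residual_mean_is_zero(self, rng):
        data = random_instance(rng, 5, 30)
        m = fit_gene_model(data, [f"tf{i}" for i in range(5)], "target")
        mq = compute_mqtrans([m], data)
        assert abs(mq.loc["target"].mean()) < 1e-8

    def test_sample_locality_under_column_permutation(self, rng):
        data = random_instance(rng, 4, 20)
        m = fit_gene_model(data, [f"tf{i}" for i in range(4)], "target")
        mq = compute_mqtrans([m], data)
        perm = list(rng.permutation(data.columns))
        mq_perm = compute_mqtrans([m], data[perm])
        assert (mq_perm[data.columns].to_numpy() == mq.to_numpy()).all()

    def test_adding_samples_leaves_existing_columns_unchanged(self, rng):
        data = random_instance(rng, 4, 20)
        m = fit_gene_model(data, [f"tf{i}" for i in range(4)], "target")
        mq = compute_mqtrans([m], data.iloc[:, :10])
        mq_full = compute_mqtrans([m], data)
        assert (mq_full[data.columns[:10]].to_numpy() == mq.to_numpy()).all()

    def test_missing_feature_rejected_by_name(self, rng):
        data = random_instance(rng, 2, 10)
        m = GeneModel("g", ["tf0", "tf_absent"], np.ones(2), 0.0, 0.9, 2)
        with pytest.raises(KeyError, match="tf_absent"):
            compute_mqtrans([m], data)


def test_model_serialization_round_trip(tmp_path, rng):
    data = random_instance(rng, 4, 25)
    m = fit_gene_model(data, [f"tf{i}" for i in range(4)], "target")
    write_models([m], tmp_path / "models")
    (back,) = read_models(tmp_path / "models")
    assert back.target_feature == m.target_feature
    assert back.predictor_features == m.predictor_features
    assert back.weights == pytest.approx(m.weights)
    assert back.intercept == pytest.approx(m.intercept)
    assert back.training_pcc == pytest.approx(m.training_pcc)
    mq_a = compute_mqtrans([m], data)
    mq_b = compute_mqtrans([back], data)
    assert np.allclose(mq_a.to_numpy(), mq_b.to_numpy(), atol=1e-12)
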