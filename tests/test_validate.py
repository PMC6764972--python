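import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mgmix.dataset import MixedDataset, VariableSpec
from mgmix.model import MGMParameters, conditional_categorical, conditional_continuous
from mgmix.network import collapse_edges, first_order_neighborhood
from mgmix.simulate import gibbs_sample, make_ground_truth
from mgmix.validate import (
    pearson_correlation,
    predict_from_neighborhood,
    roc_auc,
    validate_all_neighborhoods,
)


def pairwise_auc(labels, scores):
    """Independent oracle: fraction of positive>negative pairs, ties 1/2."""
    labels = np.asarray(labels)
    pos = np.asarray(scores)[labels == 1]
    neg = np.asarray(scores)[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestPredict:
    def test_empty_neighborhood_predicts_constant(self):
        params = MGMParameters.zeros(1, (), cont_names=("v",))
        params.alpha = np.array([0.6])
        params.beta = np.array([[-2.0]])
        d = MixedDataset([VariableSpec("v", "continuous")],
                         np.array([[1.0], [2.0], [3.0]]), np.zeros((3, 0), int),
                         ["a", "b", "c"])
        nb = first_order_neighborhood(collapse_edges(params), "v")
        scores = predict_from_neighborhood(nb, params, d)
        np.testing.assert_allclose(scores, 0.6 / 2.0)

    def test_single_neighbor_linear_formula(self):
        params = MGMParameters.zeros(2, (), cont_names=("v", "w"))
        params.alpha = np.array([0.3, 0.0])
        params.beta = np.array([[-1.0, 0.8], [0.8, -1.0]])
        X = np.array([[0.0, 1.0], [0.0, -2.0], [0.0, 0.5]])
        d = MixedDataset([VariableSpec("v", "continuous"), VariableSpec("w", "continuous")],
                         X, np.zeros((3, 0), int), ["a", "b", "c"])
        nb = first_order_neighborhood(collapse_edges(params), "v")
        scores = predict_from_neighborhood(nb, params, d)
        np.testing.assert_allclose(scores, 0.3 + 0.8 * X[:, 1])

    def test_matches_row_by_row_conditional_oracle(self):
        truth = make_ground_truth(3, 2, None, density=0.7, weight_range=(0.2, 0.5), seed=41)
        d = gibbs_sample(truth, 30, seed=42)
        params = truth.params
        net = collapse_edges(params)
        cont, cat = params.var_names()
        nb = first_order_neighborhood(net, cont[0])
        scores = predict_from_neighborhood(nb, params, d)
        for i in range(d.n):
            m, _ = conditional_continuous(params, 0, d.continuous_values[i],
                                          d.categorical_values[i])
            assert scores[i] == pytest.approx(m, rel=1e-12)
        nbc = first_order_neighborhood(net, cat[0])
        probs = predict_from_neighborhood(nbc, params, d)
        for i in range(d.n):
            expect = conditional_categorical(params, 0, d.continuous_values[i],
                                             d.categorical_values[i])
            assert probs[i] == pytest.approx(expect[1], rel=1e-12)

    def test_refit_mode_agrees_with_direct_weights_on_model_data(self):
        # data generated from the model itself: the refit regression recovers
        # (approximately) the same linear signature, so scores correlate highly
        truth = make_ground_truth(4, 1, None, density=0.8, weight_range=(0.4, 0.6), seed=43)
        d_train = gibbs_sample(truth, 2000, seed=44)
        d_test = gibbs_sample(truth, 500, seed=45)
        params = truth.params
        net = collapse_edges(params)
        cont, _ = params.var_names()
        nb = first_order_neighborhood(net, cont[0])
        direct = predict_from_neighborhood(nb, params, d_test)
        refit = predict_from_neighborhood(nb, params, d_test, refit_on=d_train)
        assert np.corrcoef(direct, refit)[0, 1] > 0.99

    def test_missing_variable_errors(self):
        params = MGMParameters.zeros(2, (), cont_names=("v", "w"))
        params.beta[0, 1] = params.beta[1, 0] = 0.5
        d = MixedDataset([VariableSpec("v", "continuous")], np.zeros((2, 1)),
                         np.zeros((2, 0), int), ["a", "b"])
        nb = first_order_neighborhood(collapse_edges(params), "v")
        with pytest.raises(ValueError, match="w"):
            predict_from_neighborhood(nb, params, d)


class TestPearson:
    def test_perfect_and_anti_correlation(self, rng):
        x = rng.normal(size=100)
        assert pearson_correlation(x, x) == pytest.approx(1.0)
        assert pearson_correlation(x, -x) == pytest.approx(-1.0)

    def test_additive_noise_analytic_value(self):
        # truth + noise with sd ratio 1:3 gives corr 3/sqrt(10)
        rng = np.random.default_rng(7)
        truth = rng.normal(size=10000) * 3.0
        pred = truth + rng.normal(size=10000)
        assert pearson_correlation(truth, pred) == pytest.approx(3 / np.sqrt(10), abs=0.01)

    def test_affine_invariance_of_predictions(self, rng):
        x, y = rng.normal(size=(2, 50))
        assert pearson_correlation(x, 3.0 * y + 7.0) == pytest.approx(
            pearson_correlation(x, y)
        )

    def test_degenerate_inputs_error(self):
        with pytest.raises(ValueError, match="3 observations"):
            pearson_correlation(np.array([1.0, 2.0]), np.array([1.0, 2.0]))
        with pytest.raises(ValueError, match="variance"):
            pearson_correlation(np.ones(5), np.arange(5.0))


class TestRocAuc:
    def test_perfect_separation(self):
        _, auc = roc_auc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9])
        assert auc == 1.0

    def test_fixed_example_matches_pairwise_oracle(self):
        labels = [0, 0, 1, 1]
        scores = [0.1, 0.4, 0.35, 0.8]
        _, auc = roc_auc(labels, scores)
        assert auc == pytest.approx(0.75)
        assert auc == pytest.approx(pairwise_auc(labels, scores))

    def test_label_independent_scores_near_half(self, rng):
        labels = rng.integers(0, 2, size=20000)
        scores = rng.normal(size=20000)
        _, auc = roc_auc(labels, scores)
        assert auc == pytest.approx(0.5, abs=0.02)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_negation_and_monotone_invariance(self, seed):
        rng = np.random.default_rng(seed)
        labels = np.array([0, 1] * 10)
        scores = rng.normal(size=20)
        _, auc = roc_auc(labels, scores)
        _, auc_neg = roc_auc(labels, -scores)
        assert auc == pytest.approx(1.0 - auc_neg, abs=1e-12)
        _, auc_mono = roc_auc(labels, np.exp(2.0 * scores))
        assert auc == pytest.approx(auc_mono, abs=1e-12)
        assert auc == pytest.approx(pairwise_auc(labels, scores), abs=1e-12)

    def test_single_class_errors(self):
        with pytest.raises(ValueError, match="two classes"):
            roc_auc([1, 1, 1], [0.1, 0.2, 0.3])

    def test_curve_starts_at_origin_ends_at_one(self):
        points, _ = roc_auc([0, 1, 0, 1], [0.2, 0.9, 0.6, 0.4])
        assert tuple(points[0]) == (0.0, 0.0)
        assert tuple(points[-1]) == (1.0, 1.0)


class TestValidateAll:
    def test_model_data_beats_permuted_labels(self):
        truth = make_ground_truth(5, 2, None, density=0.5, weight_range=(0.4, 0.7), seed=51)
        d = gibbs_sample(truth, 800, seed=52)
        net = collapse_edges(truth.params)
        report = validate_all_neighborhoods(truth.params, net, d)
        cont = report[report["metric"] == "correlation"]["value"].dropna()
        rng = np.random.default_rng(0)
        # shuffling the continuous block against the categorical block is the null
        null = MixedDataset(d.specs, d.continuous_values[rng.permutation(d.n)],
                            d.categorical_values, d.sample_ids)
        null_report = validate_all_neighborhoods(truth.params, net, null)
        null_cont = null_report[null_report["metric"] == "correlation"]["value"].dropna()
        assert cont.median() > null_cont.median()

    def test_empty_graph_flags_continuous_and_gives_chance_auc(self):
        truth = make_ground_truth(2, 1, None, density=0.0, weight_range=(0.3, 0.6), seed=53)
        d = gibbs_sample(truth, 2000, seed=54)
        params = MGMParameters.zeros(2, (2,), cont_names=("x1", "x2"), cat_names=("y1",))
        report = validate_all_neighborhoods(params, collapse_edges(params), d)
        cont = report[report["metric"] == "correlation"]
        assert (cont["flag"] == "undefined").all()
        auc = report[report["metric"] == "auc"]["value"].iloc[0]
        assert auc == pytest.approx(0.5, abs=0.05)

    def test_deterministic(self):
        truth = make_ground_truth(3, 1, None, density=0.6, weight_range=(0.3, 0.6), seed=55)
        d = gibbs_sample(truth, 200, seed=56)
        net = collapse_edges(truth.params)
        r1 = validate_all_neighborhoods(truth.params, net, d)
        r2 = validate_all_neighborhoods(truth.params, net, d)
        assert r1.equals(r2)
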