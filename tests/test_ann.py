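"""Input expansion, splitting, BFGS training, search, and Garson weights."""

import numpy as np
import pandas as pd
import pytest

from strawpoly import ann, synthetic as syn
from strawpoly.ann import (
    MLPArchitecture,
    MLPModel,
    default_candidates,
    evaluate,
    expand_inputs,
    garson_importance,
    model_search,
    predict_mlp,
    split_data,
    train_mlp,
)


@pytest.fixture(scope="module")
def study_design():
    return syn.generate_design(syn.SimulationSpec(seed=3))


@pytest.fixture(scope="module")
def study_features(study_design):
    return expand_inputs(study_design)


class TestExpandInputs:
    def test_study_design_yields_twenty_columns(self, study_features):
        X, cmap = study_features
        assert X.shape[1] == 20
        assert list(cmap["factor"].unique()) == [
            "date", "variety", "area", "infection", "harvest"
        ]

    def test_one_hot_rows_sum_to_three(self, study_features):
        X, cmap = study_features
        onehot = cmap["factor"].isin(["date", "variety", "area"]).to_numpy()
        assert np.allclose(X[:, onehot].sum(axis=1), 3.0)

    def test_small_catalog_column_count(self, study_design):
        import datetime as dt

        conds = [c for c in study_design[:8]]
        levels = {
            "date": sorted({c.collection_date for c in conds}),
            "variety": sorted({c.variety for c in conds}),
            "area": sorted({c.area for c in conds}),
        }
        X, _ = expand_inputs(conds, levels=levels)
        expected = len(levels["date"]) + len(levels["variety"]) + len(levels["area"]) + 2
        assert X.shape[1] == expected

    def test_continuous_columns_standardized(self, study_features):
        X, cmap = study_features
        cont = cmap["factor"].isin(["infection", "harvest"]).to_numpy()
        assert np.allclose(X[:, cont].mean(axis=0), 0.0, atol=1e-12)
        assert np.allclose(X[:, cont].std(axis=0), 1.0, atol=1e-12)

    def test_unseen_level_rejected(self, study_design):
        levels = {
            "date": sorted({c.collection_date for c in study_design})[:-1],
            "variety": sorted({c.variety for c in study_design}),
            "area": sorted({c.area for c in study_design}),
        }
        with pytest.raises(ValueError, match="unseen"):
            expand_inputs(study_design, levels=levels)


class TestSplit:
    def test_study_size_partitions_19_4_4(self):
        s = split_data(27, seed=0)
        assert (len(s.train), len(s.validation), len(s.test)) == (19, 4, 4)

    def test_twenty_rows_partition_14_3_3(self):
        s = split_data(20, seed=0)
        assert (len(s.train), len(s.validation), len(s.test)) == (14, 3, 3)

    @pytest.mark.parametrize("n", [3, 7, 10, 28, 55, 101])
    def test_partitions_are_disjoint_and_cover(self, n):
        s = split_data(n, seed=n)
        all_idx = sorted(s.train + s.validation + s.test)
        assert all_idx == list(range(n))

    def test_reproducible_given_seed(self):
        assert split_data(28, seed=5) == split_data(28, seed=5)
        assert split_data(28, seed=5) != split_data(28, seed=6)

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError):
            split_data(2)


class TestTraining:
    def test_linear_network_matches_ols(self):
        """An identity-activation network trained to convergence reproduces
        the least-squares fit of the same features."""
        rng = np.random.default_rng(0)
        X = rng.normal(size=(30, 3))
        y = X @ np.array([2.0, -1.0, 0.5]) + 1.0
        model = train_mlp(MLPArchitecture(3, 4, 1, "identity", "identity"), X, y, seed=1)
        coef, *_ = np.linalg.lstsq(np.column_stack([X, np.ones(30)]), y, rcond=None)
        yhat_ols = np.column_stack([X, np.ones(30)]) @ coef
        yhat_net = predict_mlp(model, X)[:, 0]
        assert np.sqrt(np.mean((yhat_net - yhat_ols) ** 2)) < 1e-3
        ev = evaluate(model, X, y)
        assert ev["pearson_r"][0] >= 0.999

    def test_zero_max_iter_returns_initialized_network(self):
        rng = np.random.default_rng(1)
        X, y = rng.normal(size=(10, 2)), rng.normal(size=10)
        a = MLPArchitecture(2, 3, 1)
        m = train_mlp(a, X, y, seed=7, max_iter=0)
        theta = np.random.default_rng(7).uniform(-0.5, 0.5, a.n_params())
        assert np.allclose(m.W.ravel(), theta[: 2 * 3])
        assert m.n_iter == 0

    def test_constant_targets_reach_zero_loss(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(12, 2))
        m = train_mlp(MLPArchitecture(2, 3, 1), X, np.full(12, 4.2), seed=0)
        assert np.allclose(predict_mlp(m, X), 4.2, atol=1e-6)
        assert m.loss_log[-1] < 1e-8

    def test_loss_log_nonincreasing(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(25, 4))
        y = np.tanh(X @ rng.normal(size=4)) + 0.1 * rng.normal(size=25)
        m = train_mlp(MLPArchitecture(4, 3, 1, "tanh"), X, y, seed=0)
        log = np.array(m.loss_log)
        assert (np.diff(log) <= 1e-9).all()
        assert log[-1] <= log[0]

    def test_gradient_matches_finite_differences(self):
        from strawpoly.ann import _sos_and_grad

        rng = np.random.default_rng(4)
        a = MLPArchitecture(3, 2, 2, "logistic", "exponential")
        X, Y = rng.normal(size=(6, 3)), rng.normal(size=(6, 2))
        theta = rng.uniform(-0.5, 0.5, a.n_params())
        loss, grad = _sos_and_grad(theta, X, Y, a)
        eps = 1e-6
        num = np.zeros_like(theta)
        for k in range(len(theta)):
            tp, tm = theta.copy(), theta.copy()
            tp[k] += eps
            tm[k] -= eps
            num[k] = (_sos_and_grad(tp, X, Y, a)[0] - _sos_and_grad(tm, X, Y, a)[0]) / (2 * eps)
        assert np.abs(grad - num).max() < 1e-4

    def test_non_finite_inputs_rejected(self):
        X = np.array([[1.0, np.nan], [0.0, 1.0]])
        with pytest.raises(ValueError, match="non-finite"):
            train_mlp(MLPArchitecture(2, 2, 1), X, np.zeros(2))

    def test_json_roundtrip_preserves_predictions(self, tmp_path):
        rng = np.random.default_rng(5)
        X, y = rng.normal(size=(15, 3)), rng.normal(size=15)
        m = train_mlp(MLPArchitecture(3, 3, 1), X, y, seed=0, max_iter=50)
        m.to_json(tmp_path / "net.json")
        back = MLPModel.from_json(tmp_path / "net.json")
        assert np.allclose(predict_mlp(back, X), predict_mlp(m, X))


class TestEvaluate:
    def test_perfect_predictions(self):
        rng = np.random.default_rng(6)
        X, y = rng.normal(size=(20, 2)), rng.normal(size=20)
        m = train_mlp(MLPArchitecture(2, 3, 1, "identity", "identity"),
                      X, y, seed=0, max_iter=0)
        # overwrite with the targets via a direct check of the metric math
        from strawpoly.compare import r_squared, rmse

        assert r_squared(y, y) == 1.0
        assert rmse(y, y) == 0.0

    def test_hand_case_rmse(self):
        from strawpoly.compare import rmse

        assert rmse([1, 2, 3], [1, 2, 4]) == pytest.approx(np.sqrt(1 / 3))

    def test_zero_variance_target_flagged(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(10, 2))
        m = train_mlp(MLPArchitecture(2, 2, 1), X, rng.normal(size=10), seed=0,
                      max_iter=10)
        with pytest.warns(UserWarning, match="zero variance"):
            ev = evaluate(m, X, np.full(10, 1.0))
        assert np.isnan(ev["pearson_r"][0])


class TestModelSearch:
    @pytest.fixture(scope="class")
    def search_setup(self, study_design):
        X, _ = expand_inputs(study_design)
        tab = syn.simulate_responses(study_design, syn.SimulationSpec(seed=3))
        Y = tab.to_numpy()
        split = split_data(len(study_design), seed=0)
        return X, Y, split

    def test_retains_exactly_five_of_twenty(self, search_setup):
        X, Y, split = search_setup
        cands = default_candidates(X.shape[1], Y.shape[1], 20)
        retained = model_search(cands, X, Y, split, seed=0, max_iter=150)
        assert len(retained) == 5
        assert all(m.architecture.n_hidden in (3, 4, 5) for m, _ in retained)

    def test_ranking_invariant_to_candidate_order(self, search_setup):
        X, Y, split = search_setup
        cands = default_candidates(X.shape[1], Y.shape[1], 20)
        a = model_search(cands, X, Y, split, seed=0, max_iter=150)
        b = model_search(list(reversed(cands)), X, Y, split, seed=0, max_iter=150)
        assert [m.seed for m, _ in a] == [m.seed for m, _ in b]
        assert [s for _, s in a] == pytest.approx([s for _, s in b])

    def test_network_names_follow_convention(self, search_setup):
        X, Y, split = search_setup
        cands = default_candidates(X.shape[1], Y.shape[1], 20)
        retained = model_search(cands, X, Y, split, seed=0, max_iter=150)
        names = {m.architecture.name for m, _ in retained}
        assert names <= {"MLP 20-3-5", "MLP 20-4-5", "MLP 20-5-5"}

    def test_five_candidates_all_retained_ranked(self, search_setup):
        X, Y, split = search_setup
        cands = default_candidates(X.shape[1], Y.shape[1], 5)
        retained = model_search(cands, X, Y, split, seed=0, max_iter=100)
        scores = [s for _, s in retained]
        assert len(retained) == 5
        assert scores == sorted(scores, reverse=True)

    def test_too_few_candidates_rejected(self, search_setup):
        X, Y, split = search_setup
        with pytest.raises(ValueError):
            model_search(default_candidates(X.shape[1], Y.shape[1], 3),
                         X, Y, split, seed=0)


class TestGarson:
    def _toy(self, W, V):
        W = np.asarray(W, dtype=float)
        V = np.asarray(V, dtype=float)
        n_in, n_h = W.shape
        n_out = V.shape[1]
        return MLPModel(
            architecture=MLPArchitecture(n_in, n_h, n_out),
            W=W, b_hidden=np.zeros(n_h), V=V, b_output=np.zeros(n_out),
            x_mean=np.zeros(n_in), x_scale=np.ones(n_in),
            y_mean=np.zeros(n_out), y_scale=np.ones(n_out), seed=0,
        )

    def test_single_input_gets_all_importance(self):
        m = self._toy([[0.3, -2.0]], [[1.0], [0.5]])
        assert garson_importance(m).to_numpy() == pytest.approx([1.0])

    def test_symmetric_weights_split_evenly(self):
        m = self._toy([[1.0], [-1.0]], [[2.0]])
        assert garson_importance(m).to_numpy() == pytest.approx([0.5, 0.5])

    def test_hand_evaluated_partition(self):
        # W = I2, V = (3, 1): input 1 carries 3/(3+1) of the weight mass
        m = self._toy([[1.0, 0.0], [0.0, 1.0]], [[3.0], [1.0]])
        assert garson_importance(m).to_numpy() == pytest.approx([0.75, 0.25])

    def test_importances_sum_to_one(self):
        rng = np.random.default_rng(8)
        m = self._toy(rng.normal(size=(6, 4)), rng.normal(size=(4, 2)))
        for out in range(2):
            ri = garson_importance(m, output=out)
            assert float(ri.sum()) == pytest.approx(1.0, abs=1e-9)
            assert (ri >= 0).all()

    def test_invariant_to_positive_rescaling_of_output_weights(self):
        rng = np.random.default_rng(9)
        m = self._toy(rng.normal(size=(5, 3)), rng.normal(size=(3, 1)))
        ri = garson_importance(m).to_numpy()
        m.V = m.V * 17.3
        assert garson_importance(m).to_numpy() == pytest.approx(ri, abs=1e-12)

    def test_invariant_to_hidden_neuron_permutation(self):
        rng = np.random.default_rng(10)
        W, V = rng.normal(size=(5, 4)), rng.normal(size=(4, 1))
        perm = [2, 0, 3, 1]
        ri1 = garson_importance(self._toy(W, V)).to_numpy()
        ri2 = garson_importance(self._toy(W[:, perm], V[perm])).to_numpy()
        assert ri2 == pytest.approx(ri1, abs=1e-12)

    def test_zero_weights_rejected(self):
        m = self._toy(np.zeros((3, 2)), np.ones((2, 1)))
        with pytest.raises(ValueError, match="importance undefined"):
            garson_importance(m)

    def test_one_hot_columns_fold_into_parent_factor(self):
        rng = np.random.default_rng(11)
        m = self._toy(rng.normal(size=(4, 3)), rng.normal(size=(3, 1)))
        cmap = pd.DataFrame(
            {"column": ["a=1", "a=2", "b", "c"], "factor": ["a", "a", "b", "c"]}
        )
        ri = garson_importance(m, cmap)
        assert set(ri.index) == {"a", "b", "c"}
        assert float(ri.sum()) == pytest.approx(1.0)

    def test_signal_factors_dominate_null_factors(self):
        """On surfaces where only date and harvest carry signal, their
        summed Garson importance exceeds that of the null factors
        (averaged over seeds)."""
        import warnings as _w

        beta = np.zeros(20)
        beta[1] = 50.0   # date linear
        beta[5] = 50.0   # harvest linear
        beta[9] = 30.0   # harvest quadratic
        beta[13] = 30.0  # date x harvest interaction
        true = {k: beta for k in
                ("hydroxybenzoic", "hydroxycinnamic", "flavones",
                 "abts_ic50", "dpph_ic50")}
        sums = []
        for seed in range(20):
            spec = syn.SimulationSpec(
                seed=seed, true_beta=true, replicates=2,
                noise_sd={k: 1.0 for k in true},
            )
            design = syn.generate_design(spec)
            tab = syn.simulate_responses(design, spec)
            X, cmap = expand_inputs(design)
            with _w.catch_warnings():
                _w.simplefilter("ignore")
                # two hidden neurons: enough for the planted surface but no
                # spare capacity to overfit the null one-hot blocks
                m = train_mlp(
                    MLPArchitecture(X.shape[1], 2, 1, "tanh", "identity"),
                    X, tab["hydroxybenzoic"].to_numpy(), seed=seed, max_iter=600,
                )
            ri = garson_importance(m, cmap)
            sums.append(ri["date"] + ri["harvest"])
        mean_signal = float(np.mean(sums))
        assert mean_signal > 1.0 - mean_signal  # signal factors > null factors
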