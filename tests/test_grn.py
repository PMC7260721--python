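import numpy as np
import pandas as pd
import pytest
from sklearn.ensemble import RandomForestRegressor

from nutrinet import (
    edge_recovery_auroc,
    rf_importance_network,
    threshold_directed,
)


@pytest.fixture(scope="module")
def copy_target_matrix():
    rng = np.random.default_rng(77)
    tfs = pd.DataFrame(
        rng.normal(size=(4, 30)), index=["TF1", "TF2", "TF3", "TF4"],
        columns=[f"s{i}" for i in range(30)],
    )
    target = tfs.loc[["TF1"]].rename(index={"TF1": "tgt"})
    return pd.concat([tfs, target])


class TestImportances:
    @pytest.mark.parametrize("seed", range(5))
    def test_exact_copy_gets_top_importance(self, copy_target_matrix, seed):
        scores = rf_importance_network(
            copy_target_matrix, ["TF1", "TF2", "TF3", "TF4"],
            n_trees=50, seed=seed, targets=["tgt"],
        )
        col = scores.scores["tgt"]
        assert col.idxmax() == "TF1"
        assert col["TF1"] > 0.5

    def test_sklearn_agrees_on_noiseless_predictor(self, copy_target_matrix):
        """Uniform-prior importances match an independent forest's verdict."""
        X = copy_target_matrix.loc[["TF1", "TF2", "TF3", "TF4"]].T.to_numpy()
        y = copy_target_matrix.loc["tgt"].to_numpy()
        ref = RandomForestRegressor(n_estimators=100, random_state=0, max_features="sqrt")
        ref.fit(X, y)
        assert int(np.argmax(ref.feature_importances_)) == 0  # TF1 wins there too

    def test_per_target_importances_sum_to_one(self, small_grn):
        matrix, _, _ = small_grn
        tfs = [g for g in matrix.index if g.startswith("TF")]
        tgs = [g for g in matrix.index if g.startswith("TG")][:6]
        scores = rf_importance_network(matrix, tfs, n_trees=30, seed=1, targets=tgs)
        np.testing.assert_allclose(scores.scores.sum(axis=0), 1.0, atol=1e-9)

    def test_deterministic_given_seed_and_ordering(self, small_grn):
        matrix, _, _ = small_grn
        tfs = [g for g in matrix.index if g.startswith("TF")]
        a = rf_importance_network(matrix, tfs, n_trees=20, seed=4, targets=["TG001", "TG002"])
        b = rf_importance_network(matrix, tfs, n_trees=20, seed=4, targets=["TG001", "TG002"])
        pd.testing.assert_frame_equal(a.scores, b.scores)

    def test_no_self_regulation(self, small_grn):
        matrix, _, _ = small_grn
        tfs = [g for g in matrix.index if g.startswith("TF")]
        scores = rf_importance_network(matrix, tfs, n_trees=10, seed=0, targets=tfs[:3])
        for tf in tfs[:3]:
            assert scores.scores.loc[tf, tf] == 0.0

    def test_priors_help_recovery(self, small_grn):
        matrix, truth, priors = small_grn
        tfs = [g for g in matrix.index if g.startswith("TF")]
        tgs = [g for g in matrix.index if g.startswith("TG")]
        uni = rf_importance_network(matrix, tfs, n_trees=100, seed=2, targets=tgs)
        inf = rf_importance_network(matrix, tfs, n_trees=100, priors=priors, seed=2, targets=tgs)
        assert edge_recovery_auroc(inf, truth.true_edges) >= edge_recovery_auroc(
            uni, truth.true_edges
        )

    def test_shuffled_target_loses_its_parents(self, small_grn):
        """Negative control: permuting a target's samples erases the signal."""
        matrix, truth, _ = small_grn
        rng = np.random.default_rng(0)
        tfs = [g for g in matrix.index if g.startswith("TF")]
        tgs = [g for g in matrix.index if g.startswith("TG")]
        shuffled = matrix.copy()
        for tg in tgs:
            shuffled.loc[tg] = rng.permutation(shuffled.loc[tg].to_numpy())
        scores = rf_importance_network(shuffled, tfs, n_trees=100, seed=3, targets=tgs)
        auroc = edge_recovery_auroc(scores, truth.true_edges)
        assert abs(auroc - 0.5) < 0.12

    def test_missing_tf_error(self, small_grn):
        matrix, _, _ = small_grn
        with pytest.raises(ValueError, match="absent"):
            rf_importance_network(matrix, ["TF001", "NOPE"], n_trees=5)

    def test_all_zero_prior_column_error(self, small_grn):
        matrix, _, priors = small_grn
        tfs = [g for g in matrix.index if g.startswith("TF")]
        bad = priors.copy()
        bad["TG001"] = 0.0
        with pytest.raises(ValueError, match="TG001"):
            rf_importance_network(matrix, tfs, n_trees=5, priors=bad, targets=["TG001"])


@pytest.fixture(scope="module")
def scores(small_grn):
    matrix, _, _ = small_grn
    tfs = [g for g in matrix.index if g.startswith("TF")]
    tgs = [g for g in matrix.index if g.startswith("TG")][:8]
    return rf_importance_network(matrix, tfs, n_trees=30, seed=1, targets=tgs)


class TestThresholdDirected:

    def test_top_zero_is_empty(self, scores):
        assert threshold_directed(scores, top_n=0).number_of_edges() == 0

    def test_top_all_keeps_everything(self, scores):
        n_edges = len(scores.ranked_edges())
        net = threshold_directed(scores, top_n=n_edges)
        assert net.number_of_edges() == n_edges
        assert net.is_directed()
        assert all(net.nodes[t]["is_tf"] for t in net.nodes if t.startswith("TF"))

    def test_selector_exclusivity(self, scores):
        with pytest.raises(ValueError, match="exactly one"):
            threshold_directed(scores)
        with pytest.raises(ValueError, match="exactly one"):
            threshold_directed(scores, top_n=5, score_cutoff=0.1)

    def test_precision_on_planted_network(self, small_grn):
        matrix, truth, _ = small_grn
        tfs = [g for g in matrix.index if g.startswith("TF")]
        tgs = [g for g in matrix.index if g.startswith("TG")]
        scores = rf_importance_network(matrix, tfs, n_trees=200, seed=1, targets=tgs)
        net = threshold_directed(scores, top_n=30)
        hits = sum(1 for e in net.edges() if e in truth.true_edges)
        assert hits / 30 >= 0.6
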