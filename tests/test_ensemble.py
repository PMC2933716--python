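"""Bootstrap mechanics, winner selection, voting, importance, persistence."""

import logging

import numpy as np
import pytest

import rankbag as rb
from rankbag.ensemble import draw_bootstrap


class TestDrawBootstrap:
    def test_partition_property(self, rng):
        y = rng.integers(0, 2, 50)
        draw = draw_bootstrap(y, rng)
        in_set = set(draw.in_bag.tolist())
        oob = set(draw.oob.tolist())
        assert in_set | oob == set(range(50))
        assert in_set & oob == set()
        assert len(draw.in_bag) == 50

    def test_all_classes_in_bag(self, rng):
        y = np.array([0] * 48 + [1] * 2)  # rare class
        for _ in range(50):
            draw = draw_bootstrap(y, rng)
            assert set(np.unique(y[draw.in_bag])) == {0, 1}

    def test_singleton_class_always_sampled(self, rng):
        y = np.array([0] * 29 + [1])
        for _ in range(20):
            draw = draw_bootstrap(y, rng)
            assert 29 in draw.in_bag

    def test_degenerate_draws_error(self):
        y = np.array([0, 1])
        rng = np.random.default_rng(0)
        # with n = 2 an admissible draw (both classes in-bag AND non-empty
        # OOB) is impossible, so the redraw loop must give up
        with pytest.raises(RuntimeError, match="bootstrap"):
            draw_bootstrap(y, rng, max_redraws=50)

    def test_632_distinct_fraction(self):
        rng = np.random.default_rng(2)
        y = rng.integers(0, 2, 1000)
        fracs = [
            len(np.unique(draw_bootstrap(y, rng).in_bag)) / 1000 for _ in range(200)
        ]
        assert np.mean(fracs) == pytest.approx(1 - 1 / np.e, abs=0.01)


class TestTrainEnsemble:
    def test_single_spec_reduces_to_bagging(self, toy_data):
        train, test = toy_data
        config = rb.EnsembleConfig(specs=(rb.make_spec("LDA"),), n_bootstrap=7, seed=1)
        model = rb.train_ensemble(train.X, train.y, config)
        assert model.winner_ids() == ["LDA"] * 7
        assert model.selection_counts() == {"LDA": 7}
        assert (model.predict(test.X) == test.y).mean() >= 0.95

    def test_dominant_spec_selected_overwhelmingly(self, small_ensemble):
        counts = small_ensemble.selection_counts()
        assert sum(counts.values()) == small_ensemble.n_members
        assert counts["LDA"] >= 0.9 * small_ensemble.n_members

    def test_selection_counts_sum_to_n(self, small_ensemble):
        assert sum(small_ensemble.selection_counts().values()) == 15

    def test_seed_determinism_end_to_end(self, toy_data):
        train, test = toy_data
        specs = (rb.make_spec("LDA"), rb.make_spec("RF", n_trees=10))
        cfg = lambda: rb.EnsembleConfig(specs=specs, n_bootstrap=9, seed=77)
        m1 = rb.train_ensemble(train.X, train.y, cfg())
        m2 = rb.train_ensemble(train.X, train.y, cfg())
        assert m1.winner_ids() == m2.winner_ids()
        np.testing.assert_array_equal(m1.predict(test.X), m2.predict(test.X))
        np.testing.assert_array_equal(
            m1.predict_proba(test.X), m2.predict_proba(test.X)
        )

    def test_failing_spec_excluded_with_warning(self, toy_data, caplog):
        train, _ = toy_data
        # raw QDA on a 2-feature problem is fine; force failure via a spec
        # whose reduced dimension exceeds the smallest class
        bad = rb.ClassifierSpec(id="QDA-wide", family="qda")
        specs = (rb.make_spec("LDA"), bad)
        X = np.hstack([train.X, np.random.default_rng(0).normal(size=(train.n, 60))])
        config = rb.EnsembleConfig(specs=specs, n_bootstrap=3, seed=2)
        with caplog.at_level(logging.WARNING, logger="rankbag.ensemble"):
            model = rb.train_ensemble(X, train.y, config)
        assert model.winner_ids() == ["LDA"] * 3
        assert any("QDA-wide" in r.message for r in caplog.records)

    def test_all_specs_failing_aborts(self, toy_data):
        train, _ = toy_data
        bad = rb.ClassifierSpec(id="QDA-wide", family="qda")
        X = np.hstack([train.X, np.random.default_rng(0).normal(size=(train.n, 60))])
        config = rb.EnsembleConfig(specs=(bad,), n_bootstrap=2, seed=2)
        with pytest.raises(RuntimeError, match="failed"):
            rb.train_ensemble(X, train.y, config)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            rb.EnsembleConfig(specs=())
        with pytest.raises(ValueError):
            rb.EnsembleConfig(specs=(rb.make_spec("LDA"), rb.make_spec("LDA")))
        with pytest.raises(ValueError):
            rb.EnsembleConfig(specs=(rb.make_spec("LDA"),), measures=("brier",))
        with pytest.raises(ValueError):
            rb.EnsembleConfig(
                specs=(rb.make_spec("LDA"),),
                measures=("accuracy",),
                weights=(1.0, 2.0),
            )


class TestPrediction:
    def test_vote_proportions_on_grid_and_sum_to_one(self, small_ensemble, toy_data):
        _, test = toy_data
        proba = small_ensemble.predict_proba(test.X)
        n = small_ensemble.n_members
        np.testing.assert_allclose(proba.sum(axis=1), 1.0)
        grid = np.round(proba * n)
        np.testing.assert_allclose(proba * n, grid, atol=1e-9)

    def test_predict_consistent_with_argmax_proba(self, small_ensemble, toy_data):
        _, test = toy_data
        proba = small_ensemble.predict_proba(test.X)
        pred = small_ensemble.predict(test.X)
        clear = np.abs(proba[:, 0] - proba[:, 1]) > 1e-12
        expected = small_ensemble.classes_[np.argmax(proba, axis=1)]
        np.testing.assert_array_equal(pred[clear], expected[clear])

    def test_unanimous_vote(self, small_ensemble, toy_data):
        _, test = toy_data
        proba = small_ensemble.predict_proba(test.X)
        unanimous = np.isclose(proba.max(axis=1), 1.0)
        assert unanimous.any()
        pred = small_ensemble.predict(test.X)
        winners = small_ensemble.classes_[np.argmax(proba, axis=1)]
        np.testing.assert_array_equal(pred[unanimous], winners[unanimous])

    def test_exact_tie_goes_to_positive_class(self, toy_data):
        train, _ = toy_data
        config = rb.EnsembleConfig(specs=(rb.make_spec("LDA"),), n_bootstrap=2, seed=4)
        model = rb.train_ensemble(train.X, train.y, config)

        class _FixedVoter:
            def __init__(self, label):
                self.label = label

            def predict(self, X):
                return np.full(len(X), self.label, dtype=int)

        # force an exact 1-1 vote split between the two members
        model.members[0].model = _FixedVoter(0)
        model.members[1].model = _FixedVoter(1)
        pred = model.predict(np.zeros((3, 2)))
        assert np.all(pred == model.positive_class)

    def test_mean_vote_within_member_rate_range(self, small_ensemble):
        big = rb.dominant_spec_toy(300, rng=31)
        proba = small_ensemble.predict_proba(big.X)
        pos_col = int(
            np.nonzero(small_ensemble.classes_ == small_ensemble.positive_class)[0][0]
        )
        member_rates = [
            (m.model.predict(big.X) == small_ensemble.positive_class).mean()
            for m in small_ensemble.members
        ]
        assert min(member_rates) - 1e-12 <= proba[:, pos_col].mean() <= max(member_rates) + 1e-12


class TestVariableImportance:
    def test_informative_feature_dominates(self, small_ensemble, toy_data):
        train, _ = toy_data
        imp = small_ensemble.variable_importance(train.X, train.y, rng=0)
        assert imp[0] > 0
        assert imp[0] == imp.max()
        assert abs(imp[1]) <= 0.05  # pure-noise column: ~0 within MC noise

    def test_single_member_equals_error_difference(self, toy_data):
        train, _ = toy_data
        config = rb.EnsembleConfig(specs=(rb.make_spec("LDA"),), n_bootstrap=1, seed=6)
        model = rb.train_ensemble(train.X, train.y, config)
        member = model.members[0]
        oob = member.draw.oob
        rng = np.random.default_rng(0)
        imp = model.variable_importance(train.X, train.y, rng=0)
        base = (member.model.predict(train.X[oob]) != train.y[oob]).mean()
        Xp = train.X[oob].copy()
        Xp[:, 0] = Xp[rng.permutation(len(oob)), 0]
        manual = (member.model.predict(Xp) != train.y[oob]).mean() - base
        assert imp[0] == pytest.approx(manual)

    def test_feature_index_bounds(self, small_ensemble, toy_data):
        train, _ = toy_data
        with pytest.raises(ValueError):
            small_ensemble.variable_importance(train.X[:, :1], train.y)


def test_model_persistence_round_trip(tmp_path, small_ensemble, toy_data):
    _, test = toy_data
    path = tmp_path / "model.joblib"
    small_ensemble.save(path)
    back = rb.EnsembleModel.load(path)
    np.testing.assert_array_equal(back.predict(test.X), small_ensemble.predict(test.X))
    assert back.winner_ids() == small_ensemble.winner_ids()
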