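"""Health-grading network, max-voting, sparse-subset protocol."""

import numpy as np
import pandas as pd
import pytest

from embryoqpi import grading
from embryoqpi.grading import FBMConfig, FBMModel, PolicyError


def separable_dataset(n_per_class=500, seed=0, shift=4.0):
    rng = np.random.default_rng(seed)
    hi = rng.normal(0.0, 1.0, size=(n_per_class, 5))
    s = rng.normal(shift, 1.0, size=(n_per_class, 5))
    x = np.vstack([hi, s])
    y = np.array([0] * n_per_class + [1] * n_per_class)
    return x, y


class TestTrainFBM:
    def test_separable_classes_high_accuracy(self):
        x, y = separable_dataset(2000, seed=1)
        model = grading.train_fbm(x, y, FBMConfig(seed=7))
        x_test, y_test = separable_dataset(500, seed=2)
        pred = grading.predict_items(model, x_test)
        acc = ((pred.predicted_class == "S").to_numpy() == (y_test == 1)).mean()
        assert acc >= 0.95

    def test_ridge_shrinks_weights(self):
        x, y = separable_dataset(300, seed=3)
        small = grading.train_fbm(x, y, FBMConfig(seed=5, l2_lambda=1e-6))
        big = grading.train_fbm(x, y, FBMConfig(seed=5, l2_lambda=10.0))
        norm = lambda m: sum(float((w**2).sum()) for w in m.weights)
        assert norm(big) < norm(small)

    def test_deterministic_given_seed(self):
        x, y = separable_dataset(200, seed=4)
        m1 = grading.train_fbm(x, y, FBMConfig(seed=9))
        m2 = grading.train_fbm(x, y, FBMConfig(seed=9))
        for w1, w2 in zip(m1.weights, m2.weights):
            assert np.array_equal(w1, w2)

    def test_single_class_rejected(self):
        x = np.random.default_rng(0).normal(size=(50, 5))
        with pytest.raises(ValueError):
            grading.train_fbm(x, np.zeros(50, dtype=int))

    def test_nan_features_rejected(self):
        x, y = separable_dataset(30, seed=0)
        x[0, 0] = np.nan
        with pytest.raises(ValueError):
            grading.train_fbm(x, y)

    def test_json_round_trip(self):
        x, y = separable_dataset(100, seed=6)
        model = grading.train_fbm(x, y, FBMConfig(seed=1))
        restored = FBMModel.from_json(model.to_json())
        probs_a = model.predict_proba(x[:10])
        probs_b = restored.predict_proba(x[:10])
        assert np.allclose(probs_a, probs_b)


class TestPredictItems:
    def zero_model(self):
        sizes = grading._layer_sizes()
        return FBMModel(
            weights=[np.zeros(s) for s in sizes],
            biases=[np.zeros(s[1]) for s in sizes],
            feature_mean=np.zeros(5),
            feature_sd=np.ones(5),
        )

    def test_zero_weights_tie_resolves_to_hi(self):
        pred = grading.predict_items(self.zero_model(), np.ones((3, 5)))
        assert (pred.predicted_class == "HI").all()
        assert np.allclose(pred.score, 0.5)

    def test_batch_order_preserved(self):
        x, y = separable_dataset(200, seed=8)
        model = grading.train_fbm(x, y, FBMConfig(seed=2))
        pred_full = grading.predict_items(model, x)
        pred_rev = grading.predict_items(model, x[::-1])
        assert (pred_full.p_s.to_numpy()[::-1] == pred_rev.p_s.to_numpy()).all()

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError, match="missing feature columns"):
            grading.predict_items(self.zero_model(), pd.DataFrame({"bw3dB": [1.0]}))


def preds(classes, scores, z=None):
    df = pd.DataFrame(dict(predicted_class=classes, score=scores))
    if z is not None:
        df["z_um"] = z
    return df


class TestMaxVote:
    def test_majority_and_confidence(self):
        g = grading.max_vote(preds(["HI", "HI", "S"], [0.9, 0.8, 0.7]))
        assert g.predicted_class == "HI"
        assert g.cp == pytest.approx(0.85)
        assert g.majority_fraction == pytest.approx(2 / 3)
        assert not g.tie

    def test_all_sick(self):
        g = grading.max_vote(preds(["S"] * 4, [0.6, 0.7, 0.8, 0.9]))
        assert g.predicted_class == "S"
        assert g.cp == pytest.approx(0.75)

    def test_exact_tie_downgrades_to_sick(self):
        g = grading.max_vote(preds(["HI", "HI", "S", "S"], [0.9, 0.9, 0.6, 0.6]))
        assert g.predicted_class == "S"
        assert g.tie

    def test_permutation_invariance(self, rng):
        classes = ["HI"] * 5 + ["S"] * 3
        scores = list(rng.uniform(0.5, 1.0, 8))
        g1 = grading.max_vote(preds(classes, scores))
        order = rng.permutation(8)
        g2 = grading.max_vote(
            preds([classes[i] for i in order], [scores[i] for i in order])
        )
        assert g1.predicted_class == g2.predicted_class
        assert g1.cp == pytest.approx(g2.cp)

    def test_cp_within_majority_score_range(self, rng):
        scores = rng.uniform(0.5, 1.0, 9)
        g = grading.max_vote(preds(["HI"] * 6 + ["S"] * 3, scores))
        maj = scores[:6]
        assert maj.min() <= g.cp <= maj.max()

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            grading.max_vote(pd.DataFrame(columns=["predicted_class", "score"]))


class TestSparseVote:
    def full_stack(self, n=100, step=1.0):
        return preds(["HI"] * n, [0.9] * n, z=np.arange(n) * step)

    def test_ten_um_selection_proceeds(self):
        result, selected = grading.sparse_vote(self.full_stack(), step_um=10.0)
        assert 10 <= len(selected) <= 11
        assert result.predicted_class == "HI"

    def test_spacing_above_policy_rejected(self):
        with pytest.raises(PolicyError, match="exceeds"):
            grading.sparse_vote(self.full_stack(), step_um=15.0)

    def test_too_few_slices_rejected(self):
        with pytest.raises(PolicyError, match="policy requires"):
            grading.sparse_vote(self.full_stack(n=6), step_um=1.0)

    def test_force_overrides_policy(self):
        result, _ = grading.sparse_vote(self.full_stack(n=6), step_um=1.0, force=True)
        assert result.predicted_class == "HI"
        result, _ = grading.sparse_vote(self.full_stack(), step_um=15.0, force=True)
        assert result.predicted_class == "HI"

    def test_missing_z_rejected(self):
        with pytest.raises(ValueError):
            grading.sparse_vote(preds(["HI"] * 8, [0.9] * 8), step_um=5.0)


from hypothesis import given, settings, strategies as st  # noqa: E402


@settings(derandomize=True, deadline=None, max_examples=50)
@given(
    st.lists(
        st.tuples(st.sampled_from(["HI", "S"]), st.floats(0.5, 1.0)),
        min_size=1,
        max_size=15,
    ),
    st.randoms(use_true_random=False),
)
def test_max_vote_permutation_invariance_property(items, rnd):
    """The grade, confidence and majority fraction never depend on item order."""
    classes = [c for c, _ in items]
    scores = [s for _, s in items]
    base = grading.max_vote(preds(classes, scores))
    order = list(range(len(items)))
    rnd.shuffle(order)
    shuffled = grading.max_vote(
        preds([classes[i] for i in order], [scores[i] for i in order])
    )
    assert shuffled.predicted_class == base.predicted_class
    assert shuffled.cp == pytest.approx(base.cp)
    assert shuffled.majority_fraction == pytest.approx(base.majority_fraction)
    assert shuffled.tie == base.tie
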