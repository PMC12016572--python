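"""The single-hidden-node model: arithmetic, loss, training, scoring."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import spearmanr

from statescore import (
    BinaryMatrix,
    CellStateModel,
    FeatureModel,
    GeneUniverse,
    LabeledDataset,
    TrainConfig,
    class_weights,
    forward,
    loss,
    predict_state,
    score_cells,
    train_feature,
)
from statescore.errors import (
    TrainingError,
    UniverseMismatchError,
    ValidationError,
)

from conftest import TRAIN_SEED


class TestClassWeights:
    @pytest.mark.parametrize(
        "n0, n1, expected",
        [
            (50, 50, (1.0, 1.0)),
            (90, 10, (100 / 180, 100 / 20)),
            (10, 90, (100 / 20, 100 / 180)),
        ],
    )
    def test_balanced_formula(self, n0, n1, expected):
        labels = np.array([0] * n0 + [1] * n1)
        np.testing.assert_allclose(class_weights(labels), expected)

    def test_single_class_rejected(self):
        with pytest.raises(TrainingError):
            class_weights(np.ones(10, dtype=int))


class TestForward:
    def test_zero_weights_give_softmax_of_output_bias(self, toy_model):
        m = dataclasses.replace(toy_model, w=np.zeros(3), b=0.0)
        z, h, p = forward(m, np.array([1, 1, 1]))
        assert z == 0 and h == 0
        expect = np.exp(m.c) / np.exp(m.c).sum()
        np.testing.assert_allclose(p, expect)

    def test_preactivation_arithmetic(self, toy_model):
        # w = (1, -1, 0), b = 0.5, g = (1, 1, 0) -> z = 0.5
        z, h, _ = forward(toy_model, np.array([1, 1, 0]))
        assert z == pytest.approx(0.5)
        assert h == pytest.approx(0.5)

    def test_relu_clips_negative_preactivation(self, toy_model):
        m = dataclasses.replace(toy_model, w=np.array([-2.0, 0.0, 0.0]), b=0.0)
        z1, h1, p1 = forward(m, np.array([1, 0, 0]))
        m2 = dataclasses.replace(m, w=np.array([-50.0, 0.0, 0.0]))
        z2, h2, p2 = forward(m2, np.array([1, 0, 0]))
        assert h1 == h2 == 0.0
        np.testing.assert_allclose(p1, p2)  # p independent of |z| below 0

    def test_non_binary_input_rejected(self, toy_model):
        with pytest.raises(ValidationError):
            forward(toy_model, np.array([0.5, 0, 1]))

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=25, deadline=None)
    def test_probabilities_sum_to_one(self, seed):
        rng = np.random.default_rng(seed)
        uni = GeneUniverse(tuple(f"g{i}" for i in range(6)))
        m = FeatureModel(
            universe=uni,
            w=rng.normal(size=6),
            b=float(rng.normal()),
            v=rng.normal(size=2),
            c=rng.normal(size=2),
        )
        g = rng.integers(0, 2, size=(4, 6))
        _, _, p = forward(m, g)
        np.testing.assert_allclose(p.sum(axis=-1), 1.0, atol=1e-12)


class TestLoss:
    def test_confident_correct_prediction_drives_loss_to_zero(self, toy_model):
        # huge positive logit gap toward the true class, no weights to penalize
        m = dataclasses.replace(
            toy_model, w=np.zeros(3), b=5.0, v=np.array([-50.0, 50.0]), c=np.zeros(2)
        )
        val = loss(m, np.ones((2, 3)), np.array([1, 1]), np.ones(2), 0.0)
        assert val == pytest.approx(0.0, abs=1e-6)

    def test_uniform_prediction_is_ln2(self, toy_model):
        m = dataclasses.replace(
            toy_model, w=np.zeros(3), b=0.0, v=np.zeros(2), c=np.zeros(2)
        )
        val = loss(m, np.ones((4, 3)), np.array([0, 1, 0, 1]), np.ones(2), 0.0)
        assert val == pytest.approx(math.log(2))

    def test_l1_term_adds_coefficient_times_weight_norm(self, toy_model):
        m = dataclasses.replace(
            toy_model, w=np.array([1.0, -1.0, 1.0]), v=np.zeros(2), c=np.zeros(2)
        )
        batch, y, cw = np.ones((2, 3)), np.array([0, 1]), np.ones(2)
        base = loss(m, batch, y, cw, 0.0)
        assert loss(m, batch, y, cw, 0.01) == pytest.approx(base + 0.03)

    def test_loss_never_nan_at_extreme_confidence(self, toy_model):
        m = dataclasses.replace(
            toy_model, w=np.zeros(3), b=5.0, v=np.array([500.0, -500.0]), c=np.zeros(2)
        )
        # label 1 receives numerically zero probability -> clamped, finite
        val = loss(m, np.ones((1, 3)), np.array([1]), np.ones(2), 0.0)
        assert np.isfinite(val) and val > 0


class TestScoreCells:
    def test_all_zero_cell_scores_orientation_times_bias(self, toy_model):
        bm = BinaryMatrix(["c0"], toy_model.universe, np.zeros((1, 3), dtype=int))
        assert score_cells(toy_model, bm).values[0] == pytest.approx(0.5)
        flipped = dataclasses.replace(toy_model, orientation=-1)
        assert score_cells(flipped, bm).values[0] == pytest.approx(-0.5)

    def test_dot_product_example(self):
        uni = GeneUniverse(("a", "b"))
        m = FeatureModel(uni, np.array([2.0, -1.0]), 0.0, np.zeros(2), np.zeros(2))
        bm = BinaryMatrix(["c0"], uni, np.array([[1, 1]]))
        assert score_cells(m, bm).values[0] == pytest.approx(1.0)

    def test_matches_loop_oracle_on_random_cells(self):
        rng = np.random.default_rng(3)
        uni = GeneUniverse(tuple(f"g{i}" for i in range(30)))
        m = FeatureModel(
            uni, rng.normal(size=30), float(rng.normal()), np.zeros(2), np.zeros(2),
            orientation=-1,
        )
        g = rng.integers(0, 2, size=(100, 30))
        bm = BinaryMatrix([f"c{i}" for i in range(100)], uni, g)
        got = score_cells(m, bm).values
        for i in range(100):
            expected = sum(m.w[j] * g[i, j] for j in range(30)) + m.b
            assert got[i] == pytest.approx(m.orientation * expected, rel=1e-9)

    def test_universe_mismatch_names_the_fix(self, toy_model):
        other = GeneUniverse(("X", "Y", "Z"))
        bm = BinaryMatrix(["c0"], other, np.zeros((1, 3), dtype=int))
        with pytest.raises(UniverseMismatchError, match="align_and_binarize"):
            score_cells(toy_model, bm)


class TestPredictState:
    def test_zero_output_weights_give_constant_probability(self, toy_model):
        m = dataclasses.replace(toy_model, v=np.zeros(2))
        rng = np.random.default_rng(0)
        bm = BinaryMatrix(
            [f"c{i}" for i in range(5)],
            m.universe,
            rng.integers(0, 2, size=(5, 3)),
        )
        p = predict_state(m, bm).values
        expect = np.exp(m.c[1]) / np.exp(m.c).sum()
        np.testing.assert_allclose(p, expect)

    def test_probabilities_complement_to_one(self, toy_model):
        rng = np.random.default_rng(1)
        g = rng.integers(0, 2, size=(10, 3))
        _, _, p = forward(toy_model, g)
        np.testing.assert_allclose(p[:, 0] + p[:, 1], 1.0, atol=1e-12)

    def test_monotone_in_score_on_trained_model(self, fitted, holdout_sim):
        params = fitted.params
        # effective slope of p(state1) along the oriented score
        assert params.orientation * (params.v[1] - params.v[0]) > 0
        sc = fitted.score(holdout_sim.dataset.matrix).values
        p = fitted.predict_state(holdout_sim.dataset.matrix).values
        order = np.argsort(sc, kind="stable")
        assert np.all(np.diff(p[order]) >= -1e-12)


class TestTraining:
    def test_single_class_data_rejected(self):
        uni = GeneUniverse(("a", "b"))
        bm = BinaryMatrix(["c0", "c1"], uni, np.array([[0, 1], [1, 0]]))
        with pytest.raises(TrainingError):
            train_feature(LabeledDataset(bm, np.array([1, 1])), TrainConfig())

    def test_identical_seed_gives_bit_identical_fit(self, default_sim):
        cfg = TrainConfig(seed=11, max_epochs=8)
        m1, h1 = train_feature(default_sim.dataset, cfg)
        m2, h2 = train_feature(default_sim.dataset, cfg)
        np.testing.assert_array_equal(m1.w, m2.w)
        assert m1.b == m2.b
        np.testing.assert_array_equal(m1.v, m2.v)
        assert h1.train_loss == h2.train_loss
        assert h1.val_loss == h2.val_loss

    def test_history_bounded_by_max_epochs(self, default_sim):
        _, h = train_feature(default_sim.dataset, TrainConfig(seed=0, max_epochs=5))
        assert 1 <= h.n_epochs <= 5

    def test_orientation_invariant_holds(self, default_sim, fitted):
        sc = fitted.score().values
        y = default_sim.labels
        assert sc[y == 1].mean() > sc[y == 0].mean()

    def test_duplicated_cells_preserve_weight_ordering(self):
        from statescore import SyntheticSpec, simulate_labeled

        sim = simulate_labeled(
            SyntheticSpec(n_genes=300, n_up=20, n_down=20,
                          n_cells_per_state=(150, 150), seed=5)
        )
        data = sim.dataset
        doubled = LabeledDataset(
            BinaryMatrix(
                [f"{c}_dup{k}" for k in (0, 1) for c in data.matrix.cell_ids],
                data.matrix.universe,
                np.vstack([data.matrix.g, data.matrix.g]),
            ),
            np.concatenate([data.labels, data.labels]),
        )
        cfg = TrainConfig(seed=2, max_epochs=60)
        m1, _ = train_feature(data, cfg)
        m2, _ = train_feature(doubled, cfg)
        # background weights sit at ~0 under L1 and carry no stable order,
        # so compare where the model carries information: the planted genes
        # and the resulting top-gene lists
        planted = sim.truth.s_up + sim.truth.s_down
        symbols = list(sim.truth.universe.symbols)
        idx = [symbols.index(g) for g in planted]
        rho = spearmanr(
            m1.orientation * m1.w[idx], m2.orientation * m2.w[idx]
        ).statistic
        assert rho > 0.9
        from statescore import rank_weights, top_weights

        p1, _ = top_weights(rank_weights(m1), n=20, side="both")
        p2, _ = top_weights(rank_weights(m2), n=20, side="both")
        assert len(set(p1) & set(p2)) / 20 >= 0.8

    def test_l1_shrinks_background_weights_monotonically(self):
        from statescore import SyntheticSpec, simulate_labeled

        sim = simulate_labeled(
            SyntheticSpec(n_genes=400, n_up=20, n_down=20,
                          n_cells_per_state=(200, 200), seed=3)
        )
        planted = set(sim.truth.s_up) | set(sim.truth.s_down)
        bg = [s not in planted for s in sim.truth.universe.symbols]
        medians = []
        for l1 in (0.0, 0.01, 0.1):
            m, _ = train_feature(
                sim.dataset, TrainConfig(seed=4, l1_coefficient=l1, max_epochs=40)
            )
            medians.append(np.median(np.abs(m.w[bg])))
        assert medians[0] >= medians[1] >= medians[2]


class TestStatsmodelsSurface:
    def test_from_dataframe_round_trip(self, default_sim):
        # slice spanning the state0/state1 boundary so both classes appear
        df = default_sim.dataset.matrix.to_frame().iloc[470:530, :50]
        labels = default_sim.labels[470:530]
        res = CellStateModel.from_dataframe(df, labels).fit(
            seed=TRAIN_SEED, max_epochs=5
        )
        assert len(res.weights) == 50
        assert res.params.orientation in (1, -1)

    def test_summary_mentions_fit_facts(self, fitted):
        text = fitted.summary()
        assert "planted" in text
        assert "Orientation" in text
        assert "2000" in text  # universe size
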