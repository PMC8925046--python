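"""Latent ranking model: sampling, loss, gradients, training, augmentation."""

import math

import numpy as np
import pytest

import microrank as mr
from microrank.model import (
    GroupSample,
    TrainingConfig,
    _TrainIndex,
    augment_with_similarity,
    combined_preference,
    group_preference,
    init_model,
    predict_scores,
    rank_microbes_for_disease,
    raw_score,
    sample_loss,
    sample_quadruple,
    sgd_step,
    train,
)


def _zero_model(nm, nd, z=4):
    return mr.LatentModel(np.zeros((nm, z)), np.zeros((nd, z)), np.zeros(nd))


def _random_model(rng, nm, nd, z=4, scale=0.5):
    return mr.LatentModel(
        rng.normal(scale=scale, size=(nm, z)),
        rng.normal(scale=scale, size=(nd, z)),
        rng.normal(scale=scale, size=nd),
    )


class TestConfig:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"z": 0},
            {"group_size": 0},
            {"rho": 1.5},
            {"gamma": -0.1},
            {"group_axis": "both"},
            {"iterations": -1},
        ],
    )
    def test_invalid_values_rejected(self, kwargs):
        with pytest.raises(ValueError):
            TrainingConfig(**kwargs)

    def test_defaults(self):
        cfg = TrainingConfig()
        assert (cfg.z, cfg.group_size, cfg.rho) == (30, 5, 0.5)
        assert (cfg.gamma, cfg.iterations) == (0.01, 100)


class TestInitModel:
    def test_seeded_determinism(self):
        cfg = TrainingConfig(seed=11)
        a = init_model(5, 3, cfg)
        b = init_model(5, 3, cfg)
        assert np.array_equal(a.U, b.U) and np.array_equal(a.V, b.V)

    def test_zero_scale_gives_zero_scores(self, toy_dataset):
        cfg = TrainingConfig(init_scale=0.0, seed=0)
        model = init_model(toy_dataset.nm, toy_dataset.nd, cfg)
        scores = predict_scores(model, toy_dataset)
        assert np.all(scores.values == 0.0)

    def test_distinct_seeds_differ(self):
        a = init_model(5, 3, TrainingConfig(seed=1))
        b = init_model(5, 3, TrainingConfig(seed=2))
        assert not np.array_equal(a.U, b.U)


class TestPreferences:
    def test_singleton_group_equals_individual(self, rng):
        model = _random_model(rng, 4, 3)
        assert group_preference(model, (2,), 1) == pytest.approx(
            raw_score(model, 1, 2)
        )

    def test_zero_model_group_preference_is_bias(self):
        model = _zero_model(4, 3)
        model.b[1] = 0.7
        assert group_preference(model, (0, 2), 1) == pytest.approx(0.7)

    def test_group_mean_of_two_members(self):
        model = _zero_model(2, 1, z=1)
        model.U[:, 0] = [0.2, 0.4]
        model.V[0, 0] = 1.0
        assert group_preference(model, (0, 1), 0) == pytest.approx(0.3)

    @pytest.mark.parametrize("rho,expected", [(0.0, 0.4), (1.0, 0.2), (0.5, 0.3)])
    def test_combined_preference_blend(self, rho, expected, monkeypatch):
        model = _zero_model(2, 2, z=1)
        monkeypatch.setattr(
            "microrank.model.group_preference", lambda m, g, d: 0.2
        )
        monkeypatch.setattr(
            "microrank.model.raw_score", lambda m, d, i: 0.4
        )
        assert combined_preference(model, (0,), 0, 0, rho) == pytest.approx(expected)


class TestSampling:
    def test_group_capped_by_known_microbes(self, toy_dataset, rng):
        cfg = TrainingConfig(group_size=10, seed=0)
        for _ in range(50):
            s = sample_quadruple(toy_dataset, rng, cfg)
            known = set(np.flatnonzero(toy_dataset.matrix[:, s.d]))
            assert set(s.group) == known  # group_size exceeds every |M_d|

    def test_axis_none_always_singleton(self, toy_dataset, rng):
        cfg = TrainingConfig(group_axis="none", seed=0)
        for _ in range(20):
            s = sample_quadruple(toy_dataset, rng, cfg)
            assert s.group == (s.i,)

    def test_positive_pairs_uniform(self, rng):
        matrix = np.array([[1, 1, 0], [0, 1, 1], [1, 0, 1]])
        data = mr.AssociationDataset(["a", "b", "c"], ["x", "y", "z"], matrix)
        cfg = TrainingConfig(group_size=1, seed=0)
        n_draws = 10_000
        counts = {}
        for _ in range(n_draws):
            s = sample_quadruple(data, rng, cfg)
            counts[(s.i, s.d)] = counts.get((s.i, s.d), 0) + 1
        p = 1 / 6
        sigma = math.sqrt(n_draws * p * (1 - p))
        for pair in map(tuple, data.positives()):
            assert abs(counts.get(pair, 0) - n_draws * p) < 3 * sigma

    def test_saturated_microbe_resampled(self, rng):
        # m1 is associated with every disease; m2 leaves room for a negative
        matrix = np.array([[1, 1], [1, 0]])
        data = mr.AssociationDataset(["m1", "m2"], ["d1", "d2"], matrix)
        cfg = TrainingConfig(group_size=1, seed=0)
        for _ in range(50):
            s = sample_quadruple(data, rng, cfg)
            assert s.i == 1  # only m2 admits a negative disease

    def test_all_saturated_errors(self, rng):
        data = mr.AssociationDataset(["m1", "m2"], ["d1"], np.ones((2, 1)))
        with pytest.raises(RuntimeError, match="sample"):
            sample_quadruple(data, rng, TrainingConfig(seed=0))

    def test_negative_never_positive_for_anchor(self, toy_dataset, rng):
        cfg = TrainingConfig(seed=0)
        for _ in range(100):
            s = sample_quadruple(toy_dataset, rng, cfg)
            assert toy_dataset.matrix[s.i, s.neg] == 0
            assert toy_dataset.matrix[s.i, s.d] == 1


class TestSampleLoss:
    def test_zero_model_no_reg_is_ln2(self):
        model = _zero_model(3, 3)
        cfg = TrainingConfig(alpha_u=0, alpha_v=0, beta_v=0, seed=0)
        sample = GroupSample(0, 0, 1, (0, 2))
        assert sample_loss(model, sample, cfg) == pytest.approx(math.log(2))

    def test_large_margin_leaves_regularization_only(self):
        model = _zero_model(2, 2, z=1)
        model.U[0, 0] = 100.0
        model.V[0, 0] = 100.0  # huge positive margin
        cfg = TrainingConfig(alpha_u=0.02, alpha_v=0.04, beta_v=0.06, seed=0)
        sample = GroupSample(0, 0, 1, (0,))
        reg = 0.02 / 2 * 100.0**2 + 0.04 / 2 * 100.0**2
        assert sample_loss(model, sample, cfg) == pytest.approx(reg, rel=1e-6)

    def test_hand_symbolic_evaluation(self):
        # 2 microbes, 2 diseases, z=1; every quantity written out by hand
        model = mr.LatentModel(
            np.array([[0.3], [-0.2]]),
            np.array([[0.5], [0.1]]),
            np.array([0.05, -0.1]),
        )
        cfg = TrainingConfig(
            rho=0.4, alpha_u=0.01, alpha_v=0.02, beta_v=0.03, seed=0
        )
        sample = GroupSample(0, 0, 1, (0, 1))
        r_gd = ((0.3 * 0.5) + (-0.2 * 0.5)) / 2 + 0.05
        r_id = 0.3 * 0.5 + 0.05
        r_gid = 0.4 * r_gd + 0.6 * r_id
        r_ib = 0.3 * 0.1 - 0.1
        expected = math.log1p(math.exp(-(r_gid - r_ib)))
        expected += 0.01 / 2 * (0.3**2 + 0.2**2)
        expected += 0.02 / 2 * (0.5**2 + 0.1**2)
        expected += 0.03 / 2 * (0.05**2 + 0.1**2)
        assert sample_loss(model, sample, cfg) == pytest.approx(expected, abs=1e-12)


def _numeric_gradient(model, sample, cfg, h=1e-6):
    """Central finite differences of sample_loss over every parameter."""
    grads = {}
    for name in ("U", "V", "b"):
        arr = getattr(model, name)
        g = np.zeros_like(arr)
        it = np.nditer(arr, flags=["multi_index"])
        for _ in it:
            idx = it.multi_index
            orig = arr[idx]
            arr[idx] = orig + h
            up = sample_loss(model, sample, cfg)
            arr[idx] = orig - h
            down = sample_loss(model, sample, cfg)
            arr[idx] = orig
            g[idx] = (up - down) / (2 * h)
        grads[name] = g
    return grads


def _analytic_gradient(model, sample, cfg):
    """Recover the analytic gradient from one SGD step at known gamma."""
    before = model.copy()
    stepped = sgd_step(model.copy(), sample, cfg)
    return {
        name: (getattr(before, name) - getattr(stepped, name)) / cfg.gamma
        for name in ("U", "V", "b")
    }


@pytest.mark.parametrize("axis", ["microbe", "disease", "none"])
def test_gradient_matches_finite_differences(axis):
    """Analytic SGD gradients agree with central differences on random models."""
    rng = np.random.default_rng(99)
    for trial in range(35):
        nm, nd, z = rng.integers(3, 7), rng.integers(3, 6), rng.integers(1, 5)
        cfg = TrainingConfig(
            z=int(z),
            rho=float(rng.uniform(0, 1)),
            alpha_u=float(rng.uniform(0, 0.1)),
            alpha_v=float(rng.uniform(0, 0.1)),
            beta_v=float(rng.uniform(0, 0.1)),
            gamma=1.0,
            group_axis=axis,
            group_size=int(rng.integers(1, 4)),
            seed=int(trial),
        )
        model = _random_model(rng, nm, nd, z=int(z))
        matrix = (rng.random((nm, nd)) < 0.5).astype(int)
        matrix[0, 0] = 1
        matrix[1, -1] = 0
        try:
            data = mr.AssociationDataset(
                [f"m{i}" for i in range(nm)], [f"d{j}" for j in range(nd)], matrix
            )
            sample = sample_quadruple(data, rng, cfg)
        except RuntimeError:
            continue
        numeric = _numeric_gradient(model.copy(), sample, cfg)
        analytic = _analytic_gradient(model, sample, cfg)
        for name in ("U", "V", "b"):
            denom = np.maximum(np.abs(numeric[name]), 1e-3)
            rel = np.abs(analytic[name] - numeric[name]) / denom
            assert rel.max() < 1e-4, f"{name} gradient off for axis={axis}"


class TestSgdStep:
    def test_zero_learning_rate_is_noop(self, rng):
        model = _random_model(rng, 4, 3)
        before = model.copy()
        cfg = TrainingConfig(gamma=0.0, seed=0)
        sgd_step(model, GroupSample(0, 0, 1, (0, 2)), cfg)
        assert np.array_equal(model.U, before.U)
        assert np.array_equal(model.V, before.V)

    def test_step_decreases_sample_loss(self, rng):
        cfg = TrainingConfig(gamma=0.01, seed=0)
        sample = GroupSample(0, 0, 1, (0, 2))
        for _ in range(10):
            model = _random_model(rng, 4, 3)
            before = sample_loss(model, sample, cfg)
            sgd_step(model, sample, cfg)
            assert sample_loss(model, sample, cfg) < before

    def test_untouched_parameters_stay(self, rng):
        model = _random_model(rng, 5, 4)
        before = model.copy()
        cfg = TrainingConfig(seed=0)
        sgd_step(model, GroupSample(0, 0, 1, (0, 2)), cfg)
        assert np.array_equal(model.U[3], before.U[3])  # not in group
        assert np.array_equal(model.V[2], before.V[2])  # neither d nor neg


class TestTrain:
    def test_seeded_determinism(self, toy_dataset):
        cfg = TrainingConfig(iterations=5, seed=42)
        a = train(toy_dataset, cfg)
        b = train(toy_dataset, cfg)
        assert np.array_equal(a.U, b.U)
        assert np.array_equal(a.V, b.V)
        assert np.array_equal(a.b, b.b)

    def test_zero_iterations_returns_init(self, toy_dataset):
        cfg = TrainingConfig(iterations=0, seed=3)
        model = train(toy_dataset, cfg)
        rng = np.random.default_rng(3)
        expected = init_model(toy_dataset.nm, toy_dataset.nd, cfg, rng)
        assert np.array_equal(model.U, expected.U)

    def test_recovers_planted_blocks(self):
        spec = mr.SyntheticSpec(nm=24, nd=8, p_in=0.8, p_out=0.02, seed=2)
        data, mb, db = mr.make_network(spec)
        cfg = TrainingConfig(iterations=60, seed=2)
        model = train(data, cfg)
        scores = predict_scores(model, data).values  # nd x nm
        same = db[:, None] == mb[None, :]
        assert scores[same].mean() > scores[~same].mean()


class TestPredictScores:
    def test_zero_model_rows_constant_at_bias(self, toy_dataset):
        model = _zero_model(toy_dataset.nm, toy_dataset.nd)
        model.b[:] = [0.1, -0.2, 0.3]
        scores = predict_scores(model, toy_dataset)
        for j, bias in enumerate(model.b):
            assert np.all(scores.values[j] == bias)

    def test_rank_one_hand_model(self):
        data = mr.AssociationDataset(["m1", "m2"], ["d1", "d2"], np.eye(2))
        model = mr.LatentModel(
            np.array([[2.0], [3.0]]), np.array([[0.5], [-1.0]]), np.array([0.0, 1.0])
        )
        scores = predict_scores(model, data)
        assert scores.values.tolist() == [[1.0, 1.5], [-1.0, -2.0]]

    def test_bias_shift_covariance(self, toy_dataset, rng):
        model = _random_model(rng, toy_dataset.nm, toy_dataset.nd)
        base = predict_scores(model, toy_dataset).values.copy()
        model.b[1] += 0.25
        shifted = predict_scores(model, toy_dataset).values
        assert np.allclose(shifted[1], base[1] + 0.25)
        assert np.allclose(shifted[0], base[0])


class TestAugmentation:
    def test_zero_weights_unchanged(self, toy_dataset, rng, planted_similarities):
        sd, sm = planted_similarities
        model = _random_model(rng, toy_dataset.nm, toy_dataset.nd)
        scores = predict_scores(model, toy_dataset)
        sd_toy = mr.SimilarityMatrix(toy_dataset.disease_names, np.eye(3))
        sm_toy = mr.SimilarityMatrix(toy_dataset.microbe_names, np.eye(4))
        out = augment_with_similarity(
            scores, toy_dataset, sd_toy, sm_toy, alpha_d=0.0, alpha_m=0.0
        )
        assert np.array_equal(out.values, scores.values)

    def test_single_neighbor_mean(self):
        # m2's only training disease has similarity 1 to d1 -> score += 0.5
        data = mr.AssociationDataset(
            ["m1", "m2"], ["d1", "d2"], np.array([[1, 0], [0, 1]])
        )
        sd = mr.SimilarityMatrix(["d1", "d2"], np.array([[1.0, 1.0], [1.0, 1.0]]))
        scores = mr.ScoreMatrix(["d1", "d2"], ["m1", "m2"], np.zeros((2, 2)))
        out = augment_with_similarity(scores, data, sd, None, alpha_d=0.5)
        assert out.values[0, 1] == pytest.approx(0.5)

    def test_microbe_without_training_assoc_gets_only_disease_term(self):
        data = mr.AssociationDataset(
            ["m1", "m2"], ["d1"], np.array([[1], [0]])
        )
        sd = mr.SimilarityMatrix(["d1"], np.array([[1.0]]))
        sm = mr.SimilarityMatrix(["m1", "m2"], np.array([[1.0, 0.8], [0.8, 1.0]]))
        scores = mr.ScoreMatrix(["d1"], ["m1", "m2"], np.zeros((1, 2)))
        out = augment_with_similarity(scores, data, sd, sm, 0.5, 0.5)
        # m2 has no training diseases: alpha_d term is 0 for it,
        # alpha_m term uses d1's known microbe m1 with similarity 0.8
        assert out.values[0, 1] == pytest.approx(0.5 * 0.8)

    def test_additive_and_order_independent(self, toy_dataset, rng):
        model = _random_model(rng, toy_dataset.nm, toy_dataset.nd)
        scores = predict_scores(model, toy_dataset)
        sd = mr.SimilarityMatrix(toy_dataset.disease_names, np.eye(3))
        sm = mr.SimilarityMatrix(toy_dataset.microbe_names, np.eye(4))
        both = augment_with_similarity(scores, toy_dataset, sd, sm, 0.5, 0.5)
        d_only = augment_with_similarity(scores, toy_dataset, sd, None, 0.5, 0.0)
        m_only = augment_with_similarity(scores, toy_dataset, None, sm, 0.0, 0.5)
        np.testing.assert_allclose(
            both.values, d_only.values + m_only.values - scores.values
        )

    def test_uncovered_label_errors(self, toy_dataset, rng):
        model = _random_model(rng, toy_dataset.nm, toy_dataset.nd)
        scores = predict_scores(model, toy_dataset)
        bad_sd = mr.SimilarityMatrix(["d1", "d2"], np.eye(2))  # missing d3
        with pytest.raises(KeyError, match="d3"):
            augment_with_similarity(scores, toy_dataset, bad_sd, None)


class TestRanking:
    def test_descending_order(self):
        scores = mr.ScoreMatrix(
            ["d1"], ["m1", "m2", "m3"], np.array([[0.9, 0.1, 0.5]])
        )
        ranked = rank_microbes_for_disease(scores, "d1")
        assert [m for m, _ in ranked] == ["m1", "m3", "m2"]

    def test_tie_breaks_lexicographic(self):
        scores = mr.ScoreMatrix(["d1"], ["mb", "ma"], np.array([[0.5, 0.5]]))
        ranked = rank_microbes_for_disease(scores, "d1")
        assert [m for m, _ in ranked] == ["ma", "mb"]

    def test_exclude_train_leaves_singleton(self):
        data = mr.AssociationDataset(
            ["m1", "m2", "m3"], ["d1"], np.array([[1], [1], [0]])
        )
        scores = mr.ScoreMatrix(["d1"], ["m1", "m2", "m3"], np.array([[3.0, 2.0, 1.0]]))
        ranked = rank_microbes_for_disease(
            scores, "d1", exclude_train=True, dataset_train=data
        )
        assert ranked == [("m3", 1.0)]

    def test_unknown_disease_errors(self):
        scores = mr.ScoreMatrix(["d1"], ["m1"], np.array([[0.0]]))
        with pytest.raises(KeyError):
            rank_microbes_for_disease(scores, "nope")
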