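import numpy as np
import pytest

import _oracles
from hybridbci.classifier import (SolverSettings, decision_value,
                                  logistic_objective, predict,
                                  project_nuclear_ball, spectrum, topography,
                                  train)
from hybridbci.core import CHANNELS, DataError, DSModel, ParameterError


def _model(blocks, b=0.0, C=100.0):
    return DSModel(blocks=[np.asarray(B, dtype=float) for B in blocks], b=b,
                   C=C, block_dims=tuple(np.shape(B) for B in blocks))


class TestDecisionValue:
    def test_zero_weights_return_bias(self):
        m = _model([np.zeros((3, 2))], b=0.5)
        assert decision_value(m, np.ones((3, 2))) == 0.5

    def test_single_entry_product(self):
        W = np.zeros((3, 2)); W[0, 0] = 2.0
        x = np.zeros((3, 2)); x[0, 0] = 3.0
        assert decision_value(_model([W]), x) == 6.0

    def test_matches_double_loop(self):
        rng = np.random.default_rng(0)
        W = rng.standard_normal((5, 4))
        x = rng.standard_normal((5, 4))
        m = _model([W], b=0.3)
        brute = sum(W[j, k] * x[j, k] for j in range(5) for k in range(4)) + 0.3
        assert abs(decision_value(m, x) - brute) < 1e-10


class TestPredict:
    def test_tie_maps_to_plus_one(self):
        m = _model([np.zeros((2, 2))], b=0.0)
        assert predict(m, np.ones((2, 2))) == 1

    def test_strictly_negative_is_minus_one(self):
        m = _model([np.zeros((2, 2))], b=-1e-12)
        assert predict(m, np.zeros((2, 2))) == -1

    def test_negation_flips_nontied_labels(self):
        rng = np.random.default_rng(1)
        W = rng.standard_normal((3, 3))
        m = _model([W], b=0.2)
        neg = _model([-W], b=-0.2)
        for _ in range(10):
            x = rng.standard_normal((3, 3))
            assert predict(neg, x) == -predict(m, x)


class TestLogisticObjective:
    def test_zero_model_gives_log_two(self):
        rng = np.random.default_rng(2)
        X = [rng.standard_normal((3, 2)) for _ in range(8)]
        y = [1, -1] * 4
        m = _model([np.zeros((3, 2))])
        assert np.isclose(logistic_objective(m, X, y), np.log(2.0))

    def test_perfect_separation_vanishes(self):
        W = np.zeros((2, 2)); W[0, 0] = 100.0
        m = _model([W])
        x = np.zeros((2, 2)); x[0, 0] = 1.0
        assert logistic_objective(m, [x, -x], [1, -1]) < 1e-40

    def test_matches_per_sample_evaluation(self):
        rng = np.random.default_rng(3)
        X = [rng.standard_normal((4, 3)) for _ in range(6)]
        y = np.array([1, 1, -1, 1, -1, -1])
        W = rng.standard_normal((4, 3))
        m = _model([W], b=-0.4)
        naive = np.mean([np.log1p(np.exp(-yi * (np.sum(W * xi) - 0.4)))
                         for xi, yi in zip(X, y)])
        assert abs(logistic_objective(m, X, y) - naive) < 1e-12


class TestProjection:
    def test_interior_point_unchanged(self):
        A = np.diag([0.5, 0.3])
        assert np.array_equal(project_nuclear_ball(A, 2.0), A)

    def test_diag_3_1_radius_2(self):
        out = project_nuclear_ball(np.diag([3.0, 1.0]), 2.0)
        assert np.allclose(out, np.diag([2.0, 0.0]), atol=1e-12)

    def test_matches_convex_oracle_on_random_draws(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            A = rng.standard_normal((5, 4)) * rng.uniform(0.3, 3.0)
            for C in (0.5, 1.0, 2.0):
                d = np.linalg.norm(project_nuclear_ball(A, C)
                                   - _oracles.project_nuclear_oracle(A, C))
                assert d < 1e-6

    def test_idempotent_and_nonexpansive(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            A, B = rng.standard_normal((2, 6, 4))
            C = 1.5
            PA, PB = project_nuclear_ball(A, C), project_nuclear_ball(B, C)
            assert np.allclose(project_nuclear_ball(PA, C), PA, atol=1e-10)
            assert (np.linalg.norm(PA - PB, "fro")
                    <= np.linalg.norm(A - B, "fro") + 1e-10)


def _toy_problem(seed=0, N=20, shape=(4, 3), sep=0.5):
    rng = np.random.default_rng(seed)
    y = np.array([1] * (N // 2) + [-1] * (N - N // 2), dtype=float)
    proto = rng.standard_normal(shape)
    X = rng.standard_normal((N, *shape)) + sep * y[:, None, None] * proto
    return list(X), y


class TestTrain:
    def test_vanishing_budget_recovers_intercept_only_logit(self):
        X, _ = _toy_problem(seed=6, N=20)
        y = np.array([1] * 15 + [-1] * 5, dtype=float)
        m = train(X, y, C=1e-8, block_dims=((4, 3),))
        assert np.max(np.abs(m.W)) < 1e-6
        assert np.isclose(m.b, np.log(15 / 5), atol=1e-3)

    def test_separable_toy_reaches_perfect_training_accuracy(self):
        X, y = _toy_problem(seed=7, sep=3.0)
        m = train(X, y, C=50.0, block_dims=((4, 3),))
        preds = [predict(m, x) for x in X]
        assert np.array_equal(preds, y)

    def test_objective_trace_is_monotone(self):
        X, y = _toy_problem(seed=8)
        m = train(X, y, C=1.0, block_dims=((4, 3),))
        trace = np.asarray(m.objective_trace)
        assert np.all(np.diff(trace) <= 1e-15)

    def test_feasibility_after_training(self):
        X, y = _toy_problem(seed=9)
        for C in (0.3, 1.0, 4.0):
            m = train(X, y, C=C, block_dims=((4, 3),))
            assert m.nuclear_norm() <= C * (1 + 1e-6)

    def test_single_class_rejected(self):
        X, _ = _toy_problem(seed=10)
        with pytest.raises(DataError):
            train(X, np.ones(len(X)), C=1.0, block_dims=((4, 3),))

    def test_invalid_settings_rejected(self):
        with pytest.raises(ParameterError):
            SolverSettings(tol_obj=0.5)

    def test_rank_nonincreasing_along_shrinking_budget(self):
        X, y = _toy_problem(seed=11, N=30, shape=(5, 4), sep=0.8)
        ranks = []
        for C in (8.0, 4.0, 2.0, 1.0, 0.5, 0.1):
            m = train(X, y, C=C, block_dims=((5, 4),),
                      settings=SolverSettings(max_iter=5000, tol_obj=1e-9))
            ranks.append(spectrum(m).rank)
        assert all(r2 <= r1 for r1, r2 in zip(ranks, ranks[1:]))

    def test_block_diagonal_trainer_matches_unrestricted_oracle(self):
        # pinching: with block-diagonal inputs, restricting W to the blocks
        # loses nothing against the full-matrix optimum
        rng = np.random.default_rng(12)
        N = 20
        y = np.array([1] * 10 + [-1] * 10, dtype=float)
        B1 = rng.standard_normal((N, 3, 2)) + 0.6 * y[:, None, None]
        B2 = rng.standard_normal((N, 2, 2)) + 0.4 * y[:, None, None]
        C = 1.0
        full = np.zeros((N, 5, 4))
        full[:, :3, :2] = B1
        full[:, 3:, 2:] = B2
        obj_oracle, gap = _oracles.fw_train_oracle(full, y, C, tol_gap=2e-5)
        feats = [[B1[i], B2[i]] for i in range(N)]
        m = train(feats, y, C, block_dims=((3, 2), (2, 2)),
                  settings=SolverSettings(max_iter=20000, tol_obj=1e-10))
        obj_blocks = logistic_objective(m, feats, y)
        assert abs(obj_blocks - obj_oracle) < 1e-4 + gap


class TestSpectrumAndTopography:
    def test_zero_model_has_rank_zero(self):
        m = _model([np.zeros((4, 3))])
        rep = spectrum(m)
        assert rep.rank == 0
        assert rep.nuclear_norm == 0.0

    def test_rank_one_plant_recovered(self):
        rng = np.random.default_rng(13)
        u = rng.standard_normal(37)
        v = rng.standard_normal(15)
        m = _model([np.outer(u, v)])
        rep = spectrum(m)
        w = rep.block_right_vectors[0][:, 0]
        cos = abs(w @ v) / (np.linalg.norm(w) * np.linalg.norm(v))
        assert cos > 0.999
        assert rep.rank == 1

    def test_singular_values_sum_to_nuclear_norm(self):
        rng = np.random.default_rng(14)
        m = _model([rng.standard_normal((6, 4)), rng.standard_normal((3, 3))])
        rep = spectrum(m)
        assert np.isclose(rep.nuclear_norm, m.nuclear_norm(), atol=1e-8)

    def test_topography_peaks_at_planted_channel(self):
        c3 = CHANNELS.index("C3")
        v = np.zeros(15); v[c3] = 1.0; v[0] = 0.2
        blocks = [np.zeros((37, 15)), np.outer(v, v)]
        topo = topography(DSModel(blocks=blocks, b=0.0, C=10.0,
                                  block_dims=((37, 15), (15, 15))))
        assert np.argmax(np.abs(topo["mi"])) == c3
        assert np.isclose(np.abs(topo["mi"]).max(), 1.0)
        assert np.all(topo["p300"] == 0)
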