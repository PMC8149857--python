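"""Weight learning: loss/gradient correctness, discrete projection, search."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qsperceptron.patterns import TargetSpec
from qsperceptron.training import (
    TrainingConfig,
    coordinate_search,
    default_target_levels,
    direct_search,
    gradient,
    loss,
    project_discrete,
    responses,
    train,
    train_multiclass,
)


def brute_force_loss_min(palette, P, t, receiver):
    """Independent exhaustive-enumeration oracle over palette^d."""
    span = receiver.params.beta_m
    best = np.inf
    best_w = None
    for combo in itertools.product(palette, repeat=P.shape[1]):
        s = np.maximum(P @ np.array(combo), 0.0)
        u = (s / receiver.params.K_d) ** receiver.params.n
        h = np.where(s == 0, 0.0, u / (1 + u))
        R = receiver.params.beta_m * (h + receiver.params.beta_0)
        L = 0.5 * np.sum(((R - t) / span) ** 2)
        if L < best:
            best, best_w = L, np.array(combo)
    return best, best_w


class TestLoss:
    def test_zero_iff_equal(self, rng):
        R = rng.uniform(0, 1e4, 12)
        assert loss(R, R, span=1.0) == 0.0

    def test_unit_example(self):
        assert loss([1.0, 0.0], [0.0, 1.0], span=1.0) == pytest.approx(1.0)

    def test_matches_direct_formula(self, rng, receiver):
        R = rng.uniform(0, 2e4, 30)
        t = rng.uniform(0, 2e4, 30)
        direct = 0.5 * np.sum(((R - t) / receiver.span) ** 2)
        assert loss(R, t, receiver=receiver) == pytest.approx(direct, rel=1e-14)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            loss([1.0, 2.0], [1.0])


class TestGradient:
    def test_zero_at_perfect_fit(self, receiver, rng):
        w = rng.uniform(100, 2000, 4)
        P = rng.integers(0, 2, (6, 4)).astype(float)
        t = responses(w, P, receiver)  # targets exactly achievable
        g = gradient(w, P, t, receiver)
        np.testing.assert_allclose(g, 0.0, atol=1e-12)

    def test_analytic_matches_finite_differences(self, receiver, rng, set3):
        high, low = default_target_levels(receiver)
        t = TargetSpec.one_vs_rest(set3, high, low).vectors["z"]
        w = rng.uniform(-500, 3000, 9)
        ga = gradient(w, set3, t, receiver)
        gf = gradient(w, set3, t, receiver, mode="fd", grad_step=0.5)
        assert np.linalg.norm(ga - gf) / np.linalg.norm(gf) < 1e-4

    def test_zero_inputs_kill_partials(self, receiver):
        P = np.array([[1.0, 0.0, 0.0]])
        t = np.array([5000.0])
        g = gradient(np.array([800.0, 800.0, 800.0]), P, t, receiver)
        assert g[0] != 0.0
        assert g[1] == 0.0 and g[2] == 0.0

    def test_nonfinite_weights_flagged(self, receiver):
        with pytest.raises(FloatingPointError):
            gradient(np.array([np.nan, 1.0]), np.eye(2), np.zeros(2), receiver)


class TestProjectDiscrete:
    def test_idempotent_on_palette(self):
        w = np.array([-735.0, 450.0, 3500.0])
        np.testing.assert_array_equal(project_discrete(w, [-735, 0, 450, 3500]), w)

    def test_nearest_level_wins_when_not_tied(self):
        # 700 is 200 from 900 and 250 from 450: strictly nearest applies
        assert project_discrete([700.0], [450.0, 900.0])[0] == 900.0

    def test_tie_breaks_toward_smaller_magnitude(self):
        assert project_discrete([675.0], [450.0, 900.0])[0] == 450.0
        assert project_discrete([-225.0], [-450.0, 0.0])[0] == 0.0

    def test_matches_scan_oracle(self, rng):
        palette = sorted(rng.uniform(-1000, 4000, 6).tolist())
        w = rng.uniform(-1500, 4500, 40)
        out = project_discrete(w, palette)
        for wi, oi in zip(w, out):
            dists = [abs(wi - v) for v in palette]
            assert abs(wi - oi) == pytest.approx(min(dists))

    def test_empty_palette_rejected(self):
        with pytest.raises(ValueError):
            project_discrete([1.0], [])

    @given(st.lists(st.floats(-5000, 5000), min_size=1, max_size=8))
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_output_always_in_palette(self, w):
        palette = [-735.0, 0.0, 450.0, 900.0, 3500.0]
        out = project_discrete(np.array(w), palette)
        assert all(v in palette for v in out)


class TestDirectSearch:
    def test_never_increases_loss(self, receiver, rng, target_levels):
        high, low = target_levels
        P = rng.integers(0, 2, (8, 3)).astype(float)
        t = rng.choice([high, low], 8)
        palette = [-735.0, 0.0, 900.0, 3500.0]
        w0 = project_discrete(rng.uniform(0, 3500, 3), palette)
        before = loss(responses(w0, P, receiver), t, receiver=receiver)
        w1, _ = direct_search(w0, palette, 1, P, t, receiver)
        after = loss(responses(w1, P, receiver), t, receiver=receiver)
        assert after <= before

    def test_full_radius_equals_exhaustive_optimum(self, receiver, rng, target_levels):
        high, low = target_levels
        palette = [-735.0, 0.0, 900.0, 3500.0]
        P = rng.integers(0, 2, (6, 2)).astype(float)
        t = rng.choice([high, low], 6)
        w0 = np.array([0.0, 0.0])
        w1, _ = direct_search(w0, palette, len(palette), P, t, receiver)
        best, _ = brute_force_loss_min(palette, P, t, receiver)
        got = loss(responses(w1, P, receiver), t, receiver=receiver)
        assert got == pytest.approx(best, abs=1e-12)

    def test_unchanged_at_optimum(self, receiver, target_levels):
        high, low = target_levels
        palette = [0.0, 3500.0]
        P = np.eye(2)
        t = np.array([high, low])
        best, w_star = brute_force_loss_min(palette, P, t, receiver)
        w1, _ = direct_search(w_star.astype(float), palette, 2, P, t, receiver)
        np.testing.assert_array_equal(w1, w_star)

    def test_budget_refusal(self, receiver, target_levels):
        high, low = target_levels
        palette = list(range(0, 4000, 400))
        P = np.ones((2, 12))
        t = np.array([high, low])
        w0 = project_discrete(np.zeros(12), palette)
        with pytest.raises(ValueError, match="budget"):
            direct_search(w0, palette, 4, P, t, receiver, budget=100)

    def test_off_palette_start_rejected(self, receiver):
        with pytest.raises(ValueError):
            direct_search(np.array([123.0]), [0.0, 450.0], 1, np.ones((1, 1)),
                          np.array([400.0]), receiver)


class TestCoordinateSearch:
    def test_monotone_and_on_palette(self, receiver, rng, target_levels):
        high, low = target_levels
        palette = [-735.0, 0.0, 450.0, 900.0, 3500.0]
        P = rng.integers(0, 2, (20, 10)).astype(float)
        t = rng.choice([high, low], 20)
        w0 = project_discrete(rng.uniform(0, 3500, 10), palette)
        before = loss(responses(w0, P, receiver), t, receiver=receiver)
        w1, _ = coordinate_search(w0, palette, P, t, receiver)
        after = loss(responses(w1, P, receiver), t, receiver=receiver)
        assert after <= before
        assert all(v in palette for v in w1)


class TestTrain:
    def test_seeded_determinism(self, receiver, set3, target_levels):
        high, low = target_levels
        t = TargetSpec.one_vs_rest(set3, high, low).vectors["z"]
        cfg = TrainingConfig(palette=[-735.0, 0.0, 900.0, 3500.0], seed=4,
                             max_iter=500, n_restarts=1)
        a = train(set3, t, cfg, receiver)
        b = train(set3, t, cfg, receiver)
        np.testing.assert_array_equal(a.weights, b.weights)
        assert a.loss_trajectory == b.loss_trajectory

    def test_optimal_start_unchanged(self, receiver, target_levels):
        high, low = target_levels
        palette = [0.0, 3500.0]
        P = np.eye(3)
        _, w_star = brute_force_loss_min(palette, P, np.array([high, low, high]), receiver)
        cfg = TrainingConfig(palette=palette, max_iter=50, n_restarts=1,
                             direct_search_radius=len(palette))
        res = train(P, np.array([high, low, high]), cfg, receiver, w0=w_star.astype(float))
        np.testing.assert_array_equal(res.weights, w_star)

    def test_discrete_weights_land_on_palette(self, receiver, set3, target_levels):
        high, low = target_levels
        t = TargetSpec.one_vs_rest(set3, high, low).vectors["v"]
        palette = [-735.0, 0.0, 450.0, 900.0, 3500.0]
        res = train(set3, t, TrainingConfig(palette=palette, max_iter=1000, n_restarts=1),
                    receiver)
        assert all(v in palette for v in res.weights)

    def test_every_step_projection_mode(self, receiver, set3, target_levels):
        high, low = target_levels
        t = TargetSpec.one_vs_rest(set3, high, low).vectors["z"]
        palette = [-735.0, 0.0, 450.0, 900.0, 3500.0]
        res = train(set3, t, TrainingConfig(palette=palette, projection="every",
                                            max_iter=500, n_restarts=1), receiver)
        assert all(v in palette for v in res.weights)

    def test_continuous_trajectory_non_increasing(self, receiver, set3, target_levels):
        high, low = target_levels
        t = TargetSpec.one_vs_rest(set3, high, low).vectors["z"]
        res = train(set3, t, TrainingConfig(palette=None, max_iter=2000, n_restarts=1),
                    receiver)
        traj = np.array(res.loss_trajectory)
        assert np.all(np.diff(traj) <= 1e-12)

    def test_separable_dichotomy_zero_misclassification(self, receiver, target_levels):
        high, low = target_levels
        P = np.array([[0, 0], [0, 1], [1, 0], [1, 1]], float)
        t = np.array([low, low, low, high])
        res = train(P, t, TrainingConfig(palette=None, seed=0), receiver)
        assert res.converged
        thr = 0.5 * (high + low)
        predicted = res.responses >= thr
        np.testing.assert_array_equal(predicted, t == high)

    def test_trainer_attains_exhaustive_optimum_small(self, receiver, rng, target_levels):
        high, low = target_levels
        palette = [-735.0, 0.0, 900.0, 3500.0]
        for trial in range(3):
            P = rng.integers(0, 2, (6, 3)).astype(float)
            t = rng.choice([high, low], 6)
            cfg = TrainingConfig(palette=palette, direct_search_radius=len(palette),
                                 seed=trial, max_iter=2000)
            res = train(P, t, cfg, receiver)
            best, _ = brute_force_loss_min(palette, P, t, receiver)
            assert res.final_loss <= best + 1e-12

    def test_parameter_recovery_from_synthetic_targets(self, receiver):
        # positive palette + unit patterns: responses identify each weight
        palette = [450.0, 900.0, 1800.0, 3500.0]
        w_true = np.array([900.0, 3500.0, 450.0])
        P = np.vstack([np.eye(3), np.ones((1, 3))])
        t = responses(w_true, P, receiver)
        cfg = TrainingConfig(palette=palette, direct_search_radius=len(palette),
                             seed=1, max_iter=3000)
        res = train(P, t, cfg, receiver)
        np.testing.assert_array_equal(res.weights, w_true)

    def test_dimension_mismatch_rejected(self, receiver):
        with pytest.raises(ValueError):
            train(np.ones((3, 2)), np.ones(4), TrainingConfig(max_iter=1), receiver)


class TestTrainMulticlass:
    def test_three_categories_with_positive_margins(self, receiver, set3):
        cfg = TrainingConfig(palette=[-735.0, 0.0, 450.0, 900.0, 3500.0],
                             max_iter=3000, n_restarts=2)
        mc = train_multiclass(set3, cfg=cfg, receiver=receiver)
        assert set(mc.results) == {"z", "v", "n"}
        for c, margin in mc.margins.items():
            assert margin > 0, f"category {c} not separated"

    def test_config_validation(self):
        with pytest.raises(ValueError):
            TrainingConfig(eta=0.0)
        with pytest.raises(ValueError):
            TrainingConfig(palette=[])
        with pytest.raises(ValueError):
            TrainingConfig(projection="sometimes")
        with pytest.raises(ValueError):
            TrainingConfig(direct_search_radius=0)
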