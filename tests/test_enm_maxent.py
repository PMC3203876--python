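"""Maximum-entropy model: features, fitting vs a convex oracle, evaluation."""

import numpy as np
import pytest
from scipy.optimize import minimize

from nichephylo.containers import EnvStack, OccurrenceSet
from nichephylo.enm_maxent import (
    EmptySurfaceError,
    ModelFallbackError,
    NicheModel,
    auc,
    build_features,
    fit_maxent,
    jackknife_contribution,
    range_fallback_surface,
    regularized_objective,
    replicate_models,
)
from nichephylo.geo_ranges import buffer_range
from nichephylo.synthetic_data import TrueNiche, generate_env_stack, simulate_species


def constant_env(value=5.0, shape=(10, 10), n_layers=2):
    data = np.full((n_layers, *shape), value)
    return EnvStack([f"env{i+1}" for i in range(n_layers)], data, cell_size_km=1.0)


def oracle_objective(features, occ, reg=1.0):
    """Generic convex solver on the same L1 objective (split positive/negative)."""
    k = features.n_features

    def f(z):
        return regularized_objective(features, occ, z[:k] - z[k:], reg)

    res = minimize(
        f, np.zeros(2 * k), bounds=[(0, None)] * (2 * k), method="L-BFGS-B",
        options={"maxiter": 3000, "ftol": 1e-14},
    )
    return res.fun


class TestFeatures:
    def test_midpoint_scales_to_half(self):
        env = generate_env_stack(1, (10, 10), corr_length_km=0, seed=0)
        env.data[0] = np.linspace(10, 30, 100).reshape(10, 10)
        fs = build_features(env)
        r, c = np.array([0]), np.array([0])
        env.data[0][0, 0] = 20.0
        F = fs.matrix(r, c)
        assert F[0, 0] == pytest.approx(0.5)  # linear
        assert F[0, 1] == pytest.approx(0.25)  # quadratic of the scaled value

    def test_background_features_within_unit_interval(self):
        env = generate_env_stack(3, (15, 15), corr_length_km=4, seed=2)
        fs = build_features(env)
        F = fs.matrix(*fs.background_rc)
        assert F.min() >= 0.0 and F.max() <= 1.0

    def test_constant_layer_dropped_with_warning(self):
        env = generate_env_stack(2, (10, 10), corr_length_km=0, seed=1)
        env.data[1] = 3.0
        with pytest.warns(UserWarning, match="constant"):
            fs = build_features(env)
        assert {l for l, _ in fs.definitions} == {"env1"}


class TestFitMaxent:
    def test_constant_layers_give_uniform_surface_and_zero_gain(self):
        env = constant_env()
        with pytest.warns(UserWarning):
            fs = build_features(env)
        occ = OccurrenceSet("s", [[1.5, 1.5], [4.5, 7.5], [2.5, 2.5]])
        model = fit_maxent(fs, occ)
        assert np.allclose(model.raw_surface, 1 / 100)
        assert model.training_gain == 0.0

    def test_huge_regularization_zeroes_all_weights(self):
        env = generate_env_stack(2, (15, 15), corr_length_km=4, seed=5)
        fs = build_features(env)
        occ = simulate_species(env, TrueNiche([1.0, 0.5], [0.5, 0.5]), 25, seed=1)
        model = fit_maxent(fs, occ, reg_multiplier=1e6)
        assert np.allclose(model.weights, 0.0)
        assert np.allclose(model.raw_surface, 1 / 225)

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_objective_matches_convex_oracle(self, seed):
        env = generate_env_stack(2, (15, 15), corr_length_km=4, seed=seed)
        fs = build_features(env)
        occ = simulate_species(env, TrueNiche([0.8, -0.3], [0.6, 0.9]), 30, seed=seed)
        model = fit_maxent(fs, occ, max_iter=2000, tol=1e-10)
        ours = regularized_objective(fs, occ, model.weights)
        oracle = oracle_objective(fs, occ)
        assert ours <= oracle + 1e-4

    def test_objective_path_is_monotone_nonincreasing(self):
        env = generate_env_stack(2, (20, 20), corr_length_km=5, seed=7)
        fs = build_features(env)
        occ = simulate_species(env, TrueNiche([1.0, 0.0], [0.5, 2.0]), 30, seed=4)
        model = fit_maxent(fs, occ)
        assert np.all(np.diff(model.objective_path) <= 1e-12)

    def test_surface_sums_to_one(self):
        env = generate_env_stack(2, (12, 12), corr_length_km=3, seed=9)
        fs = build_features(env)
        occ = simulate_species(env, TrueNiche([0.0, 0.0], [1.0, 1.0]), 20, seed=2)
        model = fit_maxent(fs, occ)
        assert model.raw_surface.sum() == pytest.approx(1.0, abs=1e-9)

    def test_single_presence_rejected(self):
        env = generate_env_stack(1, (10, 10), corr_length_km=0, seed=0)
        fs = build_features(env)
        with pytest.raises(ModelFallbackError):
            fit_maxent(fs, (np.array([0]), np.array([0])))

    def test_linear_coefficient_direction_recovered(self):
        # occurrences concentrated at high values of one layer must yield a
        # positive linear weight for that layer in nearly every seeded run
        hits = 0
        for seed in range(100):
            env = generate_env_stack(1, (15, 15), corr_length_km=4, seed=seed)
            fs = build_features(env, kinds=("linear",))
            occ = simulate_species(env, TrueNiche([3.0], [1.0]), 25, seed=seed)
            model = fit_maxent(fs, occ, max_iter=200, tol=1e-7)
            hits += model.weights[0] > 0
        assert hits >= 95


class TestAUC:
    def grid_model(self, scores):
        surf = np.asarray(scores, dtype=float)
        return NicheModel(np.zeros(0), [], surf / surf.sum(), 0.0)

    def test_perfect_separation_gives_one(self):
        m = self.grid_model([[0.9, 0.8], [0.1, 0.2]])
        assert auc(m, (np.array([0, 0]), np.array([0, 1])), (np.array([1, 1]), np.array([0, 1]))) == 1.0

    def test_all_tied_gives_half(self):
        m = self.grid_model([[1.0, 1.0], [1.0, 1.0]])
        assert auc(m, (np.array([0]), np.array([0])), (np.array([1]), np.array([1]))) == 0.5

    def test_hand_enumeration(self):
        # presences score 0.9, 0.7; background 0.8, 0.1:
        # pairs (0.9>0.8)=1, (0.9>0.1)=1, (0.7<0.8)=0, (0.7>0.1)=1 -> 3/4
        m = self.grid_model([[0.9, 0.7], [0.8, 0.1]])
        got = auc(m, (np.array([0, 0]), np.array([0, 1])), (np.array([1, 1]), np.array([0, 1])))
        assert got == pytest.approx(0.75)


@pytest.fixture(scope="module")
def env_occ():
    env = generate_env_stack(2, (15, 15), corr_length_km=4, seed=3)
    occ = simulate_species(env, TrueNiche([1.0, 0.0], [0.5, 1.0]), 30, seed=5)
    return env, build_features(env), occ


class TestReplicates:
    def test_averaged_surface_sums_to_one(self, env_occ):
        _, fs, occ = env_occ
        model, _ = replicate_models(fs, occ, n_reps=5, seed=0, max_iter=80, tol=1e-5)
        assert model.raw_surface.sum() == pytest.approx(1.0, abs=1e-9)

    def test_sd_grid_present_for_enough_presences(self, env_occ):
        _, fs, occ = env_occ
        model, ev = replicate_models(fs, occ, n_reps=5, seed=0, max_iter=80, tol=1e-5)
        assert model.replicate_sd is not None
        assert ev.auc_sd is not None

    def test_sd_grid_absent_below_eight_presences(self, env_occ):
        env, fs, occ = env_occ
        small = OccurrenceSet("s", occ.points[:6], deduplicated=True)
        model, ev = replicate_models(fs, small, n_reps=5, seed=0, max_iter=80, tol=1e-5)
        assert model.replicate_sd is None
        assert ev.auc_sd is None

    def test_too_few_presences_raise_fallback(self, env_occ):
        _, fs, occ = env_occ
        lone = OccurrenceSet("s", occ.points[:1], deduplicated=True)
        with pytest.raises(ModelFallbackError):
            replicate_models(fs, lone, n_reps=2)


class TestJackknife:
    def test_informative_layer_wins_gain_alone(self):
        env = generate_env_stack(3, (15, 15), corr_length_km=4, seed=11)
        occ = simulate_species(
            env, TrueNiche([2.0, 0.0, 0.0], [0.3, 100.0, 100.0]), 30, seed=6
        )
        fs = build_features(env)
        df = jackknife_contribution(fs, occ, max_iter=200, tol=1e-7)
        assert df.attrs["top_layer"] == "env1"

    def test_duplicated_layer_is_redundant(self):
        env = generate_env_stack(2, (15, 15), corr_length_km=4, seed=13)
        env.data[1] = env.data[0]
        occ = simulate_species(env, TrueNiche([1.5, 1.5], [0.4, 0.4]), 30, seed=7)
        fs = build_features(env)
        df = jackknife_contribution(fs, occ, max_iter=400, tol=1e-9).set_index("layer")
        full = fit_maxent(fs, occ, max_iter=400, tol=1e-9).training_gain
        assert df.loc["env1", "gain_without"] == pytest.approx(full, abs=1e-3)


class TestRangeFallback:
    def test_uniform_over_in_range_cells(self):
        env = generate_env_stack(1, (10, 10), corr_length_km=0, seed=0, cell_size_km=1.0)
        rng = buffer_range(OccurrenceSet("s", [[5.0, 5.0]]).dedup(), 2.5)
        model = range_fallback_surface(rng, env)
        vals = model.raw_surface[model.raw_surface > 0]
        assert np.allclose(vals, vals[0])
        assert model.raw_surface.sum() == pytest.approx(1.0)

    def test_full_grid_range_is_uniform(self):
        env = generate_env_stack(1, (6, 6), corr_length_km=0, seed=0)
        rng = buffer_range(OccurrenceSet("s", [[3.0, 3.0]]).dedup(), 50.0)
        model = range_fallback_surface(rng, env)
        assert np.allclose(model.raw_surface, 1 / 36)

    def test_empty_intersection_raises(self):
        env = generate_env_stack(1, (6, 6), corr_length_km=0, seed=0)
        rng = buffer_range(OccurrenceSet("s", [[100.0, 100.0]]).dedup(), 1.0)
        with pytest.raises(EmptySurfaceError):
            range_fallback_surface(rng, env)
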