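"""Generators: random fields, occurrence sampling, Brownian clades, fixture."""

import numpy as np
import pytest
from scipy import stats

from nichephylo.containers import Chronogram, InvalidArgumentError
from nichephylo.synthetic_data import (
    MALAGASY_CLADE,
    TrueNiche,
    generate_env_stack,
    jitter_posterior,
    random_ultrametric_tree,
    sample_cells,
    simulate_clade,
    simulate_species,
    study_fixture,
    suitability_grid,
)

from conftest import masked_single_cell_env


class TestEnvStackGenerator:
    def test_same_seed_is_bitwise_identical(self):
        a = generate_env_stack(3, (30, 30), corr_length_km=5, seed=11)
        b = generate_env_stack(3, (30, 30), corr_length_km=5, seed=11)
        assert np.array_equal(a.data, b.data)

    def test_white_noise_layers_are_uncorrelated(self):
        env = generate_env_stack(2, (100, 100), corr_length_km=0, inter_layer_corr=0, seed=2)
        r = np.corrcoef(env.data[0].ravel(), env.data[1].ravel())[0, 1]
        assert abs(r) < 0.1

    def test_target_inter_layer_correlation_is_reached(self):
        env = generate_env_stack(
            2, (200, 200), corr_length_km=3, inter_layer_corr=0.9, seed=5
        )
        r = np.corrcoef(env.data[0].ravel(), env.data[1].ravel())[0, 1]
        assert 0.8 <= r <= 0.97

    def test_layers_are_standardized(self):
        env = generate_env_stack(2, (50, 50), corr_length_km=8, seed=7)
        for layer in env.data:
            assert abs(layer.mean()) < 1e-9
            assert abs(layer.std() - 1) < 1e-9

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_layers": 0, "shape": (10, 10)},
            {"n_layers": 2, "shape": (0, 10)},
            {"n_layers": 2, "shape": (10, 10), "cell_size_km": 0},
            {"n_layers": 2, "shape": (10, 10), "corr_length_km": -1},
            {"n_layers": 3, "shape": (10, 10), "inter_layer_corr": -0.5},
        ],
    )
    def test_invalid_arguments_raise(self, kwargs):
        with pytest.raises(InvalidArgumentError):
            generate_env_stack(seed=0, **kwargs)


class TestSpeciesSimulation:
    def test_flat_niche_gives_uniform_occupancy(self):
        env = generate_env_stack(2, (10, 10), corr_length_km=0, seed=1)
        niche = TrueNiche([0.0, 0.0], [1e6, 1e6])
        rows, cols = sample_cells(env, niche, 5000, seed=4)
        counts = np.bincount(rows * 10 + cols, minlength=100)
        p = stats.chisquare(counts).pvalue
        assert p > 0.001

    def test_sampling_matches_analytic_suitability(self):
        env = generate_env_stack(2, (10, 10), corr_length_km=5, seed=9)
        niche = TrueNiche([0.5, -0.2], [1.0, 0.8])
        suit = suitability_grid(env, niche).ravel()
        expected = suit / suit.sum()
        rows, cols = sample_cells(env, niche, 5000, seed=13)
        counts = np.bincount(rows * 10 + cols, minlength=100)
        keep = expected > 0
        p = stats.chisquare(counts[keep], 5000 * expected[keep] / expected[keep].sum()).pvalue
        assert p > 0.001

    def test_single_unmasked_cell_forces_all_points_there(self):
        env = masked_single_cell_env()
        occ = simulate_species(env, TrueNiche([0.0], [1.0]), 50, seed=0)
        assert len(occ) == 1
        r, c = env.xy_to_rc(occ.points)
        assert (r[0], c[0]) == (2, 3)

    def test_tight_niche_concentrates_in_top_decile(self):
        env = generate_env_stack(2, (30, 30), corr_length_km=10, seed=21)
        # optimum at the environment of the most suitable cell
        flat = np.argmax(env.data.sum(axis=0))
        r0, c0 = np.unravel_index(flat, env.shape)
        opt = env.data[:, r0, c0]
        niche = TrueNiche(opt, [0.2, 0.2])
        suit = suitability_grid(env, niche)
        cutoff = np.quantile(suit[~env.nodata_mask], 0.9)
        rows, cols = sample_cells(env, niche, 500, seed=22)
        frac = np.mean(suit[rows, cols] >= cutoff)
        assert frac >= 0.9

    def test_dimension_mismatch_raises(self):
        env = generate_env_stack(2, (10, 10), seed=0)
        with pytest.raises(InvalidArgumentError):
            simulate_species(env, TrueNiche([0.0], [1.0]), 10)


class TestCladeSimulation:
    def test_zero_rate_keeps_all_optima_at_root(self, small_env):
        tree = random_ultrametric_tree(5, seed=3)
        sim = simulate_clade(tree, 0.0, [0.3, -0.1], small_env, 10, seed=1)
        for niche, _ in sim.values():
            assert np.allclose(niche.optimum, [0.3, -0.1])

    def test_two_tip_divergence_variance_matches_brownian_law(self):
        # Var(x_A - x_B) = 2 * sigma2 * t for tips diverged t Ma ago
        tree = Chronogram.from_newick("(A:2.0,B:2.0);")
        sigma2 = 0.7
        diffs = []
        rng = np.random.default_rng(17)
        for _ in range(1000):
            tips = tree.simulate_bm(sigma2, np.zeros(1), rng)
            diffs.append(tips["A"][0] - tips["B"][0])
        var = np.var(diffs)
        expected = 2 * sigma2 * 2.0
        se = expected * np.sqrt(2 / 999)  # SE of a sample variance
        assert abs(var - expected) < 3 * se

    def test_fixed_seed_reproduces_tip_optima(self, small_env):
        tree = random_ultrametric_tree(6, seed=8)
        a = simulate_clade(tree, 0.5, np.zeros(2), small_env, 15, seed=42)
        b = simulate_clade(tree, 0.5, np.zeros(2), small_env, 15, seed=42)
        for sp in a:
            assert np.array_equal(a[sp][0].optimum, b[sp][0].optimum)
            assert np.array_equal(a[sp][1].points, b[sp][1].points)

    def test_negative_rate_raises(self, small_env):
        tree = random_ultrametric_tree(4, seed=1)
        with pytest.raises(InvalidArgumentError):
            simulate_clade(tree, -1.0, np.zeros(2), small_env, 5)


class TestTrees:
    def test_random_tree_is_ultrametric_with_requested_depth(self):
        tree = random_ultrametric_tree(12, seed=5, mean_depth_ma=7.5)
        assert tree.n_tips == 12
        assert tree.root_age == pytest.approx(7.5)

    def test_posterior_jitter_preserves_tips_and_ultrametricity(self):
        tree = random_ultrametric_tree(8, seed=2)
        post = jitter_posterior(tree, 20, sigma=0.2, seed=3)
        assert len(post.posterior_sample) == 20
        for t in post.posterior_sample:
            c = Chronogram(tree=t)  # raises if not ultrametric
            assert sorted(c.tip_labels) == sorted(tree.tip_labels)


class TestStudyFixture:
    def test_tree_shape(self):
        chron, _ = study_fixture()
        assert chron.n_tips == 27
        assert chron.root_age == pytest.approx(14.9)
        polytomies = [
            n for n in chron.tree.postorder_internal_node_iter()
            if len(n.child_nodes()) > 2
        ]
        assert len(polytomies) == 1  # the unresolved three-species group

    def test_malagasy_clade_is_monophyletic(self):
        chron, _ = study_fixture()
        mrca = chron.tree.mrca(taxon_labels=MALAGASY_CLADE)
        tips = {leaf.taxon.label for leaf in mrca.leaf_iter()}
        assert tips == set(MALAGASY_CLADE)

    @pytest.mark.parametrize(
        "a,b,age,overlap",
        [
            ("Isolona_pleurocarpa", "Isolona_zenkeri", 4.5, 19.6),
            ("Monodora_carolinae", "Monodora_stenopetala", 2.6, 0.0),
            ("Monodora_hastipetala", "Monodora_junodii", 1.5, 89.3),
        ],
    )
    def test_pair_table_values(self, a, b, age, overlap):
        _, table = study_fixture()
        row = table[(table.species_a == a) & (table.species_b == b)].iloc[0]
        assert row.mrca_age_ma == age
        assert row.overlap_pct == overlap

    def test_eleven_pairs_listed(self):
        _, table = study_fixture()
        assert len(table) == 11
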