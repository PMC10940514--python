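"""Modular-graph generation: balance, edge densities, weights, scaling."""

import numpy as np
import pytest
import scipy.linalg

from mesn import (
    ConfigurationError,
    DegenerateReservoirError,
    TopologyConfig,
    assign_modules,
    assign_weights,
    generate_input_weights,
    generate_reservoir,
    load_reservoir,
    sample_pairs,
    save_reservoir,
    scale_spectral_radius,
    spectral_radius,
)


class TestAssignModules:
    @pytest.mark.parametrize(
        "n,m,expected_sizes",
        [
            (600, 6, [100] * 6),
            (5, 2, [3, 2]),
            (6, 1, [6]),
            (7, 3, [3, 2, 2]),
        ],
    )
    def test_balanced_sizes(self, n, m, expected_sizes, rng):
        labels = assign_modules(n, m, rng)
        sizes = sorted(np.bincount(labels, minlength=m), reverse=True)
        assert sizes == sorted(expected_sizes, reverse=True)
        assert set(labels) == set(range(m))

    def test_deterministic_given_seed(self):
        a = assign_modules(50, 4, np.random.default_rng(9))
        b = assign_modules(50, 4, np.random.default_rng(9))
        assert np.array_equal(a, b)

    @pytest.mark.parametrize("m", [0, 11])
    def test_invalid_module_count(self, m, rng):
        with pytest.raises(ConfigurationError):
            assign_modules(10, m, rng)


class TestSamplePairs:
    def test_full_intra_empty_inter(self, rng):
        labels = np.array([0, 0, 1, 1])
        pairs = sample_pairs(labels, 1.0, 0.0, rng)
        assert len(pairs) == 2
        assert all(labels[i] == labels[j] for i, j in pairs)

    def test_empty_graph(self, rng):
        pairs = sample_pairs(np.zeros(10, dtype=int), 0.0, 0.0, rng)
        assert len(pairs) == 0

    def test_p2_above_p1_rejected(self, rng):
        with pytest.raises(ConfigurationError):
            sample_pairs(np.zeros(4, dtype=int), 0.1, 0.5, rng)

    def test_p2_above_p1_warns_when_allowed(self, rng):
        with pytest.warns(UserWarning):
            sample_pairs(np.zeros(4, dtype=int), 0.1, 0.5, rng, allow_p2_greater=True)

    def test_no_self_pairs_no_duplicates(self, rng):
        labels = assign_modules(80, 4, rng)
        pairs = sample_pairs(labels, 0.5, 0.2, rng)
        assert np.all(pairs[:, 0] < pairs[:, 1])
        assert len({tuple(p) for p in pairs}) == len(pairs)

    def test_expected_counts_at_experiment_scale(self):
        # N=600, M=6, P1=0.05, P2=0.02: E[intra]=1485, E[inter]=3000
        rng = np.random.default_rng(0)
        labels = assign_modules(600, 6, rng)
        pairs = sample_pairs(labels, 0.05, 0.02, rng)
        intra = labels[pairs[:, 0]] == labels[pairs[:, 1]]
        n_intra, n_inter = int(intra.sum()), int((~intra).sum())
        sd_intra = np.sqrt(29700 * 0.05 * 0.95)
        sd_inter = np.sqrt(150000 * 0.02 * 0.98)
        assert abs(n_intra - 1485) < 4 * sd_intra
        assert abs(n_inter - 3000) < 4 * sd_inter


class TestAssignWeights:
    def test_empty_pairs_zero_matrix(self, rng):
        w = assign_weights(np.empty((0, 2), dtype=int), 5, rng)
        assert np.all(w == 0)

    def test_single_pair_bidirectional(self, rng):
        w = assign_weights(np.array([[0, 1]]), 4, rng)
        nz = np.argwhere(w != 0)
        assert {tuple(r) for r in nz} == {(0, 1), (1, 0)}
        assert 0 < abs(w[0, 1]) < 1 and 0 < abs(w[1, 0]) < 1

    @pytest.mark.parametrize("sign_rule", ["symmetric", "flip_one"])
    def test_half_of_pairs_opposite_signed(self, sign_rule):
        # 10,000 pairs: binomial 4-sigma band around 0.5 is +/- 0.02
        rng = np.random.default_rng(1)
        n = 201
        pairs = np.array([(i, j) for i in range(n) for j in range(i + 1, n)])[:10000]
        w = assign_weights(pairs, n, rng, sign_rule=sign_rule)
        signs = np.sign(w[pairs[:, 0], pairs[:, 1]]) * np.sign(w[pairs[:, 1], pairs[:, 0]])
        frac_opposite = np.mean(signs < 0)
        assert 0.48 <= frac_opposite <= 0.52

    def test_structural_symmetry(self, rng):
        labels = assign_modules(60, 3, rng)
        pairs = sample_pairs(labels, 0.4, 0.1, rng)
        w = assign_weights(pairs, 60, rng)
        assert np.array_equal(w != 0, (w != 0).T)
        assert np.all(np.diag(w) == 0)


class TestSpectralScaling:
    def test_identity_scaled_directly(self):
        out = scale_spectral_radius(np.eye(2), 0.85)
        assert np.allclose(out, 0.85 * np.eye(2))

    def test_nilpotent_raises(self):
        w = np.array([[0.0, 1.0], [0.0, 0.0]])
        with pytest.raises(DegenerateReservoirError):
            scale_spectral_radius(w, 0.85)

    def test_matches_independent_eigensolver(self):
        rng = np.random.default_rng(2)
        w = rng.normal(size=(300, 300)) * (rng.random((300, 300)) < 0.05)
        scaled = scale_spectral_radius(w, 0.85)
        rho = np.max(np.abs(scipy.linalg.eigvals(scaled)))
        assert abs(rho - 0.85) / 0.85 < 1e-8


class TestInputWeights:
    def test_bounds_and_shape(self, rng):
        w = generate_input_weights(600, 128, 0.1, rng)
        assert w.shape == (600, 128)
        assert np.all(np.abs(w) < 0.1)

    def test_zero_scale_rejected(self, rng):
        with pytest.raises(ConfigurationError):
            generate_input_weights(10, 2, 0.0, rng)

    def test_sample_mean_near_zero(self, rng):
        w = generate_input_weights(600, 128, 0.1, rng)
        se = (0.1 / np.sqrt(3)) / np.sqrt(600 * 128)
        assert abs(w.mean()) < 4 * se


class TestGenerateReservoir:
    def test_experiment_configuration_invariants(self, big_mats):
        w = big_mats.w_rc
        assert np.array_equal(w != 0, (w != 0).T)
        assert abs(spectral_radius(w) - 0.85) / 0.85 < 1e-8
        assert np.all(np.abs(big_mats.w_in) < 0.1)
        assert big_mats.labels is not None and set(big_mats.labels) == set(range(6))

    def test_bit_identical_given_seed(self):
        cfg = TopologyConfig(n=80, modules=4, p_intra=0.2, p_inter=0.05, seed=42)
        a = generate_reservoir(cfg, 0.85, n_inputs=5)
        b = generate_reservoir(cfg, 0.85, n_inputs=5)
        assert np.array_equal(a.w_rc, b.w_rc)
        assert np.array_equal(a.w_in, b.w_in)
        assert np.array_equal(a.labels, b.labels)

    def test_disconnected_configuration_raises(self):
        cfg = TopologyConfig(n=30, modules=3, p_intra=0.0, p_inter=0.0, seed=0)
        with pytest.raises(DegenerateReservoirError):
            generate_reservoir(cfg, 0.85, n_inputs=2)

    def test_single_module_matches_erdos_renyi_statistics(self):
        """M=1 (or P1=P2) degenerates to a plain random reservoir."""
        p = 0.05
        n = 600
        degs = []
        for seed in range(3):
            cfg = TopologyConfig(n=n, modules=1, p_intra=p, p_inter=p, seed=seed)
            mats = generate_reservoir(cfg, 0.85, n_inputs=1)
            degs.append(np.count_nonzero(mats.w_rc, axis=1))
        degs = np.concatenate(degs)
        # Binomial(n-1, p) oracle for the in-degree distribution
        mean_expected = (n - 1) * p
        var_expected = (n - 1) * p * (1 - p)
        assert abs(degs.mean() - mean_expected) < 4 * np.sqrt(var_expected / degs.size)
        assert abs(degs.var() - var_expected) < 0.15 * var_expected

    def test_round_trip_archive(self, small_mats, tmp_path):
        path = tmp_path / "reservoir.zip"
        save_reservoir(small_mats, path)
        loaded = load_reservoir(path)
        assert np.array_equal(loaded.w_rc, small_mats.w_rc)
        assert np.array_equal(loaded.w_in, small_mats.w_in)
        assert np.array_equal(loaded.labels, small_mats.labels)
        assert loaded.config == small_mats.config
        assert loaded.rho_target == small_mats.rho_target


class TestTopologyConfig:
    def test_p2_greater_rejected(self):
        with pytest.raises(ConfigurationError):
            TopologyConfig(n=10, modules=2, p_intra=0.1, p_inter=0.2)

    def test_p2_greater_allowed_with_flag(self):
        with pytest.warns(UserWarning):
            TopologyConfig(
                n=10, modules=2, p_intra=0.1, p_inter=0.2, allow_p2_greater=True
            )

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n": 0},
            {"modules": 0},
            {"modules": 11, "n": 10},
            {"p_intra": 1.5},
            {"p_inter": -0.1},
            {"weight_dist": "cauchy"},
            {"sign_rule": "nope"},
        ],
    )
    def test_invalid_configurations(self, kwargs):
        base = dict(n=10, modules=2, p_intra=0.5, p_inter=0.1)
        base.update(kwargs)
        with pytest.raises(ConfigurationError):
            TopologyConfig(**base)
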