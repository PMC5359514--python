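import numpy as np
import pytest

from cvevents.factors import (
    compute_scores,
    extract_factors,
    select_one_way_factors,
    standardize,
    varimax_criterion,
    varimax_rotate,
)

from conftest import varimax_grid_criterion_max


class TestStandardize:
    def test_columns_become_zero_mean_unit_sd(self, rng):
        sp = standardize(rng.normal(3.0, 2.0, size=(200, 5)))
        assert np.abs(sp.X.mean(axis=0)).max() < 1e-10
        assert np.abs(sp.X.std(axis=0) - 1.0).max() < 1e-10
        assert sp.dropped_cvs == []

    def test_constant_column_is_dropped_and_reported(self, rng):
        x = rng.normal(size=(100, 3))
        x[:, 1] = 4.2
        sp = standardize(x, ["a", "b", "c"])
        assert sp.dropped_cvs == ["b"]
        assert sp.cv_ids == ["a", "c"]

    def test_idempotent(self, rng):
        x = rng.normal(size=(150, 4))
        once = standardize(x).X
        twice = standardize(once).X
        np.testing.assert_allclose(twice, once, atol=1e-10)

    def test_all_constant_rejected(self):
        with pytest.raises(ValueError):
            standardize(np.ones((50, 3)))


class TestExtractFactors:
    def test_two_planted_latents_recovered_by_kaiser(self, rng):
        t = 400
        lat = np.column_stack([np.linspace(0, 1, t), np.sin(np.linspace(0, 3, t))])
        mix = np.array(
            [[1.0, 0.0], [0.9, 0.1], [1.1, -0.1], [0.0, 1.0], [0.1, 0.9], [-0.1, 1.1]]
        )
        x = standardize(lat @ mix.T + rng.normal(0, 0.05, size=(t, 6))).X
        fm = extract_factors(x, k="kaiser")
        assert fm.loadings.shape[1] == 2
        assert fm.explained_variance_fraction.sum() > 0.9

    def test_spectral_identity_on_retained_components(self, rng):
        x = standardize(rng.normal(size=(300, 5))).X
        fm = extract_factors(x, k=5)
        corr = x.T @ x / x.shape[0]
        np.testing.assert_allclose(fm.loadings @ fm.loadings.T, corr, atol=1e-8)

    def test_k_out_of_range_rejected(self, rng):
        x = standardize(rng.normal(size=(100, 4))).X
        with pytest.raises(ValueError):
            extract_factors(x, k=9)


class TestVarimax:
    def test_block_diagonal_is_a_fixed_point(self):
        loadings = np.array(
            [[0.9, 0.0], [0.85, 0.0], [0.8, 0.0], [0.0, 0.9], [0.0, 0.85], [0.0, 0.8]]
        )
        rotated, rotation, history = varimax_rotate(loadings)
        assert varimax_criterion(rotated) == pytest.approx(
            varimax_criterion(loadings), abs=1e-10
        )
        # identity up to column sign/permutation
        assert np.allclose(np.abs(rotation), np.eye(2), atol=1e-6) or np.allclose(
            np.abs(rotation), np.eye(2)[::-1], atol=1e-6
        )

    def test_matches_exhaustive_grid_for_two_factors(self, rng):
        for _ in range(15):
            loadings = rng.normal(size=(rng.integers(4, 10), 2))
            rotated, _, _ = varimax_rotate(loadings)
            assert varimax_criterion(rotated) == pytest.approx(
                varimax_grid_criterion_max(loadings), abs=1e-6
            )

    def test_single_factor_is_unchanged(self, rng):
        loadings = rng.normal(size=(6, 1))
        rotated, rotation, _ = varimax_rotate(loadings)
        np.testing.assert_allclose(rotation, [[1.0]])
        np.testing.assert_allclose(rotated, loadings)

    def test_criterion_history_is_non_decreasing(self, rng):
        for _ in range(5):
            _, _, history = varimax_rotate(rng.normal(size=(12, 4)))
            assert all(b - a >= -1e-12 for a, b in zip(history, history[1:]))

    def test_rotation_preserves_communalities_and_fit(self, rng):
        loadings = rng.normal(size=(10, 3))
        rotated, rotation, _ = varimax_rotate(loadings)
        np.testing.assert_allclose(rotation.T @ rotation, np.eye(3), atol=1e-8)
        np.testing.assert_allclose(
            (rotated**2).sum(axis=1), (loadings**2).sum(axis=1), atol=1e-10
        )
        np.testing.assert_allclose(rotated @ rotated.T, loadings @ loadings.T, atol=1e-8)


class TestScores:
    def test_noiseless_latents_recovered_up_to_sign_and_scale(self, rng):
        t = 300
        u = np.linspace(-1.0, 1.0, t)
        lat = np.column_stack([u, u**2 - np.mean(u**2)])  # orthogonal latents
        loadings = rng.normal(size=(6, 2)) + np.array([2.0, 0.0])
        x = lat @ loadings.T
        scores = compute_scores(x, loadings)
        for j in range(2):
            r = abs(np.corrcoef(scores[:, j], lat[:, j])[0, 1])
            assert r > 0.999

    def test_zero_matrix_gives_zero_scores(self):
        loadings = np.array([[0.8, 0.0], [0.0, 0.8], [0.5, 0.5]])
        scores = compute_scores(np.zeros((40, 3)), loadings)
        assert np.allclose(scores, 0.0)

    def test_score_columns_are_mean_centered(self, rng):
        x = standardize(rng.normal(size=(200, 5))).X
        fm = extract_factors(x, k=3)
        scores = compute_scores(x, fm.loadings)
        assert np.abs(scores.mean(axis=0)).max() < 1e-10

    def test_rank_deficient_loadings_rejected(self, rng):
        bad = np.column_stack([np.ones(4), np.ones(4)])
        with pytest.raises(np.linalg.LinAlgError):
            compute_scores(rng.normal(size=(50, 4)), bad)

    def test_scores_follow_loading_sign_flips(self, rng):
        x = standardize(rng.normal(size=(100, 4))).X
        fm = extract_factors(x, k=2)
        s0 = compute_scores(x, fm.loadings)
        flipped = fm.loadings * np.array([1.0, -1.0])
        s1 = compute_scores(x, flipped)
        np.testing.assert_allclose(s1[:, 0], s0[:, 0], atol=1e-10)
        np.testing.assert_allclose(s1[:, 1], -s0[:, 1], atol=1e-10)


class TestOneWaySelection:
    def test_linear_ramp_selected(self):
        flags = select_one_way_factors(np.linspace(0.0, 1.0, 500))
        assert flags[0].selected
        assert flags[0].net_displacement_ratio > 0.95
        assert flags[0].trend_rho > 0.99

    def test_full_oscillation_period_rejected(self):
        # one full period: the series ends at the level it started from
        t = np.linspace(0.0, 2 * np.pi, 600)
        flags = select_one_way_factors(np.cos(t))
        assert not flags[0].selected
        assert flags[0].net_displacement_ratio < 0.1

    def test_white_noise_rarely_selected(self):
        hits = 0
        for seed in range(200):
            g = np.random.default_rng(seed)
            flags = select_one_way_factors(g.normal(size=1000))
            hits += flags[0].selected
        assert hits / 200 <= 0.05

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            select_one_way_factors(np.arange(10.0))


class TestPlantedEventStructureRecovery:
    def test_rotated_factors_match_planted_cv_blocks(self):
        """With well-separated sequential sigmoid latents, each varimax factor's
        top-|loading| CV set equals one planted block in >= 90% of seeds."""
        t = np.arange(600.0)
        blocks = [list(range(0, 4)), list(range(4, 7)), list(range(7, 10))]
        centers = [150.0, 300.0, 450.0]
        wins = 0
        n_seeds = 50
        for seed in range(n_seeds):
            g = np.random.default_rng(seed)
            x = np.zeros((600, 10))
            for block, c in zip(blocks, centers):
                latent = 3.0 / (1.0 + np.exp(-(t - c) / 15.0))
                for m in block:
                    x[:, m] += latent
            x += g.normal(0, 1.0, x.shape)
            sp = standardize(x)
            fm = extract_factors(sp.X, k=3)
            rotated, _, _ = varimax_rotate(fm.loadings)
            found = []
            for j in range(3):
                order = np.argsort(-np.abs(rotated[:, j]))
                for block in blocks:
                    if set(order[: len(block)]) == set(block):
                        found.append(tuple(block))
            wins += len(set(found)) == 3
        assert wins / n_seeds >= 0.9
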