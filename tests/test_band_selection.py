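"""Band scoring oracles and configuration construction rules."""

import warnings

import numpy as np
import pytest
from scipy.optimize import minimize

from hyperyield.band_selection import (
    BandDefinition,
    BandScores,
    SpectralConfig,
    consensus_config,
    lcmv_cbs_scores,
    pca_mv_scores,
    rf_importance_scores,
    rf_table_config,
    select_bands,
    width_variant,
)
from hyperyield.datacube import SpectralCube


class TestPCAMV:
    def test_single_band_is_unity(self):
        _, s = pca_mv_scores(np.array([[1.0], [2.0], [3.0]]))
        np.testing.assert_allclose(s.scores, [1.0])

    def test_hand_worked_diagonal_case(self):
        X = np.array([[1.0, 0.0], [-1.0, 0.0], [0.0, 2.0], [0.0, -2.0]])
        result, s = pca_mv_scores(X)
        np.testing.assert_allclose(np.sort(result.eigenvalues), [2.0, 8.0])
        np.testing.assert_allclose(s.scores, [0.2, 0.8])

    def test_full_component_closed_form(self, random_cube):
        """With every component kept, rho is diag(Sigma)/trace(Sigma)."""
        for seed in range(5):
            cube = random_cube(n_bands=6, rows=5, cols=7, seed=seed)
            X = cube.values.reshape(6, -1).T
            _, s = pca_mv_scores(cube)
            expected = np.diag(X.T @ X) / np.trace(X.T @ X)
            np.testing.assert_allclose(s.scores, expected, atol=1e-9)
            assert s.scores.sum() == pytest.approx(1.0, abs=1e-9)

    def test_truncation_differs_from_closed_form(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(50, 5))
        _, full = pca_mv_scores(X)
        _, top1 = pca_mv_scores(X, n_components=1)
        assert top1.scores.sum() < full.scores.sum()

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(1)
        X = rng.uniform(0.1, 1.0, (30, 4))
        perm = [2, 0, 3, 1]
        _, s = pca_mv_scores(X)
        _, sp = pca_mv_scores(X[:, perm])
        np.testing.assert_allclose(sp.scores, s.scores[perm], atol=1e-12)

    def test_fewer_pixels_than_bands_warns(self):
        rng = np.random.default_rng(2)
        with pytest.warns(UserWarning, match="ridge"):
            pca_mv_scores(rng.normal(size=(3, 8)))


def _qp_tau(X, epsilon):
    """Independent oracle: numerically minimize w'Rw s.t. b_l'w = 1."""
    P, L = X.shape
    B = X.T
    R = B.T @ B / L + epsilon * (np.trace(B.T @ B) / L) / P * np.eye(P)
    taus = []
    for l in range(L):
        b = B[l]
        res = minimize(
            lambda w: w @ R @ w,
            x0=b / (b @ b),
            jac=lambda w: 2 * R @ w,
            constraints=[{"type": "eq", "fun": lambda w: b @ w - 1.0, "jac": lambda w: b}],
            method="SLSQP",
            options={"maxiter": 500, "ftol": 1e-14},
        )
        taus.append(res.x @ R @ res.x)
    return np.array(taus)


class TestLCMV:
    def test_identical_band_images_tie(self):
        X = np.tile(np.array([[1.0], [2.0], [0.5]]), (1, 2))
        _, s = lcmv_cbs_scores(X, epsilon=1e-3)
        assert s.scores[0] == pytest.approx(s.scores[1], rel=1e-12)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_constrained_qp_oracle(self, seed):
        rng = np.random.default_rng(seed)
        L = rng.integers(2, 5)
        P = rng.integers(max(3, L), 9)
        X = rng.uniform(0.2, 2.0, (P, L))
        eps = 1e-3
        result, s = lcmv_cbs_scores(X, epsilon=eps)
        np.testing.assert_allclose(s.scores, _qp_tau(X, eps), atol=1e-6)
        assert np.all(result.tau > 0)

    def test_filters_satisfy_unity_constraint(self):
        rng = np.random.default_rng(3)
        X = rng.uniform(0.2, 2.0, (6, 3))
        result, _ = lcmv_cbs_scores(X, epsilon=1e-3, retain_filters=True)
        B = X.T
        np.testing.assert_allclose(
            np.einsum("lp,lp->l", B, result.filters), 1.0, atol=1e-6
        )

    def test_pixel_permutation_invariance(self):
        rng = np.random.default_rng(4)
        X = rng.uniform(0.2, 2.0, (8, 3))
        _, s1 = lcmv_cbs_scores(X, epsilon=1e-2)
        _, s2 = lcmv_cbs_scores(X[rng.permutation(8)], epsilon=1e-2)
        np.testing.assert_allclose(s1.scores, s2.scores, rtol=1e-10)

    def test_singular_without_regularization(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(10, 3))  # P > L: rank-deficient R
        with pytest.raises(np.linalg.LinAlgError, match="epsilon"):
            lcmv_cbs_scores(X, epsilon=0.0)


class TestRFImportance:
    def test_planted_band_recovered(self):
        wins = 0
        for trial in range(10):
            rng = np.random.default_rng(100 + trial)
            X = rng.normal(0.3, 0.05, (40, 20))
            signal = 5.0 * X[:, 5]
            y = 10.0 + signal + rng.normal(0, signal.std() / 5.0, 40)
            s = rf_importance_scores(X, y, n_trees=200, seed=trial)
            wins += int(np.argmax(s.scores) == 5)
        assert wins >= 9

    def test_shuffled_yields_give_diffuse_importance(self):
        peak = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            X = rng.normal(0.3, 0.05, (120, 20))
            y = rng.normal(10.0, 1.0, 120)  # independent of X
            s = rf_importance_scores(X, y, n_trees=500, seed=seed)
            peak.append(s.scores.max())
        assert np.mean(peak) < 3.0 / 20

    def test_determinism_and_normalization(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(30, 10))
        y = X[:, 2] + rng.normal(0, 0.1, 30)
        a = rf_importance_scores(X, y, n_trees=100, seed=1)
        b = rf_importance_scores(X, y, n_trees=100, seed=1)
        np.testing.assert_array_equal(a.scores, b.scores)
        assert a.scores.sum() == pytest.approx(1.0)

    def test_too_few_subplots(self):
        with pytest.raises(ValueError, match="3 subplots"):
            rf_importance_scores(np.ones((2, 4)), np.array([1.0, 2.0]))


class TestSelectBands:
    def test_single_gaussian_bump_recovered(self):
        wl = np.arange(400.0, 1000.0, 2.0)
        sigma = 30.0 / (2 * np.sqrt(2 * np.log(2)))
        scores = np.exp(-0.5 * ((wl - 700.0) / sigma) ** 2)
        bands = select_bands(BandScores("pca_mv", scores, wl))
        assert len(bands) == 1
        assert abs(bands[0].center - 700.0) <= 2.0
        assert abs(bands[0].fwhm - 30.0) <= 4.0

    def test_two_separated_bumps_sorted(self):
        wl = np.arange(400.0, 1000.0, 2.0)
        sigma = 30.0 / 2.3548
        scores = np.exp(-0.5 * ((wl - 550.0) / sigma) ** 2) + np.exp(
            -0.5 * ((wl - 800.0) / sigma) ** 2
        )
        bands = select_bands(BandScores("pca_mv", scores, wl))
        assert [round(b.center) for b in bands] == [550, 800]

    def test_scale_invariance(self):
        wl = np.arange(400.0, 1000.0, 2.0)
        rng = np.random.default_rng(0)
        scores = rng.random(len(wl)) + np.exp(-0.5 * ((wl - 700.0) / 15.0) ** 2) * 5
        a = select_bands(BandScores("rf", scores, wl))
        b = select_bands(BandScores("rf", scores * 137.0, wl))
        assert [(x.center, x.fwhm) for x in a] == [(x.center, x.fwhm) for x in b]

    def test_flat_scores_yield_empty_list(self):
        wl = np.arange(400.0, 500.0, 2.0)
        with pytest.warns(UserWarning, match="noise floor"):
            assert select_bands(BandScores("rf", np.ones(len(wl)), wl)) == []


class TestConfigsAndVariants:
    def test_packaged_rf_table(self):
        cfg = rf_table_config()
        assert [b.center for b in cfg.bands] == [432, 512, 592, 686, 766, 844, 929]
        assert [b.fwhm for b in cfg.bands] == [30, 30, 30, 20, 30, 20, 10]

    def test_width_scaling(self):
        cfg = SpectralConfig("x", [BandDefinition(700.0, 30.0)])
        assert width_variant(cfg, "narrow").bands[0].fwhm == pytest.approx(15.0)
        assert width_variant(cfg, "wide").bands[0].fwhm == pytest.approx(45.0)

    def test_default_variant_is_identity(self):
        cfg = rf_table_config()
        out = width_variant(cfg, "default")
        assert [(b.center, b.fwhm) for b in out.bands] == [
            (b.center, b.fwhm) for b in cfg.bands
        ]

    def test_wide_variant_drops_violating_band(self):
        cfg = SpectralConfig(
            "x", [BandDefinition(700.0, 30.0, score=2.0), BandDefinition(730.0, 30.0, score=1.0)]
        )
        with pytest.warns(UserWarning, match="dropping"):
            out = width_variant(cfg, "wide")
        assert len(out.bands) == 1
        assert out.bands[0].center == 700.0  # the higher-scoring band survives

    def test_separation_invariant_enforced(self):
        with pytest.raises(ValueError, match="closer than"):
            SpectralConfig("bad", [BandDefinition(700.0, 30.0), BandDefinition(720.0, 30.0)])

    def test_json_round_trip(self, tmp_path):
        cfg = rf_table_config()
        cfg.to_json(tmp_path / "cfg.json")
        back = SpectralConfig.from_json(tmp_path / "cfg.json")
        assert [(b.center, b.fwhm) for b in back.bands] == [
            (b.center, b.fwhm) for b in cfg.bands
        ]
        assert back.srf == cfg.srf


class TestConsensus:
    def test_identical_configs_round_trip(self):
        cfg = rf_table_config()
        out = consensus_config([cfg, cfg], tolerance_nm=10.0)
        assert [(b.center, b.fwhm) for b in out.bands] == [
            (b.center, b.fwhm) for b in cfg.bands
        ]

    def test_worked_clustering_example(self):
        a = SpectralConfig("a", [BandDefinition(c, 20.0) for c in (450, 550, 660, 840)])
        b = SpectralConfig("b", [BandDefinition(c, 20.0) for c in (455, 548, 715, 838)])
        out = consensus_config([a, b], tolerance_nm=10.0)
        np.testing.assert_allclose([x.center for x in out.bands], [452.5, 549.0, 839.0])
        out_re = consensus_config([a, b], tolerance_nm=10.0, include_red_edge=True)
        centers = [x.center for x in out_re.bands]
        assert 715.0 in centers
        red = next(x for x in out_re.bands if x.center == 715.0)
        assert red.fwhm == 30.0

    def test_no_common_bands_errors(self):
        a = SpectralConfig("a", [BandDefinition(450.0, 20.0)])
        b = SpectralConfig("b", [BandDefinition(800.0, 20.0)])
        with pytest.raises(ValueError, match="shared"):
            consensus_config([a, b], tolerance_nm=10.0)
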