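"""IS-RSA tests: similarity formula oracles, BH-FDR hand cases, cluster
extraction, the OLS reduction of the dyadic model, the statsmodels
MixedLM cross-check, planted-signal recovery and null calibration."""

import numpy as np
import pandas as pd
import pytest

from harmalloc.isrsa import (
    BetaMaps,
    _DyadGLS,
    dyad_indices,
    dyadic_regress_voxelwise,
    extract_clusters,
    fdr_threshold,
    run_isrsa,
    similarity_matrix,
)
from harmalloc.synthetic_data import PlantSpec, generate_beta_maps


class TestSimilarity:
    def test_identical_values(self):
        s = similarity_matrix(np.array([3.0, 3.0]))
        assert s[0, 1] == 1.0

    @pytest.mark.parametrize("d,expected", [(1.0, 0.5), (3.0, 0.25)])
    def test_direct_formula(self, d, expected):
        s = similarity_matrix(np.array([0.0, d]))
        assert s[0, 1] == pytest.approx(expected)

    def test_hand_phi_triple(self):
        s = similarity_matrix(np.array([-10.0, -8.0, 0.0]))
        assert s[0, 1] == pytest.approx(1 / 3)
        assert s[0, 2] == pytest.approx(1 / 11)
        assert s[1, 2] == pytest.approx(1 / 9)

    def test_matrix_properties(self, rng):
        vals = rng.normal(size=(12, 4))
        s = similarity_matrix(vals)
        assert np.allclose(s, s.T)
        assert np.allclose(np.diag(s), 1.0)
        assert ((s > 0) & (s <= 1)).all()

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            similarity_matrix(np.array([0.0, np.nan]))


class TestFdr:
    def test_all_survive_hand_case(self):
        out = fdr_threshold(np.array([0.01, 0.02, 0.03, 0.04]), q=0.05)
        assert out["survivors"].all()

    def test_none_survive_hand_case(self):
        out = fdr_threshold(np.array([0.04, 0.5, 0.9, 1.0]), q=0.05)
        assert not out["survivors"].any()

    def test_zero_pvalues_survive(self):
        out = fdr_threshold(np.zeros(7), q=0.05)
        assert out["survivors"].all()

    def test_qvalues_dominate_pvalues(self, rng):
        p = rng.random(100)
        out = fdr_threshold(p)
        assert (out["q_values"] >= p - 1e-12).all()

    def test_nan_excluded(self):
        out = fdr_threshold(np.array([0.001, np.nan, 0.002]))
        assert not out["survivors"][1]
        assert np.isnan(out["q_values"][1])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            fdr_threshold(np.array([]))


class TestClusters:
    def test_straight_line(self):
        vol = np.zeros((8, 8, 8), bool)
        vol[1, 1, 1:7] = True
        out = extract_clusters(vol, min_size=5)
        assert out["n_clusters"] == 1 and out["sizes"] == [6]

    def test_small_block_discarded(self):
        vol = np.zeros((8, 8, 8), bool)
        vol[0:2, 0:2, 0] = True  # 4 voxels
        assert extract_clusters(vol, min_size=5)["n_clusters"] == 0

    def test_two_separated_blocks(self):
        vol = np.zeros((10, 10, 10), bool)
        vol[0:5, 0, 0] = True
        vol[0:5, 5, 5] = True
        out = extract_clusters(vol, min_size=5)
        assert out["n_clusters"] == 2

    def test_diagonal_touch_requires_wider_connectivity(self):
        vol = np.zeros((6, 6, 6), bool)
        vol[0:5, 0, 0] = True
        vol[5, 1, 0] = True  # touches only diagonally in-plane
        assert extract_clusters(vol, min_size=6, connectivity=6)[
            "n_clusters"] == 0
        assert extract_clusters(vol, min_size=6, connectivity=18)[
            "n_clusters"] == 1


class TestDyadicRegression:
    def test_reduces_to_ols_without_random_effects(self, rng):
        """With the random intercepts removed (theta = 0), the GLS solution
        must equal the closed-form OLS solution on the dyads."""
        n = 7
        ii, jj = dyad_indices(n)
        nd = len(ii)
        X = np.column_stack([np.ones(nd), rng.random(nd), rng.random(nd)])
        beta_true = np.array([0.2, 0.8, -0.3])
        y = X @ beta_true + rng.normal(0, 0.1, nd)  # no subject structure
        gls = _DyadGLS(n, X)
        _, beta0, _, _ = gls._profile(0.0, gls.Q.T @ y)
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        np.testing.assert_allclose(beta0, ols, atol=1e-10)
        # and the full REML fit stays near OLS on structureless data
        np.testing.assert_allclose(gls.fit(y)["coef"], ols, atol=0.05)

    def test_matches_statsmodels_mixedlm(self, rng):
        import statsmodels.api as sm

        n = 9
        ii, jj = dyad_indices(n)
        nd = len(ii)
        x1, x2 = rng.random(nd), rng.random(nd)
        u = rng.normal(0, 0.6, n)
        y = 0.3 + 1.1 * x1 - 0.4 * x2 + u[ii] + u[jj] + rng.normal(0, 0.4, nd)
        X = np.column_stack([np.ones(nd), x1, x2])
        ours = _DyadGLS(n, X).fit(y)

        Z = np.zeros((nd, n))
        Z[np.arange(nd), ii] = 1.0
        Z[np.arange(nd), jj] = 1.0
        import warnings as _w
        with _w.catch_warnings():
            _w.simplefilter("ignore")
            ref = sm.MixedLM(y, X, groups=np.ones(nd),
                             exog_vc={"subj": {1.0: Z}}).fit(reml=True)
        np.testing.assert_allclose(ours["coef"], np.asarray(ref.fe_params),
                                   atol=1e-5)
        assert ours["s2_subject"] == pytest.approx(float(ref.vcomp[0]),
                                                   abs=1e-4)
        assert ours["s2_resid"] == pytest.approx(float(ref.scale), abs=1e-4)

    def test_planted_deterministic_voxel(self, rng):
        # neural similarity constructed to equal the phi similarity
        n = 12
        phi = rng.normal(0, 5, n)
        maps = BetaMaps(phi[:, None], (1, 1, 1), mask=np.array([True]))
        res = dyadic_regress_voxelwise(
            maps, similarity_matrix(phi),
            similarity_matrix(rng.normal(size=n)))
        assert res["coef_phi"].iloc[0] == pytest.approx(1.0, abs=1e-6)
        assert res["p_phi"].iloc[0] < 1e-8

    def test_zero_variance_voxel_flagged(self, rng):
        n = 8
        data = np.column_stack([np.full(n, 2.5), rng.normal(size=n)])
        maps = BetaMaps(data, (2, 1, 1))
        res = dyadic_regress_voxelwise(
            maps, similarity_matrix(rng.normal(size=n)),
            similarity_matrix(rng.normal(size=n)))
        assert not res["defined"].iloc[0]
        assert np.isnan(res["p_phi"].iloc[0])
        assert res["defined"].iloc[1]

    def test_too_few_subjects_rejected(self, rng):
        maps = BetaMaps(rng.normal(size=(2, 3)), (3, 1, 1))
        with pytest.raises(ValueError):
            dyadic_regress_voxelwise(maps, np.eye(2), np.eye(2))

    def test_null_voxels_type_one_calibration(self, rng):
        """Independent-noise voxels: the phi coefficient's p-values should
        be approximately uniform (empirical rate at .05 within ~4 binomial
        SDs for 500 voxels)."""
        n = 16
        phi = rng.normal(-10, 12, n)
        alpha = rng.normal(0.9, 0.05, n)
        maps = BetaMaps(rng.normal(size=(n, 500)), (500, 1, 1))
        res = dyadic_regress_voxelwise(
            maps, similarity_matrix(phi), similarity_matrix(alpha))
        p = res["p_phi"].to_numpy()
        rate = float(np.mean(p < 0.05))
        assert 0.01 <= rate <= 0.09
        # gross uniformity: median near 0.5
        assert 0.35 < np.median(p) < 0.65


class TestPlantedPipeline:
    def test_planted_region_recovered_and_null_clean(self):
        params = pd.DataFrame({
            "subject": np.arange(16),
            "phi": np.random.default_rng(3).normal(-10, 12, 16),
            "alpha": np.random.default_rng(4).normal(0.92, 0.04, 16),
        })
        plant = PlantSpec(corner=(2, 2, 2), size=(5, 5, 5), slope=1.0)
        maps = generate_beta_maps(params, grid_shape=(10, 10, 10),
                                  plant=plant, noise_sd=1.0, seed=5)
        res = run_isrsa(maps, params["phi"].to_numpy(),
                        params["alpha"].to_numpy())
        assert res["clusters"]["n_clusters"] >= 1
        labels = res["clusters"]["labels"] > 0
        inside = plant.voxel_weights((10, 10, 10)).reshape(10, 10, 10) > 0
        # the dominant cluster lies inside the plant
        assert (labels & inside).sum() > 0.5 * inside.sum()
        assert (labels & ~inside).sum() < 0.1 * (~inside).sum()

    def test_no_plant_no_clusters_beyond_chance(self):
        params = pd.DataFrame({
            "subject": np.arange(14),
            "phi": np.random.default_rng(6).normal(-10, 12, 14),
            "alpha": np.random.default_rng(7).normal(0.92, 0.04, 14),
        })
        maps = generate_beta_maps(params, grid_shape=(10, 10, 10),
                                  plant=None, seed=8)
        res = run_isrsa(maps, params["phi"].to_numpy(),
                        params["alpha"].to_numpy())
        assert res["survivors"].sum() <= 5  # FDR on a global null
        assert res["clusters"]["n_clusters"] == 0
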