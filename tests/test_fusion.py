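import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from scipy.stats import pearsonr, spearmanr

import ipf
from ipf.datasets import OmicsDataset
from ipf.fusion import (
    FeatureDissimilarity,
    ThinPlateSmoother,
    concatenate,
    correlation_matrix,
    dissimilarity,
    embed,
    ftp_render,
    mixed_correlation,
    smooth_patients,
    unit_grid,
)


def _dissim_from_points(points, ids=None):
    D = squareform(pdist(points))
    D = D / D.max() if D.max() > 0 else D
    ids = ids or [f"f{i}" for i in range(len(points))]
    Ddf = pd.DataFrame(D, index=ids, columns=ids)
    return dissimilarity(pd.DataFrame(1 - 2 * Ddf.to_numpy(), index=ids, columns=ids))


class TestConcatenate:
    def test_stacking_and_origin(self):
        ids = ["s1", "s2", "s3"]
        a = OmicsDataset("a", pd.DataFrame(np.ones((3, 5)), index=ids,
                                           columns=[f"a{j}" for j in range(5)]))
        b = OmicsDataset("b", pd.DataFrame(np.zeros((3, 3)), index=ids,
                                           columns=[f"b{j}" for j in range(3)]))
        cat = concatenate([a, b])
        assert cat.matrix.shape == (8, 3)
        assert list(cat.origin) == ["a"] * 5 + ["b"] * 3

    def test_misaligned_samples_rejected(self):
        a = OmicsDataset("a", pd.DataFrame(np.ones((2, 2)), index=["s1", "s2"],
                                           columns=["a1", "a2"]))
        b = OmicsDataset("b", pd.DataFrame(np.ones((2, 2)), index=["s2", "s1"],
                                           columns=["b1", "b2"]))
        with pytest.raises(ValueError, match="align"):
            concatenate([a, b])

    def test_split_by_origin_round_trips(self):
        ids = ["s1", "s2", "s3", "s4"]
        rng = np.random.default_rng(0)
        a = OmicsDataset("a", pd.DataFrame(rng.normal(size=(4, 3)), index=ids,
                                           columns=["a1", "a2", "a3"]))
        b = OmicsDataset("b", pd.DataFrame(rng.normal(size=(4, 2)), index=ids,
                                           columns=["b1", "b2"]))
        parts = concatenate([a, b]).split_by_origin()
        pd.testing.assert_frame_equal(parts["a"], a.values.T)
        pd.testing.assert_frame_equal(parts["b"], b.values.T)


class TestMixedCorrelation:
    def test_self_and_antisymmetry(self):
        x = np.array([0.3, 1.2, -0.5, 2.0, 0.1])
        assert mixed_correlation(x, x, "continuous", "continuous") == pytest.approx(1.0)
        assert mixed_correlation(x, -x, "continuous", "continuous") == pytest.approx(-1.0)

    def test_point_biserial_equals_pearson(self):
        b = np.array([0.0, 0.0, 1.0, 1.0])
        y = np.array([1.0, 2.0, 3.0, 4.0])
        expected = pearsonr(b, y).statistic
        assert mixed_correlation(b, y, "binary", "continuous") == pytest.approx(expected)

    def test_phi_perfect_association(self):
        b1 = np.array([0.0, 0.0, 1.0, 1.0])
        assert mixed_correlation(b1, b1, "binary", "binary") == pytest.approx(1.0)
        assert mixed_correlation(b1, 1 - b1, "binary", "binary") == pytest.approx(-1.0)

    def test_ordinal_pair_uses_spearman(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=30)
        o = np.floor(rng.uniform(0, 4, 30))
        expected = spearmanr(x, o).statistic
        assert mixed_correlation(x, o, "continuous", "ordinal") == pytest.approx(expected)

    def test_categorical_perfect_association_is_one(self):
        c = np.array([0, 0, 1, 1, 2, 2], dtype=float)
        assert mixed_correlation(c, c, "categorical", "categorical") == pytest.approx(1.0)

    def test_too_few_complete_pairs_warns_and_zeroes(self):
        x = np.array([1.0, np.nan, np.nan, 2.0])
        y = np.array([np.nan, 1.0, 2.0, 3.0])
        with pytest.warns(UserWarning, match="complete pairs"):
            assert mixed_correlation(x, y, "continuous", "continuous") == 0.0

    def test_matrix_agrees_with_pairwise_dispatch(self, mixed_dataset):
        from ipf.preprocess import standardize

        std = standardize(mixed_dataset)
        cat = concatenate([std])
        R = correlation_matrix(cat)
        ids = cat.feature_ids
        X = cat.matrix.to_numpy()
        types = list(cat.var_types)
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                expected = mixed_correlation(X[i], X[j], types[i], types[j])
                assert R.iloc[i, j] == pytest.approx(expected, abs=1e-10), (
                    ids[i], ids[j],
                )


class TestDissimilarity:
    @pytest.mark.parametrize("r,d", [(1.0, 0.0), (-1.0, 1.0), (0.0, 0.5)])
    def test_endpoints_and_midpoint(self, r, d):
        R = pd.DataFrame([[1.0, r], [r, 1.0]], index=["a", "b"], columns=["a", "b"])
        out = dissimilarity(R)
        assert out.D.loc["a", "b"] == pytest.approx(d)
        assert out.D.loc["a", "a"] == 0.0

    def test_out_of_range_rejected(self):
        R = pd.DataFrame([[1.0, 1.5], [1.5, 1.0]], index=["a", "b"], columns=["a", "b"])
        with pytest.raises(ValueError, match=r"\[-1, 1\]"):
            dissimilarity(R)


class TestEmbed:
    def test_equidistant_triangle_stays_equilateral(self):
        ids = ["a", "b", "c"]
        D = pd.DataFrame(0.5 - 0.5 * np.eye(3), index=ids, columns=ids)
        emb = embed(FeatureDissimilarity(D, 1 - 2 * D), seed=0)
        d = pdist(emb.coords_raw)
        assert (d.max() - d.min()) / d.mean() < 0.05

    def test_identical_features_are_nearest_neighbours(self):
        rng = np.random.default_rng(0)
        pts = rng.random((8, 2))
        pts[2] = pts[1]  # duplicate feature
        dis = _dissim_from_points(pts)
        emb = embed(dis, seed=0)
        C = emb.coords.to_numpy()
        dup = np.linalg.norm(C[1] - C[2])
        assert dup == pytest.approx(pdist(C).min(), abs=1e-9)
        assert dup < 0.25 * np.median(pdist(C))

    def test_rank_order_preserved_on_small_instance(self):
        rng = np.random.default_rng(5)
        dis = _dissim_from_points(rng.random((8, 2)))
        emb = embed(dis, seed=0)
        rho = spearmanr(
            pdist(emb.coords_raw), squareform(dis.D.to_numpy(), checks=False)
        ).statistic
        assert rho > 0.9

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(1)
        dis = _dissim_from_points(rng.random((10, 2)))
        a = embed(dis, seed=3)
        b = embed(dis, seed=3)
        assert np.array_equal(a.coords.to_numpy(), b.coords.to_numpy())
        assert a.stress == b.stress

    def test_unit_square_rescaling(self):
        rng = np.random.default_rng(2)
        dis = _dissim_from_points(rng.random((12, 2)))
        emb = embed(dis, seed=0)
        C = emb.coords.to_numpy()
        np.testing.assert_allclose(C.min(axis=0), [0, 0], atol=1e-12)
        np.testing.assert_allclose(C.max(axis=0), [1, 1], atol=1e-12)


@pytest.fixture(scope="module")
def coords():
    return np.random.default_rng(0).random((60, 2))


class TestSmoothing:

    def test_constants_reproduced(self, coords):
        sm = ThinPlateSmoother(coords)
        g = sm.fit(np.full((60, 1), 2.5)).predict(unit_grid(10))
        np.testing.assert_allclose(g, 2.5, atol=1e-6)

    def test_linear_surface_reproduced(self, coords):
        sm = ThinPlateSmoother(coords)
        y = 1.0 + 2.0 * coords[:, 0] - 3.0 * coords[:, 1]
        grid = unit_grid(10)
        truth = 1.0 + 2.0 * grid[:, 0] - 3.0 * grid[:, 1]
        g = sm.fit(y[:, None]).predict(grid)[:, 0]
        np.testing.assert_allclose(g, truth, atol=1e-3)

    def test_shift_equivariance(self, coords):
        rng = np.random.default_rng(4)
        y = rng.normal(size=60)
        sm = ThinPlateSmoother(coords)
        grid = unit_grid(10)
        g1 = sm.fit(y[:, None]).predict(grid)[:, 0]
        g2 = sm.fit((y + 7.0)[:, None]).predict(grid)[:, 0]
        np.testing.assert_allclose(g2 - g1, 7.0, atol=1e-6)

    def test_noise_suppression(self, coords):
        rng = np.random.default_rng(8)
        signal = np.sin(2 * np.pi * coords[:, 0]) * np.cos(2 * np.pi * coords[:, 1])
        noisy = signal + 0.5 * rng.normal(size=60)
        fit = ThinPlateSmoother(coords).fit(noisy[:, None])
        smoothed = fit.predict(coords)[:, 0]
        assert np.mean((smoothed - signal) ** 2) < np.mean((noisy - signal) ** 2)

    def test_missing_features_excluded_per_patient(self):
        rng = np.random.default_rng(1)
        coords = rng.random((40, 2))
        emb = ipf.FeatureEmbedding(
            pd.DataFrame(coords, index=[f"f{i}" for i in range(40)],
                         columns=["u1", "u2"]),
            0.0,
        )
        vals = pd.DataFrame(
            rng.normal(size=(5, 40)), index=[f"s{i}" for i in range(5)],
            columns=emb.feature_ids,
        )
        vals.iloc[0, :5] = np.nan
        prof = smooth_patients(emb, vals, grid_n=8)
        assert prof.values.shape == (5, 81)
        assert np.isfinite(prof.values.to_numpy()).all()

    def test_profile_length_invariant(self, fitted_pipeline):
        prof = fitted_pipeline["trained"].profiles
        assert prof.values.shape[1] == (prof.grid_n + 1) ** 2


class TestFtpRender:
    def test_constant_profile_renders(self):
        import matplotlib

        matplotlib.use("Agg")
        ftp_render(np.zeros(81), 8)

    def test_opposite_signals_anticorrelated_grids(self, fitted_pipeline):
        trained = fitted_pipeline["trained"]
        from ipf.clustering import cluster_average_ftp

        avg = cluster_average_ftp(trained.profiles, trained.solution)
        # mean-centred cluster averages: at least one pair of clusters shows
        # inverted fields (negative correlation)
        A = avg.values.to_numpy()
        A = A - A.mean(axis=0)
        cors = np.corrcoef(A)
        assert cors[np.triu_indices(len(A), 1)].min() < 0
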