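"""Tree proximity, classical MDS, Gaussian-mixture EM and hot/cold labels."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial import procrustes

from immunemap.immune_map import (
    GmmFit,
    build_immune_map,
    classical_mds,
    gmm_em,
    label_hot_cold,
    mds_embed,
    tree_proximity,
)
from immunemap.types import ValidationError


def blob_features(rng, n_per=15, n_feat=40, sep=4.0):
    """Two well-separated Gaussian blobs with sample ids P*_L*."""
    a = rng.normal(0.0, 1.0, size=(n_per, n_feat))
    b = rng.normal(sep, 1.0, size=(n_per, n_feat))
    ids = [f"P{i:02d}_L1" for i in range(n_per)] + [f"Q{i:02d}_L1" for i in range(n_per)]
    return pd.DataFrame(np.vstack([a, b]), index=ids)


class TestProximity:
    def test_identical_rows_have_proximity_one(self, rng):
        df = blob_features(rng, n_per=6)
        df.iloc[1] = df.iloc[0]
        prox = tree_proximity(df, n_iter=20, seed=0)
        assert prox.iloc[0, 1] == pytest.approx(1.0)

    def test_structural_invariants(self, rng):
        df = blob_features(rng, n_per=8)
        prox = tree_proximity(df, n_iter=25, seed=1).to_numpy()
        assert np.allclose(prox, prox.T)
        assert np.allclose(np.diag(prox), 1.0)
        assert prox.min() >= 0.0 and prox.max() <= 1.0

    def test_constant_features_rejected(self):
        df = pd.DataFrame(np.ones((8, 5)), index=[f"P{i}_L1" for i in range(8)])
        with pytest.raises(ValidationError, match="constant"):
            tree_proximity(df)

    def test_blob_structure_recovered(self, rng):
        hits = 0
        for seed in range(5):
            df = blob_features(np.random.default_rng(100 + seed))
            prox = tree_proximity(df, n_iter=40, seed=seed).to_numpy()
            n = len(df) // 2
            within = (prox[:n, :n].sum() - n) / (n * n - n) / 2 + (
                prox[n:, n:].sum() - n
            ) / (n * n - n) / 2
            between = prox[:n, n:].mean()
            if within > between:
                hits += 1
        assert hits == 5

    def test_deterministic_given_seed(self, rng):
        df = blob_features(rng, n_per=7)
        a = tree_proximity(df, n_iter=15, seed=3)
        b = tree_proximity(df, n_iter=15, seed=3)
        pd.testing.assert_frame_equal(a, b)


class TestMds:
    def test_all_ones_proximity_collapses_to_origin(self):
        prox = pd.DataFrame(np.ones((5, 5)), index=list("abcde"), columns=list("abcde"))
        with pytest.warns(UserWarning):
            coords = mds_embed(prox)
        assert np.allclose(coords.to_numpy(), 0.0)

    def test_exact_recovery_of_planar_points(self, rng):
        pts = rng.normal(size=(6, 2))
        d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2))
        coords = classical_mds(d)
        _, _, disparity = procrustes(pts, coords)
        assert disparity < 1e-18  # squared error; RMS < 1e-9

    def test_permutation_equivariance(self, rng):
        pts = rng.normal(size=(7, 2))
        d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2))
        perm = rng.permutation(7)
        base = classical_mds(d)
        permuted = classical_mds(d[np.ix_(perm, perm)])
        _, _, disparity = procrustes(base[perm], permuted)
        assert disparity < 1e-18


class TestGmm:
    def test_loglik_monotone(self, rng):
        x = np.vstack(
            [rng.normal(0, 1, size=(40, 2)), rng.normal(3, 1, size=(40, 2))]
        )
        fit = gmm_em(x, k=2, seed=0)
        diffs = np.diff(fit.log_likelihoods)
        assert (diffs >= -1e-9).all()

    def test_k1_closed_form(self, rng):
        x = rng.normal(size=(30, 2))
        fit = gmm_em(x, k=1)
        assert np.allclose(fit.means[0], x.mean(axis=0), atol=1e-12)
        assert np.allclose(fit.covariances[0], np.cov(x.T, ddof=0), atol=1e-12)

    def test_planted_two_component_recovery(self):
        rng = np.random.default_rng(5)
        a = rng.normal((-2.0, 0.0), 0.5, size=(100, 2))
        b = rng.normal((2.0, 0.0), 0.5, size=(100, 2))
        x = np.vstack([a, b])
        fit = gmm_em(x, k=2, seed=0)
        means = fit.means[np.argsort(fit.means[:, 0])]
        assert np.abs(means[0] - np.array([-2.0, 0.0])).max() < 0.2
        assert np.abs(means[1] - np.array([2.0, 0.0])).max() < 0.2
        labels = fit.labels
        truth = np.r_[np.zeros(100), np.ones(100)]
        acc = max((labels == truth).mean(), (labels != truth).mean())
        assert acc >= 0.98

    def test_too_few_points_rejected(self):
        with pytest.raises(ValidationError):
            gmm_em(np.zeros((3, 2)), k=2)


class TestLabels:
    def _fit_and_coords(self, rng):
        coords = pd.DataFrame(
            np.vstack([rng.normal(-2, 0.3, (10, 2)), rng.normal(2, 0.3, (10, 2))]),
            index=[f"P{i:02d}_L{j}" for i in range(10) for j in (1, 2)],
            columns=["MDS1", "MDS2"],
        )
        fit = gmm_em(coords.to_numpy(), k=2, seed=0)
        return fit, coords

    def test_component_with_higher_cytolytic_is_hot(self, rng):
        fit, coords = self._fit_and_coords(rng)
        cyto = pd.Series(
            np.where(coords["MDS1"] > 0, 50.0, 5.0), index=coords.index
        )
        res = label_hot_cold(fit, cyto, coords)
        assert (res.labels[coords["MDS1"] > 0] == "hot").all()
        assert (res.labels[coords["MDS1"] < 0] == "cold").all()
        assert np.allclose(res.responsibilities.sum(axis=1), 1.0)

    def test_component_swap_invariance(self, rng):
        fit, coords = self._fit_and_coords(rng)
        cyto = pd.Series(np.where(coords["MDS1"] > 0, 50.0, 5.0), index=coords.index)
        swapped = GmmFit(
            weights=fit.weights[::-1].copy(),
            means=fit.means[::-1].copy(),
            covariances=fit.covariances[::-1].copy(),
            responsibilities=fit.responsibilities[:, ::-1].copy(),
            log_likelihoods=fit.log_likelihoods,
            converged=fit.converged,
        )
        a = label_hot_cold(fit, cyto, coords)
        b = label_hot_cold(swapped, cyto, coords)
        pd.testing.assert_series_equal(a.labels, b.labels)

    def test_patient_status_all_same_state(self, rng):
        fit, coords = self._fit_and_coords(rng)
        cyto = pd.Series(np.where(coords["MDS1"] > 0, 50.0, 5.0), index=coords.index)
        res = label_hot_cold(fit, cyto, coords)
        # force an all-hot label set: every patient must read homogeneous
        res.labels[:] = "hot"
        status = res.patient_status()
        assert (status["status"] == "homogeneous").all()


def test_full_map_pipeline_deterministic(rng):
    df = blob_features(rng, n_per=10, n_feat=30)
    cyto = pd.Series(
        np.r_[np.full(10, 5.0), np.full(10, 50.0)] + rng.normal(0, 0.1, 20),
        index=df.index,
    )
    a = build_immune_map(df, cyto, n_iter=30, seed=4)
    b = build_immune_map(df, cyto, n_iter=30, seed=4)
    pd.testing.assert_series_equal(a.labels, b.labels)
    pd.testing.assert_frame_equal(a.coords, b.coords)
    # the high-cytolytic blob is the hot one
    assert (a.labels[10:] == "hot").all()
    assert (a.labels[:10] == "cold").all()
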