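"""Immune-map construction: tree proximity, MDS embedding, Gaussian-mixture
hot/cold categorization.

The map is built in three unsupervised stages from the 278-feature matrix:

1. **Proximity.** 100 iterations; each draws two-thirds of the samples as a
   discovery set, trains a single classification tree to separate the real
   discovery rows from a synthetic contrast (each feature column permuted
   independently, the Breiman unsupervised-forest device), and pushes *all*
   samples down the tree. A pair's proximity is the fraction of iterations
   in which it lands in the same terminal node. Trees whose real-vs-synthetic
   accuracy on the held-out third is below 0.55 are rebuilt once.
2. **Embedding.** Classical (Torgerson) MDS on D = sqrt(1 - proximity)
   projects samples to the plane.
3. **Categorization.** A two-component full-covariance Gaussian mixture is
   fitted by EM on the 2-D coordinates; the component with the higher
   responsibility-weighted mean cytolytic activity is labelled *hot*, the
   other *cold*.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeClassifier

from .types import ValidationError

N_ITER_DEFAULT = 100
DISCOVERY_FRAC = 2.0 / 3.0
TREE_MIN_ACCURACY = 0.55
GMM_RIDGE = 1e-6


def _as_frame(features) -> pd.DataFrame:
    df = getattr(features, "df", features)
    if not isinstance(df, pd.DataFrame):
        raise TypeError("features must be a DataFrame or FeatureMatrix")
    return df


def tree_proximity(
    features,
    n_iter: int = N_ITER_DEFAULT,
    discovery_frac: float = DISCOVERY_FRAC,
    seed: int = 0,
    trees_per_iter: int = 1,
) -> pd.DataFrame:
    """Samples x samples proximity matrix from iterated unsupervised trees."""
    df = _as_frame(features)
    x = df.to_numpy(dtype=float)
    n, p = x.shape
    if n < 6:
        raise ValidationError("proximity needs at least 6 samples")
    if np.all(x.std(axis=0) == 0):
        raise ValidationError("all features are constant; no tree splits possible")
    rng = np.random.default_rng(seed)
    n_disc = math.ceil(discovery_frac * n)
    prox = np.zeros((n, n))

    def permuted(r: np.random.Generator) -> np.ndarray:
        synth = np.empty_like(x)
        for j in range(p):
            synth[:, j] = x[r.permutation(n), j]
        return synth

    def fit_one(r: np.random.Generator, disc: np.ndarray) -> DecisionTreeClassifier:
        synth = permuted(r)
        train = np.vstack([x[disc], synth[disc]])
        labels = np.r_[np.ones(len(disc)), np.zeros(len(disc))]
        tree = DecisionTreeClassifier(
            max_features="sqrt", random_state=int(r.integers(2**31 - 1))
        )
        tree.fit(train, labels)
        valid = np.setdiff1d(np.arange(n), disc)
        if len(valid):
            vx = np.vstack([x[valid], synth[valid]])
            vy = np.r_[np.ones(len(valid)), np.zeros(len(valid))]
            acc = (tree.predict(vx) == vy).mean()
        else:
            acc = 1.0
        return tree, acc

    for _ in range(n_iter):
        disc = rng.choice(n, size=n_disc, replace=False)
        incr = np.zeros((n, n))
        for _t in range(trees_per_iter):
            tree, acc = fit_one(rng, disc)
            if acc < TREE_MIN_ACCURACY:  # degenerate tree: rebuild once
                tree, acc = fit_one(rng, disc)
            leaves = tree.apply(x)
            incr += (leaves[:, None] == leaves[None, :]).astype(float)
        prox += incr / trees_per_iter
    prox /= n_iter
    np.fill_diagonal(prox, 1.0)
    return pd.DataFrame(prox, index=df.index, columns=df.index)


def mds_embed(prox: pd.DataFrame, dissimilarity: str = "sqrt") -> pd.DataFrame:
    """Classical (Torgerson) MDS of a proximity matrix to 2 dimensions.

    Dissimilarity is sqrt(1 - proximity) by default (``dissimilarity="linear"``
    uses 1 - proximity). The sign of each axis is fixed so the first sample
    has non-negative coordinates.
    """
    p = prox.to_numpy(dtype=float)
    if not np.allclose(p, p.T):
        raise ValidationError("proximity matrix must be symmetric")
    if dissimilarity == "sqrt":
        d = np.sqrt(np.clip(1.0 - p, 0.0, None))
    elif dissimilarity == "linear":
        d = np.clip(1.0 - p, 0.0, None)
    else:
        raise ValidationError(f"unknown dissimilarity {dissimilarity!r}")
    coords = classical_mds(d, n_components=2)
    return pd.DataFrame(coords, index=prox.index, columns=["MDS1", "MDS2"])


def classical_mds(d: np.ndarray, n_components: int = 2) -> np.ndarray:
    """Torgerson double-centering MDS of a distance matrix."""
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d ** 2) @ j
    b = (b + b.T) / 2.0
    evals, evecs = np.linalg.eigh(b)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = evals > 1e-12
    n_pos = int(pos[:n_components].sum())
    if n_pos < n_components:
        warnings.warn(
            f"only {n_pos} positive eigenvalues; padding remaining dimensions with zeros",
            stacklevel=2,
        )
    coords = np.zeros((n, n_components))
    for k in range(n_pos):
        coords[:, k] = evecs[:, k] * np.sqrt(evals[k])
    for k in range(n_components):  # deterministic axis orientation
        if coords[0, k] < 0:
            coords[:, k] = -coords[:, k]
    return coords


@dataclass
class GmmFit:
    """Parameters and responsibilities of a fitted Gaussian mixture."""

    weights: np.ndarray
    means: np.ndarray
    covariances: np.ndarray
    responsibilities: np.ndarray
    log_likelihoods: list[float]
    converged: bool

    @property
    def labels(self) -> np.ndarray:
        return self.responsibilities.argmax(axis=1)


def _log_gauss(x: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> np.ndarray:
    dim = x.shape[1]
    chol = np.linalg.cholesky(cov)
    diff = x - mean
    sol = np.linalg.solve(chol, diff.T)
    maha = (sol ** 2).sum(axis=0)
    logdet = 2.0 * np.log(np.diag(chol)).sum()
    return -0.5 * (dim * np.log(2 * np.pi) + logdet + maha)


def gmm_em(
    coords,
    k: int = 2,
    seed: int = 0,
    tol: float = 1e-8,
    max_iter: int = 500,
    ridge: float = GMM_RIDGE,
) -> GmmFit:
    """Full-covariance Gaussian-mixture EM.

    Means are initialized at a farthest-point traversal of the data (for k=2,
    the farthest pair), components start with the shared sample covariance,
    and near-singular M-step covariances get a small diagonal ridge. The EM
    log likelihood is non-decreasing; convergence is a gain below ``tol``.
    """
    x = np.asarray(getattr(coords, "values", coords), dtype=float)
    if x.ndim != 2:
        raise ValidationError("coords must be 2-dimensional (n x d)")
    n, dim = x.shape
    if n < 2 * k:
        raise ValidationError(f"need at least {2 * k} points for k={k}")
    base_cov = np.cov(x.T, ddof=0).reshape(dim, dim) + ridge * np.eye(dim)

    if k == 1:
        mean = x.mean(axis=0)
        cov = np.cov(x.T, ddof=0).reshape(dim, dim)
        resp = np.ones((n, 1))
        ll = float(_log_gauss(x, mean, cov + ridge * np.eye(dim)).sum())
        return GmmFit(np.array([1.0]), mean[None, :], cov[None, :, :], resp, [ll], True)

    # farthest-point initialization (deterministic given the data)
    d2 = ((x[:, None, :] - x[None, :, :]) ** 2).sum(axis=2)
    i, j = np.unravel_index(np.argmax(d2), d2.shape)
    centers = [x[i], x[j]]
    while len(centers) < k:
        dist = np.min([((x - c) ** 2).sum(axis=1) for c in centers], axis=0)
        centers.append(x[int(np.argmax(dist))])
    means = np.array(centers)
    covs = np.array([base_cov.copy() for _ in range(k)])
    weights = np.full(k, 1.0 / k)

    lls: list[float] = []
    converged = False
    resp = np.full((n, k), 1.0 / k)
    for _ in range(max_iter):
        # E-step
        logp = np.column_stack(
            [np.log(weights[c]) + _log_gauss(x, means[c], covs[c]) for c in range(k)]
        )
        m = logp.max(axis=1, keepdims=True)
        lse = m[:, 0] + np.log(np.exp(logp - m).sum(axis=1))
        resp = np.exp(logp - lse[:, None])
        ll = float(lse.sum())
        if lls and (ll - lls[-1]) < tol:
            lls.append(ll)
            converged = True
            break
        lls.append(ll)
        # M-step; the ridge is applied only to near-singular covariances so
        # the exact-EM monotonicity guarantee holds in the regular case
        nk = resp.sum(axis=0)
        weights = nk / n
        means = (resp.T @ x) / nk[:, None]
        for c in range(k):
            diff = x - means[c]
            cov = (resp[:, c][:, None] * diff).T @ diff / nk[c]
            if np.linalg.eigvalsh(cov).min() < ridge:
                cov = cov + ridge * np.eye(dim)
            covs[c] = cov
    if not converged:
        warnings.warn(f"EM did not converge in {max_iter} iterations", stacklevel=2)
    return GmmFit(weights, means, covs, resp, lls, converged)


@dataclass
class ImmuneMapResult:
    """Full immune-map output for one cohort."""

    proximity: pd.DataFrame
    coords: pd.DataFrame
    gmm: GmmFit
    labels: pd.Series  # "hot" / "cold" per sample
    hot_component: int
    component_cytolytic: np.ndarray
    responsibilities: pd.DataFrame = field(default=None)

    def patient_status(self) -> pd.DataFrame:
        """Per-patient homogeneous/heterogeneous immune-status summary.

        Patients are recovered from sample ids of the form
        ``<patient>_<locus>``.
        """
        patients = self.labels.index.str.rsplit("_", n=1).str[0]
        rows = []
        for pat, grp in self.labels.groupby(patients):
            kinds = set(grp)
            rows.append(
                {
                    "patient_id": pat,
                    "n_hot": int((grp == "hot").sum()),
                    "n_cold": int((grp == "cold").sum()),
                    "status": "heterogeneous" if len(kinds) > 1 else "homogeneous",
                }
            )
        return pd.DataFrame(rows).set_index("patient_id")


def label_hot_cold(gmm: GmmFit, cytolytic: pd.Series, coords: pd.DataFrame) -> ImmuneMapResult:
    """Name mixture components hot/cold by responsibility-weighted cytolytic
    activity and produce per-sample labels."""
    act = cytolytic.reindex(coords.index)
    if act.isna().any():
        missing = act.index[act.isna()].tolist()
        raise ValidationError(f"cytolytic activity missing for sample(s): {missing[:5]}")
    resp = gmm.responsibilities
    comp_act = (resp * act.to_numpy()[:, None]).sum(axis=0) / resp.sum(axis=0)
    order = np.argsort(comp_act)
    if comp_act[order[-1]] == comp_act[order[-2]]:
        raise ValidationError("components have identical mean cytolytic activity; re-seed")
    hot = int(np.argmax(comp_act))
    hard = gmm.labels
    labels = pd.Series(
        np.where(hard == hot, "hot", "cold"), index=coords.index, name="immune_status"
    )
    resp_df = pd.DataFrame(
        resp,
        index=coords.index,
        columns=["hot" if c == hot else "cold" for c in range(resp.shape[1])],
    )
    return ImmuneMapResult(
        proximity=None,
        coords=coords,
        gmm=gmm,
        labels=labels,
        hot_component=hot,
        component_cytolytic=comp_act,
        responsibilities=resp_df,
    )


def build_immune_map(
    features,
    cytolytic: pd.Series,
    n_iter: int = N_ITER_DEFAULT,
    seed: int = 0,
    discovery_frac: float = DISCOVERY_FRAC,
) -> ImmuneMapResult:
    """Proximity -> MDS -> GMM -> hot/cold labels in one call."""
    prox = tree_proximity(features, n_iter=n_iter, discovery_frac=discovery_frac, seed=seed)
    coords = mds_embed(prox)
    fit = gmm_em(coords.to_numpy(), k=2, seed=seed)
    result = label_hot_cold(fit, cytolytic, coords)
    result.proximity = prox
    return result
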