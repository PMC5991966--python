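"""Low-dimensional embeddings of the conformational ensemble.

Three complementary maps of the n x 3m coordinate matrix are provided:

* PCA — linear modes ranked by captured variance (covariance eigenvectors);
* FastICA — statistically independent, non-Gaussian directions (deflationary
  fixed-point iteration with the log cosh contrast, after PCA whitening);
* LLE — neighborhood-preserving nonlinear embedding (per-sample barycentric
  reconstruction weights over k nearest neighbors, then the bottom
  non-trivial eigenvectors of (I-W)'(I-W)).

Hierarchical clustering of any of these score spaces picks representative
structures (clustroids).  PCA and LLE are deterministic; FastICA requires a
seed.  All component signs are fixed deterministically so repeated runs
write identical score files.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist
from scipy.stats import pearsonr

from .ensemble_geometry import EnsembleMatrix

logger = logging.getLogger(__name__)


@dataclass
class Embedding:
    method: str
    scores: np.ndarray                        # (n, d)
    components: np.ndarray | None = None      # (d, 3m), PCA/ICA only
    variance_fractions: np.ndarray | None = None  # PCA only
    params: dict = field(default_factory=dict)
    converged: bool = True

    @property
    def d(self) -> int:
        return self.scores.shape[1]


def _fix_signs(scores: np.ndarray, components: np.ndarray | None = None):
    """Flip each component so its largest-magnitude loading (or score, if no
    loadings exist) is positive.  In-place on copies; returns the pair."""
    scores = scores.copy()
    components = None if components is None else components.copy()
    ref = components if components is not None else scores.T
    for j in range(scores.shape[1]):
        v = ref[j] if components is not None else scores[:, j]
        if v[int(np.argmax(np.abs(v)))] < 0:
            scores[:, j] *= -1
            if components is not None:
                components[j] *= -1
    return scores, components


def pca(ensemble: EnsembleMatrix, d: int) -> Embedding:
    """Principal component analysis of the column-centered coordinate matrix.

    ``variance_fractions[j]`` is the j-th covariance eigenvalue divided by
    the total variance, so the full-rank fractions sum to 1.
    """
    X = ensemble.coords
    n = X.shape[0]
    if not 1 <= d <= n - 1:
        raise ValueError(f"d={d} out of range 1..{n - 1}")
    Xc = X - X.mean(axis=0)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    total = float(np.sum(S**2))
    fractions = (S[:d] ** 2) / total
    scores = U[:, :d] * S[:d]
    components = Vt[:d]
    scores, components = _fix_signs(scores, components)
    return Embedding(
        method="pca",
        scores=scores,
        components=components,
        variance_fractions=fractions,
        params={"d": d},
    )


def fastica(ensemble: EnsembleMatrix, d: int, seed: int,
            tol: float = 1e-6, max_iter: int = 200) -> Embedding:
    """Deflationary FastICA with the log cosh contrast after PCA whitening.

    Scores have unit variance and are mutually uncorrelated.  If the fixed
    point iteration does not converge within ``max_iter`` the embedding is
    returned with ``converged=False`` rather than raising — pure Gaussian
    inputs have no preferred independent directions.
    """
    from sklearn.decomposition import FastICA
    from sklearn.exceptions import ConvergenceWarning

    X = ensemble.coords
    n = X.shape[0]
    if not 1 <= d <= n - 1:
        raise ValueError(f"d={d} out of range 1..{n - 1}")
    ica = FastICA(
        n_components=d,
        algorithm="deflation",
        fun="logcosh",
        whiten="unit-variance",
        tol=tol,
        max_iter=max_iter,
        random_state=seed,
    )
    converged = True
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        scores = ica.fit_transform(X)
        if any(issubclass(w.category, ConvergenceWarning) for w in caught):
            converged = False
            logger.warning("FastICA did not converge in %d iterations", max_iter)
    scores, components = _fix_signs(scores, ica.components_)
    return Embedding(
        method="ica",
        scores=scores,
        components=components,
        params={"d": d, "seed": seed, "tol": tol, "max_iter": max_iter},
        converged=converged,
    )


def reconstruction_weights(X: np.ndarray, k: int, reg: float = 1e-3) -> np.ndarray:
    """Barycentric reconstruction weights over k nearest neighbors.

    Row i holds weights (summing to 1) on the k nearest neighbors of sample
    i; the local Gram matrix is regularized by ``reg * trace`` so the solve
    stays well-posed when k exceeds the local intrinsic rank.
    Returns the dense (n, n) weight matrix W.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if not 1 <= k < n:
        raise ValueError(f"k={k} out of range 1..{n - 1}")
    d2 = np.sum((X[:, None, :] - X[None, :, :]) ** 2, axis=2)
    np.fill_diagonal(d2, np.inf)
    W = np.zeros((n, n))
    for i in range(n):
        nbrs = np.argsort(d2[i], kind="stable")[:k]
        Z = X[nbrs] - X[i]
        G = Z @ Z.T
        trace = np.trace(G)
        if trace > 0:
            G = G + np.eye(k) * reg * trace
        else:
            G = G + np.eye(k) * reg
        w = np.linalg.solve(G, np.ones(k))
        W[i, nbrs] = w / w.sum()
    return W


def _neighbor_components(W: np.ndarray) -> int:
    """Number of connected components of the symmetrized neighbor graph."""
    import networkx as nx

    A = (W != 0) | (W.T != 0)
    g = nx.from_numpy_array(A.astype(int))
    return nx.number_connected_components(g)


def lle(ensemble: EnsembleMatrix, k: int, d: int, reg: float = 1e-3) -> Embedding:
    """Locally linear embedding into d dimensions using k nearest neighbors.

    Raises if the k-neighbor graph is disconnected (the bottom eigenvectors
    then only separate components, not geometry).
    """
    X = ensemble.coords
    n = X.shape[0]
    if not 1 <= d < n:
        raise ValueError(f"d={d} out of range 1..{n - 1}")
    W = reconstruction_weights(X, k, reg=reg)
    ncomp = _neighbor_components(W)
    if ncomp > 1:
        raise ValueError(
            f"k={k} neighbor graph is disconnected ({ncomp} components); increase k"
        )
    I = np.eye(n)
    M = (I - W).T @ (I - W)
    vals, vecs = np.linalg.eigh(M)
    # discard the constant bottom eigenvector, keep the next d
    scores = vecs[:, 1 : d + 1] * np.sqrt(n)
    scores, _ = _fix_signs(scores)
    return Embedding(
        method="lle",
        scores=scores,
        params={"d": d, "k": k, "reg": reg},
    )


def lle_k_scan(ensemble: EnsembleMatrix, k_candidates: list[int], d: int) -> dict[int, float]:
    """Distance-preservation criterion for each candidate neighborhood size:
    the Pearson correlation between high-dimensional pairwise distances and
    embedded pairwise distances.  Invalid candidates score -inf."""
    hi = pdist(ensemble.coords)
    out: dict[int, float] = {}
    for k in k_candidates:
        try:
            emb = lle(ensemble, k=k, d=d)
            lo = pdist(emb.scores)
            r = float(pearsonr(hi, lo)[0]) if lo.std() > 0 else -np.inf
        except ValueError:
            r = -np.inf
        out[k] = r
        logger.info("LLE k-selection: k=%d criterion=%.6f", k, r)
    return out


def select_lle_k(ensemble: EnsembleMatrix, k_candidates: list[int], d: int) -> int:
    """Neighborhood size maximizing the distance-preservation criterion
    (ties broken toward the smaller k); deterministic."""
    if not k_candidates:
        raise ValueError("empty candidate list")
    scores = lle_k_scan(ensemble, k_candidates, d)
    finite = {k: v for k, v in scores.items() if np.isfinite(v)}
    if not finite:
        raise ValueError("no valid LLE neighborhood size among candidates")
    best = max(sorted(finite), key=lambda k: finite[k])
    return best
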