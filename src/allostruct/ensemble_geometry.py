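"""Superposition, flexibility and clustering of a C-alpha coordinate ensemble.

The ensemble lives in an n x 3m matrix: one row per crystal structure, the
columns the C-alpha coordinates over a shared residue frame.  Members are
rigid-body superposed on the most structurally invariant core of the
molecule before any fluctuation, deviation, correlation or embedding
analysis — the core is found iteratively by trimming the residue whose
positional scatter ellipsoid is largest until the remaining scatter is
small, so that flexible loops (the nucleotide switches in Rab GTPases) do
not pollute the reference frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
from scipy.spatial.distance import squareform

from .structures_io import ResidueFrame, Structure


@dataclass
class EnsembleMatrix:
    """n structures x 3m C-alpha coordinates over a common residue frame."""

    ids: list[str]
    frame: ResidueFrame
    coords: np.ndarray  # shape (n, 3m), Angstrom

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        n, w = self.coords.shape
        if n < 2:
            raise ValueError("ensemble needs at least 2 members")
        if w != 3 * len(self.frame):
            raise ValueError(f"row width {w} != 3 * {len(self.frame)} frame residues")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        if len(self.ids) != n:
            raise ValueError("ids/coords length mismatch")

    @property
    def n_members(self) -> int:
        return self.coords.shape[0]

    @property
    def n_residues(self) -> int:
        return len(self.frame)

    def member_xyz(self, i: int) -> np.ndarray:
        """Member i as an (m, 3) array."""
        return self.coords[i].reshape(-1, 3)


def ensemble_matrix(structures: list[Structure], frame: ResidueFrame) -> EnsembleMatrix:
    """Stack the C-alpha coordinates of each structure over the frame."""
    rows = []
    for st in structures:
        xyz = np.array([st.residue(num).ca.xyz for num in frame], dtype=float)
        rows.append(xyz.ravel())
    return EnsembleMatrix([st.id for st in structures], frame, np.vstack(rows))


@dataclass
class SuperpositionResult:
    rotation: np.ndarray      # 3x3, det +1
    translation: np.ndarray   # 3-vector: y = x @ R.T + t
    rmsd: float               # over the fitted subset, Angstrom

    def apply(self, xyz: np.ndarray) -> np.ndarray:
        return xyz @ self.rotation.T + self.translation


def kabsch_superpose(
    mobile: np.ndarray, reference: np.ndarray, subset: list[int] | None = None
) -> SuperpositionResult:
    """Least-squares optimal rigid superposition of ``mobile`` onto
    ``reference`` fitted on ``subset`` (point indices; default all points).

    Both inputs are (m, 3) or flat 3m arrays.  The optimal rotation is the
    Kabsch solution (SVD of the cross-covariance with a determinant
    correction, so reflections are never returned).  Raises on degenerate
    (fewer than 3, collinear or coincident) fitting points.
    """
    P = np.asarray(mobile, dtype=float).reshape(-1, 3)
    Q = np.asarray(reference, dtype=float).reshape(-1, 3)
    if P.shape != Q.shape:
        raise ValueError("mobile/reference shape mismatch")
    idx = np.arange(len(P)) if subset is None else np.asarray(list(subset), int)
    if len(idx) < 3:
        raise ValueError("need at least 3 points to superpose")
    p, q = P[idx], Q[idx]
    pc, qc = p.mean(axis=0), q.mean(axis=0)
    p0, q0 = p - pc, q - qc
    H = p0.T @ q0
    U, S, Vt = np.linalg.svd(H)
    # rank < 2 means the points are (near-)collinear or coincident
    if S[1] <= 1e-10 * max(S[0], 1.0):
        raise ValueError("degenerate fitting subset (collinear or coincident points)")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = qc - pc @ R.T
    moved = p @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - q) ** 2, axis=1))))
    return SuperpositionResult(R, t, rmsd)


def _scatter_volumes(coords: np.ndarray) -> np.ndarray:
    """Per-residue scatter-ellipsoid volume over the ensemble.

    coords: (n, m, 3).  For each residue the 3x3 positional covariance is
    eigendecomposed; the 'volume' is the product of the ellipsoid semi-axes
    (square roots of the eigenvalues), in cubic Angstrom.
    """
    mean = coords.mean(axis=0)
    d = coords - mean
    vols = np.empty(coords.shape[1])
    for j in range(coords.shape[1]):
        cov = d[:, j, :].T @ d[:, j, :] / coords.shape[0]
        eig = np.clip(np.linalg.eigvalsh(cov), 0.0, None)
        vols[j] = float(np.prod(np.sqrt(eig)))
    return vols


def _align_stack(ensemble: EnsembleMatrix, core: list[int]) -> np.ndarray:
    """Superpose every member on member 0 over `core`, then one refinement
    pass onto the running mean.  Returns (n, m, 3)."""
    n, m = ensemble.n_members, ensemble.n_residues
    stack = ensemble.coords.reshape(n, m, 3).copy()
    ref = stack[0]
    for i in range(n):
        fit = kabsch_superpose(stack[i], ref, core)
        stack[i] = fit.apply(stack[i])
    mean = stack.mean(axis=0)
    for i in range(n):
        fit = kabsch_superpose(stack[i], mean, core)
        stack[i] = fit.apply(stack[i])
    return stack


def find_invariant_core(
    ensemble: EnsembleMatrix,
    v_stop: float = 1.0,
    floor: int | None = None,
) -> list[int]:
    """Iteratively trim the most scattered residue until the remaining
    per-residue scatter volume is at most ``v_stop`` (cubic Angstrom) or the
    core has shrunk to ``floor`` residues (default max(30, 0.4 m)).

    Returns sorted residue positions (0-based into the frame).
    """
    if ensemble.n_members < 3:
        raise ValueError("core finding needs at least 3 members")
    m = ensemble.n_residues
    if floor is None:
        floor = max(30, int(np.ceil(0.4 * m)))
    floor = min(floor, m)
    if floor < 3:
        raise ValueError("core floor below 3 residues")
    core = list(range(m))
    while True:
        stack = _align_stack(ensemble, core)
        vols = _scatter_volumes(stack)[core]
        if len(core) <= floor or vols.max() <= v_stop:
            return sorted(core)
        core.pop(int(np.argmax(vols)))


def superpose_ensemble(ensemble: EnsembleMatrix, core: list[int]) -> EnsembleMatrix:
    """Rigid-fit every member onto member 0 over the core, then refine once
    onto the ensemble mean.  Deterministic; returns a new matrix."""
    stack = _align_stack(ensemble, list(core))
    return EnsembleMatrix(
        list(ensemble.ids), ensemble.frame, stack.reshape(ensemble.n_members, -1)
    )


def rmsf(aligned: EnsembleMatrix) -> np.ndarray:
    """Per-residue root-mean-square fluctuation about the ensemble mean (A)."""
    stack = aligned.coords.reshape(aligned.n_members, aligned.n_residues, 3)
    d = stack - stack.mean(axis=0)
    return np.sqrt(np.mean(np.sum(d * d, axis=2), axis=0))


def pairwise_rmsd(aligned: EnsembleMatrix, subset: list[int] | None = None) -> np.ndarray:
    """n x n C-alpha RMSD matrix over ``subset`` residues, after the shared
    superposition (no re-fitting per pair)."""
    n, m = aligned.n_members, aligned.n_residues
    stack = aligned.coords.reshape(n, m, 3)
    if subset is not None:
        subset = list(subset)
        if not subset:
            raise ValueError("empty residue subset")
        stack = stack[:, subset, :]
    diff = stack[:, None, :, :] - stack[None, :, :, :]
    msd = np.mean(np.sum(diff * diff, axis=3), axis=2)
    return np.sqrt(msd)


@dataclass
class ClusterModel:
    labels: np.ndarray            # per-member cluster id, 0..k-1
    linkage_method: str
    merge_tree: np.ndarray        # scipy linkage matrix
    clustroids: list[str] = field(default_factory=list)  # one member id per cluster
    clustroid_indices: list[int] = field(default_factory=list)

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) + 1


def clustroid_index(distances: np.ndarray, members: list[int]) -> int:
    """Member minimizing summed distance to its cluster mates (ties: lowest index)."""
    sub = distances[np.ix_(members, members)]
    return members[int(np.argmin(sub.sum(axis=1)))]


def hierarchical_cluster(
    distances: np.ndarray,
    k: int,
    method: str = "average",
    ids: list[str] | None = None,
) -> ClusterModel:
    """Agglomerative clustering of a distance matrix cut into k clusters,
    with the clustroid of each cluster as its representative."""
    D = np.asarray(distances, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-8) or (D < -1e-12).any():
        raise ValueError("distance matrix must be symmetric and non-negative")
    n = D.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k={k} out of range 1..{n}")
    if ids is None:
        ids = [str(i) for i in range(n)]
    Z = scipy_linkage(squareform(D, checks=False), method=method)
    raw = fcluster(Z, t=k, criterion="maxclust")
    # relabel clusters 0..k-1 in order of first appearance, for determinism
    remap: dict[int, int] = {}
    labels = np.empty(n, dtype=int)
    for i, lab in enumerate(raw):
        if lab not in remap:
            remap[lab] = len(remap)
        labels[i] = remap[lab]
    clustroid_idx = []
    for c in range(labels.max() + 1):
        members = [i for i in range(n) if labels[i] == c]
        clustroid_idx.append(clustroid_index(D, members))
    return ClusterModel(
        labels=labels,
        linkage_method=method,
        merge_tree=Z,
        clustroids=[ids[i] for i in clustroid_idx],
        clustroid_indices=clustroid_idx,
    )
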