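"""Synthetic fixtures with recorded ground truth.

Every stage of the ensemble pipeline can be exercised without downloading a
single structure: this module fabricates C-alpha ensembles with planted
cluster structure and planted principal modes, ensembles with planted
pairwise motion correlations, toy protein-ligand complexes with planted
interaction geometry, and docking score tables with a known ranking.  Each
generator is deterministic per seed and returns the ground truth it planted
alongside the data.

The planted ensembles emulate what a crystallographic ensemble of a small
GTPase looks like to the pipeline: a rigid core common to all members, a
mobile region whose displacements carry the cluster/mode signal, isotropic
positional noise everywhere, and an arbitrary rigid placement of every
member (crystals are deposited in arbitrary orientations, so tests cannot
accidentally bypass superposition).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ensemble_geometry import EnsembleMatrix
from .structures_io import Atom, LigandGroup, Residue, ResidueFrame, Structure

BOND_LENGTH = 3.8   # virtual C-alpha/C-alpha bond, Angstrom
CLASH_FLOOR = 3.0   # minimal non-bonded C-alpha separation


@dataclass
class GroundTruth:
    labels: np.ndarray | None = None              # per-member cluster ids
    mode_vectors: np.ndarray | None = None        # (q, 3m) planted modes
    correlations: dict[tuple[int, int], float] = field(default_factory=dict)
    interactions: dict[str, int] = field(default_factory=dict)
    core_positions: list[int] = field(default_factory=list)  # 0-based frame positions
    ranking: list[str] = field(default_factory=list)          # ligand ids, best first


@dataclass
class EnsembleSpec:
    m: int                                  # residues
    n: int                                  # members
    cluster_means: np.ndarray               # (c, 3m) displacement per cluster
    mode_vectors: np.ndarray                # (q, 3m) unit directions
    mode_stds: np.ndarray                   # (q,) amplitudes (A)
    noise_sigma: float                      # isotropic per-coordinate noise (A)
    seed: int
    rigid_transforms: bool = True

    def __post_init__(self):
        self.cluster_means = np.atleast_2d(np.asarray(self.cluster_means, float))
        self.mode_vectors = np.asarray(self.mode_vectors, float).reshape(-1, 3 * self.m)
        self.mode_stds = np.asarray(self.mode_stds, float).ravel()
        if self.cluster_means.shape[1] != 3 * self.m:
            raise ValueError("cluster mean width != 3m")
        if len(self.mode_stds) != self.mode_vectors.shape[0]:
            raise ValueError("one std per mode required")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.cluster_means.shape[0] < 1:
            raise ValueError("need at least one cluster")


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation via QR of a Gaussian matrix (det forced +1)."""
    A = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] *= -1
    return Q


def make_chain(m: int, seed: int) -> Structure:
    """Self-avoiding C-alpha trace with 3.8 A virtual bonds plus minimal
    backbone (N, C, O) and side-chain (CB) dummy atoms, so center-of-mass
    and interaction-profiling operations have something to chew on."""
    if m < 3:
        raise ValueError("need at least 3 residues")
    rng = np.random.default_rng(seed)
    pts = [np.zeros(3)]
    while len(pts) < m:
        for _ in range(1000):
            v = rng.normal(size=3)
            v = v / np.linalg.norm(v) * BOND_LENGTH
            cand = pts[-1] + v
            prior = np.asarray(pts[:-1]) if len(pts) > 1 else None
            if prior is None or np.min(np.linalg.norm(prior - cand, axis=1)) >= CLASH_FLOOR:
                pts.append(cand)
                break
        else:  # dead end: drop the last point and re-grow
            pts.pop()
            if not pts:
                pts = [np.zeros(3)]

    names = ["ALA", "SER", "VAL", "THR", "LEU", "GLY"]
    residues = []
    for i, ca in enumerate(pts):
        # local frame from the chain direction; arbitrary but deterministic
        nxt = pts[i + 1] if i + 1 < m else pts[i - 1]
        u = (nxt - ca) / np.linalg.norm(nxt - ca)
        ref = np.array([0.0, 0.0, 1.0]) if abs(u[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
        v = np.cross(u, ref)
        v /= np.linalg.norm(v)
        w = np.cross(u, v)
        name = names[i % len(names)]
        atoms = [
            Atom("N", "N", *(ca + 1.46 * v)),
            Atom("CA", "C", *ca),
            Atom("C", "C", *(ca + 1.52 * w)),
            Atom("O", "O", *(ca + 1.52 * w + 1.23 * v)),
        ]
        if name != "GLY":
            atoms.append(Atom("CB", "C", *(ca - 1.53 * v)))
        residues.append(Residue(i + 1, name, atoms))
    return Structure(f"SYN_{seed}_A", residues, [])


def make_ensemble(spec: EnsembleSpec) -> tuple[EnsembleMatrix, GroundTruth]:
    """Members = base chain + cluster mean + mode contributions + isotropic
    noise, each then placed by a random rigid transform (unless disabled)."""
    rng = np.random.default_rng(spec.seed)
    base = np.array(
        [r.ca.xyz for r in make_chain(spec.m, spec.seed).residues], float
    ).ravel()
    c = spec.cluster_means.shape[0]
    labels = np.sort(rng.integers(0, c, size=spec.n)) if c > 1 else np.zeros(spec.n, int)
    # guarantee every cluster is populated
    labels[:c] = np.arange(c)
    rows = np.empty((spec.n, 3 * spec.m))
    for i in range(spec.n):
        x = base + spec.cluster_means[labels[i]]
        for q in range(spec.mode_vectors.shape[0]):
            x = x + rng.normal(0.0, spec.mode_stds[q]) * spec.mode_vectors[q]
        x = x + rng.normal(0.0, spec.noise_sigma, size=3 * spec.m)
        if spec.rigid_transforms:
            R = _random_rotation(rng)
            t = rng.uniform(-50, 50, size=3)
            x = (x.reshape(-1, 3) @ R.T + t).ravel()
        rows[i] = x

    moved = np.zeros(3 * spec.m, dtype=bool)
    for mean in spec.cluster_means:
        moved |= mean != 0
    for vec in spec.mode_vectors:
        moved |= vec != 0
    core = [j for j in range(spec.m) if not moved[3 * j : 3 * j + 3].any()]

    frame = ResidueFrame(range(1, spec.m + 1))
    ids = [f"syn_{i:02d}" for i in range(spec.n)]
    truth = GroundTruth(
        labels=labels,
        mode_vectors=spec.mode_vectors.copy(),
        core_positions=core,
    )
    return EnsembleMatrix(ids, frame, rows), truth


def three_cluster_spec(
    m: int = 60,
    n: int = 27,
    noise_sigma: float = 0.5,
    separation: float = 10.0,
    seed: int = 0,
    mobile_fraction: float = 0.4,
) -> EnsembleSpec:
    """Planted 3-cluster ensemble: displacements of amplitude
    ``separation * noise_sigma`` per mobile coordinate, restricted to the
    C-terminal ``mobile_fraction`` of the chain so the N-terminal part stays
    a rigid superposition core."""
    rng = np.random.default_rng(seed + 1)
    mobile_start = int(np.floor(m * (1 - mobile_fraction)))
    means = np.zeros((3, 3 * m))
    for ci in range(3):
        disp = rng.normal(size=3 * (m - mobile_start))
        disp *= separation * noise_sigma / np.abs(disp).mean()
        means[ci, 3 * mobile_start :] = disp
    means -= means.mean(axis=0)  # center the planted clusters
    return EnsembleSpec(
        m=m, n=n,
        cluster_means=means,
        mode_vectors=np.zeros((0, 3 * m)),
        mode_stds=np.zeros(0),
        noise_sigma=noise_sigma,
        seed=seed,
    )


def single_mode_spec(
    m: int = 60, n: int = 27, mode_std: float = 10.0,
    noise_sigma: float = 0.1, seed: int = 0, mobile_fraction: float = 0.4,
) -> EnsembleSpec:
    """One dominant planted mode in the mobile region plus faint noise."""
    rng = np.random.default_rng(seed + 2)
    mobile_start = int(np.floor(m * (1 - mobile_fraction)))
    vec = np.zeros(3 * m)
    vec[3 * mobile_start :] = rng.normal(size=3 * (m - mobile_start))
    vec /= np.linalg.norm(vec)
    return EnsembleSpec(
        m=m, n=n,
        cluster_means=np.zeros((1, 3 * m)),
        mode_vectors=vec[None, :],
        mode_stds=np.array([mode_std]),
        noise_sigma=noise_sigma,
        seed=seed,
    )


def make_correlated_ensemble(
    m: int,
    pairs: dict[tuple[int, int], float],
    n: int,
    seed: int,
    sigma: float = 1.0,
) -> tuple[EnsembleMatrix, GroundTruth]:
    """Ensemble whose residue displacements realize the requested pairwise
    cross-correlations (0-based residue position pairs -> rho).

    All residues fluctuate with amplitude ``sigma`` along one common
    direction; the scalar amplitudes are drawn from a multivariate normal
    whose correlation matrix carries the planted rhos, so the normalized
    cross-correlation of residues i and j equals rho by construction.  No
    rigid transforms are applied: the output is already superposed.
    """
    R = np.eye(m)
    for (i, j), rho in pairs.items():
        if not -1.0 <= rho <= 1.0:
            raise ValueError(f"|rho| > 1 for pair {(i, j)}")
        R[i, j] = R[j, i] = rho
    eigvals, eigvecs = np.linalg.eigh(R)
    if eigvals.min() < -1e-10:
        raise ValueError("correlation specification is not positive definite")
    # semi-definite factor, so perfectly correlated pairs (|rho| = 1) work too
    L = eigvecs @ np.diag(np.sqrt(np.clip(eigvals, 0.0, None)))
    rng = np.random.default_rng(seed)
    base = np.array([r.ca.xyz for r in make_chain(m, seed).residues], float)
    u = rng.normal(size=3)
    u /= np.linalg.norm(u)
    amplitudes = rng.normal(size=(n, m)) @ L.T * sigma
    rows = (base[None, :, :] + amplitudes[:, :, None] * u[None, None, :]).reshape(n, 3 * m)
    frame = ResidueFrame(range(1, m + 1))
    ids = [f"cor_{i:03d}" for i in range(n)]
    return EnsembleMatrix(ids, frame, rows), GroundTruth(correlations=dict(pairs))


def _far_grid(origin: np.ndarray, spacing: float = 25.0):
    """Generator of well-separated anchor points for independent motifs."""
    k = 0
    while True:
        yield origin + np.array([k * spacing, 0.0, 0.0])
        k += 1


def make_complex_fixture(kind: str, seed: int = 0) -> tuple[Structure, LigandGroup, GroundTruth]:
    """A toy protein-ligand complex containing exactly the planted
    interactions of ``kind`` at planted distances.

    kinds: hydrogen_bond, hydrophobic, salt_bridge, salt_bridge_far (just
    over the cutoff), pi_cation, mixed.
    """
    kinds = {"hydrogen_bond", "hydrophobic", "salt_bridge", "salt_bridge_far",
             "pi_cation", "mixed"}
    if kind not in kinds:
        raise ValueError(f"unsupported kind {kind!r}; choose from {sorted(kinds)}")
    anchors = _far_grid(np.zeros(3))
    residues: list[Residue] = []
    lig_atoms: list[Atom] = []
    truth: dict[str, int] = {
        "hydrogen_bond": 0, "hydrophobic": 0, "salt_bridge": 0, "pi_cation": 0
    }
    num = 1
    lig_serial = 1

    def lig_atom(element: str, pos: np.ndarray) -> Atom:
        nonlocal lig_serial
        a = Atom(f"{element}{lig_serial}", element, *pos)
        lig_serial += 1
        return a

    if kind in ("hydrogen_bond", "mixed"):
        p = next(anchors)
        # SER hydroxyl 2.9 A from a ligand oxygen; CA/CB kept > 4 A from
        # ligand carbon-free surroundings so nothing else registers
        residues.append(Residue(num, "SER", [
            Atom("N", "N", *(p + [0, 8, 0])),
            Atom("CA", "C", *(p + [0, 6.5, 0])),
            Atom("CB", "C", *(p + [0, 5, 0])),
            Atom("OG", "O", *(p + [0, 2.9, 0])),
        ]))
        num += 1
        lig_atoms.append(lig_atom("O", p))
        truth["hydrogen_bond"] += 1

    if kind in ("hydrophobic", "mixed"):
        p = next(anchors)
        # LEU delta carbon 3.8 A from a ligand carbon
        residues.append(Residue(num, "LEU", [
            Atom("N", "N", *(p + [0, 9.5, 0])),
            Atom("CA", "C", *(p + [0, 8, 0])),
            Atom("CB", "C", *(p + [0, 6.6, 0])),
            Atom("CG", "C", *(p + [0, 5.2, 0])),
            Atom("CD1", "C", *(p + [0, 3.8, 0])),
        ]))
        num += 1
        lig_atoms.append(lig_atom("C", p))
        truth["hydrophobic"] += 1

    if kind in ("salt_bridge", "salt_bridge_far", "mixed"):
        p = next(anchors)
        gap = 5.6 if kind == "salt_bridge_far" else 4.0
        # LYS ammonium `gap` A from a ligand carboxylate midpoint; the two
        # oxygens sit perpendicular to the N..C axis so neither gets within
        # hydrogen-bond range of NZ when gap = 4.0
        residues.append(Residue(num, "LYS", [
            Atom("N", "N", *(p + [0, gap + 7, 0])),
            Atom("CA", "C", *(p + [0, gap + 5.5, 0])),
            Atom("NZ", "N", *(p + [0, gap, 0])),
        ]))
        num += 1
        cmid = p + np.array([0.0, -0.64, 0.0])
        lig_atoms.append(lig_atom("C", cmid))
        lig_atoms.append(lig_atom("O", p + [1.1, 0, 0]))
        lig_atoms.append(lig_atom("O", p + [-1.1, 0, 0]))
        if kind != "salt_bridge_far":
            truth["salt_bridge"] += 1

    if kind in ("pi_cation", "mixed"):
        p = next(anchors)
        # PHE ring centroid 5.5 A below a ligand nitrogen
        ring = []
        for ang_i, aname in enumerate(("CG", "CD1", "CD2", "CE1", "CE2", "CZ")):
            ang = 2 * np.pi * ang_i / 6
            ring.append(Atom(aname, "C", *(p + [1.39 * np.cos(ang), 5.5, 1.39 * np.sin(ang)])))
        residues.append(Residue(num, "PHE", [
            Atom("N", "N", *(p + [0, 9.5, 4])),
            Atom("CA", "C", *(p + [0, 8, 4])),
            Atom("CB", "C", *(p + [0, 6.8, 4])),
            *ring,
        ]))
        num += 1
        lig_atoms.append(lig_atom("N", p))
        truth["pi_cation"] += 1

    structure = Structure(f"CPLX_{kind.upper()}_A", residues, [])
    pose = LigandGroup("LIG", 900, lig_atoms)
    return structure, pose, GroundTruth(interactions=truth)


def make_screen_table(
    n_ligands: int,
    energy_range: tuple[float, float] = (-10.0, -6.0),
    count_range: tuple[int, int] = (1, 10),
    seed: int = 0,
) -> tuple[str, GroundTruth]:
    """A parseable docking score table plus its ground-truth weighted
    ranking, computed here by the 80/20 formula applied directly (min-max
    normalized negated energy and interaction count)."""
    if n_ligands < 1:
        raise ValueError("need at least one ligand")
    rng = np.random.default_rng(seed)
    lo, hi = min(energy_range), max(energy_range)
    energies = np.round(rng.uniform(lo, hi, size=n_ligands), 1)
    counts = rng.integers(count_range[0], count_range[1] + 1, size=n_ligands)
    ligands = [f"LIG{i:04d}" for i in range(n_ligands)]
    lines = ["ligand,target,site,energy_kcal_mol,n_interactions"]
    for lig, e, c in zip(ligands, energies, counts):
        lines.append(f"{lig},SYN_0_A,site1,{e:.1f},{int(c)}")
    text = "\n".join(lines) + "\n"

    def norm(v):
        v = np.asarray(v, float)
        return np.ones_like(v) if v.max() == v.min() else (v - v.min()) / (v.max() - v.min())

    scores = 0.8 * norm(-energies) + 0.2 * norm(counts)
    order = sorted(range(n_ligands), key=lambda i: (-scores[i], energies[i], ligands[i]))
    return text, GroundTruth(ranking=[ligands[i] for i in order])
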