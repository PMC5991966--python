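"""Dynamical cross-correlation matrix (DCCM) over a superposed ensemble.

For residues i and j with displacement vectors dr from the ensemble-mean
structure, C_ij = <dr_i . dr_j> / sqrt(<|dr_i|^2><|dr_j|^2>).  Values near
+1 mean the two residues move in the same direction across the ensemble,
near -1 in opposite directions.  Computed here on a crystal-structure
ensemble (displacements about the ensemble mean after core superposition),
not on a trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ensemble_geometry import EnsembleMatrix
from .structures_io import RegionDef, ResidueFrame, select_region


@dataclass
class DCCMatrix:
    matrix: np.ndarray          # (m, m), symmetric, unit diagonal, in [-1, 1]
    frame: ResidueFrame
    rigid: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=bool))
    # rigid[i] flags residues with zero fluctuation whose correlations are
    # undefined and reported as 0 (diagonal included)

    def block(self, rows: list[int], cols: list[int]) -> np.ndarray:
        return self.matrix[np.ix_(rows, cols)]


def compute_dccm(aligned: EnsembleMatrix) -> DCCMatrix:
    """Normalized cross-correlations of residue displacements about the
    ensemble mean.  Requires n >= 3 members.  Residues that do not move at
    all get flagged zero rows/columns instead of NaNs."""
    n, m = aligned.n_members, aligned.n_residues
    if n < 3:
        raise ValueError("DCCM needs at least 3 ensemble members")
    stack = aligned.coords.reshape(n, m, 3)
    d = stack - stack.mean(axis=0)
    # inner products <dr_i . dr_j> averaged over members
    flat = d.transpose(1, 0, 2).reshape(m, n * 3)  # residue-major
    cov = flat @ flat.T / n
    var = np.diag(cov).copy()
    # tolerance: summation rounding leaves ~1e-30 variance on rigid residues
    rigid = var <= 1e-18 * max(1.0, float(var.max()))
    denom = np.sqrt(np.outer(var, var))
    with np.errstate(invalid="ignore", divide="ignore"):
        C = np.where(denom > 0, cov / denom, 0.0)
    C = np.clip(C, -1.0, 1.0)
    np.fill_diagonal(C, np.where(rigid, 0.0, 1.0))
    C = (C + C.T) / 2.0
    return DCCMatrix(C, aligned.frame, rigid)


def region_correlation(
    dccm: DCCMatrix, region_a: RegionDef, region_b: RegionDef
) -> dict[str, float]:
    """Mean / min / max correlation over the region_a x region_b block."""
    ia = select_region(dccm.frame, region_a)
    ib = select_region(dccm.frame, region_b)
    vals = dccm.block(ia, ib).ravel()
    return {
        "mean": float(vals.mean()),
        "min": float(vals.min()),
        "max": float(vals.max()),
        "n_pairs": int(vals.size),
    }
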