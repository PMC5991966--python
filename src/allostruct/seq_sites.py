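"""Pairwise global alignment and binding-site sequence conservation.

Percent identity between full sequences, and identity restricted to the
alignment columns of a residue sub-selection (e.g. the ligand-contact
residues of a binding pocket), quantify how conserved a pocket is between
homologs.  Alignments are Needleman-Wunsch with BLOSUM62 and affine gaps
(open -10, extend -0.5); identity is counted over mutually non-gap columns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

VALID_RESIDUES = set("ACDEFGHIKLMNPQRSTVWYX")


@dataclass
class AlignmentResult:
    aligned_a: str
    aligned_b: str
    score: float
    matrix: str = "BLOSUM62"
    gap_open: float = -10.0
    gap_extend: float = -0.5

    def __post_init__(self):
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned sequences differ in length")

    @property
    def seq_a(self) -> str:
        return self.aligned_a.replace("-", "")

    @property
    def seq_b(self) -> str:
        return self.aligned_b.replace("-", "")


def global_align(
    seq_a: str,
    seq_b: str,
    matrix: str = "BLOSUM62",
    gap_open: float = -10.0,
    gap_extend: float = -0.5,
) -> AlignmentResult:
    """Optimal global alignment under affine gap penalties.

    The traceback is deterministic: of the co-optimal alignments the first
    one enumerated is returned (match preferred over gaps).
    """
    for name, seq in (("A", seq_a), ("B", seq_b)):
        if not seq:
            raise ValueError(f"sequence {name} is empty")
        bad = set(seq.upper()) - VALID_RESIDUES
        if bad:
            raise ValueError(f"invalid residues in sequence {name}: {sorted(bad)}")
    seq_a, seq_b = seq_a.upper(), seq_b.upper()
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    aln = aligner.align(seq_a, seq_b)[0]
    a, b = str(aln[0]), str(aln[1])
    return AlignmentResult(a, b, float(aln.score), matrix, gap_open, gap_extend)


def percent_identity(alignment: AlignmentResult) -> float:
    """100 x identical columns / mutually non-gap columns."""
    both = [
        (x, y)
        for x, y in zip(alignment.aligned_a, alignment.aligned_b)
        if x != "-" and y != "-"
    ]
    if not both:
        raise ValueError("alignment has no mutually non-gap columns")
    same = sum(1 for x, y in both if x == y)
    return 100.0 * same / len(both)


def _columns_for_positions(alignment: AlignmentResult, positions: set[int]) -> list[int]:
    """Alignment columns whose sequence-A residue number (1-based) is wanted."""
    cols, res_num = [], 0
    for col, x in enumerate(alignment.aligned_a):
        if x != "-":
            res_num += 1
            if res_num in positions:
                cols.append(col)
    return cols


def site_identity(alignment: AlignmentResult, positions_a: set[int]) -> float:
    """Percent identity over only the alignment columns whose A-sequence
    residue number (1-based) belongs to ``positions_a``.  As in
    :func:`percent_identity`, columns where B is gapped are excluded from
    the denominator, so restricting to all positions reproduces the
    full-sequence identity."""
    positions_a = set(positions_a)
    if not positions_a:
        raise ValueError("empty position set")
    n_res_a = len(alignment.seq_a)
    unknown = {p for p in positions_a if not 1 <= p <= n_res_a}
    if unknown:
        raise ValueError(f"positions outside sequence A (length {n_res_a}): {sorted(unknown)}")
    cols = [
        c for c in _columns_for_positions(alignment, positions_a)
        if alignment.aligned_b[c] != "-"
    ]
    if not cols:
        raise ValueError("no mutually non-gap alignment columns selected")
    same = sum(1 for c in cols if alignment.aligned_a[c] == alignment.aligned_b[c])
    return 100.0 * same / len(cols)


def identity_matrix(sequences: dict[str, str], **align_kwargs) -> pd.DataFrame:
    """Symmetric pairwise percent-identity matrix; diagonal 100."""
    names = list(sequences)
    if len(names) < 2:
        raise ValueError("need at least 2 sequences")
    mat = np.full((len(names), len(names)), 100.0)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            aln = global_align(sequences[names[i]], sequences[names[j]], **align_kwargs)
            mat[i, j] = mat[j, i] = percent_identity(aln)
    return pd.DataFrame(mat, index=names, columns=names)
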