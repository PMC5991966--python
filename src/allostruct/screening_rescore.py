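"""Docking-hit ingestion, geometric interaction profiling and re-scoring.

Docking engines are not run here: their score tables are inputs.  Hits are
re-ranked with a weighted score giving 80% weight to the (normalized)
binding free energy and 20% to the number of protein-ligand interactions,
the idea being that a pose anchored by many specific contacts is a more
trustworthy hit than an equally scored pose held by few.

The interaction profiler is purely geometric — crystal structures carry no
hydrogens, so distance criteria between heavy atoms are used and angle
criteria are omitted:

* hydrogen bond:  protein N/O to ligand N/O at <= 3.5 A;
* hydrophobic:    apolar carbon to ligand carbon at <= 4.0 A;
* salt bridge:    charged-group centers (Lys NZ / Arg CZ cations,
  Asp/Glu carboxylate midpoints, ligand carboxylate midpoints and ligand
  nitrogen cations) at <= 5.5 A;
* pi-cation:      ligand nitrogen cation to aromatic ring centroid
  (Phe/Tyr/Trp/His) at <= 6.0 A.

Lipinski's rule of five is evaluated with the conventional "at most one
violation" pass criterion (donors <= 5, acceptors <= 10, mass < 500 g/mol,
logP <= 5).
"""

from __future__ import annotations

import io
import logging
import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .structures_io import LigandGroup, Structure

logger = logging.getLogger(__name__)

# geometric cutoffs (Angstrom)
HBOND_CUTOFF = 3.5
HYDROPHOBIC_CUTOFF = 4.0
SALT_BRIDGE_CUTOFF = 5.5
PI_CATION_CUTOFF = 6.0
SITE_ASSIGN_CUTOFF = 4.5

AROMATIC_RING_ATOMS = {
    "PHE": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TYR": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TRP": ("CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
    "HIS": ("CG", "ND1", "CD2", "CE1", "NE2"),
}

#: Backbone carbons are polar company; side-chain carbons listed here are
#: the apolar ones used for hydrophobic contacts.
POLAR_ADJACENT_CARBONS = {"C", "CA"}  # carbonyl C and CA next to N


@dataclass(frozen=True)
class SiteDefinition:
    name: str
    residues: frozenset[int]

    def __post_init__(self):
        if not self.residues:
            raise ValueError(f"site {self.name}: empty residue set")


#: Ligand-contact residues of the two putative allosteric pockets flanking
#: helix 102-112 of Rab11 (author numbering).
SITE1 = SiteDefinition("site1", frozenset({19, 20, 74, 77, 97, 101, 104, 107, 108, 111, 112}))
SITE2 = SiteDefinition(
    "site2",
    frozenset({103, 106, 109, 110, 113, 115, 116, 117, 118, 119, 146, 147, 148, 149, 171, 175}),
)


@dataclass(frozen=True)
class Interaction:
    kind: str            # hydrogen_bond | hydrophobic | salt_bridge | pi_cation
    residue: int
    ligand_atom: str
    distance: float


@dataclass
class InteractionSet:
    interactions: list[Interaction] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.interactions)

    def count(self, kind: str | None = None) -> int:
        if kind is None:
            return len(self.interactions)
        return sum(1 for i in self.interactions if i.kind == kind)


@dataclass
class ScreenRecord:
    ligand: str
    target: str
    site: str
    energy: float                    # kcal/mol, <= 0 for retained hits
    n_interactions: int | None = None
    weighted_score: float | None = None
    rank: int | None = None


@dataclass(frozen=True)
class LigandDescriptors:
    donors: int
    acceptors: int
    mass: float        # g/mol
    logp: float

    def __post_init__(self):
        if self.donors < 0 or self.acceptors < 0:
            raise ValueError("descriptor counts must be non-negative")
        if self.mass <= 0:
            raise ValueError("molecular mass must be positive")


def load_scores(table: str) -> list[ScreenRecord]:
    """Parse a docking score table (CSV/TSV text or a path to one).

    Required columns: ligand, target, site, energy (or energy_kcal_mol);
    optional: n_interactions.  Duplicate (ligand, target, site) rows are
    collapsed to the lowest energy; rows with positive energy are dropped.
    """
    if os.path.exists(table):
        with open(table) as fh:
            text = fh.read()
    else:
        text = table
    lines = [l for l in text.splitlines() if l.strip() and not l.lstrip().startswith("#")]
    if not lines:
        raise ValueError("empty score table")
    text = "\n".join(lines)
    sep = "\t" if "\t" in lines[0] else ","
    df = pd.read_csv(io.StringIO(text), sep=sep, skipinitialspace=True)
    df.columns = [c.strip().lower() for c in df.columns]
    if "energy_kcal_mol" in df.columns:
        df = df.rename(columns={"energy_kcal_mol": "energy"})
    missing = {"ligand", "target", "site", "energy"} - set(df.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    if df.empty:
        raise ValueError("score table has no rows")
    # tolerate unicode minus signs from copied tables
    energies = pd.to_numeric(
        df["energy"].astype(str).str.replace("−", "-", regex=False), errors="coerce"
    )
    if energies.isna().any():
        bad = df.loc[energies.isna(), "energy"].iloc[0]
        raise ValueError(f"unparsable energy value: {bad!r}")
    df["energy"] = energies.astype(float)

    records: dict[tuple[str, str, str], ScreenRecord] = {}
    for _, row in df.iterrows():
        if row["energy"] > 0:
            logger.warning("dropping %s/%s: positive energy", row["ligand"], row["target"])
            continue
        n_int = None
        if "n_interactions" in df.columns and not pd.isna(row["n_interactions"]):
            n_int = int(row["n_interactions"])
            if n_int < 0:
                raise ValueError("negative interaction count")
        key = (str(row["ligand"]).strip(), str(row["target"]).strip(), str(row["site"]).strip())
        rec = ScreenRecord(*key, float(row["energy"]), n_int)
        if key not in records or rec.energy < records[key].energy:
            records[key] = rec
    return list(records.values())


def _dist(a, b) -> float:
    return float(np.linalg.norm(np.asarray(a, float) - np.asarray(b, float)))


def _residue_charged_centers(res) -> list[tuple[str, np.ndarray]]:
    """(sign, center) pairs: 'cation' / 'anion' charged-group centers."""
    centers = []
    try:
        if res.name == "LYS":
            centers.append(("cation", np.asarray(res.atom("NZ").xyz)))
        elif res.name == "ARG":
            centers.append(("cation", np.asarray(res.atom("CZ").xyz)))
        elif res.name == "ASP":
            o1, o2 = res.atom("OD1").xyz, res.atom("OD2").xyz
            centers.append(("anion", (np.asarray(o1) + np.asarray(o2)) / 2))
        elif res.name == "GLU":
            o1, o2 = res.atom("OE1").xyz, res.atom("OE2").xyz
            centers.append(("anion", (np.asarray(o1) + np.asarray(o2)) / 2))
    except KeyError:
        pass  # side chain partly unresolved
    return centers


def _ligand_anion_centers(pose: LigandGroup) -> list[np.ndarray]:
    """Carboxylate-like centers: a ligand carbon bonded (<=1.6 A) to two
    oxygens; the center is the oxygen midpoint."""
    atoms = pose.heavy_atoms()
    centers = []
    for c in atoms:
        if c.element != "C":
            continue
        oxy = [o for o in atoms if o.element == "O" and _dist(c.xyz, o.xyz) <= 1.6]
        if len(oxy) >= 2:
            centers.append((np.asarray(oxy[0].xyz) + np.asarray(oxy[1].xyz)) / 2)
    return centers


def profile_interactions(structure: Structure, pose: LigandGroup) -> InteractionSet:
    """Geometric protein-ligand interaction profile (see module docstring).

    Hydrogen bonds and hydrophobic contacts are counted per qualifying atom
    pair; salt bridges and pi-cation contacts per charged-group/ring pair.
    """
    lig_atoms = pose.heavy_atoms()
    if not lig_atoms:
        raise ValueError("pose has no heavy atoms")
    lig_no = [a for a in lig_atoms if a.element in ("N", "O")]
    lig_c = [a for a in lig_atoms if a.element == "C"]
    lig_n = [a for a in lig_atoms if a.element == "N"]
    lig_anions = _ligand_anion_centers(pose)

    found: list[Interaction] = []
    for res in structure.residues:
        heavy = [a for a in res.atoms if a.element != "H"]
        # hydrogen bonds: N/O ... N/O
        for pa in heavy:
            if pa.element not in ("N", "O"):
                continue
            for la in lig_no:
                d = _dist(pa.xyz, la.xyz)
                if d <= HBOND_CUTOFF:
                    found.append(Interaction("hydrogen_bond", res.number, la.name, round(d, 3)))
        # hydrophobic: apolar side-chain carbon ... ligand carbon
        for pa in heavy:
            if pa.element != "C" or pa.name in POLAR_ADJACENT_CARBONS:
                continue
            for la in lig_c:
                d = _dist(pa.xyz, la.xyz)
                if d <= HYDROPHOBIC_CUTOFF:
                    found.append(Interaction("hydrophobic", res.number, la.name, round(d, 3)))
        # salt bridges: opposite-sign group centers
        for sign, center in _residue_charged_centers(res):
            if sign == "cation":
                partners = [(f"O-midpoint", c) for c in lig_anions]
            else:
                partners = [(a.name, np.asarray(a.xyz)) for a in lig_n]
            for label, pos in partners:
                d = _dist(center, pos)
                if d <= SALT_BRIDGE_CUTOFF:
                    found.append(Interaction("salt_bridge", res.number, label, round(d, 3)))
        # pi-cation: ligand nitrogen over an aromatic ring
        ring = AROMATIC_RING_ATOMS.get(res.name)
        if ring:
            try:
                centroid = np.mean([np.asarray(res.atom(n).xyz) for n in ring], axis=0)
            except KeyError:
                centroid = None
            if centroid is not None:
                for la in lig_n:
                    d = _dist(centroid, la.xyz)
                    if d <= PI_CATION_CUTOFF:
                        found.append(Interaction("pi_cation", res.number, la.name, round(d, 3)))
    return InteractionSet(found)


def weighted_score(records: list[ScreenRecord]) -> list[ScreenRecord]:
    """80/20 energy/interaction weighted re-score within one record list.

    Both the negated energy and the interaction count are min-max normalized
    over the list (a constant column normalizes to 1.0); the weighted score
    is 0.8 * energy-term + 0.2 * interaction-term.  Returns new records
    sorted by descending score, ties broken by lower energy then ligand id.
    """
    if not records:
        raise ValueError("no records to score")
    if any(r.n_interactions is None for r in records):
        missing = [r.ligand for r in records if r.n_interactions is None]
        raise ValueError(f"records missing interaction counts: {missing}")

    def minmax(values: np.ndarray) -> np.ndarray:
        lo, hi = values.min(), values.max()
        if hi - lo == 0:
            return np.ones_like(values)
        return (values - lo) / (hi - lo)

    e = minmax(np.array([-r.energy for r in records], float))
    c = minmax(np.array([r.n_interactions for r in records], float))
    scored = [
        replace(r, weighted_score=float(0.8 * ei + 0.2 * ci))
        for r, ei, ci in zip(records, e, c)
    ]
    scored.sort(key=lambda r: (-r.weighted_score, r.energy, r.ligand))
    return [replace(r, rank=i + 1) for i, r in enumerate(scored)]


def assign_site(
    structure: Structure,
    pose: LigandGroup,
    site1: SiteDefinition = SITE1,
    site2: SiteDefinition = SITE2,
    cutoff: float = SITE_ASSIGN_CUTOFF,
) -> str:
    """Label of the site whose residues place the most heavy atoms within
    ``cutoff`` of any pose atom; ties favor site 1; no contacts at all
    yields "unassigned"."""
    lig_xyz = np.array([a.xyz for a in pose.heavy_atoms()])
    if lig_xyz.size == 0:
        raise ValueError("pose has no heavy atoms")

    def contact_atoms(site: SiteDefinition) -> int:
        total = 0
        for res in structure.residues:
            if res.number not in site.residues:
                continue
            for a in res.atoms:
                if a.element == "H":
                    continue
                d = np.linalg.norm(lig_xyz - np.asarray(a.xyz), axis=1)
                if (d <= cutoff).any():
                    total += 1
        return total

    c1, c2 = contact_atoms(site1), contact_atoms(site2)
    if c1 == 0 and c2 == 0:
        return "unassigned"
    return site1.name if c1 >= c2 else site2.name


def lipinski(desc: LigandDescriptors) -> tuple[int, bool]:
    """Rule-of-five violations and the <=1-violation pass flag."""
    violations = sum(
        [desc.donors > 5, desc.acceptors > 10, desc.mass >= 500, desc.logp > 5]
    )
    return violations, violations <= 1
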