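"""Reading protein chains from PDB text and building a common residue frame.

A :class:`Structure` is one crystallographic chain reduced to what the
ensemble analysis needs: ordered amino-acid residues (each guaranteed to
carry a C-alpha atom) plus any non-water hetero groups (nucleotides, ions,
cryoprotectants) kept as :class:`LigandGroup` objects.  Author residue
numbering is used verbatim throughout, because all region definitions
(switch 1, switch 2, P-loop, the RabF/RabSF motifs) are expressed in author
numbers.

Parsing is delegated to :mod:`gemmi`; this module only applies the domain
policies: alternate locations resolved to the highest-occupancy conformer
(ties broken by altloc letter, so 'A' wins), waters dropped, residues with
insertion codes dropped (and logged), selenomethionine treated as
methionine for sequence purposes.
"""

from __future__ import annotations

import logging
import os
import urllib.request
from dataclasses import dataclass, field

import gemmi

logger = logging.getLogger(__name__)

#: Three-letter codes accepted as polymer residues.  MSE (selenomethionine)
#: is a common crystallographic substitution and is kept as a residue.
STANDARD_AA = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "MSE",
}

WATER_NAMES = {"HOH", "WAT", "DOD"}

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    "MSE": "M",
}


@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    x: float
    y: float
    z: float

    @property
    def xyz(self) -> tuple[float, float, float]:
        return (self.x, self.y, self.z)


@dataclass
class Residue:
    """One amino-acid residue with author number and resolved atoms."""

    number: int
    name: str
    atoms: list[Atom] = field(default_factory=list)

    def atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(f"residue {self.name}{self.number} has no atom {name!r}")

    @property
    def ca(self) -> Atom:
        return self.atom("CA")

    @property
    def one_letter(self) -> str:
        return THREE_TO_ONE.get(self.name, "X")


@dataclass
class LigandGroup:
    """A non-water hetero group (e.g. GDP, GNP, BEF, EDO, MG)."""

    het_code: str
    number: int
    atoms: list[Atom] = field(default_factory=list)

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if a.element != "H"]


@dataclass
class Structure:
    """One protein chain: `pdb_id + "_" + chain`, residues and ligands."""

    id: str
    residues: list[Residue] = field(default_factory=list)
    ligands: list[LigandGroup] = field(default_factory=list)

    def residue(self, number: int) -> Residue:
        for r in self.residues:
            if r.number == number:
                return r
        raise KeyError(f"{self.id}: no residue numbered {number}")

    @property
    def residue_numbers(self) -> list[int]:
        return [r.number for r in self.residues]

    def sequence(self) -> str:
        return "".join(r.one_letter for r in self.residues)

    def ligand(self, het_code: str) -> LigandGroup:
        for lig in self.ligands:
            if lig.het_code == het_code:
                return lig
        raise KeyError(f"{self.id}: no ligand {het_code}")


@dataclass(frozen=True)
class RegionDef:
    """A named, inclusive author-numbered residue range."""

    name: str
    start: int
    end: int

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"region {self.name}: start {self.start} > end {self.end}")

    def contains(self, number: int) -> bool:
        return self.start <= number <= self.end


#: Functional regions of Rab11 in author numbering (UniProt P62491 frame).
RAB11_REGIONS: dict[str, RegionDef] = {
    "p_loop": RegionDef("p_loop", 18, 25),
    "switch1": RegionDef("switch1", 39, 46),
    "interswitch": RegionDef("interswitch", 47, 67),
    "switch2": RegionDef("switch2", 68, 79),
    "rabf1": RegionDef("rabf1", 44, 48),
    "rabf2": RegionDef("rabf2", 61, 65),
    "rabf3": RegionDef("rabf3", 71, 77),
    "rabf4": RegionDef("rabf4", 80, 84),
    "rabsf1": RegionDef("rabsf1", 8, 13),
    "rabsf2": RegionDef("rabsf2", 25, 42),
    "rabsf3": RegionDef("rabsf3", 100, 122),
}


class ResidueFrame:
    """Ordered residue numbers resolved (with C-alpha) in every ensemble member.

    The frame fixes the column ordering shared by every downstream
    coordinate matrix, fluctuation profile and correlation matrix.
    """

    def __init__(self, numbers):
        numbers = list(numbers)
        if sorted(numbers) != numbers or len(set(numbers)) != len(numbers):
            raise ValueError("frame residue numbers must be strictly increasing")
        self.numbers: list[int] = numbers

    def __len__(self) -> int:
        return len(self.numbers)

    def __iter__(self):
        return iter(self.numbers)

    def __eq__(self, other) -> bool:
        return isinstance(other, ResidueFrame) and self.numbers == other.numbers

    def index_of(self, number: int) -> int:
        return self.numbers.index(number)

    def __repr__(self) -> str:
        return f"ResidueFrame({len(self.numbers)} residues, {self.numbers[0]}..{self.numbers[-1]})"


def _resolve_altlocs(atoms: list[gemmi.Atom]) -> list[gemmi.Atom]:
    """Per atom name keep the highest-occupancy altloc; ties -> lowest letter."""
    by_name: dict[str, list[gemmi.Atom]] = {}
    order: list[str] = []
    for a in atoms:
        if a.name not in by_name:
            order.append(a.name)
        by_name.setdefault(a.name, []).append(a)
    picked = []
    for name in order:
        group = by_name[name]
        # blank altloc sorts before 'A', preserving the single-conformer case
        best = min(group, key=lambda a: (-a.occ, a.altloc or " "))
        picked.append(best)
    return picked


def read_structure(pdb_text: str, chain: str, pdb_id: str = "XXXX") -> Structure:
    """Parse one chain out of PDB-format text.

    Raises ``ValueError`` if the chain is absent or carries no C-alpha
    residue.  Waters are dropped; hetero groups become ligands; amino-acid
    residues without a resolved C-alpha are dropped (logged).
    """
    st = gemmi.read_pdb_string(pdb_text)
    if len(st) == 0:
        raise ValueError("no models in PDB text")
    model = st[0]
    gchain = model.find_chain(chain)
    if gchain is None:
        raise ValueError(f"no chain {chain!r} in PDB text")

    residues: list[Residue] = []
    ligands: list[LigandGroup] = []
    seen_numbers: set[int] = set()
    for gres in gchain:
        name = gres.name
        if name in WATER_NAMES:
            continue
        atoms = [
            Atom(a.name, a.element.name.upper(), a.pos.x, a.pos.y, a.pos.z)
            for a in _resolve_altlocs(list(gres))
        ]
        if name in STANDARD_AA:
            if gres.seqid.icode.strip():
                logger.info(
                    "%s_%s: dropping residue %s%d%s (insertion code)",
                    pdb_id, chain, name, gres.seqid.num, gres.seqid.icode,
                )
                continue
            if not any(a.name == "CA" for a in atoms):
                logger.info(
                    "%s_%s: dropping residue %s%d (no C-alpha)",
                    pdb_id, chain, name, gres.seqid.num,
                )
                continue
            if gres.seqid.num in seen_numbers:
                logger.info(
                    "%s_%s: duplicate residue number %d, keeping first",
                    pdb_id, chain, gres.seqid.num,
                )
                continue
            seen_numbers.add(gres.seqid.num)
            residues.append(Residue(gres.seqid.num, name, atoms))
        else:
            if atoms:
                ligands.append(LigandGroup(name, gres.seqid.num, atoms))

    residues.sort(key=lambda r: r.number)
    if not residues:
        raise ValueError(f"chain {chain!r} has no C-alpha residues")
    return Structure(f"{pdb_id}_{chain}", residues, ligands)


def write_structure(structure: Structure, chain: str | None = None) -> str:
    """Serialize a Structure back to minimal PDB text (ATOM/HETATM/TER/END)."""
    if chain is None:
        chain = structure.id.rsplit("_", 1)[-1][:1] or "A"
    lines = []
    serial = 1

    def fmt(record, serial, name, resname, resnum, atom):
        aname = name if len(name) >= 4 else f" {name:<3s}"
        return (
            f"{record:<6s}{serial:>5d} {aname:<4s}{resname:>4s} {chain}"
            f"{resnum:>4d}    {atom.x:8.3f}{atom.y:8.3f}{atom.z:8.3f}"
            f"{1.00:6.2f}{0.00:6.2f}          {atom.element:>2s}"
        )

    for res in structure.residues:
        for atom in res.atoms:
            lines.append(fmt("ATOM", serial, atom.name, res.name, res.number, atom))
            serial += 1
    lines.append(f"TER   {serial:>5d}")
    serial += 1
    for lig in structure.ligands:
        for atom in lig.atoms:
            lines.append(fmt("HETATM", serial, atom.name, lig.het_code, lig.number, atom))
            serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"


def common_residue_frame(structures: list[Structure]) -> ResidueFrame:
    """Residue numbers with a C-alpha resolved in *every* ensemble member."""
    if len(structures) < 2:
        raise ValueError("need at least 2 structures to define a common frame")
    common = set(structures[0].residue_numbers)
    for st in structures[1:]:
        common &= set(st.residue_numbers)
    if not common:
        raise ValueError("ensemble members share no residue numbers")
    return ResidueFrame(sorted(common))


def select_region(frame: ResidueFrame, region: RegionDef) -> list[int]:
    """0-based positions (into frame order) of residues inside the region."""
    idx = [i for i, num in enumerate(frame) if region.contains(num)]
    if not idx:
        raise ValueError(f"region {region.name} ({region.start}-{region.end}) misses the frame")
    return idx


def read_fasta(path_or_text: str) -> dict[str, str]:
    """Read FASTA into {name: sequence}; name = first token of the header.

    Accepts either a filesystem path or raw FASTA text.
    """
    from Bio import SeqIO
    from io import StringIO

    if os.path.exists(path_or_text):
        handle = open(path_or_text)
    else:
        handle = StringIO(path_or_text)
    with handle:
        records = list(SeqIO.parse(handle, "fasta"))
    if not records:
        raise ValueError("no FASTA records found")
    return {rec.id: str(rec.seq).upper().replace("U", "X") for rec in records}


RCSB_URL = "https://files.rcsb.org/download/{pdb_id}.pdb"


def fetch_structure(pdb_id: str, chain: str, cache_dir: str) -> Structure:
    """Fetch-by-ID helper: read ``<cache_dir>/<pdb_id>.pdb``, downloading it
    from the RCSB on a cache miss (requires network access)."""
    pdb_id = pdb_id.upper()
    os.makedirs(cache_dir, exist_ok=True)
    path = os.path.join(cache_dir, f"{pdb_id}.pdb")
    if not os.path.exists(path):
        url = RCSB_URL.format(pdb_id=pdb_id)
        logger.info("downloading %s -> %s", url, path)
        with urllib.request.urlopen(url, timeout=60) as resp, open(path, "wb") as out:
            out.write(resp.read())
    with open(path) as fh:
        return read_structure(fh.read(), chain, pdb_id=pdb_id)
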