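"""Residue interaction networks (RINs) and communication analysis.

A structure is abstracted as an undirected graph: one node per residue, an
edge whenever the C-alpha/C-alpha distance is within a cutoff (7 A by
default), weighted by that Euclidean distance.  Weighted betweenness
centrality and weighted shortest paths between ligand-contact residues and
nucleotide-contact residues quantify how efficiently a perturbation at a
surface site can reach the active site.  Residue distances to the protein
center of mass complement the centrality picture: high-betweenness residues
tend to sit near the core.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .structures_io import Structure

#: Nucleotide het codes recognized at the active site.
NUCLEOTIDE_CODES = {"GDP", "GTP", "GNP", "GSP"}

#: Standard atomic masses (g/mol) for the elements found in polypeptides.
ATOMIC_MASS = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "SE": 78.971, "P": 30.974,
}


@dataclass
class ResidueInteractionNetwork:
    graph: nx.Graph     # nodes: residue numbers; edge attr 'weight' (A)
    cutoff: float
    structure_id: str = ""

    @property
    def nodes(self) -> list[int]:
        return sorted(self.graph.nodes)

    def edge_weight(self, i: int, j: int) -> float:
        return self.graph.edges[i, j]["weight"]


@dataclass
class PathReport:
    source: int
    target: int
    nodes: list[int] = field(default_factory=list)
    length: float = math.inf
    reachable: bool = False


def build_rin(structure: Structure, cutoff: float = 7.0) -> ResidueInteractionNetwork:
    """All residue pairs whose C-alpha atoms are within ``cutoff`` Angstrom,
    weighted by the distance (rounded to 3 decimals)."""
    if len(structure.residues) < 2:
        raise ValueError("need at least 2 residues to build a network")
    g = nx.Graph()
    numbers = [r.number for r in structure.residues]
    xyz = np.array([r.ca.xyz for r in structure.residues])
    g.add_nodes_from(numbers)
    diff = xyz[:, None, :] - xyz[None, :, :]
    dist = np.sqrt(np.sum(diff * diff, axis=2))
    n = len(numbers)
    for i in range(n):
        for j in range(i + 1, n):
            if dist[i, j] <= cutoff:
                g.add_edge(numbers[i], numbers[j], weight=round(float(dist[i, j]), 3))
    return ResidueInteractionNetwork(g, cutoff, structure.id)


def betweenness(network: ResidueInteractionNetwork) -> dict[int, float]:
    """Weighted-shortest-path betweenness centrality, normalized by
    (N-1)(N-2)/2 for an undirected network."""
    if network.graph.number_of_nodes() == 0:
        raise ValueError("empty network")
    return nx.betweenness_centrality(network.graph, normalized=True, weight="weight")


def shortest_paths(
    network: ResidueInteractionNetwork,
    sources: set[int],
    targets: set[int],
) -> list[PathReport]:
    """Minimum-total-weight path for every (source, target) pair.

    Ties among equally short paths are broken by fewer nodes, then by the
    lexicographically smallest node sequence, so outputs are deterministic.
    Unreachable pairs come back flagged rather than raising.
    """
    g = network.graph
    unknown = (set(sources) | set(targets)) - set(g.nodes)
    if unknown:
        raise ValueError(f"residues not in network: {sorted(unknown)}")
    reports = []
    for s in sorted(sources):
        dist, _ = nx.single_source_dijkstra(g, s, weight="weight")
        for t in sorted(targets):
            if t not in dist:
                reports.append(PathReport(s, t))
                continue
            if s == t:
                reports.append(PathReport(s, t, [s], 0.0, True))
                continue
            best = min(
                nx.all_shortest_paths(g, s, t, weight="weight"),
                key=lambda p: (len(p), p),
            )
            length = sum(g.edges[a, b]["weight"] for a, b in zip(best, best[1:]))
            reports.append(PathReport(s, t, list(best), float(length), True))
    return reports


def nucleotide_contacts(
    structure: Structure,
    het_codes: set[str] | None = None,
    cutoff: float = 4.0,
) -> set[int]:
    """Residues with any heavy atom within ``cutoff`` of any heavy atom of a
    bound nucleotide (GDP/GTP or a non-hydrolyzable analog)."""
    codes = NUCLEOTIDE_CODES if het_codes is None else set(het_codes)
    ligs = [l for l in structure.ligands if l.het_code in codes]
    if not ligs:
        raise ValueError(f"{structure.id}: no ligand with code in {sorted(codes)}")
    lig_xyz = np.array([a.xyz for lig in ligs for a in lig.heavy_atoms()])
    contacts = set()
    for res in structure.residues:
        res_xyz = np.array([a.xyz for a in res.atoms if a.element != "H"])
        d = np.sqrt(((res_xyz[:, None, :] - lig_xyz[None, :, :]) ** 2).sum(axis=2))
        if (d <= cutoff).any():
            contacts.add(res.number)
    return contacts


def center_of_mass(structure: Structure) -> np.ndarray:
    """Mass-weighted center of all heavy atoms of the polypeptide (ligands
    and hydrogens excluded).  Unknown elements default to carbon mass."""
    coords, masses = [], []
    for res in structure.residues:
        for a in res.atoms:
            if a.element == "H":
                continue
            coords.append(a.xyz)
            masses.append(ATOMIC_MASS.get(a.element, ATOMIC_MASS["C"]))
    xyz = np.asarray(coords)
    w = np.asarray(masses)
    return (xyz * w[:, None]).sum(axis=0) / w.sum()


def center_of_mass_distances(
    structure: Structure, residues: set[int] | None = None
) -> dict[int, float]:
    """Distance (A) from each requested residue's C-alpha to the protein
    center of mass."""
    com = center_of_mass(structure)
    wanted = sorted(residues) if residues is not None else structure.residue_numbers
    out = {}
    for num in wanted:
        ca = structure.residue(num).ca  # KeyError -> unknown residue
        out[num] = float(np.linalg.norm(np.asarray(ca.xyz) - com))
    return out
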