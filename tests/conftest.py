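import numpy as np
import pytest

from allostruct import ensemble_geometry as geo
from allostruct import synthetic_data as synth


def pdb_line(record, serial, name, resname, chain, resseq, xyz,
             occ=1.00, altloc=" ", element=None, icode=" "):
    """One fixed-width ATOM/HETATM line."""
    element = element or name[0]
    aname = name if len(name) >= 4 else f" {name:<3s}"
    return (
        f"{record:<6s}{serial:>5d} {aname:<4s}{altloc}{resname:>3s} {chain}"
        f"{resseq:>4d}{icode}   {xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
        f"{occ:6.2f}{0.0:6.2f}          {element:>2s}"
    )


def make_pdb_text(residues, hetero=(), chain="A"):
    """residues: [(resseq, resname, [(atom, element, xyz), ...])]; hetero
    likewise.  Returns PDB text."""
    lines, serial = [], 1
    for resseq, resname, atoms in residues:
        for name, element, xyz in atoms:
            lines.append(pdb_line("ATOM", serial, name, resname, chain, resseq, xyz,
                                  element=element))
            serial += 1
    lines.append(f"TER   {serial:>5d}")
    for resseq, resname, atoms in hetero:
        for name, element, xyz in atoms:
            lines.append(pdb_line("HETATM", serial, name, resname, chain, resseq, xyz,
                                  element=element))
            serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"


def simple_residue(resseq, x0=0.0, resname="ALA"):
    return (
        resseq, resname,
        [("N", "N", (x0, 1.4, 0.0)),
         ("CA", "C", (x0, 0.0, 0.0)),
         ("C", "C", (x0 + 1.2, -0.8, 0.0)),
         ("O", "O", (x0 + 1.2, -2.0, 0.0))],
    )


@pytest.fixture(scope="session")
def three_cluster():
    """Planted 3-cluster ensemble (27 members) with its ground truth."""
    return synth.make_ensemble(synth.three_cluster_spec(seed=11))


@pytest.fixture(scope="session")
def aligned_three_cluster(three_cluster):
    ensemble, truth = three_cluster
    core = geo.find_invariant_core(ensemble)
    return geo.superpose_ensemble(ensemble, core), truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
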