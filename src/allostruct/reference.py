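"""Default reference inputs for the Rab11 ensemble analysis.

The crystallographic ensemble is configuration, not code: the default chain
list below reconstructs the 27-chain human Rab11 ensemble (Rab11a and
Rab11b, with and without effector partners) and can be overridden freely.
Coordinates and sequences are *not* bundled; they are fetched into a local
cache (``data/reference`` by convention) with
``scripts/fetch_reference_data.py`` or :func:`load_ensemble` /
:func:`load_sequences` given an existing cache.
"""

from __future__ import annotations

import os
import urllib.request

from .structures_io import Structure, fetch_structure, read_fasta

#: (pdb_id, chain) pairs of the default Rab11 ensemble.
RAB11_ENSEMBLE_CHAINS: list[tuple[str, str]] = [
    ("1OIV", "A"), ("1OIV", "B"), ("1OIW", "A"), ("1OIX", "A"),
    ("1YZK", "A"), ("2F9M", "A"), ("2GZD", "A"), ("2GZD", "B"),
    ("2GZH", "A"), ("2D7C", "A"), ("2D7C", "B"), ("2HV8", "A"),
    ("2HV8", "B"), ("2HV8", "C"), ("4C4P", "A"), ("4UJ3", "A"),
    ("4UJ3", "G"), ("4LX0", "A"), ("4LX0", "C"), ("4D0L", "B"),
    ("4D0L", "D"), ("4D0L", "F"), ("4OJK", "A"), ("4UJ5", "B"),
    ("5C46", "F"), ("5JCZ", "A"), ("5JCZ", "D"),
]

#: The eight representative structures (cluster clustroids).
RAB11_REPRESENTATIVES: list[str] = [
    "1OIV_A", "1YZK_A", "4C4P_A", "4LX0_C", "4OJK_A", "4UJ5_B", "5C46_F", "5JCZ_D",
]

#: H-Ras comparison structure (chain A).
HRAS_CHAIN: tuple[str, str] = ("2Q21", "A")

#: UniProt accessions of the compared sequences.
UNIPROT_ACCESSIONS: dict[str, str] = {
    "rab11a": "P62491",
    "rab11b": "Q15907",
    "rab1a": "P62820",
    "rab1b": "Q9H0U4",
    "hras": "P01112",
}

UNIPROT_URL = "https://rest.uniprot.org/uniprotkb/{accession}.fasta"


def fetch_fasta(accession: str, cache_dir: str) -> str:
    """Return the path of ``<cache_dir>/<accession>.fasta``, downloading it
    from UniProt on a cache miss (requires network access)."""
    os.makedirs(cache_dir, exist_ok=True)
    path = os.path.join(cache_dir, f"{accession}.fasta")
    if not os.path.exists(path):
        url = UNIPROT_URL.format(accession=accession)
        with urllib.request.urlopen(url, timeout=60) as resp, open(path, "wb") as out:
            out.write(resp.read())
    return path


def load_sequences(cache_dir: str) -> dict[str, str]:
    """{short name: sequence} for the reference proteins from the cache."""
    out = {}
    for name, acc in UNIPROT_ACCESSIONS.items():
        path = os.path.join(cache_dir, f"{acc}.fasta")
        records = read_fasta(path)
        out[name] = next(iter(records.values()))
    return out


def load_ensemble(cache_dir: str, chains=None) -> list[Structure]:
    """The ensemble chains from cached PDB files (downloading on misses)."""
    chains = RAB11_ENSEMBLE_CHAINS if chains is None else chains
    return [fetch_structure(pdb_id, ch, cache_dir) for pdb_id, ch in chains]
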