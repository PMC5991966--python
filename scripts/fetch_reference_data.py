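"""Populate the local reference-data cache (requires network access).

Downloads the PDB entries of the Rab11 ensemble, the H-Ras comparison
structure and the UniProt FASTA sequences into ``data/reference/``, where
the accession-based checks in the test suite expect to find them:

    python scripts/fetch_reference_data.py [--cache data/reference]
"""

from __future__ import annotations

import argparse
import sys
import urllib.request
from pathlib import Path

from allostruct import reference
from allostruct.structures_io import RCSB_URL


def main(argv=None) -> int:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cache", default="data/reference")
    args = ap.parse_args(argv)
    cache = Path(args.cache)
    cache.mkdir(parents=True, exist_ok=True)

    pdb_ids = sorted({pid for pid, _ in reference.RAB11_ENSEMBLE_CHAINS}
                     | {reference.HRAS_CHAIN[0]})
    for pdb_id in pdb_ids:
        path = cache / f"{pdb_id}.pdb"
        if not path.exists():
            with urllib.request.urlopen(RCSB_URL.format(pdb_id=pdb_id), timeout=60) as r:
                path.write_bytes(r.read())
        print(f"{pdb_id}: cached -> {path}")
    for name, acc in reference.UNIPROT_ACCESSIONS.items():
        path = reference.fetch_fasta(acc, str(cache))
        print(f"{name} ({acc}): {path}")
    print(f"reference cache ready under {cache}/")
    return 0


if __name__ == "__main__":
    sys.exit(main())
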