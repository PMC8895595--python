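#!/usr/bin/env python
"""One-time fetch of the 19 candidate-protein sequences from UniProt.

Writes data/table1_sequences.fasta (record ids are the accessions), enabling
the optional accession-based checks in the test suite: hornerin's serine
rank and its glycine/serine bias coverage.  Requires network access; the
library itself never fetches anything.

Usage: python scripts/fetch_table1.py [--out data/table1_sequences.fasta]
"""

import argparse
import urllib.request
from pathlib import Path

from depositcomp import load_table1_manifest

UNIPROT_FASTA = "https://rest.uniprot.org/uniprotkb/{acc}.fasta"


def fetch(accession: str) -> str:
    with urllib.request.urlopen(UNIPROT_FASTA.format(acc=accession), timeout=60) as r:
        text = r.read().decode()
    header, *lines = text.strip().splitlines()
    # normalize the header to ">ACCESSION original description"
    return ">" + accession + " " + header.lstrip(">") + "\n" + "\n".join(lines) + "\n"


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument(
        "--out",
        type=Path,
        default=Path(__file__).resolve().parent.parent / "data" / "table1_sequences.fasta",
    )
    args = parser.parse_args()
    args.out.parent.mkdir(parents=True, exist_ok=True)
    manifest = load_table1_manifest()
    with open(args.out, "w") as fh:
        for description, accession in manifest.entries:
            print(f"fetching {accession} ({description})")
            fh.write(fetch(accession))
    print(f"wrote {len(manifest)} sequences to {args.out}")


if __name__ == "__main__":
    main()
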