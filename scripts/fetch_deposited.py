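#!/usr/bin/env python
"""One-time fetch of the 17 deposited exon-2 allele sequences
(GenBank HQ902164-HQ902180) into data/deposited_exon2.fasta.

Requires network access; the analysis pipeline and acceptance report
then run fully offline.
"""

from __future__ import annotations

import argparse
from pathlib import Path

from Bio import Entrez, SeqIO

ACCESSIONS = [f"HQ9021{n}" for n in range(64, 81)]
DEFAULT_OUT = (
    Path(__file__).resolve().parent.parent / "data" / "deposited_exon2.fasta"
)


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--email", required=True,
                        help="contact email for NCBI E-utilities")
    parser.add_argument("--out", type=Path, default=DEFAULT_OUT)
    args = parser.parse_args()

    Entrez.email = args.email
    with Entrez.efetch(
        db="nuccore", id=",".join(ACCESSIONS), rettype="fasta",
        retmode="text",
    ) as handle:
        records = list(SeqIO.parse(handle, "fasta"))
    if len(records) != len(ACCESSIONS):
        raise SystemExit(
            f"expected {len(ACCESSIONS)} records, got {len(records)}"
        )
    args.out.parent.mkdir(parents=True, exist_ok=True)
    SeqIO.write(records, str(args.out), "fasta")
    print(f"wrote {len(records)} records to {args.out}")


if __name__ == "__main__":
    main()
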