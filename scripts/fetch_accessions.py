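#!/usr/bin/env python
"""Optional helper: download the study's GenBank records for the
accession-level checks. The library itself never touches the network.

Fetches the two complete mitochondrial genomes and the cox1 panel into
data/accessions/ as GenBank flat files / FASTA. Requires internet
access; run once, then the accession-level test in the suite activates.
"""

from __future__ import annotations

import sys
import urllib.request
from pathlib import Path

EUTILS = "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"
GENOMES = ["FN424190", "NC001324", "NC000862"]
COX1 = [f"FN4213{n}" for n in range(24, 35)] + ["AM072773", "AM072766"]

OUT = Path(__file__).resolve().parent.parent / "data" / "accessions"


def fetch(acc: str, rettype: str, suffix: str) -> None:
    url = f"{EUTILS}?db=nuccore&id={acc}&rettype={rettype}&retmode=text"
    dest = OUT / f"{acc}.{suffix}"
    if dest.exists():
        print(f"{dest} exists, skipping")
        return
    print(f"fetching {acc} -> {dest}")
    with urllib.request.urlopen(url, timeout=60) as resp:
        dest.write_bytes(resp.read())


def main() -> int:
    OUT.mkdir(parents=True, exist_ok=True)
    for acc in GENOMES:
        fetch(acc, "gbwithparts", "gb")
    for acc in COX1:
        fetch(acc, "fasta", "fasta")
    return 0


if __name__ == "__main__":
    sys.exit(main())
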