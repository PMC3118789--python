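#!/usr/bin/env python
"""Annotation and composition of the synthetic genome vs its ground truth.

Runs the six-frame ORF scan, spacer derivation, coding-density summary,
composition by region class, positional GC and the codon-usage profile
(rare codons, Nc) on the genome written by 02_simulate_genome.py, and
contrasts each quantity with the generator ledger. Writes
results/annotation_composition.tsv.
"""

import json
from pathlib import Path

from mitocomp.annotate import coding_summary, find_orfs
from mitocomp.codon_usage import usage_profile
from mitocomp.composition import composition_by_region, gc_by_codon_position, round1
from mitocomp.seq_io import extract_cds, read_genbank

BASE = Path(__file__).resolve().parent.parent / "results"
SIM = BASE / "sim"


def main() -> None:
    record = read_genbank(SIM / "genome.gb")
    truth = json.loads((SIM / "truth.json").read_text())
    rows = []

    cs = coding_summary(record)
    rows.append(("total_bp", cs.total_bp, truth["total_bp"]))
    rows.append(("coding_bp", cs.coding_bp, truth["coding_bp"]))
    rows.append(
        ("coding_fraction_pct", round1(100 * cs.coding_fraction),
         round1(100 * truth["coding_bp"] / truth["total_bp"]))
    )

    orfs = find_orfs(record.sequence, code_id=truth["code_id"])
    longest = max(orfs, key=lambda c: c.length_aa)
    ymf64 = max(
        (g for g in truth["genes"] if g["gene_class"] == "orf"),
        key=lambda g: g["length_nt"],
    )
    rows.append(("longest_orf_bp", 3 * longest.length_aa, ymf64["length_nt"] - 3))

    for comp in composition_by_region(record):
        rows.append((f"gc_{comp.region_class}_pct", round1(comp.gc), ""))

    cds_set = [extract_cds(record, f, 4) for f in record.genes() if f.ftype == "CDS"]
    pos = gc_by_codon_position(cds_set)
    rows.append(("gc3_pct", round1(pos.gc3), ""))
    prof = usage_profile(cds_set)
    rows.append(("nc", round(prof.nc, 1), ""))
    rows.append(("rare_codons", prof.rare_count, ""))

    out = BASE / "annotation_composition.tsv"
    out.write_text(
        "quantity\tmeasured\tledger\n"
        + "\n".join(f"{k}\t{m}\t{t}" for k, m, t in rows) + "\n"
    )
    for k, m, t in rows:
        print(f"{k}\t{m}\t{t}")
    print(f"-> {out}")


if __name__ == "__main__":
    main()
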