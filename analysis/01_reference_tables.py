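#!/usr/bin/env python
"""Reanalysis of the published comparative tables.

Recomputes, from the bundled per-gene divergence and codon-frequency
tables of the three ciliate mitochondrial genomes: the known-gene vs
unassigned-ORF Ka/Ks contrast (class means and Mann–Whitney z), the
coding-density fractions, Wright's Nc under the code-4 degeneracy
census, and the rare-codon counts. Writes results/reference_tables.tsv.

Finding: known genes average Ka/Ks 0.080 vs 0.203 for ORFs (z = -3.31,
p < 0.001); Nc 31.5 / 33.4 / 51.9 and rare counts 28 / 23 / 5 for
T. pyriformis / P. caudatum / P. tetraurelia — the aurelia-lineage
genome is far less codon-biased than either AT-rich genome.
"""

from pathlib import Path

from mitocomp import refdata
from mitocomp.annotate import CodingSummary
from mitocomp.codon_usage import UsageProfile, classify_rare, nc_from_frequencies
from mitocomp.composition import round1
from mitocomp.divergence import mann_whitney

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    rows = []

    df = refdata.gene_divergence()
    known = df[df.gene_class == "known"].kaks.dropna().tolist()
    orf = df[df.gene_class == "orf"].kaks.dropna().tolist()
    rows.append(("known_gene_mean_kaks", round(sum(known) / len(known), 3)))
    rows.append(("orf_mean_kaks", round(sum(orf) / len(orf), 3)))
    test = mann_whitney(known, orf)
    rows.append(("mann_whitney_z", round(test.z, 2)))
    rows.append(("mann_whitney_p", f"{test.p_two_sided:.2g}"))

    stats = refdata.genome_stats().set_index("species").loc["P_caudatum"]
    cs = CodingSummary(
        total_bp=int(stats.total_bp),
        coding_bp=int(stats.coding_bp),
        protein_coding_bp=int(stats.protein_coding_bp),
    )
    rows.append(("coding_fraction_pct", round1(100 * cs.coding_fraction)))
    rows.append(("protein_coding_fraction_pct", round1(100 * cs.protein_coding_fraction)))

    for species in refdata.SPECIES:
        freqs = refdata.codon_frequencies(species)
        rows.append((f"nc_{species}", round(nc_from_frequencies(freqs), 1)))
        prof = UsageProfile(frequencies=freqs, family_totals={}, most_frequent={})
        _, n_rare = classify_rare(prof)
        rows.append((f"rare_codons_{species}", n_rare))

    out = OUT / "reference_tables.tsv"
    out.write_text("quantity\tvalue\n" + "\n".join(f"{k}\t{v}" for k, v in rows) + "\n")
    for k, v in rows:
        print(f"{k}\t{v}")
    print(f"-> {out}")


if __name__ == "__main__":
    main()
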