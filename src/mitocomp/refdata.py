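"""Published comparative reference tables for the three ciliate
mitochondrial genomes (P. caudatum FN424190, P. tetraurelia NC001324,
T. pyriformis NC000862), bundled as TSV.

These tables carry the published per-gene divergence statistics, the
per-amino-acid relative codon frequencies, the region-class base
composition, and genome-level summary numbers. They serve two roles:
inputs to the reanalysis drivers (class contrasts, Nc, rare-codon
classification are recomputed from them), and realistic parameter
sources for the synthetic-data generator.
"""

from __future__ import annotations

from importlib import resources
from typing import Dict, Tuple

import pandas as pd

SPECIES = ("T_pyriformis", "P_caudatum", "P_tetraurelia")

#: published copy numbers of the ymf64 minisatellite locus across strains
STRAIN_REPEAT_COPIES: Dict[str, int] = {
    "a": 18, "b": 11, "c": 11, "d": 9, "e": 9, "f": 14, "g": 10,
}


def _read(name: str) -> pd.DataFrame:
    with resources.files("mitocomp.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def gene_divergence() -> pd.DataFrame:
    """Per-gene aa length, protein identity and Ka/Ks (NA = not alignable)."""
    return _read("ciliate_mt_gene_divergence.tsv")


def codon_usage() -> pd.DataFrame:
    """Within-family relative codon frequencies per species (2 dp)."""
    return _read("ciliate_mt_codon_usage.tsv")


def codon_frequencies(species: str) -> Dict[str, float]:
    """codon -> within-family relative frequency for one species."""
    if species not in SPECIES:
        raise KeyError(f"unknown species {species!r}; choose from {SPECIES}")
    df = codon_usage()
    return dict(zip(df["codon"], df[species]))


def region_composition() -> pd.DataFrame:
    """Percent G/A/T/C by region class per species."""
    return _read("ciliate_mt_region_composition.tsv")


def region_composition_fractions(species: str, region_class: str) -> Dict[str, float]:
    """base -> fraction (sums to 1) for one species and region class."""
    df = region_composition()
    sub = df[df["region_class"] == region_class]
    vals = dict(zip(sub["base"], sub[species]))
    total = sum(vals.values())
    return {b: v / total for b, v in vals.items()}


def genome_stats() -> pd.DataFrame:
    """Genome-level summary values per species (lengths, GC, Nc, rare)."""
    return _read("ciliate_mt_genome_stats.tsv")
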