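"""Genetic-code bookkeeping on top of the NCBI translation tables.

Ciliate mitochondria use NCBI translation table 4 (the mold/protozoan
mitochondrial code): TGA encodes tryptophan and only TAA/TAG terminate.
That reshuffles the synonymous-family structure relative to the standard
code — Trp becomes a two-codon family — so everything downstream
(relative codon frequencies, Wright's Nc, NG86 site counting) derives
the family structure from the active code at runtime instead of assuming
the standard-code census.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from functools import lru_cache

from Bio.Data import CodonTable

BASES = "ACGT"
DEFAULT_CODE_ID = 4
STOP = "*"


@dataclass(frozen=True)
class GeneticCode:
    """A codon→amino-acid map with its synonymous-family structure."""

    code_id: int
    forward: dict  # codon -> one-letter aa, sense codons only
    stop_codons: frozenset

    @property
    def sense_codons(self) -> tuple:
        return tuple(sorted(self.forward))

    def translate_codon(self, codon: str) -> str:
        """One-letter amino acid, '*' for stops, 'X' for codons with N."""
        codon = codon.upper()
        if codon in self.stop_codons:
            return STOP
        aa = self.forward.get(codon)
        return aa if aa is not None else "X"

    def translate(self, nt: str) -> str:
        return "".join(
            self.translate_codon(nt[i : i + 3]) for i in range(0, len(nt) - len(nt) % 3, 3)
        )

    def family(self, aa: str) -> tuple:
        """Sorted synonymous codons of an amino acid ('*' = stop family)."""
        if aa == STOP:
            return tuple(sorted(self.stop_codons))
        return tuple(sorted(c for c, a in self.forward.items() if a == aa))

    @property
    def amino_acids(self) -> tuple:
        return tuple(sorted(set(self.forward.values())))

    def degeneracy_census(self) -> dict:
        """Map family size k -> number of amino-acid families of that size.

        Under code 4 this is {1: 1, 2: 10, 3: 1, 4: 5, 6: 3} (62 sense
        codons), not the standard-code {1: 2, 2: 9, 3: 1, 4: 5, 6: 3}.
        """
        sizes = Counter(len(self.family(aa)) for aa in self.amino_acids)
        return dict(sorted(sizes.items()))

    @property
    def n_sense(self) -> int:
        return len(self.forward)


@lru_cache(maxsize=None)
def get_code(code_id: int = DEFAULT_CODE_ID) -> GeneticCode:
    table = CodonTable.unambiguous_dna_by_id[code_id]
    return GeneticCode(
        code_id=code_id,
        forward=dict(table.forward_table),
        stop_codons=frozenset(table.stop_codons),
    )


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]
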