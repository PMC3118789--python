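"""Nucleotide composition by region class and codon position.

Reports follow the conventions of comparative mtDNA tables: percentages
of G/A/T/C (N excluded from the denominator), G+C per region class
(protein-coding / noncoding / rRNA / whole genome), and G+C at the
three codon positions pooled over a set of in-frame coding sequences
(GC1/GC2/GC3). Stop codons are excluded from positional GC by default,
matching the usual sense-codon convention; a flag reinstates them.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Dict, Iterable, List, Sequence

from .annotate import derive_spacers
from .codes import DEFAULT_CODE_ID, get_code
from .seq_io import CodingSequence, GenomeRecord, extract_cds, feature_nucleotides

log = logging.getLogger(__name__)

REGION_CLASSES = ("protein_coding", "noncoding", "rRNA", "whole")


@dataclass
class CompositionSummary:
    region_class: str
    g: float
    a: float
    t: float
    c: float
    n_bases: int

    @property
    def gc(self) -> float:
        return self.g + self.c


@dataclass
class PositionalGC:
    gc1: float
    gc2: float
    gc3: float
    n_codons: int


def round1(x: float) -> float:
    """1-decimal report rounding, half away from zero (table convention)."""
    return float(Decimal(repr(x)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def base_composition(sequence: str, region_class: str = "whole") -> CompositionSummary:
    """Percent G/A/T/C of a sequence; Ns excluded from the denominator."""
    if not sequence:
        raise ValueError("empty sequence")
    counts = Counter(sequence.upper())
    denom = sum(counts[b] for b in "GATC")
    if denom == 0:
        raise ValueError("sequence contains no unambiguous bases")
    if counts.get("N"):
        log.warning("%d N bases excluded from composition denominator", counts["N"])
    pct = {b: 100.0 * counts[b] / denom for b in "GATC"}
    return CompositionSummary(
        region_class=region_class,
        g=pct["G"],
        a=pct["A"],
        t=pct["T"],
        c=pct["C"],
        n_bases=denom,
    )


def composition_by_region(
    record: GenomeRecord, code_id: int = DEFAULT_CODE_ID
) -> List[CompositionSummary]:
    """Composition of concatenated CDS (coding strand), spacers, and rRNA.

    Empty region classes are omitted with a warning. The whole-genome
    summary is always included last.
    """
    pools: Dict[str, str] = {"protein_coding": "", "noncoding": "", "rRNA": ""}
    for f in record.genes():
        if f.ftype == "CDS":
            pools["protein_coding"] += feature_nucleotides(record, f)
        elif f.ftype == "rRNA":
            pools["rRNA"] += feature_nucleotides(record, f)
    pools["noncoding"] = "".join(
        record.sequence[s.start : s.end] for s in derive_spacers(record)
    )
    out = []
    for cls in ("protein_coding", "noncoding", "rRNA"):
        if not pools[cls]:
            log.warning("region class %s empty; omitted", cls)
            continue
        out.append(base_composition(pools[cls], region_class=cls))
    out.append(base_composition(record.sequence, region_class="whole"))
    return out


def gc_by_codon_position(
    cds_set: Iterable[CodingSequence | str],
    include_stops: bool = False,
    code_id: int = DEFAULT_CODE_ID,
) -> PositionalGC:
    """Pooled percent G+C at codon positions 1/2/3 over coding sequences.

    Accepts CodingSequence objects or raw in-frame nucleotide strings.
    Stop codons are dropped unless ``include_stops``; codons containing
    N are skipped entirely.
    """
    code = get_code(code_id)
    gc = [0, 0, 0]
    total = 0
    for item in cds_set:
        nt = item.nucleotides if isinstance(item, CodingSequence) else item.upper()
        name = item.name if isinstance(item, CodingSequence) else "<sequence>"
        if len(nt) % 3 != 0:
            raise ValueError(f"{name}: length {len(nt)} not a multiple of 3")
        for i in range(0, len(nt), 3):
            codon = nt[i : i + 3]
            if "N" in codon:
                continue
            if not include_stops and codon in code.stop_codons:
                continue
            total += 1
            for p in range(3):
                if codon[p] in "GC":
                    gc[p] += 1
    if total == 0:
        raise ValueError("no scorable codons")
    return PositionalGC(
        gc1=100.0 * gc[0] / total,
        gc2=100.0 * gc[1] / total,
        gc3=100.0 * gc[2] / total,
        n_codons=total,
    )


AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"


def aa_composition(proteins: Iterable[str]) -> Dict[str, float]:
    """Percent of each amino acid over all residues of all proteins."""
    counts = Counter()
    for p in proteins:
        counts.update(p.upper())
    total = sum(counts[a] for a in AA_ORDER)
    if total == 0:
        return {a: 0.0 for a in AA_ORDER}
    return {a: 100.0 * counts[a] / total for a in AA_ORDER}
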