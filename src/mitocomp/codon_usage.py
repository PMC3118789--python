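"""Codon counting, relative synonymous frequencies, rare codons, and
Wright's effective number of codons (Nc).

Nc summarizes codon-usage bias: it equals the number of amino-acid
families (20) when exactly one codon is used per amino acid and the
number of sense codons when synonymous codons are used uniformly. The
classic formulation assumes the standard-code degeneracy census
(2/9/1/5/3 families of size 1/2/3/4/6, maximum 61). Here the census is
derived from the active genetic code at runtime: under the mold/
protozoan mitochondrial code (table 4) tryptophan is a two-codon family
(TGA/TGG), giving the census 1/10/1/5/3 and a maximum of 62.

A codon is "rare" when its within-family relative frequency falls below
a threshold (default 0.085, i.e. frequencies that print as <= 0.08 at
two decimals); stop codons participate in rare classification but never
in Nc.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Tuple

from .codes import DEFAULT_CODE_ID, GeneticCode, get_code
from .seq_io import CodingSequence

log = logging.getLogger(__name__)

DEFAULT_RARE_THRESHOLD = 0.085


@dataclass
class CodonCountTable:
    counts: Dict[str, int]
    code_id: int
    scope: str = "genome"
    n_skipped: int = 0  # codons containing N

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def __add__(self, other: "CodonCountTable") -> "CodonCountTable":
        if self.code_id != other.code_id:
            raise ValueError("cannot add tables under different genetic codes")
        merged = Counter(self.counts)
        merged.update(other.counts)
        return CodonCountTable(
            counts=dict(merged),
            code_id=self.code_id,
            scope="genome",
            n_skipped=self.n_skipped + other.n_skipped,
        )


@dataclass
class UsageProfile:
    """Within-family relative codon frequencies plus summary statistics."""

    frequencies: Dict[str, float]  # codon -> frequency within its aa family
    family_totals: Dict[str, int]  # aa (incl '*') -> codon count
    most_frequent: Dict[str, str]  # aa -> codon (ties: alphabetical first)
    rare: set = field(default_factory=set)
    nc: Optional[float] = None
    code_id: int = DEFAULT_CODE_ID

    @property
    def rare_count(self) -> int:
        return len(self.rare)


def count_codons(
    cds_set: Iterable[CodingSequence | str],
    code_id: int = DEFAULT_CODE_ID,
    scope: str = "genome",
) -> CodonCountTable:
    """Count codons over in-frame sequences; N-containing codons skipped."""
    counts: Counter = Counter()
    skipped = 0
    for item in cds_set:
        nt = item.nucleotides if isinstance(item, CodingSequence) else item.upper()
        if len(nt) % 3 != 0:
            raise ValueError(f"in-frame sequence required, got length {len(nt)}")
        for i in range(0, len(nt), 3):
            codon = nt[i : i + 3]
            if "N" in codon:
                skipped += 1
            else:
                counts[codon] += 1
    return CodonCountTable(
        counts=dict(counts), code_id=code_id, scope=scope, n_skipped=skipped
    )


def _families(code: GeneticCode, include_stops: bool = True):
    aas = list(code.amino_acids)
    if include_stops:
        aas.append("*")
    return {aa: code.family(aa) for aa in aas}


def relative_frequencies(table: CodonCountTable) -> UsageProfile:
    """Per-amino-acid relative synonymous codon frequencies.

    Within each family of the active code (stops treated as their own
    family), frequency = count / family total. Families with zero total
    are flagged by omission from ``frequencies``.
    """
    if table.total == 0:
        raise ValueError("empty codon count table")
    code = get_code(table.code_id)
    freqs: Dict[str, float] = {}
    family_totals: Dict[str, int] = {}
    most: Dict[str, str] = {}
    for aa, codons in _families(code).items():
        fam_total = sum(table.counts.get(c, 0) for c in codons)
        family_totals[aa] = fam_total
        if fam_total == 0:
            log.warning("family %s unobserved; frequencies undefined", aa)
            continue
        for c in codons:
            freqs[c] = table.counts.get(c, 0) / fam_total
        most[aa] = max(codons, key=lambda c: (freqs[c], c))  # noqa: B023
    return UsageProfile(
        frequencies=freqs,
        family_totals=family_totals,
        most_frequent=most,
        code_id=table.code_id,
    )


def classify_rare(
    profile: UsageProfile, threshold: float = DEFAULT_RARE_THRESHOLD
) -> Tuple[set, int]:
    """Flag codons with within-family frequency below ``threshold``.

    Stop codons are classified too (a never-used stop codon counts as
    rare). Returns (rare set, rare count) and records them on the
    profile.
    """
    rare = {c for c, f in profile.frequencies.items() if f < threshold}
    profile.rare = rare
    return rare, len(rare)


def _family_homozygosity(counts: List[int]) -> Optional[float]:
    """Wright's F-hat = (n * sum p^2 - 1) / (n - 1); None if undefined."""
    n = sum(counts)
    if n <= 1:
        return None
    sum_p2 = sum((c / n) ** 2 for c in counts)
    f = (n * sum_p2 - 1) / (n - 1)
    return f if f > 0 else None


def effective_number_of_codons(table: CodonCountTable) -> float:
    """Wright's Nc generalized to the active code's degeneracy census.

    Per family, F-hat = (n*sum p_i^2 - 1)/(n - 1); Nc = sum_k N_k /
    mean(F-hat of size-k families), with single-codon families added
    directly. Families with n <= 1 or F-hat <= 0 are dropped from their
    class mean (Wright's averaging fallback); a wholly absent class of
    size 3 borrows the mean of the size-2 and size-4 classes, and any
    other absent class rescales the result by its census share. The
    value is capped at the number of sense codons.
    """
    if table.total == 0:
        raise ValueError("empty codon count table")
    code = get_code(table.code_id)
    census = code.degeneracy_census()
    f_by_class: Dict[int, List[float]] = defaultdict(list)
    for aa in code.amino_acids:
        codons = code.family(aa)
        k = len(codons)
        if k == 1:
            continue
        f = _family_homozygosity([table.counts.get(c, 0) for c in codons])
        if f is not None:
            f_by_class[k].append(f)

    mean_f: Dict[int, float] = {
        k: sum(v) / len(v) for k, v in f_by_class.items() if v
    }
    nc = float(census.get(1, 0))
    missing_share = 0
    n_sense = code.n_sense
    for k, nk in census.items():
        if k == 1:
            continue
        if k in mean_f:
            nc += nk / mean_f[k]
        elif k == 3 and 2 in mean_f and 4 in mean_f:
            nc += nk / ((mean_f[2] + mean_f[4]) / 2)
            log.warning("no observed 3-fold family; borrowed F from 2-/4-fold")
        else:
            missing_share += k * nk
            log.warning("degeneracy class %d wholly absent; rescaling by census share", k)
    if missing_share:
        nc *= n_sense / (n_sense - missing_share)
    return min(nc, float(n_sense))


def nc_from_frequencies(
    frequencies: Mapping[str, float], code_id: int = DEFAULT_CODE_ID
) -> float:
    """Large-n Nc directly from within-family frequencies (F = sum p^2).

    Used when only published relative frequencies — not raw counts —
    are available; equals the n -> infinity limit of
    :func:`effective_number_of_codons`.
    """
    code = get_code(code_id)
    census = code.degeneracy_census()
    f_by_class: Dict[int, List[float]] = defaultdict(list)
    for aa in code.amino_acids:
        codons = code.family(aa)
        k = len(codons)
        if k == 1:
            continue
        ps = [frequencies.get(c) for c in codons]
        if any(p is None for p in ps):
            continue
        f_by_class[k].append(sum(p * p for p in ps))
    nc = float(census.get(1, 0))
    for k, nk in census.items():
        if k == 1:
            continue
        fs = f_by_class.get(k)
        if not fs:
            raise ValueError(f"no complete family of degeneracy {k} in input")
        nc += nk / (sum(fs) / len(fs))
    return min(nc, float(code.n_sense))


def usage_profile(
    cds_set: Iterable[CodingSequence | str],
    code_id: int = DEFAULT_CODE_ID,
    rare_threshold: float = DEFAULT_RARE_THRESHOLD,
    scope: str = "genome",
) -> UsageProfile:
    """Convenience pipeline: counts -> frequencies -> rare flags -> Nc."""
    table = count_codons(cds_set, code_id=code_id, scope=scope)
    profile = relative_frequencies(table)
    classify_rare(profile, rare_threshold)
    try:
        profile.nc = effective_number_of_codons(table)
    except ValueError:
        profile.nc = None
    return profile
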