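"""Pairwise protein identity, Nei–Gojobori (1986) Ka/Ks, and the
rank-based contrast of gene classes.

The NG86 estimator counts, per codon, the expected fraction of single-
nucleotide changes that are synonymous under the active genetic code
(synonymous sites), averages site counts across the two sequences,
counts synonymous/nonsynonymous differences by averaging over all
orderings of substitutions in multi-difference codons with equal
weights, and applies the Jukes–Cantor correction
d = -(3/4) ln(1 - (4/3) p) to both proportions. Changes to or from stop
codons count as nonsynonymous.

Known genes and unassigned ORFs are compared with a Mann–Whitney U test
(midranks, tie-corrected normal approximation, no continuity
correction; exact permutation p for small samples). The z sign follows
group A minus its null mean, so when group A is the known genes and
they rank lower, z is negative.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from Bio import Align
from scipy.stats import norm, rankdata

from .codes import BASES, DEFAULT_CODE_ID, get_code
from .seq_io import CodingSequence


class SaturationError(ValueError):
    """Observed proportion of differences too large for the JC correction."""


@dataclass
class KaKsRecord:
    gene: str
    gene_class: str  # known | orf
    identity: float
    ka: float
    ks: float
    aligned_codons: int

    @property
    def ratio(self) -> Optional[float]:
        """Ka/Ks; None when both are 0, inf when only Ks is 0."""
        if self.ks == 0:
            return None if self.ka == 0 else math.inf
        return self.ka / self.ks


@dataclass
class RankTestResult:
    u_statistic: float  # U of group A
    z: float
    p_two_sided: float
    n_a: int
    n_b: int
    p_exact: Optional[float] = None


# ---------------------------------------------------------------------------
# identity and alignment

def _default_aligner(protein: bool) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -2
    return aligner


def align_pair(a: str, b: str, protein: bool = True) -> Tuple[str, str]:
    """Global alignment of two sequences (match 1/mismatch -1/gap -2)."""
    aligner = _default_aligner(protein)
    alignment = aligner.align(a, b)[0]
    return str(alignment[0]), str(alignment[1])


def pairwise_identity(a: str, b: str, aligned: bool = False) -> float:
    """Fraction of identical columns among columns with residues in both."""
    if not a or not b:
        raise ValueError("empty input sequence")
    if aligned:
        if len(a) != len(b):
            raise ValueError("aligned=True requires equal-length strings")
    else:
        a, b = align_pair(a, b)
    pairs = [(x, y) for x, y in zip(a, b) if x != "-" and y != "-"]
    if not pairs:
        raise ValueError("no aligned residue columns")
    return sum(x == y for x, y in pairs) / len(pairs)


def codon_align(
    cds_a: CodingSequence, cds_b: CodingSequence
) -> Tuple[str, str]:
    """Codon-aligned nucleotides via protein alignment back-threading.

    Gap-containing codon columns are dropped pairwise, so the result is
    a pair of equal-length in-frame sequences.
    """
    pa, pb = align_pair(cds_a.protein, cds_b.protein)
    nt_a, nt_b = [], []
    ia = ib = 0
    for x, y in zip(pa, pb):
        ca = cds_a.nucleotides[3 * ia : 3 * ia + 3] if x != "-" else None
        cb = cds_b.nucleotides[3 * ib : 3 * ib + 3] if y != "-" else None
        if x != "-":
            ia += 1
        if y != "-":
            ib += 1
        if ca is not None and cb is not None:
            nt_a.append(ca)
            nt_b.append(cb)
    return "".join(nt_a), "".join(nt_b)


# ---------------------------------------------------------------------------
# NG86

def _syn_site_count(codon: str, code) -> float:
    """Expected synonymous sites of one codon: syn fraction summed per position."""
    aa = code.translate_codon(codon)
    s = 0.0
    for pos in range(3):
        syn = 0
        for b in BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1 :]
            if code.translate_codon(alt) == aa and aa != "*":
                syn += 1
        s += syn / 3.0
    return s


def _path_differences(codon_a: str, codon_b: str, code) -> Tuple[float, float]:
    """Mean (syn, nonsyn) differences over all substitution orderings."""
    diff_pos = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_pos:
        return 0.0, 0.0
    syn_tot = nonsyn_tot = 0.0
    n_paths = 0
    for order in itertools.permutations(diff_pos):
        cur = codon_a
        syn = nonsyn = 0
        for pos in order:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1 :]
            if (
                code.translate_codon(cur) == code.translate_codon(nxt)
                and code.translate_codon(cur) != "*"
            ):
                syn += 1
            else:
                nonsyn += 1
            cur = nxt
        syn_tot += syn
        nonsyn_tot += nonsyn
        n_paths += 1
    return syn_tot / n_paths, nonsyn_tot / n_paths


def jukes_cantor(p: float) -> float:
    """JC69 multiple-hit correction of a proportion of differences."""
    if p >= 0.75:
        raise SaturationError(f"proportion {p:.3f} >= 3/4; distance undefined")
    if p == 0:
        return 0.0
    return -0.75 * math.log(1 - 4.0 * p / 3.0)


@dataclass
class NG86Result:
    ka: float
    ks: float
    s_sites: float
    n_sites: float
    sd: float
    nd: float

    @property
    def ratio(self) -> Optional[float]:
        if self.ks == 0:
            return None if self.ka == 0 else math.inf
        return self.ka / self.ks


def ng86_kaks(
    nt_a: str, nt_b: str, code_id: int = DEFAULT_CODE_ID
) -> NG86Result:
    """NG86 Ka/Ks on codon-aligned, equal-length, stop-free sequences."""
    if len(nt_a) != len(nt_b) or len(nt_a) % 3 != 0:
        raise ValueError("codon-aligned equal-length sequences required")
    code = get_code(code_id)
    n_codons = len(nt_a) // 3
    if n_codons == 0:
        raise ValueError("empty alignment")
    s_a = s_b = sd = nd = 0.0
    for i in range(n_codons):
        ca = nt_a[3 * i : 3 * i + 3]
        cb = nt_b[3 * i : 3 * i + 3]
        if code.translate_codon(ca) == "*" or code.translate_codon(cb) == "*":
            raise ValueError(f"internal stop codon at codon {i}")
        s_a += _syn_site_count(ca, code)
        s_b += _syn_site_count(cb, code)
        ds, dn = _path_differences(ca, cb, code)
        sd += ds
        nd += dn
    s_sites = (s_a + s_b) / 2.0
    n_sites = 3.0 * n_codons - s_sites
    ps = sd / s_sites if s_sites > 0 else 0.0
    pn = nd / n_sites if n_sites > 0 else 0.0
    return NG86Result(
        ka=jukes_cantor(pn),
        ks=jukes_cantor(ps),
        s_sites=s_sites,
        n_sites=n_sites,
        sd=sd,
        nd=nd,
    )


def kaks_record(
    cds_a: CodingSequence,
    cds_b: CodingSequence,
    gene_class: str,
    code_id: int = DEFAULT_CODE_ID,
) -> KaKsRecord:
    """Full per-gene record: protein identity plus NG86 on the codon alignment."""
    ident = pairwise_identity(cds_a.protein, cds_b.protein)
    nt_a, nt_b = codon_align(cds_a, cds_b)
    res = ng86_kaks(nt_a, nt_b, code_id=code_id)
    return KaKsRecord(
        gene=cds_a.name,
        gene_class=gene_class,
        identity=ident,
        ka=res.ka,
        ks=res.ks,
        aligned_codons=len(nt_a) // 3,
    )


# ---------------------------------------------------------------------------
# Mann–Whitney

def mann_whitney(
    group_a: Sequence[float], group_b: Sequence[float], exact_max_n: int = 20
) -> RankTestResult:
    """Mann–Whitney U with midranks and tie-corrected normal z.

    z = (U_a - n_a n_b / 2) / sigma with the tie-corrected sigma and no
    continuity correction. For n_a + n_b <= ``exact_max_n`` the exact
    permutation two-sided p (on |U - mean|) is also computed.
    """
    if len(group_a) == 0 or len(group_b) == 0:
        raise ValueError("both groups must be non-empty")
    n_a, n_b = len(group_a), len(group_b)
    pooled = list(group_a) + list(group_b)
    ranks = rankdata(pooled)  # midranks
    r_a = float(sum(ranks[:n_a]))
    u_a = r_a - n_a * (n_a + 1) / 2.0
    mean_u = n_a * n_b / 2.0
    n = n_a + n_b
    # tie correction over tied groups of size t: subtract (t^3 - t)
    _, tie_counts = _tie_sizes(pooled)
    tie_term = sum(t**3 - t for t in tie_counts)
    var_u = n_a * n_b / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var_u <= 0:
        z = 0.0
        p = 1.0
    else:
        z = (u_a - mean_u) / math.sqrt(var_u)
        p = 2.0 * norm.sf(abs(z))
    p_exact = None
    if n <= exact_max_n:
        obs = abs(u_a - mean_u)
        count = total = 0
        idx = range(n)
        for combo in itertools.combinations(idx, n_a):
            r = float(sum(ranks[i] for i in combo))
            u = r - n_a * (n_a + 1) / 2.0
            if abs(u - mean_u) >= obs - 1e-12:
                count += 1
            total += 1
        p_exact = count / total
    return RankTestResult(
        u_statistic=u_a, z=z, p_two_sided=p, n_a=n_a, n_b=n_b, p_exact=p_exact
    )


def _tie_sizes(values: Sequence[float]) -> Tuple[List[float], List[int]]:
    uniq: Dict[float, int] = {}
    for v in values:
        uniq[v] = uniq.get(v, 0) + 1
    ties = [c for c in uniq.values() if c > 1]
    return list(uniq), ties


@dataclass
class ClassSummary:
    mean_by_class: Dict[str, float]
    n_by_class: Dict[str, int]
    n_excluded: int
    test: RankTestResult


def class_summary(records: Iterable[KaKsRecord]) -> ClassSummary:
    """Mean Ka/Ks per gene class and the known-vs-orf Mann–Whitney test.

    Records with undefined or infinite ratios are excluded and counted.
    Group A of the test is the known genes, so negative z means known
    genes have systematically lower Ka/Ks.
    """
    groups: Dict[str, List[float]] = {"known": [], "orf": []}
    excluded = 0
    for rec in records:
        r = rec.ratio
        if r is None or math.isinf(r):
            excluded += 1
            continue
        groups.setdefault(rec.gene_class, []).append(r)
    for cls in ("known", "orf"):
        if not groups[cls]:
            raise ValueError(f"no usable records in class {cls!r}")
    test = mann_whitney(groups["known"], groups["orf"])
    return ClassSummary(
        mean_by_class={c: sum(v) / len(v) for c, v in groups.items() if v},
        n_by_class={c: len(v) for c, v in groups.items() if v},
        n_excluded=excluded,
        test=test,
    )
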