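"""Synthetic genomes, coding sequences, alignments and strain sets with
machine-readable ground truth.

Every generator takes an explicit seed and returns, alongside the
sequences, a truth ledger recording exactly what was generated (feature
layout, composition targets, realized substitution counts, true tree
splits, repeat locus), so each pipeline stage has at least one recovery
test driven solely by ledgers. Defaults emulate the study system: a
linear, densely packed ~40 kb mitochondrial genome with AT-rich
composition, short intergenic spacers (0–85 bp, occasionally ~500 bp),
a large ORF carrying an imperfect 18-bp minisatellite, and cox1-like
alignments on a known tree where one clade has strongly elevated GC3.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Sequence, Tuple

import dendropy
import numpy as np

from . import refdata
from .codes import BASES, DEFAULT_CODE_ID, get_code, revcomp
from .seq_io import CodingSequence, Feature, GenomeRecord

# AT-rich mitochondrial-like default amino-acid composition (normalized
# at use); hydrophobic and AT-codable residues dominate.
DEFAULT_AA_WEIGHTS: Dict[str, float] = {
    "L": 12, "I": 9, "F": 9, "S": 8, "K": 8, "N": 7, "Y": 5, "T": 5,
    "V": 5, "G": 5, "A": 4, "E": 4, "D": 3, "Q": 3, "M": 3, "P": 3,
    "R": 2, "H": 2, "W": 2, "C": 1,
}


@dataclass
class RepeatSpec:
    host_gene: Optional[str] = None  # None = longest ORF-class gene
    unit_length: int = 18
    copies: int = 9
    # substitutions per bp per unit relative to the founder unit; kept low
    # enough that adjacent units stay above a 0.8 identity floor w.h.p.
    per_unit_sub_rate: float = 0.02


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic genome generator.

    ``genes`` is a list of (name, length_aa, gene_class, ftype); when
    None the published gene complement of the P. caudatum-like genome
    (25 known genes, 17 unassigned ORFs, 2 rRNAs, 3 tRNAs) is used.
    Codon usage and per-class composition default to the published
    P. caudatum columns.
    """

    genes: Optional[List[Tuple[str, int, str, str]]] = None
    code_id: int = DEFAULT_CODE_ID
    codon_profile: Optional[Dict[str, float]] = None  # within-family freqs
    aa_weights: Dict[str, float] = field(default_factory=lambda: dict(DEFAULT_AA_WEIGHTS))
    noncoding_base_fractions: Optional[Dict[str, float]] = None
    spacer_range: Tuple[int, int] = (0, 85)
    long_spacers: Tuple[int, ...] = (503,)
    minus_strand_fraction: float = 0.2
    repeat: Optional[RepeatSpec] = field(default_factory=RepeatSpec)
    genome_length: Optional[int] = None  # None = emergent from the layout


def _default_genes() -> List[Tuple[int, str, str, str]]:
    df = refdata.gene_divergence()
    genes = [
        (row.gene, int(row.length_aa), row.gene_class, "CDS")
        for row in df.itertuples()
    ]
    genes += [("rns", 1500, "rna", "rRNA"), ("rnl", 2800, "rna", "rRNA")]
    genes += [(f"trn{x}", 72, "rna", "tRNA") for x in ("F", "W", "Y")]
    return genes


def _sample_codon(rng, aa: str, profile: Dict[str, float], code) -> str:
    fam = code.family(aa)
    ps = np.array([max(profile.get(c, 0.0), 0.0) for c in fam])
    if ps.sum() <= 0:
        ps = np.ones(len(fam))
    ps = ps / ps.sum()
    return fam[rng.choice(len(fam), p=ps)]


def _sample_cds(
    rng, name: str, length_aa: int, profile: Dict[str, float], aa_weights, code
) -> str:
    """An in-frame gene: Met start, profile-sampled body, sampled stop."""
    aas = list(aa_weights)
    w = np.array([aa_weights[a] for a in aas], dtype=float)
    w /= w.sum()
    body = ["ATG"]
    for _ in range(length_aa - 1):
        aa = aas[rng.choice(len(aas), p=w)]
        body.append(_sample_codon(rng, aa, profile, code))
    body.append(_sample_codon(rng, "*", profile, code))
    return "".join(body)


def _sample_noncoding(rng, length: int, base_fractions: Dict[str, float]) -> str:
    if length == 0:
        return ""
    bases = list("GATC")
    p = np.array([base_fractions[b] for b in bases])
    p = p / p.sum()
    return "".join(bases[i] for i in rng.choice(4, size=length, p=p))


def _build_repeat_array(
    rng, spec: RepeatSpec, profile: Dict[str, float], aa_weights, code
) -> Tuple[str, str]:
    """(array nucleotides, consensus unit); in-frame and stop-free."""
    n_codons = spec.unit_length // 3
    if spec.unit_length % 3 != 0:
        raise ValueError("repeat unit length must be a codon multiple here")
    aas = list(aa_weights)
    w = np.array([aa_weights[a] for a in aas], dtype=float)
    w /= w.sum()
    unit = "".join(
        _sample_codon(rng, aas[rng.choice(len(aas), p=w)], profile, code)
        for _ in range(n_codons)
    )
    units = []
    for _ in range(spec.copies):
        u = list(unit)
        n_subs = rng.binomial(spec.unit_length, spec.per_unit_sub_rate)
        for _ in range(n_subs):
            pos = int(rng.integers(spec.unit_length))
            alt = BASES[int(rng.integers(4))]
            old = u[pos]
            u[pos] = alt
            codon_i = pos // 3
            codon = "".join(u[3 * codon_i : 3 * codon_i + 3])
            if codon in code.stop_codons:
                u[pos] = old  # never introduce a nonsense codon
        units.append("".join(u))
    return "".join(units), unit


def simulate_genome(
    spec: Optional[SyntheticSpec] = None, seed: int = 0
) -> Tuple[GenomeRecord, Dict]:
    """Generate a linear genome and its ground-truth ledger.

    Genes are laid end to end separated by spacers sampled from the
    noncoding composition; one designated ORF carries the minisatellite
    array at its codon midpoint. The ledger records every feature, the
    per-class composition targets, the emitted per-gene codon counts
    and the exact repeat locus.
    """
    spec = spec or SyntheticSpec()
    rng = np.random.default_rng(seed)
    code = get_code(spec.code_id)
    profile = spec.codon_profile or refdata.codon_frequencies("P_caudatum")
    noncoding = spec.noncoding_base_fractions or refdata.region_composition_fractions(
        "P_caudatum", "noncoding"
    )
    genes = spec.genes or _default_genes()

    # choose repeat host
    host = None
    if spec.repeat is not None:
        if spec.repeat.host_gene is not None:
            host = spec.repeat.host_gene
        else:
            orfs = [g for g in genes if g[2] == "orf"]
            host = max(orfs, key=lambda g: g[1])[0] if orfs else None

    long_spacer_slots: Dict[int, int] = {}
    if spec.long_spacers and len(genes) > 2:
        slots = rng.choice(len(genes) - 1, size=len(spec.long_spacers), replace=False)
        long_spacer_slots = {int(s): spec.long_spacers[i] for i, s in enumerate(np.atleast_1d(slots))}

    chunks: List[str] = []
    features: List[Feature] = []
    ledger_genes = []
    repeat_truth = None
    cursor = 0
    lo, hi = spec.spacer_range
    for gi, (name, length_aa, gene_class, ftype) in enumerate(genes):
        is_host = host is not None and name == host and ftype == "CDS"
        if ftype == "CDS":
            body_aa = length_aa
            if is_host:
                # the repeat array counts toward the host ORF's length
                body_aa = max(length_aa - (spec.repeat.unit_length * spec.repeat.copies) // 3,
                              2 * spec.repeat.copies)
            nt = _sample_cds(rng, name, body_aa, profile, spec.aa_weights, code)
        else:
            nt = _sample_noncoding(rng, length_aa if ftype != "tRNA" else length_aa,
                                   refdata.region_composition_fractions("P_caudatum", "rRNA"))
        if is_host:
            array, unit = _build_repeat_array(rng, spec.repeat, profile, spec.aa_weights, code)
            mid_codon = (len(nt) // 3) // 2
            insert_at = 3 * mid_codon
            nt = nt[:insert_at] + array + nt[insert_at:]
            repeat_truth = {
                "gene": name,
                "unit_length": spec.repeat.unit_length,
                "copies": spec.repeat.copies,
                "unit": unit,
                "offset_in_gene": insert_at,
            }
        strand = "-" if rng.random() < spec.minus_strand_fraction else "+"
        genome_nt = revcomp(nt) if strand == "-" else nt
        start, end = cursor, cursor + len(genome_nt)
        features.append(
            Feature(name=name, ftype=ftype, start=start, end=end, strand=strand,
                    gene_class=gene_class)
        )
        ledger_genes.append(
            {"name": name, "ftype": ftype, "gene_class": gene_class,
             "start": start, "end": end, "strand": strand, "length_nt": len(genome_nt)}
        )
        if repeat_truth is not None and repeat_truth["gene"] == name and "start" not in repeat_truth:
            off = repeat_truth["offset_in_gene"]
            array_len = spec.repeat.unit_length * spec.repeat.copies
            if strand == "+":
                repeat_truth["start"] = start + off
            else:
                repeat_truth["start"] = end - off - array_len
            repeat_truth["end"] = repeat_truth["start"] + array_len
        chunks.append(genome_nt)
        cursor = end
        if gi < len(genes) - 1:
            sp_len = long_spacer_slots.get(gi, int(rng.integers(lo, hi + 1)))
            sp = _sample_noncoding(rng, sp_len, noncoding)
            chunks.append(sp)
            cursor += sp_len

    sequence = "".join(chunks)
    if spec.genome_length is not None:
        if len(sequence) > spec.genome_length:
            raise ValueError(
                f"layout needs {len(sequence)} bp > genome_length {spec.genome_length}"
            )
        pad = spec.genome_length - len(sequence)
        sequence += _sample_noncoding(rng, pad, noncoding)

    record = GenomeRecord(
        id=f"synthetic_{seed}", sequence=sequence, topology="linear", features=features
    )
    coding_bp = sum(g["length_nt"] for g in ledger_genes)
    protein_bp = sum(g["length_nt"] for g in ledger_genes if g["ftype"] == "CDS")
    truth = {
        "seed": seed,
        "genes": ledger_genes,
        "total_bp": len(sequence),
        "coding_bp": coding_bp,
        "protein_coding_bp": protein_bp,
        "spacer_lengths": sorted(
            [len(sequence) - cursor] * 0  # no terminal spacer unless padded
            + [len(c) for c in chunks[1::2]]
            + ([spec.genome_length - cursor] if spec.genome_length else [])
        ),
        "noncoding_fractions": noncoding,
        "codon_profile": profile,
        "repeat": repeat_truth,
        "code_id": spec.code_id,
    }
    return record, truth


# ---------------------------------------------------------------------------
# pairwise codon evolution

def evolve_pair(
    cds: str,
    t_syn: float,
    omega: float,
    code_id: int = DEFAULT_CODE_ID,
    seed: int = 0,
) -> Tuple[str, str, Dict]:
    """Evolve two lineages from an ancestral CDS under an ω filter.

    Mutation attempts are uniform over positions and alternative bases;
    an attempt is rejected if it creates a stop codon, accepted with
    probability 1 if synonymous and ω if nonsynonymous. The attempt
    count per lineage is Poisson(3·C·t_syn/2), which makes the expected
    accepted synonymous substitutions per synonymous site equal t_syn
    between the two tips. The ledger records realized counts.
    """
    if omega < 0:
        raise ValueError("omega must be >= 0")
    if len(cds) % 3 != 0:
        raise ValueError("in-frame CDS required")
    code = get_code(code_id)
    rng = np.random.default_rng(seed)
    n_codons = len(cds) // 3
    realized = {"syn": 0, "nonsyn": 0, "attempts": 0}

    def one_lineage(seq: List[str]) -> List[str]:
        attempts = rng.poisson(3.0 * n_codons * t_syn / 2.0)
        for _ in range(attempts):
            realized["attempts"] += 1
            pos = int(rng.integers(len(seq)))
            others = [b for b in BASES if b != seq[pos]]
            alt = others[int(rng.integers(3))]
            ci = pos // 3
            old_codon = "".join(seq[3 * ci : 3 * ci + 3])
            new_codon = old_codon[: pos % 3] + alt + old_codon[pos % 3 + 1 :]
            if new_codon in code.stop_codons or old_codon in code.stop_codons:
                continue
            syn = code.translate_codon(new_codon) == code.translate_codon(old_codon)
            if syn or rng.random() < omega:
                seq[pos] = alt
                realized["syn" if syn else "nonsyn"] += 1
        return seq

    a = one_lineage(list(cds.upper()))
    b = one_lineage(list(cds.upper()))
    return "".join(a), "".join(b), dict(realized, omega=omega, t_syn=t_syn)


# ---------------------------------------------------------------------------
# alignments on a known tree

def _draw_base(rng, pi: Dict[str, float], exclude: Optional[str] = None) -> str:
    bases = [b for b in BASES if b != exclude]
    p = np.array([pi[b] for b in bases])
    p = p / p.sum()
    return bases[rng.choice(len(bases), p=p)]


def simulate_alignment(
    tree_newick: str,
    n_codons: int = 300,
    seed: int = 0,
    branch_sub_prob: Optional[float] = None,
    background_gc3: float = 10.0,
    high_clade: Sequence[str] = (),
    clade_gc3: float = 48.0,
    code_id: int = DEFAULT_CODE_ID,
) -> Tuple[List[Tuple[str, str]], Dict]:
    """Evolve a cox1-like in-frame alignment on a known tree (JC sites).

    Sites evolve independently; per edge of length t the substitution
    probability is 3/4·(1−e^{−4t/3}). Third codon positions inside the
    ``high_clade`` subtree (stem edge included) draw replacement bases
    from a GC-biased equilibrium targeting ``clade_gc3`` percent, and
    on the stem edge third positions are redrawn from that equilibrium
    outright — the compositional shift. The ledger stores the true
    splits, the clade and the targets.
    """
    rng = np.random.default_rng(seed)
    code = get_code(code_id)
    tree = dendropy.Tree.get(
        data=tree_newick, schema="newick", preserve_underscores=True
    )
    taxa = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    high = set(high_clade)
    if high - set(taxa):
        raise ValueError(f"high_clade taxa not in tree: {sorted(high - set(taxa))}")
    if not 0 <= clade_gc3 <= 100 or not 0 <= background_gc3 <= 100:
        raise ValueError("GC3 targets must be percentages in [0, 100]")

    def pi3(gc: float) -> Dict[str, float]:
        g = gc / 100.0
        return {"G": g / 2, "C": g / 2, "A": (1 - g) / 2, "T": (1 - g) / 2}

    pi_bg3 = pi3(background_gc3)
    pi_high3 = pi3(clade_gc3)
    pi12 = {"A": 0.35, "T": 0.35, "G": 0.15, "C": 0.15}

    # root codons, stop-free under the active code
    def root_codon() -> str:
        while True:
            c = (
                _draw_base(rng, pi12)
                + _draw_base(rng, pi12)
                + _draw_base(rng, pi3(background_gc3))
            )
            if c not in code.stop_codons:
                return c

    root_seq = "".join(root_codon() for _ in range(n_codons))

    def in_high_subtree(node) -> bool:
        leaves = {l.taxon.label for l in node.leaf_iter()}
        return bool(high) and leaves <= high

    def is_stem(node) -> bool:
        leaves = {l.taxon.label for l in node.leaf_iter()}
        return bool(high) and leaves == high

    out: List[Tuple[str, str]] = []

    def evolve_edge(seq: str, node) -> str:
        t = node.edge.length or 0.0
        p_sub = 0.75 * (1.0 - math.exp(-4.0 * t / 3.0)) if branch_sub_prob is None else branch_sub_prob
        biased = in_high_subtree(node)
        chars = list(seq)
        for i in range(len(chars)):
            third = i % 3 == 2
            if rng.random() < p_sub:
                if third and biased:
                    chars[i] = _draw_base(rng, pi_high3, exclude=chars[i])
                elif third:
                    chars[i] = _draw_base(rng, pi_bg3, exclude=chars[i])
                else:
                    chars[i] = _draw_base(rng, pi12, exclude=chars[i])
        if is_stem(node):
            for i in range(2, len(chars), 3):
                chars[i] = _draw_base(rng, pi_high3)
        return "".join(chars)

    def walk(node, seq: str):
        for child in node.child_nodes():
            child_seq = evolve_edge(seq, child)
            if child.is_leaf():
                out.append((child.taxon.label, child_seq))
            else:
                walk(child, child_seq)

    walk(tree.seed_node, root_seq)
    out.sort(key=lambda r: taxa.index(r[0]))

    splits: List[FrozenSet[str]] = []
    all_taxa = frozenset(taxa)
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node is tree.seed_node:
            continue
        side = frozenset(l.taxon.label for l in node.leaf_iter())
        if 1 < len(side) < len(all_taxa) - 1:
            splits.append(min(side, all_taxa - side, key=lambda s: sorted(s)))
    truth = {
        "seed": seed,
        "taxa": taxa,
        "true_splits": splits,
        "high_clade": sorted(high),
        "clade_gc3": clade_gc3,
        "background_gc3": background_gc3,
        "n_codons": n_codons,
    }
    return out, truth


# ---------------------------------------------------------------------------
# strain sets for the minisatellite locus

def simulate_repeat_strains(
    copy_numbers: Optional[Dict[str, int]] = None,
    unit_length: int = 18,
    flank_length: int = 300,
    per_unit_sub_rate: float = 0.02,
    seed: int = 0,
) -> Tuple[Dict[str, str], Dict]:
    """Strain sequences sharing flanks but differing in repeat copy number.

    Defaults reproduce the published strain panel of the ymf64 locus
    (copy numbers a:18, b:11, c:11, d:9, e:9, f:14, g:10).
    """
    copy_numbers = copy_numbers or dict(refdata.STRAIN_REPEAT_COPIES)
    rng = np.random.default_rng(seed)
    code = get_code(DEFAULT_CODE_ID)
    profile = refdata.codon_frequencies("P_caudatum")
    left = _sample_cds(rng, "flank_l", flank_length // 3, profile, DEFAULT_AA_WEIGHTS, code)
    right = _sample_cds(rng, "flank_r", flank_length // 3, profile, DEFAULT_AA_WEIGHTS, code)
    strains: Dict[str, str] = {}
    truth: Dict = {"copy_numbers": dict(copy_numbers), "unit_length": unit_length}
    for strain in sorted(copy_numbers):
        spec = RepeatSpec(
            unit_length=unit_length,
            copies=copy_numbers[strain],
            per_unit_sub_rate=per_unit_sub_rate,
        )
        array, _ = _build_repeat_array(rng, spec, profile, DEFAULT_AA_WEIGHTS, code)
        strains[strain] = left + array + right
    truth["flank_length"] = flank_length
    return strains, truth
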