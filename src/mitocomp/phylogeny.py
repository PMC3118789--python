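"""Distance-based phylogenetics: K2P distances, Saitou–Nei neighbor
joining, bootstrap support, per-taxon positional GC, and placement of a
compositional (GC3) shift on the tree.

The tree container is deliberately minimal: an unrooted tree stored as
a child-list rooted at an arbitrary internal node, with branch lengths
and per-edge bootstrap support. Internal edges are identified by their
leaf bipartitions, which is all that support values and shift placement
need. Newick export labels internal nodes with support percentages.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Sequence, Tuple

import numpy as np

from .composition import PositionalGC

log = logging.getLogger(__name__)

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")


class SaturationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# distances

def k2p_distance(seq_a: str, seq_b: str) -> float:
    """Kimura two-parameter distance with pairwise deletion of gap/N sites.

    d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q), with P and Q the
    transition and transversion proportions over comparable sites.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError("aligned equal-length sequences required")
    n = ts = tv = 0
    for x, y in zip(seq_a.upper(), seq_b.upper()):
        if x not in "ACGT" or y not in "ACGT":
            continue
        n += 1
        if x == y:
            continue
        same_class = (x in PURINES) == (y in PURINES)
        if same_class:
            ts += 1
        else:
            tv += 1
    if n == 0:
        raise ValueError("no comparable sites")
    p, q = ts / n, tv / n
    w1 = 1 - 2 * p - q
    w2 = 1 - 2 * q
    if w1 <= 0 or w2 <= 0:
        raise SaturationError("K2P log argument <= 0; sequences saturated")
    return -0.5 * math.log(w1) - 0.25 * math.log(w2)


def p_distance(seq_a: str, seq_b: str) -> float:
    if len(seq_a) != len(seq_b):
        raise ValueError("aligned equal-length sequences required")
    pairs = [
        (x, y)
        for x, y in zip(seq_a.upper(), seq_b.upper())
        if x in "ACGT" and y in "ACGT"
    ]
    if not pairs:
        raise ValueError("no comparable sites")
    return sum(x != y for x, y in pairs) / len(pairs)


def jc_distance(seq_a: str, seq_b: str) -> float:
    p = p_distance(seq_a, seq_b)
    if p >= 0.75:
        raise SaturationError("JC log argument <= 0; sequences saturated")
    return -0.75 * math.log(1 - 4 * p / 3)


DISTANCE_MODELS = {"k2p": k2p_distance, "jc": jc_distance, "p": p_distance}


@dataclass
class DistanceMatrix:
    taxa: List[str]
    d: np.ndarray

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.taxa)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match taxa")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.d), 0):
            raise ValueError("distance matrix diagonal must be zero")

    @classmethod
    def from_alignment(
        cls, alignment: Sequence[Tuple[str, str]], model: str = "k2p"
    ) -> "DistanceMatrix":
        dist = DISTANCE_MODELS[model]
        taxa = [t for t, _ in alignment]
        seqs = [s for _, s in alignment]
        n = len(taxa)
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                d[i, j] = d[j, i] = dist(seqs[i], seqs[j])
        return cls(taxa=taxa, d=d)


# ---------------------------------------------------------------------------
# trees

@dataclass
class TreeNode:
    name: Optional[str] = None  # leaf label
    length: float = 0.0  # branch to parent
    support: Optional[float] = None  # percent, internal edges only
    children: List["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> List[str]:
        if self.is_leaf:
            return [self.name]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out


@dataclass
class PhyloTree:
    root: TreeNode
    taxa: List[str]
    clamped_deficit: float = 0.0  # total negative NJ length clamped to 0

    def bipartitions(self) -> Dict[FrozenSet[str], TreeNode]:
        """Non-trivial leaf bipartitions, keyed by the child-side leaf set."""
        all_taxa = frozenset(self.taxa)
        out: Dict[FrozenSet[str], TreeNode] = {}

        def walk(node: TreeNode):
            for child in node.children:
                side = frozenset(child.leaves())
                if 1 < len(side) < len(all_taxa) - 1:
                    out[side] = child
                walk(child)

        walk(self.root)
        return out

    def canonical_splits(self) -> set:
        """Orientation-free bipartitions (min side by sorted labels)."""
        all_taxa = frozenset(self.taxa)
        splits = set()
        for side in self.bipartitions():
            other = all_taxa - side
            splits.add(min(side, other, key=lambda s: sorted(s)))
        return splits

    def to_newick(self, support: bool = True) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_leaf:
                return f"{node.name}:{node.length:.6f}"
            inner = ",".join(fmt(c) for c in node.children)
            label = (
                f"{node.support:.0f}" if support and node.support is not None else ""
            )
            return f"({inner}){label}:{node.length:.6f}"

        inner = ",".join(fmt(c) for c in self.root.children)
        return f"({inner});"


def neighbor_joining(matrix: DistanceMatrix) -> PhyloTree:
    """Saitou–Nei NJ with the Q-criterion and deterministic tie-breaking.

    Ties in Q are broken by the lowest (i, j) index pair. Negative
    branch lengths are clamped to zero with the total deficit recorded
    on the tree. The root is the final three-way (or n=2 two-way) join;
    the tree is to be read as unrooted.
    """
    n = len(matrix.taxa)
    if n < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")
    nodes: List[TreeNode] = [TreeNode(name=t) for t in matrix.taxa]
    d = matrix.d.astype(float).copy()
    active = list(range(n))
    deficit = 0.0

    def clamp(x: float) -> float:
        nonlocal deficit
        if x < 0:
            deficit += -x
            return 0.0
        return x

    while len(active) > 3:
        m = len(active)
        r = {i: sum(d[i, j] for j in active if j != i) for i in active}
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * d[i, j] - r[i] - r[j]
                key = (q, i, j)
                if best is None or key < best:
                    best = key
        _, i, j = best
        li = d[i, j] / 2.0 + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = d[i, j] - li
        parent = TreeNode()
        nodes[i].length = clamp(li)
        nodes[j].length = clamp(lj)
        parent.children = [nodes[i], nodes[j]]
        # new distances
        new_row = np.zeros(d.shape[0] + 1)
        d = np.pad(d, ((0, 1), (0, 1)))
        k = d.shape[0] - 1
        for x in active:
            if x in (i, j):
                continue
            d[k, x] = d[x, k] = (d[i, x] + d[j, x] - d[i, j]) / 2.0
        nodes.append(parent)
        active = [x for x in active if x not in (i, j)] + [k]

    # final three-way join: v_a = (d_ab + d_ac - d_bc) / 2 etc.
    a, b, c = active
    root = TreeNode()
    nodes[a].length = clamp((d[a, b] + d[a, c] - d[b, c]) / 2.0)
    nodes[b].length = clamp((d[a, b] + d[b, c] - d[a, c]) / 2.0)
    nodes[c].length = clamp((d[a, c] + d[b, c] - d[a, b]) / 2.0)
    root.children = [nodes[a], nodes[b], nodes[c]]
    return PhyloTree(root=root, taxa=list(matrix.taxa), clamped_deficit=deficit)


def bootstrap_nj(
    alignment: Sequence[Tuple[str, str]],
    n_reps: int = 2000,
    seed: int = 0,
    model: str = "k2p",
) -> PhyloTree:
    """NJ tree of the full data, with bootstrap support on internal edges.

    Alignment columns are resampled with replacement ``n_reps`` times;
    support is the percentage of replicates whose NJ tree contains each
    internal bipartition of the full-data tree. Replicates whose
    distances saturate are skipped (counted against the denominator of
    successfully computed replicates).
    """
    if len(alignment) < 4:
        raise ValueError("bootstrap requires at least 4 taxa")
    length = len(alignment[0][1])
    if any(len(s) != length for _, s in alignment):
        raise ValueError("alignment rows differ in length")
    if length < 1:
        raise ValueError("alignment has no columns")
    tree = neighbor_joining(DistanceMatrix.from_alignment(alignment, model=model))
    splits = tree.bipartitions()
    if not splits:
        log.warning("full-data tree has no resolved internal bipartitions")
    counts = {side: 0 for side in tree.canonical_splits()}
    rng = np.random.default_rng(seed)
    taxa = [t for t, _ in alignment]
    cols = np.array([list(s) for _, s in alignment])  # taxa x sites
    done = 0
    for _ in range(n_reps):
        idx = rng.integers(0, length, size=length)
        rep_aln = [(t, "".join(cols[i, idx])) for i, t in enumerate(taxa)]
        try:
            rep_tree = neighbor_joining(
                DistanceMatrix.from_alignment(rep_aln, model=model)
            )
        except (SaturationError, ValueError):
            continue
        done += 1
        rep_splits = rep_tree.canonical_splits()
        for side in counts:
            if side in rep_splits:
                counts[side] += 1
    all_taxa = frozenset(taxa)
    for side, node in splits.items():
        canon = min(side, all_taxa - side, key=lambda s: sorted(s))
        node.support = 100.0 * counts[canon] / done if done else 0.0
    return tree


# ---------------------------------------------------------------------------
# GC3 shift

def gc3_by_taxon(
    cds_alignment: Sequence[Tuple[str, str]]
) -> Dict[str, PositionalGC]:
    """Per-taxon GC at codon positions 1/2/3, skipping gap/N codons."""
    out: Dict[str, PositionalGC] = {}
    for taxon, seq in cds_alignment:
        seq = seq.upper()
        if len(seq) % 3 != 0:
            raise ValueError(f"{taxon}: alignment length not a multiple of 3")
        gc = [0, 0, 0]
        total = 0
        for i in range(0, len(seq), 3):
            codon = seq[i : i + 3]
            if any(b not in "ACGT" for b in codon):
                continue
            total += 1
            for p in range(3):
                if codon[p] in "GC":
                    gc[p] += 1
        if total == 0:
            raise ValueError(f"{taxon}: no scorable codons")
        out[taxon] = PositionalGC(
            gc1=100.0 * gc[0] / total,
            gc2=100.0 * gc[1] / total,
            gc3=100.0 * gc[2] / total,
            n_codons=total,
        )
    return out


@dataclass
class ShiftPlacement:
    high_taxa: FrozenSet[str]
    monophyletic: bool
    edge: Optional[FrozenSet[str]] = None  # leaf set on one side of the edge


def place_shift(
    tree: PhyloTree, gc3: Dict[str, float], cut: float
) -> ShiftPlacement:
    """Locate the edge separating high-GC3 taxa from the rest.

    Taxa with gc3 >= cut form the high set. If that set is exactly one
    side of a single tree edge (including the trivial pendant edge of a
    one-taxon set), that edge is the placement; otherwise the high set
    is flagged non-monophyletic.
    """
    if not (0 < cut < 100):
        raise ValueError("cut must be inside (0, 100)")
    missing = [t for t in tree.taxa if t not in gc3]
    if missing:
        raise ValueError(f"taxa without gc3 values: {missing}")
    high = frozenset(t for t in tree.taxa if gc3[t] >= cut)
    all_taxa = frozenset(tree.taxa)
    if not high or high == all_taxa:
        return ShiftPlacement(high_taxa=high, monophyletic=False)
    if len(high) == 1 or len(high) == len(all_taxa) - 1:
        # pendant edge: always a valid split
        return ShiftPlacement(high_taxa=high, monophyletic=True, edge=high)
    canon = min(high, all_taxa - high, key=lambda s: sorted(s))
    if canon in tree.canonical_splits():
        return ShiftPlacement(high_taxa=high, monophyletic=True, edge=high)
    return ShiftPlacement(high_taxa=high, monophyletic=False)
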