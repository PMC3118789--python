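"""Independent reference implementations used only by the test suite.

Each oracle re-derives a quantity from first principles by a different
route than the library (direct enumeration, closed forms, third-party
translation tables), so agreement is evidence rather than tautology.
"""

from __future__ import annotations

from itertools import accumulate
from typing import Dict, List, Tuple

from Bio.Seq import Seq


def sixframe_orfs_bruteforce(sequence: str, code_id: int, min_aa: int):
    """All stop-to-stop ORFs by translating every frame with Biopython
    and splitting on '*'. Returns a set of (start, end, strand)."""
    out = set()
    n = len(sequence)
    for strand, seq in (("+", sequence), ("-", str(Seq(sequence).reverse_complement()))):
        for frame in range(3):
            sub = seq[frame : frame + 3 * ((n - frame) // 3)]
            aa = str(Seq(sub).translate(table=code_id))
            pos = 0
            for chunk in aa.split("*"):
                if len(chunk) >= min_aa:
                    s = frame + 3 * pos
                    e = s + 3 * len(chunk)
                    if strand == "-":
                        s, e = n - e, n - s
                    out.add((s, e, strand))
                pos += len(chunk) + 1
    return out


def tandem_calls_bruteforce(
    seq: str,
    min_unit: int = 6,
    max_unit: int = 100,
    min_copies: int = 3,
    min_identity: float = 0.8,
) -> List[Tuple[int, int, int, float]]:
    """All-(period, offset) tandem-array scan, no seeding heuristics.

    For every period, every offset is tested for a maximal run of
    adjacent units with Hamming identity >= min_identity; runs below
    min_copies are dropped, calls are reduced to the primitive period
    of their consensus, sub-range primitives are discarded, and
    overlapping calls are resolved by longest span then smallest unit.
    Returns (start, end, unit_length, copy_number) tuples sorted by
    start.
    """
    n = len(seq)
    raw = []
    for d in range(min_unit, min(max_unit, n // 2) + 1):
        eq = [1 if seq[i] == seq[i + d] else 0 for i in range(n - d)]
        csum = [0] + list(accumulate(eq))

        def jid(p):
            return (csum[p + d] - csum[p]) / d

        starts_done = set()
        runs = []
        for p in range(0, n - 2 * d + 1):
            if jid(p) < min_identity:
                continue
            start = p
            while start - d >= 0 and jid(start - d) >= min_identity:
                start -= d
            if start in starts_done:
                continue
            starts_done.add(start)
            k = 0
            while start + (k + 2) * d <= n and jid(start + k * d) >= min_identity:
                k += 1
            copies = k + 1
            if copies < min_copies:
                continue
            end = start + copies * d
            units = [seq[start + i * d : start + (i + 1) * d] for i in range(copies)]
            # trim boundary units dissimilar to the consensus (phantom
            # flank units of shifted phases)
            cons = consensus(units)

            def to_cons(u):
                return sum(a == b for a, b in zip(u, cons)) / d

            while units and to_cons(units[0]) < min_identity:
                units.pop(0)
                start += d
            while units and to_cons(units[-1]) < min_identity:
                units.pop()
                end -= d
            copies = len(units)
            if copies < min_copies:
                continue
            cons = consensus(units)
            tail = 0
            while end + tail < n and tail < d and eq[end - d + tail]:
                tail += 1
            mean_ident = sum(jid(start + i * d) for i in range(copies - 1)) / (copies - 1)
            runs.append((start, end + tail, d, copies + tail / d, cons, mean_ident))
        # best phase among overlapping same-period runs: alignment score
        # (junction matches minus mismatches, plus tail), span, leftmost
        runs.sort(key=lambda r: (-_score(r), -(r[1] - r[0]), r[0]))
        kept = []
        for r in runs:
            if any(r[0] < o[1] and o[0] < r[1] for o in kept):
                continue
            kept.append(r)
        raw.extend((s, e, d2, cp, cons) for s, e, d2, cp, cons, _ in kept)

    # primitive-period reduction (identity recomputed at the new period,
    # with the same boundary trimming as the primary scan)
    reduced = []
    for start, end, d, copies, cons in raw:
        p = primitive_period(cons, min_identity)
        if p < d:
            d2 = p
            full = int((end - start) // d2)
            frac_tail = (end - start) - full * d2
            units = [seq[start + i * d2 : start + (i + 1) * d2] for i in range(full)]
            cons2 = consensus(units) if units else cons[:d2]

            def to_cons2(u):
                return sum(a == b for a, b in zip(u, cons2)) / d2

            while units and to_cons2(units[0]) < min_identity:
                units.pop(0)
                start += d2
            while units and to_cons2(units[-1]) < min_identity:
                units.pop()
                frac_tail = 0
            end = start + len(units) * d2 + frac_tail
            idents = [
                sum(a == b for a, b in zip(u, v)) / d2
                for u, v in zip(units, units[1:])
            ]
            ident = sum(idents) / len(idents) if idents else 1.0
            reduced.append((start, end, d2, len(units) + frac_tail / d2, ident))
        else:
            units = [
                seq[start + i * d : start + (i + 1) * d]
                for i in range(int((end - start) // d))
            ]
            idents = [
                sum(a == b for a, b in zip(u, v)) / d
                for u, v in zip(units, units[1:])
            ]
            ident = sum(idents) / len(idents) if idents else 1.0
            reduced.append((start, end, d, copies, ident))
    reduced = [c for c in reduced if c[2] >= min_unit and c[3] >= min_copies]
    # stage 1: same-unit-length overlaps -> best identity, span, leftmost
    by_unit = {}
    for c in reduced:
        by_unit.setdefault(c[2], []).append(c)
    stage1 = []
    for group in by_unit.values():
        group.sort(key=lambda c: (-_score(c), -(c[1] - c[0]), c[0]))
        kept = []
        for c in group:
            if any(c[0] < o[1] and o[0] < c[1] for o in kept):
                continue
            kept.append(c)
        stage1.extend(kept)
    # stage 2: across unit lengths -> longest span, smallest unit, leftmost
    stage1.sort(key=lambda c: (-(c[1] - c[0]), c[2], c[0]))
    chosen = []
    for c in stage1:
        if any(c[0] < o[1] and o[0] < c[1] for o in chosen):
            continue
        chosen.append(c)
    return sorted((s, e, d, cp) for s, e, d, cp, _ in chosen)



def _score(run):
    """(start, end, d, copies, [cons,] ident) -> junction match-mismatch
    score over full units; tails carry no support."""
    start, end, d = run[0], run[1], run[2]
    ident = run[-1]
    full = int((end - start) // d)
    return max(full - 1, 0) * d * (2 * ident - 1)


def consensus(units):
    out = []
    for col in zip(*units):
        counts = {}
        for ch in col:
            counts[ch] = counts.get(ch, 0) + 1
        out.append(sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[0][0])
    return "".join(out)


def primitive_period(unit: str, min_identity: float = 1.0) -> int:
    d = len(unit)
    for p in range(1, d):
        if d % p != 0:
            continue
        if sum(unit[i] == unit[i + p] for i in range(d - p)) / (d - p) >= min_identity:
            return p
    return d


def nc_from_frequencies_oracle(freqs: Dict[str, float], families: Dict[str, tuple]) -> float:
    """Straight-line Wright Nc from frequencies: per-class mean of
    F = sum p^2, summed as N_k / F_bar_k with singleton families direct."""
    by_k: Dict[int, List[float]] = {}
    singles = 0
    for aa, codons in families.items():
        if aa == "*":
            continue
        k = len(codons)
        if k == 1:
            singles += 1
            continue
        f = sum(freqs[c] ** 2 for c in codons)
        by_k.setdefault(k, []).append(f)
    nc = float(singles)
    for k, fs in by_k.items():
        nc += len(fs) / (sum(fs) / len(fs)) * 1.0
    return nc


def patristic_distances(tree) -> Dict[frozenset, float]:
    """Leaf-pair path lengths of a mitocomp PhyloTree (for NJ exactness)."""
    dists: Dict[frozenset, float] = {}

    def walk(node):
        # returns {leaf: distance to this node}
        if node.is_leaf:
            return {node.name: 0.0}
        below = []
        for child in node.children:
            sub = walk(child)
            sub = {k: v + child.length for k, v in sub.items()}
            below.append(sub)
        for i in range(len(below)):
            for j in range(i + 1, len(below)):
                for a, da in below[i].items():
                    for b, db in below[j].items():
                        dists[frozenset((a, b))] = da + db
        merged = {}
        for sub in below:
            merged.update(sub)
        return merged

    walk(tree.root)
    return dists
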