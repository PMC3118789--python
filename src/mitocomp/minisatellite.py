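"""Intragenic tandem-repeat (minisatellite) detection.

A tandem array of period d starting at p is a run of units
s[p:p+d], s[p+d:p+2d], ... in which every adjacent pair of units has
ungapped (Hamming) identity of at least ``min_identity``. Detection is
seed-and-extend: exact matches between positions i and i+d seed
candidate arrays, which are extended unit-by-unit in both directions;
each call is reduced to its primitive (smallest) period and overlapping
calls are merged. Units whose length is a multiple of three leave the
reading frame of the host gene intact however many copies are present —
the property that makes an intragenic minisatellite tolerable under
purifying selection.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np


@dataclass
class RepeatCall:
    start: int
    end: int
    unit_length: int
    copy_number: float  # fractional tail copies allowed
    consensus: str
    mean_identity: float  # mean adjacent-unit identity over full units

    @property
    def frame_preserving(self) -> bool:
        return self.unit_length % 3 == 0

    @property
    def span(self) -> int:
        return self.end - self.start

    @property
    def score(self) -> float:
        """Alignment-style support over full-unit junctions: matches
        minus mismatches. Separates the true phase of an array from
        boundary-extended or truncated phase shifts; the fractional
        tail carries no support (a shifted phase ending inside the
        array would otherwise collect guaranteed tail matches)."""
        full = int(self.span // self.unit_length)
        junctions = max(full - 1, 0)
        return junctions * self.unit_length * (2 * self.mean_identity - 1)


def frame_preserving(call: RepeatCall) -> bool:
    """True iff copy-number variation cannot shift the host reading frame."""
    return call.unit_length % 3 == 0


def _junction_identity(eq_csum: np.ndarray, p: int, d: int) -> float:
    """Identity between units at p and p+d from the prefix-summed eq array."""
    return (eq_csum[p + d] - eq_csum[p]) / d


def _full_unit_run(eq_csum: np.ndarray, n: int, p: int, d: int, min_identity: float) -> int:
    """Number of consecutive valid junctions starting at offset p."""
    k = 0
    while p + (k + 2) * d <= n and _junction_identity(eq_csum, p + k * d, d) >= min_identity:
        k += 1
    return k


def _consensus(units: Sequence[str]) -> str:
    cols = zip(*units)
    out = []
    for col in cols:
        vals, counts = np.unique(list(col), return_counts=True)
        out.append(sorted(zip(-counts, vals))[0][1])
    return "".join(out)


def _primitive_period(unit: str, min_identity: float = 1.0) -> int:
    """Smallest divisor p of len(unit) at which the unit is (approximately)
    periodic: self-shift identity at lag p >= min_identity. With the
    default 1.0 this is exact string primitivity."""
    d = len(unit)
    for p in range(1, d):
        if d % p != 0:
            continue
        matches = sum(unit[i] == unit[i + p] for i in range(d - p))
        if matches / (d - p) >= min_identity:
            return p
    return d


def find_tandem_repeats(
    sequence: str,
    min_unit: int = 6,
    max_unit: int = 100,
    min_copies: int = 3,
    min_identity: float = 0.8,
) -> List[RepeatCall]:
    """Detect tandem arrays with unit length in [min_unit, max_unit].

    For each candidate period d, boolean agreement between the sequence
    and itself shifted by d is prefix-summed so adjacent-unit identity
    at any offset is O(1); maximal runs of valid junctions become
    calls. A fractional tail copy is the matching prefix of the next
    partial unit. Calls are reduced to their primitive period, then
    overlapping calls are merged keeping the one with the smaller unit
    (ties: longer span, then leftmost). Calls are returned sorted by
    start.
    """
    if min_unit > max_unit:
        raise ValueError("min_unit > max_unit")
    if min_copies < 2:
        raise ValueError("min_copies must be >= 2")
    sequence = sequence.upper()
    n = len(sequence)
    if n < min_unit * min_copies:
        return []
    arr = np.frombuffer(sequence.encode(), dtype="S1")
    raw: List[RepeatCall] = []
    for d in range(min_unit, min(max_unit, n // 2) + 1):
        eq = (arr[:-d] == arr[d:]).astype(np.int64)
        eq_csum = np.concatenate([[0], np.cumsum(eq)])
        seen_starts = set()
        runs: List[RepeatCall] = []
        for p in range(0, n - 2 * d + 1):
            if _junction_identity(eq_csum, p, d) < min_identity:
                continue
            # a maximal run is phase-determined: extend left to its start
            start = p
            while (
                start - d >= 0
                and _junction_identity(eq_csum, start - d, d) >= min_identity
            ):
                start -= d
            if start in seen_starts:
                continue
            seen_starts.add(start)
            k = _full_unit_run(eq_csum, n, start, d, min_identity)
            copies = k + 1
            if copies < min_copies:
                continue
            end = start + copies * d
            units = [sequence[start + i * d : start + (i + 1) * d] for i in range(copies)]
            # trim boundary units that do not resemble the array consensus:
            # a phase shifted into the flank passes its boundary junction on
            # partially guaranteed matches, but its outer unit is mostly
            # flank sequence
            cons = _consensus(units)

            def _to_cons(u: str) -> float:
                return sum(a == b for a, b in zip(u, cons)) / d

            while units and _to_cons(units[0]) < min_identity:
                units.pop(0)
                start += d
            while units and _to_cons(units[-1]) < min_identity:
                units.pop()
                end -= d
            copies = len(units)
            if copies < min_copies:
                continue
            cons = _consensus(units)
            idents = [
                _junction_identity(eq_csum, start + i * d, d) for i in range(copies - 1)
            ]
            # fractional tail: leading matches of the next partial unit
            tail = 0
            while end + tail < n and tail < d and eq[end - d + tail]:
                tail += 1
            runs.append(
                RepeatCall(
                    start=start,
                    end=end + tail,
                    unit_length=d,
                    copy_number=copies + tail / d,
                    consensus=cons,
                    mean_identity=float(np.mean(idents)),
                )
            )
        # among overlapping runs of one period (phase shifts of each other),
        # keep the best-supported phase by alignment score
        runs.sort(key=lambda c: (-c.score, -(c.span), c.start))
        kept: List[RepeatCall] = []
        for c in runs:
            if any(c.start < o.end and o.start < c.end for o in kept):
                continue
            kept.append(c)
        raw.extend(kept)
    calls = [_reduce_primitive(c, sequence, min_identity) for c in raw]
    # arrays whose true period is below the search range are short-motif
    # runs (homopolymers, triplet repeats), not minisatellites in range;
    # reduction may also have trimmed a call below the copy floor
    calls = [
        c for c in calls if c.unit_length >= min_unit and c.copy_number >= min_copies
    ]
    return _merge_overlaps(calls)


def _reduce_primitive(call: RepeatCall, sequence: str, min_identity: float) -> RepeatCall:
    """Re-report a call at the primitive period of its consensus unit.

    Imperfect arrays detected at a multiple of their true period have a
    consensus that is approximately, not exactly, periodic, so the
    periodicity test reuses the detector's identity floor.
    """
    p = _primitive_period(call.consensus, min_identity)
    if p == call.unit_length:
        return call
    d = p
    start, end = call.start, call.end
    full = int((end - start) // d)
    frac_tail = (end - start) - full * d
    units = [sequence[start + i * d : start + (i + 1) * d] for i in range(full)]
    # same boundary-trimming rule as the primary scan, at the new period
    cons = _consensus(units) if units else call.consensus[:d]

    def _to_cons(u: str) -> float:
        return sum(a == b for a, b in zip(u, cons)) / d

    while units and _to_cons(units[0]) < min_identity:
        units.pop(0)
        start += d
    while units and _to_cons(units[-1]) < min_identity:
        units.pop()
        frac_tail = 0
    end = start + len(units) * d + frac_tail
    if units:
        cons = _consensus(units)
    idents = [
        sum(a == b for a, b in zip(u, v)) / d for u, v in zip(units, units[1:])
    ]
    return RepeatCall(
        start=start,
        end=end,
        unit_length=d,
        copy_number=len(units) + frac_tail / d,
        consensus=cons,
        mean_identity=float(np.mean(idents)) if idents else 1.0,
    )


def _merge_overlaps(calls: List[RepeatCall]) -> List[RepeatCall]:
    """Resolve overlapping calls in two stages.

    Same-unit-length overlaps are phase/period duplicates of one locus:
    the best-supported phase (highest adjacent-unit identity, then span)
    wins. Between different unit lengths the longer-spanning array wins,
    with the smaller (more primitive) unit breaking ties.
    """
    by_unit: Dict[int, List[RepeatCall]] = {}
    for c in calls:
        by_unit.setdefault(c.unit_length, []).append(c)
    stage1: List[RepeatCall] = []
    for group in by_unit.values():
        group.sort(key=lambda c: (-c.score, -(c.span), c.start))
        kept: List[RepeatCall] = []
        for c in group:
            if any(c.start < o.end and o.start < c.end for o in kept):
                continue
            kept.append(c)
        stage1.extend(kept)
    stage1.sort(key=lambda c: (-(c.span), c.unit_length, c.start))
    chosen: List[RepeatCall] = []
    for c in stage1:
        if any(c.start < o.end and o.start < c.end for o in chosen):
            continue
        chosen.append(c)
    return sorted(chosen, key=lambda c: c.start)


@dataclass
class StrainRepeatTable:
    rows: List[Tuple[str, Optional[float]]]  # (strain, copy number or None)

    @property
    def copy_range(self) -> Tuple[float, float]:
        vals = [v for _, v in self.rows if v is not None]
        return (min(vals), max(vals))

    @property
    def n_variants(self) -> int:
        return len({round(v) for _, v in self.rows if v is not None})


def compare_strain_repeats(
    calls_by_strain: Dict[str, List[RepeatCall]],
    unit_length: Optional[int] = None,
) -> StrainRepeatTable:
    """Copy numbers of the homologous locus across strains.

    Per strain the call with the expected unit length (or, without one,
    the longest-span call) represents the locus; strains without any
    call are reported as absent rather than erroring. Rows are sorted
    by copy number (absent strains last).
    """
    rows: List[Tuple[str, Optional[float]]] = []
    for strain, calls in calls_by_strain.items():
        pool = [
            c for c in calls if unit_length is None or c.unit_length == unit_length
        ]
        if not pool:
            rows.append((strain, None))
        else:
            best = max(pool, key=lambda c: c.span)
            rows.append((strain, best.copy_number))
    rows.sort(key=lambda r: (r[1] is None, r[1] if r[1] is not None else 0, r[0]))
    return StrainRepeatTable(rows=rows)
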