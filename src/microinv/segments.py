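"""From seed matches to a pairwise non-overlapping candidate set of matching
segment pairs (MSPs).

An MSP is an ungapped aligned segment between the read target and the
reference target, on either strand, with match count M and mismatch count MS
recomputed by direct base comparison (so M + MS always equals the span).
Reverse MSPs align the read window against the reverse complement of the
reference window; their read interval is stored in forward read coordinates
and their ref interval in forward reference coordinates.

Overlapping MSPs are resolved by partition-and-recombine: for every
overlapping pair the overlap is cut off each member and the trimmed pieces
join the candidate pool, iterated to a fixpoint, so any selection of
pairwise non-overlapping trimmed segments remains realizable downstream
(the transformation is lossless).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .io_core import _rc
from .seeding import FORWARD, REVERSE, SeedMatch

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SegmentConfig:
    """min_seed_run: collinear consecutive seeds needed to keep a segment
    (>= threshold by default; set strict_run_threshold for strictly
    greater).  merge_dist: largest identical read/ref gap bridged when
    merging same-diagonal neighbors (absorbs SNV-broken seeds)."""

    min_seed_run: int = 5
    merge_dist: int = 3
    strict_run_threshold: bool = False

    def run_ok(self, run: int) -> bool:
        return run > self.min_seed_run if self.strict_run_threshold else run >= self.min_seed_run


@dataclass(frozen=True)
class MSP:
    """Matching segment pair; all intervals 0-based half-open in target
    coordinates."""

    read_start: int
    read_end: int
    ref_start: int
    ref_end: int
    strand: str
    M: int
    MS: int

    @property
    def span(self) -> int:
        return self.read_end - self.read_start

    def __post_init__(self) -> None:
        if self.read_end - self.read_start != self.ref_end - self.ref_start:
            raise ValueError("MSP read and ref spans differ (MSPs are ungapped)")
        if self.M + self.MS != self.span:
            raise ValueError("M + MS must equal the MSP span")

    @property
    def key(self) -> tuple:
        return (self.read_start, self.read_end, self.ref_start, self.ref_end, self.strand)


def _count_matches(read_seg: str, ref_seg: str) -> tuple[int, int]:
    m = sum(1 for a, b in zip(read_seg, ref_seg) if a == b and a != "N")
    return m, len(read_seg) - m


def make_msp(
    read_target: str,
    ref_target: str,
    read_start: int,
    read_end: int,
    ref_start: int,
    ref_end: int,
    strand: str,
) -> MSP | None:
    """Build an MSP with M/MS recomputed over the span; None when the span is
    empty or carries no matching base at all."""
    if read_end <= read_start:
        return None
    ref_seg = ref_target[ref_start:ref_end]
    if strand == REVERSE:
        ref_seg = _rc(ref_seg)
    m, ms = _count_matches(read_target[read_start:read_end], ref_seg)
    if m < 1:
        return None
    return MSP(read_start, read_end, ref_start, ref_end, strand, m, ms)


def _diagonal_key(match: SeedMatch) -> tuple:
    if match.strand == FORWARD:
        return (FORWARD, match.ref_offset - match.read_offset)
    return (REVERSE, match.read_offset + match.ref_offset)


def merge_consecutive_seeds(
    matches: list[SeedMatch],
    cfg: SegmentConfig,
    k: int,
    read_target: str,
    ref_target: str,
    step: int = 1,
) -> list[MSP]:
    """Collapse maximal runs of collinear consecutive seeds into MSPs.

    Collinear means consecutive read offsets paired with consecutive ref
    offsets on one diagonal (anti-diagonal for the reverse strand).  The same
    seed can sit on several diagonals, yielding several MSPs.
    """
    groups: dict[tuple, list[SeedMatch]] = {}
    for m in matches:
        groups.setdefault(_diagonal_key(m), []).append(m)
    out: list[MSP] = []
    for (strand, diag), group in sorted(groups.items()):
        group.sort(key=lambda m: m.read_offset)
        run_start = 0
        offsets = [m.read_offset for m in group]
        for i in range(1, len(group) + 1):
            if i < len(group) and offsets[i] == offsets[i - 1] + step:
                continue
            run = i - run_start
            if cfg.run_ok(run):
                p0, p1 = offsets[run_start], offsets[i - 1]
                rs, re = p0, p1 + k
                if strand == FORWARD:
                    fs, fe = rs + diag, re + diag
                else:
                    fs, fe = diag - p1, diag - p0 + k
                msp = make_msp(read_target, ref_target, rs, re, fs, fe, strand)
                if msp is not None:
                    out.append(msp)
            run_start = i
    return out


def _anti_key(msp: MSP) -> int:
    # constant along a reverse anti-diagonal
    return msp.read_start + msp.ref_end


def merge_neighbor_msps(
    msps: list[MSP],
    cfg: SegmentConfig,
    read_target: str,
    ref_target: str,
) -> list[MSP]:
    """Merge same-strand, same-diagonal MSPs whose read gap equals their ref
    gap and is at most ``merge_dist`` (the gap bases become matches or, for
    the SNVs that broke the seeds, mismatches).  Merging is transitive.
    Differently-oriented neighbors are never merged, and unequal gaps
    (micro-indels) are left to the path finder's gap penalty."""
    groups: dict[tuple, list[MSP]] = {}
    for m in msps:
        diag = m.ref_start - m.read_start if m.strand == FORWARD else _anti_key(m)
        groups.setdefault((m.strand, diag), []).append(m)
    out: list[MSP] = []
    for (strand, _), group in sorted(groups.items()):
        group.sort(key=lambda m: m.read_start)
        cur = group[0]
        for nxt in group[1:]:
            gap = nxt.read_start - cur.read_end
            # same diagonal => ref gap equals read gap on both strands
            if 0 <= gap <= cfg.merge_dist:
                if strand == FORWARD:
                    fs, fe = cur.ref_start, nxt.ref_end
                else:
                    fs, fe = nxt.ref_start, cur.ref_end
                merged = make_msp(
                    read_target, ref_target, cur.read_start, nxt.read_end, fs, fe, strand
                )
                if merged is not None:
                    cur = merged
                    continue
            out.append(cur)
            cur = nxt
        out.append(cur)
    return out


def _interval_overlap(a0: int, a1: int, b0: int, b1: int) -> tuple[int, int] | None:
    lo, hi = max(a0, b0), min(a1, b1)
    return (lo, hi) if lo < hi else None


def _read_sub(msp: MSP, rs: int, re: int, read_target: str, ref_target: str) -> MSP | None:
    """Restrict an MSP to a read subinterval (ref interval follows the
    diagonal)."""
    if msp.strand == FORWARD:
        d = msp.ref_start - msp.read_start
        return make_msp(read_target, ref_target, rs, re, rs + d, re + d, msp.strand)
    K = _anti_key(msp)
    return make_msp(read_target, ref_target, rs, re, K - re, K - rs, msp.strand)


def _cut_read(msp: MSP, c0: int, c1: int, read_target: str, ref_target: str) -> list[MSP]:
    pieces = []
    for rs, re in ((msp.read_start, c0), (c1, msp.read_end)):
        if re > rs:
            sub = _read_sub(msp, rs, re, read_target, ref_target)
            if sub is not None:
                pieces.append(sub)
    return pieces


def _cut_ref(msp: MSP, c0: int, c1: int, read_target: str, ref_target: str) -> list[MSP]:
    pieces = []
    for fs, fe in ((msp.ref_start, c0), (c1, msp.ref_end)):
        if fe <= fs:
            continue
        if msp.strand == FORWARD:
            d = msp.ref_start - msp.read_start
            sub = make_msp(read_target, ref_target, fs - d, fe - d, fs, fe, msp.strand)
        else:
            K = _anti_key(msp)
            sub = make_msp(read_target, ref_target, K - fe, K - fs, fs, fe, msp.strand)
        if sub is not None:
            pieces.append(sub)
    return pieces


def msps_overlap(a: MSP, b: MSP) -> bool:
    return (
        _interval_overlap(a.read_start, a.read_end, b.read_start, b.read_end) is not None
        or _interval_overlap(a.ref_start, a.ref_end, b.ref_start, b.ref_end) is not None
    )


def resolve_overlaps(
    msps: list[MSP],
    read_target: str,
    ref_target: str,
    max_candidates: int = 512,
) -> list[MSP]:
    """Partition-and-recombine to a fixpoint.

    For every overlapping pair (A, B) with overlap c -- checked on the read
    and on the reference intervals -- the trimmed pieces of A and B with c
    cut off are added, so the pool realizes {(A, b), (a, B), (a, b)} and
    every recombination thereof.  The pool keeps the originals too; the path
    finder enforces pairwise disjointness when chaining.  Candidates are
    deduplicated by (read interval, ref interval, strand) and returned sorted
    by reference location.
    """
    pool: dict[tuple, MSP] = {}
    for m in msps:
        pool[m.key] = m
    changed = True
    while changed:
        changed = False
        items = list(pool.values())
        for i in range(len(items)):
            for j in range(i + 1, len(items)):
                a, b = items[i], items[j]
                new: list[MSP] = []
                ov = _interval_overlap(a.read_start, a.read_end, b.read_start, b.read_end)
                if ov is not None:
                    new += _cut_read(a, *ov, read_target, ref_target)
                    new += _cut_read(b, *ov, read_target, ref_target)
                ov = _interval_overlap(a.ref_start, a.ref_end, b.ref_start, b.ref_end)
                if ov is not None:
                    new += _cut_ref(a, *ov, read_target, ref_target)
                    new += _cut_ref(b, *ov, read_target, ref_target)
                for piece in new:
                    if piece.key not in pool:
                        pool[piece.key] = piece
                        changed = True
            if len(pool) > max_candidates:
                log.warning(
                    "overlap resolution capped at %d candidates", max_candidates
                )
                changed = False
                break
        if len(pool) > max_candidates:
            break
    return sorted(pool.values(), key=lambda m: (m.ref_start, m.ref_end, m.read_start, m.strand))
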