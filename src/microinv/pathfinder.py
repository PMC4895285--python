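"""Maximum-score chaining of non-overlapping MSPs.

Each segment scores F = 100*M - 100*MS, minus a reverse penalty
R = 3*(M + MS)^2 when it aligns to the reverse strand.  The quadratic
reverse penalty is what separates true inversions from palindromic
sequence: a palindrome matches both strands, so its forward version always
scores R higher and wins, whereas a genuine inversion matches only the
reverse strand and beats the alternative of leaving a large gap.

Gaps between consecutive chain members (and before the first / after the
last member) score 0 when absent and -400 - 30*G otherwise, with G the
larger of the unaligned read and reference stretches.  The best chain is
found by an O(n^2) dynamic program over MSPs in read order; chains must be
non-overlapping on both read and reference but need not be
reference-monotonic (a translocated segment may chain out of reference
order).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .segments import MSP
from .seeding import REVERSE


@dataclass(frozen=True)
class PathScoreParams:
    match_weight: int = 100
    mismatch_weight: int = 100
    gap_open: int = 400
    gap_extend: int = 30
    reverse_penalty_coeff: int = 3

    def __post_init__(self) -> None:
        for name, v in self.__dict__.items():
            if v < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class Path:
    """An ordered chain of pairwise non-overlapping MSPs with its score
    decomposition.  gap_scores has len(msps)+1 entries: leading gap,
    inter-segment gaps, trailing gap."""

    msps: list[MSP]
    total_score: int
    segment_scores: list[int] = field(default_factory=list)
    gap_scores: list[int] = field(default_factory=list)

    @property
    def reverse_msps(self) -> list[MSP]:
        return [m for m in self.msps if m.strand == REVERSE]


def reverse_penalty(msp: MSP, params: PathScoreParams = PathScoreParams()) -> int:
    """R = coeff * (M + MS)^2 for reverse-strand segments, 0 otherwise."""
    if msp.strand != REVERSE:
        return 0
    return params.reverse_penalty_coeff * (msp.M + msp.MS) ** 2


def segment_score(msp: MSP, params: PathScoreParams = PathScoreParams()) -> int:
    """F = 100*M - 100*MS, minus R on the reverse strand."""
    return (
        params.match_weight * msp.M
        - params.mismatch_weight * msp.MS
        - reverse_penalty(msp, params)
    )


def count_gap(msp_i: MSP, msp_j: MSP) -> int:
    """Gap count between two chainable MSPs: the larger of the unaligned read
    and reference stretches (order-agnostic on the reference so inverted or
    translocated segments chain freely).  Zero iff the segments abut on both
    sequences."""
    read_gap = msp_j.read_start - msp_i.read_end
    if read_gap < 0:
        raise ValueError("MSPs overlap on the read; not chainable")
    ref_gap = max(msp_i.ref_start, msp_j.ref_start) - min(msp_i.ref_end, msp_j.ref_end)
    if ref_gap < 0:
        raise ValueError("MSPs overlap on the reference; not chainable")
    return max(read_gap, ref_gap)


def gap_score(G: int, params: PathScoreParams = PathScoreParams()) -> int:
    """GS = 0 for no gap, else -(gap_open + gap_extend * G)."""
    if G < 0:
        raise ValueError("negative gap count")
    if G == 0:
        return 0
    return -(params.gap_open + params.gap_extend * G)


def _chainable(a: MSP, b: MSP) -> bool:
    if b.read_start < a.read_end:
        return False
    return max(a.ref_start, b.ref_start) - min(a.ref_end, b.ref_end) >= 0


def _tiebreak_key(msps: list[MSP]) -> tuple:
    """Smaller is preferred: fewer reverse members, fewer members, leftmost
    read starts."""
    n_rev = sum(1 for m in msps if m.strand == REVERSE)
    return (n_rev, len(msps), tuple(m.read_start for m in msps))


def max_score_path(
    msps: list[MSP],
    params: PathScoreParams = PathScoreParams(),
    read_target_len: int = 0,
) -> Path:
    """Best-scoring chain by dynamic programming, O(n^2) in the number of
    MSPs.  Terminal gaps over the read target are included.  The chain ends
    at some member; the empty path only arises when no MSPs exist at all
    (score: one terminal gap over the whole target).  Ties are broken towards
    fewer reverse-strand members, then fewer members, then leftmost starts,
    so output is deterministic and conservatively avoids inversion calls."""
    order = sorted(
        range(len(msps)),
        key=lambda i: (msps[i].read_start, msps[i].read_end, msps[i].ref_start, msps[i].strand),
    )
    seq = [msps[i] for i in order]
    n = len(seq)
    F = [segment_score(m, params) for m in seq]
    T: list[int] = [0] * n
    chains: list[tuple[int, ...]] = [()] * n
    for i in range(n):
        best_score = gap_score(seq[i].read_start, params)  # start fresh: GS[0,i]
        best_chain: tuple[int, ...] = ()
        for j in range(i):
            if not _chainable(seq[j], seq[i]):
                continue
            cand = T[j] + gap_score(count_gap(seq[j], seq[i]), params)
            if cand > best_score or (
                cand == best_score
                and _tiebreak_key([seq[x] for x in chains[j]])
                < _tiebreak_key([seq[x] for x in best_chain])
            ):
                best_score = cand
                best_chain = chains[j]
        T[i] = best_score + F[i]
        chains[i] = best_chain + (i,)

    # the chain must end at some MSP; only a segment-free instance yields the
    # empty path (the whole target scored as one terminal gap)
    final_score = gap_score(read_target_len, params)
    final_chain: tuple[int, ...] = ()
    for i in range(n):
        cand = T[i] + gap_score(read_target_len - seq[i].read_end, params)
        if not final_chain or cand > final_score or (
            cand == final_score
            and _tiebreak_key([seq[x] for x in chains[i]])
            < _tiebreak_key([seq[x] for x in final_chain])
        ):
            final_score = cand
            final_chain = chains[i]

    members = [seq[x] for x in final_chain]
    seg_scores = [segment_score(m, params) for m in members]
    gaps: list[int] = []
    if members:
        gaps.append(gap_score(members[0].read_start, params))
        for a, b in zip(members, members[1:]):
            gaps.append(gap_score(count_gap(a, b), params))
        gaps.append(gap_score(read_target_len - members[-1].read_end, params))
    else:
        gaps.append(gap_score(read_target_len, params))
    return Path(members, final_score, seg_scores, gaps)
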