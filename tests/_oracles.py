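"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive (direct scans, exhaustive
enumeration) and shares no code with the package implementation paths it
checks.
"""

from __future__ import annotations

from itertools import combinations

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def rc(seq: str) -> str:
    return "".join(_COMP[c] for c in reversed(seq))


def hamming(a: str, b: str) -> int:
    """Hamming distance with N matching nothing."""
    assert len(a) == len(b)
    return sum(1 for x, y in zip(a, b) if x != y or x == "N")


def scan_hits(query: str, text: str, max_mm: int) -> dict[int, int]:
    """Every position of text where query matches with <= max_mm mismatches."""
    k = len(query)
    out = {}
    for i in range(len(text) - k + 1):
        d = hamming(query, text[i : i + k])
        if d <= max_mm:
            out[i] = d
    return out


def two_strand_seed_matches(
    read_target: str, ref_target: str, k: int, max_mm: int, keep_reverse_seed
) -> set[tuple[int, int, str, int]]:
    """Brute-force (read_offset, ref_offset, strand, mismatches) set.

    A reverse match at (read window w, ref window v) exists iff
    hamming(rc(read[w]), ref[v]) <= max_mm and the reverse-complemented seed
    passes the caller-supplied filter predicate.
    """
    out = set()
    for p in range(len(read_target) - k + 1):
        w = read_target[p : p + k]
        for q, mm in scan_hits(w, ref_target, max_mm).items():
            out.add((p, q, "+", mm))
        w_rc = rc(w)
        if keep_reverse_seed(w_rc):
            for q, mm in scan_hits(w_rc, ref_target, max_mm).items():
                out.add((p, q, "-", mm))
    return out


def _chainable(a, b) -> bool:
    if b.read_start < a.read_end:
        return False
    return max(a.ref_start, b.ref_start) - min(a.ref_end, b.ref_end) >= 0


def _gap(a, b) -> int:
    return max(
        b.read_start - a.read_end,
        max(a.ref_start, b.ref_start) - min(a.ref_end, b.ref_end),
    )


def chain_score(chain, params, target_len: int) -> int:
    """Score of one ordered chain under the segment/gap/reverse formulas."""
    def seg(m):
        f = params.match_weight * m.M - params.mismatch_weight * m.MS
        if m.strand == "-":
            f -= params.reverse_penalty_coeff * (m.M + m.MS) ** 2
        return f

    def gs(g):
        return 0 if g == 0 else -(params.gap_open + params.gap_extend * g)

    total = gs(chain[0].read_start)
    for a, b in zip(chain, chain[1:]):
        total += gs(_gap(a, b))
    total += sum(seg(m) for m in chain)
    total += gs(target_len - chain[-1].read_end)
    return total


def best_chain_score(msps, params, target_len: int) -> int:
    """Exhaustive maximum over every valid nonempty chain: members in
    increasing read order, consecutive members non-overlapping on read and
    reference.  With no MSPs the whole target is one gap."""
    def gs(g):
        return 0 if g == 0 else -(params.gap_open + params.gap_extend * g)

    if not msps:
        return gs(target_len)
    order = sorted(msps, key=lambda m: (m.read_start, m.read_end, m.ref_start, m.strand))
    best = None
    n = len(order)
    for r in range(1, n + 1):
        for idxs in combinations(range(n), r):
            chain = [order[i] for i in idxs]
            if any(not _chainable(a, b) for a, b in zip(chain, chain[1:])):
                continue
            s = chain_score(chain, params, target_len)
            if best is None or s > best:
                best = s
    return best if best is not None else gs(target_len)


def _match_count(read_seg: str, ref_seg: str, strand: str) -> int:
    if strand == "-":
        ref_seg = rc(ref_seg)
    return sum(1 for a, b in zip(read_seg, ref_seg) if a == b and a != "N")


def _piece_ref_iv(piece, r0, r1):
    """Map a read subinterval of a piece to its reference subinterval."""
    rs, re, fs, fe, strand = piece
    if strand == "+":
        d = fs - rs
        return r0 + d, r1 + d
    K = rs + fe
    return K - r1, K - r0


def _subtract_read(piece, c0, c1):
    rs, re, fs, fe, strand = piece
    lo, hi = max(rs, c0), min(re, c1)
    if lo >= hi:
        return [piece]
    out = []
    for a, b in ((rs, lo), (hi, re)):
        if b > a:
            f0, f1 = _piece_ref_iv(piece, a, b)
            out.append((a, b, f0, f1, strand))
    return out


def _subtract_ref(piece, c0, c1):
    rs, re, fs, fe, strand = piece
    lo, hi = max(fs, c0), min(fe, c1)
    if lo >= hi:
        return [piece]
    if strand == "+":
        d = fs - rs
        read_cut = (lo - d, hi - d)
    else:
        K = rs + fe
        read_cut = (K - hi, K - lo)
    return _subtract_read(piece, *read_cut)


def achievable_trimmed_pieces(msps, read_target: str, ref_target: str):
    """Every trimmed piece reachable by placing a subset of the original
    MSPs in read order, trimming each newcomer against everything already
    placed (read and reference overlaps cut off, flanks kept as separate
    pieces).  Pieces with zero matching bases are dropped, mirroring the
    M >= 1 segment invariant."""
    order = sorted(msps, key=lambda m: (m.read_start, m.read_end, m.ref_start, m.strand))
    found = set()

    def visit(i, placed):
        if i == len(order):
            return
        m = order[i]
        visit(i + 1, placed)  # skip this original
        frags = [(m.read_start, m.read_end, m.ref_start, m.ref_end, m.strand)]
        for p in placed:
            nxt = []
            for f in frags:
                step = _subtract_read(f, p[0], p[1])
                for g in step:
                    nxt.extend(_subtract_ref(g, p[2], p[3]))
            frags = nxt
        frags = [
            f
            for f in frags
            if _match_count(read_target[f[0] : f[1]], ref_target[f[2] : f[3]], f[4]) >= 1
        ]
        found.update(frags)
        visit(i + 1, placed + frags)

    visit(0, [])
    return found
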