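"""Anchor extraction and paired anchor placement.

The head and tail of each unmapped read serve as a pseudo paired-end unit:
both anchors must match the forward reference strand with at most
``max_anchor_mismatch`` Hamming mismatches, on the same contig, with the
reference distance between their inner edges inside a window derived from the
read geometry.  The stretch between the anchors is the read *target region*;
the reference stretch between the placed anchors is the reference *target
region*.  Reads originating from the reverse genome strand are handled by
also querying the reverse complement of the whole read (done in the
pipeline), so anchors themselves are only ever placed forward.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, product

import numpy as np

from .io_core import ReferenceGenome, Read, encode


@dataclass(frozen=True)
class AnchorConfig:
    """Geometry of the anchored search.

    anchor_len: anchor size in bp (>= 10; shorter anchors stop being unique).
    cut_size: bases trimmed from each read end before taking anchors.
    max_anchor_mismatch: Hamming tolerance per anchor.
    min_mi_len: smallest inversion of interest; also floors the inner window.
    slack: +/- allowance on the anchor inner distance relative to the read's
        own inner length (25 bp reproduces the 15-65 bp window for 76 bp
        reads with 18 bp anchors).
    """

    anchor_len: int = 18
    cut_size: int = 0
    max_anchor_mismatch: int = 1
    min_mi_len: int = 15
    slack: int = 25

    def __post_init__(self) -> None:
        if self.anchor_len < 10:
            raise ValueError("anchor_len must be >= 10")
        if self.cut_size < 0 or self.slack < 0 or self.max_anchor_mismatch < 0:
            raise ValueError("negative anchoring parameter")

    def read_target_len(self, read_len: int) -> int:
        return read_len - 2 * (self.anchor_len + self.cut_size)

    def inner_window(self, read_len: int) -> tuple[int, int]:
        """[min_inner, max_inner] allowed reference distance between anchors."""
        inner = self.read_target_len(read_len)
        lo = max(self.min_mi_len, inner - self.slack)
        hi = inner + self.slack
        return lo, hi


@dataclass(frozen=True)
class AnchorPlacement:
    """Reference window delimited by one placed head/tail anchor pair.

    All coordinates 0-based half-open on the forward reference strand.
    ``read_target`` is in coordinates of the query sequence that was anchored
    (the read itself or its reverse complement).
    """

    contig: str
    head_ref_start: int
    head_ref_end: int
    tail_ref_start: int
    tail_ref_end: int
    read_target: tuple[int, int]
    head_mismatches: int = 0
    tail_mismatches: int = 0

    @property
    def ref_target(self) -> tuple[int, int]:
        return (self.head_ref_end, self.tail_ref_start)

    @property
    def inner_dist(self) -> int:
        return self.tail_ref_start - self.head_ref_end


def extract_anchors(
    read: Read, cfg: AnchorConfig
) -> tuple[str, str, tuple[int, int]] | None:
    """Head anchor, tail anchor and the read target interval between them.

    Returns None when the read is too short to host two anchors plus a
    minimum-length target (such reads are skipped, not an error).
    """
    n = read.length
    need = 2 * (cfg.anchor_len + cfg.cut_size) + cfg.min_mi_len
    if n < need:
        return None
    c, a = cfg.cut_size, cfg.anchor_len
    head = read.sequence[c : c + a]
    tail = read.sequence[n - c - a : n - c]
    return head, tail, (c + a, n - c - a)


def _window_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Pack every k-mer of a 2-bit encoded sequence into int64; windows
    containing N get code -1."""
    n = codes.shape[0]
    if n < k:
        return np.empty(0, dtype=np.int64)
    m = n - k + 1
    out = np.zeros(m, dtype=np.int64)
    for j in range(k):
        out = (out << 2) | np.where(codes[j : j + m] > 3, 0, codes[j : j + m])
    has_n = np.convolve((codes > 3).astype(np.int64), np.ones(k, dtype=np.int64))[
        k - 1 : k - 1 + m
    ]
    out[has_n > 0] = -1
    return out


def _kmer_neighborhood(kmer: str, max_mm: int) -> list[tuple[int, int]]:
    """(packed code, mismatch count) for every sequence within Hamming
    distance max_mm of kmer.  N positions match nothing, so each one must be
    substituted and costs one mismatch."""
    k = len(kmer)
    base = encode(kmer).astype(np.int64)
    n_pos = [i for i in range(k) if base[i] > 3]
    if len(n_pos) > max_mm:
        return []
    free = max_mm - len(n_pos)
    other_pos = [i for i in range(k) if base[i] <= 3]
    shifts = [2 * (k - 1 - i) for i in range(k)]
    vals = [int(b) if b <= 3 else 0 for b in base]  # N packs as 0
    base_code = 0
    for v in vals:
        base_code = (base_code << 2) | v
    out: list[tuple[int, int]] = []
    for extra in range(free + 1):
        for subset in combinations(other_pos, extra):
            positions = list(n_pos) + list(subset)
            mm = len(positions)
            choices = [
                [b for b in range(4) if base[p] > 3 or b != vals[p]]
                for p in positions
            ]
            for combo in product(*choices):
                code = base_code
                for p, b in zip(positions, combo):
                    code += (b - vals[p]) << shifts[p]
                out.append((code, mm))
    return out


class AnchorIndex:
    """Exact/approximate lookup of fixed-length anchor words on a genome.

    Every position of every contig contributes its anchor-length word;
    approximate lookup enumerates the Hamming neighborhood of the query.
    """

    def __init__(self, genome: ReferenceGenome, anchor_len: int):
        if anchor_len < 10:
            raise ValueError("anchor_len must be >= 10")
        if anchor_len > 31:
            raise ValueError("anchor_len too large for 2-bit packing")
        self.anchor_len = anchor_len
        self.genome = genome
        self._sorted: dict[str, np.ndarray] = {}
        self._positions: dict[str, np.ndarray] = {}
        for contig, seq in genome.sequences.items():
            codes = _window_codes(encode(seq), anchor_len)
            order = np.argsort(codes, kind="stable")
            self._sorted[contig] = codes[order]
            self._positions[contig] = order.astype(np.int64)

    def lookup_exact(self, kmer: str) -> dict[str, np.ndarray]:
        """Contig -> sorted array of exact match positions."""
        hits = self.lookup(kmer, max_mismatch=0)
        return {c: np.array(sorted(d), dtype=np.int64) for c, d in hits.items()}

    def lookup(self, kmer: str, max_mismatch: int) -> dict[str, dict[int, int]]:
        """Contig -> {position: mismatch count} within the tolerance."""
        if len(kmer) != self.anchor_len:
            raise ValueError("query length does not match anchor_len")
        neigh = _kmer_neighborhood(kmer, max_mismatch)
        if not neigh:
            return {}
        codes = np.array([c for c, _ in neigh], dtype=np.int64)
        mms = np.array([m for _, m in neigh], dtype=np.int64)
        out: dict[str, dict[int, int]] = {}
        for contig, sorted_codes in self._sorted.items():
            lo = np.searchsorted(sorted_codes, codes, side="left")
            hi = np.searchsorted(sorted_codes, codes, side="right")
            found = {}
            positions = self._positions[contig]
            for a, b, mm in zip(lo, hi, mms):
                for pos in positions[a:b]:
                    p = int(pos)
                    if p not in found or mm < found[p]:
                        found[p] = int(mm)
            if found:
                out[contig] = found
        return out


def place_anchor_pair(
    head: str,
    tail: str,
    index: AnchorIndex,
    cfg: AnchorConfig,
    read_len: int,
    read_target: tuple[int, int] | None = None,
) -> list[AnchorPlacement]:
    """All placements where head and tail match forward, same contig, with an
    inner reference distance inside the configured window.

    Placements closer than the window floor (possible deletion shorter than
    any reportable inversion) or farther than the ceiling (insertion beyond
    what a single read target can host) are discarded.
    """
    a = cfg.anchor_len
    if read_target is None:
        read_target = (cfg.cut_size + a, read_len - cfg.cut_size - a)
    lo, hi = cfg.inner_window(read_len)
    head_hits = index.lookup(head, cfg.max_anchor_mismatch)
    if not head_hits:
        return []
    tail_hits = index.lookup(tail, cfg.max_anchor_mismatch)
    placements: list[AnchorPlacement] = []
    for contig, heads in head_hits.items():
        tails = tail_hits.get(contig)
        if not tails:
            continue
        tail_pos = np.array(sorted(tails), dtype=np.int64)
        for h, hmm in sorted(heads.items()):
            # tail start t must satisfy lo <= t - (h + a) <= hi
            left = np.searchsorted(tail_pos, h + a + lo, side="left")
            right = np.searchsorted(tail_pos, h + a + hi, side="right")
            for t in tail_pos[left:right]:
                t = int(t)
                placements.append(
                    AnchorPlacement(
                        contig=contig,
                        head_ref_start=h,
                        head_ref_end=h + a,
                        tail_ref_start=t,
                        tail_ref_end=t + a,
                        read_target=read_target,
                        head_mismatches=hmm,
                        tail_mismatches=tails[t],
                    )
                )
    return placements
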