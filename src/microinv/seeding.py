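"""Two-strand k-mer seeding of the read target against the reference target.

Seeds are consecutive k-mers (step 1 by default) taken from the read target
region and, separately, from its reverse complement.  Every seed is compared
against every window of the reference target region; all positions within
the mismatch tolerance are kept ("store all possible locations"), with no
best-hit selection.  Reverse-strand seeds rich in AT/GC dinucleotide repeats
are discarded before matching, because such tandem palindromic repeats match
both strands equally well and would flood the reverse diagonal with spurious
hits.  N never matches any base.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .io_core import _rc, encode

FORWARD = "+"
REVERSE = "-"


@dataclass(frozen=True)
class SeedConfig:
    k: int = 14
    step: int = 1
    max_seed_mismatch: int = 2
    at_gc_fraction: float = 0.25

    def __post_init__(self) -> None:
        if self.k < 8:
            raise ValueError("k must be >= 8")
        if self.step < 1:
            raise ValueError("step must be >= 1")
        if not 0 <= self.max_seed_mismatch < self.k:
            raise ValueError("max_seed_mismatch must be in [0, k)")

    @property
    def palindrome_threshold(self) -> int:
        return math.ceil(self.k * self.at_gc_fraction)


@dataclass(frozen=True)
class SeedMatch:
    """One seed placed on the reference target.

    ``read_offset`` is always in forward read-target coordinates: a
    reverse-strand seed covering read positions [p, p+k) is recorded at p, so
    a contiguous inverted block shows up as an anti-diagonal (read_offset +
    ref_offset constant) in match space.
    """

    read_offset: int
    ref_offset: int
    strand: str
    mismatches: int


def extract_seeds(
    target: str, cfg: SeedConfig, strand: str = FORWARD
) -> list[tuple[int, str]]:
    """(read_offset, k-mer) seeds of the target (or its reverse complement).

    For the reverse strand the k-mer is the reverse complement of the window
    it covers, and the offset is the window start in forward coordinates.
    """
    k, step = cfg.k, cfg.step
    n = len(target)
    if n < k:
        return []
    if strand == FORWARD:
        return [(i, target[i : i + k]) for i in range(0, n - k + 1, step)]
    if strand == REVERSE:
        rc = _rc(target)
        # rc offset j covers forward window starting at n - j - k
        return [(n - j - k, rc[j : j + k]) for j in range(0, n - k + 1, step)]
    raise ValueError(f"unknown strand {strand!r}")


def is_palindromic_seed(seed: str, cfg: SeedConfig) -> bool:
    """True when the seed carries >= ceil(k/4) non-overlapping "AT" or "GC"
    dinucleotides (counted left to right) and must be discarded from
    reverse-strand matching."""
    if len(seed) != cfg.k:
        raise ValueError("seed length does not match k")
    count = 0
    i = 0
    while i < len(seed) - 1:
        if seed[i : i + 2] in ("AT", "GC"):
            count += 1
            i += 2
        else:
            i += 1
    return count >= cfg.palindrome_threshold


def _ref_windows(ref_target: str, k: int) -> np.ndarray:
    enc = encode(ref_target)
    return np.lib.stride_tricks.sliding_window_view(enc, k)


def _mismatch_counts(seed_codes: np.ndarray, windows: np.ndarray) -> np.ndarray:
    # N (code 4) on either side counts as a mismatch
    diff = (windows != seed_codes) | (windows > 3) | (seed_codes > 3)
    return diff.sum(axis=1)


def match_seed(
    seed: str, ref_target: str, cfg: SeedConfig
) -> list[tuple[int, int]]:
    """All (ref_offset, mismatches) with Hamming distance <= tolerance."""
    if len(ref_target) < cfg.k:
        return []
    counts = _mismatch_counts(encode(seed), _ref_windows(ref_target, cfg.k))
    return [
        (int(j), int(m)) for j, m in enumerate(counts) if m <= cfg.max_seed_mismatch
    ]


def match_all_seeds(
    read_target: str, ref_target: str, cfg: SeedConfig
) -> list[SeedMatch]:
    """Union of forward matches (all seeds) and reverse matches (palindrome-
    filtered seeds only).  The two strands stay separable via the strand
    field."""
    out: list[SeedMatch] = []
    if len(ref_target) < cfg.k or len(read_target) < cfg.k:
        return out
    windows = _ref_windows(ref_target, cfg.k)
    for strand in (FORWARD, REVERSE):
        for read_offset, seed in extract_seeds(read_target, cfg, strand):
            if strand == REVERSE and is_palindromic_seed(seed, cfg):
                continue
            counts = _mismatch_counts(encode(seed), windows)
            hit = np.nonzero(counts <= cfg.max_seed_mismatch)[0]
            for j in hit:
                out.append(SeedMatch(read_offset, int(j), strand, int(counts[j])))
    return out
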