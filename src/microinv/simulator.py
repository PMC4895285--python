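"""Benchmark simulation: plant micro-inversions (and confounding variants)
into a reference, emit paired-end reads with substitution errors, and score
calls against the truth.

The generator emulates the benchmark conditions the detector is designed
for: inversions of 15-40 bp with truncated-normal sizes planted at random
non-overlapping positions, optionally surrounded by SNVs, insertions,
deletions and tandem duplications; 76 bp paired-end Illumina-like reads at
2-60X coverage with a uniform per-base substitution error rate of 0.02.
Read emission replaces an external read simulator with uniform fragment
sampling, uniform strand choice and independent substitution errors (no
quality model, no indel errors); candidate selection replaces an external
aligner's unmapped-read filter with a truth-guided overlap filter.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path as FsPath

import numpy as np

from .io_core import ReferenceGenome, Read, _rc, decode, encode

log = logging.getLogger(__name__)


@dataclass
class SimConfig:
    ref_len: int = 1_000_000
    gc_fraction: float = 0.41
    contig: str = "sim1"
    n_mi: int = 50
    mi_size_mean: float = 27.5
    mi_size_sd: float = 6.0
    mi_min: int = 15
    mi_max: int = 40
    n_snv: int = 0
    n_ins: int = 0
    n_del: int = 0
    n_dup: int = 0
    indel_max: int = 10
    read_len: int = 76
    coverage: float = 10.0
    error_rate: float = 0.02
    insert_mean: float = 250.0
    insert_sd: float = 25.0
    min_variant_gap: int = 76
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.mi_min <= self.mi_size_mean <= self.mi_max:
            raise ValueError("mi size mean outside [mi_min, mi_max]")
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")

    @classmethod
    def with_other_variants(cls, n_other: int, **kw) -> "SimConfig":
        """Split a total count of confounding variants into equal quarters of
        SNVs, insertions, deletions and duplications."""
        q, r = divmod(n_other, 4)
        counts = [q + (1 if i < r else 0) for i in range(4)]
        return cls(n_snv=counts[0], n_ins=counts[1], n_del=counts[2], n_dup=counts[3], **kw)


@dataclass(frozen=True)
class PlantedMI:
    contig: str
    start: int  # 1-based inclusive on the original reference
    end: int
    mut_start: int  # 0-based half-open on the mutated genome
    mut_end: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class TruthSet:
    mis: list[PlantedMI] = field(default_factory=list)
    others: list[tuple[str, int, int]] = field(default_factory=list)  # (type, pos0, len)


@dataclass
class EvalResult:
    """detectable/correctly_detected count planted inversions;
    detected/matched_calls count unique call intervals."""

    detectable: int
    correctly_detected: int
    detected: int
    sn: float | None
    ppv: float | None
    n_truth: int = 0
    breakpoint_exact: int = 0
    matched_calls: int = 0

    @property
    def breakpoint_exact_fraction(self) -> float | None:
        if self.correctly_detected == 0:
            return None
        return self.breakpoint_exact / self.correctly_detected


def synthesize_reference(
    length: int, gc_fraction: float, rng: np.random.Generator, contig: str = "sim1"
) -> ReferenceGenome:
    """Random i.i.d. reference; at the sizes used here it is effectively free
    of repeated anchor words."""
    p_gc = gc_fraction / 2.0
    p_at = (1.0 - gc_fraction) / 2.0
    codes = rng.choice(4, size=length, p=[p_at, p_gc, p_gc, p_at]).astype(np.uint8)
    return ReferenceGenome({contig: decode(codes)})


def sample_mi_sizes(n: int, cfg: SimConfig, rng: np.random.Generator) -> list[int]:
    """Truncated-normal inversion sizes in [mi_min, mi_max] by resampling."""
    sizes: list[int] = []
    while len(sizes) < n:
        draw = rng.normal(cfg.mi_size_mean, cfg.mi_size_sd, size=n)
        for v in draw:
            s = int(round(v))
            if cfg.mi_min <= s <= cfg.mi_max:
                sizes.append(s)
                if len(sizes) == n:
                    break
    return sizes


_COMP_CODE = np.array([3, 2, 1, 0, 4], dtype=np.uint8)


def _edges_unambiguous(seq: str, s: int, e: int) -> bool:
    """A planted inversion [s, e) has well-defined breakpoints only when its
    outermost inverted base does not coincide with the forward base it
    replaces; otherwise a strictly shorter inversion explains the same
    mutated sequence and truth comparison would be ill-posed."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    return seq[s] != comp[seq[e - 1]] and seq[e - 1] != comp[seq[s]]


def plant_variants(
    genome: ReferenceGenome, cfg: SimConfig, rng: np.random.Generator
) -> tuple[ReferenceGenome, TruthSet]:
    """Plant all configured variants at random non-overlapping positions.

    Inversions replace a window with its reverse complement; truth
    coordinates are recorded on the original reference (1-based inclusive)
    and on the mutated genome (0-based half-open).  Raises when placement
    fails after bounded retries.
    """
    contig = cfg.contig if cfg.contig in genome else next(iter(genome.sequences))
    seq = genome.sequences[contig]
    n = len(seq)

    mi_sizes = sample_mi_sizes(cfg.n_mi, cfg, rng)
    for s in mi_sizes:
        if not cfg.mi_min <= s <= cfg.mi_max:
            raise ValueError(f"MI size {s} outside [{cfg.mi_min}, {cfg.mi_max}]")
    other_spec = (
        [("snv", 1)] * cfg.n_snv
        + [("ins", None)] * cfg.n_ins
        + [("del", None)] * cfg.n_del
        + [("dup", None)] * cfg.n_dup
    )
    events: list[tuple[int, str, int]] = []  # (pos0, type, length)
    taken: list[tuple[int, int]] = []

    def _place(length: int, check_edges: bool) -> int:
        for _ in range(10_000):
            pos = int(rng.integers(cfg.min_variant_gap, n - length - cfg.min_variant_gap))
            lo, hi = pos - cfg.min_variant_gap, pos + length + cfg.min_variant_gap
            if any(not (hi <= a or b <= lo) for a, b in taken):
                continue
            if check_edges and not _edges_unambiguous(seq, pos, pos + length):
                continue
            taken.append((pos, pos + length))
            return pos
        raise RuntimeError("could not place variant without overlap")

    for size in mi_sizes:
        events.append((_place(size, check_edges=True), "mi", size))
    for kind, _ in other_spec:
        if kind == "snv":
            length = 1
        elif kind in ("ins", "del"):
            length = int(rng.integers(1, cfg.indel_max + 1))
        else:  # tandem duplication
            length = int(rng.integers(cfg.mi_min, cfg.mi_max + 1))
        events.append((_place(length, check_edges=False), kind, length))

    events.sort()
    pieces: list[str] = []
    truth = TruthSet()
    cursor = 0
    shift = 0  # mutated minus original coordinate, left of the current event
    for pos, kind, length in events:
        pieces.append(seq[cursor:pos])
        if kind == "mi":
            pieces.append(_rc(seq[pos : pos + length]))
            truth.mis.append(
                PlantedMI(contig, pos + 1, pos + length, pos + shift, pos + shift + length)
            )
            cursor = pos + length
        elif kind == "snv":
            old = seq[pos]
            choices = [b for b in "ACGT" if b != old]
            pieces.append(choices[int(rng.integers(3))])
            truth.others.append(("snv", pos, 1))
            cursor = pos + 1
        elif kind == "ins":
            ins = decode(rng.choice(4, size=length).astype(np.uint8))
            pieces.append(ins)
            truth.others.append(("ins", pos, length))
            shift += length
            cursor = pos
        elif kind == "del":
            truth.others.append(("del", pos, length))
            shift -= length
            cursor = pos + length
        elif kind == "dup":
            seg = seq[pos : pos + length]
            pieces.append(seg + seg)
            truth.others.append(("dup", pos, length))
            shift += length
            cursor = pos + length
    pieces.append(seq[cursor:])
    mutated = ReferenceGenome({contig: "".join(pieces)})
    return mutated, truth


def generate_reads(
    genome: ReferenceGenome,
    cfg: SimConfig,
    rng: np.random.Generator,
    sample_id: str = "sim",
) -> tuple[list[Read], list[tuple[int, int, str]]]:
    """Paired-end reads with uniform substitution errors.

    Returns the reads and their origins (start, end, strand) on the source
    genome, in read order.  Mate 1 is the forward end of the fragment, mate
    2 the reverse complement of the other end.
    """
    contig = cfg.contig if cfg.contig in genome else next(iter(genome.sequences))
    seq = genome.sequences[contig]
    n = len(seq)
    rl = cfg.read_len
    n_pairs = int(round(cfg.coverage * n / (2 * rl)))
    inserts = np.clip(
        np.rint(rng.normal(cfg.insert_mean, cfg.insert_sd, size=n_pairs)), rl, n
    ).astype(np.int64)
    starts = (rng.random(n_pairs) * (n - inserts)).astype(np.int64)
    codes = encode(seq)

    def _emit(origin_starts: np.ndarray) -> np.ndarray:
        mat = codes[origin_starts[:, None] + np.arange(rl)[None, :]].copy()
        if cfg.error_rate > 0:
            err = rng.random(mat.shape) < cfg.error_rate
            err &= mat < 4
            bump = rng.integers(1, 4, size=mat.shape).astype(np.uint8)
            mat[err] = (mat[err] + bump[err]) % 4
        return mat

    r1 = _emit(starts)
    r2_starts = starts + inserts - rl
    r2 = _emit(r2_starts)

    reads: list[Read] = []
    origins: list[tuple[int, int, str]] = []
    for i in range(n_pairs):
        reads.append(Read(f"{sample_id}:p{i}/1", decode(r1[i]), sample_id))
        origins.append((int(starts[i]), int(starts[i]) + rl, "+"))
        reads.append(Read(f"{sample_id}:p{i}/2", _rc(decode(r2[i])), sample_id))
        origins.append((int(r2_starts[i]), int(r2_starts[i]) + rl, "-"))
    return reads, origins


def select_candidate_reads(
    reads: list[Read],
    origins: list[tuple[int, int, str]],
    truth: TruthSet,
    mode: str = "mi_overlap",
) -> tuple[list[Read], list[tuple[int, int, str]]]:
    """Truth-guided stand-in for an aligner's unmapped-read filter: keep
    reads whose origin overlaps a planted inversion.  ``mode='all'`` passes
    everything through."""
    if mode == "all":
        return reads, origins
    if mode != "mi_overlap":
        raise ValueError(f"unknown candidate mode {mode!r}")
    ivs = sorted((mi.mut_start, mi.mut_end) for mi in truth.mis)
    starts = np.array([a for a, _ in ivs], dtype=np.int64)
    ends = np.array([b for _, b in ivs], dtype=np.int64)
    keep_reads, keep_origins = [], []
    for read, origin in zip(reads, origins):
        s, e, _ = origin
        # planted intervals are disjoint and sorted; overlap iff the last
        # interval starting before e extends past s
        i = int(np.searchsorted(starts, e, side="left"))
        if i > 0 and ends[i - 1] > s:
            keep_reads.append(read)
            keep_origins.append(origin)
    return keep_reads, keep_origins


def _reciprocal_overlap(a: tuple[int, int], b: tuple[int, int]) -> float:
    """Overlap fraction relative to the *longer* interval (1-based
    inclusive); >= threshold on this is the same as >= threshold of both."""
    inter = min(a[1], b[1]) - max(a[0], b[0]) + 1
    if inter <= 0:
        return 0.0
    return inter / max(a[1] - a[0] + 1, b[1] - b[0] + 1)


def evaluate(
    calls,
    truth: TruthSet,
    origins: list[tuple[int, int, str]],
    flank: int = 18,
    min_reciprocal: float = 0.8,
) -> EvalResult:
    """Sensitivity and positive predictive value under reciprocal-overlap
    matching.

    detectable: planted inversions lying wholly inside some read's inner
    target window, i.e. with at least ``flank`` (anchor-length) read bases on
    both sides -- reads merely touching an inversion cannot reveal it.
    A call and a planted inversion match when their overlap covers >= 80% of
    both.  A detectable inversion with at least one matching unique call is
    correctly detected; SN = correctly detected / detectable.  A unique call
    matching any planted inversion is a true call; PPV = true calls /
    detected, undefined (None) when nothing was detected.  An inversion's
    breakpoints count as exact when its best-overlap call equals it.
    """
    unique_calls = sorted({(c.contig, c.start, c.end) for c in calls})
    detected = len(unique_calls)

    origin_starts = np.sort(np.array([s for s, _, _ in origins], dtype=np.int64))
    origin_ends = np.array(sorted(e for _, e, _ in origins), dtype=np.int64)
    rl = int(origin_ends[0] - origin_starts[0]) if len(origin_starts) else 0

    detectable_keys: set[tuple[str, int, int]] = set()
    for mi in truth.mis:
        lo_needed = mi.mut_start - flank
        hi_needed = mi.mut_end + flank
        # any read with start in [hi_needed - rl, lo_needed]
        if rl and hi_needed - rl <= lo_needed:
            i = np.searchsorted(origin_starts, hi_needed - rl, side="left")
            j = np.searchsorted(origin_starts, lo_needed, side="right")
            if j > i:
                detectable_keys.add((mi.contig, mi.start, mi.end))
    detectable = len(detectable_keys)

    matched_calls: set[int] = set()
    best_for_truth: dict[int, tuple[float, int]] = {}
    for ci, c in enumerate(unique_calls):
        for ti, mi in enumerate(truth.mis):
            if c[0] != mi.contig:
                continue
            ov = _reciprocal_overlap((c[1], c[2]), (mi.start, mi.end))
            if ov < min_reciprocal:
                continue
            matched_calls.add(ci)
            prev = best_for_truth.get(ti)
            if prev is None or ov > prev[0]:
                best_for_truth[ti] = (ov, ci)

    correct = 0
    exact = 0
    for ti, (_, ci) in best_for_truth.items():
        mi = truth.mis[ti]
        if (mi.contig, mi.start, mi.end) not in detectable_keys:
            continue
        correct += 1
        c = unique_calls[ci]
        if c[1] == mi.start and c[2] == mi.end:
            exact += 1

    sn = correct / detectable if detectable else None
    ppv = len(matched_calls) / detected if detected else None
    return EvalResult(
        detectable=detectable,
        correctly_detected=correct,
        detected=detected,
        sn=sn,
        ppv=ppv,
        n_truth=len(truth.mis),
        breakpoint_exact=exact,
        matched_calls=len(matched_calls),
    )


def write_truth(truth: TruthSet, origins, path: str | FsPath) -> None:
    data = {
        "mis": [asdict(mi) for mi in truth.mis],
        "others": truth.others,
        "origins": origins,
    }
    FsPath(path).write_text(json.dumps(data))


def load_truth(path: str | FsPath) -> tuple[TruthSet, list[tuple[int, int, str]]]:
    data = json.loads(FsPath(path).read_text())
    truth = TruthSet(
        mis=[PlantedMI(**mi) for mi in data["mis"]],
        others=[tuple(o) for o in data["others"]],
    )
    origins = [tuple(o) for o in data["origins"]]
    return truth, origins
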