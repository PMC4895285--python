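"""Turn reverse-strand path members into genome-coordinate inversion calls
and aggregate them across reads, samples and populations.

Seed-granular segment boundaries over- or under-shoot the true inversion
edges by a couple of bases (a seed tolerating up to 2 mismatches happily
crosses a breakpoint), so each reverse segment's breakpoints are refined
before reporting: the boundary between the flanking forward frame and the
reverse frame slides to the split that maximizes per-base agreement
(+1 match / -1 mismatch on each side).  Ties go to the smaller inverted
span, which reports the minimal inversion consistent with the read.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .anchoring import AnchorPlacement
from .io_core import _COMPLEMENT
from .pathfinder import Path
from .seeding import FORWARD, REVERSE
from .segments import MSP, _count_matches

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class MICall:
    """A called micro-inversion; start/end are 1-based inclusive genome
    coordinates of the inverted segment."""

    contig: str
    start: int
    end: int
    read_id: str
    sample_id: str
    path_score: int
    M: int
    MS: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def interval(self) -> tuple[str, int, int]:
        return (self.contig, self.start, self.end)


@dataclass
class AggregatedMI:
    """Cross-read roll-up of one unique inversion interval."""

    key: tuple[str, int, int]
    occurrence: int  # supporting reads
    samples: set[str] = field(default_factory=set)
    populations: set[str] = field(default_factory=set)
    sample_reads: dict[str, int] = field(default_factory=dict)
    sample_population: dict[str, str] = field(default_factory=dict)


def _fwd_agree(read_target: str, ref_target: str, y: int, diag: int) -> int:
    fy = y + diag
    if 0 <= fy < len(ref_target) and read_target[y] == ref_target[fy] != "N":
        return 1
    return -1


def _rev_agree(read_target: str, ref_target: str, y: int, K: int) -> int:
    fy = K - y - 1
    if (
        0 <= fy < len(ref_target)
        and read_target[y] != "N"
        and read_target[y] == ref_target[fy].translate(_COMPLEMENT)
    ):
        return 1
    return -1


def _refine_reverse_msp(
    msp: MSP,
    path: Path,
    read_target: str,
    ref_target: str,
    window: int,
) -> tuple[int, int]:
    """Slide each breakpoint of a reverse segment within +/- window bases to
    the split maximizing per-base agreement: forward-frame agreement outside
    the inversion, reverse-frame agreement inside.  Returns the refined read
    interval; the ref interval follows the anti-diagonal."""
    K = msp.read_start + msp.ref_end
    idx = path.msps.index(msp)
    prev_fwd = next(
        (m for m in reversed(path.msps[:idx]) if m.strand == FORWARD), None
    )
    next_fwd = next((m for m in path.msps[idx + 1 :] if m.strand == FORWARD), None)
    d_left = (
        prev_fwd.ref_start - prev_fwd.read_start if prev_fwd is not None else 0
    )
    d_right = (
        next_fwd.ref_start - next_fwd.read_start
        if next_fwd is not None
        else len(ref_target) - len(read_target)
    )
    mid = (msp.read_start + msp.read_end) // 2

    # left boundary: read positions < x score in the forward frame, >= x in
    # the reverse frame; ties prefer larger x (smaller inversion)
    lo = max(0, msp.read_start - window)
    hi = min(mid, msp.read_start + window)
    best_x, best_s = lo, None
    score = sum(_rev_agree(read_target, ref_target, y, K) for y in range(lo, mid))
    for x in range(lo, hi + 1):
        if best_s is None or score >= best_s:
            best_s, best_x = score, x
        if x < hi:
            score += _fwd_agree(read_target, ref_target, x, d_left) - _rev_agree(
                read_target, ref_target, x, K
            )
    left = best_x

    # right boundary: read positions < z reverse frame, >= z forward frame;
    # ties prefer smaller z
    lo = max(mid, msp.read_end - window)
    hi = min(len(read_target), msp.read_end + window)
    best_z, best_s = lo, None
    score = sum(_rev_agree(read_target, ref_target, y, K) for y in range(mid, lo))
    for z in range(lo, hi + 1):
        if best_s is None or score > best_s:
            best_s, best_z = score, z
        if z < hi:
            score += _rev_agree(read_target, ref_target, z, K) - _fwd_agree(
                read_target, ref_target, z, d_right
            )
    right = best_z
    if right <= left:
        return msp.read_start, msp.read_end
    return left, right


def _coalesce_reverse_runs(path: Path, read_target: str, ref_target: str) -> Path:
    """Merge consecutive path members that are collinear abutting
    reverse-strand fragments back into single blocks.

    The quadratic reverse penalty makes the chain score of two abutting
    fragments strictly higher than the same bases as one segment, so the
    optimizer fragments long inversions whenever overlap resolution offers
    trimmed pieces; one contiguous inverted block is nevertheless one
    inversion and must be reported as such."""
    from .segments import make_msp

    merged: list[MSP] = []
    for msp in path.msps:
        prev = merged[-1] if merged else None
        if (
            prev is not None
            and prev.strand == REVERSE
            and msp.strand == REVERSE
            and msp.read_start == prev.read_end
            and prev.read_start + prev.ref_end == msp.read_start + msp.ref_end
        ):
            joined = make_msp(
                read_target, ref_target, prev.read_start, msp.read_end,
                msp.ref_start, prev.ref_end, REVERSE,
            )
            if joined is not None:
                merged[-1] = joined
                continue
        merged.append(msp)
    return Path(merged, path.total_score)


def call_mis(
    path: Path,
    placement: AnchorPlacement,
    read_target: str,
    ref_target: str,
    read_id: str,
    sample_id: str,
    min_mi_len: int = 15,
    refine: bool = True,
    refine_window: int = 14,
) -> list[MICall]:
    """One call per reverse-strand block of the winning path whose refined
    reference span is at least ``min_mi_len``; forward members emit
    nothing."""
    out: list[MICall] = []
    ref_target_start = placement.ref_target[0]
    from .io_core import _rc

    path = _coalesce_reverse_runs(path, read_target, ref_target)
    for msp in path.msps:
        if msp.strand != REVERSE:
            continue
        K = msp.read_start + msp.ref_end
        rs, re = msp.read_start, msp.read_end
        if refine:
            rs, re = _refine_reverse_msp(msp, path, read_target, ref_target, refine_window)
        fs, fe = K - re, K - rs
        if fe - fs < min_mi_len or fs < 0 or fe > len(ref_target):
            continue
        m, ms = _count_matches(read_target[rs:re], _rc(ref_target[fs:fe]))
        start0 = ref_target_start + fs
        out.append(
            MICall(
                contig=placement.contig,
                start=start0 + 1,
                end=ref_target_start + fe,
                read_id=read_id,
                sample_id=sample_id,
                path_score=path.total_score,
                M=m,
                MS=ms,
            )
        )
    return out


def aggregate_calls(
    calls: list[MICall],
    sample_to_population: dict[str, str] | None = None,
) -> list[AggregatedMI]:
    """Group calls by exact interval.  One read supports a given inversion at
    most once, even when it anchored at several placements.  Samples missing
    from the population mapping are binned as UNKNOWN with a warning."""
    sample_to_population = sample_to_population or {}
    seen: set[tuple] = set()
    grouped: dict[tuple[str, int, int], AggregatedMI] = {}
    warned: set[str] = set()
    for c in calls:
        dedup_key = (c.read_id, c.sample_id, c.interval)
        if dedup_key in seen:
            continue
        seen.add(dedup_key)
        agg = grouped.get(c.interval)
        if agg is None:
            agg = grouped[c.interval] = AggregatedMI(key=c.interval, occurrence=0)
        pop = sample_to_population.get(c.sample_id)
        if pop is None:
            if sample_to_population and c.sample_id not in warned:
                log.warning("sample %s missing from population map", c.sample_id)
                warned.add(c.sample_id)
            pop = "UNKNOWN"
        agg.occurrence += 1
        agg.samples.add(c.sample_id)
        agg.populations.add(pop)
        agg.sample_reads[c.sample_id] = agg.sample_reads.get(c.sample_id, 0) + 1
        agg.sample_population[c.sample_id] = pop
    return sorted(grouped.values(), key=lambda a: a.key)


def expand_aggregates(aggs: list[AggregatedMI]) -> list[MICall]:
    """Inverse of aggregation for idempotence checks: one synthetic call per
    supporting read."""
    out = []
    for agg in aggs:
        contig, start, end = agg.key
        for sample, nreads in sorted(agg.sample_reads.items()):
            for i in range(nreads):
                out.append(
                    MICall(contig, start, end, f"{sample}:{start}:{i}", sample, 0,
                           end - start + 1, 0)
                )
    return out


def summarize_populations(
    aggs: list[AggregatedMI],
    groups: dict[str, str],
    samples_per_population: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Per-population and per-group overview table.

    Per population: MI-num counts unique inversions seen in the population,
    MI-occ sums (sample, inversion) incidences, mul-sup counts inversions
    supported by >= 2 samples of the population, read-num counts supporting
    reads.  Per group ("Total <group>" rows): MI-occ counts (population,
    inversion) incidences and mul-sup counts inversions supported by >= 2
    populations of the group.  occ/num, mul-sup/num (percent) and read/num
    are the corresponding ratios.
    """
    pops = sorted({p for agg in aggs for p in agg.populations} | set(groups))
    rows = []

    def _ratios(mi_num, mi_occ, mul_sup, read_num):
        if mi_num == 0:
            return (float("nan"),) * 3
        return (mi_occ / mi_num, 100.0 * mul_sup / mi_num, read_num / mi_num)

    for pop in pops:
        mi_num = mi_occ = mul_sup = read_num = 0
        samples: set[str] = set()
        for agg in aggs:
            pop_samples = [s for s, p in agg.sample_population.items() if p == pop]
            if not pop_samples:
                continue
            mi_num += 1
            mi_occ += len(pop_samples)
            if len(pop_samples) >= 2:
                mul_sup += 1
            read_num += sum(agg.sample_reads[s] for s in pop_samples)
            samples.update(pop_samples)
        sam_num = (
            samples_per_population.get(pop, len(samples))
            if samples_per_population
            else len(samples)
        )
        occ_per_num, mul_sup_pct, read_per_num = _ratios(mi_num, mi_occ, mul_sup, read_num)
        rows.append(
            dict(population=pop, sam_num=sam_num, mi_num=mi_num, mi_occ=mi_occ,
                 mul_sup=mul_sup, read_num=read_num, occ_per_num=occ_per_num,
                 mul_sup_pct=mul_sup_pct, read_per_num=read_per_num)
        )

    for group in sorted(set(groups.values())):
        gpops = {p for p, g in groups.items() if g == group}
        mi_num = mi_occ = mul_sup = read_num = 0
        samples = set()
        for agg in aggs:
            in_group = {p for p in agg.populations if p in gpops}
            if not in_group:
                continue
            mi_num += 1
            mi_occ += len(in_group)
            if len(in_group) >= 2:
                mul_sup += 1
            gs = [s for s, p in agg.sample_population.items() if p in gpops]
            read_num += sum(agg.sample_reads[s] for s in gs)
            samples.update(gs)
        sam_num = (
            sum(samples_per_population.get(p, 0) for p in gpops)
            if samples_per_population
            else len(samples)
        )
        occ_per_num, mul_sup_pct, read_per_num = _ratios(mi_num, mi_occ, mul_sup, read_num)
        rows.append(
            dict(population=f"Total {group}", sam_num=sam_num, mi_num=mi_num,
                 mi_occ=mi_occ, mul_sup=mul_sup, read_num=read_num,
                 occ_per_num=occ_per_num, mul_sup_pct=mul_sup_pct,
                 read_per_num=read_per_num)
        )
    return pd.DataFrame(rows)
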