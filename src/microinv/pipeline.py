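"""Per-read detection pipeline: anchoring -> seeding -> segments -> chaining
-> calling, plus cross-read aggregation helpers."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .anchoring import AnchorConfig, AnchorIndex, extract_anchors, place_anchor_pair
from .caller import MICall, call_mis
from .io_core import ReferenceGenome, Read, _rc
from .pathfinder import PathScoreParams, max_score_path
from .seeding import SeedConfig, match_all_seeds, FORWARD, REVERSE
from .segments import SegmentConfig, merge_consecutive_seeds, merge_neighbor_msps, resolve_overlaps

log = logging.getLogger(__name__)


@dataclass
class DetectorConfig:
    anchor: AnchorConfig = field(default_factory=AnchorConfig)
    seed: SeedConfig = field(default_factory=SeedConfig)
    segment: SegmentConfig = field(default_factory=SegmentConfig)
    score: PathScoreParams = field(default_factory=PathScoreParams)
    min_mi_len: int = 15
    refine_breakpoints: bool = True


@dataclass
class ReadReport:
    """Per-read alignment outcome for the detailed report."""

    read_id: str
    status: str  # too_short | unanchored | aligned
    n_placements: int = 0
    best_score: int | None = None
    n_reverse_segments: int = 0
    calls: list[MICall] = field(default_factory=list)


class MicroInversionDetector:
    """End-to-end detector over one reference genome.

    Builds the anchor index once; reads are independent work units, so the
    unique-inversion output never depends on input order.
    """

    def __init__(self, genome: ReferenceGenome, config: DetectorConfig | None = None):
        self.genome = genome
        self.config = config or DetectorConfig()
        self.index = AnchorIndex(genome, self.config.anchor.anchor_len)

    def detect_read(self, read: Read) -> ReadReport:
        cfg = self.config
        anchors = extract_anchors(read, cfg.anchor)
        if anchors is None:
            return ReadReport(read.read_id, "too_short")
        report = ReadReport(read.read_id, "unanchored")
        best_score: int | None = None
        calls: dict[tuple, MICall] = {}
        queries = [read.sequence]
        rc = _rc(read.sequence)
        if rc != read.sequence:
            queries.append(rc)
        for query in queries:
            qread = Read(read.read_id, query, read.sample_id)
            extracted = extract_anchors(qread, cfg.anchor)
            head, tail, read_target_iv = extracted
            placements = place_anchor_pair(
                head, tail, self.index, cfg.anchor, len(query), read_target_iv
            )
            report.n_placements += len(placements)
            read_target = query[read_target_iv[0] : read_target_iv[1]]
            for placement in placements:
                fs, fe = placement.ref_target
                ref_target = self.genome.fetch(placement.contig, fs, fe)
                if ref_target == read_target:
                    # perfect forward alignment; its score is the attainable
                    # maximum and the chain is all-forward, so no call can
                    # come from this placement
                    score = cfg.score.match_weight * len(read_target)
                    if best_score is None or score > best_score:
                        best_score = score
                    report.status = "aligned"
                    continue
                matches = match_all_seeds(read_target, ref_target, cfg.seed)
                msps = merge_consecutive_seeds(
                    [m for m in matches if m.strand == FORWARD],
                    cfg.segment, cfg.seed.k, read_target, ref_target,
                    step=cfg.seed.step,
                ) + merge_consecutive_seeds(
                    [m for m in matches if m.strand == REVERSE],
                    cfg.segment, cfg.seed.k, read_target, ref_target,
                    step=cfg.seed.step,
                )
                msps = merge_neighbor_msps(msps, cfg.segment, read_target, ref_target)
                msps = resolve_overlaps(msps, read_target, ref_target)
                path = max_score_path(msps, cfg.score, len(read_target))
                report.status = "aligned"
                if best_score is None or path.total_score > best_score:
                    best_score = path.total_score
                report.n_reverse_segments += len(path.reverse_msps)
                for call in call_mis(
                    path, placement, read_target, ref_target,
                    read.read_id, read.sample_id,
                    min_mi_len=cfg.min_mi_len,
                    refine=cfg.refine_breakpoints,
                    refine_window=cfg.seed.k,
                ):
                    calls.setdefault(call.interval, call)
        report.best_score = best_score
        report.calls = sorted(calls.values(), key=lambda c: c.interval)
        return report

    def detect(self, reads) -> tuple[list[MICall], dict]:
        """Run every read; returns all read-level calls plus stage counters."""
        stats = {
            "reads_in": 0,
            "too_short": 0,
            "unanchored": 0,
            "aligned": 0,
            "reads_with_calls": 0,
            "calls": 0,
        }
        all_calls: list[MICall] = []
        for read in reads:
            stats["reads_in"] += 1
            rep = self.detect_read(read)
            stats[rep.status] += 1
            if rep.calls:
                stats["reads_with_calls"] += 1
                stats["calls"] += len(rep.calls)
                all_calls.extend(rep.calls)
        return all_calls, stats


def unique_intervals(calls: list[MICall]) -> list[tuple[str, int, int]]:
    return sorted({c.interval for c in calls})
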