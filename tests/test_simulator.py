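import numpy as np
import pytest

from microinv.caller import MICall
from microinv.io_core import reverse_complement
from microinv.simulator import (
    EvalResult,
    PlantedMI,
    SimConfig,
    TruthSet,
    evaluate,
    generate_reads,
    load_truth,
    plant_variants,
    sample_mi_sizes,
    select_candidate_reads,
    synthesize_reference,
    write_truth,
)


def _cfg(**kw):
    base = dict(ref_len=50_000, n_mi=5, coverage=2.0, error_rate=0.0, seed=7,
                mi_min=18)
    base.update(kw)
    return SimConfig(**base)


class TestPlantVariants:
    def test_inversion_windows_are_reverse_complemented(self):
        cfg = _cfg()
        rng = np.random.default_rng(cfg.seed)
        genome = synthesize_reference(cfg.ref_len, 0.41, rng)
        mutated, truth = plant_variants(genome, cfg, rng)
        assert len(truth.mis) == 5
        orig = genome.sequences["sim1"]
        mut = mutated.sequences["sim1"]
        for mi in truth.mis:
            s, e = mi.start - 1, mi.end
            assert mut[s:e] == reverse_complement(orig[s:e])
        # differences are confined to the planted windows
        planted = set()
        for mi in truth.mis:
            planted.update(range(mi.start - 1, mi.end))
        diffs = {i for i, (a, b) in enumerate(zip(orig, mut)) if a != b}
        assert diffs <= planted

    def test_no_variants_identity(self):
        cfg = _cfg(n_mi=0)
        rng = np.random.default_rng(0)
        genome = synthesize_reference(cfg.ref_len, 0.41, rng)
        mutated, truth = plant_variants(genome, cfg, rng)
        assert mutated.sequences == genome.sequences
        assert truth.mis == [] and truth.others == []

    def test_planting_involution(self):
        cfg = _cfg()
        rng = np.random.default_rng(3)
        genome = synthesize_reference(cfg.ref_len, 0.41, rng)
        mutated, truth = plant_variants(genome, cfg, rng)
        seq = mutated.sequences["sim1"]
        for mi in truth.mis:
            s, e = mi.mut_start, mi.mut_end
            seq = seq[:s] + reverse_complement(seq[s:e]) + seq[e:]
        assert seq == genome.sequences["sim1"]

    def test_size_bounds_enforced(self):
        with pytest.raises(ValueError):
            SimConfig(mi_size_mean=50.0)
        sizes = sample_mi_sizes(500, _cfg(), np.random.default_rng(1))
        assert all(18 <= s <= 40 for s in sizes)

    def test_other_variants_recorded(self):
        cfg = SimConfig(ref_len=100_000, n_mi=3, mi_min=18, n_snv=4, n_ins=3,
                        n_del=3, n_dup=2, coverage=1.0, seed=5)
        rng = np.random.default_rng(cfg.seed)
        genome = synthesize_reference(cfg.ref_len, 0.41, rng)
        mutated, truth = plant_variants(genome, cfg, rng)
        kinds = [k for k, _, _ in truth.others]
        assert kinds.count("snv") == 4 and kinds.count("ins") == 3
        assert kinds.count("del") == 3 and kinds.count("dup") == 2
        delta = sum(
            (l if k == "ins" else -l if k == "del" else l if k == "dup" else 0)
            for k, _, l in truth.others
        )
        assert len(mutated.sequences["sim1"]) == cfg.ref_len + delta

    def test_mut_coordinates_track_indel_shifts(self):
        cfg = SimConfig(ref_len=100_000, n_mi=4, mi_min=18, n_ins=5, n_del=5,
                        coverage=1.0, seed=11)
        rng = np.random.default_rng(cfg.seed)
        genome = synthesize_reference(cfg.ref_len, 0.41, rng)
        mutated, truth = plant_variants(genome, cfg, rng)
        orig, mut = genome.sequences["sim1"], mutated.sequences["sim1"]
        for mi in truth.mis:
            assert mut[mi.mut_start : mi.mut_end] == reverse_complement(
                orig[mi.start - 1 : mi.end]
            )


class TestGenerateReads:
    def test_read_pair_count_arithmetic(self):
        cfg = _cfg(ref_len=100_000, coverage=2.0)
        rng = np.random.default_rng(1)
        genome = synthesize_reference(cfg.ref_len, 0.41, rng)
        reads, origins = generate_reads(genome, cfg, rng)
        assert len(reads) == 2 * round(2.0 * 100_000 / (2 * 76)) == len(origins)
        assert all(r.length == 76 for r in reads)

    def test_error_free_reads_are_substrings_or_rc(self):
        cfg = _cfg(ref_len=20_000, coverage=1.0, error_rate=0.0)
        rng = np.random.default_rng(2)
        genome = synthesize_reference(cfg.ref_len, 0.41, rng)
        reads, origins = generate_reads(genome, cfg, rng)
        seq = genome.sequences["sim1"]
        for read, (s, e, strand) in zip(reads[:50], origins[:50]):
            window = seq[s:e]
            assert read.sequence == (window if strand == "+" else reverse_complement(window))

    def test_error_rate_materializes(self):
        cfg = _cfg(ref_len=50_000, coverage=2.0, error_rate=0.02)
        rng = np.random.default_rng(3)
        genome = synthesize_reference(cfg.ref_len, 0.41, rng)
        reads, origins = generate_reads(genome, cfg, rng)
        seq = genome.sequences["sim1"]
        mismatches = bases = 0
        for read, (s, e, strand) in zip(reads, origins):
            window = seq[s:e] if strand == "+" else reverse_complement(seq[s:e])
            mismatches += sum(1 for a, b in zip(read.sequence, window) if a != b)
            bases += read.length
        assert 0.015 < mismatches / bases < 0.025

    def test_seeded_determinism(self):
        cfg = _cfg(ref_len=20_000)
        out = []
        for _ in range(2):
            rng = np.random.default_rng(99)
            genome = synthesize_reference(cfg.ref_len, 0.41, rng)
            reads, origins = generate_reads(genome, cfg, rng)
            out.append(([r.sequence for r in reads], origins))
        assert out[0] == out[1]


class TestSelectCandidates:
    def _setup(self):
        cfg = _cfg(ref_len=50_000, coverage=4.0)
        rng = np.random.default_rng(13)
        genome = synthesize_reference(cfg.ref_len, 0.41, rng)
        mutated, truth = plant_variants(genome, cfg, rng)
        reads, origins = generate_reads(mutated, cfg, rng)
        return reads, origins, truth

    def test_only_overlapping_reads_kept(self):
        reads, origins, truth = self._setup()
        kept, kept_origins = select_candidate_reads(reads, origins, truth)
        ivs = [(mi.mut_start, mi.mut_end) for mi in truth.mis]
        for s, e, _ in kept_origins:
            assert any(s < b and a < e for a, b in ivs)
        dropped = set(id(r) for r in reads) - set(id(r) for r in kept)
        assert dropped  # most reads come from variant-free regions

    def test_pass_through_mode(self):
        reads, origins, truth = self._setup()
        kept, kept_origins = select_candidate_reads(reads, origins, truth, mode="all")
        assert kept == reads and kept_origins == origins


def _call(start, end):
    return MICall("sim1", start, end, "r", "s", 0, end - start + 1, 0)


def _truth_mi(start, end):
    return PlantedMI("sim1", start, end, start - 1, end)


class TestEvaluate:
    def test_perfect_single_call(self):
        truth = TruthSet(mis=[_truth_mi(1001, 1025)])
        origins = [(970, 1046, "+")]  # contains the MI with 18 bp flanks
        res = evaluate([_call(1001, 1025)], truth, origins)
        assert (res.detectable, res.correctly_detected, res.detected) == (1, 1, 1)
        assert res.sn == 1.0 and res.ppv == 1.0
        assert res.breakpoint_exact_fraction == 1.0

    def test_half_overlap_not_correct(self):
        truth = TruthSet(mis=[_truth_mi(1001, 1020)])
        origins = [(970, 1046, "+")]
        res = evaluate([_call(1011, 1030)], truth, origins)
        assert res.correctly_detected == 0 and res.sn == 0.0

    def test_derived_counts_arithmetic(self):
        """10 planted, 8 covered well enough, 7 unique calls of which 6 hit
        distinct planted inversions -> SN 0.75, PPV 6/7."""
        mis = [_truth_mi(1 + 1000 * i, 25 + 1000 * i) for i in range(10)]
        truth = TruthSet(mis=mis)
        origins = [(1000 * i - 30, 1000 * i + 46, "+") for i in range(8)]
        calls = [_call(1 + 1000 * i, 25 + 1000 * i) for i in range(6)]
        calls.append(_call(500_000, 500_024))  # false positive
        res = evaluate(calls, truth, origins)
        assert (res.detectable, res.correctly_detected, res.detected) == (8, 6, 7)
        assert res.sn == 0.75
        assert res.ppv == pytest.approx(6 / 7)

    def test_uncovered_mi_not_detectable(self):
        truth = TruthSet(mis=[_truth_mi(1001, 1025)])
        # read touches the inversion but lacks anchor-length flanks
        res = evaluate([], truth, [(1000, 1076, "+")], flank=18)
        assert res.detectable == 0

    def test_no_detections_gives_undefined_ppv(self):
        truth = TruthSet(mis=[_truth_mi(1001, 1025)])
        res = evaluate([], truth, [(970, 1046, "+")])
        assert res.sn == 0.0 and res.ppv is None

    def test_truth_counted_once_but_all_matching_calls_are_true(self):
        truth = TruthSet(mis=[_truth_mi(1001, 1025)])
        origins = [(970, 1046, "+")]
        res = evaluate([_call(1001, 1025), _call(1000, 1025)], truth, origins)
        # one inversion correctly detected, both call variants are true calls
        assert res.correctly_detected == 1 and res.detected == 2
        assert res.matched_calls == 2 and res.ppv == 1.0
        # the best-overlap variant defines breakpoint exactness
        assert res.breakpoint_exact == 1

    def test_order_invariance(self, rng):
        mis = [_truth_mi(1 + 500 * i, 20 + 500 * i) for i in range(6)]
        truth = TruthSet(mis=mis)
        origins = [(500 * i - 40, 500 * i + 36, "+") for i in range(6)]
        calls = [_call(1 + 500 * i, 20 + 500 * i) for i in range(4)]
        perm = list(calls)
        rng.shuffle(perm)
        a = evaluate(calls, truth, origins)
        b = evaluate(perm, truth, origins)
        assert (a.sn, a.ppv, a.detectable) == (b.sn, b.ppv, b.detectable)


def test_truth_round_trip(tmp_path):
    truth = TruthSet(mis=[_truth_mi(100, 130)], others=[("snv", 5, 1)])
    origins = [(1, 77, "+"), (50, 126, "-")]
    write_truth(truth, origins, tmp_path / "t.json")
    loaded, lorigins = load_truth(tmp_path / "t.json")
    assert loaded.mis == truth.mis
    assert loaded.others == truth.others
    assert lorigins == origins
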