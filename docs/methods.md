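# Methods

## Model and assumptions

`microinv` treats each unmapped read independently as a small local-alignment
problem. A read is assumed to fail end-to-end alignment because a short
segment of it is reverse-complemented relative to the reference, possibly
accompanied by SNVs and small indels. Two assumptions make the search
tractable:

* **Intact flanks.** The first and last `anchor_len` bases of the read are
  assumed collinear with the reference. A read whose inversion extends into
  an anchor beyond the anchor's 1-mismatch budget is invisible to the method;
  this bounds the largest recoverable inversion by
  `read_len − 2·anchor_len + slack` and shapes every sensitivity number below.
* **Ungapped segments.** Within one matching segment pair (MSP) the alignment
  is ungapped (M + MS = span). Indels are carried entirely by the inter-segment
  gap penalty; an indel inside what would otherwise be one segment splits it
  in two.

Chaining uses the segment score `F = 100·M − 100·MS` (minus
`R = 3·(M+MS)²` on the reverse strand), the gap score `0` or `−400 − 30·G`,
and the `T_i` recurrence with terminal gaps; the winning chain must end at a
segment — an instance with no segments at all yields the empty path scored as
one whole-target gap. Within the recurrence the segment's own score applies
on every branch, including the fresh-start branch. G between two chained
segments is the larger of the unaligned read and reference stretches,
order-agnostic on the reference so inverted and translocated segments chain
freely; terminal gaps count unaligned read bases.

Ties in the chain DP are broken toward fewer reverse-strand members, then
fewer members, then leftmost read starts: deterministic output that never
reports an inversion when an equally good inversion-free explanation exists.

## Parameters

| parameter | default | meaning / why |
|---|---|---|
| `anchor_len` | 18 bp | anchor size; ≥ 10 bp needed for near-unique placement on a genome-scale reference |
| `cut_size` | 0 bp | end-trim before anchoring, for degraded read ends |
| `max_anchor_mismatch` | 1 | Hamming tolerance per anchor |
| `slack` | 25 bp | half-width of the allowed anchor inner-distance window; with 76 bp reads gives 15–65 bp |
| `min_mi_len` | 15 bp | smallest reportable inversion; also floors the distance window |
| `k` | 14 bp | seed length |
| `step` | 1 bp | seed stride |
| `max_seed_mismatch` | 2 | per-seed Hamming tolerance; lets seeds cross SNVs |
| `at_gc_fraction` | 1/4 | reverse-seed discard threshold: ≥ ⌈k/4⌉ non-overlapping AT/GC dinucleotides |
| `min_seed_run` | 5 | collinear consecutive seeds needed to keep a segment (non-strict ≥) |
| `merge_dist` | 3 bp | same-diagonal neighbour merge distance (SNV absorption) |
| match / mismatch / gap open / gap extend / reverse coeff | 100 / 100 / 400 / 30 / 3 | chain scoring constants |

Two consequences worth knowing. The run threshold sets a hard detection
floor: an inversion produces `L − k + 1` interior reverse seeds, so with the
defaults only inversions of ≥ 18 bp are callable even though 15 bp ones are
reportable. And the 1/4 AT/GC rule is evaluated on the seed (L = k), counting
non-overlapping occurrences left to right; both the fraction and the
counting are configurable because the rule's constants are genuinely
convention-dependent.

## Reporting rules the scoring forces

Two post-processing steps in the caller exist because the raw optimum is not
directly reportable:

* **Reverse-block coalescing.** R is quadratic, so two abutting collinear
  reverse fragments score strictly more than the same bases as one segment
  (3(L₁²+L₂²) < 3(L₁+L₂)²); whenever overlap resolution offers trimmed
  pieces, the optimizer fragments long inversions. Consecutive collinear
  abutting reverse members of the winning chain are therefore merged back
  into one block before calling. Chain scores are unaffected.
* **Breakpoint refinement.** A 14-mer tolerating 2 mismatches always crosses
  an inversion edge by up to 2 bp, so raw segment ends systematically
  overshoot breakpoints, and partition-and-recombine only offers cut points
  at other segments' endpoints — never exactly at the breakpoint. Each
  reverse block's boundaries are slid (within a seed length) to the split
  maximising per-base agreement, +1/−1, scored in the flanking forward frame
  outside the boundary and the reverse frame inside. Score ties go to the
  smaller inverted span: when the outermost inverted base happens to equal
  the forward base it replaced, the shorter inversion explains the read
  equally well and is the conservative report.

Reads are queried as-is and reverse-complemented (reverse-strand reads);
every anchor placement is processed independently and per-read duplicate
intervals are collapsed. A placement whose reference target equals the read
target verbatim short-circuits: the all-forward full-span chain is already
the attainable maximum and can emit no call.

## The synthetic benchmark

`simulator` emulates the validation design the detector is built for:

* a uniform-random reference (41% GC, human-like); at 1–5 Mb it is
  effectively free of repeated 18-mers, i.e. anchors are unique;
* `n_mi` inversions with truncated-normal sizes (mean 27.5, sd 6, clipped to
  15–40 bp — symmetric over the design range; the full-scale experiment
  states only the range and the normal shape), planted non-overlapping with
  ≥ read-length separation;
* optional confounders split into equal quarters SNV / insertion / deletion /
  tandem duplication (indels 1–10 bp, duplications 15–40 bp);
* 76 bp paired-end reads, insert 250 ± 25 bp, uniform fragment positions and
  strands, independent per-base substitution errors (default 0.02), no
  quality model and no indel errors;
* truth-guided candidate selection (reads overlapping a planted inversion)
  standing in for an aligner's unmapped-read filter, or pass-through-all.

Planted inversions are additionally required to have **unambiguous
breakpoints**: positions where the outermost inverted base coincides with the
forward base it replaces are resampled (about a quarter of random positions),
because there a strictly shorter inversion produces the identical mutated
sequence and "exact breakpoint" truth would be ill-posed.

**Detectability.** An inversion counts as detectable when it lies wholly
inside some read's inner target window, i.e. with at least `anchor_len` read
bases on both sides. This is the geometric precondition for single-read
calling: a read merely overlapping an inversion cannot reveal it, and at 2X
coverage the expected number of capable reads per inversion is well below 1,
so any looser definition makes low-coverage sensitivity a statement about
read placement luck rather than about the detector.

**Scoring calls.** A call matches a planted inversion when their overlap
covers ≥ 80% of both. SN is the fraction of detectable inversions with at
least one matching unique call; PPV is the fraction of unique calls matching
some planted inversion; breakpoint exactness is judged on each inversion's
best-overlap call. SN and PPV numerators are deliberately decoupled: reads in
which an inversion reaches 1–2 bp into an anchor (yet the anchor still
places) yield legitimate truncated views as distinct unique intervals, and
under one-to-one matching these would read as false positives.

**What passing these benchmarks does and does not show.** The synthetic
reference has no repeats, no low-complexity tracts and no N runs, and
candidate selection is optimistic (a real aligner maps away some
inversion-bearing reads and rejects others for unrelated reasons). Results
here therefore bound what the method achieves when anchoring is unique and
every informative read is presented — on real chromosomes both assumptions
fail for a substantial minority of loci, and published full-scale
sensitivities at low coverage are markedly lower (≈ 0.69–0.73 at 2–4X)
than the ≈ 0.88–0.91 measured here, while precision transfers well
(≈ 0.90–0.91 full-scale vs ≈ 0.97–0.98 here). The error-free 10X benchmark
(SN, PPV and exact-breakpoint fraction all 1.0 in the shipped runs) checks
the algorithmic chain end to end, not sequencing reality.

## Numerical and degenerate-input choices

* Internal coordinates are 0-based half-open everywhere; TSV/VCF output is
  1-based inclusive, BED 0-based half-open.
* N matches nothing: anchor words containing N in the genome are unindexed,
  N in seeds or segments counts as mismatch, all-N targets produce no seeds.
* Overlap resolution iterates pairwise cuts to a fixpoint, deduplicating by
  (read interval, reference interval, strand); a safety cap (default 512
  candidates) guards pathological repeat structures, logging when hit.
* Segments must keep at least one matching base (M ≥ 1); zero-length or
  all-mismatch trimmed fragments are dropped.
* Reads shorter than `2·(anchor_len + cut_size) + min_mi_len` are skipped and
  counted, not errors; unanchorable reads simply produce no output.
* PPV is reported as missing (None/null), not 0, when nothing was detected.
* The anchor index packs words into 64-bit integers (anchor_len ≤ 31) over a
  sorted array; approximate lookup enumerates the Hamming neighborhood, so
  `max_anchor_mismatch` beyond 2 gets expensive.

## Problem sizes used in the shipped checks

The test suite and `scripts/acceptance.py` exercise: chaining vs exhaustive
enumeration on 1000 (tests) / 500 (script) random instances of ≤ 8 segments;
partition-and-recombine losslessness on 60 random instances of ≤ 8 segments
against a brute-force trim enumerator; 100 palindrome-bearing reads; 50
inversions in 1 Mb at 10X error-free with all ≈ 131,600 reads processed; and
200 inversions in 5 Mb at 2X and 4X with 2% read errors over three seeds.
These sizes keep a full run in minutes on one CPU while leaving every rate
estimated from hundreds of events.

## Known limitations

* Inversions smaller than `k + min_seed_run − 1` (18 bp at defaults) are
  undetectable; inversions close to the target-window size are only seen by
  reads that bracket them almost exactly.
* One inversion per anchor window: two inversions within the same 40 bp
  target are chained if both leave ≥ 5-seed runs, but nearby heterozygous
  events and inverted duplications are not modelled.
* The unique-inversion identity is exact interval equality; near-identical
  truncated views from edge reads appear as separate table rows (a ±b bp
  clustering hook exists in the aggregator but is off by default).
* No base-quality awareness anywhere; the simulator's error model is
  substitution-only.
* Anchoring is hash-exact Hamming, not an FM-index: memory is ~16 bytes per
  reference base, comfortable to ~100 Mb references but not beyond.
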