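"""Sequence primitives and file I/O shared by the whole pipeline.

Internal coordinates are 0-based half-open everywhere.  Report formats state
their own convention: TSV and VCF are written 1-based inclusive, BED 0-based
half-open.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Iterator

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .caller import MICall

log = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# byte -> 2-bit code; N (and anything unexpected) -> 4
_ENCODE_LUT = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENCODE_LUT[_b] = _i
_DECODE_LUT = np.frombuffer(b"ACGTN", dtype=np.uint8)


class FormatError(ValueError):
    """Raised for malformed or unsupported input files."""


class AlphabetError(ValueError):
    """Raised when a sequence contains characters outside {A,C,G,T,N}."""


def _check_alphabet(seq: str) -> None:
    bad = set(seq) - VALID_BASES
    if bad:
        raise AlphabetError(f"illegal nucleotide characters: {sorted(bad)!r}")


def reverse_complement(seq: str) -> str:
    """Reverse complement of ``seq``; N maps to N. Involution by construction."""
    _check_alphabet(seq)
    return seq.translate(_COMPLEMENT)[::-1]


def _rc(seq: str) -> str:
    # hot-path variant without alphabet validation
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string as uint8 codes A=0 C=1 G=2 T=3 N=4."""
    return _ENCODE_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    return _DECODE_LUT[codes].tobytes().decode("ascii")


@dataclass
class ReferenceGenome:
    """Uppercase reference sequences keyed by contig name."""

    sequences: dict[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.sequences.items():
            bad = set(seq) - VALID_BASES
            if bad:
                raise AlphabetError(
                    f"contig {name!r} contains illegal characters {sorted(bad)!r}"
                )

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.sequences.items()}

    def __contains__(self, contig: str) -> bool:
        return contig in self.sequences

    def fetch(self, contig: str, start: int, end: int) -> str:
        return self.sequences[contig][start:end]


@dataclass(frozen=True)
class Read:
    """One unmapped short read."""

    read_id: str
    sequence: str
    sample_id: str = "sample"

    @property
    def length(self) -> int:
        return len(self.sequence)


def load_reference(path: str | Path) -> ReferenceGenome:
    """Load a FASTA reference; sequences are uppercased, IUPAC ambiguity -> N.

    Raises :class:`FormatError` for empty or non-FASTA input and for duplicate
    contig names.
    """
    from Bio import SeqIO

    path = Path(path)
    text_head = path.open("rb").read(1)
    if not text_head:
        raise FormatError(f"{path}: empty FASTA file")
    if text_head != b">":
        raise FormatError(f"{path}: not a FASTA file (missing '>' header)")
    sequences: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in sequences:
            raise FormatError(f"{path}: duplicate contig name {rec.id!r}")
        seq = str(rec.seq).upper()
        if set(seq) - VALID_BASES:
            seq = "".join(c if c in VALID_BASES else "N" for c in seq)
        sequences[rec.id] = seq
    if not sequences:
        raise FormatError(f"{path}: no FASTA records found")
    return ReferenceGenome(sequences)


def iter_unmapped_reads(
    path: str | Path,
    fmt: str | None = None,
    sample_id: str = "sample",
    stats: dict | None = None,
) -> Iterator[Read]:
    """Yield unmapped reads from FASTQ/SAM/BAM in file order.

    For SAM/BAM only records flagged unmapped are consumed; mapped records are
    skipped and counted in ``stats['skipped_mapped']``.  Records without a
    sequence (``*``) are skipped with a warning.
    """
    import pysam

    path = Path(path)
    if fmt is None:
        suffix = path.suffix.lower()
        fmt = {".fastq": "fastq", ".fq": "fastq", ".sam": "sam", ".bam": "bam"}.get(
            suffix
        )
        if fmt is None:
            raise FormatError(f"cannot infer read format from {path.name!r}")
    fmt = fmt.lower()
    if stats is None:
        stats = {}
    stats.setdefault("skipped_mapped", 0)
    stats.setdefault("skipped_noseq", 0)
    stats.setdefault("yielded", 0)

    if fmt == "fastq":
        with pysam.FastxFile(str(path)) as fx:
            for i, rec in enumerate(fx):
                if rec.sequence is None:
                    raise FormatError(f"{path}: truncated FASTQ record at index {i}")
                stats["yielded"] += 1
                yield Read(rec.name, rec.sequence.upper(), sample_id)
    elif fmt in ("sam", "bam"):
        mode = "rb" if fmt == "bam" else "r"
        with pysam.AlignmentFile(str(path), mode, check_sq=False) as af:
            for rec in af.fetch(until_eof=True):
                if not rec.is_unmapped:
                    stats["skipped_mapped"] += 1
                    continue
                seq = rec.query_sequence
                if seq is None:
                    warnings.warn(
                        f"{path}: unmapped record {rec.query_name!r} has no "
                        "sequence; skipped"
                    )
                    stats["skipped_noseq"] += 1
                    continue
                stats["yielded"] += 1
                yield Read(rec.query_name, seq.upper(), sample_id)
    else:
        raise FormatError(f"unknown read format {fmt!r}")


def load_unmapped_reads(
    path: str | Path,
    fmt: str | None = None,
    sample_id: str = "sample",
    stats: dict | None = None,
) -> list[Read]:
    return list(iter_unmapped_reads(path, fmt, sample_id, stats))


_TSV_COLUMNS = (
    "contig",
    "start",
    "end",
    "length",
    "read_id",
    "sample_id",
    "path_score",
    "matches",
    "mismatches",
)


def write_calls(calls: Iterable["MICall"], path: str | Path, fmt: str = "tsv") -> None:
    """Write micro-inversion calls as TSV (1-based inclusive), BED (0-based
    half-open) or VCF 4.2 (symbolic <INV> with END/SVLEN)."""
    calls = list(calls)
    for c in calls:
        if c.end < c.start:
            raise ValueError(f"call {c.contig}:{c.start}-{c.end} has end < start")
    fmt = fmt.lower()
    path = Path(path)
    with path.open("w") as fh:
        if fmt == "tsv":
            fh.write("#" + "\t".join(_TSV_COLUMNS) + "\n")
            for c in calls:
                fh.write(
                    f"{c.contig}\t{c.start}\t{c.end}\t{c.length}\t{c.read_id}\t"
                    f"{c.sample_id}\t{c.path_score}\t{c.M}\t{c.MS}\n"
                )
        elif fmt == "bed":
            fh.write('track name="micro_inversions"\n')
            for c in calls:
                fh.write(f"{c.contig}\t{c.start - 1}\t{c.end}\t{c.read_id}\n")
        elif fmt == "vcf":
            fh.write("##fileformat=VCFv4.2\n")
            fh.write('##ALT=<ID=INV,Description="Inversion">\n')
            fh.write(
                '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">\n'
                '##INFO=<ID=END,Number=1,Type=Integer,Description="SV end">\n'
                '##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="SV length">\n'
                '##INFO=<ID=READID,Number=1,Type=String,Description="Supporting read">\n'
                '##INFO=<ID=SAMPLE,Number=1,Type=String,Description="Sample">\n'
            )
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
            for c in calls:
                info = (
                    f"SVTYPE=INV;END={c.end};SVLEN={c.length};"
                    f"READID={c.read_id};SAMPLE={c.sample_id}"
                )
                fh.write(f"{c.contig}\t{c.start}\t.\tN\t<INV>\t.\t.\t{info}\n")
        else:
            raise FormatError(f"unknown call format {fmt!r}")


def read_calls(path: str | Path, fmt: str = "tsv") -> list[tuple[str, int, int]]:
    """Parse a call file back to 1-based inclusive (contig, start, end) tuples."""
    fmt = fmt.lower()
    out: list[tuple[str, int, int]] = []
    with Path(path).open() as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if fmt == "tsv":
                out.append((fields[0], int(fields[1]), int(fields[2])))
            elif fmt == "bed":
                out.append((fields[0], int(fields[1]) + 1, int(fields[2])))
            elif fmt == "vcf":
                info = dict(
                    kv.split("=", 1) for kv in fields[7].split(";") if "=" in kv
                )
                out.append((fields[0], int(fields[1]), int(info["END"])))
            else:
                raise FormatError(f"unknown call format {fmt!r}")
    return out
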