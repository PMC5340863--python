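"""Sequence file input, read trimming and per-sample dereplication.

The denoiser operates on one sample at a time.  This module turns a FASTA or
FASTQ file (or a directory of per-sample files) into :class:`SampleReads`
objects, trims reads to a fixed length, and collapses identical reads into
``(sequence, count)`` pairs with singletons removed — the standard
preprocessing for exact-sequence (sub-OTU) inference.
"""

from __future__ import annotations

import gzip
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO

logger = logging.getLogger(__name__)

_VALID_BASES = frozenset("ACGTN")

_FASTA_EXTS = {".fa", ".fasta", ".fna", ".ffn"}
_FASTQ_EXTS = {".fq", ".fastq"}


class SequenceFileError(ValueError):
    """Raised when a sequence file cannot be parsed."""


@dataclass
class SampleReads:
    """Raw reads for one sample.

    qualities (phred+33 strings) are carried through trimming but never used
    by the denoiser itself, which assumes quality filtering happened upstream.
    """

    sample_id: str
    reads: list[str]
    qualities: list[str] | None = None

    def __post_init__(self) -> None:
        for i, r in enumerate(self.reads):
            if not r:
                raise ValueError(f"sample {self.sample_id!r}: read {i} is empty")
            if not set(r) <= _VALID_BASES:
                bad = sorted(set(r) - _VALID_BASES)
                raise ValueError(
                    f"sample {self.sample_id!r}: read {i} contains invalid "
                    f"characters {bad}; alphabet is A/C/G/T/N"
                )
        if self.qualities is not None and len(self.qualities) != len(self.reads):
            raise ValueError("qualities must parallel reads")

    def __len__(self) -> int:
        return len(self.reads)


@dataclass(frozen=True, order=True)
class DereplicatedSeq:
    """A unique sequence and the number of identical reads supporting it."""

    sequence: str
    count: int

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError("count must be positive")


def _open_maybe_gzip(path: Path):
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def _sniff_format(path: Path) -> str:
    stem = path.name[:-3] if path.suffix == ".gz" else path.name
    ext = Path(stem).suffix.lower()
    if ext in _FASTA_EXTS:
        return "fasta"
    if ext in _FASTQ_EXTS:
        return "fastq"
    # fall back to first non-blank character
    with _open_maybe_gzip(path) as fh:
        for line in fh:
            if line.strip():
                return "fastq" if line[0] == "@" else "fasta"
    return "fasta"


def _sample_id_from_path(path: Path) -> str:
    name = path.name
    if name.endswith(".gz"):
        name = name[:-3]
    return Path(name).stem


def _parse_one_file(path: Path) -> SampleReads:
    fmt = _sniff_format(path)
    reads: list[str] = []
    quals: list[str] | None = [] if fmt == "fastq" else None
    sample_id = _sample_id_from_path(path)
    with _open_maybe_gzip(path) as fh:
        records = SeqIO.parse(fh, fmt)
        index = 0
        while True:
            try:
                rec = next(records)
            except StopIteration:
                break
            except ValueError as exc:
                raise SequenceFileError(
                    f"{path}: malformed {fmt} record {index}: {exc}"
                ) from exc
            seq = str(rec.seq).upper()
            if not seq or not set(seq) <= _VALID_BASES:
                raise SequenceFileError(
                    f"{path}: malformed {fmt} record {index}: invalid sequence "
                    f"{seq[:30]!r}"
                )
            reads.append(seq)
            if quals is not None:
                phred = rec.letter_annotations.get("phred_quality", [])
                quals.append("".join(chr(q + 33) for q in phred))
            index += 1
    if not reads:
        logger.warning("%s: no records found; sample %r is empty", path, sample_id)
    return SampleReads(sample_id=sample_id, reads=reads, qualities=quals)


def read_sample_files(path: str | Path) -> list[SampleReads]:
    """Read one FASTA/FASTQ file or a directory of per-sample files.

    In directory mode every FASTA/FASTQ file (optionally gzipped) becomes one
    sample whose id is the file stem.  Read order within a file is preserved
    and N bases are kept; sequences are stored uppercase.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file or directory: {path}")
    if path.is_dir():
        files = sorted(
            p
            for p in path.iterdir()
            if p.is_file() and _sample_id_from_path(p) != p.name  # has an extension
        )
        samples = [_parse_one_file(p) for p in files]
        ids = [s.sample_id for s in samples]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise SequenceFileError(f"{path}: duplicate sample ids {dup}")
        return samples
    return [_parse_one_file(path)]


def trim_reads(sample: SampleReads, length: int) -> SampleReads:
    """Trim every read to its first ``length`` bases; discard shorter reads."""
    if length < 1:
        raise ValueError("trim length must be >= 1")
    reads: list[str] = []
    quals: list[str] | None = [] if sample.qualities is not None else None
    discarded = 0
    for i, r in enumerate(sample.reads):
        if len(r) < length:
            discarded += 1
            continue
        reads.append(r[:length])
        if quals is not None:
            quals.append(sample.qualities[i][:length])
    if discarded:
        logger.info(
            "sample %s: discarded %d/%d reads shorter than %d nt",
            sample.sample_id, discarded, len(sample.reads), length,
        )
    return SampleReads(sample_id=sample.sample_id, reads=reads, qualities=quals)


def dereplicate(sample: SampleReads) -> list[DereplicatedSeq]:
    """Collapse identical reads into counts and drop singletons.

    Output is sorted by count descending, ties broken lexicographically on
    the sequence, making downstream processing order deterministic.
    """
    lengths = {len(r) for r in sample.reads}
    if len(lengths) > 1:
        raise ValueError(
            f"sample {sample.sample_id!r}: reads have unequal lengths "
            f"{sorted(lengths)}; run trim_reads first"
        )
    counts = Counter(sample.reads)
    dereps = [
        DereplicatedSeq(sequence=s, count=c) for s, c in counts.items() if c >= 2
    ]
    dereps.sort(key=lambda d: (-d.count, d.sequence))
    return dereps


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    """Write ``(id, sequence)`` pairs as FASTA."""
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n{seq}\n")


def write_sample_fasta(sample: SampleReads, path: str | Path) -> None:
    write_fasta(
        ((f"{sample.sample_id}_{i}", r) for i, r in enumerate(sample.reads)), path
    )
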