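"""Reference-based artifact depletion via k-mer containment.

Amplicon runs carry non-amplicon reads (spike-ins such as PhiX, host DNA,
adapter dimers).  Before denoising, each dereplicated sequence is screened
against a reference set: in *positive* mode sequences resembling the
reference (e.g. known 16S) are kept, in *negative* mode sequences resembling
it (e.g. known artifacts) are removed.  Resemblance is the fraction of a
query's k-mers found in the reference k-mer set, built over both strands so
the verdict is orientation-independent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

from .seqio import DereplicatedSeq, read_sample_files

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class ReferenceScreen:
    """A double-stranded k-mer index over a reference sequence set."""

    kmers: frozenset[str]
    k: int = 16
    mode: Literal["positive", "negative"] = "negative"
    min_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if not (0.0 < self.min_fraction <= 1.0):
            raise ValueError("min_fraction must be in (0, 1]")
        if self.mode not in ("positive", "negative"):
            raise ValueError("mode must be 'positive' or 'negative'")

    def match_fraction(self, seq: str) -> float:
        """Fraction of the query's distinct k-mers present in the reference."""
        qk = {seq[i : i + self.k] for i in range(len(seq) - self.k + 1)}
        if not qk:
            return 0.0
        return len(qk & self.kmers) / len(qk)

    def matches(self, seq: str) -> bool:
        return self.match_fraction(seq) >= self.min_fraction


def build_screen(
    refs: str | Path | Sequence[str],
    k: int = 16,
    mode: Literal["positive", "negative"] = "negative",
    min_fraction: float = 0.5,
) -> ReferenceScreen:
    """Index a reference FASTA (or sequence list) for screening.

    References shorter than k contribute no k-mers and are skipped with a
    warning; if none is long enough the screen is unusable and an error is
    raised.
    """
    if isinstance(refs, (str, Path)):
        samples = read_sample_files(refs)
        sequences: list[str] = [r for s in samples for r in s.reads]
    else:
        sequences = [s.upper() for s in refs]
    if not sequences:
        raise ValueError("reference set is empty")
    kmers: set[str] = set()
    skipped = 0
    for seq in sequences:
        if len(seq) < k:
            skipped += 1
            continue
        for i in range(len(seq) - k + 1):
            kmers.add(seq[i : i + k])
        rc = reverse_complement(seq)
        for i in range(len(rc) - k + 1):
            kmers.add(rc[i : i + k])
    if skipped:
        logger.warning("%d reference sequences shorter than k=%d skipped", skipped, k)
    if not kmers:
        raise ValueError(f"k={k} exceeds the length of every reference sequence")
    return ReferenceScreen(kmers=frozenset(kmers), k=k, mode=mode, min_fraction=min_fraction)


def screen_sequences(
    seqs: Iterable[DereplicatedSeq], screen: ReferenceScreen
) -> tuple[list[DereplicatedSeq], list[DereplicatedSeq]]:
    """Partition sequences into (kept, removed) under the screen's mode.

    Counts are untouched; kept and removed partition the input exactly.
    """
    kept: list[DereplicatedSeq] = []
    removed: list[DereplicatedSeq] = []
    for d in seqs:
        hit = screen.matches(d.sequence)
        keep = hit if screen.mode == "positive" else not hit
        (kept if keep else removed).append(d)
    return kept, removed
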