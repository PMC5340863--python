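"""Pairwise and center-star multiple alignment for indel detection.

Amplicon reads trimmed to a fixed length differ mostly by substitutions;
the alignment exists so that the rare indel-bearing read pairs can be
recognised and penalised differently by the denoiser.  A center-star
progressive alignment seeded on the most abundant sequence is sufficient for
this purpose and keeps the pipeline self-contained and deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .seqio import DereplicatedSeq

GAP = "-"

#: default alignment scores.  The gap penalty encodes the rare-indel prior
#: of Illumina amplicon data: a genuine indel read aligns against its
#: template with a near-full-length exact run, beating the gapless
#: alignment by ~100 score units, whereas between two unrelated reads
#: (~25% background identity) a shifted alignment only beats gapless via a
#: chance match-count fluctuation.  At gap -60 a spurious shift would need
#: a ~6.5 sigma fluctuation, so unrelated fixed-length reads align
#: gap-free in practice and gap columns mark real indels.
DEFAULT_MATCH = 1.0
DEFAULT_MISMATCH = -1.5
DEFAULT_GAP = -60.0


@dataclass(frozen=True)
class PairDistance:
    """Substitution (Hamming) and indel column counts between aligned reads."""

    substitutions: int
    indel_positions: int


@dataclass
class AlignedWorkspace:
    """Dereplicated, gap-aligned sequences with observed and residual counts.

    This is the state the greedy denoiser mutates: ``counts`` are the
    observed dereplicated abundances and ``residuals`` start equal to them,
    then only ever decrease as predicted error reads are subtracted.
    """

    gapped_sequences: list[str]
    counts: list[int]
    residuals: list[float] = field(default_factory=list)
    sample_id: str = ""

    def __post_init__(self) -> None:
        if not self.residuals:
            self.residuals = [float(c) for c in self.counts]
        lengths = {len(s) for s in self.gapped_sequences}
        if len(lengths) > 1:
            raise ValueError(f"gapped sequences have unequal lengths {sorted(lengths)}")
        if not (len(self.gapped_sequences) == len(self.counts) == len(self.residuals)):
            raise ValueError("gapped_sequences, counts and residuals must be parallel")

    def __len__(self) -> int:
        return len(self.gapped_sequences)

    def ungapped(self, i: int) -> str:
        return self.gapped_sequences[i].replace(GAP, "")


def alignment_score(
    ga: str,
    gb: str,
    match: float = DEFAULT_MATCH,
    mismatch: float = DEFAULT_MISMATCH,
    gap: float = DEFAULT_GAP,
) -> float:
    """Score a finished alignment column by column."""
    if len(ga) != len(gb):
        raise ValueError("gapped lengths differ")
    score = 0.0
    for x, y in zip(ga, gb):
        if x == GAP or y == GAP:
            score += gap
        elif x == y:
            score += match
        else:
            score += mismatch
    return score


def pairwise_align(
    a: str,
    b: str,
    match: float = DEFAULT_MATCH,
    mismatch: float = DEFAULT_MISMATCH,
    gap: float = DEFAULT_GAP,
) -> tuple[str, str]:
    """Global (Needleman–Wunsch) alignment with a deterministic traceback.

    Ties are resolved preferring diagonal, then up (gap in ``b``), then left
    (gap in ``a``), so identical inputs always yield identical alignments.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    if GAP in a or GAP in b:
        raise ValueError("inputs must be gap-free")
    n, m = len(a), len(b)
    H = np.empty((n + 1, m + 1), dtype=np.float64)
    H[0, :] = np.arange(m + 1) * gap
    H[:, 0] = np.arange(n + 1) * gap
    for i in range(1, n + 1):
        ai = a[i - 1]
        prev = H[i - 1]
        row = H[i]
        for j in range(1, m + 1):
            diag = prev[j - 1] + (match if ai == b[j - 1] else mismatch)
            up = prev[j] + gap
            left = row[j - 1] + gap
            row[j] = diag if diag >= up and diag >= left else (up if up >= left else left)
    # traceback, recomputing the achieving move with the tie preference
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = n, m
    while i > 0 or j > 0:
        here = H[i, j]
        if i > 0 and j > 0 and here == H[i - 1, j - 1] + (
            match if a[i - 1] == b[j - 1] else mismatch
        ):
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            i -= 1
            j -= 1
        elif i > 0 and here == H[i - 1, j] + gap:
            out_a.append(a[i - 1])
            out_b.append(GAP)
            i -= 1
        else:
            out_a.append(GAP)
            out_b.append(b[j - 1])
            j -= 1
    return "".join(reversed(out_a)), "".join(reversed(out_b))


def _merge_into_master(
    master_center: str, rows: list[list[str]], gc: str, gs: str
) -> tuple[str, list[str]]:
    """Merge a pairwise (center, new) alignment into the master alignment.

    ``master_center`` and ``gc`` are two gapped spellings of the same center
    sequence; gaps introduced by either are unioned ("once a gap, always a
    gap"), existing rows receive gap columns where the new alignment opens
    them and vice versa.
    """
    merged_center: list[str] = []
    merged_rows: list[list[str]] = [[] for _ in rows]
    new_row: list[str] = []
    i = j = 0
    while i < len(master_center) or j < len(gc):
        mc = master_center[i] if i < len(master_center) else None
        nc = gc[j] if j < len(gc) else None
        if mc is not None and nc is not None and mc != GAP and nc != GAP:
            # same center base in both spellings
            merged_center.append(mc)
            for r, mr in zip(rows, merged_rows):
                mr.append(r[i])
            new_row.append(gs[j])
            i += 1
            j += 1
        elif mc == GAP:
            # gap column already in the master; new sequence gets a gap
            merged_center.append(GAP)
            for r, mr in zip(rows, merged_rows):
                mr.append(r[i])
            new_row.append(GAP)
            i += 1
        else:  # nc == GAP: new alignment opens a column the master lacks
            merged_center.append(GAP)
            for mr in merged_rows:
                mr.append(GAP)
            new_row.append(gs[j])
            j += 1
    return "".join(merged_center), ["".join(r) for r in merged_rows] + ["".join(new_row)]


def center_star_msa(
    seqs: list[DereplicatedSeq],
    sample_id: str = "",
    match: float = DEFAULT_MATCH,
    mismatch: float = DEFAULT_MISMATCH,
    gap: float = DEFAULT_GAP,
) -> AlignedWorkspace:
    """Center-star progressive MSA seeded on the most abundant sequence.

    The center is the highest-count sequence (ties: lexicographically
    smallest); every other sequence is pairwise-aligned to it and the
    pairwise alignments are merged under "once a gap, always a gap".
    """
    if not seqs:
        raise ValueError("need at least one sequence")
    order = sorted(range(len(seqs)), key=lambda i: (-seqs[i].count, seqs[i].sequence))
    center_idx = order[0]
    center = seqs[center_idx].sequence
    master_center = center
    rows = [center]
    placed = [center_idx]
    for idx in order[1:]:
        gc, gs = pairwise_align(center, seqs[idx].sequence, match, mismatch, gap)
        if GAP not in gc:
            # fast path: no new columns; thread the new row through any gap
            # columns the master alignment already carries
            if GAP in master_center:
                out: list[str] = []
                k = 0
                for ch in master_center:
                    if ch == GAP:
                        out.append(GAP)
                    else:
                        out.append(gs[k])
                        k += 1
                rows.append("".join(out))
            else:
                rows.append(gs)
        else:
            master_center, rows = _merge_into_master(
                master_center, [list(r) for r in rows], gc, gs
            )
        placed.append(idx)
    return AlignedWorkspace(
        gapped_sequences=rows,
        counts=[seqs[i].count for i in placed],
        sample_id=sample_id,
    )


def pair_distance(ga: str, gb: str) -> PairDistance:
    """Count substitution and one-sided-gap columns between aligned reads.

    Columns where both members are gaps are ignored; a run of g consecutive
    one-sided gap columns counts as g indel positions.
    """
    if len(ga) != len(gb):
        raise ValueError(f"gapped lengths differ: {len(ga)} vs {len(gb)}")
    subs = 0
    indels = 0
    for x, y in zip(ga, gb):
        xg, yg = x == GAP, y == GAP
        if xg and yg:
            continue
        if xg or yg:
            indels += 1
        elif x != y:
            subs += 1
    return PairDistance(substitutions=subs, indel_positions=indels)


def distance_matrices(gapped: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs (substitution, indel) column counts, vectorised.

    Equivalent to calling :func:`pair_distance` on every pair; used by the
    denoiser where the O(n^2 L) python loop would dominate runtime.
    """
    n = len(gapped)
    if n == 0:
        return np.zeros((0, 0), dtype=np.int64), np.zeros((0, 0), dtype=np.int64)
    arr = np.frombuffer("".join(gapped).encode(), dtype="S1").reshape(n, -1)
    is_gap = arr == b"-"
    subs = np.zeros((n, n), dtype=np.int64)
    indels = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        diff = arr[i] != arr  # (n, L)
        one_gap = is_gap[i] ^ is_gap
        both_base = ~(is_gap[i] | is_gap)
        subs[i] = (diff & both_base).sum(axis=1)
        indels[i] = one_gap.sum(axis=1)
    return subs, indels
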