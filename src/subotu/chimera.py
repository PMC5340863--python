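"""De novo detection of two-parent PCR chimeras among denoised sequences.

A chimera arises when PCR template switching concatenates the prefix of one
real sequence with the suffix of another.  Because chimeras form late in
amplification they are less abundant than their parents, so the detector
only considers parents at an abundance-skew multiple of the query.  A query
is flagged when some parent pair and crossover column reconstruct it (almost)
exactly while each parent alone is clearly different on the segment the
other parent contributes — the latter guard keeps near-identical
parent/query pairs (i.e. sequencing error survivors) from being mislabelled
as chimeras.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .denoise import DenoiseResult


@dataclass
class ChimeraParams:
    """Thresholds of the two-parent crossover test.

    abundance_skew: minimum parent/query count ratio (default 2.0).
    min_parent_diffs: minimum differences between the query and each single
        parent within the segment the *other* parent contributes (default 3).
    max_model_diffs: maximum differences tolerated between the query and the
        best two-parent model (default 0: exact reconstruction).
    """

    abundance_skew: float = 2.0
    min_parent_diffs: int = 3
    max_model_diffs: int = 0

    def __post_init__(self) -> None:
        if self.abundance_skew < 1.0:
            raise ValueError("abundance_skew must be >= 1")
        if self.min_parent_diffs < 0 or self.max_model_diffs < 0:
            raise ValueError("thresholds must be >= 0")


@dataclass
class ChimeraVerdict:
    sequence: str
    is_chimera: bool
    parents: tuple[str, str] | None = None
    crossover: int | None = None

    def __post_init__(self) -> None:
        if self.is_chimera != (self.parents is not None and self.crossover is not None):
            raise ValueError("parents/crossover must be present iff is_chimera")


def _seq_matrix(seqs: list[str]) -> np.ndarray:
    return np.frombuffer("".join(seqs).encode(), dtype="S1").reshape(len(seqs), -1)


def detect_chimeras(
    result: DenoiseResult, params: ChimeraParams | None = None
) -> list[ChimeraVerdict]:
    """Flag chimeric sequences in a denoised sample.

    Queries are processed from least to most abundant; candidate parents are
    unflagged sequences with count >= abundance_skew * query count.  For a
    parent pair (P1, P2) and crossover column x the model is
    ``P1[:x] + P2[x:]``; the first qualifying (P1, P2, x) — parents in
    descending abundance, x leftmost — determines the verdict, so results
    are deterministic.  Flagged sequences leave the parent pool, preventing
    chimeras of chimeras from serving as parents.
    """
    params = params or ChimeraParams()
    entries = list(result.retained)
    if not entries:
        return []
    lengths = {len(s) for s, _ in entries}
    if len(lengths) > 1:
        raise ValueError(
            f"sequences must have equal length for chimera detection; saw {sorted(lengths)}"
        )
    L = lengths.pop()

    # ascending-abundance processing order; descending order for parent scans
    asc = sorted(range(len(entries)), key=lambda i: (entries[i][1], entries[i][0]))
    desc = sorted(range(len(entries)), key=lambda i: (-entries[i][1], entries[i][0]))
    seqs = [s for s, _ in entries]
    counts = np.array([c for _, c in entries], dtype=np.float64)
    mat = _seq_matrix(seqs)

    flagged = np.zeros(len(entries), dtype=bool)
    verdicts: dict[int, ChimeraVerdict] = {}
    for qi in asc:
        q = mat[qi]
        verdict = ChimeraVerdict(sequence=seqs[qi], is_chimera=False)
        pool = [
            pi
            for pi in desc
            if pi != qi
            and not flagged[pi]
            and counts[pi] >= params.abundance_skew * counts[qi]
        ]
        # per-parent prefix diff counts against the query
        prefix = {pi: np.concatenate(([0], np.cumsum(mat[pi] != q))) for pi in pool}
        found = False
        for p1 in pool:
            if found:
                break
            d1 = prefix[p1]
            total1 = d1[L]
            for p2 in pool:
                if p2 == p1:
                    continue
                d2 = prefix[p2]
                total2 = d2[L]
                # crossover x in 1..L-1: model = P1[:x] + P2[x:]
                x = np.arange(1, L)
                model_diffs = d1[x] + (total2 - d2[x])
                p1_alone = total1 - d1[x]  # P1 vs query on P2's segment
                p2_alone = d2[x]           # P2 vs query on P1's segment
                ok = (
                    (model_diffs <= params.max_model_diffs)
                    & (p1_alone >= params.min_parent_diffs)
                    & (p2_alone >= params.min_parent_diffs)
                )
                if ok.any():
                    xstar = int(x[np.argmax(ok)])
                    verdict = ChimeraVerdict(
                        sequence=seqs[qi],
                        is_chimera=True,
                        parents=(seqs[p1], seqs[p2]),
                        crossover=xstar,
                    )
                    flagged[qi] = True
                    found = True
                    break
        verdicts[qi] = verdict
    return [verdicts[i] for i in range(len(entries))]


def remove_chimeras(
    result: DenoiseResult, verdicts: list[ChimeraVerdict]
) -> DenoiseResult:
    """Drop flagged sequences; counts of the survivors are unchanged."""
    flagged = {v.sequence for v in verdicts if v.is_chimera}
    retained = [(s, c) for s, c in result.retained if s not in flagged]
    removed = list(result.removed) + [s for s, _ in result.retained if s in flagged]
    return DenoiseResult(retained=retained, removed=removed)
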