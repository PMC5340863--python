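"""The greedy sub-OTU denoising core.

The model: a true template sequence read N times spawns error-derived reads
at Hamming distance h from itself.  An upper-bound error profile E[h] bounds
the expected fraction of reads landing at each distance, and the observed
abundance of a candidate template is scaled up by 1/(1-mean_error)^L — the
reciprocal probability that a read of length L is error-free — to estimate
how many reads it presented to the sequencer.  Walking candidates from most
to least abundant, each subtracts its predicted error reads from every
neighbour; whatever abundance survives is considered real.

Because E is an upper bound, the subtraction over-corrects: it can only
remove sequences, never invent them, so every output sequence was observed
and every output count is at most its observed count.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .alignment import AlignedWorkspace, distance_matrices

logger = logging.getLogger(__name__)


@dataclass
class ErrorProfile:
    """Upper-bound probabilities of a read landing at Hamming distance h.

    ``upper_bounds[h]`` bounds the fraction of a template's reads observed at
    distance h; ``upper_bounds[0]`` is 1 by convention (the self term is
    never applied).  Values must be non-increasing for h >= 1; distances past
    the last bin reuse the last value.
    """

    upper_bounds: np.ndarray

    def __post_init__(self) -> None:
        e = np.asarray(self.upper_bounds, dtype=np.float64)
        if e.ndim != 1 or e.size < 1:
            raise ValueError("error profile must be a non-empty 1-D vector")
        if np.any(e < 0) or np.any(e > 1):
            raise ValueError("error profile values must be probabilities in [0, 1]")
        if e[0] != 1.0:
            logger.warning(
                "error profile E[0]=%g overridden to 1 (self term is never applied)",
                e[0],
            )
            e = e.copy()
            e[0] = 1.0
        if e.size > 2 and np.any(np.diff(e[1:]) > 1e-12):
            raise ValueError("error profile must be non-increasing for h >= 1")
        self.upper_bounds = e

    @property
    def max_h(self) -> int:
        return self.upper_bounds.size - 1

    def at(self, h: int | np.ndarray) -> np.ndarray:
        """E[min(h, H)] — distances beyond the profile reuse the last bin."""
        return self.upper_bounds[np.minimum(h, self.max_h)]


#: shipped default profile for h = 1..12.  This is a configuration default
#: reflecting typical Illumina amplicon error mass at increasing Hamming
#: distances; studies with calibrated profiles should load their own via
#: :func:`load_error_profile`.
DEFAULT_ERROR_PROFILE = ErrorProfile(
    np.array(
        [1.0, 0.06, 0.02, 0.02, 0.01, 0.005, 0.005, 0.005,
         0.001, 0.001, 0.001, 0.0005, 0.0005]
    )
)


@dataclass
class DenoiseParams:
    """Scalar parameters of the error model.

    mean_error: mean per-nucleotide read error rate used for abundance
        normalisation (default 0.5%).
    indel_prob: maximal probability of an indel-bearing error read
        (default 0.01); applied once to any neighbour pair separated by
        1..indel_max one-sided gap columns.
    indel_max: neighbours separated by more gap columns than this are not
        considered error-derived at all (default 3).
    read_length: ungapped trimmed read length L; if None it is taken from
        the workspace.
    """

    mean_error: float = 0.005
    indel_prob: float = 0.01
    indel_max: int = 3
    read_length: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.mean_error <= 1.0 and 0.0 <= self.indel_prob <= 1.0):
            raise ValueError("probabilities must be in [0, 1]")
        if self.indel_max < 0:
            raise ValueError("indel_max must be >= 0")
        if self.read_length is not None and self.read_length < 1:
            raise ValueError("read_length must be >= 1")


@dataclass
class DenoiseResult:
    """Sequences that survive the subtraction, with their output counts."""

    retained: list[tuple[str, int]]
    removed: list[str] = field(default_factory=list)

    @property
    def sequences(self) -> list[str]:
        return [s for s, _ in self.retained]

    def total(self) -> int:
        return sum(c for _, c in self.retained)


def mod_factor(params: DenoiseParams, read_length: int | None = None) -> float:
    """(1 - mean_error)^L: the probability a read of length L is error-free.

    Dividing an observed abundance by this factor scales it up to the implied
    number of reads the template presented to the sequencer.
    """
    L = params.read_length if read_length is None else read_length
    if L is None:
        raise ValueError("read_length not set")
    return (1.0 - params.mean_error) ** L


def predicted_errors(
    residual: float,
    profile: ErrorProfile,
    params: DenoiseParams,
    max_h: int | None = None,
) -> np.ndarray:
    """Predicted number of error reads at each Hamming distance h = 0..max_h."""
    if residual <= 0:
        raise ValueError("residual must be positive; zeroed sequences are not sources")
    hmax = profile.max_h if max_h is None else max_h
    h = np.arange(hmax + 1)
    return residual * profile.at(h) / mod_factor(params)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def denoise_sample(
    ws: AlignedWorkspace,
    profile: ErrorProfile = DEFAULT_ERROR_PROFILE,
    params: DenoiseParams | None = None,
) -> DenoiseResult:
    """Greedy abundance-ordered subtraction of predicted error reads.

    Sequences are visited once in descending observed-count order (ties:
    lexicographic on the ungapped sequence, fixed up front).  Each source
    with positive residual subtracts ``residual * E[h] / (1-mean_error)^L``
    from every neighbour at substitution distance h, damped by
    ``indel_prob`` when the pair is separated by 1..indel_max gap columns and
    skipped entirely beyond ``indel_max``.  A neighbour whose residual drops
    to or below zero is removed and never acts as a source.  Output counts
    are the residuals rounded half-up; sequences rounding to zero are
    dropped.
    """
    params = params or DenoiseParams()
    n = len(ws)
    if n == 0:
        return DenoiseResult(retained=[], removed=[])
    seqs = [ws.ungapped(i) for i in range(n)]
    L = params.read_length if params.read_length is not None else len(seqs[0])
    eff = DenoiseParams(
        mean_error=params.mean_error,
        indel_prob=params.indel_prob,
        indel_max=params.indel_max,
        read_length=L,
    )
    M = mod_factor(eff)
    subs, indels = distance_matrices(ws.gapped_sequences)
    E_at = profile.at(subs)  # (n, n) upper bounds at each pair's distance

    order = sorted(range(n), key=lambda i: (-ws.counts[i], seqs[i]))
    r = np.asarray(ws.residuals, dtype=np.float64).copy()
    for i in order:
        if r[i] <= 0:
            continue  # removed sequences never act as sources
        penalty = r[i] * E_at[i] / M
        gapped_pair = indels[i] >= 1
        penalty = np.where(gapped_pair, penalty * eff.indel_prob, penalty)
        penalty[indels[i] > eff.indel_max] = 0.0
        penalty[i] = 0.0  # no self-subtraction
        r -= penalty

    retained: list[tuple[str, int]] = []
    removed: list[str] = []
    for i in range(n):
        out = _round_half_up(r[i])
        if out >= 1:
            retained.append((seqs[i], out))
        else:
            removed.append(seqs[i])
    return DenoiseResult(retained=retained, removed=removed)


def load_error_profile(path: str | Path) -> ErrorProfile:
    """Load an error profile from a whitespace-delimited text table.

    Accepts one value per line (implicit h = 0, 1, ...), all values on one
    line, or two columns ``h value``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"error profile not found: {path}")
    rows: list[list[float]] = []
    for lineno, line in enumerate(path.read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        try:
            rows.append([float(tok) for tok in line.split()])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: not numeric: {line!r}") from exc
    if not rows:
        raise ValueError(f"{path}: empty error profile")
    if len(rows) == 1:
        values = rows[0]
    elif all(len(row) == 2 for row in rows):
        by_h = {int(h): v for h, v in rows}
        if sorted(by_h) != list(range(len(by_h))):
            raise ValueError(f"{path}: two-column profile must cover h = 0..H")
        values = [by_h[h] for h in sorted(by_h)]
    elif all(len(row) == 1 for row in rows):
        values = [row[0] for row in rows]
    else:
        raise ValueError(f"{path}: expected 1 or 2 columns per line")
    return ErrorProfile(np.asarray(values, dtype=np.float64))
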