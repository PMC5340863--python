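"""Simulation and evaluation apparatus for the denoiser.

Provides a minimal Illumina-like amplicon read simulator (position-
independent substitutions at ~0.1%/nt plus rare indels), ground-truth
scoring of denoised output, technical-replicate stability curves,
unweighted UniFrac between samples on a rooted tree, and a deterministic
UPGMA dendrogram over Hamming distances.  Together these reproduce the
standard validation designs for exact-sequence denoisers: parameter
recovery, degradation as community sequences become more similar, and
integration of independently processed sequencing runs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode
from skbio.diversity import beta_diversity

from .denoise import DenoiseResult
from .seqio import SampleReads
from .table import FeatureTable

_ALPHABET = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class TruthCommunity:
    """Ground truth for simulation: sequences and relative abundances."""

    sequences: list[str]
    rel_abundances: np.ndarray
    similarity_radius: int | None = None

    def __post_init__(self) -> None:
        self.rel_abundances = np.asarray(self.rel_abundances, dtype=np.float64)
        if len(self.sequences) != self.rel_abundances.size:
            raise ValueError("sequences and abundances must be parallel")
        if len(set(self.sequences)) != len(self.sequences):
            raise ValueError("truth sequences must be unique")
        if abs(self.rel_abundances.sum() - 1.0) > 1e-9:
            raise ValueError("relative abundances must sum to 1")

    def __len__(self) -> int:
        return len(self.sequences)


@dataclass
class SimParams:
    """Read-simulator error model parameters.

    Defaults reflect Illumina amplicon sequencing: 0.1% substitutions per
    nucleotide and indels two orders of magnitude rarer.
    """

    n_reads: int = 10000
    sub_rate: float = 0.001
    ins_rate: float = 0.00005
    del_rate: float = 0.00005
    seed: int = 0

    def __post_init__(self) -> None:
        for r in (self.sub_rate, self.ins_rate, self.del_rate):
            if not (0.0 <= r < 1.0):
                raise ValueError("rates must be in [0, 1)")
        if self.n_reads < 0:
            raise ValueError("n_reads must be >= 0")


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(["A", "C", "G", "T"], size=length))


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def make_truth_community(
    k: int,
    length: int,
    min_hamming: int,
    abundance_model: str = "uniform",
    seed: int = 0,
    max_tries: int = 10000,
    min_rel_abundance: float = 0.005,
) -> TruthCommunity:
    """Draw k sequences whose pairwise Hamming distances sit at >= min_hamming.

    The community is a star phylogeny around a random ancestor: member i
    carries m_i random substitutions with m_i drawn uniformly from
    [ceil(min_hamming/2), 2*ceil(min_hamming/2)], so the *minimum* pairwise
    distance sits at the radius while typical distances are larger
    (candidates violating the floor are rejection-sampled away).  This makes
    ``min_hamming`` a true similarity radius — communities at a small radius
    genuinely contain near-identical members, the regime where denoisers
    start merging real sequences — rather than a vacuous lower bound that
    unrelated random sequences exceed a hundredfold.  Abundances are equal
    ("uniform", an even community) or lognormal(0, 1) normalized
    ("lognormal", the standard rank-abundance model for real communities).
    Lognormal draws are resampled until every member is at or above
    ``min_rel_abundance`` (default 0.5%): like mock designs built from the
    most abundant taxa of a real community, the truth excludes members too
    rare to be detectable — an upper-bound subtracter removes a fraction
    ~E_last/(1-mean_error)^L (~0.1%) of total reads from every sequence, so
    members below roughly twice that are undetectable by construction.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if min_hamming > length:
        raise ValueError("min_hamming cannot exceed the sequence length")
    rng = np.random.default_rng(seed)
    ancestor = _random_seq(rng, length)
    m_min = max(1, -(-min_hamming // 2))  # ceil; >= 1 so members are distinct
    seqs: list[str] = []
    tries = 0
    while len(seqs) < k:
        if tries >= max_tries:
            raise RuntimeError(
                f"could not place {k} sequences of length {length} with pairwise "
                f"Hamming >= {min_hamming} after {max_tries} tries"
            )
        tries += 1
        n_mut = int(rng.integers(m_min, min(2 * m_min, length) + 1))
        positions = rng.choice(length, size=n_mut, replace=False)
        cand_list = list(ancestor)
        for p in positions:
            alternatives = [b for b in "ACGT" if b != cand_list[p]]
            cand_list[p] = alternatives[rng.integers(0, 3)]
        cand = "".join(cand_list)
        if all(_hamming(cand, s) >= min_hamming for s in seqs):
            seqs.append(cand)
    if abundance_model == "uniform":
        ab = np.full(k, 1.0 / k)
    elif abundance_model == "lognormal":
        if min_rel_abundance * k >= 1.0:
            raise ValueError("min_rel_abundance infeasible for this k")
        for _ in range(max_tries):
            ab = rng.lognormal(mean=0.0, sigma=1.0, size=k)
            ab = ab / ab.sum()
            if ab.min() >= min_rel_abundance:
                break
        else:
            raise RuntimeError(
                f"no lognormal draw with all members >= {min_rel_abundance} "
                f"in {max_tries} tries"
            )
    else:
        raise ValueError("abundance_model must be 'uniform' or 'lognormal'")
    return TruthCommunity(sequences=seqs, rel_abundances=ab, similarity_radius=min_hamming)


def simulate_reads(
    truth: TruthCommunity, params: SimParams, sample_id: str = "sim"
) -> SampleReads:
    """Simulate error-prone amplicon reads from a truth community.

    Each read draws its source per the relative abundances; every position
    is substituted (uniformly to one of the 3 other bases) with probability
    ``sub_rate``; insertions and deletions are applied per position at their
    own rates, so reads are emitted at their natural (possibly shifted)
    length — downstream trimming restores a fixed length.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_reads
    if n == 0:
        return SampleReads(sample_id=sample_id, reads=[])
    L = len(truth.sequences[0])
    src_mat = np.stack(
        [np.frombuffer(s.encode(), dtype="S1") for s in truth.sequences]
    )
    src_idx = rng.choice(len(truth), size=n, p=truth.rel_abundances)
    reads_mat = src_mat[src_idx].copy()  # (n, L)

    # substitutions, vectorised: shift the base by 1..3 in alphabet order
    sub_mask = rng.random((n, L)) < params.sub_rate
    if sub_mask.any():
        base_codes = np.searchsorted(_ALPHABET, reads_mat.ravel()).reshape(n, L)
        shifts = rng.integers(1, 4, size=int(sub_mask.sum()))
        flat = base_codes[sub_mask]
        base_codes[sub_mask] = (flat + shifts) % 4
        reads_mat = _ALPHABET[base_codes]

    # indels are rare: rework only the affected reads
    ins_mask = rng.random((n, L)) < params.ins_rate
    del_mask = rng.random((n, L)) < params.del_rate
    touched = np.flatnonzero(ins_mask.any(axis=1) | del_mask.any(axis=1))
    reads = [row.tobytes().decode() for row in reads_mat]
    for i in touched:
        out: list[str] = []
        base_row = reads[i]
        for p in range(L):
            if ins_mask[i, p]:
                out.append("ACGT"[rng.integers(0, 4)])
            if not del_mask[i, p]:
                out.append(base_row[p])
        reads[i] = "".join(out) if out else base_row
    return SampleReads(sample_id=sample_id, reads=reads)


@dataclass
class TruthMetrics:
    recall: float
    precision: float
    observed_ratio: float
    abundance_estimates: dict[str, float]
    empty_output: bool = False


def score_against_truth(result: DenoiseResult, truth: TruthCommunity) -> TruthMetrics:
    """Recall/precision of the retained set against the truth set.

    Truth sequences are compared at the retained read length (prefix
    truncation), since the pipeline trims reads before denoising.
    """
    retained = result.sequences
    if retained:
        L = len(retained[0])
        truth_set = {s[:L] for s in truth.sequences}
    else:
        truth_set = set(truth.sequences)
    retained_set = set(retained)
    hits = retained_set & truth_set
    total_out = result.total()
    estimates = {
        s: (c / total_out if total_out else 0.0)
        for s, c in result.retained
        if s in truth_set
    }
    if not retained_set:
        return TruthMetrics(0.0, 0.0, 0.0, {}, empty_output=True)
    return TruthMetrics(
        recall=len(hits) / len(truth_set),
        precision=len(hits) / len(retained_set),
        observed_ratio=len(retained_set) / len(truth_set),
        abundance_estimates=estimates,
    )


def stability_overlap(
    t1: FeatureTable, t2: FeatureTable, min_freq_grid: Sequence[int]
) -> pd.DataFrame:
    """Replicate overlap as a function of a minimum-frequency threshold.

    For each threshold f, the fraction of features with total count >= f in
    one replicate that are present (count >= 1) in the other; reported in
    both directions.  High-abundance features of a stable method should be
    recovered by both replicates, driving the curve to 1 as f grows.
    """
    tot1 = dict(zip(t1.feature_ids, t1.feature_totals()))
    tot2 = dict(zip(t2.feature_ids, t2.feature_totals()))
    present1 = {f for f, c in tot1.items() if c >= 1}
    present2 = {f for f, c in tot2.items() if c >= 1}
    rows = []
    for f in min_freq_grid:
        sel1 = [x for x, c in tot1.items() if c >= f]
        sel2 = [x for x, c in tot2.items() if c >= f]
        fwd = sum(1 for x in sel1 if x in present2) / len(sel1) if sel1 else float("nan")
        rev = sum(1 for x in sel2 if x in present1) / len(sel2) if sel2 else float("nan")
        rows.append({"threshold": f, "overlap_1_in_2": fwd, "overlap_2_in_1": rev})
    return pd.DataFrame(rows)


def unweighted_unifrac(t: FeatureTable, tree: TreeNode) -> DistanceMatrix:
    """Pairwise unweighted UniFrac distances between the table's samples.

    Presence is count >= 1.  Every feature with a nonzero count must be a
    leaf of the rooted tree; the distance between two samples is the branch
    length unique to either sample's leaf set divided by the branch length
    observed in their union.
    """
    observed = [
        f for f, tot in zip(t.feature_ids, t.feature_totals()) if tot >= 1
    ]
    leaf_names = {tip.name for tip in tree.tips()}
    missing = [f for f in observed if f not in leaf_names]
    if missing:
        raise ValueError(
            f"{len(missing)} feature(s) missing from the tree, e.g. {missing[0]!r}"
        )
    if not observed:
        return DistanceMatrix(np.zeros((len(t.sample_ids),) * 2), ids=t.sample_ids)
    cols = [t.feature_ids.index(f) for f in observed]
    counts = t.counts[:, cols]
    return beta_diversity(
        "unweighted_unifrac",
        counts,
        ids=t.sample_ids,
        taxa=observed,
        tree=tree,
    )


def hamming_upgma(seqs: Sequence[str]) -> TreeNode:
    """UPGMA dendrogram over pairwise Hamming distances, leaves = sequences.

    Average-linkage agglomeration with a deterministic tie-break: among
    minimum-distance cluster pairs, merge the pair whose (lexicographically
    smallest member, then second member) sorts first.  Branch lengths are
    ultrametric height differences.
    """
    seqs = list(seqs)
    if len(seqs) < 2:
        raise ValueError("need at least two sequences")
    if len({len(s) for s in seqs}) != 1:
        raise ValueError("sequences must have equal length")
    if len(set(seqs)) != len(seqs):
        raise ValueError("sequences must be unique")

    nodes: dict[int, TreeNode] = {}
    heights: dict[int, float] = {}
    sizes: dict[int, int] = {}
    minlabel: dict[int, str] = {}
    dist: dict[tuple[int, int], float] = {}
    for i, s in enumerate(seqs):
        nodes[i] = TreeNode(name=s)
        heights[i] = 0.0
        sizes[i] = 1
        minlabel[i] = s
    for i in range(len(seqs)):
        for j in range(i + 1, len(seqs)):
            dist[(i, j)] = float(_hamming(seqs[i], seqs[j]))

    active = set(range(len(seqs)))
    next_id = len(seqs)
    while len(active) > 1:
        best = min(
            (
                (dist[(min(i, j), max(i, j))], *sorted((minlabel[i], minlabel[j])), i, j)
                for i in active
                for j in active
                if i < j
            ),
        )
        d, _, _, i, j = best
        if minlabel[j] < minlabel[i]:
            i, j = j, i  # canonical child order: smallest leaf label first
        h = d / 2.0
        left, right = nodes[i], nodes[j]
        left.length = h - heights[i]
        right.length = h - heights[j]
        parent = TreeNode(children=[left, right])
        for k in active - {i, j}:
            dik = dist[(min(i, k), max(i, k))]
            djk = dist[(min(j, k), max(j, k))]
            dnew = (sizes[i] * dik + sizes[j] * djk) / (sizes[i] + sizes[j])
            dist[(min(next_id, k), max(next_id, k))] = dnew
        nodes[next_id] = parent
        heights[next_id] = h
        sizes[next_id] = sizes[i] + sizes[j]
        minlabel[next_id] = min(minlabel[i], minlabel[j])
        active -= {i, j}
        active.add(next_id)
        next_id += 1
    root = nodes[active.pop()]
    root.length = None
    return root


def read_newick(path: str | Path) -> TreeNode:
    """Read a rooted Newick tree, reporting the offset of unbalanced parens."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such tree file: {path}")
    text = path.read_text()
    depth = 0
    for offset, ch in enumerate(text):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise ValueError(
                    f"{path}: unbalanced ')' at character offset {offset}"
                )
    if depth != 0:
        raise ValueError(
            f"{path}: {depth} unclosed '(' by character offset {len(text)}"
        )
    try:
        return TreeNode.read(str(path), format="newick")
    except Exception as exc:  # skbio raises its own format error hierarchy
        raise ValueError(f"{path}: malformed newick: {exc}") from exc


def write_newick(tree: TreeNode, path: str | Path) -> None:
    tree.write(str(path), format="newick")
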