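"""Independent brute-force oracles used by the test suite.

Everything here is written from the contracts alone, in the most direct
way possible (loops, enumeration, explicit set construction), so that the
optimised implementations in the package can be checked against code that
shares none of their structure.
"""

from __future__ import annotations

import math


# ---------------------------------------------------------------------------
# alignment

def enumerate_alignments(a: str, b: str):
    """Yield every global alignment of a and b as (ga, gb) pairs."""
    if not a and not b:
        yield "", ""
        return
    if a:
        for ga, gb in enumerate_alignments(a[1:], b):
            yield a[0] + ga, "-" + gb
    if b:
        for ga, gb in enumerate_alignments(a, b[1:]):
            yield "-" + ga, b[0] + gb
    if a and b:
        for ga, gb in enumerate_alignments(a[1:], b[1:]):
            yield a[0] + ga, b[0] + gb


def best_alignment_score(a: str, b: str, match: float, mismatch: float, gap: float) -> float:
    best = -math.inf
    for ga, gb in enumerate_alignments(a, b):
        score = 0.0
        for x, y in zip(ga, gb):
            if x == "-" or y == "-":
                score += gap
            elif x == y:
                score += match
            else:
                score += mismatch
        best = max(best, score)
    return best


def scan_pair_distance(ga: str, gb: str) -> tuple[int, int]:
    """Column-by-column substitution / one-sided-gap count."""
    subs = indels = 0
    for x, y in zip(ga, gb):
        if x == "-" and y == "-":
            continue
        if x == "-" or y == "-":
            indels += 1
        elif x != y:
            subs += 1
    return subs, indels


# ---------------------------------------------------------------------------
# greedy subtraction

def brute_force_denoise(
    gapped: list[str],
    counts: list[int],
    profile: list[float],
    mean_error: float,
    indel_prob: float,
    indel_max: int,
    read_length: int,
) -> tuple[list[tuple[str, int]], list[str]]:
    """Loop-based re-statement of the greedy subtraction contract.

    Fixed descending-count order (ties: lexicographic on the ungapped
    sequence); each positive-residual source subtracts
    residual * E[min(h, H)] / (1 - mean_error)^L from every other sequence,
    damped by indel_prob for 1..indel_max one-sided gap columns and skipped
    beyond; outputs are residuals rounded half-up, >= 1 retained.
    """
    n = len(gapped)
    seqs = [g.replace("-", "") for g in gapped]
    mod = (1.0 - mean_error) ** read_length
    order = sorted(range(n), key=lambda i: (-counts[i], seqs[i]))
    resid = [float(c) for c in counts]
    for i in order:
        if resid[i] <= 0:
            continue
        for j in range(n):
            if j == i:
                continue
            h, g = scan_pair_distance(gapped[i], gapped[j])
            if g > indel_max:
                continue
            pen = resid[i] * profile[min(h, len(profile) - 1)] / mod
            if g >= 1:
                pen *= indel_prob
            resid[j] -= pen
    retained = []
    removed = []
    for i in range(n):
        out = int(math.floor(resid[i] + 0.5))
        if out >= 1:
            retained.append((seqs[i], out))
        else:
            removed.append(seqs[i])
    return retained, removed


# ---------------------------------------------------------------------------
# chimeras

def brute_force_chimera_flags(
    entries: list[tuple[str, int]],
    abundance_skew: float,
    min_parent_diffs: int,
    max_model_diffs: int,
) -> dict[str, bool]:
    """Exhaustive scan over every (P1, P2, x) in the contract's order."""
    asc = sorted(range(len(entries)), key=lambda i: (entries[i][1], entries[i][0]))
    flagged: set[int] = set()
    out: dict[str, bool] = {}
    for qi in asc:
        q, qc = entries[qi]
        L = len(q)
        pool = sorted(
            (
                pi
                for pi in range(len(entries))
                if pi != qi
                and pi not in flagged
                and entries[pi][1] >= abundance_skew * qc
            ),
            key=lambda i: (-entries[i][1], entries[i][0]),
        )
        hit = False
        for p1 in pool:
            if hit:
                break
            s1 = entries[p1][0]
            for p2 in pool:
                if hit:
                    break
                if p2 == p1:
                    continue
                s2 = entries[p2][0]
                for x in range(1, L):
                    model = s1[:x] + s2[x:]
                    model_diffs = sum(a != b for a, b in zip(model, q))
                    if model_diffs > max_model_diffs:
                        continue
                    p1_alone = sum(a != b for a, b in zip(s1[x:], q[x:]))
                    p2_alone = sum(a != b for a, b in zip(s2[:x], q[:x]))
                    if p1_alone >= min_parent_diffs and p2_alone >= min_parent_diffs:
                        hit = True
                        break
        if hit:
            flagged.add(qi)
        out[q] = hit
    return out


# ---------------------------------------------------------------------------
# unweighted UniFrac via explicit branch sets

def branch_set_unifrac(tree, presence_a: set[str], presence_b: set[str]) -> float:
    """Unique / observed branch length via explicit root-to-leaf edge sets.

    ``tree`` is an skbio TreeNode; presence sets are leaf names.
    """

    def edges_to(leaves: set[str]):
        edges = set()
        for tip in tree.tips():
            if tip.name not in leaves:
                continue
            node = tip
            while node.parent is not None:
                edges.add(id(node))
                node = node.parent
        return edges

    ea, eb = edges_to(presence_a), edges_to(presence_b)
    by_id = {id(n): n for n in tree.traverse() if n.parent is not None}
    union = sum(by_id[e].length or 0.0 for e in ea | eb)
    unique = sum(by_id[e].length or 0.0 for e in ea ^ eb)
    if union == 0:
        return 0.0
    return unique / union


# ---------------------------------------------------------------------------
# k-mer screen

def kmer_match_fraction(query: str, refs: list[str], k: int) -> float:
    comp = str.maketrans("ACGTN", "TGCAN")
    ref_kmers = set()
    for r in refs:
        for s in (r, r.translate(comp)[::-1]):
            for i in range(len(s) - k + 1):
                ref_kmers.add(s[i : i + k])
    q = {query[i : i + k] for i in range(len(query) - k + 1)}
    if not q:
        return 0.0
    return len(q & ref_kmers) / len(q)
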