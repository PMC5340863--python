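# Methods

## Error model and the greedy subtraction

A template sequence presented to the sequencer N times yields error-bearing
reads at various Hamming distances h from itself.  The model bounds the
expected number of reads observed at distance h by N·E[h], where E is an
*upper-bound error profile*: a vector of probabilities, E[0] = 1 by
convention, non-increasing for h ≥ 1, with distances beyond the last bin
reusing the last value.  The observed abundance of a candidate template
understates N because only error-free reads dereplicate onto it; the *mod
factor* (1 − ε)^L — the probability that a read of length L is error-free
at mean per-nucleotide error rate ε — converts between the two, so a
sequence with residual abundance r projects r·E[h]/(1 − ε)^L error reads
onto each neighbour at distance h.

The greedy pass visits sequences once, in an order fixed up front from the
observed counts (descending; ties broken lexicographically on the
sequence, so results are platform-independent).  Each source with positive
residual subtracts its projected error reads from every other sequence;
sources use their *current* residual, not their observed count, because a
partially explained sequence should project proportionally fewer errors.
A sequence whose residual reaches zero or below is removed immediately and
never acts as a source ("drops to 0" is read as ≤ 0).  Output counts are
residuals rounded half-up; values rounding to 0 are dropped.  Two
consequences are load-bearing and tested: the output is always a subset of
the input with counts bounded by the observed counts (subtraction-only),
and the all-zero profile returns the input unchanged.

Full monotonicity in the profile does **not** hold and is deliberately not
asserted: raising E[h] can push an intermediate source's residual to zero,
silencing its own subtraction of third parties, whose retained counts then
*increase*.  Only the zero-profile bound is a theorem.

### Parameters

| parameter | default | meaning |
|---|---|---|
| ε (`mean_error`) | 0.005 | mean per-nucleotide read error rate used for abundance normalisation |
| `indel_prob` | 0.01 | maximal probability of an indel-bearing error read; damps the penalty once for any pair separated by 1..`indel_max` gap columns |
| `indel_max` | 3 | pairs separated by more one-sided gap columns are not considered error-derived at all |
| L (`trim_length`) | 150 | fixed read length after prefix trimming; shorter reads are discarded |
| `min_reads` | 10 | features with strictly fewer total reads are dropped at the table stage |
| E (profile) | see below | shipped default, h = 1..12 |

The shipped profile (0.06, 0.02, 0.02, 0.01, 0.005, 0.005, 0.005, 0.001,
0.001, 0.001, 0.0005, 0.0005) is a configuration default reflecting typical
Illumina amplicon error mass by distance; studies with a calibrated
profile should load their own text file (`load_error_profile`), and every
validation in this package passes the profile explicitly.

The subtraction implies a detection floor: every sequence loses about
(total reads)·E_last/(1 − ε)^L ≈ 0.1% of the sample's reads to far-distance
subtraction under the default profile, so community members below roughly
twice that relative abundance cannot be recovered, whatever the data.

## Alignment

Indel-bearing error reads are rare but must be recognised, because a
shifted read looks like a high-Hamming-distance sequence and would
otherwise escape its template's error cloud.  Each sample is aligned by
center-star progressive alignment: the most abundant sequence is the
center (ties: lexicographic), every other sequence is Needleman–Wunsch
aligned to it (deterministic traceback: diagonal, then up, then left), and
pairwise alignments merge under "once a gap, always a gap".

Scores are match +1, mismatch −1.5, gap −60; the gap penalty encodes the
rare-indel prior of fixed-length amplicon reads.  A genuine indel read aligns to its template with a
near-full-length exact run and beats the gapless alignment by ~100 score
units, so it is still detected for indels in roughly the first half of the
read.  Between two *unrelated* reads (~25% background identity) a shifted
alignment beats the gapless one only through a chance excess of matches;
at gap −60 that excess must reach ≈ 48 matches, a ~6.5σ fluctuation, so
unrelated pairs align gap-free in practice.  This matters because the
denoiser treats gap columns as indel evidence: at milder penalties (−3 or
−20) chance shifts between unrelated sequences put substitution variants
and their templates into inconsistent alignment coordinates, and the
indel gate then shields error reads from subtraction.  Indel reads the
aligner misses (late-read insertions) are still removed by the cumulative
far-distance subtraction, so the asymmetry is safe in the direction that
matters.  Terminal gaps are scored like internal ones (reads are
fixed-length prefixes, so terminal gaps are genuine length variation), a
run of g one-sided gap columns counts as g indel positions, and columns
with two gaps are ignored.

## Chimera detection

PCR chimeras concatenate the prefix of one real template with the suffix
of another, late in amplification, so they are rarer than their parents.
Queries are tested in ascending abundance against parent pairs at an
abundance skew ≥ 2: a query is a chimera if some crossover column
reconstructs it exactly (`max_model_diffs` = 0) from two parents that each
differ from the query by ≥ 3 positions on the segment the *other* parent
contributes — the guard that keeps ordinary error variants from being
mislabelled.  The first qualifying (parent, parent, column) triple in
(abundance desc, abundance desc, leftmost) order is reported, and flagged
sequences leave the parent pool so chimeras cannot sponsor further flags.
Only single-crossover, two-parent models are considered.

## The simulator and what passing tests do (and do not) show

`make_truth_community` builds a star phylogeny around a random ancestor:
member i carries m_i substitutions, m_i uniform on
[⌈r/2⌉, 2·⌈r/2⌉] for similarity radius r, with candidates violating the
pairwise floor rejected.  The minimum pairwise distance therefore sits at
the radius while typical distances are larger — communities at small radius
genuinely contain near-identical members, which is the regime where any
denoiser starts merging real sequences.  Abundances are equal ("uniform")
or lognormal(0, 1) normalized, with lognormal draws resampled until every
member is at or above 0.5% relative abundance: like mock designs built from
the most abundant taxa of a real community, the truth excludes members
that sit below the method's detection floor.

`simulate_reads` applies position-independent substitutions (default
0.001/nt, uniform over the three alternatives) and insertions/deletions at
5·10⁻⁵/nt each; reads are emitted at natural length and the pipeline's
prefix trim restores fixed length (deletion reads become short and are
discarded there).  The simulator does not model position-dependent quality
decay, homopolymer effects, or correlated errors, so perfect recovery on
simulated data bounds idealised behaviour; on real data the error profile
and trim length must absorb those effects, and results depend on how well
the configured profile bounds the instrument's true error distribution.

Validation problem sizes: 20-member communities at L = 150 with 10,000
reads per sample (5,000 for replicate stability), 10 seeds per condition,
and 3 samples per simulated run for the integration check; the greedy core
is additionally checked bit-for-bit against a brute-force oracle on 200
random 30-sequence instances.

## Other numerical choices

- Rarefaction is multivariate hypergeometric (without replacement), one
  seeded generator across samples in table order; samples below the depth
  are dropped, never padded, and features left with zero total are dropped.
- The minimum-count feature filter is strict (`< min_total` dropped).
- Feature IDs are the literal uppercase sequence, which makes cross-run
  merging associative and order-independent; `merge_tables` can optionally
  truncate features to the shortest feature length first when runs were
  trimmed differently.
- UPGMA (for the Hamming dendrogram) breaks distance ties by merging the
  pair whose smallest leaf labels sort first and orders children the same
  way, so trees are byte-reproducible.
- Unweighted UniFrac uses presence = count ≥ 1 and is computed by
  scikit-bio; the test suite cross-checks it against an explicit
  branch-set construction to 10⁻¹².
- BIOM output is 1.0 JSON (sparse) with an empty `date` field by default
  so identical tables produce byte-identical files.
- Reads containing N survive trimming and dereplication but are removed
  before alignment: the Hamming model is defined over unambiguous bases.
- Reads shorter than the trim length are discarded (not padded); the
  count is logged.

## Known limitations

Single-crossover chimera models only; no quality-score-aware error model
(the profile is global, not per-position); center-star alignment is not
guaranteed to match an external MSA tool column-for-column; detection
floor as described above; BIOM 2.x/HDF5 is not written.
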