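"""Integrate two sequencing runs and compare samples with unweighted UniFrac.

Because feature IDs are the exact sequences, tables denoised per-sample in
different runs merge with no centroid matching: the same organism gets the
same ID everywhere.  If integration works, the run of origin should leave no
signal — between-run distances should look like within-run distances.
"""

import numpy as np

from subotu import (
    SimParams, hamming_upgma, make_truth_community, simulate_reads,
    unweighted_unifrac,
)
from subotu.pipeline import PipelineConfig, process_sample
from subotu.table import build_table, filter_min_count, merge_tables, rarefy

truth = make_truth_community(20, 150, 10, "lognormal", seed=1)

run_tables = []
for run_id, base_seed in (("runA", 100), ("runB", 200)):
    results = []
    for i in range(3):
        sample = simulate_reads(
            truth, SimParams(n_reads=10000, seed=base_seed + i), f"{run_id}_s{i}"
        )
        res, _ = process_sample(sample, PipelineConfig(trim_length=150, seed=base_seed + i))
        results.append((f"{run_id}_s{i}", res))
    run_tables.append(filter_min_count(build_table(results), 10))

merged = rarefy(merge_tables(run_tables), depth=5000, seed=1)
tree = hamming_upgma(merged.feature_ids)
dm = unweighted_unifrac(merged, tree)

ids = merged.sample_ids
within, between = [], []
for i in range(len(ids)):
    for j in range(i + 1, len(ids)):
        (within if ids[i][:4] == ids[j][:4] else between).append(dm[ids[i], ids[j]])

print(f"merged table: {merged.shape[0]} samples x {merged.shape[1]} features")
print(f"mean within-run  UniFrac = {np.mean(within):.4f}")
print(f"mean between-run UniFrac = {np.mean(between):.4f}")
# near-zero and near-equal means: the sequencing run leaves no artifactual
# separation once features are keyed by exact sequence.
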