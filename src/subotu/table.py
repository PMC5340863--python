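"""Exact-sequence feature tables: assembly, merging, filtering, rarefaction.

The feature ID *is* the sequence.  Because denoising emits exact sequences,
tables from different sequencing runs can be merged by string identity with
no centroid-matching step: the same organism observed in two runs yields the
same feature ID by construction.  This is the property that makes
per-sample denoising composable across studies.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .denoise import DenoiseResult

_BIOM_FORMAT = "Biological Observation Matrix 1.0.0"
_BIOM_URL = "http://biom-format.org/documentation/format_versions/biom-1.0.html"


@dataclass
class FeatureTable:
    """Samples x features integer count matrix keyed by exact sequences.

    ``counts[i, j]`` is the count of feature ``feature_ids[j]`` (an uppercase
    nucleotide sequence) in sample ``sample_ids[i]``.
    """

    sample_ids: list[str]
    feature_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (len(self.sample_ids), len(self.feature_ids)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.feature_ids)} features"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise ValueError("duplicate feature ids")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def sample_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def feature_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def to_dataframe(self) -> pd.DataFrame:
        """Features as rows, samples as columns (the classic table layout)."""
        return pd.DataFrame(
            self.counts.T, index=self.feature_ids, columns=self.sample_ids
        )

    def equals(self, other: "FeatureTable") -> bool:
        """Equality up to row/column order."""
        if set(self.sample_ids) != set(other.sample_ids):
            return False
        if set(self.feature_ids) != set(other.feature_ids):
            return False
        a = self.to_dataframe().sort_index()
        b = other.to_dataframe().sort_index()
        return a[sorted(self.sample_ids)].equals(b[sorted(self.sample_ids)])


def build_table(
    results: Mapping[str, DenoiseResult] | Sequence[tuple[str, DenoiseResult]],
) -> FeatureTable:
    """Combine per-sample denoised results into one table.

    Features are the union of retained sequences across samples, ordered
    lexicographically; a sequence absent from a sample gets count 0.  Samples
    keep their input order; an empty result keeps its (all-zero) row.
    """
    pairs = list(results.items()) if isinstance(results, Mapping) else list(results)
    sample_ids = [sid for sid, _ in pairs]
    if len(set(sample_ids)) != len(sample_ids):
        dup = sorted({s for s in sample_ids if sample_ids.count(s) > 1})
        raise ValueError(f"duplicate sample ids {dup}")
    features = sorted({seq for _, res in pairs for seq, _ in res.retained})
    col = {f: j for j, f in enumerate(features)}
    counts = np.zeros((len(pairs), len(features)), dtype=np.int64)
    for i, (_, res) in enumerate(pairs):
        for seq, c in res.retained:
            counts[i, col[seq]] += c
    return FeatureTable(sample_ids=sample_ids, feature_ids=features, counts=counts)


def sample_result(t: FeatureTable, sample_id: str) -> DenoiseResult:
    """Extract one sample's nonzero features back into a DenoiseResult.

    Convenience for scoring a sample *after* table-level operations
    (minimum-count filtering, rarefaction) with the same metrics used on
    raw denoiser output.
    """
    i = t.sample_ids.index(sample_id)
    retained = [
        (f, int(c)) for f, c in zip(t.feature_ids, t.counts[i]) if c > 0
    ]
    return DenoiseResult(retained=retained, removed=[])


def filter_min_count(t: FeatureTable, min_total: int) -> FeatureTable:
    """Drop features whose total count across samples is below ``min_total``.

    The comparison is strict: a feature with exactly ``min_total`` reads is
    kept ("fewer than" semantics).
    """
    if min_total < 0:
        raise ValueError("min_total must be >= 0")
    if min_total == 0:
        return FeatureTable(
            sample_ids=list(t.sample_ids),
            feature_ids=list(t.feature_ids),
            counts=t.counts.copy(),
        )
    keep = t.feature_totals() >= min_total
    return FeatureTable(
        sample_ids=list(t.sample_ids),
        feature_ids=[f for f, k in zip(t.feature_ids, keep) if k],
        counts=t.counts[:, keep],
    )


def merge_tables(
    tables: Sequence[FeatureTable], trim_to_common: bool = False
) -> FeatureTable:
    """Merge run-level tables on exact sequence identity.

    Sample ids must be disjoint across tables.  With ``trim_to_common`` all
    feature sequences are first truncated to the minimum feature length seen
    across tables and counts of now-identical prefixes are summed per
    sample — useful when runs were trimmed to different read lengths.
    """
    if not tables:
        raise ValueError("need at least one table")
    all_samples = [s for t in tables for s in t.sample_ids]
    if len(set(all_samples)) != len(all_samples):
        dup = sorted({s for s in all_samples if all_samples.count(s) > 1})
        raise ValueError(f"sample ids overlap across tables: {dup}")

    prepared = tables
    if trim_to_common:
        min_len = min(
            (len(f) for t in tables for f in t.feature_ids), default=0
        )
        prepared = []
        for t in tables:
            trimmed: dict[str, np.ndarray] = {}
            for j, f in enumerate(t.feature_ids):
                key = f[:min_len]
                if key in trimmed:
                    trimmed[key] = trimmed[key] + t.counts[:, j]
                else:
                    trimmed[key] = t.counts[:, j].copy()
            feats = sorted(trimmed)
            counts = (
                np.stack([trimmed[f] for f in feats], axis=1)
                if feats
                else np.zeros((len(t.sample_ids), 0), dtype=np.int64)
            )
            prepared.append(
                FeatureTable(
                    sample_ids=list(t.sample_ids), feature_ids=feats, counts=counts
                )
            )

    features = sorted({f for t in prepared for f in t.feature_ids})
    col = {f: j for j, f in enumerate(features)}
    counts = np.zeros((len(all_samples), len(features)), dtype=np.int64)
    row = 0
    for t in prepared:
        for j, f in enumerate(t.feature_ids):
            counts[row : row + len(t.sample_ids), col[f]] = t.counts[:, j]
        row += len(t.sample_ids)
    return FeatureTable(sample_ids=all_samples, feature_ids=features, counts=counts)


def rarefy(t: FeatureTable, depth: int, seed: int) -> FeatureTable:
    """Subsample every sample to exactly ``depth`` reads without replacement.

    Samples with fewer than ``depth`` total reads are dropped.  Sampling is
    multivariate hypergeometric per sample, driven by one seeded generator
    over samples in table order, so the result is deterministic.  Features
    left with zero total count are dropped.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = np.random.default_rng(seed)
    totals = t.sample_totals()
    rows: list[np.ndarray] = []
    kept_samples: list[str] = []
    for i, sid in enumerate(t.sample_ids):
        if totals[i] < depth:
            continue
        rows.append(rng.multivariate_hypergeometric(t.counts[i], depth))
        kept_samples.append(sid)
    if not rows:
        return FeatureTable(
            sample_ids=[], feature_ids=[], counts=np.zeros((0, 0), dtype=np.int64)
        )
    counts = np.stack(rows).astype(np.int64)
    keep = counts.sum(axis=0) > 0
    return FeatureTable(
        sample_ids=kept_samples,
        feature_ids=[f for f, k in zip(t.feature_ids, keep) if k],
        counts=counts[:, keep],
    )


def write_table(
    t: FeatureTable,
    path: str | Path,
    format: Literal["biom-json", "tsv"] = "biom-json",
    date: str = "",
) -> None:
    """Write a table as BIOM 1.0 JSON (sparse) or TSV (features x samples).

    ``date`` defaults to the empty string rather than wall-clock time so that
    identical tables produce byte-identical files; pass a timestamp to
    record one.
    """
    path = Path(path)
    if format == "tsv":
        with open(path, "w") as fh:
            fh.write("#OTU ID\t" + "\t".join(t.sample_ids) + "\n")
            for j, f in enumerate(t.feature_ids):
                fh.write(f + "\t" + "\t".join(str(int(c)) for c in t.counts[:, j]) + "\n")
        return
    if format != "biom-json":
        raise ValueError(f"unknown format {format!r}")
    data = [
        [j, i, int(t.counts[i, j])]
        for j in range(len(t.feature_ids))
        for i in range(len(t.sample_ids))
        if t.counts[i, j] != 0
    ]
    doc = {
        "id": None,
        "format": _BIOM_FORMAT,
        "format_url": _BIOM_URL,
        "type": "OTU table",
        "generated_by": "subotu",
        "date": date,
        "matrix_type": "sparse",
        "matrix_element_type": "int",
        "shape": [len(t.feature_ids), len(t.sample_ids)],
        "rows": [{"id": f, "metadata": None} for f in t.feature_ids],
        "columns": [{"id": s, "metadata": None} for s in t.sample_ids],
        "data": data,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)
        fh.write("\n")


def read_table(path: str | Path, format: Literal["biom-json", "tsv", None] = None) -> FeatureTable:
    """Read a table written by :func:`write_table` (format auto-detected)."""
    path = Path(path)
    if format is None:
        head = open(path).read(1)
        format = "biom-json" if head == "{" else "tsv"
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
        return FeatureTable(
            sample_ids=[str(c) for c in df.columns],
            feature_ids=[str(i) for i in df.index],
            counts=df.to_numpy(dtype=np.int64).T,
        )
    doc = json.loads(Path(path).read_text())
    n_feat, n_samp = doc["shape"]
    features = [r["id"] for r in doc["rows"]]
    samples = [c["id"] for c in doc["columns"]]
    counts = np.zeros((n_samp, n_feat), dtype=np.int64)
    if doc["matrix_type"] == "sparse":
        for r, c, v in doc["data"]:
            counts[c, r] = int(v)
    else:
        for r, rowvals in enumerate(doc["data"]):
            counts[:, r] = np.asarray(rowvals, dtype=np.int64)
    return FeatureTable(sample_ids=samples, feature_ids=features, counts=counts)
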