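"""End-to-end per-sample denoising pipeline.

Every sample is processed independently — trim, dereplicate with singleton
removal, artifact screening, multiple alignment, greedy error subtraction,
chimera removal — and only then are the per-sample results combined into a
feature table.  Per-sample independence is the architectural property that
lets runs processed at different times or places be merged afterwards: a
sample's output never depends on what it was batched with.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

from . import seqio
from .alignment import center_star_msa
from .artifact_filter import build_screen, screen_sequences
from .chimera import ChimeraParams, detect_chimeras, remove_chimeras
from .denoise import (
    DEFAULT_ERROR_PROFILE,
    DenoiseParams,
    DenoiseResult,
    ErrorProfile,
    load_error_profile,
)
from .table import FeatureTable, build_table, filter_min_count, rarefy, write_table

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All knobs of the per-sample pipeline, with field-standard defaults."""

    input_path: str | Path = ""
    output_dir: str | Path = ""
    trim_length: int = 150
    mean_error: float = 0.005
    indel_prob: float = 0.01
    indel_max: int = 3
    error_profile: str | Path | None = None
    pos_ref: str | Path | None = None
    neg_ref: str | Path | None = None
    min_reads: int = 10
    rarefy_depth: int | None = None
    seed: int = 0
    jobs: int = 1
    chimera_check: bool = True
    chimera_params: ChimeraParams = field(default_factory=ChimeraParams)

    def resolve_profile(self) -> ErrorProfile:
        if self.error_profile is None:
            return DEFAULT_ERROR_PROFILE
        return load_error_profile(self.error_profile)


def process_sample(
    sample: seqio.SampleReads,
    config: PipelineConfig,
    profile: ErrorProfile | None = None,
    neg_screen=None,
    pos_screen=None,
) -> tuple[DenoiseResult, dict]:
    """Run one sample through the full pipeline; returns (result, stage report)."""
    profile = profile if profile is not None else config.resolve_profile()
    if neg_screen is None and config.neg_ref:
        neg_screen = build_screen(config.neg_ref, mode="negative")
    if pos_screen is None and config.pos_ref:
        pos_screen = build_screen(config.pos_ref, mode="positive")
    report: dict = {"sample_id": sample.sample_id, "n_input_reads": len(sample)}

    trimmed = seqio.trim_reads(sample, config.trim_length)
    report["n_after_trim"] = len(trimmed)

    dereps = seqio.dereplicate(trimmed)
    report["n_derep_seqs"] = len(dereps)
    report["reads_after_singleton_removal"] = sum(d.count for d in dereps)

    # the Hamming error model is defined over unambiguous bases only
    dereps = [d for d in dereps if "N" not in d.sequence]
    report["n_after_n_removal"] = len(dereps)

    if neg_screen is not None:
        dereps, removed = screen_sequences(dereps, neg_screen)
        report["n_removed_negative_screen"] = len(removed)
    if pos_screen is not None:
        dereps, removed = screen_sequences(dereps, pos_screen)
        report["n_removed_positive_screen"] = len(removed)
    report["n_after_artifact_filter"] = len(dereps)

    if not dereps:
        report["n_retained"] = 0
        return DenoiseResult(retained=[], removed=[]), report

    ws = center_star_msa(dereps, sample_id=sample.sample_id)
    params = DenoiseParams(
        mean_error=config.mean_error,
        indel_prob=config.indel_prob,
        indel_max=config.indel_max,
        read_length=config.trim_length,
    )
    from .denoise import denoise_sample

    result = denoise_sample(ws, profile, params)
    report["n_after_denoise"] = len(result.retained)

    if config.chimera_check and result.retained:
        verdicts = detect_chimeras(result, config.chimera_params)
        result = remove_chimeras(result, verdicts)
        report["n_chimeras_removed"] = sum(1 for v in verdicts if v.is_chimera)
    report["n_retained"] = len(result.retained)
    report["reads_retained"] = result.total()
    return result, report


def run_pipeline(
    config: PipelineConfig,
    samples: list[seqio.SampleReads] | None = None,
) -> tuple[FeatureTable, list[dict]]:
    """Run the pipeline over all samples and assemble the feature table.

    ``samples`` may be passed directly (e.g. from the simulator); otherwise
    they are read from ``config.input_path``.  A sample that fails aborts
    with a logged reason while the others proceed.  Results are combined in
    sample-name order, filtered by ``min_reads`` total counts, optionally
    rarefied, and (when ``output_dir`` is set) written as BIOM JSON, TSV and
    a JSON run manifest.
    """
    if samples is None:
        samples = seqio.read_sample_files(config.input_path)
    profile = config.resolve_profile()
    neg_screen = (
        build_screen(config.neg_ref, mode="negative") if config.neg_ref else None
    )
    pos_screen = (
        build_screen(config.pos_ref, mode="positive") if config.pos_ref else None
    )

    ordered = sorted(samples, key=lambda s: s.sample_id)

    def _one(sample: seqio.SampleReads):
        try:
            return sample.sample_id, process_sample(
                sample, config, profile, neg_screen, pos_screen
            ), None
        except Exception as exc:  # keep other samples alive
            logger.error("sample %s failed: %s", sample.sample_id, exc)
            return sample.sample_id, None, str(exc)

    if config.jobs > 1:
        from joblib import Parallel, delayed

        outcomes = Parallel(n_jobs=config.jobs)(delayed(_one)(s) for s in ordered)
    else:
        outcomes = [_one(s) for s in ordered]

    results: list[tuple[str, DenoiseResult]] = []
    reports: list[dict] = []
    for sid, payload, err in outcomes:
        if err is not None:
            reports.append({"sample_id": sid, "error": err})
            continue
        result, report = payload
        results.append((sid, result))
        reports.append(report)

    table = build_table(results)
    table = filter_min_count(table, config.min_reads)
    if config.rarefy_depth is not None:
        table = rarefy(table, config.rarefy_depth, seed=config.seed)

    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_table(table, out / "table.biom", format="biom-json")
        write_table(table, out / "table.tsv", format="tsv")
        manifest = {
            "config": {
                k: (str(v) if isinstance(v, Path) else v)
                for k, v in asdict(config).items()
                if k != "chimera_params"
            },
            "chimera_params": asdict(config.chimera_params),
            "samples": reports,
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
    return table, reports
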