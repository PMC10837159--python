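"""End-to-end pipeline: annotate -> prefilter -> QC -> normalize ->
deconvolve -> profiles/markers/correlations, with a reproducibility manifest.

Every intermediate table is written under the run directory; re-running the
same configuration reproduces byte-identical outputs. Progress and stage
timings go to standard error, never results.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import annotation, deconvolution, io, preprocess, qc, stats
from .errors import BloodSRNAError
from .matrix import make_sample_meta

logger = logging.getLogger("bloodsrna")


@dataclass
class PipelineConfig:
    """All inputs, outputs and parameters of one pipeline run.

    Paths point at the plain-text tables produced by the simulator or an
    upstream annotation pipeline; thresholds default to the values the
    analysis is defined with (purity > 70%, RPM >= 2 kept, detection in >= 3
    samples of a component, length > 17 nt, 2% profile pooling, 5% FDR,
    25-nt bins, plasma fraction 0.5).
    """

    assignments: str | Path = "assignments.tsv"
    sort_samples: str | Path = "sort_samples.tsv"
    donors: str | Path = "donors.tsv"
    whole_blood: str | Path | None = None
    out_dir: str | Path = "run"
    purity_threshold_pct: float = qc.PURITY_THRESHOLD_PCT
    low_expression_rpm: float = preprocess.LOW_EXPRESSION_RPM
    min_samples_per_component: int = preprocess.MIN_SAMPLES_PER_COMPONENT
    min_length_exclusive: int = preprocess.MIN_LENGTH_EXCLUSIVE
    others_threshold: float = stats.OTHERS_THRESHOLD
    marker_alpha: float = stats.MARKER_ALPHA
    bin_size: int = annotation.DEFAULT_BIN_SIZE
    plasma_fraction: float = deconvolution.DEFAULT_PLASMA_FRACTION
    perplexity: float = qc.DEFAULT_PERPLEXITY
    knn_k: int = qc.DEFAULT_KNN
    knn_min_same_frac: float = qc.DEFAULT_MIN_SAME_FRAC
    seed: int = 0
    verbose: bool = False

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("assignments", "sort_samples", "donors", "whole_blood", "out_dir"):
            if d[key] is not None:
                d[key] = str(d[key])
        return d


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class _Stage:
    """Context manager logging a stage's wall time to stderr."""

    def __init__(self, name: str):
        self.name = name

    def __enter__(self):
        self.t0 = time.perf_counter()
        logger.info("stage %s: started", self.name)
        return self

    def __exit__(self, exc_type, exc, tb):
        dt = time.perf_counter() - self.t0
        if exc_type is None:
            logger.info("stage %s: done in %.2fs", self.name, dt)
        else:
            logger.error("stage %s: FAILED after %.2fs", self.name, dt)
        return False


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute every stage on the configured inputs; returns the run dir.

    The first failing stage aborts the run with a stage-named error; a
    ``FAILED`` marker file flags partial outputs.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    marker = out / "FAILED"
    stage = "setup"
    try:
        with _Stage("read-inputs"):
            stage = "read-inputs"
            records = io.read_sequence_records(config.assignments)
            sort_samples = io.read_sort_samples(config.sort_samples)
            donors = io.read_donors(config.donors)
            meta = make_sample_meta(
                [s.sample_id for s in sort_samples],
                [s.donor_id for s in sort_samples],
                [s.component for s in sort_samples],
            )

        with _Stage("prefilter"):
            stage = "prefilter"
            records = preprocess.prefilter_sequences(
                records,
                preprocess.component_map(meta),
                min_samples=config.min_samples_per_component,
                min_len_exclusive=config.min_length_exclusive,
            )

        with _Stage("annotate"):
            stage = "annotate"
            counts = annotation.collapse_counts(records, sample_meta=meta, bin_size=config.bin_size)
            io.write_count_matrix(counts, out / "counts")

        with _Stage("qc"):
            stage = "qc"
            passed, failed = qc.purity_filter(sort_samples, config.purity_threshold_pct)
            pure = counts.subset_samples(passed)
            log_all = preprocess.log_transform(preprocess.rpm_normalize(pure))
            coords = qc.embed(log_all, seed=config.seed, perplexity=config.perplexity)
            flagged = qc.flag_outliers(
                coords, pure.components, k=config.knn_k, min_same_frac=config.knn_min_same_frac
            )
            report = qc.QCReport(
                excluded_purity=failed,
                excluded_embedding=flagged,
                n_input=len(sort_samples),
                n_pass=len(sort_samples) - len(failed) - len(flagged),
                embedding=coords,
                parameters={
                    "purity_threshold_pct": config.purity_threshold_pct,
                    "perplexity": config.perplexity,
                    "k": config.knn_k,
                    "min_same_frac": config.knn_min_same_frac,
                    "seed": config.seed,
                },
            )
            coords.to_csv(out / "embedding.tsv", sep="\t")
            exclusions = [
                {"sample_id": s, "reason": "purity"} for s in sorted(failed)
            ] + [{"sample_id": s, "reason": "embedding"} for s in sorted(flagged)]
            io.write_table(
                pd.DataFrame(exclusions, columns=["sample_id", "reason"]),
                out / "qc_exclusions.tsv",
            )
            (out / "qc_report.json").write_text(
                json.dumps(
                    {
                        "n_input": report.n_input,
                        "n_excluded_purity": len(failed),
                        "n_excluded_embedding": len(flagged),
                        "n_pass": report.n_pass,
                        "parameters": report.parameters,
                    },
                    indent=2,
                )
                + "\n"
            )

        with _Stage("normalize"):
            stage = "normalize"
            keep = [s for s in passed if s not in set(flagged)]
            rpm = preprocess.rpm_normalize(counts.subset_samples(keep))
            rpm = preprocess.low_expression_filter(rpm, threshold=config.low_expression_rpm)
            log_rpm = preprocess.log_transform(rpm)
            io.write_count_matrix(rpm, out / "rpm")
            io.write_count_matrix(log_rpm, out / "log2rpm")

        with _Stage("deconvolve"):
            stage = "deconvolve"
            keep_samples = [s for s in sort_samples if s.sample_id in set(keep)]
            contents = deconvolution.compute_contents(
                keep_samples, donors, plasma_fraction=config.plasma_fraction
            )
            contents.to_csv(out / "contents.tsv", sep="\t")
            result = deconvolution.deconvolve(rpm, contents)
            for sid in result.skipped_samples:
                logger.info("deconvolve: skipped %s (no sRNA content)", sid)
            result.scaled_means.to_csv(out / "scaled_means.tsv", sep="\t")
            result.proportions.to_csv(out / "contributions.tsv", sep="\t")

        with _Stage("profiles-markers"):
            stage = "profiles-markers"
            io.write_table(
                stats.component_profile(rpm, others_threshold=config.others_threshold),
                out / "component_profiles.tsv",
            )
            if rpm.feature_classes is not None:
                stats.class_profile(rpm).to_csv(out / "class_profiles.tsv", sep="\t")
            markers = stats.overrepresented_srnas(
                log_rpm, alpha=config.marker_alpha, rpm_matrix=rpm
            )
            io.write_table(markers, out / "markers.tsv")

        if config.whole_blood is not None:
            with _Stage("correlate"):
                stage = "correlate"
                wb = io.read_count_matrix(config.whole_blood)
                wb_rpm = preprocess.rpm_normalize(wb)
                corr = stats.whole_blood_correlation(wb_rpm, io.blood_count_frame(donors))
                corr.to_csv(out / "wb_correlations.tsv", sep="\t")

        with _Stage("manifest"):
            stage = "manifest"
            inputs = {
                "assignments": str(config.assignments),
                "sort_samples": str(config.sort_samples),
                "donors": str(config.donors),
            }
            if config.whole_blood is not None:
                inputs["whole_blood"] = str(config.whole_blood)
            manifest = {
                "config": config.to_dict(),
                "seed": config.seed,
                "input_checksums": {
                    k: _sha256(Path(v)) for k, v in inputs.items() if Path(v).exists()
                },
            }
            (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    except BloodSRNAError as err:
        marker.write_text(f"stage {stage}: {err}\n")
        raise BloodSRNAError(f"pipeline failed at stage {stage!r}: {err}") from err
    marker.unlink(missing_ok=True)
    return out
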