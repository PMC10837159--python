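"""Inclusion filters and normalization.

Canonical order: sequence-level prefilter (length and per-component
detection) -> collapse -> RPM normalization -> low-expression filter.
Library size is the per-sample total after the prefilter; it is not
recomputed after discarding low-expressed features, so a feature's RPM value
is stable under the final filter.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import MetadataError, NormalizationError
from .matrix import CountMatrix
from .types import SequenceRecord

MIN_SAMPLES_PER_COMPONENT = 3
MIN_LENGTH_EXCLUSIVE = 17
LOW_EXPRESSION_RPM = 2.0


def prefilter_sequences(
    records: Iterable[SequenceRecord],
    sample_components: Mapping[str, str],
    min_samples: int = MIN_SAMPLES_PER_COMPONENT,
    min_len_exclusive: int = MIN_LENGTH_EXCLUSIVE,
) -> list[SequenceRecord]:
    """Keep sequences longer than ``min_len_exclusive`` nt that are detected
    (>= 1 read) in at least ``min_samples`` samples of at least one blood
    component type.

    ``sample_components`` maps every sample id that may occur in the count
    maps to its component label; a sample without a label is a metadata
    error because the detection rule is evaluated per component.
    """
    kept: list[SequenceRecord] = []
    for rec in records:
        if rec.length_nt <= min_len_exclusive:
            continue
        per_component: dict[str, int] = {}
        for sample_id, n in rec.counts.items():
            if n < 1:
                continue
            try:
                comp = sample_components[sample_id]
            except KeyError:
                raise MetadataError(
                    f"sample {sample_id!r} (counts of {rec.seq_id!r}) has no component label"
                ) from None
            per_component[comp] = per_component.get(comp, 0) + 1
        if any(n >= min_samples for n in per_component.values()):
            kept.append(rec)
    return kept


def rpm_normalize(matrix: CountMatrix) -> CountMatrix:
    """Scale each sample to reads-per-million (column sum 1e6)."""
    matrix.require_units("reads")
    sums = matrix.values.sum(axis=0)
    zero = sums[sums <= 0]
    if len(zero) > 0:
        raise NormalizationError(
            f"cannot RPM-normalize all-zero sample(s): {zero.index.tolist()}"
        )
    values = matrix.values.div(sums, axis=1) * 1e6
    out = CountMatrix(
        values=values,
        sample_meta=matrix.sample_meta,
        units="RPM",
        feature_classes=matrix.feature_classes,
    )
    out.check_rpm_sums()
    return out


def log_transform(matrix: CountMatrix) -> CountMatrix:
    """log2(RPM + 1), the scale used for embeddings and marker testing."""
    matrix.require_units("RPM")
    return CountMatrix(
        values=np.log2(matrix.values + 1.0),
        sample_meta=matrix.sample_meta,
        units="log2RPM",
        feature_classes=matrix.feature_classes,
    )


def low_expression_filter(
    matrix: CountMatrix,
    threshold: float = LOW_EXPRESSION_RPM,
    statistic: str = "max",
) -> CountMatrix:
    """Drop features whose expression never reaches ``threshold`` RPM.

    A feature is discarded when its ``statistic`` ("max" by default,
    "mean" optionally) across all samples is strictly below the threshold;
    a feature hitting the threshold exactly in any sample is kept. Feature
    removal (rather than per-cell masking) keeps the matrix rectangular.
    """
    matrix.require_units("RPM")
    if statistic == "max":
        stat = matrix.values.max(axis=1)
    elif statistic == "mean":
        stat = matrix.values.mean(axis=1)
    else:
        raise ValueError(f"statistic must be 'max' or 'mean', got {statistic!r}")
    keep = stat >= threshold
    classes = matrix.feature_classes
    if classes is not None:
        classes = classes.reindex(matrix.values.index[keep])
    return CountMatrix(
        values=matrix.values.loc[keep],
        sample_meta=matrix.sample_meta,
        units="RPM",
        feature_classes=classes,
    )


def component_map(sample_meta: pd.DataFrame) -> dict[str, str]:
    """sample id -> component label, from a sample-metadata frame."""
    return sample_meta["component"].to_dict()
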