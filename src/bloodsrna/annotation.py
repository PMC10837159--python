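"""Annotation resolution and count collapsing.

A sequenced small RNA may map to several reference transcripts of different
RNA classes. The class hierarchy miRNA > tRNA > rRNA > Y RNA > snoRNA >
lncRNA > snRNA > piRNA decides which annotation wins. Fragments of rRNA and
Y RNA are further subcategorized by the ~25-nt bin of their start position on
the parent transcript, so that e.g. 5' and 3' fragments of the same rRNA are
distinct features. Reads are then collapsed per annotation label.
"""

from __future__ import annotations

import math
from collections import defaultdict
from collections.abc import Iterable, Sequence

import pandas as pd

from .errors import CoordinateError
from .matrix import CountMatrix, make_sample_meta
from .types import (
    BINNED_CLASSES,
    CLASS_RANK,
    AnnotationLabel,
    AssignmentCandidate,
    SequenceRecord,
)

DEFAULT_BIN_SIZE = 25


def bin_label(parent_gene: str, start_pos: int, bin_size: int = DEFAULT_BIN_SIZE) -> str:
    """Label a parent-transcript fragment by the bin containing its start.

    Bins are 1-based, contiguous and ``bin_size`` wide: bin k covers
    positions ``[bin_size*(k-1)+1, bin_size*k]``, so position 25 falls in
    bin 1 and position 26 in bin 2 (with the default width).
    """
    if bin_size < 1:
        raise CoordinateError(f"bin_size must be >= 1, got {bin_size}")
    if start_pos < 1:
        raise CoordinateError(f"start_pos must be 1-based (>= 1), got {start_pos}")
    k = math.ceil(start_pos / bin_size)
    return f"{parent_gene}-bin{k}"


def candidate_label(candidate: AssignmentCandidate, bin_size: int = DEFAULT_BIN_SIZE) -> str:
    """The annotation label a candidate would produce if it won."""
    if candidate.rna_class in BINNED_CLASSES:
        return bin_label(candidate.parent_gene, candidate.start_pos, bin_size)
    return candidate.parent_gene


def resolve_assignment(
    candidates: Sequence[AssignmentCandidate],
    bin_size: int = DEFAULT_BIN_SIZE,
) -> AnnotationLabel:
    """Pick the winning annotation among multi-assigned candidates.

    The candidate whose RNA class ranks highest wins; within a class, ties
    are broken by the lexicographically smallest synthesized label, which
    makes resolution deterministic and independent of input order.
    """
    if not candidates:
        raise ValueError("cannot resolve an empty candidate list")
    best = min(
        candidates,
        key=lambda c: (CLASS_RANK[c.rna_class], candidate_label(c, bin_size)),
    )
    return AnnotationLabel(label=candidate_label(best, bin_size), rna_class=best.rna_class)


def collapse_counts(
    records: Iterable[SequenceRecord],
    sample_meta: pd.DataFrame | None = None,
    bin_size: int = DEFAULT_BIN_SIZE,
) -> CountMatrix:
    """Sum sequence-level counts into one row per annotation label.

    Total reads per sample are conserved: every sequence contributes its
    counts to exactly one label. Returns a ``reads``-unit matrix whose
    ``feature_classes`` records the winning class per label.
    """
    label_counts: dict[str, dict[str, int]] = defaultdict(lambda: defaultdict(int))
    label_class: dict[str, str] = {}
    sample_ids: dict[str, None] = {}  # insertion-ordered set
    for rec in records:
        resolved = resolve_assignment(rec.candidates, bin_size)
        label_class[resolved.label] = resolved.rna_class
        row = label_counts[resolved.label]
        for sample_id, n in rec.counts.items():
            sample_ids.setdefault(sample_id)
            row[sample_id] += n

    columns = (
        list(sample_meta.index) if sample_meta is not None else list(sample_ids)
    )
    values = pd.DataFrame(
        {s: [label_counts[lab].get(s, 0) for lab in label_counts] for s in columns},
        index=pd.Index(list(label_counts), name="label"),
        dtype=float,
    )
    if sample_meta is None:
        sample_meta = make_sample_meta(
            columns, ["unknown"] * len(columns), ["unknown"] * len(columns)
        )
    classes = pd.Series(label_class, name="rna_class")
    return CountMatrix(values=values, sample_meta=sample_meta, units="reads", feature_classes=classes)
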