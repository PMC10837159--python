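"""Plain-text readers and writers.

Canonical dialect: tab-separated values, UTF-8, '.' decimal separator, one
header line. A count matrix on disk is a file triple sharing a prefix:
``<prefix>.counts.tsv`` (features x samples), ``<prefix>.samples.tsv``
(sample metadata) and ``<prefix>.meta.json`` (units and bookkeeping), plus
an optional ``<prefix>.classes.tsv`` label-to-class map. Large matrices can
be stored as MatrixMarket triplets instead.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .errors import SchemaError
from .matrix import SAMPLE_META_COLUMNS, CountMatrix
from .simulate import SyntheticTruth
from .types import AssignmentCandidate, DonorRecord, SequenceRecord, SortSample

# ---------------------------------------------------------------------------
# generic schema-checked tables


def read_table(path, required_columns: tuple[str, ...] = ()) -> pd.DataFrame:
    """Read a TSV, enforcing the presence of ``required_columns``."""
    path = Path(path)
    table = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in required_columns if c not in table.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing required column(s) {missing}")
    return table


def write_table(table: pd.DataFrame, path, index: bool = False) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, sep="\t", index=index)


def _to_float(raw: str, path, row: int, column: str) -> float:
    try:
        return float(raw)
    except ValueError:
        raise SchemaError(
            f"{Path(path).name}: malformed numeric value {raw!r} at row {row}, "
            f"column {column!r}"
        ) from None


# ---------------------------------------------------------------------------
# count matrices


def write_count_matrix(matrix: CountMatrix, prefix) -> None:
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    values = matrix.values.copy()
    values.index.name = "label"
    values.to_csv(prefix.with_suffix(".counts.tsv"), sep="\t")
    matrix.sample_meta.to_csv(prefix.with_suffix(".samples.tsv"), sep="\t")
    meta = {"units": matrix.units, "n_features": int(values.shape[0]), "n_samples": int(values.shape[1])}
    prefix.with_suffix(".meta.json").write_text(json.dumps(meta, indent=2) + "\n")
    if matrix.feature_classes is not None:
        classes = matrix.feature_classes.rename("rna_class").rename_axis("label")
        classes.to_csv(prefix.with_suffix(".classes.tsv"), sep="\t")


def read_count_matrix(prefix) -> CountMatrix:
    prefix = Path(prefix)
    counts_path = prefix.with_suffix(".counts.tsv")
    raw = read_table(counts_path, required_columns=("label",)).set_index("label")
    values = pd.DataFrame(
        {
            col: [
                _to_float(v, counts_path, i + 2, col)  # +2: header is line 1
                for i, v in enumerate(raw[col])
            ]
            for col in raw.columns
        },
        index=raw.index,
    )
    sample_meta = pd.read_csv(prefix.with_suffix(".samples.tsv"), sep="\t", index_col="sample_id")
    missing = [c for c in SAMPLE_META_COLUMNS if c not in sample_meta.columns]
    if missing:
        raise SchemaError(f"{prefix.name}.samples.tsv: missing column(s) {missing}")
    meta = json.loads(prefix.with_suffix(".meta.json").read_text())
    classes_path = prefix.with_suffix(".classes.tsv")
    classes = None
    if classes_path.exists():
        classes = pd.read_csv(classes_path, sep="\t", index_col="label")["rna_class"]
    return CountMatrix(
        values=values,
        sample_meta=sample_meta,
        units=meta["units"],
        feature_classes=classes,
    )


def write_count_matrix_mtx(matrix: CountMatrix, prefix) -> None:
    """Sparse MatrixMarket triplet alternative for large matrices."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(str(prefix.with_suffix(".mtx")), sparse.coo_matrix(matrix.values.to_numpy()))
    pd.Series(matrix.features, name="label").to_csv(
        prefix.with_suffix(".features.tsv"), sep="\t", index=False
    )
    matrix.sample_meta.to_csv(prefix.with_suffix(".samples.tsv"), sep="\t")
    meta = {"units": matrix.units}
    prefix.with_suffix(".meta.json").write_text(json.dumps(meta, indent=2) + "\n")


def read_count_matrix_mtx(prefix) -> CountMatrix:
    prefix = Path(prefix)
    values = np.asarray(spio.mmread(str(prefix.with_suffix(".mtx"))).todense())
    features = pd.read_csv(prefix.with_suffix(".features.tsv"), sep="\t")["label"]
    sample_meta = pd.read_csv(prefix.with_suffix(".samples.tsv"), sep="\t", index_col="sample_id")
    meta = json.loads(prefix.with_suffix(".meta.json").read_text())
    return CountMatrix(
        values=pd.DataFrame(values, index=pd.Index(features, name="label"), columns=sample_meta.index),
        sample_meta=sample_meta,
        units=meta["units"],
    )


# ---------------------------------------------------------------------------
# cohort tables

DONOR_COLUMNS = ("donor_id", "group", "age", "sex")
SORT_COLUMNS = (
    "sample_id",
    "donor_id",
    "component",
    "sorted_count",
    "purity_pct",
    "elution_volume",
    "srna_conc",
    "plasma_input_volume",
)
ASSIGNMENT_COLUMNS = ("seq_id", "length", "class", "parent_gene", "start_pos")


def write_donors(donors: list[DonorRecord], path) -> None:
    components = sorted({c for d in donors for c in d.blood_counts})
    rows = []
    for d in donors:
        row = {"donor_id": d.donor_id, "group": d.group, "age": d.age, "sex": d.sex}
        for c in components:
            row[f"count_{c}"] = d.blood_counts.get(c, "")
        rows.append(row)
    write_table(pd.DataFrame(rows), path)


def read_donors(path) -> list[DonorRecord]:
    table = read_table(path, required_columns=DONOR_COLUMNS)
    count_cols = [c for c in table.columns if c.startswith("count_")]
    donors = []
    for i, row in table.iterrows():
        counts = {
            c[len("count_"):]: _to_float(row[c], path, i + 2, c)
            for c in count_cols
            if row[c] != ""
        }
        donors.append(
            DonorRecord(
                donor_id=row["donor_id"],
                group=row["group"],
                age=_to_float(row["age"], path, i + 2, "age"),
                sex=row["sex"],
                blood_counts=counts,
            )
        )
    return donors


def blood_count_frame(donors: list[DonorRecord]) -> pd.DataFrame:
    """Donor x cell-type blood counts (cells/µl) for correlation analysis."""
    frame = pd.DataFrame(
        {d.donor_id: d.blood_counts for d in donors}
    ).T.sort_index(axis=1)
    frame.index.name = "donor_id"
    return frame


def write_sort_samples(samples: list[SortSample], path) -> None:
    rows = []
    for s in samples:
        rows.append(
            {
                "sample_id": s.sample_id,
                "donor_id": s.donor_id,
                "component": s.component,
                "sorted_count": "" if s.sorted_count is None else s.sorted_count,
                "purity_pct": "" if s.purity_pct is None else s.purity_pct,
                "elution_volume": s.elution_volume,
                "srna_conc": "" if s.srna_conc is None else s.srna_conc,
                "plasma_input_volume": (
                    "" if s.plasma_input_volume is None else s.plasma_input_volume
                ),
            }
        )
    write_table(pd.DataFrame(rows, columns=list(SORT_COLUMNS)), path)


def read_sort_samples(path) -> list[SortSample]:
    table = read_table(path, required_columns=SORT_COLUMNS)

    def opt(row, col, i):
        return None if row[col] == "" else _to_float(row[col], path, i + 2, col)

    return [
        SortSample(
            sample_id=row["sample_id"],
            donor_id=row["donor_id"],
            component=row["component"],
            sorted_count=opt(row, "sorted_count", i),
            purity_pct=opt(row, "purity_pct", i),
            elution_volume=_to_float(row["elution_volume"], path, i + 2, "elution_volume"),
            srna_conc=opt(row, "srna_conc", i),
            plasma_input_volume=opt(row, "plasma_input_volume", i),
        )
        for i, row in table.iterrows()
    ]


# ---------------------------------------------------------------------------
# sequence-level assignment tables


def write_sequence_records(records: list[SequenceRecord], path) -> None:
    """Assignment table: one row per (sequence, candidate); count columns are
    repeated on every row of a sequence."""
    sample_ids = sorted({s for r in records for s in r.counts})
    rows = []
    for r in records:
        for cand in r.candidates:
            row = {
                "seq_id": r.seq_id,
                "length": r.length_nt,
                "class": cand.rna_class,
                "parent_gene": cand.parent_gene,
                "start_pos": "" if cand.start_pos is None else cand.start_pos,
            }
            for s in sample_ids:
                row[s] = r.counts.get(s, 0)
            rows.append(row)
    write_table(pd.DataFrame(rows, columns=list(ASSIGNMENT_COLUMNS) + sample_ids), path)


def read_sequence_records(path) -> list[SequenceRecord]:
    table = read_table(path, required_columns=ASSIGNMENT_COLUMNS)
    sample_ids = [c for c in table.columns if c not in ASSIGNMENT_COLUMNS]
    records: dict[str, SequenceRecord] = {}
    for i, row in table.iterrows():
        cand = AssignmentCandidate(
            rna_class=row["class"],
            parent_gene=row["parent_gene"],
            start_pos=None if row["start_pos"] == "" else int(float(row["start_pos"])),
        )
        if row["seq_id"] in records:
            records[row["seq_id"]].candidates.append(cand)
            continue
        counts = {}
        for s in sample_ids:
            v = _to_float(row[s], path, i + 2, s)
            if v > 0:
                counts[s] = int(v) if float(v).is_integer() else v
        records[row["seq_id"]] = SequenceRecord(
            seq_id=row["seq_id"],
            length_nt=int(float(row["length"])),
            candidates=[cand],
            counts=counts,
        )
    return list(records.values())


# ---------------------------------------------------------------------------
# synthetic truth


def write_truth(truth: SyntheticTruth, out_dir) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    truth.component_profiles.to_csv(out_dir / "truth_profiles.tsv", sep="\t")
    truth.true_contributions.to_csv(out_dir / "truth_contributions.tsv", sep="\t")
    sidecar = {
        "content_per_cell": truth.content_per_cell,
        "outlier_samples": sorted(truth.outlier_samples),
        "outlier_component": truth.outlier_component,
        "sample_alpha": truth.sample_alpha,
        "features": {
            label: {
                "rna_class": truth.feature_catalog.loc[label, "rna_class"],
                "marker_component": truth.marker_map[label],
                "contributions": {
                    c: (None if np.isnan(v) else v)
                    for c, v in truth.true_contributions.loc[label].items()
                },
            }
            for label in truth.feature_catalog.index
        },
    }
    (out_dir / "truth.json").write_text(json.dumps(sidecar, indent=1) + "\n")
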