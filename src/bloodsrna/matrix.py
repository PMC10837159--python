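"""Feature-by-sample expression container with tracked units."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import UnitsError

VALID_UNITS = ("reads", "RPM", "log2RPM")

#: Columns every sample-metadata table carries.
SAMPLE_META_COLUMNS = ("donor_id", "component", "is_whole_blood")


@dataclass
class CountMatrix:
    """A feature x sample matrix of read counts or normalized expression.

    Parameters
    ----------
    values
        DataFrame with annotation labels as the index and sample ids as
        columns. Non-negative.
    sample_meta
        DataFrame indexed by sample id with columns ``donor_id``,
        ``component`` and ``is_whole_blood``, aligned to ``values.columns``.
    units
        ``"reads"`` for raw counts, ``"RPM"`` for reads-per-million, or
        ``"log2RPM"`` for log2(RPM + 1).
    feature_classes
        Optional Series mapping each feature label to its RNA class.
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame
    units: str = "reads"
    feature_classes: pd.Series | None = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.units not in VALID_UNITS:
            raise UnitsError(f"units must be one of {VALID_UNITS}, got {self.units!r}")
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate feature labels: {dups}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        if not set(self.values.columns) <= set(self.sample_meta.index):
            missing = sorted(set(self.values.columns) - set(self.sample_meta.index))
            raise ValueError(f"samples without metadata: {missing}")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression values must be non-negative")
        # keep metadata aligned and restricted to the matrix columns
        self.sample_meta = self.sample_meta.loc[list(self.values.columns)]

    def check_rpm_sums(self, rtol: float = 1e-6) -> None:
        """Assert freshly normalized RPM columns sum to 1e6.

        Holds right after normalization; feature filters applied afterwards
        legitimately reduce column totals, so this is not part of general
        validation.
        """
        self.require_units("RPM")
        sums = self.values.sum(axis=0).to_numpy(dtype=float)
        nonzero = sums > 0
        if nonzero.any() and not np.allclose(sums[nonzero], 1e6, rtol=rtol):
            raise UnitsError("RPM columns with nonzero library must sum to 1e6")

    # -- convenience accessors -------------------------------------------------

    @property
    def features(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    @property
    def components(self) -> pd.Series:
        """Component label per sample, aligned to columns."""
        return self.sample_meta["component"]

    def require_units(self, units: str) -> None:
        if self.units != units:
            raise UnitsError(f"operation requires {units} matrix, got {self.units}")

    def copy(self) -> "CountMatrix":
        return CountMatrix(
            values=self.values.copy(),
            sample_meta=self.sample_meta.copy(),
            units=self.units,
            feature_classes=None if self.feature_classes is None else self.feature_classes.copy(),
        )

    def subset_samples(self, sample_ids) -> "CountMatrix":
        ids = [s for s in self.samples if s in set(sample_ids)]
        return CountMatrix(
            values=self.values[ids],
            sample_meta=self.sample_meta.loc[ids],
            units=self.units,
            feature_classes=self.feature_classes,
        )

    def samples_of(self, component: str) -> list[str]:
        meta = self.sample_meta
        mask = (meta["component"] == component) & ~meta["is_whole_blood"].astype(bool)
        return meta.index[mask].tolist()


def make_sample_meta(
    sample_ids,
    donor_ids,
    components,
    is_whole_blood=False,
) -> pd.DataFrame:
    """Assemble a sample-metadata frame from parallel sequences."""
    n = len(sample_ids)
    if np.isscalar(is_whole_blood):
        is_whole_blood = [bool(is_whole_blood)] * n
    return pd.DataFrame(
        {
            "donor_id": list(donor_ids),
            "component": list(components),
            "is_whole_blood": list(is_whole_blood),
        },
        index=pd.Index(list(sample_ids), name="sample_id"),
    )
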