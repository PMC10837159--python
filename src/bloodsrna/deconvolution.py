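"""Content-weighted deconvolution of blood-component contributions.

The method is a forward apportioning, not a regression: each purified
fraction's sRNA content per microliter of whole blood (alpha) is estimated
from bench metrics, the fraction's RPM expression is scaled by alpha, scaled
values are averaged per component, and each feature's scaled means are
normalized across components to proportions.

For a cellular fraction of cell type c from donor d:

    alpha_{c,d} = c_sRNA * V_elution * n_blood_count / n_sorted_count

(pg sRNA eluted per sorted cell, times the cell type's blood count). For
plasma, with V_input microliters of plasma extracted:

    alpha_d = c_sRNA * V_elution / V_input * plasma_fraction

where plasma_fraction is the assumed volume fraction of plasma in whole
blood (default 0.5). Then, per component b and feature s, over the D_b
samples of b with available content,

    xbar_{b,s} = (1/D_b) * sum_d x_{b,s,d} * alpha_{b,d}
    P_{b,s}    = xbar_{b,s} / sum_b' xbar_{b',s}

P rows sum to 1 and are invariant under any global rescaling of alpha.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from collections.abc import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import DataConsistencyError, MetadataError
from .matrix import CountMatrix
from .types import DonorRecord, SortSample

DEFAULT_PLASMA_FRACTION = 0.5


def srna_content_cell(
    c_srna: float,
    v_elution: float,
    n_blood_count: float,
    n_sorted_count: float,
) -> float:
    """sRNA content (pg per µl blood) of a purified cellular fraction.

    ``c_srna`` in pg/µl eluate, ``v_elution`` in µl, ``n_blood_count`` in
    cells/µl blood, ``n_sorted_count`` in cells.
    """
    if n_sorted_count <= 0:
        raise MetadataError(
            f"n_sorted_count must be > 0 (got {n_sorted_count}); cannot divide"
        )
    if min(c_srna, v_elution, n_blood_count) < 0:
        raise MetadataError("content inputs must be non-negative")
    return c_srna * v_elution * n_blood_count / n_sorted_count


def srna_content_plasma(
    c_srna: float,
    v_elution: float,
    v_input: float,
    plasma_fraction: float = DEFAULT_PLASMA_FRACTION,
) -> float:
    """sRNA content (pg per µl blood) of a plasma fraction.

    The eluted mass per µl of input plasma is scaled by the assumed volume
    fraction of plasma in whole blood.
    """
    if v_input <= 0:
        raise MetadataError(f"v_input must be > 0 (got {v_input}); cannot divide")
    if not 0.0 <= plasma_fraction <= 1.0:
        raise MetadataError(f"plasma_fraction must be in [0, 1], got {plasma_fraction}")
    if min(c_srna, v_elution) < 0:
        raise MetadataError("content inputs must be non-negative")
    return c_srna * v_elution / v_input * plasma_fraction


def compute_contents(
    sort_samples: Iterable[SortSample],
    donors: Iterable[DonorRecord] | Mapping[str, DonorRecord],
    plasma_fraction: float = DEFAULT_PLASMA_FRACTION,
) -> pd.DataFrame:
    """Per-sample sRNA content table (columns: donor_id, component, alpha).

    ``alpha`` is NaN for samples whose sRNA concentration could not be
    determined; such samples are skipped downstream.
    """
    if not isinstance(donors, Mapping):
        donors = {d.donor_id: d for d in donors}
    rows = {}
    for s in sort_samples:
        if s.srna_conc is None:
            alpha = np.nan
        elif s.is_plasma:
            alpha = srna_content_plasma(
                s.srna_conc, s.elution_volume, s.plasma_input_volume, plasma_fraction
            )
        else:
            donor = donors.get(s.donor_id)
            if donor is None or s.component not in donor.blood_counts:
                raise DataConsistencyError(
                    f"sample {s.sample_id!r}: no blood count for component "
                    f"{s.component!r} of donor {s.donor_id!r}"
                )
            alpha = srna_content_cell(
                s.srna_conc,
                s.elution_volume,
                donor.blood_counts[s.component],
                s.sorted_count,
            )
        rows[s.sample_id] = {"donor_id": s.donor_id, "component": s.component, "alpha": alpha}
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "sample_id"
    return table


@dataclass
class ContributionMatrix:
    """Per-feature proportional contribution of each blood component.

    ``proportions`` is feature x component; rows with any signal sum to 1,
    features with all-zero scaled means have NaN rows (``n_undefined`` of
    them). ``scaled_means`` holds the content-scaled mean expression and
    ``donor_counts`` the number of contributing samples per component.
    """

    proportions: pd.DataFrame
    scaled_means: pd.DataFrame
    donor_counts: pd.Series
    n_undefined: int = 0
    skipped_samples: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        sums = self.proportions.sum(axis=1, skipna=False).to_numpy()
        defined = ~np.isnan(sums)
        if not np.allclose(sums[defined], 1.0, atol=1e-9):
            raise ValueError("defined contribution rows must sum to 1 (tol 1e-9)")


def scaled_mean_expression(
    rpm: CountMatrix,
    contents: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.Series, list[str]]:
    """Content-scaled mean RPM per component (features x components).

    Only samples present in both the matrix and the content table with a
    defined alpha contribute; samples with missing alpha are skipped and
    reported. Every component must retain at least one contributing sample.
    """
    rpm.require_units("RPM")
    meta = rpm.sample_meta
    fraction_ids = [s for s in rpm.samples if not bool(meta.loc[s, "is_whole_blood"])]
    skipped = [
        s
        for s in fraction_ids
        if s not in contents.index or np.isnan(contents.loc[s, "alpha"])
    ]
    usable = [s for s in fraction_ids if s not in set(skipped)]
    components = sorted({meta.loc[s, "component"] for s in fraction_ids})
    empty = [
        c for c in components if not any(meta.loc[s, "component"] == c for s in usable)
    ]
    if empty:
        raise DataConsistencyError(
            f"component(s) without any content-bearing sample: {empty}"
        )
    xbar = {}
    counts = {}
    for comp in components:
        ids = [s for s in usable if meta.loc[s, "component"] == comp]
        alphas = contents.loc[ids, "alpha"].to_numpy(dtype=float)
        scaled = rpm.values[ids].to_numpy() * alphas[None, :]
        xbar[comp] = scaled.mean(axis=1)
        counts[comp] = len(ids)
    frame = pd.DataFrame(xbar, index=rpm.features)
    frame.columns.name = "component"
    return frame, pd.Series(counts, name="n_samples"), skipped


def contribution_proportions(
    xbar: pd.DataFrame,
    donor_counts: pd.Series | None = None,
    skipped_samples: list[str] | None = None,
) -> ContributionMatrix:
    """Normalize scaled means across components to proportions per feature."""
    if (xbar.to_numpy() < 0).any():
        raise ValueError("scaled mean expression must be non-negative")
    totals = xbar.sum(axis=1)
    undefined = totals <= 0
    proportions = xbar.div(totals.where(~undefined), axis=0)
    if donor_counts is None:
        donor_counts = pd.Series(0, index=xbar.columns, name="n_samples")
    return ContributionMatrix(
        proportions=proportions,
        scaled_means=xbar,
        donor_counts=donor_counts,
        n_undefined=int(undefined.sum()),
        skipped_samples=list(skipped_samples or []),
    )


def deconvolve(
    rpm: CountMatrix,
    contents: pd.DataFrame,
) -> ContributionMatrix:
    """Full pipeline: content-scaled means, then per-feature proportions."""
    xbar, counts, skipped = scaled_mean_expression(rpm, contents)
    return contribution_proportions(xbar, counts, skipped)
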