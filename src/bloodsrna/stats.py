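"""Descriptive and inferential statistics over component expression.

Covers relative sRNA profiles per blood component (with pooling of minor
features into 'others'), class-aggregated profiles, one-vs-rest
overrepresentation testing (Wilcoxon rank-sum with Benjamini-Hochberg
adjustment), detected-in-all-samples feature sets, whole-blood expression
versus blood-count correlation, and cross-dataset mean-expression
correlation.
"""

from __future__ import annotations

from dataclasses import dataclass
from collections.abc import Mapping

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import DataConsistencyError, StatisticsError, VocabularyError
from .matrix import CountMatrix

OTHERS_THRESHOLD = 0.02
MARKER_ALPHA = 0.05


def _component_samples(matrix: CountMatrix) -> dict[str, list[str]]:
    meta = matrix.sample_meta
    comps = {}
    for sample_id, row in meta.iterrows():
        if bool(row["is_whole_blood"]):
            continue
        comps.setdefault(row["component"], []).append(sample_id)
    return comps


# ---------------------------------------------------------------------------
# profiles


def component_profile(
    rpm: CountMatrix,
    others_threshold: float = OTHERS_THRESHOLD,
) -> pd.DataFrame:
    """Relative sRNA profile per component, minor features pooled.

    Per component: mean RPM per feature divided by the sum of all mean RPM
    values; features contributing less than ``others_threshold`` of the
    profile are combined into an ``others`` entry. Returns a tidy frame with
    columns component, feature, proportion (rows per component sum to 1).
    """
    rpm.require_units("RPM")
    groups = _component_samples(rpm)
    if not groups:
        raise DataConsistencyError("matrix contains no component fractions")
    rows = []
    for comp, ids in sorted(groups.items()):
        if not ids:
            raise DataConsistencyError(f"component {comp!r} has no samples")
        means = rpm.values[ids].mean(axis=1)
        prop = means / means.sum()
        minor = prop < others_threshold
        for feature, p in prop[~minor].sort_values(ascending=False).items():
            rows.append({"component": comp, "feature": feature, "proportion": float(p)})
        if minor.any():
            rows.append(
                {"component": comp, "feature": "others", "proportion": float(prop[minor].sum())}
            )
    return pd.DataFrame(rows)


def class_profile(
    rpm: CountMatrix,
    class_map: Mapping[str, str] | pd.Series | None = None,
) -> pd.DataFrame:
    """Per-component profile aggregated by RNA class.

    RPM values of all features of one class are summed per sample first,
    then averaged across the component's samples and normalized; the order
    (sum within sample, then mean) matters when library composition differs
    between samples. Returns a component x class proportion frame, rows
    summing to 1.
    """
    rpm.require_units("RPM")
    if class_map is None:
        class_map = rpm.feature_classes
    if class_map is None:
        raise VocabularyError("no feature class map available")
    classes = pd.Series(class_map)
    unmapped = [f for f in rpm.features if f not in classes.index or pd.isna(classes[f])]
    if unmapped:
        raise VocabularyError(f"features without RNA class: {unmapped[:5]}")
    per_sample = rpm.values.groupby(classes.loc[rpm.features].to_numpy()).sum()
    groups = _component_samples(rpm)
    out = {}
    for comp, ids in sorted(groups.items()):
        means = per_sample[ids].mean(axis=1)
        out[comp] = means / means.sum()
    frame = pd.DataFrame(out).T
    frame.index.name = "component"
    frame.columns.name = "rna_class"
    return frame


# ---------------------------------------------------------------------------
# overrepresented features


@dataclass(frozen=True)
class MarkerResult:
    """One feature x component overrepresentation test outcome."""

    feature: str
    component: str
    log2_fold_change: float
    p_value: float
    adj_p_value: float
    expressed_in_all_group_samples: bool

    @property
    def passes(self) -> bool:
        return (
            self.log2_fold_change > 0
            and self.adj_p_value < MARKER_ALPHA
            and self.expressed_in_all_group_samples
        )


def wilcoxon_rank_sum(group: np.ndarray, rest: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p-value (normal approximation with tie
    correction), as used by standard one-vs-rest marker scans."""
    res = sps.mannwhitneyu(group, rest, alternative="two-sided", method="asymptotic")
    return float(res.pvalue)


def overrepresented_srnas(
    log_matrix: CountMatrix,
    alpha: float = MARKER_ALPHA,
    min_log2_fc: float = 0.0,
    rpm_matrix: CountMatrix | None = None,
) -> pd.DataFrame:
    """One-vs-rest Wilcoxon scan for component-overrepresented features.

    Per component and feature, the log2(RPM+1) expression of the component's
    samples is compared against all other components' samples pooled;
    p-values are Benjamini-Hochberg adjusted across features within each
    component. The fold change is log2((mean RPM + 1) / (mean rest RPM + 1))
    with means taken on the linear RPM scale; the +1 pseudocount keeps it
    finite at zeros. A feature passes when its fold change exceeds
    ``min_log2_fc`` (default: any increase), its adjusted p-value is below
    ``alpha`` and it is expressed (RPM > 0) in every sample of the
    component.

    ``rpm_matrix`` may supply the linear-scale values; otherwise they are
    recovered from the log matrix as 2**x - 1.
    """
    log_matrix.require_units("log2RPM")
    groups = _component_samples(log_matrix)
    for comp, ids in groups.items():
        if len(ids) < 2:
            raise StatisticsError(f"component {comp!r} has {len(ids)} sample(s); need >= 2")
    if rpm_matrix is not None:
        rpm_matrix.require_units("RPM")
        linear = rpm_matrix.values
    else:
        linear = 2.0 ** log_matrix.values - 1.0
    rows = []
    all_fraction_ids = [s for ids in groups.values() for s in ids]
    for comp in sorted(groups):
        ids = groups[comp]
        rest_ids = [s for s in all_fraction_ids if s not in set(ids)]
        if len(rest_ids) < 2:
            raise StatisticsError(f"rest group for {comp!r} has fewer than 2 samples")
        G = log_matrix.values[ids].to_numpy()
        R = log_matrix.values[rest_ids].to_numpy()
        mean_g = linear[ids].to_numpy().mean(axis=1)
        mean_r = linear[rest_ids].to_numpy().mean(axis=1)
        expressed_all = (linear[ids].to_numpy() > 0).all(axis=1)
        pvals = np.array(
            [wilcoxon_rank_sum(G[i], R[i]) for i in range(len(log_matrix.features))]
        )
        adj = multipletests(pvals, method="fdr_bh")[1]
        lfc = np.log2((mean_g + 1.0) / (mean_r + 1.0))
        for i, feature in enumerate(log_matrix.features):
            rows.append(
                {
                    "feature": feature,
                    "component": comp,
                    "log2_fold_change": float(lfc[i]),
                    "p_value": float(pvals[i]),
                    "adj_p_value": float(adj[i]),
                    "expressed_in_all_group_samples": bool(expressed_all[i]),
                    "passes": bool(
                        lfc[i] > min_log2_fc and adj[i] < alpha and expressed_all[i]
                    ),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# detection and correlations


def detection_set(counts: CountMatrix) -> dict[str, set[str]]:
    """Features detected (count > 0) in every sample of each component."""
    groups = _component_samples(counts)
    out = {}
    for comp, ids in groups.items():
        detected = (counts.values[ids] > 0).all(axis=1)
        out[comp] = set(counts.features[detected])
    return out


def whole_blood_correlation(
    wb_rpm: CountMatrix,
    blood_counts: pd.DataFrame,
) -> pd.DataFrame:
    """Pearson r of each feature's whole-blood RPM against each cell-type
    blood count, across donors.

    ``blood_counts`` is donor x cell-type (cells/µl). Only donors with both
    an expression sample and counts enter; at least three are required.
    Pairs where either side has zero variance yield NaN.
    """
    wb_rpm.require_units("RPM")
    meta = wb_rpm.sample_meta
    donor_of = meta["donor_id"]
    shared = [s for s in wb_rpm.samples if donor_of[s] in blood_counts.index]
    if len(shared) < 3:
        raise StatisticsError(
            f"need >= 3 donors with expression and blood counts, got {len(shared)}"
        )
    expr = wb_rpm.values[shared].to_numpy()  # features x donors
    counts = blood_counts.loc[[donor_of[s] for s in shared]].to_numpy()  # donors x celltypes
    ex = expr - expr.mean(axis=1, keepdims=True)
    cx = counts - counts.mean(axis=0, keepdims=True)
    ex_sd = np.sqrt((ex**2).sum(axis=1))
    cx_sd = np.sqrt((cx**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (ex @ cx) / np.outer(ex_sd, cx_sd)
    r[:, cx_sd == 0] = np.nan
    r[ex_sd == 0, :] = np.nan
    return pd.DataFrame(r, index=wb_rpm.features, columns=blood_counts.columns)


def mean_expression_correlation(
    matrix_a: CountMatrix,
    matrix_b: CountMatrix,
    shared_features: list[str] | None = None,
) -> pd.Series:
    """Per-component Pearson r of mean log2(RPM+1) across shared features.

    Both matrices must carry RPM units; components present in both are
    compared on the features common to both (or an explicit list).
    """
    matrix_a.require_units("RPM")
    matrix_b.require_units("RPM")
    if shared_features is None:
        shared_features = [f for f in matrix_a.features if f in set(matrix_b.features)]
    if len(shared_features) < 3:
        raise StatisticsError(
            f"need >= 3 shared features, got {len(shared_features)}"
        )
    groups_a = _component_samples(matrix_a)
    groups_b = _component_samples(matrix_b)
    out = {}
    for comp in sorted(set(groups_a) & set(groups_b)):
        mean_a = np.log2(matrix_a.values.loc[shared_features, groups_a[comp]] + 1.0).mean(axis=1)
        mean_b = np.log2(matrix_b.values.loc[shared_features, groups_b[comp]] + 1.0).mean(axis=1)
        out[comp] = float(sps.pearsonr(mean_a, mean_b).statistic)
    return pd.Series(out, name="pearson_r")
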