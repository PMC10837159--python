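"""Reference cohort scenarios for recovery benchmarking.

These functions wire the simulator to the analysis stages under the study
conditions the package is designed around — a 52-donor, 11-component cohort
with 539 fractions after volume-driven dropout, 25 impure fractions, 4
mislabeled samples — and under controlled closure conditions (noise-free or
multinomial counts at fixed depth). They are used by the analysis drivers
and by the acceptance harness; every number they return is computed by
running the pipeline on freshly generated data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import deconvolution, preprocess, qc, simulate, stats
from .simulate import SimConfig

#: Study-scale cohort: 52 donors x 11 components with 33 deprioritized
#: fractions dropped (539 total), 25 purity failures, 4 mislabeled samples,
#: ~3% of samples without content metrics.
STUDY_COHORT = dict(
    n_donors=52,
    dropout=33,
    n_purity_fail=25,
    n_outliers=4,
    missing_content_rate=0.03,
    library_size=100_000,
)


@dataclass
class QCBookkeeping:
    n_fractions: int
    n_purity_excluded: int
    pct_purity_excluded: float
    n_after_purity: int
    n_embedding_excluded: int
    pct_embedding_excluded: float
    n_pass: int
    flagged_equals_planted: bool
    n_missing_content_after_qc: int
    pct_missing_content_after_qc: float


def study_qc_bookkeeping(seed: int, knn_k: int = qc.DEFAULT_KNN) -> QCBookkeeping:
    """Simulate the study-scale cohort and run both QC stages end to end."""
    cfg = SimConfig(seed=seed, **STUDY_COHORT)
    donors, samples, truth = simulate.simulate_cohort(cfg)
    records = simulate.simulate_counts(donors, samples, truth, cfg)
    counts = simulate.cohort_count_matrix(samples, records)
    passed, failed = qc.purity_filter(samples)
    log = preprocess.log_transform(preprocess.rpm_normalize(counts.subset_samples(passed)))
    coords = qc.embed(log, seed=seed)
    flagged = qc.flag_outliers(coords, log.components, k=knn_k)
    n_in, n_fail, n_flag = len(samples), len(failed), len(flagged)
    final = set(passed) - set(flagged)
    missing = [s.sample_id for s in samples if s.srna_conc is None and s.sample_id in final]
    return QCBookkeeping(
        n_fractions=n_in,
        n_purity_excluded=n_fail,
        pct_purity_excluded=100.0 * n_fail / n_in,
        n_after_purity=n_in - n_fail,
        n_embedding_excluded=n_flag,
        pct_embedding_excluded=100.0 * n_flag / (n_in - n_fail),
        n_pass=n_in - n_fail - n_flag,
        flagged_equals_planted=set(flagged) == truth.outlier_samples,
        n_missing_content_after_qc=len(missing),
        pct_missing_content_after_qc=100.0 * len(missing) / len(final),
    )


def deconvolution_closure(
    seed: int,
    n_donors: int = 40,
    exact_counts: bool = True,
    library_size: int = 1_000_000,
) -> dict:
    """Run content-weighted deconvolution on a synthetic cohort and measure
    recovery of the ground-truth contribution matrix.

    With ``exact_counts`` the cohort is noise-free (expectation-valued
    counts, exact metrics); otherwise counts are one multinomial draw per
    sample at ``library_size``.
    """
    cfg = SimConfig(
        n_donors=n_donors,
        library_size=library_size,
        exact_counts=exact_counts,
        content_noise_sd=0.0 if exact_counts else 0.25,
        outlier_rate=0.0,
        seed=seed,
    )
    donors, samples, truth = simulate.simulate_cohort(cfg)
    records = simulate.simulate_counts(donors, samples, truth, cfg)
    counts = simulate.cohort_count_matrix(samples, records)
    passed, _ = qc.purity_filter(samples)
    rpm = preprocess.rpm_normalize(counts.subset_samples(passed))
    contents = deconvolution.compute_contents(
        [s for s in samples if s.sample_id in set(passed)], donors
    )
    result = deconvolution.deconvolve(rpm, contents)
    diff = (result.proportions - truth.true_contributions).abs().to_numpy()
    return {
        "n_features": int(result.proportions.shape[0]),
        "n_components": int(result.proportions.shape[1]),
        "n_samples": len(passed),
        "max_abs_error": float(np.nanmax(diff)),
        "mean_abs_error": float(np.nanmean(diff)),
        "row_sum_max_abs_dev": float(
            np.nanmax(np.abs(result.proportions.sum(axis=1).to_numpy() - 1.0))
        ),
        "rpm_column_sum_max_rel_dev": float(
            np.abs(rpm.values.sum(axis=0).to_numpy() / 1e6 - 1.0).max()
        ),
    }


def marker_recovery(seed: int) -> dict:
    """One-vs-rest marker scan on a cohort with injected exclusive markers.

    Four components with 10 samples each; sensitivity is the fraction of
    planted markers called in their own component, and wrong-component calls
    count planted markers passing anywhere else.
    """
    cfg = SimConfig(
        n_donors=10,
        components=("monocytes", "neutrophils", "B cells", "NK cells"),
        library_size=100_000,
        purity_fail_rate=0.0,
        outlier_rate=0.0,
        missing_content_rate=0.0,
        seed=seed,
    )
    donors, samples, truth = simulate.simulate_cohort(cfg)
    records = simulate.simulate_counts(donors, samples, truth, cfg)
    counts = simulate.cohort_count_matrix(samples, records)
    rpm = preprocess.rpm_normalize(counts)
    scan = stats.overrepresented_srnas(preprocess.log_transform(rpm), rpm_matrix=rpm)
    passing = scan[scan["passes"]]
    markers = truth.marker_map.dropna()
    hit = 0
    wrong = 0
    for feature, comp in markers.items():
        called = set(passing.loc[passing["feature"] == feature, "component"])
        hit += comp in called
        wrong += len(called - {comp})
    return {
        "n_markers": int(len(markers)),
        "sensitivity": hit / len(markers),
        "wrong_component_calls": wrong,
        "n_samples_per_group": 10,
    }


def outlier_recovery(seed: int, knn_k: int = qc.DEFAULT_KNN) -> dict:
    """Embedding QC on the study-scale cohort: are exactly the planted
    mislabeled samples flagged?"""
    book = study_qc_bookkeeping(seed, knn_k=knn_k)
    return {
        "n_flagged": book.n_embedding_excluded,
        "exact": book.flagged_equals_planted,
        "n_samples": book.n_after_purity,
    }
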