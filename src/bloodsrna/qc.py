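"""Sample quality control: purity gating and embedding-outlier detection.

Two sequential filters mirror a sorted-blood-fraction study design. First,
cellular fractions need a flow-cytometry purity strictly above 70% (plasma
and whole blood carry no purity and bypass the gate). Second, the
log-normalized expression of the remaining samples is embedded into two
t-SNE dimensions and samples that do not sit among their own blood
component are excluded. "Does not cluster" is operationalized as a
k-nearest-neighbour majority rule: a sample is flagged when fewer than
``min_same_frac`` of its k nearest neighbours in the embedding share its
component label.
"""

from __future__ import annotations

from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE
from sklearn.neighbors import NearestNeighbors

from .errors import MetadataError, ParameterError
from .matrix import CountMatrix
from .types import SortSample

PURITY_THRESHOLD_PCT = 70.0
DEFAULT_PERPLEXITY = 30.0
DEFAULT_KNN = 15
DEFAULT_MIN_SAME_FRAC = 0.5


@dataclass
class QCReport:
    """Outcome of both QC stages for one cohort."""

    excluded_purity: list[str]
    excluded_embedding: list[str]
    n_input: int
    n_pass: int
    embedding: pd.DataFrame | None = None
    parameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        excluded = set(self.excluded_purity) | set(self.excluded_embedding)
        if self.n_pass != self.n_input - len(excluded):
            raise ValueError("n_pass must equal n_input minus the excluded set")

    @property
    def purity_excluded_pct(self) -> float:
        return 100.0 * len(self.excluded_purity) / self.n_input if self.n_input else 0.0

    @property
    def embedding_excluded_pct(self) -> float:
        n_after_purity = self.n_input - len(self.excluded_purity)
        return 100.0 * len(self.excluded_embedding) / n_after_purity if n_after_purity else 0.0


def purity_filter(
    sort_samples: Iterable[SortSample],
    threshold_pct: float = PURITY_THRESHOLD_PCT,
) -> tuple[list[str], list[str]]:
    """Split samples into (pass, fail) ids by the strict purity gate.

    A cellular fraction passes iff purity_pct > threshold (a purity of
    exactly 70 fails). Plasma fractions have no purity and always pass;
    a cellular fraction without a purity value is a metadata error.
    """
    passed, failed = [], []
    for s in sort_samples:
        if s.is_plasma:
            passed.append(s.sample_id)
            continue
        if s.purity_pct is None:
            raise MetadataError(f"cellular fraction {s.sample_id!r} has no purity value")
        (passed if s.purity_pct > threshold_pct else failed).append(s.sample_id)
    return passed, failed


def embed(
    log_matrix: CountMatrix,
    seed: int,
    perplexity: float = DEFAULT_PERPLEXITY,
    n_pca: int = 50,
) -> pd.DataFrame:
    """2-D t-SNE of log2(RPM+1) expression, samples as points.

    Expression is first reduced by PCA (at most ``n_pca`` components) for
    speed and stability, then embedded with a fixed random state. The
    requested perplexity is reduced automatically when the cohort is small
    (it must be below the number of samples).
    """
    log_matrix.require_units("log2RPM")
    X = log_matrix.values.to_numpy().T  # samples x features
    n = X.shape[0]
    if n < 3:
        raise ParameterError(f"t-SNE needs >= 3 samples, got {n}")
    perplexity = min(perplexity, (n - 1) / 3.0)
    if perplexity < 1:
        raise ParameterError(
            f"{n} samples leave no valid perplexity; provide more samples"
        )
    k = min(n_pca, n - 1, X.shape[1])
    if k >= 2 and X.shape[1] > k:
        X = PCA(n_components=k, random_state=seed).fit_transform(X)
    coords = TSNE(
        n_components=2,
        perplexity=perplexity,
        random_state=seed,
        init="pca",
    ).fit_transform(X)
    return pd.DataFrame(
        coords, index=log_matrix.samples, columns=["tsne1", "tsne2"]
    )


def flag_outliers(
    coords: pd.DataFrame,
    component_labels: Sequence[str] | pd.Series,
    k: int = DEFAULT_KNN,
    min_same_frac: float = DEFAULT_MIN_SAME_FRAC,
) -> list[str]:
    """Samples whose embedding neighbourhood disagrees with their label.

    Flags a sample iff the fraction of its ``k`` nearest neighbours
    (Euclidean, in the 2-D embedding, excluding itself) with the same
    component label is strictly below ``min_same_frac``.
    """
    if k <= 0:
        raise ParameterError(f"k must be positive, got {k}")
    n = len(coords)
    if k >= n:
        raise ParameterError(f"k={k} must be below the number of samples ({n})")
    labels = np.asarray(pd.Series(component_labels, index=coords.index).loc[coords.index])
    nn = NearestNeighbors(n_neighbors=k + 1).fit(coords.to_numpy())
    _, idx = nn.kneighbors(coords.to_numpy())
    flagged = []
    for i, sample_id in enumerate(coords.index):
        neigh = idx[i][idx[i] != i][:k]
        same = float(np.mean(labels[neigh] == labels[i]))
        if same < min_same_frac:
            flagged.append(sample_id)
    return flagged


def run_qc(
    sort_samples: list[SortSample],
    log_matrix: CountMatrix,
    seed: int,
    purity_threshold_pct: float = PURITY_THRESHOLD_PCT,
    perplexity: float = DEFAULT_PERPLEXITY,
    k: int = DEFAULT_KNN,
    min_same_frac: float = DEFAULT_MIN_SAME_FRAC,
) -> QCReport:
    """Purity gate, then embedding-outlier detection on the survivors."""
    passed, failed = purity_filter(sort_samples, purity_threshold_pct)
    sub = log_matrix.subset_samples(passed)
    coords = embed(sub, seed=seed, perplexity=perplexity)
    flagged = flag_outliers(coords, sub.components, k=k, min_same_frac=min_same_frac)
    n_input = len(sort_samples)
    return QCReport(
        excluded_purity=failed,
        excluded_embedding=flagged,
        n_input=n_input,
        n_pass=n_input - len(failed) - len(flagged),
        embedding=coords,
        parameters={
            "purity_threshold_pct": purity_threshold_pct,
            "perplexity": perplexity,
            "k": k,
            "min_same_frac": min_same_frac,
            "seed": seed,
        },
    )
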