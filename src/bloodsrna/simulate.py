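"""Seeded synthetic cohorts with ground truth.

The generator emulates the structure of a purified-blood-component sRNA
study: ~50 donors, 11 blood components (plasma plus ten cell types), eight
small-RNA classes, component-specific expression profiles with
component-exclusive marker features, cell-sorting metrics (sorted cell
count, purity, elution volume, sRNA concentration), donor blood counts, and
whole-blood samples formed as sRNA-content-weighted mixtures of the
component profiles. Injected defects — purity failures, mislabeled
(wrong-profile) samples, missing content metrics, dropped low-priority
fractions — exercise the QC and bookkeeping paths.

Counts follow a multinomial model: each sample draws ``library_size`` reads
from its component's relative-abundance profile, optionally perturbed by a
Dirichlet draw whose variance is controlled by ``noise_dispersion``
(dispersion 0 = pure multinomial). ``exact_counts=True`` replaces the draw
by its expectation, the noise-free limit used for closure checks.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataConsistencyError
from .matrix import CountMatrix, make_sample_meta
from .types import AssignmentCandidate, DonorRecord, SequenceRecord, SortSample

DEFAULT_COMPONENTS: tuple[str, ...] = (
    "plasma",
    "erythrocytes",
    "thrombocytes",
    "monocytes",
    "neutrophils",
    "eosinophils",
    "basophils",
    "NK cells",
    "CD4 T cells",
    "CD8 T cells",
    "B cells",
)

#: Fractions skipped first when blood volume runs short: lymphocyte
#: purification takes precedence over these.
DEPRIORITIZED_COMPONENTS: tuple[str, ...] = (
    "thrombocytes",
    "eosinophils",
    "basophils",
    "plasma",
)

#: Typical absolute blood counts (cells per µl whole blood) used as donor
#: means; per-donor values vary log-normally around these.
DEFAULT_BLOOD_COUNTS: dict[str, float] = {
    "erythrocytes": 5.0e6,
    "thrombocytes": 2.5e5,
    "monocytes": 500.0,
    "neutrophils": 4000.0,
    "eosinophils": 200.0,
    "basophils": 50.0,
    "NK cells": 300.0,
    "CD4 T cells": 900.0,
    "CD8 T cells": 500.0,
    "B cells": 250.0,
}

#: Assumed sRNA mass per cell (pg/cell); for plasma, pg per µl plasma.
#: Free parameters of the simulation, not calibrated to any measured values.
DEFAULT_CONTENT_PER_CELL: dict[str, float] = {
    "plasma": 10.0,
    "erythrocytes": 5.0e-4,
    "thrombocytes": 2.0e-3,
    "monocytes": 0.10,
    "neutrophils": 0.05,
    "eosinophils": 0.05,
    "basophils": 0.05,
    "NK cells": 0.08,
    "CD4 T cells": 0.08,
    "CD8 T cells": 0.08,
    "B cells": 0.08,
}

#: Typical sorted-cell yields per fraction (cells), log-normal per sample.
DEFAULT_SORTED_COUNTS: dict[str, float] = {
    "erythrocytes": 3.0e7,
    "thrombocytes": 1.0e8,
    "monocytes": 3.0e6,
    "neutrophils": 1.0e7,
    "eosinophils": 1.0e6,
    "basophils": 3.0e5,
    "NK cells": 1.0e6,
    "CD4 T cells": 4.0e6,
    "CD8 T cells": 2.0e6,
    "B cells": 1.0e6,
}

DEFAULT_FEATURES_PER_CLASS: dict[str, int] = {
    "miRNA": 65,
    "tRNA": 45,
    "rRNA": 40,
    "YRNA": 15,
    "snoRNA": 35,
    "lncRNA": 35,
    "snRNA": 30,
    "piRNA": 35,
}

#: Parent transcripts for binned classes with their lengths (nt).
RRNA_PARENTS: dict[str, int] = {
    "RNA18SN5": 1869,
    "RNA28SN5": 5070,
    "RNA5-8SN5": 157,
    "RNA5S1": 121,
}
YRNA_PARENTS: dict[str, int] = {"RNY1": 112, "RNY3": 101, "RNY4": 93, "RNY5": 83}

_AMINO = ("Ala", "Arg", "Asp", "Cys", "Gly", "Glu", "His", "Leu", "Lys", "Val")
_ANTICODON = ("AGC", "ACG", "GTC", "GCA", "GCC", "TTC", "GTG", "AAG", "CTT", "CAC")

#: Cohort group mix and demographics echoing a mixed clinical cohort.
GROUP_WEIGHTS: dict[str, float] = {
    "healthy": 12 / 52,
    "lung_cancer": 19 / 52,
    "non_malignant_lung_disease": 21 / 52,
}
GROUP_AGE: dict[str, tuple[float, float]] = {
    "healthy": (55.0, 3.0),
    "lung_cancer": (67.0, 8.0),
    "non_malignant_lung_disease": (63.0, 7.0),
}
FEMALE_FRACTION = 30 / 52


@dataclass
class SimConfig:
    """Parameters of one synthetic cohort.

    Rates are fractions in [0, 1]; the corresponding integer overrides
    (``n_purity_fail``, ``n_outliers``) pin exact counts when a scenario
    requires them (rates are rounded otherwise). ``dropout`` removes that
    many fractions from the deprioritized components to mimic limited blood
    volume. ``exact_counts`` replaces count sampling by its expectation.
    """

    n_donors: int = 52
    components: tuple[str, ...] = DEFAULT_COMPONENTS
    n_features_per_class: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_FEATURES_PER_CLASS)
    )
    marker_fraction: float = 0.2
    library_size: int = 1_000_000
    noise_dispersion: float = 0.0
    purity_fail_rate: float = 0.046
    outlier_rate: float = 0.008
    missing_content_rate: float = 0.03
    plasma_fraction: float = 0.5
    dropout: int = 0
    n_purity_fail: int | None = None
    n_outliers: int | None = None
    content_noise_sd: float = 0.25
    exact_counts: bool = False
    split_fraction: float = 0.1
    decoy_probability: float = 0.3
    elution_volume: float = 14.0
    plasma_input_volume: float = 200.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_donors < 2:
            raise ConfigurationError(f"n_donors must be >= 2, got {self.n_donors}")
        self.components = tuple(self.components)
        if not self.components:
            raise ConfigurationError("components must be non-empty")
        if len(set(self.components)) != len(self.components):
            raise ConfigurationError("components must be unique")
        for name in (
            "marker_fraction",
            "purity_fail_rate",
            "outlier_rate",
            "missing_content_rate",
            "plasma_fraction",
            "split_fraction",
            "decoy_probability",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        if self.library_size <= 0:
            raise ConfigurationError(f"library_size must be > 0, got {self.library_size}")
        if self.noise_dispersion < 0:
            raise ConfigurationError(
                f"noise_dispersion must be >= 0, got {self.noise_dispersion}"
            )
        if self.content_noise_sd < 0:
            raise ConfigurationError(
                f"content_noise_sd must be >= 0, got {self.content_noise_sd}"
            )
        if self.dropout < 0:
            raise ConfigurationError(f"dropout must be >= 0, got {self.dropout}")
        bad = {c for c in self.n_features_per_class if self.n_features_per_class[c] < 0}
        if bad:
            raise ConfigurationError(f"n_features_per_class negative for {sorted(bad)}")
        if not isinstance(self.seed, (int, np.integer)):
            raise ConfigurationError(f"seed must be an integer, got {self.seed!r}")

    @property
    def cellular_components(self) -> tuple[str, ...]:
        return tuple(c for c in self.components if c != "plasma")


@dataclass
class SyntheticTruth:
    """Ground truth of a simulated cohort.

    ``component_profiles`` is a component x feature matrix of relative
    abundances (rows sum to 1). ``true_contributions`` is the feature x
    component matrix of expected content-weighted proportions over exactly
    the samples the deconvolution will use (QC-passing, non-outlier, with
    content metrics); its rows sum to 1. ``sample_alpha`` records the
    realized sRNA content (pg per µl blood) of every sample with metrics.
    """

    component_profiles: pd.DataFrame
    content_per_cell: dict[str, float]
    true_contributions: pd.DataFrame
    outlier_samples: set[str]
    marker_map: pd.Series
    feature_catalog: pd.DataFrame
    outlier_component: dict[str, str] = field(default_factory=dict)
    sample_alpha: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        prof_sums = self.component_profiles.sum(axis=1).to_numpy()
        if not np.allclose(prof_sums, 1.0, atol=1e-9):
            raise DataConsistencyError("component profile rows must sum to 1")
        contrib = self.true_contributions.to_numpy()
        sums = contrib.sum(axis=1)
        if not np.allclose(sums[sums > 0], 1.0, atol=1e-9):
            raise DataConsistencyError("true contribution rows must sum to 1")


def absolute_subpopulation_counts(rel_freq: float, parent_abs: float) -> float:
    """Convert a subpopulation's relative frequency to cells/µl by scaling
    its parent population's absolute count."""
    if not 0.0 <= rel_freq <= 1.0:
        raise ConfigurationError(f"rel_freq must be in [0, 1], got {rel_freq}")
    if parent_abs < 0:
        raise ConfigurationError(f"parent_abs must be >= 0, got {parent_abs}")
    return rel_freq * parent_abs


# ---------------------------------------------------------------------------
# feature catalog and profiles


def _round_counts(weights: dict[str, float], total: int) -> dict[str, int]:
    """Largest-remainder apportionment of ``total`` across weights."""
    raw = {k: w * total for k, w in weights.items()}
    counts = {k: int(math.floor(v)) for k, v in raw.items()}
    left = total - sum(counts.values())
    for k in sorted(raw, key=lambda k: raw[k] - counts[k], reverse=True)[:left]:
        counts[k] += 1
    return counts


def _binned_catalog(parents: dict[str, int], n: int, cls: str, rng) -> list[dict]:
    pairs = [
        (parent, b)
        for parent, length in parents.items()
        for b in range(1, math.ceil(length / 25) + 1)
    ]
    if n > len(pairs):
        raise ConfigurationError(
            f"n_features_per_class[{cls!r}]={n} exceeds the {len(pairs)} distinct bins"
        )
    chosen = [pairs[i] for i in rng.choice(len(pairs), size=n, replace=False)]
    rows = []
    for parent, b in sorted(chosen):
        lo, hi = 25 * (b - 1) + 1, min(25 * b, parents[parent])
        start = int(rng.integers(lo, hi + 1))
        rows.append(
            {
                "label": f"{parent}-bin{b}",
                "rna_class": cls,
                "parent_gene": parent,
                "start_pos": start,
            }
        )
    return rows


def build_feature_catalog(config: SimConfig, rng) -> pd.DataFrame:
    """One row per feature: label, RNA class, parent gene, start position."""
    rows: list[dict] = []
    for cls, n in config.n_features_per_class.items():
        if cls == "rRNA":
            rows.extend(_binned_catalog(RRNA_PARENTS, n, cls, rng))
        elif cls == "YRNA":
            rows.extend(_binned_catalog(YRNA_PARENTS, n, cls, rng))
        else:
            for i in range(n):
                if cls == "miRNA":
                    arm = "5p" if i % 2 == 0 else "3p"
                    name = f"hsa-miR-{100 + i}-{arm}"
                elif cls == "tRNA":
                    name = f"tRNA-{_AMINO[i % 10]}-{_ANTICODON[i % 10]}-{i // 10 + 1}"
                elif cls == "snoRNA":
                    name = f"SNORD{10 + i}"
                elif cls == "lncRNA":
                    name = f"LINC{1000 + i:05d}"
                elif cls == "snRNA":
                    name = f"RNU{1 + i}-1"
                elif cls == "piRNA":
                    name = f"piR-hsa-{1000 + i}"
                else:
                    name = f"{cls}-{i}"
                rows.append(
                    {"label": name, "rna_class": cls, "parent_gene": name, "start_pos": None}
                )
    catalog = pd.DataFrame(rows)
    if catalog["label"].duplicated().any():
        raise DataConsistencyError("feature catalog produced duplicate labels")
    return catalog.set_index("label")


def _make_profiles(
    config: SimConfig, catalog: pd.DataFrame, rng
) -> tuple[pd.DataFrame, pd.Series]:
    """Component x feature relative abundances with exclusive markers.

    Each component's own markers jointly carry half of its profile mass,
    giving well-separated components; marker features are zero everywhere
    else.
    """
    features = catalog.index
    n_feat = len(features)
    comps = list(config.components)
    n_markers = int(round(config.marker_fraction * n_feat))
    marker_idx = rng.choice(n_feat, size=n_markers, replace=False)
    marker_map = pd.Series([None] * n_feat, index=features, dtype=object, name="component")
    for j, idx in enumerate(sorted(marker_idx)):
        marker_map.iloc[idx] = comps[j % len(comps)]

    profiles = np.zeros((len(comps), n_feat))
    shared = (marker_map.isna()).to_numpy()
    for i, comp in enumerate(comps):
        own = (marker_map == comp).to_numpy()
        row = np.zeros(n_feat)
        row[shared] = rng.lognormal(mean=0.0, sigma=1.5, size=shared.sum())
        if own.any():
            w = rng.lognormal(mean=0.0, sigma=0.5, size=own.sum())
            # own markers carry the same total mass as all shared features
            row[own] = w / w.sum() * row[shared].sum()
        profiles[i] = row / row.sum()
    return (
        pd.DataFrame(profiles, index=pd.Index(comps, name="component"), columns=features),
        marker_map,
    )


# ---------------------------------------------------------------------------
# cohort


def _sample_id(donor_id: str, component: str) -> str:
    return f"{donor_id}_{component.replace(' ', '-')}"


def _make_donors(config: SimConfig, rng) -> list[DonorRecord]:
    counts = _round_counts(GROUP_WEIGHTS, config.n_donors)
    groups = [g for g, n in counts.items() for _ in range(n)]
    donors = []
    width = max(2, len(str(config.n_donors)))
    for i, group in enumerate(groups):
        mu, sd = GROUP_AGE[group]
        blood_counts = {}
        for comp in config.cellular_components:
            base = DEFAULT_BLOOD_COUNTS.get(comp, 1000.0)
            blood_counts[comp] = float(base * rng.lognormal(0.0, 0.15))
        donors.append(
            DonorRecord(
                donor_id=f"D{i + 1:0{width}d}",
                group=group,
                age=float(np.clip(rng.normal(mu, sd), 18, 95)),
                sex="female" if rng.random() < FEMALE_FRACTION else "male",
                blood_counts=blood_counts,
            )
        )
    return donors


def expected_alpha(component: str, donor: DonorRecord, config: SimConfig) -> float:
    """Noise-free sRNA content (pg per µl blood) of one donor's fraction."""
    content = DEFAULT_CONTENT_PER_CELL.get(component, 0.05)
    if component == "plasma":
        return content * config.plasma_fraction
    if component not in donor.blood_counts:
        raise DataConsistencyError(
            f"donor {donor.donor_id!r} has no blood count for {component!r}"
        )
    return content * donor.blood_counts[component]


def simulate_cohort(
    config: SimConfig,
) -> tuple[list[DonorRecord], list[SortSample], SyntheticTruth]:
    """Generate donors, sorted fractions with metrics, and ground truth.

    Deterministic given ``config.seed``. One fraction per donor x component,
    minus ``config.dropout`` fractions removed from the deprioritized
    components. Purity failures, missing content metrics and mislabeled
    (outlier) samples are planted at the configured rates/counts.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    donors = _make_donors(config, rng)
    catalog = build_feature_catalog(config, rng)
    profiles, marker_map = _make_profiles(config, catalog, rng)

    # fractions, with dropout restricted to deprioritized components
    all_pairs = [(d, c) for d in donors for c in config.components]
    droppable = [
        i for i, (_, c) in enumerate(all_pairs) if c in DEPRIORITIZED_COMPONENTS
    ]
    if config.dropout > len(droppable):
        raise ConfigurationError(
            f"dropout={config.dropout} exceeds the {len(droppable)} deprioritized fractions"
        )
    dropped = set(rng.choice(droppable, size=config.dropout, replace=False)) if config.dropout else set()
    pairs = [p for i, p in enumerate(all_pairs) if i not in dropped]

    cellular_idx = [i for i, (_, c) in enumerate(pairs) if c != "plasma"]
    n_fail = (
        config.n_purity_fail
        if config.n_purity_fail is not None
        else int(round(config.purity_fail_rate * len(cellular_idx)))
    )
    if n_fail > len(cellular_idx):
        raise ConfigurationError("n_purity_fail exceeds the number of cellular fractions")
    fail_set = set(rng.choice(cellular_idx, size=n_fail, replace=False)) if n_fail else set()

    n_missing = int(round(config.missing_content_rate * len(pairs)))
    missing_set = set(rng.choice(len(pairs), size=n_missing, replace=False)) if n_missing else set()

    samples: list[SortSample] = []
    sample_alpha: dict[str, float] = {}
    for i, (donor, comp) in enumerate(pairs):
        sid = _sample_id(donor.donor_id, comp)
        noise = float(np.exp(rng.normal(0.0, config.content_noise_sd))) if config.content_noise_sd else 1.0
        content = DEFAULT_CONTENT_PER_CELL.get(comp, 0.05)
        if comp == "plasma":
            # c_sRNA chosen so Eq. 2 recovers content * plasma_fraction * noise
            c_srna = content * config.plasma_input_volume / config.elution_volume * noise
            sample = SortSample(
                sample_id=sid,
                donor_id=donor.donor_id,
                component=comp,
                purity_pct=None,
                elution_volume=config.elution_volume,
                srna_conc=None if i in missing_set else c_srna,
                plasma_input_volume=config.plasma_input_volume,
            )
            alpha = content * config.plasma_fraction * noise
        else:
            sorted_count = float(
                DEFAULT_SORTED_COUNTS.get(comp, 1.0e6) * rng.lognormal(0.0, 0.3)
            )
            if i in fail_set:
                purity = float(rng.uniform(40.0, 70.0))
            else:
                purity = float(rng.uniform(85.0, 99.9))
            # c_sRNA chosen so Eq. 1 recovers content * blood_count * noise
            c_srna = content * sorted_count / config.elution_volume * noise
            sample = SortSample(
                sample_id=sid,
                donor_id=donor.donor_id,
                component=comp,
                sorted_count=sorted_count,
                purity_pct=purity,
                elution_volume=config.elution_volume,
                srna_conc=None if i in missing_set else c_srna,
            )
            alpha = content * donor.blood_counts[comp] * noise
        if sample.srna_conc is not None:
            sample_alpha[sid] = alpha
        samples.append(sample)

    # outliers: planted only among samples that survive the purity filter
    eligible = [
        s.sample_id
        for s in samples
        if s.is_plasma or (s.purity_pct is not None and s.purity_pct > 70.0)
    ]
    n_out = (
        config.n_outliers
        if config.n_outliers is not None
        else int(round(config.outlier_rate * len(samples)))
    )
    if n_out > len(eligible):
        raise ConfigurationError("n_outliers exceeds the number of eligible samples")
    outlier_ids = sorted(
        rng.choice(eligible, size=n_out, replace=False).tolist()
    ) if n_out else []
    comp_of = {s.sample_id: s.component for s in samples}
    outlier_component = {}
    for sid in outlier_ids:
        others = [c for c in config.components if c != comp_of[sid]]
        outlier_component[sid] = str(rng.choice(others))

    truth = SyntheticTruth(
        component_profiles=profiles,
        content_per_cell={c: DEFAULT_CONTENT_PER_CELL.get(c, 0.05) for c in config.components},
        true_contributions=_true_contributions(
            config, samples, profiles, sample_alpha, set(outlier_ids)
        ),
        outlier_samples=set(outlier_ids),
        marker_map=marker_map,
        feature_catalog=catalog,
        outlier_component=outlier_component,
        sample_alpha=sample_alpha,
    )
    return donors, samples, truth


def _true_contributions(
    config: SimConfig,
    samples: list[SortSample],
    profiles: pd.DataFrame,
    sample_alpha: dict[str, float],
    outlier_ids: set[str],
) -> pd.DataFrame:
    """Expected contribution proportions over the usable samples.

    Uses the realized per-sample contents of exactly those samples that pass
    purity, are not planted outliers and carry content metrics — the set the
    deconvolution will average over — with the noise-free expression
    expectation (profile x 1e6 RPM).
    """
    mean_alpha = {}
    for comp in config.components:
        alphas = [
            sample_alpha[s.sample_id]
            for s in samples
            if s.component == comp
            and s.sample_id in sample_alpha
            and s.sample_id not in outlier_ids
            and (s.is_plasma or (s.purity_pct is not None and s.purity_pct > 70.0))
        ]
        mean_alpha[comp] = float(np.mean(alphas)) if alphas else 0.0
    xbar = profiles.mul(pd.Series(mean_alpha), axis=0) * 1e6  # component x feature
    totals = xbar.sum(axis=0)
    contrib = xbar.T.div(totals.replace(0.0, np.nan), axis=0).fillna(0.0)
    contrib.index.name = "label"
    contrib.columns.name = "component"
    return contrib


# ---------------------------------------------------------------------------
# counts


def _draw_profile(profile: np.ndarray, dispersion: float, rng) -> np.ndarray:
    if dispersion <= 0:
        return profile
    p = np.zeros_like(profile)
    pos = profile > 0
    p[pos] = rng.dirichlet(profile[pos] / dispersion)
    return p


def _draw_counts(p: np.ndarray, library_size: int, exact: bool, rng) -> np.ndarray:
    if exact:
        return p * library_size
    return rng.multinomial(library_size, p).astype(float)


def simulate_counts(
    donors: list[DonorRecord],
    sort_samples: list[SortSample],
    truth: SyntheticTruth,
    config: SimConfig,
) -> list[SequenceRecord]:
    """Sequence-level assignment records with per-sample counts.

    Each sample's counts are multinomial draws of ``library_size`` reads from
    its component's profile (planted outliers draw from their wrong
    component's profile). Each feature becomes one sequence record — or two
    records sharing the winning annotation for a ``split_fraction`` of
    features — and a ``decoy_probability`` fraction of records carry an
    additional lower-priority candidate, so annotation resolution and
    collapsing are genuinely exercised.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    catalog = truth.feature_catalog
    features = catalog.index.to_list()
    profiles = truth.component_profiles
    for s in sort_samples:
        comp = truth.outlier_component.get(s.sample_id, s.component)
        if comp not in profiles.index:
            raise DataConsistencyError(
                f"sample {s.sample_id!r}: component {comp!r} has no profile"
            )

    counts = np.zeros((len(features), len(sort_samples)))
    for j, s in enumerate(sort_samples):
        comp = truth.outlier_component.get(s.sample_id, s.component)
        p = _draw_profile(profiles.loc[comp].to_numpy(), config.noise_dispersion, rng)
        counts[:, j] = _draw_counts(p, config.library_size, config.exact_counts, rng)

    sample_ids = [s.sample_id for s in sort_samples]
    split = rng.random(len(features)) < config.split_fraction
    records: list[SequenceRecord] = []
    seq_no = 0
    for i, label in enumerate(features):
        row = catalog.loc[label]
        primary = AssignmentCandidate(
            rna_class=row["rna_class"],
            parent_gene=row["parent_gene"],
            start_pos=None if pd.isna(row["start_pos"]) else int(row["start_pos"]),
        )
        parts: list[np.ndarray]
        if split[i]:
            if config.exact_counts:
                parts = [counts[i] / 2.0, counts[i] / 2.0]
            else:
                first = rng.binomial(counts[i].astype(int), 0.5).astype(float)
                parts = [first, counts[i] - first]
        else:
            parts = [counts[i]]
        for part in parts:
            seq_no += 1
            cands = [primary]
            if row["rna_class"] != "piRNA" and rng.random() < config.decoy_probability:
                cands.append(
                    AssignmentCandidate(rna_class="piRNA", parent_gene=f"piR-hsa-9{seq_no:04d}")
                )
            records.append(
                SequenceRecord(
                    seq_id=f"seq{seq_no:05d}",
                    length_nt=int(rng.integers(18, 34)),
                    candidates=cands,
                    counts={
                        sid: float(v) if config.exact_counts else int(v)
                        for sid, v in zip(sample_ids, part)
                        if v > 0
                    },
                )
            )
    return records


def simulate_whole_blood(
    donors: list[DonorRecord],
    truth: SyntheticTruth,
    config: SimConfig,
) -> CountMatrix:
    """Whole-blood samples as content-weighted mixtures of component profiles.

    For donor d the expected abundance of feature s is
    ``sum_b alpha_{b,d} * x_{b,s}`` (normalized), where alpha is the
    noise-free sRNA content per µl blood of component b computed from the
    donor's blood counts and the assumed per-cell masses; counts are then
    sampled at ``library_size``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    profiles = truth.component_profiles
    features = profiles.columns
    values = {}
    for donor in donors:
        alpha = np.array([expected_alpha(c, donor, config) for c in profiles.index])
        mix = alpha @ profiles.to_numpy()
        mix = mix / mix.sum()
        values[f"{donor.donor_id}_WB"] = _draw_counts(
            mix, config.library_size, config.exact_counts, rng
        )
    frame = pd.DataFrame(values, index=features)
    meta = make_sample_meta(
        frame.columns,
        [d.donor_id for d in donors],
        ["whole_blood"] * len(donors),
        is_whole_blood=True,
    )
    return CountMatrix(values=frame, sample_meta=meta, units="reads")


def cohort_count_matrix(
    sort_samples: list[SortSample],
    records: list[SequenceRecord],
) -> CountMatrix:
    """Collapse simulated sequence records into a component-sample matrix."""
    from .annotation import collapse_counts

    meta = make_sample_meta(
        [s.sample_id for s in sort_samples],
        [s.donor_id for s in sort_samples],
        [s.component for s in sort_samples],
    )
    return collapse_counts(records, sample_meta=meta)


def config_to_dict(config: SimConfig) -> dict:
    d = dataclasses.asdict(config)
    d["components"] = list(config.components)
    return d
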