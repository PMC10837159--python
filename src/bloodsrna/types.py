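"""Core record types shared across pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import CoordinateError, MetadataError, VocabularyError

#: The eight small non-coding RNA classes, ordered by annotation priority
#: (highest first).  When a sequence maps to several references, the class
#: earliest in this tuple wins.
RNA_CLASSES: tuple[str, ...] = (
    "miRNA",
    "tRNA",
    "rRNA",
    "YRNA",
    "snoRNA",
    "lncRNA",
    "snRNA",
    "piRNA",
)

#: RNA classes whose fragments are labelled by the ~25-nt bin of their start
#: position on the parent transcript rather than by the parent symbol alone.
BINNED_CLASSES: frozenset[str] = frozenset({"rRNA", "YRNA"})

CLASS_RANK: dict[str, int] = {c: i for i, c in enumerate(RNA_CLASSES)}


@dataclass(frozen=True)
class AssignmentCandidate:
    """One candidate annotation of a small-RNA sequence.

    Parameters
    ----------
    rna_class
        One of the eight classes in :data:`RNA_CLASSES`.
    parent_gene
        Gene symbol of the parental transcript (e.g. ``hsa-miR-21-5p`` for a
        mature miRNA, ``RNY1`` for a Y RNA fragment).
    start_pos
        1-based position of the sequence's first nucleotide on the parent.
        Required for rRNA/Y RNA candidates (it determines the bin label),
        optional otherwise.
    """

    rna_class: str
    parent_gene: str
    start_pos: int | None = None

    def __post_init__(self) -> None:
        if self.rna_class not in CLASS_RANK:
            raise VocabularyError(
                f"unknown RNA class {self.rna_class!r}; expected one of {RNA_CLASSES}"
            )
        if self.start_pos is not None and self.start_pos < 1:
            raise CoordinateError(
                f"start_pos must be 1-based (>= 1), got {self.start_pos}"
            )
        if self.rna_class in BINNED_CLASSES and self.start_pos is None:
            raise CoordinateError(
                f"{self.rna_class} candidate {self.parent_gene!r} requires start_pos"
            )


@dataclass(frozen=True)
class AnnotationLabel:
    """Resolved feature identifier plus the winning RNA class."""

    label: str
    rna_class: str


@dataclass
class SequenceRecord:
    """One distinct small-RNA sequence before annotation collapsing.

    ``counts`` maps sample id to the (UMI-deduplicated) read count of this
    exact sequence in that sample.
    """

    seq_id: str
    length_nt: int
    candidates: list[AssignmentCandidate]
    counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.length_nt < 1:
            raise ValueError(f"length_nt must be >= 1, got {self.length_nt}")
        if not self.candidates:
            raise ValueError(f"sequence {self.seq_id!r} has no candidate annotations")


@dataclass
class DonorRecord:
    """One blood donor with clinical blood counts.

    ``blood_counts`` maps cellular component name to cells per microliter of
    whole blood (the n_blood_count of the content calculation). Plasma has no
    entry: its content is volume- rather than count-based.
    """

    donor_id: str
    group: str
    age: float
    sex: str
    blood_counts: dict[str, float] = field(default_factory=dict)


@dataclass
class SortSample:
    """Cell-sorting and RNA-extraction metrics for one purified fraction.

    Exactly one of ``sorted_count`` (cellular fractions) and
    ``plasma_input_volume`` (plasma) is set. ``srna_conc`` may be None when
    the sRNA content of the fraction could not be determined; such samples
    are excluded from content-weighted averaging downstream.
    """

    sample_id: str
    donor_id: str
    component: str
    sorted_count: float | None = None
    purity_pct: float | None = None
    elution_volume: float = 14.0
    srna_conc: float | None = None
    plasma_input_volume: float | None = None

    def __post_init__(self) -> None:
        has_cells = self.sorted_count is not None
        has_volume = self.plasma_input_volume is not None
        if has_cells == has_volume:
            raise MetadataError(
                f"sample {self.sample_id!r}: exactly one of sorted_count and "
                "plasma_input_volume must be set"
            )
        if has_cells and self.sorted_count <= 0:
            raise MetadataError(
                f"sample {self.sample_id!r}: sorted_count must be > 0"
            )
        if self.srna_conc is not None and self.srna_conc < 0:
            raise MetadataError(f"sample {self.sample_id!r}: srna_conc must be >= 0")

    @property
    def is_plasma(self) -> bool:
        return self.plasma_input_volume is not None
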