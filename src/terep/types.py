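"""Core value types shared by every stage of the pipeline.

All genomic coordinates inside the package are 0-based half-open.
Formats that use other conventions (RepeatMasker .out/.align and GTF are
1-based inclusive) are converted at parse time and converted back when
written, so a parse/write round trip restores the original numbers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

STRANDS = {"+", "-", "."}

#: RepeatMasker class strings collapsed to the five classes used throughout.
TE_CLASSES = ("SINE", "LINE", "LTR", "DNA", "Other")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open interval ``[start, end)`` on ``chrom``."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self}")
        if self.end <= self.start:
            raise ValueError(f"empty or inverted interval: {self}")
        if self.strand not in STRANDS:
            raise ValueError(f"bad strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


def te_class_of(class_family: str) -> str:
    """Collapse a RepeatMasker class/family string to one of TE_CLASSES.

    ``"SINE/Alu"`` -> ``"SINE"``; retroposons, satellites, simple repeats
    and anything unrecognised map to ``"Other"``.
    """
    head = class_family.split("/", 1)[0].rstrip("?")
    if head in ("SINE", "LINE", "LTR", "DNA"):
        return head
    return "Other"


def split_class_family(class_family: str) -> tuple[str, str]:
    """Return (te_class, family) from a class/family string.

    The family is the token after the slash (``SINE/Alu`` -> ``Alu``); when
    there is no slash the whole string doubles as the family name.
    """
    te_class = te_class_of(class_family)
    parts = class_family.split("/", 1)
    family = parts[1] if len(parts) == 2 else parts[0]
    return te_class, family


@dataclass
class TECopy:
    """One annotated repeat interval from a RepeatMasker .out row."""

    interval: GenomicInterval
    family: str
    subfamily: str
    te_class: str
    sw_score: int
    divergence: float
    copy_id: str
    #: original class/family string, kept so .out rows round-trip verbatim
    class_family: str = ""
    # .out bookkeeping columns (deletion/insertion %, bases left of the hit
    # on query and consensus, consensus span) kept so rows round-trip
    pct_del: float = 0.0
    pct_ins: float = 0.0
    query_left: int = 0
    cons_start: int = 1
    cons_end: int = 1
    cons_left: int = 0

    def __post_init__(self) -> None:
        if self.divergence < 0:
            raise ValueError(f"negative divergence for {self.copy_id}")
        if self.te_class not in TE_CLASSES:
            raise ValueError(f"unknown te_class {self.te_class!r}")


@dataclass
class AlignmentRecord:
    """A gapped copy-vs-consensus alignment from a RepeatMasker .align block.

    ``gapped_query`` is the TE copy read 5'->3' along the *consensus*
    orientation; for ``orientation == "reverse"`` it is the reverse
    complement of the genomic segment.  ``consensus_start``/``consensus_end``
    are 1-based inclusive and stored normalised (start <= end) regardless of
    how a reverse hit printed them.
    """

    copy_id: str
    genomic: GenomicInterval
    consensus_name: str
    consensus_start: int
    consensus_end: int
    orientation: str  # forward | reverse
    gapped_query: str
    gapped_consensus: str

    def __post_init__(self) -> None:
        if self.orientation not in ("forward", "reverse"):
            raise ValueError(f"bad orientation {self.orientation!r}")
        if len(self.gapped_query) != len(self.gapped_consensus):
            raise ValueError(
                f"alignment length mismatch for {self.copy_id}: "
                f"{len(self.gapped_query)} != {len(self.gapped_consensus)}"
            )
        q_len = sum(1 for c in self.gapped_query if c != "-")
        if q_len != len(self.genomic):
            raise ValueError(
                f"ungapped query length {q_len} != genomic span "
                f"{len(self.genomic)} for {self.copy_id}"
            )
        c_len = sum(1 for c in self.gapped_consensus if c != "-")
        span = self.consensus_end - self.consensus_start + 1
        if c_len != span:
            raise ValueError(
                f"ungapped consensus length {c_len} != consensus span "
                f"{span} for {self.copy_id}"
            )


@dataclass
class PeakSummit:
    """A single-base ChIP-seq binding location with its TF and cell labels."""

    interval: GenomicInterval
    tf: str
    cell: str
    peak_id: str
    score: Optional[float] = None

    def __post_init__(self) -> None:
        if len(self.interval) != 1:
            raise ValueError(f"summit {self.peak_id} is not 1 bp")

    @property
    def pos(self) -> int:
        return self.interval.start


BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}


@dataclass
class PWM:
    """A position-weight matrix of per-position base probabilities."""

    name: str
    matrix: np.ndarray  # shape (width, 4), rows sum to 1
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("PWM matrix must have shape (width, 4)")
        if np.any(self.matrix < 0) or np.any(self.background < 0):
            raise ValueError("PWM probabilities must be non-negative")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError(f"PWM {self.name}: rows must each sum to 1")
        if not np.isclose(self.background.sum(), 1.0, atol=1e-6):
            raise ValueError(f"PWM {self.name}: background must sum to 1")

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.matrix.argmax(axis=1))
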