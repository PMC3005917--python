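"""Core sequence containers and alphabet helpers shared across the pipeline.

All transcript sequences are held internally as sense-strand RNA (alphabet
``ACGU``); coordinates are 1-based and inclusive on the spliced transcript,
matching the convention of the tag-mapping and annotation stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

RNA_BASES: tuple[str, ...] = ("A", "C", "G", "U")
START_CODON = "AUG"
STOP_CODONS = frozenset({"UAA", "UAG", "UGA"})

NUCLEAR = "nuclear"
MITOCHONDRIAL = "mitochondrial"
CHLOROPLAST = "chloroplast"
COMPARTMENTS: tuple[str, ...] = (NUCLEAR, MITOCHONDRIAL, CHLOROPLAST)

#: The 12 ordered one-base conversion patterns, "X-to-Y" with X != Y.
EDITING_PATTERNS: tuple[str, ...] = tuple(
    f"{a}-to-{b}" for a in RNA_BASES for b in RNA_BASES if a != b
)


def to_rna(sequence: str) -> str:
    """Uppercase and convert T to U."""
    return sequence.upper().replace("T", "U")


def to_dna(sequence: str) -> str:
    """Uppercase and convert U to T (used at the FASTA boundary)."""
    return sequence.upper().replace("U", "T")


def _check_rna(sequence: str, *, allow_n: bool = False) -> None:
    allowed = set(RNA_BASES) | ({"N"} if allow_n else set())
    bad = set(sequence) - allowed
    if bad:
        raise ValueError(f"non-RNA characters in sequence: {sorted(bad)}")


@dataclass(frozen=True)
class Transcript:
    """A spliced, sense-strand mRNA with exon/CDS structure.

    ``exons`` and ``cds`` are 1-based closed intervals in transcript
    coordinates. UTRs are derived from the CDS interval.
    """

    id: str
    sequence: str
    compartment: str = NUCLEAR
    exons: tuple[tuple[int, int], ...] = ()
    cds: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        _check_rna(self.sequence)
        if self.compartment not in COMPARTMENTS:
            raise ValueError(f"unknown compartment {self.compartment!r}")
        n = len(self.sequence)
        for start, end in self.exons:
            if not (1 <= start <= end <= n):
                raise ValueError(
                    f"{self.id}: exon {start}..{end} outside 1..{n}"
                )
        if self.cds is not None:
            start, end = self.cds
            if not (1 <= start <= end <= n):
                raise ValueError(f"{self.id}: CDS {start}..{end} outside 1..{n}")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def utr5(self) -> tuple[int, int] | None:
        if self.cds is None or self.cds[0] <= 1:
            return None
        return (1, self.cds[0] - 1)

    @property
    def utr3(self) -> tuple[int, int] | None:
        if self.cds is None or self.cds[1] >= len(self.sequence):
            return None
        return (self.cds[1] + 1, len(self.sequence))

    @property
    def cds_sequence(self) -> str | None:
        if self.cds is None:
            return None
        return self.sequence[self.cds[0] - 1 : self.cds[1]]

    def base_at(self, position: int) -> str:
        """Base at a 1-based transcript position."""
        if not 1 <= position <= len(self.sequence):
            raise IndexError(f"{self.id}: position {position} out of range")
        return self.sequence[position - 1]


@dataclass(frozen=True)
class PremiRNA:
    """A precursor-miRNA hairpin with its annotated mature-miRNA interval."""

    id: str
    sequence: str
    mature_interval: tuple[int, int]

    def __post_init__(self) -> None:
        _check_rna(self.sequence)
        start, end = self.mature_interval
        if not (1 <= start <= end <= len(self.sequence)):
            raise ValueError(
                f"{self.id}: mature interval {start}..{end} outside sequence"
            )

    def __len__(self) -> int:
        return len(self.sequence)
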