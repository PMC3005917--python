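"""Fixed-length tag mapping with at most one substitution.

Tags are mapped to the transcript/pre-miRNA set by seed-and-extend over
half-tag exact seeds: a single substitution leaves at least one half of the
tag intact, so indexing both halves of every target window guarantees every
alignment with <=1 mismatch is found. Tags with a perfect hit anywhere are
removed from the editing-evidence pool; tags whose single-mismatch hit is
ambiguous (multiple loci) are discarded and counted.
"""

from __future__ import annotations

import logging
from collections.abc import Mapping
from dataclasses import dataclass, field

from .core import EDITING_PATTERNS, RNA_BASES
from .synthetic import TagLibrary

logger = logging.getLogger("editscan.mapping")


def classify_pattern(ref_base: str, read_base: str) -> str:
    """Classify a substitution into one of the 12 ordered editing patterns."""
    if ref_base not in RNA_BASES or read_base not in RNA_BASES:
        raise ValueError(f"bases must be in ACGU, got {ref_base!r}->{read_base!r}")
    if ref_base == read_base:
        raise ValueError(f"identical bases {ref_base!r} are not a conversion")
    label = f"{ref_base}-to-{read_base}"
    assert label in EDITING_PATTERNS
    return label


@dataclass(frozen=True)
class TagAlignment:
    """One tag aligned to one target with 0 or 1 substitutions."""

    tag_sequence: str
    target_id: str
    start: int  # 1-based position of the tag's first base on the target
    mismatch_count: int
    mismatch_offset: int | None = None  # 0-based within the tag

    def __post_init__(self) -> None:
        if self.mismatch_count not in (0, 1):
            raise ValueError("mismatch_count must be 0 or 1")
        if self.mismatch_count == 1 and self.mismatch_offset is None:
            raise ValueError("one-mismatch alignment needs an offset")

    @property
    def end(self) -> int:
        return self.start + len(self.tag_sequence) - 1

    def spans(self, position: int) -> bool:
        return self.start <= position <= self.end


@dataclass(frozen=True)
class MismatchRecord:
    """A uniquely-placed one-substitution alignment: editing evidence."""

    target_id: str
    position: int  # 1-based coordinate of the mismatched base
    ref_base: str
    read_base: str
    pattern: str
    tag_sequence: str
    library_id: str
    tag_start: int = 1
    raw_count: int = 1
    tpm: float = 0.0

    def __post_init__(self) -> None:
        if self.ref_base == self.read_base:
            raise ValueError("ref and read base identical")
        if self.pattern != f"{self.ref_base}-to-{self.read_base}":
            raise ValueError("pattern inconsistent with bases")


class OneMismatchIndex:
    """Exact + one-substitution lookup over a set of sequences.

    Every length-``tag_length`` window of every target contributes its left
    and right half as seeds; a query retrieves candidate windows through
    either half and verifies the full tag, so any alignment with at most one
    substitution is recovered.
    """

    def __init__(self, targets: Mapping[str, str], tag_length: int):
        if not targets:
            raise ValueError("empty target set")
        self.tag_length = tag_length
        self._left_len = tag_length // 2
        self.targets: dict[str, str] = {}
        self._left: dict[str, list[tuple[str, int]]] = {}
        self._right: dict[str, list[tuple[str, int]]] = {}
        skipped = 0
        for tid in sorted(targets):
            seq = targets[tid]
            if len(seq) < tag_length:
                skipped += 1
                continue
            self.targets[tid] = seq
            ll = self._left_len
            for p in range(len(seq) - tag_length + 1):
                self._left.setdefault(seq[p : p + ll], []).append((tid, p))
                self._right.setdefault(seq[p + ll : p + tag_length], []).append((tid, p))
        if skipped:
            logger.warning("%d targets shorter than tag length skipped", skipped)
        if not self.targets:
            raise ValueError("no target reaches the tag length")

    def query(self, tag: str) -> list[TagAlignment]:
        """All alignments of ``tag`` with at most one substitution."""
        if len(tag) != self.tag_length:
            raise ValueError(
                f"tag length {len(tag)} does not match index ({self.tag_length})"
            )
        ll = self._left_len
        candidates: set[tuple[str, int]] = set()
        candidates.update(self._left.get(tag[:ll], ()))
        candidates.update(self._right.get(tag[ll:], ()))
        hits: list[TagAlignment] = []
        for tid, p in candidates:
            window = self.targets[tid][p : p + self.tag_length]
            mismatches = [i for i, (a, b) in enumerate(zip(window, tag)) if a != b]
            if len(mismatches) == 0:
                hits.append(TagAlignment(tag, tid, p + 1, 0))
            elif len(mismatches) == 1:
                hits.append(TagAlignment(tag, tid, p + 1, 1, mismatches[0]))
        hits.sort(key=lambda h: (h.target_id, h.start))
        return hits


@dataclass
class MapResult:
    """Per-library mapping outcome; partitions the input tag set."""

    library_id: str
    library: TagLibrary
    perfect: list[TagAlignment] = field(default_factory=list)
    mismatches: list[MismatchRecord] = field(default_factory=list)
    ambiguous: list[str] = field(default_factory=list)
    unmapped: list[str] = field(default_factory=list)


def map_library(library: TagLibrary, index: OneMismatchIndex) -> MapResult:
    """Map every distinct tag of a library against the index.

    A tag with any perfect hit contributes all its perfect alignments and is
    excluded from editing evidence. A tag with no perfect hit and exactly one
    one-mismatch locus yields one :class:`MismatchRecord`; multiple loci are
    discarded as ambiguous; no hit at all is unmapped.
    """
    if library.tag_length != index.tag_length:
        raise ValueError("library tag length does not match index")
    result = MapResult(library.library_id, library)
    for tag in sorted(library.counts):
        hits = index.query(tag)
        perfect = [h for h in hits if h.mismatch_count == 0]
        if perfect:
            result.perfect.extend(perfect)
            continue
        near = [h for h in hits if h.mismatch_count == 1]
        if not near:
            result.unmapped.append(tag)
            continue
        if len(near) > 1:
            result.ambiguous.append(tag)
            continue
        hit = near[0]
        offset = hit.mismatch_offset
        assert offset is not None
        position = hit.start + offset
        ref = index.targets[hit.target_id][position - 1]
        read = tag[offset]
        result.mismatches.append(
            MismatchRecord(
                target_id=hit.target_id,
                position=position,
                ref_base=ref,
                read_base=read,
                pattern=classify_pattern(ref, read),
                tag_sequence=tag,
                library_id=library.library_id,
                tag_start=hit.start,
                raw_count=library.counts[tag],
                tpm=library.tpm.get(tag, 0.0),
            )
        )
    if result.ambiguous:
        logger.info(
            "%s: %d ambiguous multi-locus one-mismatch tags discarded",
            library.library_id,
            len(result.ambiguous),
        )
    return result
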