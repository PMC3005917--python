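"""Functional consequences of editing sites: codon gains, exon edges, borders.

Covers three annotations on called sites:

* codon effects — the reference codon vs the edited codon, with flags for
  newly created AUG start codons and UAA/UAG/UGA stop codons (only edits
  inside the annotated CDS are considered; frame comes from annotation);
* exon-boundary proximity — whether a site falls in the 5' first or 3' last
  three nucleotides of its exon (splicing-relevant positions);
* distance to the translation border, the junction between the CDS and the
  3' UTR (negative = inside the CDS, positive = inside the 3' UTR).

`enumerate_feasible_generations` gives the structural backbone of the
start/stop-gain count table: a (target codon, pattern) cell is possible only
when the pattern's product base occurs in the target codon.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass

import pandas as pd
from Bio.Seq import Seq

from .core import EDITING_PATTERNS, RNA_BASES, START_CODON, STOP_CODONS, Transcript
from .calling import EditingSite

logger = logging.getLogger("editscan.annotation")

TARGET_CODONS = (START_CODON, "UAA", "UAG", "UGA")


def _translate(codon: str) -> str:
    return str(Seq(codon).translate())


def parse_pattern(pattern: str) -> tuple[str, str]:
    try:
        src, dst = pattern.split("-to-")
    except ValueError as exc:
        raise ValueError(f"malformed pattern {pattern!r}") from exc
    if src not in RNA_BASES or dst not in RNA_BASES or src == dst:
        raise ValueError(f"invalid pattern {pattern!r}")
    return src, dst


@dataclass(frozen=True)
class CodonEffect:
    target_id: str
    position: int
    pattern: str
    cds_frame_offset: int  # 0..2, position of the edit within its codon
    codon_before: str
    codon_after: str
    amino_acid_before: str
    amino_acid_after: str
    creates_start: bool
    creates_stop: bool


def annotate_codon_effect(
    site: EditingSite, transcript: Transcript
) -> CodonEffect | None:
    """Codon-level consequence of one editing site, or None outside the CDS."""
    if transcript.cds is None:
        return None
    cds_start, cds_end = transcript.cds
    if not cds_start <= site.position <= cds_end:
        return None
    cds_seq = transcript.cds_sequence
    assert cds_seq is not None
    if len(cds_seq) % 3 != 0:
        raise ValueError(f"{transcript.id}: CDS length not divisible by 3")
    idx = site.position - cds_start
    codon_i, offset = divmod(idx, 3)
    before = cds_seq[codon_i * 3 : codon_i * 3 + 3]
    if before[offset] != site.ref_base:
        raise ValueError(
            f"{site.site_id}: reference base mismatch against {transcript.id}"
        )
    after = before[:offset] + site.read_base + before[offset + 1 :]
    return CodonEffect(
        target_id=site.target_id,
        position=site.position,
        pattern=site.pattern,
        cds_frame_offset=offset,
        codon_before=before,
        codon_after=after,
        amino_acid_before=_translate(before),
        amino_acid_after=_translate(after),
        creates_start=(after == START_CODON and before != START_CODON),
        creates_stop=(after in STOP_CODONS and before not in STOP_CODONS),
    )


def enumerate_feasible_generations(target_codon: str, pattern: str) -> frozenset[str]:
    """All source codons one edit of ``pattern`` away from ``target_codon``.

    Empty exactly when the pattern's product base does not occur in the
    target codon (the structural zeros of the start/stop-gain table).
    """
    if len(target_codon) != 3 or any(b not in RNA_BASES for b in target_codon):
        raise ValueError(f"invalid codon {target_codon!r}")
    src, dst = parse_pattern(pattern)
    sources = set()
    for i, base in enumerate(target_codon):
        if base == dst:
            candidate = target_codon[:i] + src + target_codon[i + 1 :]
            if candidate != target_codon:
                sources.add(candidate)
    return frozenset(sources)


def summarize_codon_table(effects: Iterable[CodonEffect]) -> pd.DataFrame:
    """Counts of start/stop-creating events: 4 target codons x 12 patterns.

    Structural zeros (cells where the pattern cannot produce the codon) are
    guaranteed zero by construction.
    """
    table = pd.DataFrame(
        0, index=list(TARGET_CODONS), columns=list(EDITING_PATTERNS), dtype=int
    )
    for eff in effects:
        if (eff.creates_start or eff.creates_stop) and eff.codon_after in TARGET_CODONS:
            table.loc[eff.codon_after, eff.pattern] += 1
    table["Total"] = table.sum(axis=1)
    return table


@dataclass(frozen=True)
class BoundaryAnnotation:
    target_id: str
    position: int
    exon_index: int  # 0-based index of the containing exon
    within_first3: bool
    within_last3: bool
    distance_to_cds_end: int | None  # pos - last CDS base; None without a CDS


def annotate_boundaries(
    site: EditingSite, transcript: Transcript
) -> BoundaryAnnotation:
    """Exon-edge flags and signed distance to the CDS/3'UTR border."""
    exon_index = None
    for i, (start, end) in enumerate(transcript.exons):
        if start <= site.position <= end:
            exon_index = i
            break
    if exon_index is None:
        raise ValueError(
            f"{site.site_id}: position outside every exon of {transcript.id}"
        )
    start, end = transcript.exons[exon_index]
    distance = None
    if transcript.cds is not None:
        distance = site.position - transcript.cds[1]
    return BoundaryAnnotation(
        target_id=site.target_id,
        position=site.position,
        exon_index=exon_index,
        within_first3=site.position - start < 3,
        within_last3=end - site.position < 3,
        distance_to_cds_end=distance,
    )


def border_window_counts(
    sites: Sequence[EditingSite],
    transcripts: Mapping[str, Transcript] | Transcript,
    window_nt: int,
) -> tuple[int, int, int]:
    """(n_inside, n_outside, window): sites within +-window of the CDS end.

    Descriptive only — the border enrichment carries no formal test.
    """
    if window_nt < 0:
        raise ValueError("window must be >= 0")
    if isinstance(transcripts, Transcript):
        transcripts = {transcripts.id: transcripts}
    inside = outside = 0
    for site in sites:
        tx = transcripts.get(site.target_id)
        if tx is None or tx.cds is None:
            continue
        if abs(site.position - tx.cds[1]) <= window_nt:
            inside += 1
        else:
            outside += 1
    return inside, outside, window_nt
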