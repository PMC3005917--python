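"""Editing of pre-miRNA hairpins and comparison of secondary structures.

Edits are applied jointly to the hairpin sequence; secondary structures are
consumed as externally produced dot-bracket strings (e.g. from an MFE
folder) and compared as base-pair sets, with a separate delta restricted to
pairs touching the mature-miRNA interval.
"""

from __future__ import annotations

from collections.abc import Sequence
from dataclasses import dataclass

from .core import RNA_BASES, PremiRNA


@dataclass(frozen=True)
class EditedPremiRNA:
    premirna_id: str
    sequence: str
    edited_positions: tuple[int, ...]
    in_mature: tuple[bool, ...]  # parallel to edited_positions


def apply_edits(
    premirna: PremiRNA, edits: Sequence[tuple[int, str, str]]
) -> EditedPremiRNA:
    """Apply (position, from, to) edits simultaneously; length preserved.

    Conflicting edits (two different products at one position) raise;
    duplicate identical edits collapse. Edits inside the mature-miRNA
    interval are flagged in the result.
    """
    seq = list(premirna.sequence)
    chosen: dict[int, tuple[str, str]] = {}
    for pos, src, dst in edits:
        if not 1 <= pos <= len(seq):
            raise ValueError(f"{premirna.id}: position {pos} out of range")
        if src not in RNA_BASES or dst not in RNA_BASES or src == dst:
            raise ValueError(f"{premirna.id}: invalid edit {src}->{dst} at {pos}")
        if seq[pos - 1] != src and seq[pos - 1] != dst:  # dst: already applied
            raise ValueError(
                f"{premirna.id}:{pos}: reference base is {seq[pos - 1]}, not {src}"
            )
        if pos in chosen and chosen[pos] != (src, dst):
            raise ValueError(f"{premirna.id}: conflicting edits at position {pos}")
        chosen[pos] = (src, dst)
    for pos, (_, dst) in chosen.items():
        seq[pos - 1] = dst
    lo, hi = premirna.mature_interval
    positions = tuple(sorted(chosen))
    return EditedPremiRNA(
        premirna_id=premirna.id,
        sequence="".join(seq),
        edited_positions=positions,
        in_mature=tuple(lo <= p <= hi for p in positions),
    )


def parse_dotbracket(structure: str) -> frozenset[tuple[int, int]]:
    """Base pairs (1-based, i<j) of a dot-bracket string; raises if unbalanced."""
    stack: list[int] = []
    pairs = set()
    for i, c in enumerate(structure, start=1):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise ValueError(f"unbalanced ')' at position {i}")
            pairs.add((stack.pop(), i))
        elif c != ".":
            raise ValueError(f"unexpected character {c!r} at position {i}")
    if stack:
        raise ValueError(f"unbalanced '(' at position {stack[-1]}")
    return frozenset(pairs)


@dataclass(frozen=True)
class StructureComparison:
    dotbracket_before: str
    dotbracket_after: str
    pairs_lost: int
    pairs_gained: int
    mature_region_pairs_delta: int


def compare_structures(
    before: str, after: str, mature_interval: tuple[int, int] | None = None
) -> StructureComparison:
    """Base-pair set differences between two structures of equal length."""
    if len(before) != len(after):
        raise ValueError("structures have different lengths")
    pairs_before = parse_dotbracket(before)
    pairs_after = parse_dotbracket(after)
    delta = 0
    if mature_interval is not None:
        lo, hi = mature_interval

        def touches(pair: tuple[int, int]) -> bool:
            return lo <= pair[0] <= hi or lo <= pair[1] <= hi

        delta = sum(1 for p in pairs_after if touches(p)) - sum(
            1 for p in pairs_before if touches(p)
        )
    return StructureComparison(
        dotbracket_before=before,
        dotbracket_after=after,
        pairs_lost=len(pairs_before - pairs_after),
        pairs_gained=len(pairs_after - pairs_before),
        mature_region_pairs_delta=delta,
    )
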