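"""Readers and writers for the pipeline's on-disk formats.

FASTA carries DNA letters on disk (T) and RNA letters (U) in memory; GFF3 is
1-based with closed intervals; BED output is 0-based half-open. Tabular
outputs are TSV with ``#``-prefixed header comments carrying the run seed
and configuration hash.
"""

from __future__ import annotations

import logging
import os
from collections.abc import Iterable, Mapping, Sequence
from pathlib import Path

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import NUCLEAR, PremiRNA, Transcript, to_dna, to_rna
from .calling import EditingSite
from .mapping import MismatchRecord, TagAlignment
from .synthetic import PlantedEvent, TagLibrary

logger = logging.getLogger("editscan.io")

_VALID_TAG_CHARS = set("ACGTU")


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """FASTA -> {id: RNA sequence} (T converted to U on read)."""
    return {rec.id: to_rna(str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(
    sequences: Mapping[str, str], path: str | os.PathLike, *, alphabet: str = "dna"
) -> None:
    """Write sequences as FASTA, emitting T unless ``alphabet='rna'``."""
    convert = to_dna if alphabet == "dna" else to_rna
    records = [
        SeqRecord(Seq(convert(seq)), id=name, description="")
        for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def write_gff3(
    transcripts: Iterable[Transcript], path: str | os.PathLike, header: str | None = None
) -> None:
    """Transcript structure as GFF3 (1-based closed; compartment attribute)."""
    lines = ["##gff-version 3"]
    if header:
        lines.append(f"# {header}")
    for tx in transcripts:
        attrs = f"ID={tx.id};compartment={tx.compartment}"
        for start, end in tx.exons:
            lines.append(
                f"{tx.id}\teditscan\texon\t{start}\t{end}\t.\t+\t.\t{attrs}"
            )
        if tx.cds is not None:
            lines.append(
                f"{tx.id}\teditscan\tCDS\t{tx.cds[0]}\t{tx.cds[1]}\t.\t+\t0\t{attrs}"
            )
            if tx.utr5 is not None:
                lines.append(
                    f"{tx.id}\teditscan\tfive_prime_UTR\t{tx.utr5[0]}\t{tx.utr5[1]}"
                    f"\t.\t+\t.\t{attrs}"
                )
            if tx.utr3 is not None:
                lines.append(
                    f"{tx.id}\teditscan\tthree_prime_UTR\t{tx.utr3[0]}\t{tx.utr3[1]}"
                    f"\t.\t+\t.\t{attrs}"
                )
    Path(path).write_text("\n".join(lines) + "\n")


def read_transcripts(
    fasta_path: str | os.PathLike, gff_path: str | os.PathLike
) -> list[Transcript]:
    """Combine a FASTA and its GFF3 structure into Transcript objects."""
    sequences = read_fasta(fasta_path)
    db = gffutils.create_db(
        str(gff_path),
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    structure: dict[str, dict] = {}
    for feat in db.all_features():
        entry = structure.setdefault(
            feat.seqid, {"exons": [], "cds": None, "compartment": NUCLEAR}
        )
        comp = feat.attributes.get("compartment")
        if comp:
            entry["compartment"] = comp[0]
        if feat.featuretype == "exon":
            entry["exons"].append((feat.start, feat.end))
        elif feat.featuretype == "CDS":
            entry["cds"] = (feat.start, feat.end)
    out = []
    for tid, seq in sequences.items():
        entry = structure.get(tid, {"exons": [(1, len(seq))], "cds": None,
                                    "compartment": NUCLEAR})
        out.append(
            Transcript(
                id=tid,
                sequence=seq,
                compartment=entry["compartment"],
                exons=tuple(sorted(entry["exons"])),
                cds=entry["cds"],
            )
        )
    return out


def read_tag_tsv(
    path: str | os.PathLike, library_id: str | None = None
) -> TagLibrary:
    """Tag TSV (columns: tag, raw_count) -> TagLibrary; rejects bad rows."""
    counts: dict[str, int] = {}
    tag_length = None
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[0] == "tag":  # header row
                continue
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns")
            tag = fields[0].upper()
            if set(tag) - _VALID_TAG_CHARS:
                raise ValueError(
                    f"{path}:{lineno}: non-ACGTU character in tag {fields[0]!r}"
                )
            tag = to_rna(tag)
            try:
                count = int(fields[1])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: bad count {fields[1]!r}") from exc
            if tag_length is None:
                tag_length = len(tag)
            elif len(tag) != tag_length:
                raise ValueError(f"{path}:{lineno}: inconsistent tag length")
            counts[tag] = counts.get(tag, 0) + count
    if tag_length is None:
        raise ValueError(f"{path}: no tags")
    if library_id is None:
        library_id = Path(path).stem
    return TagLibrary.from_counts(library_id, counts, tag_length)


def write_tag_tsv(
    library: TagLibrary, path: str | os.PathLike, header: str | None = None
) -> None:
    lines = []
    if header:
        lines.append(f"# {header}")
    lines.append("tag\traw_count")
    for tag in sorted(library.counts):
        lines.append(f"{tag}\t{library.counts[tag]}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_events_tsv(
    events: Sequence[PlantedEvent],
    path: str | os.PathLike,
    libraries: Sequence[str],
    header: str | None = None,
) -> None:
    """Ground-truth planted events with per-library ratio columns."""
    lines = []
    if header:
        lines.append(f"# {header}")
    lines.append("transcript_id\tposition\tfrom\tto\t" + "\t".join(libraries))
    for ev in events:
        ratios = "\t".join(
            f"{ev.per_library_ratio.get(lib, 0.0):.4f}" for lib in libraries
        )
        lines.append(
            f"{ev.transcript_id}\t{ev.position}\t{ev.from_base}\t{ev.to_base}\t{ratios}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_mismatch_tsv(
    records: Sequence[MismatchRecord], path: str | os.PathLike, header: str | None = None
) -> None:
    lines = []
    if header:
        lines.append(f"# {header}")
    lines.append(
        "target_id\tposition\tref\tread\tpattern\ttag\tlibrary\ttag_start"
        "\traw_count\ttpm"
    )
    for r in records:
        lines.append(
            f"{r.target_id}\t{r.position}\t{r.ref_base}\t{r.read_base}\t{r.pattern}"
            f"\t{r.tag_sequence}\t{r.library_id}\t{r.tag_start}\t{r.raw_count}"
            f"\t{r.tpm:.6g}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_mismatch_tsv(path: str | os.PathLike) -> list[MismatchRecord]:
    df = pd.read_csv(path, sep="\t", comment="#")
    return [
        MismatchRecord(
            target_id=str(row.target_id),
            position=int(row.position),
            ref_base=str(row.ref),
            read_base=str(row.read),
            pattern=str(row.pattern),
            tag_sequence=str(row.tag),
            library_id=str(row.library),
            tag_start=int(row.tag_start),
            raw_count=int(row.raw_count),
            tpm=float(row.tpm),
        )
        for row in df.itertuples()
    ]


def write_perfect_tsv(
    alignments: Sequence[TagAlignment],
    library: TagLibrary,
    path: str | os.PathLike,
    header: str | None = None,
) -> None:
    """Perfect alignments with expression, needed for ratio denominators."""
    lines = []
    if header:
        lines.append(f"# {header}")
    lines.append("target_id\tstart\ttag\tlibrary\traw_count\ttpm")
    for a in alignments:
        lines.append(
            f"{a.target_id}\t{a.start}\t{a.tag_sequence}\t{library.library_id}"
            f"\t{library.counts.get(a.tag_sequence, 0)}"
            f"\t{library.tpm.get(a.tag_sequence, 0.0):.6g}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_sites_tsv(
    sites: Sequence[EditingSite],
    path: str | os.PathLike,
    libraries: Sequence[str] | None = None,
    header: str | None = None,
) -> None:
    """Called sites with support and per-library ratio columns."""
    if libraries is None:
        libraries = sorted({lib for s in sites for lib in s.per_library_ratio})
    lines = []
    if header:
        lines.append(f"# {header}")
    cols = ["target_id", "class", "position", "ref", "read", "pattern", "support"]
    cols += [f"ratio_{lib}" for lib in libraries]
    lines.append("\t".join(cols))
    for s in sites:
        row = [
            s.target_id,
            s.target_class,
            str(s.position),
            s.ref_base,
            s.read_base,
            s.pattern,
            str(s.distinct_read_support),
        ]
        for lib in libraries:
            r = s.per_library_ratio.get(lib)
            row.append("NA" if r is None else f"{r:.6f}")
        lines.append("\t".join(row))
    Path(path).write_text("\n".join(lines) + "\n")


def read_sites_matrix(path: str | os.PathLike) -> pd.DataFrame:
    """Read a sites TSV back as a site x library ratio matrix."""
    df = pd.read_csv(path, sep="\t", comment="#", na_values=["NA"])
    idx = df.target_id + ":" + df.position.astype(str) + ":" + df.pattern
    ratios = df[[c for c in df.columns if c.startswith("ratio_")]].copy()
    ratios.columns = [c[len("ratio_"):] for c in ratios.columns]
    ratios.index = idx
    return ratios


def read_sites_tsv(path: str | os.PathLike) -> list[EditingSite]:
    """Read a sites TSV back as EditingSite objects.

    Supporting tag sequences are not stored on disk, so the support count is
    carried as an override and tag-length information is lost.
    """
    df = pd.read_csv(path, sep="\t", comment="#", na_values=["NA"])
    df = df.rename(columns={"class": "target_class"})
    ratio_cols = [c for c in df.columns if c.startswith("ratio_")]
    sites = []
    for row in df.itertuples():
        ratios = {
            c[len("ratio_"):]: (None if pd.isna(getattr(row, c)) else float(getattr(row, c)))
            for c in ratio_cols
        }
        sites.append(
            EditingSite(
                target_id=str(row.target_id),
                position=int(row.position),
                pattern=str(row.pattern),
                ref_base=str(row.ref),
                read_base=str(row.read),
                supporting_tags=frozenset(),
                per_library_support={},
                target_class=str(row.target_class),
                per_library_ratio=ratios,
                n_support=int(row.support),
            )
        )
    return sites


def read_go_tsv(path: str | os.PathLike) -> dict[str, set[str]]:
    """Gene->GO-term map from a two-column TSV (one pair per line)."""
    out: dict[str, set[str]] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("gene"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected gene<TAB>term")
            out.setdefault(fields[0], set()).add(fields[1])
    return out


def write_go_tsv(
    go_map: Mapping[str, Iterable[str]], path: str | os.PathLike
) -> None:
    lines = ["gene_id\tterm_id"]
    for gene in sorted(go_map):
        for term in sorted(go_map[gene]):
            lines.append(f"{gene}\t{term}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_bed(
    sites: Sequence[EditingSite], path: str | os.PathLike, header: str | None = None
) -> None:
    """Sites as BED: 0-based half-open, so position p becomes [p-1, p)."""
    lines = []
    if header:
        lines.append(f"# {header}")
    for s in sites:
        lines.append(
            f"{s.target_id}\t{s.position - 1}\t{s.position}\t{s.pattern}"
            f"\t{s.distinct_read_support}\t+"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_premirna_fasta(
    premirnas: Iterable[PremiRNA], path: str | os.PathLike
) -> None:
    write_fasta({p.id: p.sequence for p in premirnas}, path)


def read_vienna(path: str | os.PathLike) -> dict[str, tuple[str, str]]:
    """Vienna files: '>id' then sequence line then dot-bracket line."""
    out: dict[str, tuple[str, str]] = {}
    name, seq, struct = None, None, None
    with open(path) as handle:
        for raw in handle:
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                name, seq, struct = line[1:].split()[0], None, None
            elif seq is None:
                seq = to_rna(line)
            else:
                struct = line.split()[0]
                if name is None or len(struct) != len(seq):
                    raise ValueError(f"{path}: malformed record {name!r}")
                out[name] = (seq, struct)
    return out
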