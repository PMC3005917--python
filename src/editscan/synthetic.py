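"""Synthetic transcriptomes, planted editing events, and tag libraries.

This module emulates the inputs of an MPSS/PARE-style editing survey so the
whole pipeline can be exercised offline: a transcript set with compartment
labels (nuclear / mitochondrial / chloroplast) and exon/CDS/UTR structure,
pre-miRNA hairpins, editing events planted at chosen per-library ratios, and
fixed-length sense-strand tag libraries with a configurable single-base
substitution error and TPM normalisation.

The error model is per *signature*: with probability ``per_signature_error_rate``
an emitted tag carries exactly one substituted base, the position uniform over
the tag and the replacement uniform over the three alternative bases.  Under
a balanced base composition each of the 12 conversion patterns then occurs at
rate/12 — the arithmetic the downstream error-rate audit relies on.
"""

from __future__ import annotations

import itertools
import logging
import re
from collections import Counter
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np

from .core import (
    CHLOROPLAST,
    COMPARTMENTS,
    MITOCHONDRIAL,
    NUCLEAR,
    RNA_BASES,
    START_CODON,
    STOP_CODONS,
    PremiRNA,
    Transcript,
)

logger = logging.getLogger("editscan.synthetic")

#: DpnII recognition site on the sense strand (RNA alphabet).
MPSS_ANCHOR_MOTIF = "GAUC"

_NONSTOP_CODONS = tuple(
    "".join(c) for c in itertools.product(RNA_BASES, repeat=3)
    if "".join(c) not in STOP_CODONS
)


@dataclass
class SyntheticConfig:
    """Study-design parameters for the synthetic generator.

    Defaults mirror the reference design: 17 tissue libraries of 20-nt
    signatures with a ~5.00% per-signature substitution error (4.25% for
    17-nt signatures, 1.30% for PARE-mode 20-nt tags).
    """

    n_transcripts: int = 20
    transcript_length_range: tuple[int, int] = (300, 1200)
    compartment_fractions: Mapping[str, float] = field(
        default_factory=lambda: {NUCLEAR: 0.90, MITOCHONDRIAL: 0.06, CHLOROPLAST: 0.04}
    )
    n_libraries: int = 17
    tag_length: int = 20
    per_signature_error_rate: float | None = None
    pare_error_rate: float = 0.013
    tags_per_library: int = 20_000
    anchor: str = "gatc"  # "gatc" | "uniform"
    abundance_sigma: float = 1.0
    n_premirnas: int = 8
    premirna_length_range: tuple[int, int] = (70, 200)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_transcripts < 0:
            raise ValueError("n_transcripts must be >= 0")
        lo, hi = self.transcript_length_range
        if lo > hi:
            raise ValueError(f"degenerate length range {lo}..{hi}")
        if lo < 30:
            raise ValueError("transcript lengths below 30 nt cannot carry a CDS")
        total = sum(self.compartment_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"compartment fractions sum to {total}, not 1")
        for name in self.compartment_fractions:
            if name not in COMPARTMENTS:
                raise ValueError(f"unknown compartment {name!r}")
        if self.tag_length not in (17, 20):
            raise ValueError("tag_length must be 17 or 20")
        if self.per_signature_error_rate is not None and not (
            0.0 <= self.per_signature_error_rate <= 1.0
        ):
            raise ValueError("per_signature_error_rate must be in [0,1]")
        if not 0.0 <= self.pare_error_rate <= 1.0:
            raise ValueError("pare_error_rate must be in [0,1]")
        if self.anchor not in ("gatc", "uniform"):
            raise ValueError("anchor must be 'gatc' or 'uniform'")

    @property
    def error_rate(self) -> float:
        """MPSS per-signature error: 5.00% for 20-nt tags, 4.25% for 17-nt."""
        if self.per_signature_error_rate is not None:
            return self.per_signature_error_rate
        return 0.05 if self.tag_length == 20 else 0.0425

    @property
    def library_ids(self) -> tuple[str, ...]:
        return tuple(f"lib{i + 1:02d}" for i in range(self.n_libraries))


@dataclass(frozen=True)
class PlantedEvent:
    """A ground-truth editing event at a transcript position.

    ``per_library_ratio`` maps a library id to the fraction of transcript
    molecules carrying the edited base in that library; libraries not listed
    are unedited (ratio 0).
    """

    transcript_id: str
    position: int
    from_base: str
    to_base: str
    per_library_ratio: Mapping[str, float]

    def __post_init__(self) -> None:
        if self.from_base == self.to_base:
            raise ValueError(f"{self}: from == to")
        for base in (self.from_base, self.to_base):
            if base not in RNA_BASES:
                raise ValueError(f"{self}: base {base!r} not in ACGU")
        for lib, r in self.per_library_ratio.items():
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"{self}: ratio {r} for {lib} outside [0,1]")

    @property
    def pattern(self) -> str:
        return f"{self.from_base}-to-{self.to_base}"


@dataclass(frozen=True)
class Haplotype:
    """One edited (or reference) version of a transcript sequence."""

    sequence: str
    edited_positions: frozenset[int]
    weights: Mapping[str, float]  # library -> mixture weight

    def weight_for(self, library_id: str) -> float:
        if library_id in self.weights:
            return self.weights[library_id]
        # A library never mentioned by any event sees only the reference.
        return 1.0 if not self.edited_positions else 0.0


@dataclass
class HaplotypeSet:
    transcript: Transcript
    haplotypes: list[Haplotype]


@dataclass
class TagLibrary:
    """One tissue library of fixed-length tags with raw counts and TPM."""

    library_id: str
    counts: dict[str, int]
    tag_length: int
    tpm: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for tag, c in self.counts.items():
            if len(tag) != self.tag_length:
                raise ValueError(
                    f"{self.library_id}: tag {tag!r} is not {self.tag_length} nt"
                )
            if c <= 0:
                raise ValueError(f"{self.library_id}: non-positive count for {tag!r}")
        if not self.tpm and self.counts:
            self.tpm = normalize_tpm(self.counts)

    @classmethod
    def from_counts(
        cls, library_id: str, counts: Mapping[str, int], tag_length: int
    ) -> "TagLibrary":
        return cls(library_id, dict(counts), tag_length)

    @property
    def n_distinct(self) -> int:
        return len(self.counts)

    @property
    def total_count(self) -> int:
        return sum(self.counts.values())


def normalize_tpm(counts: Mapping[str, int | float]) -> dict[str, float]:
    """Transcripts-per-million normalisation: count / total * 1e6."""
    if any(c < 0 for c in counts.values()):
        raise ValueError("negative counts")
    total = float(sum(counts.values()))
    if total <= 0:
        raise ValueError("all-zero library cannot be TPM-normalised")
    return {tag: c / total * 1e6 for tag, c in counts.items()}


# ---------------------------------------------------------------------------
# Transcriptome generation


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(RNA_BASES, size=length))


def _random_cds(rng: np.random.Generator, cds_len: int) -> str:
    # AUG, interior sense codons (no premature stop), terminal stop.
    assert cds_len % 3 == 0 and cds_len >= 9
    n_interior = cds_len // 3 - 2
    interior = "".join(rng.choice(_NONSTOP_CODONS, size=n_interior))
    stop = rng.choice(sorted(STOP_CODONS))
    return START_CODON + interior + stop


def _make_transcript(
    rng: np.random.Generator, tid: str, length: int, compartment: str
) -> Transcript:
    utr5 = max(3, int(round(length * 0.12)))
    utr3 = max(3, int(round(length * 0.25)))
    cds_len = length - utr5 - utr3
    cds_len -= cds_len % 3
    if cds_len < 9:
        cds_len = 9
    utr3 = length - utr5 - cds_len
    seq = _random_seq(rng, utr5) + _random_cds(rng, cds_len) + _random_seq(rng, utr3)
    assert len(seq) == length
    n_exons = int(rng.integers(1, 6))
    if n_exons > 1 and length > n_exons:
        cuts = np.sort(rng.choice(np.arange(2, length + 1), size=n_exons - 1, replace=False))
    else:
        cuts = np.array([], dtype=int)
    bounds = [1, *cuts.tolist(), length + 1]
    exons = tuple(
        (bounds[i], bounds[i + 1] - 1) for i in range(len(bounds) - 1)
        if bounds[i] <= bounds[i + 1] - 1
    )
    return Transcript(
        id=tid,
        sequence=seq,
        compartment=compartment,
        exons=exons,
        cds=(utr5 + 1, utr5 + cds_len),
    )


def generate_transcriptome(
    config: SyntheticConfig,
) -> tuple[list[Transcript], list[PremiRNA]]:
    """Generate transcripts with structure plus pre-miRNA hairpins.

    Deterministic given ``config.seed``. Every transcript (nuclear or
    organellar) carries >=1 exon, a CDS starting with AUG and ending with a
    stop codon, and both UTRs.
    """
    rng = np.random.default_rng(config.seed)
    comps = sorted(config.compartment_fractions)
    probs = np.array([config.compartment_fractions[c] for c in comps])
    lo, hi = config.transcript_length_range
    transcripts: list[Transcript] = []
    for i in range(config.n_transcripts):
        compartment = str(rng.choice(comps, p=probs))
        length = int(rng.integers(lo, hi + 1))
        transcripts.append(
            _make_transcript(rng, f"TX{i + 1:04d}", length, compartment)
        )
    premirnas: list[PremiRNA] = []
    plo, phi = config.premirna_length_range
    for i in range(config.n_premirnas):
        length = int(rng.integers(plo, phi + 1))
        seq = _random_seq(rng, length)
        start = int(rng.integers(5, max(6, length - 25)))
        premirnas.append(
            PremiRNA(f"MIR{i + 1:04d}", seq, (start, min(start + 20, length)))
        )
    return transcripts, premirnas


# ---------------------------------------------------------------------------
# Planting events


def plant_events(
    transcripts: Iterable[Transcript], events: Sequence[PlantedEvent]
) -> dict[str, HaplotypeSet]:
    """Expand transcripts into per-library haplotype mixtures.

    Sites on a transcript are treated as independent, so ``k`` events produce
    up to ``2^k`` haplotypes whose library weights are the product mixture of
    the per-site ratios. The reference sequence is always present (possibly
    with weight 0 in fully edited libraries).
    """
    by_tx: dict[str, list[PlantedEvent]] = {}
    tx_map = {t.id: t for t in transcripts}
    for ev in events:
        if ev.transcript_id not in tx_map:
            raise ValueError(f"event references unknown transcript {ev.transcript_id}")
        ref = tx_map[ev.transcript_id].base_at(ev.position)
        if ref != ev.from_base:
            raise ValueError(
                f"event {ev.transcript_id}:{ev.position} {ev.pattern}: "
                f"reference base is {ref}, not {ev.from_base}"
            )
        by_tx.setdefault(ev.transcript_id, []).append(ev)

    out: dict[str, HaplotypeSet] = {}
    for tid, tx in tx_map.items():
        tx_events = sorted(by_tx.get(tid, []), key=lambda e: e.position)
        libraries = sorted({lib for ev in tx_events for lib in ev.per_library_ratio})
        haplotypes: list[Haplotype] = []
        for mask in itertools.product((False, True), repeat=len(tx_events)):
            seq = list(tx.sequence)
            positions = []
            for edited, ev in zip(mask, tx_events):
                if edited:
                    seq[ev.position - 1] = ev.to_base
                    positions.append(ev.position)
            weights = {}
            for lib in libraries:
                w = 1.0
                for edited, ev in zip(mask, tx_events):
                    r = ev.per_library_ratio.get(lib, 0.0)
                    w *= r if edited else (1.0 - r)
                weights[lib] = w
            haplotypes.append(
                Haplotype("".join(seq), frozenset(positions), weights)
            )
        out[tid] = HaplotypeSet(tx, haplotypes)
    return out


def reference_haplotypes(transcripts: Iterable[Transcript]) -> dict[str, HaplotypeSet]:
    """Haplotype sets with no edits (reference only)."""
    return plant_events(transcripts, [])


# ---------------------------------------------------------------------------
# Tag simulation


def _transcript_abundances(
    config: SyntheticConfig, transcript_ids: Sequence[str]
) -> np.ndarray:
    """Log-normal expression levels, fixed across libraries for a given seed."""
    rng = np.random.default_rng([config.seed, 0xAB])
    return rng.lognormal(mean=0.0, sigma=config.abundance_sigma, size=len(transcript_ids))


def _anchor_starts(sequence: str, tag_length: int, anchor: str) -> np.ndarray:
    """0-based candidate tag start positions for one haplotype sequence."""
    max_start = len(sequence) - tag_length
    if max_start < 0:
        return np.array([], dtype=int)
    if anchor == "gatc":
        starts = [
            m.start() + 4
            for m in re.finditer(MPSS_ANCHOR_MOTIF, sequence)
            if m.start() + 4 <= max_start
        ]
        if starts:
            return np.array(starts, dtype=int)
    return np.arange(max_start + 1)


def _corrupt(tag: str, rng: np.random.Generator) -> str:
    pos = int(rng.integers(len(tag)))
    alternatives = [b for b in RNA_BASES if b != tag[pos]]
    base = alternatives[int(rng.integers(3))]
    return tag[:pos] + base + tag[pos + 1 :]


def sample_tags_with_truth(
    haplotype_sets: Mapping[str, HaplotypeSet],
    config: SyntheticConfig,
    library_id: str,
    *,
    seed: int | None = None,
    error_rate: float | None = None,
    tag_length: int | None = None,
    starts_for: dict[str, np.ndarray] | None = None,
) -> list[tuple[str, str]]:
    """Draw the library's tags, returning (emitted tag, uncorrupted source) pairs.

    This is the sampling core behind :func:`simulate_mpss_library`; the truth
    channel exists so the substitution-error model can be audited directly.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    rate = config.error_rate if error_rate is None else error_rate
    L = config.tag_length if tag_length is None else tag_length
    usable = []
    for tid in sorted(haplotype_sets):
        hs = haplotype_sets[tid]
        if len(hs.transcript) < L:
            logger.warning("transcript %s shorter than tag length, skipped", tid)
            continue
        usable.append(hs)
    if not usable:
        return []
    abund = _transcript_abundances(config, [hs.transcript.id for hs in usable])
    probs = abund / abund.sum()
    per_tx = rng.multinomial(config.tags_per_library, probs)
    pairs: list[tuple[str, str]] = []
    for hs, n in zip(usable, per_tx):
        if n == 0:
            continue
        weights = np.array([h.weight_for(library_id) for h in hs.haplotypes])
        if weights.sum() <= 0:
            weights = np.zeros(len(weights))
            weights[0] = 1.0
        weights = weights / weights.sum()
        per_hap = rng.multinomial(int(n), weights)
        for hap, m in zip(hs.haplotypes, per_hap):
            if m == 0:
                continue
            if starts_for is not None and hs.transcript.id in starts_for:
                starts = starts_for[hs.transcript.id]
            else:
                starts = _anchor_starts(hap.sequence, L, config.anchor)
            if starts.size == 0:
                continue
            chosen = rng.choice(starts, size=int(m))
            corrupt_mask = rng.random(int(m)) < rate
            for s, bad in zip(chosen, corrupt_mask):
                src = hap.sequence[s : s + L]
                pairs.append((_corrupt(src, rng) if bad else src, src))
    return pairs


def simulate_mpss_library(
    haplotype_sets: Mapping[str, HaplotypeSet],
    config: SyntheticConfig,
    library_id: str,
    *,
    seed: int | None = None,
) -> TagLibrary:
    """Simulate one MPSS-like signature library.

    Tags are sense-strand substrings of ``tag_length`` nt, anchored
    immediately 3' of a GAUC (DpnII) motif when the configuration requests it
    and one exists (uniform start positions otherwise), corrupted with the
    per-signature error rate, with raw counts drawn proportional to
    transcript abundance x haplotype weight. TPM is computed on the counts.
    """
    pairs = sample_tags_with_truth(haplotype_sets, config, library_id, seed=seed)
    counts = Counter(tag for tag, _ in pairs)
    return TagLibrary.from_counts(library_id, counts, config.tag_length)


def simulate_pare_library(
    haplotype_sets: Mapping[str, HaplotypeSet],
    config: SyntheticConfig,
    library_id: str,
    *,
    seed: int | None = None,
    cleavage_sites: Mapping[str, Sequence[int]] | None = None,
) -> TagLibrary:
    """Simulate one PARE-like degradome library of 20-nt 5'-end tags.

    Tags start at sampled cleavage positions (1-based). When
    ``cleavage_sites`` is None, positions are uniform over each transcript;
    an explicitly empty mapping yields an empty library. Error defaults to
    the PARE rate (1.30%).
    """
    if cleavage_sites is not None and not cleavage_sites:
        return TagLibrary.from_counts(library_id, {}, 20)
    starts_for = None
    if cleavage_sites is not None:
        starts_for = {}
        for tid, positions in cleavage_sites.items():
            hs = haplotype_sets[tid]
            ok = [p - 1 for p in positions if p - 1 + 20 <= len(hs.transcript)]
            starts_for[tid] = np.array(ok, dtype=int)
    pairs = sample_tags_with_truth(
        haplotype_sets,
        config,
        library_id,
        seed=seed,
        error_rate=config.pare_error_rate,
        tag_length=20,
        starts_for=starts_for,
    )
    counts = Counter(tag for tag, _ in pairs)
    return TagLibrary.from_counts(library_id, counts, 20)


def simulate_libraries(
    haplotype_sets: Mapping[str, HaplotypeSet], config: SyntheticConfig
) -> list[TagLibrary]:
    """Simulate all ``config.n_libraries`` MPSS libraries with derived seeds."""
    seeds = np.random.SeedSequence(config.seed).spawn(config.n_libraries)
    return [
        simulate_mpss_library(
            haplotype_sets, config, lib, seed=int(ss.generate_state(1)[0] % (2**31))
        )
        for lib, ss in zip(config.library_ids, seeds)
    ]


def generate_go_map(
    gene_ids: Sequence[str],
    *,
    n_terms: int = 15,
    mean_terms_per_gene: float = 2.0,
    seed: int = 0,
) -> dict[str, set[str]]:
    """A flat synthetic gene->GO-term map (no graph propagation)."""
    rng = np.random.default_rng(seed)
    terms = [f"GO:{7000000 + i:07d}" for i in range(n_terms)]
    out: dict[str, set[str]] = {}
    for gid in gene_ids:
        k = min(n_terms, rng.poisson(mean_terms_per_gene))
        out[gid] = set(rng.choice(terms, size=k, replace=False)) if k else set()
    return out
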