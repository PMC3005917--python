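"""Aggregation of mismatch evidence into editing sites and their ratios.

Candidate sites are keyed by (target, position, pattern); support is the
number of *distinct* tag sequences across all libraries. The calling rules
are threshold-based: a protein-coding (or organellar) transcript must retain
at least ``min_sites_per_transcript`` sites each supported by at least
``min_reads_per_site`` distinct tags ("more than two sites ... more than five
distinct short reads" read strictly), while a pre-miRNA site needs only
``min_reads_per_premirna_site`` distinct tags.

The per-library editing ratio is TPM-weighted: the expression of edited
tags at the site divided by the expression of all tags spanning the site
(perfect matchers plus the edited ones); zero spanning coverage is reported
as missing, not as zero.
"""

from __future__ import annotations

from collections import defaultdict
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field, replace

from .core import CHLOROPLAST, MITOCHONDRIAL, PremiRNA, Transcript
from .mapping import MapResult, MismatchRecord

PROTEIN_CODING = "protein_coding"
PRE_MIRNA = "pre_miRNA"
TARGET_CLASSES = (PROTEIN_CODING, PRE_MIRNA, MITOCHONDRIAL, CHLOROPLAST)


@dataclass
class CallingCriteria:
    """Support thresholds for calling editing sites."""

    min_sites_per_transcript: int = 3
    min_reads_per_site: int = 6
    min_reads_per_premirna_site: int = 3
    min_ratio_report: float = 0.0

    def __post_init__(self) -> None:
        for name in (
            "min_sites_per_transcript",
            "min_reads_per_site",
            "min_reads_per_premirna_site",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0.0 <= self.min_ratio_report <= 1.0:
            raise ValueError("min_ratio_report must be in [0,1]")


@dataclass(frozen=True)
class EditingSite:
    """An aggregated candidate editing site."""

    target_id: str
    position: int
    pattern: str
    ref_base: str
    read_base: str
    supporting_tags: frozenset[str]
    per_library_support: Mapping[str, int]
    target_class: str = PROTEIN_CODING
    per_library_ratio: Mapping[str, float | None] = field(default_factory=dict)
    per_library_coverage: Mapping[str, int] = field(default_factory=dict)
    #: support count override for sites re-read from disk without tag sets
    n_support: int | None = None

    @property
    def distinct_read_support(self) -> int:
        if self.n_support is not None:
            return self.n_support
        return len(self.supporting_tags)

    @property
    def tag_lengths(self) -> frozenset[int]:
        return frozenset(len(t) for t in self.supporting_tags)

    @property
    def site_id(self) -> str:
        return f"{self.target_id}:{self.position}:{self.pattern}"

    @property
    def max_ratio(self) -> float:
        vals = [r for r in self.per_library_ratio.values() if r is not None]
        return max(vals) if vals else 0.0


def classify_targets(
    transcripts: Iterable[Transcript], premirnas: Iterable[PremiRNA] = ()
) -> dict[str, str]:
    """Target id -> class label (protein_coding / organellar / pre_miRNA)."""
    classes: dict[str, str] = {}
    for t in transcripts:
        if t.compartment in (MITOCHONDRIAL, CHLOROPLAST):
            classes[t.id] = t.compartment
        else:
            classes[t.id] = PROTEIN_CODING
    for p in premirnas:
        classes[p.id] = PRE_MIRNA
    return classes


def aggregate_sites(
    mismatches: Iterable[MismatchRecord],
    target_classes: Mapping[str, str] | None = None,
) -> list[EditingSite]:
    """Group mismatch records into candidate sites.

    Distinctness of support is by tag sequence: the same tag observed in
    several libraries counts once.
    """
    grouped: dict[tuple[str, int, str], list[MismatchRecord]] = defaultdict(list)
    for rec in mismatches:
        grouped[(rec.target_id, rec.position, rec.pattern)].append(rec)
    sites: list[EditingSite] = []
    for (tid, pos, pattern), recs in sorted(grouped.items()):
        tags = frozenset(r.tag_sequence for r in recs)
        per_lib: dict[str, set[str]] = defaultdict(set)
        for r in recs:
            per_lib[r.library_id].add(r.tag_sequence)
        sites.append(
            EditingSite(
                target_id=tid,
                position=pos,
                pattern=pattern,
                ref_base=recs[0].ref_base,
                read_base=recs[0].read_base,
                supporting_tags=tags,
                per_library_support={k: len(v) for k, v in sorted(per_lib.items())},
                target_class=(target_classes or {}).get(tid, PROTEIN_CODING),
            )
        )
    return sites


def apply_criteria(
    sites: Sequence[EditingSite], criteria: CallingCriteria | None = None
) -> list[EditingSite]:
    """Apply the support thresholds.

    Pre-miRNA sites pass on per-site support alone; all other target classes
    additionally require the transcript to retain enough passing sites.
    """
    criteria = criteria or CallingCriteria()
    called: list[EditingSite] = []
    by_target: dict[str, list[EditingSite]] = defaultdict(list)
    for site in sites:
        if site.target_class == PRE_MIRNA:
            if site.distinct_read_support >= criteria.min_reads_per_premirna_site:
                called.append(site)
        else:
            if site.distinct_read_support >= criteria.min_reads_per_site:
                by_target[site.target_id].append(site)
    for tid in sorted(by_target):
        passing = by_target[tid]
        if len(passing) >= criteria.min_sites_per_transcript:
            called.extend(passing)
    called.sort(key=lambda s: (s.target_id, s.position, s.pattern))
    if criteria.min_ratio_report > 0:
        called = [s for s in called if s.max_ratio >= criteria.min_ratio_report]
    return called


def editing_ratio(edited_tpm: float, total_tpm: float) -> float | None:
    """Edited expression over total spanning expression; None when unobserved."""
    if total_tpm <= 0:
        return None
    ratio = edited_tpm / total_tpm
    return min(max(ratio, 0.0), 1.0)


def compute_editing_ratios(
    sites: Sequence[EditingSite],
    map_results: Sequence[MapResult],
    *,
    pool_patterns: bool = False,
) -> list[EditingSite]:
    """Fill per-library editing ratios (and raw spanning coverage) for sites.

    For each library, numerator = TPM of one-mismatch tags supporting the
    site (its own pattern, or every pattern at the position when
    ``pool_patterns``); denominator = that numerator plus the TPM of perfect
    alignments spanning the position. Tags mismatching elsewhere are not part
    of the denominator.
    """
    out: list[EditingSite] = []
    # Pre-index each library's evidence.
    per_lib_perfect: dict[str, dict[str, list[tuple[int, int, float, int]]]] = {}
    per_lib_site_tpm: dict[str, dict[tuple[str, int, str], tuple[float, int]]] = {}
    per_lib_pos_tpm: dict[str, dict[tuple[str, int], tuple[float, int]]] = {}
    for res in map_results:
        lib = res.library_id
        by_target: dict[str, list[tuple[int, int, float, int]]] = defaultdict(list)
        for aln in res.perfect:
            by_target[aln.target_id].append(
                (
                    aln.start,
                    aln.end,
                    res.library.tpm.get(aln.tag_sequence, 0.0),
                    res.library.counts.get(aln.tag_sequence, 0),
                )
            )
        per_lib_perfect[lib] = by_target
        site_tpm: dict[tuple[str, int, str], tuple[float, int]] = defaultdict(
            lambda: (0.0, 0)
        )
        pos_tpm: dict[tuple[str, int], tuple[float, int]] = defaultdict(lambda: (0.0, 0))
        for rec in res.mismatches:
            key = (rec.target_id, rec.position, rec.pattern)
            t, c = site_tpm[key]
            site_tpm[key] = (t + rec.tpm, c + rec.raw_count)
            t, c = pos_tpm[(rec.target_id, rec.position)]
            pos_tpm[(rec.target_id, rec.position)] = (t + rec.tpm, c + rec.raw_count)
        per_lib_site_tpm[lib] = dict(site_tpm)
        per_lib_pos_tpm[lib] = dict(pos_tpm)

    for site in sites:
        ratios: dict[str, float | None] = {}
        coverage: dict[str, int] = {}
        for res in map_results:
            lib = res.library_id
            if pool_patterns:
                edited_tpm, edited_count = per_lib_pos_tpm[lib].get(
                    (site.target_id, site.position), (0.0, 0)
                )
            else:
                edited_tpm, edited_count = per_lib_site_tpm[lib].get(
                    (site.target_id, site.position, site.pattern), (0.0, 0)
                )
            span_tpm = 0.0
            span_count = 0
            for start, end, tpm, count in per_lib_perfect[lib].get(site.target_id, ()):
                if start <= site.position <= end:
                    span_tpm += tpm
                    span_count += count
            ratios[lib] = editing_ratio(edited_tpm, edited_tpm + span_tpm)
            coverage[lib] = edited_count + span_count
        out.append(
            replace(site, per_library_ratio=ratios, per_library_coverage=coverage)
        )
    return out


def expected_error_rate_per_pattern(overall_rate: float, n_patterns: int = 12) -> float:
    """Per-pattern substitution rate under a uniform error model.

    A per-signature rate of 5.00% spreads over the 12 conversion patterns as
    ~0.42% each (4.25% -> ~0.35%).
    """
    if n_patterns <= 0:
        raise ValueError("n_patterns must be positive")
    if not 0.0 <= overall_rate <= 1.0:
        raise ValueError("rate must be in [0,1]")
    return overall_rate / n_patterns
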