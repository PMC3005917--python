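"""Site aggregation, calling criteria, editing ratios, error arithmetic."""

from __future__ import annotations

import numpy as np
import pytest

from editscan.calling import (
    PRE_MIRNA,
    CallingCriteria,
    aggregate_sites,
    apply_criteria,
    classify_targets,
    compute_editing_ratios,
    editing_ratio,
    expected_error_rate_per_pattern,
)
from editscan.mapping import (
    MapResult,
    MismatchRecord,
    OneMismatchIndex,
    TagAlignment,
    map_library,
)
from editscan.synthetic import (
    PlantedEvent,
    SyntheticConfig,
    TagLibrary,
    plant_events,
    simulate_mpss_library,
)

from conftest import make_transcript, random_rna


def mm(target="T", pos=50, ref="C", read="U", tag="X", lib="lib01", count=1, tpm=0.0,
       start=None):
    return MismatchRecord(
        target_id=target, position=pos, ref_base=ref, read_base=read,
        pattern=f"{ref}-to-{read}", tag_sequence=tag, library_id=lib,
        tag_start=start if start is not None else max(1, pos - 5),
        raw_count=count, tpm=tpm,
    )


class TestAggregate:
    def test_six_distinct_tags_support_six(self):
        recs = [mm(tag=f"TAG{i}") for i in range(6)]
        sites = aggregate_sites(recs)
        assert len(sites) == 1 and sites[0].distinct_read_support == 6

    def test_same_tag_across_libraries_counts_once(self):
        recs = [mm(tag="SAME", lib=f"lib{i}") for i in range(3)]
        (site,) = aggregate_sites(recs)
        assert site.distinct_read_support == 1
        assert site.per_library_support == {f"lib{i}": 1 for i in range(3)}

    def test_two_patterns_at_one_position_are_two_sites(self):
        recs = [mm(read="U", tag="A1"), mm(read="G", tag="A2"), mm(read="U", tag="A3")]
        sites = aggregate_sites(recs)
        by_pattern = {s.pattern: s.distinct_read_support for s in sites}
        assert by_pattern == {"C-to-U": 2, "C-to-G": 1}

    def test_bruteforce_grouping_oracle(self, rng):
        """Aggregation equals naive grouping by (target, position, pattern)."""
        recs = []
        for _ in range(200):
            ref, read = rng.choice(list("ACGU"), size=2, replace=False)
            recs.append(
                mm(target=f"T{rng.integers(3)}", pos=int(rng.integers(10, 15)),
                   ref=ref, read=read, tag=random_rna(rng, 8),
                   lib=f"lib{rng.integers(2)}")
            )
        expected: dict = {}
        for r in recs:
            expected.setdefault((r.target_id, r.position, r.pattern), set()).add(
                r.tag_sequence
            )
        got = {
            (s.target_id, s.position, s.pattern): set(s.supporting_tags)
            for s in aggregate_sites(recs)
        }
        assert got == expected


class TestCriteria:
    def make_sites(self, supports, target="T", target_class="protein_coding"):
        recs = []
        for i, n in enumerate(supports):
            for j in range(n):
                recs.append(mm(target=target, pos=20 + 10 * i, tag=f"t{i}_{j}"))
        return aggregate_sites(recs, {target: target_class})

    def test_three_strong_sites_all_called(self):
        sites = self.make_sites([6, 6, 7])
        assert len(apply_criteria(sites)) == 3

    def test_two_sites_fail_per_transcript_rule(self):
        sites = self.make_sites([10, 10])
        assert apply_criteria(sites) == []

    def test_weak_site_drops_transcript_below_minimum(self):
        sites = self.make_sites([6, 6, 5])
        assert apply_criteria(sites) == []

    def test_premirna_site_needs_only_three_reads(self):
        sites = self.make_sites([3], target="MIR1", target_class=PRE_MIRNA)
        assert len(apply_criteria(sites)) == 1
        weak = self.make_sites([2], target="MIR1", target_class=PRE_MIRNA)
        assert apply_criteria(weak) == []

    def test_calling_is_monotone_in_thresholds(self):
        sites = self.make_sites([6, 6, 7, 3]) + self.make_sites(
            [4], target="MIR1", target_class=PRE_MIRNA
        )
        base = {s.site_id for s in apply_criteria(sites, CallingCriteria())}
        for kwargs in (
            {"min_reads_per_site": 7},
            {"min_sites_per_transcript": 4},
            {"min_reads_per_premirna_site": 5},
        ):
            stricter = {
                s.site_id for s in apply_criteria(sites, CallingCriteria(**kwargs))
            }
            assert stricter <= base

    def test_thresholds_validated(self):
        with pytest.raises(ValueError):
            CallingCriteria(min_reads_per_site=0)


def _map_result(perfect_specs, mismatch_recs, lib_id="lib01", tag_length=20):
    """Build a MapResult from (target, start, tag, count) perfect specs."""
    counts = {tag: c for _, _, tag, c in perfect_specs}
    for r in mismatch_recs:
        counts[r.tag_sequence] = r.raw_count
    library = TagLibrary(lib_id, counts, tag_length)
    perfect = [
        TagAlignment(tag, target, start, 0) for target, start, tag, _ in perfect_specs
    ]
    recs = [
        MismatchRecord(
            target_id=r.target_id, position=r.position, ref_base=r.ref_base,
            read_base=r.read_base, pattern=r.pattern, tag_sequence=r.tag_sequence,
            library_id=lib_id, tag_start=r.tag_start, raw_count=r.raw_count,
            tpm=library.tpm[r.tag_sequence],
        )
        for r in mismatch_recs
    ]
    return MapResult(lib_id, library, perfect=perfect, mismatches=recs)


class TestEditingRatio:
    def test_simple_fraction(self):
        assert editing_ratio(5.0, 100.0) == pytest.approx(0.05)

    def test_zero_denominator_is_missing(self):
        assert editing_ratio(0.0, 0.0) is None

    def test_one_edited_of_eight_equal_tags_is_one_eighth(self):
        """Equal-TPM coverage of 8 spanning tags, one edited: ratio 12.50%."""
        edited = mm(pos=30, tag="E" * 20, count=1, start=25)
        perfect = [("T", 20 + i, f"P{i}" * 10, 1) for i in range(7)]
        res = _map_result(perfect, [edited])
        sites = aggregate_sites(res.mismatches)
        (site,) = compute_editing_ratios(sites, [res])
        assert site.per_library_ratio["lib01"] == pytest.approx(0.125)
        assert site.per_library_coverage["lib01"] == 8

    def test_no_unedited_coverage_gives_ratio_one(self):
        edited = mm(pos=30, tag="E" * 20, count=3, start=25)
        res = _map_result([], [edited])
        (site,) = compute_editing_ratios(aggregate_sites(res.mismatches), [res])
        assert site.per_library_ratio["lib01"] == pytest.approx(1.0)

    def test_nonspanning_perfect_tags_excluded(self):
        edited = mm(pos=30, tag="E" * 20, count=1, start=25)
        spanning = ("T", 20, "S" * 20, 1)
        distant = ("T", 100, "D" * 20, 10)
        res = _map_result([spanning, distant], [edited])
        (site,) = compute_editing_ratios(aggregate_sites(res.mismatches), [res])
        # distant tag's large count must not dilute the ratio
        lib = res.library
        expected = lib.tpm["E" * 20] / (lib.tpm["E" * 20] + lib.tpm["S" * 20])
        assert site.per_library_ratio["lib01"] == pytest.approx(expected)

    def test_pool_patterns_switch(self):
        a = mm(pos=30, read="U", tag="E" * 20, count=1, start=25)
        b = mm(pos=30, read="G", tag="F" * 20, count=1, start=25)
        res = _map_result([("T", 25, "P" * 20, 2)], [a, b])
        sites = aggregate_sites(res.mismatches)
        own = compute_editing_ratios(sites, [res])
        pooled = compute_editing_ratios(sites, [res], pool_patterns=True)
        # own-pattern mode: the other pattern's tag belongs to its own site
        # and is excluded from the denominator -> 1 edited vs 2 perfect.
        for s in own:
            assert s.per_library_ratio["lib01"] == pytest.approx(1 / 3)
        for s in pooled:
            assert s.per_library_ratio["lib01"] == pytest.approx(0.5)

    def test_ratio_monotone_in_edited_expression(self):
        ratios = []
        for count in (1, 2, 5, 10):
            edited = mm(pos=30, tag="E" * 20, count=count, start=25)
            res = _map_result([("T", 25, "P" * 20, 10)], [edited])
            (site,) = compute_editing_ratios(aggregate_sites(res.mismatches), [res])
            ratios.append(site.per_library_ratio["lib01"])
        assert ratios == sorted(ratios)
        assert all(0.0 <= r <= 1.0 for r in ratios)


class TestErrorRateArithmetic:
    @pytest.mark.parametrize(
        "rate,expected_pct",
        [(0.0500, 0.42), (0.0425, 0.35), (0.0, 0.0)],
    )
    def test_per_pattern_rate(self, rate, expected_pct):
        per_pattern = expected_error_rate_per_pattern(rate)
        assert round(per_pattern * 100, 2) == expected_pct

    def test_invalid_n_patterns(self):
        with pytest.raises(ValueError):
            expected_error_rate_per_pattern(0.05, 0)


class TestParameterRecovery:
    def test_false_sites_fail_support_under_realistic_error(self):
        """10 replicate libraries at 5% signature error: sequencing noise alone
        never assembles a called site (support>=6 and 3 sites/transcript)."""
        cfg = SyntheticConfig(
            n_transcripts=10, seed=21, tags_per_library=20_000, anchor="uniform",
            per_signature_error_rate=0.05, transcript_length_range=(300, 800),
        )
        from editscan.synthetic import generate_transcriptome

        transcripts, _ = generate_transcriptome(cfg)
        hapsets = plant_events(transcripts, [])
        index = OneMismatchIndex({t.id: t.sequence for t in transcripts}, 20)
        classes = classify_targets(transcripts)
        clean = 0
        for rep in range(10):
            lib = simulate_mpss_library(hapsets, cfg, f"rep{rep}", seed=100 + rep)
            res = map_library(lib, index)
            called = apply_criteria(aggregate_sites(res.mismatches, classes))
            clean += not called
        assert clean / 10 >= 0.95
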