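"""Synthetic-data generator: determinism, planting, tag simulation, TPM."""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from editscan.core import START_CODON, STOP_CODONS
from editscan.synthetic import (
    PlantedEvent,
    SyntheticConfig,
    TagLibrary,
    generate_transcriptome,
    normalize_tpm,
    plant_events,
    sample_tags_with_truth,
    simulate_mpss_library,
    simulate_pare_library,
)

from conftest import make_transcript


class TestConfig:
    def test_degenerate_length_range_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            SyntheticConfig(transcript_length_range=(500, 100))

    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum"):
            SyntheticConfig(compartment_fractions={"nuclear": 0.5})

    @pytest.mark.parametrize("tag_length,rate", [(20, 0.05), (17, 0.0425)])
    def test_default_error_rate_by_tag_length(self, tag_length, rate):
        assert SyntheticConfig(tag_length=tag_length).error_rate == rate


class TestTranscriptome:
    def test_empty(self):
        txs, _ = generate_transcriptome(SyntheticConfig(n_transcripts=0))
        assert txs == []

    def test_deterministic_given_seed(self):
        cfg = SyntheticConfig(n_transcripts=8, seed=1)
        a = generate_transcriptome(cfg)
        b = generate_transcriptome(cfg)
        assert a == b

    def test_forced_compartment(self):
        cfg = SyntheticConfig(
            n_transcripts=6, compartment_fractions={"chloroplast": 1.0}
        )
        txs, _ = generate_transcriptome(cfg)
        assert all(t.compartment == "chloroplast" for t in txs)

    def test_structure_well_formed(self):
        txs, mirs = generate_transcriptome(SyntheticConfig(n_transcripts=10, seed=3))
        for t in txs:
            assert len(t.exons) >= 1
            cds = t.cds_sequence
            assert cds is not None and len(cds) % 3 == 0
            assert cds.startswith(START_CODON) and cds[-3:] in STOP_CODONS
            assert t.utr5 is not None and t.utr3 is not None
            # exons tile the transcript
            covered = sorted(p for s, e in t.exons for p in range(s, e + 1))
            assert covered == list(range(1, len(t) + 1))
        for m in mirs:
            assert 70 <= len(m) <= 200


class TestPlantEvents:
    def test_single_event_two_haplotypes(self):
        tx = make_transcript(sequence="AAACAAA" * 10, cds=None)
        ev = PlantedEvent(tx.id, 4, "C", "U", {"lib01": 0.5})
        hs = plant_events([tx], [ev])[tx.id]
        assert len(hs.haplotypes) == 2
        weights = sorted(h.weights["lib01"] for h in hs.haplotypes)
        assert weights == [0.5, 0.5]
        edited = next(h for h in hs.haplotypes if h.edited_positions)
        assert edited.sequence[3] == "U"

    def test_from_base_mismatch_rejected(self):
        tx = make_transcript(sequence="AAAAAAA")
        ev = PlantedEvent(tx.id, 3, "C", "U", {"lib01": 0.5})
        with pytest.raises(ValueError, match="TX1:3"):
            plant_events([tx], [ev])

    @pytest.mark.parametrize("ratios", [(0.3,), (0.3, 0.7), (0.2, 0.5, 0.9)])
    def test_product_mixture_matches_enumeration(self, ratios):
        """Haplotype weights for k independent sites are the subset products."""
        seq = "ACGU" * 30
        tx = make_transcript(sequence=seq)
        positions = [10, 50, 90][: len(ratios)]
        events = [
            PlantedEvent(tx.id, p, seq[p - 1], "U" if seq[p - 1] != "U" else "A",
                         {"libX": r})
            for p, r in zip(positions, ratios)
        ]
        hs = plant_events([tx], events)[tx.id]
        # brute-force oracle: weight of each edited-subset
        expected = {}
        for mask in itertools.product((0, 1), repeat=len(ratios)):
            key = frozenset(p for m, p in zip(mask, positions) if m)
            expected[key] = np.prod(
                [r if m else 1 - r for m, r in zip(mask, ratios)]
            )
        got = {h.edited_positions: h.weights["libX"] for h in hs.haplotypes}
        assert set(got) == set(expected)
        for key in expected:
            assert got[key] == pytest.approx(expected[key])

    def test_reference_unchanged(self):
        tx = make_transcript(sequence="CCCCCCCCCC")
        hs = plant_events([tx], [PlantedEvent(tx.id, 5, "C", "U", {"l": 1.0})])
        ref = next(h for h in hs[tx.id].haplotypes if not h.edited_positions)
        assert ref.sequence == tx.sequence


class TestNormalizeTpm:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            ({"a": 3, "b": 1}, {"a": 750_000.0, "b": 250_000.0}),
            ({"only": 5}, {"only": 1e6}),
            ({"a": 1, "b": 1, "c": 2}, {"a": 250_000.0, "b": 250_000.0, "c": 500_000.0}),
        ],
    )
    def test_values(self, counts, expected):
        assert normalize_tpm(counts) == expected

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            normalize_tpm({"a": 0})

    @given(st.dictionaries(st.text(alphabet="ACGU", min_size=3, max_size=6),
                           st.integers(min_value=0, max_value=10**6),
                           min_size=1, max_size=30))
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_sums_to_one_million(self, counts):
        if sum(counts.values()) == 0:
            with pytest.raises(ValueError):
                normalize_tpm(counts)
        else:
            assert sum(normalize_tpm(counts).values()) == pytest.approx(1e6, abs=0.5)


class TestMpssSimulation:
    def _hapsets(self, seed=0):
        tx = make_transcript(sequence="".join(
            np.random.default_rng(seed).choice(list("ACGU"), size=400)))
        return plant_events([tx], []), tx

    def test_zero_error_tags_are_substrings(self):
        hapsets, tx = self._hapsets()
        cfg = SyntheticConfig(per_signature_error_rate=0.0, tags_per_library=500,
                              anchor="uniform")
        lib = simulate_mpss_library(hapsets, cfg, "lib01", seed=1)
        assert lib.total_count == 500
        assert all(tag in tx.sequence for tag in lib.counts)

    def test_full_error_tags_differ_at_one_position(self):
        hapsets, _ = self._hapsets()
        cfg = SyntheticConfig(per_signature_error_rate=1.0, tags_per_library=300,
                              anchor="uniform")
        pairs = sample_tags_with_truth(hapsets, cfg, "lib01", seed=2)
        assert len(pairs) == 300
        for tag, src in pairs:
            assert sum(a != b for a, b in zip(tag, src)) == 1

    def test_gatc_anchoring(self):
        seq = "A" * 50 + "GAUC" + "C" * 19 + "G" + "A" * 50
        tx = make_transcript(sequence=seq)
        cfg = SyntheticConfig(per_signature_error_rate=0.0, tags_per_library=50,
                              anchor="gatc")
        lib = simulate_mpss_library(plant_events([tx], []), cfg, "lib01", seed=3)
        # single anchor: all tags start immediately 3' of the GAUC motif
        assert set(lib.counts) == {seq[54:74]}

    def test_short_transcripts_skipped(self):
        short = make_transcript(tid="S", sequence="ACGUACGUAC")
        cfg = SyntheticConfig(per_signature_error_rate=0.0, tags_per_library=100,
                              anchor="uniform")
        lib = simulate_mpss_library(plant_events([short], []), cfg, "l", seed=1)
        assert lib.total_count == 0

    def test_deterministic_given_seed(self):
        hapsets, _ = self._hapsets()
        cfg = SyntheticConfig(tags_per_library=1000, anchor="uniform")
        a = simulate_mpss_library(hapsets, cfg, "lib01", seed=9)
        b = simulate_mpss_library(hapsets, cfg, "lib01", seed=9)
        assert a.counts == b.counts and a.tpm == b.tpm

    def test_roundtrip_fully_edited_site(self):
        """Error 0 + planted ratio 1.0: every spanning tag carries the edit."""
        seq = "".join(np.random.default_rng(5).choice(list("ACGU"), size=300))
        tx = make_transcript(sequence=seq)
        pos = 150
        to = "U" if seq[pos - 1] != "U" else "A"
        hapsets = plant_events(
            [tx], [PlantedEvent(tx.id, pos, seq[pos - 1], to, {"lib01": 1.0})]
        )
        cfg = SyntheticConfig(per_signature_error_rate=0.0, tags_per_library=2000,
                              anchor="uniform")
        lib = simulate_mpss_library(hapsets, cfg, "lib01", seed=4)
        edited_seq = seq[: pos - 1] + to + seq[pos:]
        for tag in lib.counts:
            starts = [i for i in range(len(edited_seq) - 19)
                      if edited_seq[i:i + 20] == tag]
            assert starts, "tag not a substring of the edited haplotype"
            if any(s < pos <= s + 20 for s in starts):
                offsets = {pos - 1 - s for s in starts if s < pos <= s + 20}
                assert any(tag[o] == to for o in offsets)


class TestPareSimulation:
    def test_cleavage_position_tag(self):
        seq = "".join(np.random.default_rng(1).choice(list("ACGU"), size=200))
        tx = make_transcript(sequence=seq)
        hapsets = plant_events([tx], [])
        cfg = SyntheticConfig(pare_error_rate=0.0, tags_per_library=50)
        lib = simulate_pare_library(
            hapsets, cfg, "pare1", seed=1, cleavage_sites={tx.id: [30]}
        )
        assert set(lib.counts) == {seq[29:49]}

    def test_empty_cleavage_set(self):
        tx = make_transcript(length=200)
        lib = simulate_pare_library(
            plant_events([tx], []), SyntheticConfig(), "p", seed=1, cleavage_sites={}
        )
        assert lib.counts == {} and lib.tpm == {}


class TestTagLibrary:
    def test_length_enforced(self):
        with pytest.raises(ValueError, match="not 20 nt"):
            TagLibrary("l", {"ACGU": 1}, 20)

    def test_tpm_computed(self):
        lib = TagLibrary("l", {"A" * 17: 1, "C" * 17: 3}, 17)
        assert lib.tpm["A" * 17] == pytest.approx(250_000.0)
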