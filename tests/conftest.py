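from __future__ import annotations

import numpy as np
import pytest

from editscan.core import Transcript
from editscan.synthetic import (
    PlantedEvent,
    SyntheticConfig,
    generate_transcriptome,
    plant_events,
)

RNA = "ACGU"


def random_rna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(RNA), size=length))


def make_transcript(
    tid: str = "TX1",
    sequence: str | None = None,
    length: int = 300,
    cds: tuple[int, int] | None = None,
    exons: tuple[tuple[int, int], ...] | None = None,
    compartment: str = "nuclear",
    seed: int = 0,
) -> Transcript:
    if sequence is None:
        sequence = random_rna(np.random.default_rng(seed), length)
    if exons is None:
        exons = ((1, len(sequence)),)
    return Transcript(
        id=tid, sequence=sequence, compartment=compartment, exons=exons, cds=cds
    )


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def small_study():
    """A seeded 12-transcript study with three planted sites on one transcript."""
    config = SyntheticConfig(
        n_transcripts=12,
        seed=7,
        n_libraries=2,
        tags_per_library=6000,
        anchor="uniform",
        transcript_length_range=(300, 700),
    )
    transcripts, premirnas = generate_transcriptome(config)
    tx = transcripts[0]
    events = []
    for pos in (80, 140, 200):
        ref = tx.base_at(pos)
        to = next(b for b in RNA if b != ref)
        events.append(
            PlantedEvent(tx.id, pos, ref, to, {"lib01": 0.5, "lib02": 0.5})
        )
    hapsets = plant_events(transcripts, events)
    return config, transcripts, premirnas, events, hapsets
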