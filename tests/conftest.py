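"""Shared fixtures: tiny hand-made genomes and a mid-size simulated one.

Everything is generated programmatically; no data files ship with the
tests.
"""

import pytest

from rnmpmap.genome import GenomeIndex
from rnmpmap.simulate import generate_reference

ALL_TECHNIQUES = ("ribose-seq", "HydEn-seq", "Pu-seq", "emRiboSeq")


@pytest.fixture
def toy_genome() -> GenomeIndex:
    """Two short chromosomes with known sequences for hand-checked cases."""
    return GenomeIndex(
        names=["chrN", "chrM"],
        sequences={"chrN": "AACGTACGTTACGATC", "chrM": "ACGTACGT"},
        organelle_of={"chrN": "nuclear", "chrM": "mitochondrial"},
    )


@pytest.fixture(scope="session")
def sim_genome() -> GenomeIndex:
    """~100 kb nuclear + 10 kb mitochondrial random reference."""
    return generate_reference(
        [
            ("chrN", 100_000, "nuclear", 0.40),
            ("chrM", 10_000, "mitochondrial", 0.20),
        ],
        seed=20260926,
    )
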