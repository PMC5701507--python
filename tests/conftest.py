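import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from karyocut import Genome
from karyocut.simulate import (
    Decoy,
    FixtureConfig,
    PlantedFamily,
    UniqueLocus,
    make_genome,
    toy_audit,
)


def random_genome(seed: int, lengths: dict) -> Genome:
    """A plain random genome (uniform base composition), no planted content."""
    rng = np.random.default_rng(seed)
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    return Genome(
        {
            name: bases[rng.integers(0, 4, size=length)].tobytes().decode("ascii")
            for name, length in lengths.items()
        }
    )


@pytest.fixture(scope="session")
def demo_fixture():
    """A two-chromosome genome with planted families, unique loci, a decoy."""
    config = FixtureConfig(
        seed=7,
        chromosomes=(("chrT", 100_000), ("chrB", 60_000)),
        families=(
            PlantedFamily("fam_clustered", "chrT", 12, "clustered", span=8_000),
            PlantedFamily("fam_scattered", "chrT", 8, "scattered"),
        ),
        unique_loci=tuple(
            UniqueLocus(f"L{i}", "chrT", 30_000 + i * 3_000, 32_000 + i * 3_000, 3)
            for i in range(3)
        ),
        decoys=(Decoy("fam_clustered", 3, "chrB"),),
    )
    return make_genome(config)


@pytest.fixture(scope="session")
def cocktail_fixture():
    """A chromosome with 7 loci of planted genome-unique sites (3 per locus)."""
    config = FixtureConfig(
        seed=11,
        chromosomes=(("chrY", 120_000),),
        unique_loci=tuple(
            UniqueLocus(f"gene{i}", "chrY", 10_000 + i * 4_000, 12_500 + i * 4_000, 3)
            for i in range(7)
        ),
    )
    return make_genome(config)


@pytest.fixture()
def toy():
    return toy_audit()
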