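from pathlib import Path

import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")

DATA = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def data_dir() -> Path:
    return DATA


@pytest.fixture(scope="session")
def hand_cohort(data_dir):
    """The 10-variant hand-built fixture exercising every counting rule."""
    import batchfst as bf

    gm = bf.read_vcf(str(data_dir / "handcount.vcf"))
    meta = bf.read_metadata(str(data_dir / "handcount_metadata.tsv"))
    bf.read_annotations(str(data_dir / "handcount_annotations.tsv"), gm)
    sprime = bf.read_sprime_table(str(data_dir / "handcount_sprime.tsv"), gm)
    return gm, meta, sprime


@pytest.fixture(scope="session")
def small_cohort():
    """A small seeded synthetic cohort shared across read-only tests."""
    import batchfst as bf

    spec = bf.CohortSpec(
        n_variants=3000,
        n_populations=2,
        n_continents=1,
        samples_per_pop=60,
        seed=42,
        center_error_rates={"BCM": 0.005},
    )
    return bf.generate_cohort(spec)
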