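import numpy as np
import pandas as pd
import pytest

from metaport.filtering import run_cascade
from metaport.synthetic_data import SimConfig, simulate, worked_fixture
from metaport.tables_io import ESVTable, SampleFrame


@pytest.fixture(scope="session")
def fixture_bundle():
    return worked_fixture()


@pytest.fixture(scope="session")
def fixture_cascade(fixture_bundle):
    b = fixture_bundle
    return run_cascade(b.esvs, b.motus, b.samples)


def tiny_sim_config(seed: int = 0, **overrides) -> SimConfig:
    """A deliberately small simulation for fast tests."""
    base = dict(
        n_timepoints=3,
        n_replicates=3,
        n_blanks=2,
        n_negatives=1,
        n_nis_motus=12,
        n_nat_motus=24,
        n_other_motus=20,
        depth_meanlog=10.0,  # ~22k reads per sample
        depth_sdlog=0.3,
        shallow_sample_rate=0.0,
        seed=seed,
    )
    base.update(overrides)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def sim_bundle():
    return simulate(tiny_sim_config(11))


@pytest.fixture(scope="session")
def sim_cascade(sim_bundle):
    b = sim_bundle
    return run_cascade(b.esvs, b.motus, b.samples)


def make_samples(spec: list[tuple]) -> SampleFrame:
    """Build a SampleFrame from (id, locality, time, rep, type) tuples."""
    return SampleFrame(
        pd.DataFrame(
            spec,
            columns=[
                "sample_id",
                "locality",
                "time_point",
                "replicate",
                "sample_type",
            ],
        ).set_index("sample_id")
    )


def make_esvs(
    reads: dict[str, list[int]],
    columns: list[str],
    motu_of: dict[str, str] | None = None,
    sequences: dict[str, str] | None = None,
) -> ESVTable:
    df = pd.DataFrame(reads, index=columns).T
    df.index.name = "esv_id"
    motus = pd.Series(
        motu_of or {e: e.split("_")[0] for e in df.index}, name="motu_id"
    )
    seqs = pd.Series(sequences) if sequences else None
    return ESVTable(df, motus, seqs)
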