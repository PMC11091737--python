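import numpy as np
import pandas as pd
import pytest

from methclock.core import (
    BetaMatrix,
    SampleSheet,
    SpeciesCharacteristics,
    SpeciesTable,
    TransformSpec,
)
from methclock.simulate import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Fast 3-species cohort for unit tests (36 samples, 300 probes)."""
    cfg = SimConfig(
        n_samples_per_species=12,
        n_probes=300,
        n_signal_probes=30,
        seed=7,
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def default_cohort():
    """The default acceptance cohort: 3 species x 50 samples, 2000 probes."""
    return simulate_cohort(SimConfig())


@pytest.fixture()
def species_rec():
    return SpeciesCharacteristics("test species", max_lifespan=20.0, gestation=0.5, sexual_maturity=2.0)


@pytest.fixture()
def species_table(species_rec):
    return SpeciesTable([species_rec])


def make_betas(values, probes=None, samples=None):
    values = np.asarray(values, dtype=float)
    probes = probes or [f"cg{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return BetaMatrix(values, probes, samples)


def make_sheet(sample_ids, ages, species="test species", **extra):
    if isinstance(species, str):
        species = [species] * len(sample_ids)
    frame = pd.DataFrame({"sample_id": sample_ids, "age": ages, "species": species, **extra})
    return SampleSheet(frame)
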