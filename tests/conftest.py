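import numpy as np
import pytest

from abcfam import pipeline, synthetic

SEED = 11


@pytest.fixture(scope="session")
def archetypes():
    return synthetic.make_family_archetypes(SEED)


@pytest.fixture(scope="session")
def refdb(archetypes):
    return synthetic.make_reference_db(SEED, archetypes=archetypes)


@pytest.fixture(scope="session")
def profile(archetypes):
    return synthetic.make_profile(SEED, archetypes=archetypes)


@pytest.fixture(scope="session")
def backend(profile):
    return pipeline.BuiltinBackend(profile)


@pytest.fixture
def rng():
    return np.random.default_rng(SEED)


def run_planted(seed, plan, n_decoys=10, fragment_frac=0.3, config=None):
    """Generate a planted proteome and run the full pipeline on it."""
    arch = synthetic.make_family_archetypes(seed)
    db = synthetic.make_reference_db(seed, archetypes=arch)
    records, truth = synthetic.make_proteome(
        seed, plan, n_decoys=n_decoys, fragment_frac=fragment_frac, archetypes=arch
    )
    prof = synthetic.make_profile(seed, archetypes=arch)
    calls = pipeline.scan_species(
        records, db, pipeline.BuiltinBackend(prof), config
    )
    return records, truth, calls
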