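import numpy as np
import pytest

import flashkin as fk

TABLE_SIZES = [56, 53, 60, 33, 57, 52, 9]


@pytest.fixture(scope="session")
def library():
    return fk.default_library()


@pytest.fixture(scope="session")
def cohort(library):
    """Full-size cohort (320 traces) under the default acquisition model."""
    spec = list(zip(library.species, TABLE_SIZES))
    traces, truth = fk.simulate_cohort(
        spec, library, fk.AcquisitionConfig(), seed=1234
    )
    return traces, truth


@pytest.fixture(scope="session")
def cohort_records(cohort):
    traces, _ = cohort
    return fk.extract_first_flash(traces)


@pytest.fixture(scope="session")
def small_noiseless_records(library):
    """Three well-separated species, high-SNR acquisition; fast tests."""
    spec = [
        ("Pyrocystis fusiformis", 30),
        ("Pyrodinium bahamense", 30),
        ("Mnemiopsis leidyi", 30),
    ]
    traces, _ = fk.simulate_cohort(
        spec, library, fk.AcquisitionConfig.noiseless(), seed=7
    )
    return fk.extract_first_flash(traces)


def make_entry(**overrides):
    """A feasible all-defaults species entry for constructed tests."""
    means = dict(rt=50.0, dt=150.0, fd=200.0, ef=50.0, pi=1e9, ffmsl=1e8)
    sds = dict(rt=10.0, dt=30.0, fd=40.0, ef=10.0, pi=2e8, ffmsl=2e7)
    fields = dict(
        species_name="Testus flashii",
        genus="Testus",
        n_observed=10,
        means=means,
        sds=sds,
    )
    for key, val in overrides.items():
        if key in ("means", "sds"):
            fields[key] = {**fields[key], **val}
        else:
            fields[key] = val
    return fk.SpeciesEntry(**fields)
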