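"""Shared fixtures: small panels, cohorts and simulation parameters.

All fixtures are generated programmatically and seeded; nothing is read
from disk.
"""

import pytest

from lowdetect.simulate import (
    Sample,
    SimulationParams,
    make_cohort,
    make_reference,
)


@pytest.fixture(scope="session")
def booby_panel():
    return make_reference("booby", seed=1)


@pytest.fixture(scope="session")
def frigatebird_panel():
    return make_reference("frigatebird", seed=1)


@pytest.fixture(scope="session")
def booby_cohort():
    return make_cohort("booby", seed=2)


@pytest.fixture()
def small_params():
    """Low-depth, error-free parameters for read-level tests."""
    return SimulationParams(mean_depth=300, depth_cv=0.1, error_rate=0.0, seed=9)


@pytest.fixture()
def female_sample():
    return Sample(id="F1", species="booby", sex="F", age_years=5.0)


@pytest.fixture()
def male_sample():
    return Sample(id="M1", species="booby", sex="M", age_years=5.0)
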