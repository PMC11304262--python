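import pandas as pd
import pytest

from nhpnutri.growth import ReferenceStandard, SexParams, build_reference
from nhpnutri.synth import CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def default_cohort() -> pd.DataFrame:
    """Full synthetic cohort at the documented reference parameters."""
    return generate_cohort(CohortSpec(seed=1))


@pytest.fixture(scope="session")
def reference(default_cohort) -> ReferenceStandard:
    return build_reference(default_cohort)


@pytest.fixture(scope="session")
def exact_reference() -> ReferenceStandard:
    """Reference standard fixed at the generating parameters (no estimation
    noise), for checks against the generator's target values."""
    return ReferenceStandard(per_sex={
        "M": SexParams(mu=1.30, sigma=0.34, n=857),
        "F": SexParams(mu=1.12, sigma=0.34, n=530),
    })
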