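import numpy as np
import pytest

from tractstim.lead_vta import LeadModel, VTAParams
from tractstim.synthetic_cohort import SyntheticParams, generate_cohort
from tractstim.tract_io import Streamline, TractBundle


@pytest.fixture
def canonical_lead() -> LeadModel:
    """Lead at the origin pointing up, marker at rotation zero."""
    return LeadModel(tip=np.zeros(3), axis=np.array([0.0, 0.0, 1.0]),
                     rotation=0.0)


@pytest.fixture
def default_vta_params() -> VTAParams:
    return VTAParams()


@pytest.fixture
def small_bundle() -> TractBundle:
    """Three streamlines around the origin with distinct weights."""
    return TractBundle("HDP", "right", [
        Streamline(np.array([[0.0, 0.0, -5.0], [0.0, 0.0, 5.0]]), 1.0),
        Streamline(np.array([[3.0, 0.0, -5.0], [3.0, 0.0, 5.0]]), 3.0),
        Streamline(np.array([[50.0, 0.0, 0.0], [60.0, 0.0, 0.0]]), 2.0),
    ])


def small_cohort_params(seed: int = 11, **overrides) -> SyntheticParams:
    """Reduced problem size for fast end-to-end tests."""
    defaults = dict(seed=seed, n_subjects=6, n_streamlines_hdp=150,
                    n_streamlines_cst=500)
    defaults.update(overrides)
    return SyntheticParams(**defaults)


@pytest.fixture(scope="session")
def small_cohort():
    """A 6-subject cohort shared by the slower end-to-end tests."""
    return generate_cohort(SyntheticParams(
        seed=11, n_subjects=6, n_streamlines_hdp=150, n_streamlines_cst=500))
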