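import pytest

from teicopk import (
    CovariateVector,
    DoseEvent,
    Observation,
    PKParameterSet,
    StudyDataset,
    Subject,
)
from teicopk.estimation import PopulationModel


@pytest.fixture(scope="session")
def published_model() -> PopulationModel:
    return PopulationModel.published()


@pytest.fixture(scope="session")
def reference_covariates() -> CovariateVector:
    """The development-cohort median patient (age 62, eGFR 92.15, IBW 61)."""
    return CovariateVector.from_ibw(61.0, 92.15, 62.0)


@pytest.fixture(scope="session")
def typical_params() -> PKParameterSet:
    """Typical-individual parameters of the final model."""
    return PKParameterSet(CL=1.28, V=92.1)


def make_subject(
    sid=1,
    doses=((0.0, 600.0, 0.5), (12.0, 600.0, 0.5)),
    obs=((12.0, 9.0), (24.0, 12.5)),
    cov=None,
) -> Subject:
    cov = cov or CovariateVector.from_ibw(61.0, 92.15, 62.0)
    return Subject(
        sid,
        [DoseEvent(*d) for d in doses],
        [Observation(t, v) for t, v in obs],
        cov,
    )


@pytest.fixture()
def two_obs_subject() -> Subject:
    return make_subject()


@pytest.fixture(scope="session")
def small_dataset() -> StudyDataset:
    """A 30-subject synthetic study generated from the published model."""
    from teicopk.synthetic_cohort import CohortSpec, generate_dataset

    ds, _ = generate_dataset(CohortSpec(n_subjects=30), seed=42)
    return ds
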