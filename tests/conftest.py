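import pytest
from hypothesis import settings

from comphet import study

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def study_annotations():
    return study.study_annotations()


@pytest.fixture(scope="session")
def study_cohort():
    return study.study_cohort()


@pytest.fixture(scope="session")
def by_hgvs(study_annotations):
    return {rec.variant.hgvs_c: rec for rec in study_annotations.values()}
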