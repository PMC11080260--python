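import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

#: study start date as a reproducibility seed for the simulation fixtures
SEED = 20220317


@pytest.fixture(scope="session")
def survey_config():
    from progeval import SurveyGeneratorConfig

    return SurveyGeneratorConfig(n_respondents=50_000, seed=SEED)


@pytest.fixture(scope="session")
def big_survey(survey_config):
    """One large synthetic exit-interview sample shared across tests."""
    from progeval import generate_exit_interviews

    return generate_exit_interviews(survey_config)


@pytest.fixture(scope="session")
def big_fit(big_survey):
    """Classify -> screen -> multivariable fit on the shared large sample."""
    from progeval import AcceptabilityModel, LikertScaleSpec
    from progeval.synthetic import DEFAULT_REFERENCE_LEVELS

    model = AcceptabilityModel.from_items(
        big_survey, LikertScaleSpec(), reference_levels=DEFAULT_REFERENCE_LEVELS
    )
    return model.fit()
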