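import numpy as np
import pandas as pd
import pytest

from bivintent import SyntheticConfig, generate_survey


@pytest.fixture(scope="session")
def survey200():
    """Small synthetic survey shared by read-only tests."""
    return generate_survey(SyntheticConfig(n=200, seed=11))


@pytest.fixture(scope="session")
def survey_df(survey200):
    return survey200.table


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_wide():
    """Three hand-written respondents covering every schema field."""
    base = {
        "respondent_id": ["a", "b", "c"],
        "vaccine_intent": [90.0, 10.0, 55.0],
        "cta_intent": [50.0, 0.0, 80.0],
        "motivation_vaccine_self": [3, 0, 2],
        "motivation_vaccine_others": [4, 1, 2],
        "motivation_cta_self": [2, 0, 1],
        "motivation_cta_others": [2, 2, 3],
        "risk_likelihood": [40.0, 70.0, 10.0],
        "risk_severity": [60.0, 90.0, 30.0],
        "risk_scare": [50.0, 95.0, 20.0],
        "trust_international": [70.0, 20.0, 50.0],
        "trust_national": [60.0, 10.0, 40.0],
        "trust_scientific": [90.0, 40.0, 70.0],
        "trust_local": [55.0, 30.0, 60.0],
        "self_efficacy": [80.0, 40.0, 60.0],
        "vaccine_doubts": [0.0, 80.0, 15.0],
        "flu_vaccine_2019": [1, 0, 0],
        "conspiracy": [2, 6, 4],
        "gender": ["female", "male", "female"],
        "age": [34.0, 52.0, 24.0],
        "education": ["university degree or higher", "middle school", "high school"],
        "family_status": ["single", "married-living together", "single"],
        "job": ["employee", "business-owner", "student"],
        "salary": ["15-55k", "unknown", "<15k"],
        "covid_contact": [1, 0, 1],
    }
    return pd.DataFrame(base)
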