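import copy

import pytest
import yaml
from hypothesis import settings
from hypothesis import strategies as st
from importlib import resources

from vaxcheck.profile_model import (
    AGE_BANDS,
    CONDITIONS,
    DISEASES,
    DOSE_FIELD_BY_DRUG,
    MEDICATIONS,
    WEIGHT_DRUGS,
)
from vaxcheck.knowledge_base import build_knowledge_base, load_knowledge_base

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def kb():
    return load_knowledge_base()


@pytest.fixture()
def kb_doc():
    """A mutable parsed copy of the default KB document, for breakage tests."""
    text = (
        resources.files("vaxcheck").joinpath("data/default_kb.yaml").read_text("utf-8")
    )
    return copy.deepcopy(yaml.safe_load(text))


@pytest.fixture()
def minimal_raw():
    return {
        "disease": "psoriasis",
        "hand_involvement": False,
        "age_band": "18_59",
        "on_chronic_therapy": False,
        "conditions": [],
    }


@pytest.fixture()
def methotrexate_raw():
    return {
        "disease": "atopic_dermatitis",
        "hand_involvement": True,
        "age_band": "18_59",
        "on_chronic_therapy": True,
        "medication": "methotrexate",
        "methotrexate_weekly_dose_mg": 15,
        "weight_kg": 70,
        "conditions": ["type2_diabetes"],
    }


def _round1(x: float) -> float:
    return round(x, 1)


@st.composite
def raw_profiles(draw):
    """Valid raw checker records covering every conditional-field branch."""
    raw = {
        "disease": draw(st.sampled_from(DISEASES)),
        "hand_involvement": draw(st.booleans()),
        "age_band": draw(st.sampled_from(AGE_BANDS)),
        "on_chronic_therapy": draw(st.booleans()),
    }
    if raw["on_chronic_therapy"]:
        med = draw(st.sampled_from(MEDICATIONS))
        raw["medication"] = med
        if med in DOSE_FIELD_BY_DRUG:
            raw[DOSE_FIELD_BY_DRUG[med]] = draw(
                st.floats(min_value=0.0, max_value=500.0, allow_nan=False).map(_round1)
            )
        if med in WEIGHT_DRUGS:
            raw["weight_kg"] = draw(
                st.floats(min_value=35.0, max_value=200.0, allow_nan=False).map(_round1)
            )
    conds = draw(st.lists(st.sampled_from(CONDITIONS), unique=True, max_size=6))
    if "pregnancy" in conds and "msm" in conds:
        conds.remove("msm")
    raw["conditions"] = conds
    return raw
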