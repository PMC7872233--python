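import json

import pytest
from hypothesis import settings

from braflogic.braf_model import build_braf_model
from braflogic.logic_core import parse_model

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


def make_model(doc: dict):
    return parse_model(json.dumps(doc))


@pytest.fixture
def const_model():
    """One Boolean node whose rule is constantly true."""
    return make_model({"nodes": [{"name": "A"}], "rules": {"A": "1"}})


@pytest.fixture
def toggle_model():
    """One Boolean node that always wants to flip (symmetric 2-state chain)."""
    return make_model({"nodes": [{"name": "A"}], "rules": {"A": "!A"}})


@pytest.fixture
def chain_model():
    """Input A driving Boolean B."""
    return make_model(
        {
            "nodes": [{"name": "A", "is_input": True}, {"name": "B"}],
            "rules": {"B": "A"},
            "phenotypes": {"Output": "B"},
        }
    )


@pytest.fixture
def mv_model():
    """Small multi-valued model: inputs U, V; M reaches level 2 only via U."""
    return make_model(
        {
            "nodes": [
                {"name": "U", "is_input": True},
                {"name": "V", "is_input": True},
                {"name": "M", "max_level": 2},
            ],
            "rules": {"M": ["U | V", "U"]},
            "phenotypes": {"Level": "M"},
        }
    )


@pytest.fixture(scope="session")
def braf():
    return build_braf_model()
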