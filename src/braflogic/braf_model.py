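"""Packaged logical model of BRAF-centred MAPK / PI3K-AKT signaling.

The network covers the ERK1/2 MAPK cascade (receptors, GRB2/SOS, RAS, the
BRAF and CRAF isoforms, MEK, ERK), the PI3K/AKT axis (GAB1, PI3K, PTEN,
PDPK1, AKT, mTOR, p70), the ERK-driven negative feedbacks (SPRY on SOS-GRB2,
ERK on GAB1 and EGFR), the SOX10/FOXD3/ERBB3 axis that distinguishes the
melanoma context from the colorectal one, and a p53/p21 arm downstream of
DNA damage (ATM).  MEK, ERK, p70 and the Proliferation read-out are
multi-valued (levels 0-2); BRAF phosphorylates MEK more efficiently than
CRAF, which is captured by MEK reaching level 2 only through BRAF.

Three named initial-condition profiles encode tissue context: ``generic``
(every node at activation probability 0.5), ``IC_CRC`` (EGF ligand present,
SOX10 and NRG1 absent) and ``IC_melanoma`` (SOX10 and NRG1 present, EGF
absent).  A suite of assertions encoding literature-reported response and
resistance behaviors ships alongside the model and is used as its
validation surface.
"""

from __future__ import annotations

from importlib import resources

from .logic_core import NetworkModel, parse_model
from .model_checking import Assertion, load_assertion_suite
from .simulator import InitialCondition

__all__ = [
    "PROFILE_NAMES",
    "build_braf_model",
    "initial_condition_profile",
    "braf_assertion_suite",
]

PROFILE_NAMES = ("generic", "IC_CRC", "IC_melanoma")


def _read_data(filename: str) -> str:
    return resources.files("braflogic.data").joinpath(filename).read_text("utf-8")


def build_braf_model() -> NetworkModel:
    """Load the packaged BRAF network (30 nodes, 4 multi-valued)."""
    return parse_model(_read_data("braf_model.json"))


def initial_condition_profile(name: str) -> InitialCondition:
    """Named tissue-context initial condition (``generic``/``IC_CRC``/``IC_melanoma``)."""
    if name not in PROFILE_NAMES:
        raise KeyError(f"unknown profile {name!r}; available: {PROFILE_NAMES}")
    model = build_braf_model()
    return InitialCondition(model.initial_profiles[name])


def braf_assertion_suite() -> list[Assertion]:
    """The packaged assertion suite validating the BRAF model's dynamics."""
    return load_assertion_suite(_read_data("table1_suite.yaml"))
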