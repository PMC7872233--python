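"""Assertion-based checking of qualitative model behavior.

An assertion compares the probability of observing a condition (a
conjunction of node-level clauses at ``t_end``) between a baseline
simulation and a perturbed simulation, and states whether that probability
should *increase*, *decrease* or stay *unchanged*.  Assertions encode
literature-derived behaviors ("BRAF inhibition causes feedback activation of
EGFR in colorectal cancer") and are re-run after every model edit, in the
spirit of unit testing for software.

Because probabilities are Monte-Carlo estimates, verdicts include a
significance guard: the stated tolerance is augmented by twice the combined
binomial standard error of the two estimates, so a verdict is only rendered
when the observed difference is resolvable at the configured ensemble size.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import yaml

from .logic_core import NetworkModel, UnknownNodeError, apply_perturbations
from .simulator import (
    InitialCondition,
    SimulationConfig,
    SimulationResult,
    simulate,
)

__all__ = [
    "Clause",
    "Assertion",
    "AssertionReport",
    "SuiteReport",
    "AssertionFailure",
    "parse_condition",
    "probability_of_condition",
    "assert_state_probability",
    "run_assertion_suite",
    "load_assertion_suite",
    "dump_assertion_suite",
]

_DIRECTIONS = ("increase", "decrease", "unchanged")


class AssertionFailure(AssertionError):
    """Raised in unit mode when an assertion's verdict is fail."""


@dataclass(frozen=True)
class Clause:
    """One conjunct of a condition: ``node == level`` or ``node >= level``."""

    node: str
    level: int
    at_least: bool = False

    def __str__(self) -> str:
        op = ">=" if self.at_least else "="
        return f"{self.node}{op}{self.level}"


_CLAUSE_RE = re.compile(r"\s*(>=)?\s*(\d+)\s*\Z")


def parse_condition(condition: dict[str, int | str]) -> list[Clause]:
    """Parse a condition mapping; values are exact levels or ``\">=n\"`` strings."""
    clauses = []
    for node, value in condition.items():
        if isinstance(value, int):
            clauses.append(Clause(node, value))
            continue
        m = _CLAUSE_RE.match(str(value))
        if m is None:
            raise ValueError(f"cannot parse condition clause {node}: {value!r}")
        clauses.append(Clause(node, int(m.group(2)), at_least=m.group(1) is not None))
    return clauses


def probability_of_condition(
    result: SimulationResult, condition: dict[str, int | str] | list[Clause]
) -> float:
    """Total t_end probability mass of states satisfying every clause."""
    clauses = condition if isinstance(condition, list) else parse_condition(condition)
    mask = np.ones(result.final_states.shape[0], dtype=bool)
    for clause in clauses:
        col = result.final_states[:, result.node_column(clause.node)]
        mask &= (col >= clause.level) if clause.at_least else (col == clause.level)
    return float(mask.mean())


@dataclass(frozen=True)
class Assertion:
    """One qualitative behavior to verify.

    ``perturbations`` are applied to the perturbed run and
    ``baseline_perturbations`` (default none: wild type) to the baseline run;
    both runs share the initial-condition profile and simulation config.
    """

    perturbations: dict[str, int]
    initial_profile: str | InitialCondition
    condition: dict[str, int | str]
    direction: str
    tolerance: float = 0.01
    baseline_perturbations: dict[str, int] = field(default_factory=dict)
    label: str = ""

    def __post_init__(self) -> None:
        if self.direction not in _DIRECTIONS:
            raise ValueError(
                f"direction must be one of {_DIRECTIONS}, got {self.direction!r}"
            )
        if self.tolerance < 0:
            raise ValueError("tolerance must be >= 0")


@dataclass
class AssertionReport:
    label: str
    direction: str
    baseline_probability: float
    perturbed_probability: float
    delta: float
    se_baseline: float
    se_perturbed: float
    tolerance: float
    passed: bool

    @property
    def se_combined(self) -> float:
        return float(np.hypot(self.se_baseline, self.se_perturbed))

    def __str__(self) -> str:
        status = "PASS" if self.passed else "FAIL"
        return (
            f"[{status}] {self.label or '(unnamed)'}: {self.direction}; "
            f"baseline={self.baseline_probability:.4f} "
            f"perturbed={self.perturbed_probability:.4f} "
            f"delta={self.delta:+.4f} (+-{2 * self.se_combined:.4f})"
        )


def _binomial_se(p: float, n: int) -> float:
    return float(np.sqrt(p * (1.0 - p) / n))


def assert_state_probability(
    model: NetworkModel,
    assertion: Assertion,
    config: SimulationConfig,
    mode: str = "detailed",
) -> AssertionReport:
    """Evaluate one assertion by a baseline and a perturbed simulation.

    Verdicts: *increase* requires ``delta > tolerance + 2 SE``; *decrease* is
    symmetric; *unchanged* requires ``|delta| <= tolerance + 2 SE`` where SE
    is the combined binomial standard error.  In ``unit`` mode a failing
    verdict raises :class:`AssertionFailure`; in ``detailed`` mode the report
    is returned either way.
    """
    if mode not in ("unit", "detailed"):
        raise ValueError(f"mode must be 'unit' or 'detailed', got {mode!r}")
    clauses = parse_condition(assertion.condition)
    for clause in clauses:
        if not model.has_node(clause.node):
            raise UnknownNodeError(f"condition references unknown node {clause.node}")

    baseline_model = apply_perturbations(model, assertion.baseline_perturbations)
    perturbed_model = apply_perturbations(model, assertion.perturbations)
    base = simulate(baseline_model, assertion.initial_profile, config)
    pert = simulate(perturbed_model, assertion.initial_profile, config)

    p_base = probability_of_condition(base, clauses)
    p_pert = probability_of_condition(pert, clauses)
    se_base = _binomial_se(p_base, base.n_trajectories)
    se_pert = _binomial_se(p_pert, pert.n_trajectories)
    delta = p_pert - p_base
    guard = assertion.tolerance + 2.0 * float(np.hypot(se_base, se_pert))

    if assertion.direction == "increase":
        passed = delta > guard
    elif assertion.direction == "decrease":
        passed = delta < -guard
    else:
        passed = abs(delta) <= guard

    report = AssertionReport(
        label=assertion.label,
        direction=assertion.direction,
        baseline_probability=p_base,
        perturbed_probability=p_pert,
        delta=delta,
        se_baseline=se_base,
        se_perturbed=se_pert,
        tolerance=assertion.tolerance,
        passed=passed,
    )
    if mode == "unit" and not passed:
        raise AssertionFailure(str(report))
    return report


@dataclass
class SuiteReport:
    reports: list[AssertionReport]

    @property
    def n_pass(self) -> int:
        return sum(r.passed for r in self.reports)

    @property
    def n_fail(self) -> int:
        return len(self.reports) - self.n_pass

    @property
    def all_passed(self) -> bool:
        return self.n_fail == 0

    def __str__(self) -> str:
        lines = [str(r) for r in self.reports]
        lines.append(f"{self.n_pass} passed, {self.n_fail} failed")
        return "\n".join(lines)


def run_assertion_suite(
    model: NetworkModel,
    suite: list[Assertion],
    config: SimulationConfig,
) -> SuiteReport:
    """Evaluate every assertion in ``suite`` and collect the reports."""
    return SuiteReport(
        reports=[assert_state_probability(model, a, config) for a in suite]
    )


# ---------------------------------------------------------------------------
# Suite files (YAML/JSON lists of assertion records)
# ---------------------------------------------------------------------------


def load_assertion_suite(text: str) -> list[Assertion]:
    """Parse a YAML (or JSON) list of assertion records."""
    raw = yaml.safe_load(text)
    if not isinstance(raw, list):
        raise ValueError("assertion suite must be a list of records")
    suite = []
    for i, rec in enumerate(raw):
        profile = rec.get("profile", "generic")
        if isinstance(profile, dict):  # inline initial condition
            profile = InitialCondition(profile)
        try:
            suite.append(
                Assertion(
                    perturbations={k: int(v) for k, v in rec.get("perturbations", {}).items()},
                    initial_profile=profile,
                    condition=rec["condition"],
                    direction=rec["direction"],
                    tolerance=float(rec.get("tolerance", 0.01)),
                    baseline_perturbations={
                        k: int(v) for k, v in rec.get("baseline_perturbations", {}).items()
                    },
                    label=rec.get("label", f"assertion {i + 1}"),
                )
            )
        except KeyError as exc:
            raise ValueError(f"assertion record {i}: missing field {exc}") from None
    return suite


def dump_assertion_suite(suite: list[Assertion]) -> str:
    records = []
    for a in suite:
        rec: dict = {
            "label": a.label,
            "perturbations": dict(a.perturbations),
            "condition": dict(a.condition),
            "direction": a.direction,
        }
        if isinstance(a.initial_profile, str):
            rec["profile"] = a.initial_profile
        if a.baseline_perturbations:
            rec["baseline_perturbations"] = dict(a.baseline_perturbations)
        if a.tolerance != 0.01:
            rec["tolerance"] = a.tolerance
        records.append(rec)
    return yaml.safe_dump(records, sort_keys=False)
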