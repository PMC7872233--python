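"""Data model for multi-valued logical regulatory networks.

A network is a set of named nodes, each carrying a discrete activity level in
``[0, max_level]`` (``max_level = 1`` is the Boolean case).  Non-input nodes
are governed by one logical expression per level: the *target level* of a node
in a state is the largest level whose expression is satisfied (0 if none).
Input nodes have no rule and never transition; they model environmental
conditions whose value is drawn once from the initial condition.

The module provides parsing/serialization of a small JSON model dialect,
structural validation, and the two model rewritings used throughout the
package: forcing nodes to a fixed level (mutation-style perturbation) and
grafting an inhibitor input onto a target node (drug-style perturbation).
"""

from __future__ import annotations

import itertools
import json
import re
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "NodeSpec",
    "Expr",
    "Const",
    "Lit",
    "Not",
    "And",
    "Or",
    "NetworkModel",
    "ModelError",
    "ModelSyntaxError",
    "ModelValidationError",
    "UnknownNodeError",
    "ValidationFinding",
    "ValidationReport",
    "parse_expression",
    "parse_model",
    "serialize_model",
    "evaluate_expression",
    "target_level",
    "apply_perturbations",
    "add_inhibitor",
    "validate_model",
]

_IDENT_RE = re.compile(r"[A-Za-z][A-Za-z0-9_]*\Z")


class ModelError(ValueError):
    """Base class for model definition errors."""


class ModelSyntaxError(ModelError):
    """Malformed model document or rule expression."""


class ModelValidationError(ModelError):
    """Structurally valid document that violates a model invariant."""


class UnknownNodeError(ModelError):
    """Reference to a node that is not declared in the model."""


# ---------------------------------------------------------------------------
# Node specification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NodeSpec:
    """A network node: discrete level range, input flag and transition rates.

    ``rate_up`` (k_up) and ``rate_down`` (k_down) are the propensities of a
    one-level activation / inactivation event whenever the node's target level
    lies above / below its current level.  Both default to 1.
    """

    name: str
    max_level: int = 1
    is_input: bool = False
    rate_up: float = 1.0
    rate_down: float = 1.0

    def __post_init__(self) -> None:
        if not _IDENT_RE.match(self.name):
            raise ModelValidationError(f"invalid node identifier: {self.name!r}")
        if self.max_level < 1:
            raise ModelValidationError(f"{self.name}: max_level must be >= 1")
        if not (self.rate_up > 0 and self.rate_down > 0):
            raise ModelValidationError(f"{self.name}: transition rates must be > 0")


# ---------------------------------------------------------------------------
# Logical expressions
# ---------------------------------------------------------------------------


class Expr:
    """Base class of rule expression trees."""

    def evaluate(self, state: dict[str, int]) -> bool:
        raise NotImplementedError

    def literals(self) -> set[tuple[str, int]]:
        """All ``(node, level)`` threshold literals referenced by the tree."""
        raise NotImplementedError

    def __str__(self) -> str:  # pragma: no cover - delegated to subclasses
        raise NotImplementedError

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Expr) and str(self) == str(other)

    def __hash__(self) -> int:
        return hash(str(self))

    def __repr__(self) -> str:
        return f"{type(self).__name__}({str(self)!r})"


class Const(Expr):
    def __init__(self, value: bool):
        self.value = bool(value)

    def evaluate(self, state: dict[str, int]) -> bool:
        return self.value

    def literals(self) -> set[tuple[str, int]]:
        return set()

    def __str__(self) -> str:
        return "1" if self.value else "0"


class Lit(Expr):
    """Threshold literal ``node:level``, true iff ``state[node] >= level``."""

    def __init__(self, node: str, level: int = 1):
        if level < 1:
            raise ModelSyntaxError(f"literal level must be >= 1, got {node}:{level}")
        self.node = node
        self.level = int(level)

    def evaluate(self, state: dict[str, int]) -> bool:
        try:
            return state[self.node] >= self.level
        except KeyError:
            raise UnknownNodeError(f"unknown node in expression: {self.node}") from None

    def literals(self) -> set[tuple[str, int]]:
        return {(self.node, self.level)}

    def __str__(self) -> str:
        return self.node if self.level == 1 else f"{self.node}:{self.level}"


class Not(Expr):
    def __init__(self, operand: Expr):
        self.operand = operand

    def evaluate(self, state: dict[str, int]) -> bool:
        return not self.operand.evaluate(state)

    def literals(self) -> set[tuple[str, int]]:
        return self.operand.literals()

    def __str__(self) -> str:
        inner = str(self.operand)
        if isinstance(self.operand, (And, Or)):
            return f"!({inner})"
        return f"!{inner}"


class _NaryOp(Expr):
    symbol = ""

    def __init__(self, operands: list[Expr]):
        if len(operands) < 2:
            raise ModelSyntaxError(f"{type(self).__name__} needs >= 2 operands")
        self.operands = list(operands)

    def literals(self) -> set[tuple[str, int]]:
        out: set[tuple[str, int]] = set()
        for op in self.operands:
            out |= op.literals()
        return out


class And(_NaryOp):
    symbol = "&"

    def evaluate(self, state: dict[str, int]) -> bool:
        return all(op.evaluate(state) for op in self.operands)

    def __str__(self) -> str:
        parts = [
            f"({op})" if isinstance(op, Or) else str(op) for op in self.operands
        ]
        return " & ".join(parts)


class Or(_NaryOp):
    symbol = "|"

    def evaluate(self, state: dict[str, int]) -> bool:
        return any(op.evaluate(state) for op in self.operands)

    def __str__(self) -> str:
        return " | ".join(str(op) for op in self.operands)


# --- expression parser ------------------------------------------------------

_TOKEN_RE = re.compile(
    r"\s*(?:(?P<lparen>\()|(?P<rparen>\))|(?P<not>!)|(?P<and>&)|(?P<or>\|)"
    r"|(?P<lit>[A-Za-z][A-Za-z0-9_]*(?::\d+)?)|(?P<const>[01]))"
)


def _tokenize(text: str) -> list[tuple[str, str]]:
    tokens: list[tuple[str, str]] = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            if text[pos:].strip() == "":
                break
            raise ModelSyntaxError(
                f"unexpected character {text[pos:].strip()[0]!r} at position {pos} in rule {text!r}"
            )
        pos = m.end()
        kind = m.lastgroup
        tokens.append((kind, m.group(kind)))
    return tokens


class _Parser:
    def __init__(self, text: str):
        self.text = text
        self.tokens = _tokenize(text)
        self.pos = 0

    def peek(self) -> tuple[str, str] | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def next(self) -> tuple[str, str]:
        tok = self.peek()
        if tok is None:
            raise ModelSyntaxError(f"unexpected end of rule {self.text!r}")
        self.pos += 1
        return tok

    def parse(self) -> Expr:
        expr = self.parse_or()
        if self.peek() is not None:
            raise ModelSyntaxError(
                f"trailing tokens after expression in rule {self.text!r}"
            )
        return expr

    def parse_or(self) -> Expr:
        terms = [self.parse_and()]
        while self.peek() is not None and self.peek()[0] == "or":
            self.next()
            terms.append(self.parse_and())
        return terms[0] if len(terms) == 1 else Or(terms)

    def parse_and(self) -> Expr:
        factors = [self.parse_factor()]
        while self.peek() is not None and self.peek()[0] == "and":
            self.next()
            factors.append(self.parse_factor())
        return factors[0] if len(factors) == 1 else And(factors)

    def parse_factor(self) -> Expr:
        kind, value = self.next()
        if kind == "not":
            return Not(self.parse_factor())
        if kind == "lparen":
            inner = self.parse_or()
            kind2, _ = self.next()
            if kind2 != "rparen":
                raise ModelSyntaxError(f"unbalanced parentheses in rule {self.text!r}")
            return inner
        if kind == "const":
            return Const(value == "1")
        if kind == "lit":
            if ":" in value:
                node, level = value.split(":")
                return Lit(node, int(level))
            return Lit(value)
        raise ModelSyntaxError(f"unexpected token {value!r} in rule {self.text!r}")


def parse_expression(text: str) -> Expr:
    """Parse a rule expression in the ``&``, ``|``, ``!`` grammar.

    Threshold literals are written ``NODE:level`` (``NODE`` alone abbreviates
    ``NODE:1``); ``0`` and ``1`` denote the constant expressions.
    """
    return _Parser(text).parse()


def evaluate_expression(expr: Expr, state: dict[str, int]) -> bool:
    """Evaluate ``expr`` in ``state`` (a complete node -> level mapping)."""
    return expr.evaluate(state)


# ---------------------------------------------------------------------------
# Network model
# ---------------------------------------------------------------------------


@dataclass
class NetworkModel:
    """A multi-valued logical network.

    Attributes
    ----------
    nodes:
        Ordered node specifications; order is the canonical node order used by
        the simulator and by serialization.
    rules:
        Mapping from non-input node name to its ordered list of level
        expressions (index ``l - 1`` holds the expression for level ``l``).
    phenotypes:
        Mapping from phenotype name to the read-out node.
    initial_profiles:
        Named initial conditions: mapping profile name -> (node -> activation
        probability); unspecified nodes default to 0.5 at simulation time.
    forced:
        Nodes pinned to a fixed level: the node starts there, never
        transitions, and its target level is the forced level in every state.
    init_overrides:
        Nodes whose *initial* level is pinned but which are otherwise free to
        transition (used when an inhibitor is grafted onto a formerly forced
        node).
    """

    nodes: list[NodeSpec]
    rules: dict[str, list[Expr]] = field(default_factory=dict)
    phenotypes: dict[str, str] = field(default_factory=dict)
    initial_profiles: dict[str, dict[str, float]] = field(default_factory=dict)
    forced: dict[str, int] = field(default_factory=dict)
    init_overrides: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = [n.name for n in self.nodes]
        if len(set(names)) != len(names):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise ModelValidationError(f"duplicate node names: {dup}")
        self._index = {name: i for i, name in enumerate(names)}

    # -- accessors ----------------------------------------------------------

    @property
    def node_names(self) -> list[str]:
        return [n.name for n in self.nodes]

    def node(self, name: str) -> NodeSpec:
        try:
            return self.nodes[self._index[name]]
        except KeyError:
            raise UnknownNodeError(f"unknown node: {name}") from None

    def node_index(self, name: str) -> int:
        try:
            return self._index[name]
        except KeyError:
            raise UnknownNodeError(f"unknown node: {name}") from None

    def has_node(self, name: str) -> bool:
        return name in self._index

    def copy(self) -> "NetworkModel":
        return NetworkModel(
            nodes=list(self.nodes),
            rules={k: list(v) for k, v in self.rules.items()},
            phenotypes=dict(self.phenotypes),
            initial_profiles={k: dict(v) for k, v in self.initial_profiles.items()},
            forced=dict(self.forced),
            init_overrides=dict(self.init_overrides),
        )

    def check_structure(self) -> None:
        """Raise on structural defects (references, bounds, rule arity)."""
        for name, exprs in self.rules.items():
            if not self.has_node(name):
                raise UnknownNodeError(f"rule for undeclared node: {name}")
            spec = self.node(name)
            if spec.is_input:
                raise ModelValidationError(f"input node {name} must not have a rule")
            if len(exprs) != spec.max_level:
                raise ModelValidationError(
                    f"{name}: expected {spec.max_level} level expressions, got {len(exprs)}"
                )
            for expr in exprs:
                for lit_node, lit_level in expr.literals():
                    if not self.has_node(lit_node):
                        raise UnknownNodeError(
                            f"rule for {name} references undeclared node {lit_node}"
                        )
                    ref = self.node(lit_node)
                    if lit_level > ref.max_level:
                        raise ModelValidationError(
                            f"rule for {name}: literal {lit_node}:{lit_level} exceeds "
                            f"max_level {ref.max_level}"
                        )
        for spec in self.nodes:
            if not spec.is_input and spec.name not in self.rules:
                raise ModelValidationError(f"non-input node {spec.name} has no rule")
        for pheno, target in self.phenotypes.items():
            if not self.has_node(target):
                raise UnknownNodeError(f"phenotype {pheno} reads out unknown node {target}")
        for profile, cond in self.initial_profiles.items():
            for node, a in cond.items():
                if not self.has_node(node):
                    raise UnknownNodeError(
                        f"initial profile {profile} sets unknown node {node}"
                    )
                if not (0.0 <= a <= 1.0):
                    raise ModelValidationError(
                        f"initial profile {profile}: activation of {node} outside [0,1]"
                    )
        for mapping in (self.forced, self.init_overrides):
            for node, level in mapping.items():
                spec = self.node(node)
                if not (0 <= level <= spec.max_level):
                    raise ModelValidationError(
                        f"pinned level {level} for {node} outside [0, {spec.max_level}]"
                    )


def target_level(model: NetworkModel, node: str, state: dict[str, int]) -> int:
    """Largest level whose expression holds in ``state`` (0 if none).

    Input nodes (and forced nodes) never transition: inputs return their
    current level, forced nodes their pinned level.
    """
    spec = model.node(node)
    if node in model.forced:
        return model.forced[node]
    if spec.is_input:
        return state[node]
    exprs = model.rules[node]
    for level in range(spec.max_level, 0, -1):
        if exprs[level - 1].evaluate(state):
            return level
    return 0


# ---------------------------------------------------------------------------
# Model rewritings
# ---------------------------------------------------------------------------


def _constant_rules(spec: NodeSpec, level: int) -> list[Expr]:
    return [Const(l <= level) for l in range(1, spec.max_level + 1)]


def apply_perturbations(model: NetworkModel, perturbation: dict[str, int]) -> NetworkModel:
    """Return a copy of ``model`` with each perturbed node pinned to its level.

    The pinned node starts every trajectory at the forced level and its target
    level equals the forced level in every state, so it never transitions.
    The input model is left unmodified; applying the same perturbation twice
    is idempotent.
    """
    out = model.copy()
    for node, level in perturbation.items():
        spec = out.node(node)
        if not (0 <= level <= spec.max_level):
            raise ModelValidationError(
                f"perturbation level {level} for {node} outside [0, {spec.max_level}]"
            )
        out.forced[node] = int(level)
        out.init_overrides.pop(node, None)
        if not spec.is_input:
            out.rules[node] = _constant_rules(spec, level)
    return out


def add_inhibitor(
    model: NetworkModel, target: str, inhibitor_name: str | None = None
) -> NetworkModel:
    """Graft a Boolean inhibitor input onto ``target``.

    Every level expression of ``target`` becomes ``(old) & !inhibitor``: when
    the inhibitor is active the target's rule can no longer be satisfied and
    the node decays to 0.  With the inhibitor inactive the dynamics are
    unchanged.  If the target was forced (e.g. a gain-of-function mutation),
    the inhibitor overrides the forcing: the node still *starts* at its forced
    level but is free to decay once inhibited.
    """
    spec = model.node(target)
    if spec.is_input:
        raise ModelValidationError(f"cannot inhibit input node {target}")
    name = inhibitor_name if inhibitor_name is not None else f"anti_{target}"
    if model.has_node(name):
        raise ModelValidationError(f"inhibitor name already in use: {name}")
    if not _IDENT_RE.match(name):
        raise ModelValidationError(f"invalid inhibitor identifier: {name!r}")

    out = model.copy()
    out.nodes.append(NodeSpec(name, max_level=1, is_input=True))
    out._index[name] = len(out.nodes) - 1
    if target in out.forced:
        level = out.forced.pop(target)
        out.init_overrides[target] = level
        out.rules[target] = _constant_rules(spec, level)
    blocker = Not(Lit(name, 1))
    out.rules[target] = [And([expr, blocker]) for expr in out.rules[target]]
    # inhibitor defaults to OFF in every named profile; callers switch it on
    for cond in out.initial_profiles.values():
        cond.setdefault(name, 0.0)
    return out


# ---------------------------------------------------------------------------
# Validation report
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ValidationFinding:
    kind: str  # "dangling-reference" | "level-bound" | "nesting" | "structure"
    node: str
    message: str


@dataclass
class ValidationReport:
    findings: list[ValidationFinding] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.findings

    def __bool__(self) -> bool:
        return self.ok

    def __str__(self) -> str:
        if self.ok:
            return "model valid: no findings"
        return "\n".join(f"[{f.kind}] {f.node}: {f.message}" for f in self.findings)


_NESTING_ENUM_CAP = 2**16
_NESTING_SAMPLES = 10_000


def validate_model(model: NetworkModel, seed: int = 0) -> ValidationReport:
    """Structural and semantic validation; an empty report means valid.

    Checks dangling references, literal levels beyond a node's range
    (unreachable literals), rule arity, and the level-nesting requirement:
    for every state, satisfying the level-``l+1`` expression must imply
    satisfying the level-``l`` expression.  Nesting is checked by exhaustive
    enumeration over the referenced regulators when feasible, otherwise by
    seeded random sampling.
    """
    report = ValidationReport()

    def finding(kind: str, node: str, message: str) -> None:
        report.findings.append(ValidationFinding(kind, node, message))

    rule_nodes = set(model.rules)
    for name in rule_nodes:
        if not model.has_node(name):
            finding("dangling-reference", name, "rule for undeclared node")
    for spec in model.nodes:
        if spec.is_input:
            if spec.name in model.rules:
                finding("structure", spec.name, "input node has a rule")
            continue
        if spec.name not in model.rules:
            finding("structure", spec.name, "non-input node has no rule")
            continue
        exprs = model.rules[spec.name]
        if len(exprs) != spec.max_level:
            finding(
                "structure",
                spec.name,
                f"expected {spec.max_level} level expressions, got {len(exprs)}",
            )
            continue
        regs: set[str] = set()
        bad_refs = False
        for expr in exprs:
            for lit_node, lit_level in expr.literals():
                if not model.has_node(lit_node):
                    finding(
                        "dangling-reference",
                        spec.name,
                        f"references undeclared node {lit_node}",
                    )
                    bad_refs = True
                    continue
                regs.add(lit_node)
                if lit_level > model.node(lit_node).max_level:
                    finding(
                        "level-bound",
                        spec.name,
                        f"unreachable literal {lit_node}:{lit_level} "
                        f"(max_level {model.node(lit_node).max_level})",
                    )
        if bad_refs or spec.max_level == 1:
            continue
        report.findings.extend(
            ValidationFinding("nesting", spec.name, msg)
            for msg in _nesting_violations(model, spec.name, exprs, sorted(regs), seed)
        )
    for pheno, target in model.phenotypes.items():
        if not model.has_node(target):
            finding("dangling-reference", pheno, f"phenotype reads out unknown node {target}")
    return report


def _nesting_violations(
    model: NetworkModel,
    node: str,
    exprs: list[Expr],
    regs: list[str],
    seed: int,
) -> list[str]:
    levels = [model.node(r).max_level for r in regs]
    n_states = int(np.prod([l + 1 for l in levels])) if regs else 1
    out: list[str] = []

    def check(assignment: dict[str, int]) -> str | None:
        for l in range(len(exprs) - 1):
            if exprs[l + 1].evaluate(assignment) and not exprs[l].evaluate(assignment):
                return (
                    f"level {l + 2} expression holds but level {l + 1} does not "
                    f"in state {assignment}"
                )
        return None

    if n_states <= _NESTING_ENUM_CAP:
        for combo in itertools.product(*[range(l + 1) for l in levels]):
            msg = check(dict(zip(regs, combo)))
            if msg is not None:
                out.append(msg)
                break
    else:
        rng = np.random.default_rng(seed)
        for _ in range(_NESTING_SAMPLES):
            combo = [int(rng.integers(0, l + 1)) for l in levels]
            msg = check(dict(zip(regs, combo)))
            if msg is not None:
                out.append(msg)
                break
    return out


# ---------------------------------------------------------------------------
# Model document (JSON dialect)
# ---------------------------------------------------------------------------


def parse_model(text: str) -> NetworkModel:
    """Parse a UTF-8 JSON model document into a validated :class:`NetworkModel`.

    Document schema::

        {
          "nodes": [{"name": "...", "max_level": 1, "is_input": false,
                     "rate_up": 1.0, "rate_down": 1.0}, ...],
          "rules": {"NODE": ["level-1 expr", "level-2 expr", ...], ...},
          "phenotypes": {"Proliferation": "Proliferation"},
          "initial_profiles": {"generic": {}, "IC_CRC": {"SOX10": 0.0}},
          "forced": {},          # optional
          "init_overrides": {}   # optional
        }

    A rule value may be a single string for Boolean nodes.  Expressions use
    the ``&``, ``|``, ``!`` grammar with ``NODE:level`` threshold literals.
    """
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ModelSyntaxError(f"invalid JSON at line {exc.lineno}: {exc.msg}") from None
    if not isinstance(doc, dict):
        raise ModelSyntaxError("model document must be a JSON object")
    if "nodes" not in doc:
        raise ModelSyntaxError("model document missing 'nodes' field")

    nodes = []
    for i, entry in enumerate(doc["nodes"]):
        if isinstance(entry, str):
            entry = {"name": entry}
        if "name" not in entry:
            raise ModelSyntaxError(f"nodes[{i}]: missing 'name'")
        try:
            nodes.append(
                NodeSpec(
                    name=entry["name"],
                    max_level=int(entry.get("max_level", 1)),
                    is_input=bool(entry.get("is_input", False)),
                    rate_up=float(entry.get("rate_up", 1.0)),
                    rate_down=float(entry.get("rate_down", 1.0)),
                )
            )
        except ModelError as exc:
            raise ModelSyntaxError(f"nodes[{i}]: {exc}") from None

    rules: dict[str, list[Expr]] = {}
    for name, raw in doc.get("rules", {}).items():
        if isinstance(raw, str):
            raw = [raw]
        try:
            rules[name] = [parse_expression(r) for r in raw]
        except ModelError as exc:
            raise ModelSyntaxError(f"rule for {name}: {exc}") from None

    model = NetworkModel(
        nodes=nodes,
        rules=rules,
        phenotypes=dict(doc.get("phenotypes", {})),
        initial_profiles={
            k: {n: float(a) for n, a in v.items()}
            for k, v in doc.get("initial_profiles", {}).items()
        },
        forced={k: int(v) for k, v in doc.get("forced", {}).items()},
        init_overrides={k: int(v) for k, v in doc.get("init_overrides", {}).items()},
    )
    model.check_structure()
    return model


def serialize_model(model: NetworkModel) -> str:
    """Serialize a model back to the JSON dialect (round-trips through parse)."""
    doc = {
        "nodes": [
            {
                "name": n.name,
                "max_level": n.max_level,
                "is_input": n.is_input,
                "rate_up": n.rate_up,
                "rate_down": n.rate_down,
            }
            for n in model.nodes
        ],
        "rules": {name: [str(e) for e in exprs] for name, exprs in model.rules.items()},
        "phenotypes": dict(model.phenotypes),
        "initial_profiles": {k: dict(v) for k, v in model.initial_profiles.items()},
        "forced": dict(model.forced),
        "init_overrides": dict(model.init_overrides),
    }
    return json.dumps(doc, indent=2)
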