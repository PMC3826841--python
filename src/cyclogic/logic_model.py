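"""Multi-valued logical models: representation, parsing, validation.

A model is a set of named nodes, each taking integer levels ``0..max_level``,
updated synchronously by logical rules.  A rule targets one node at one level;
its expression is a tree of AND/OR/NOT operators over threshold leaves
``["GE", node, level]`` / ``["EQ", node, level]``.  For a multi-valued node the
rules are evaluated in descending target-level order and the first satisfied
rule sets the next level; if none is satisfied the node falls to 0.

Models carry cell-cycle specific annotations: phase signatures (expressions
classifying states into G1 / S_G2 / M), designated event nodes (the
cytokinesis node, its completion level, and the mass node used to delimit
cycles), and optional toggleable module blocks (e.g. checkpoint circuits).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterator, Mapping, Sequence

__all__ = [
    "SchemaError",
    "ValidationError",
    "NodeDef",
    "RuleDef",
    "PhaseSignature",
    "ModuleBlock",
    "ModelDefinition",
    "parse_model",
    "parse_model_dict",
    "write_model",
    "model_to_dict",
    "toggle_module",
    "make_toy_model",
    "eval_expr",
    "expr_occurrences",
    "validate_expr",
]

PHASES = ("G1", "S_G2", "M")
ROLES = ("gene", "state-variable", "event-marker")

#: toy state spaces must stay exactly enumerable
ENUMERATION_BOUND = 4096


class SchemaError(ValueError):
    """A model file violates the model-definition schema."""


class ValidationError(ValueError):
    """A structurally well-formed model fails a semantic invariant."""


# ---------------------------------------------------------------------------
# expressions
# ---------------------------------------------------------------------------

def validate_expr(expr: object, levels: Mapping[str, int], where: str) -> None:
    """Check an expression tree against known node levels.

    ``levels`` maps node name -> max_level.  Raises :class:`SchemaError`
    naming the offending rule/node on unresolved references or out-of-range
    thresholds.
    """
    if not isinstance(expr, (list, tuple)) or not expr:
        raise SchemaError(f"{where}: expression must be a non-empty array, got {expr!r}")
    op = expr[0]
    if op in ("GE", "EQ"):
        if len(expr) != 3:
            raise SchemaError(f"{where}: leaf {expr!r} must be [op, node, level]")
        _, node, level = expr
        if node not in levels:
            raise SchemaError(f"{where}: reference to undeclared node {node!r}")
        if not isinstance(level, int) or not (0 <= level <= levels[node]):
            raise SchemaError(
                f"{where}: level {level!r} out of range 0..{levels[node]} for node {node!r}"
            )
    elif op == "NOT":
        if len(expr) != 2:
            raise SchemaError(f"{where}: NOT takes exactly one operand")
        validate_expr(expr[1], levels, where)
    elif op in ("AND", "OR"):
        if len(expr) < 2:
            raise SchemaError(f"{where}: {op} needs at least one operand")
        for sub in expr[1:]:
            validate_expr(sub, levels, where)
    else:
        raise SchemaError(f"{where}: unknown operator {op!r}")


def expr_occurrences(expr: Sequence) -> Iterator[str]:
    """Yield the node name of every leaf occurrence, with multiplicity."""
    op = expr[0]
    if op in ("GE", "EQ"):
        yield expr[1]
    elif op == "NOT":
        yield from expr_occurrences(expr[1])
    else:
        for sub in expr[1:]:
            yield from expr_occurrences(sub)


def eval_expr(expr: Sequence, read: Callable[[str], int]) -> bool:
    """Evaluate an expression, calling ``read(node)`` once per occurrence.

    ``read`` supplies the level at which this particular occurrence observes
    the node — under dosage perturbation each occurrence is sampled
    independently, so the callable is invoked afresh at every leaf.
    """
    op = expr[0]
    if op == "GE":
        return read(expr[1]) >= expr[2]
    if op == "EQ":
        return read(expr[1]) == expr[2]
    if op == "NOT":
        return not eval_expr(expr[1], read)
    if op == "AND":
        return all(eval_expr(sub, read) for sub in expr[1:])
    if op == "OR":
        return any(eval_expr(sub, read) for sub in expr[1:])
    raise ValueError(f"unknown operator {op!r}")


def _canon_expr(expr: Sequence) -> list:
    op = expr[0]
    if op in ("GE", "EQ"):
        return [op, expr[1], int(expr[2])]
    return [op] + [_canon_expr(sub) for sub in expr[1:]]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NodeDef:
    name: str
    max_level: int = 1
    role: str = "gene"

    def __post_init__(self) -> None:
        if self.max_level < 1:
            raise SchemaError(f"node {self.name!r}: max_level must be >= 1")
        if self.role not in ROLES:
            raise SchemaError(f"node {self.name!r}: role must be one of {ROLES}")


@dataclass(frozen=True)
class RuleDef:
    target: str
    target_level: int
    expr: tuple

    def __post_init__(self) -> None:
        object.__setattr__(self, "expr", _freeze(self.expr))


def _freeze(expr) -> tuple:
    if isinstance(expr, (list, tuple)):
        return tuple(_freeze(e) for e in expr)
    return expr


@dataclass(frozen=True)
class PhaseSignature:
    phase: str
    expr: tuple

    def __post_init__(self) -> None:
        if self.phase not in PHASES:
            raise SchemaError(f"phase must be one of {PHASES}, got {self.phase!r}")
        object.__setattr__(self, "expr", _freeze(self.expr))


@dataclass(frozen=True)
class ModuleBlock:
    name: str
    nodes: tuple[NodeDef, ...] = ()
    rules: tuple[RuleDef, ...] = ()
    enabled: bool = False


@dataclass(frozen=True)
class ModelDefinition:
    """A validated multi-valued logical model.

    ``nodes``/``rules`` are the core network; ``modules`` hold optional
    blocks whose nodes are clamped to 0 (and whose rules are ignored) while
    the block is disabled.  ``start_state`` is the START state used as the
    initial condition and cycle delimiter.
    """

    nodes: tuple[NodeDef, ...]
    rules: tuple[RuleDef, ...]
    signatures: tuple[PhaseSignature, ...] = ()
    start_state: Mapping[str, int] = field(default_factory=dict)
    event_nodes: Mapping[str, object] = field(default_factory=dict)
    modules: tuple[ModuleBlock, ...] = ()
    name: str = "model"

    # -- derived views ----------------------------------------------------
    def all_nodes(self) -> tuple[NodeDef, ...]:
        """Core nodes followed by module nodes, in declaration order."""
        out = list(self.nodes)
        for mod in self.modules:
            out.extend(mod.nodes)
        return tuple(out)

    def node_names(self) -> tuple[str, ...]:
        return tuple(n.name for n in self.all_nodes())

    def levels(self) -> dict[str, int]:
        return {n.name: n.max_level for n in self.all_nodes()}

    def active_node_names(self) -> tuple[str, ...]:
        out = [n.name for n in self.nodes]
        for mod in self.modules:
            if mod.enabled:
                out.extend(n.name for n in mod.nodes)
        return tuple(out)

    def active_rules(self) -> tuple[RuleDef, ...]:
        out = list(self.rules)
        for mod in self.modules:
            if mod.enabled:
                out.extend(mod.rules)
        return tuple(out)

    def rules_by_target(self) -> dict[str, tuple[RuleDef, ...]]:
        """Active rules grouped by target, descending target level."""
        grouped: dict[str, list[RuleDef]] = {}
        for rule in self.active_rules():
            grouped.setdefault(rule.target, []).append(rule)
        return {
            t: tuple(sorted(rs, key=lambda r: -r.target_level))
            for t, rs in grouped.items()
        }

    def full_start_state(self) -> dict[str, int]:
        """start_state extended with zeros for every unlisted (module) node."""
        state = {name: 0 for name in self.node_names()}
        state.update({k: int(v) for k, v in self.start_state.items()})
        return state

    def state_space_size(self) -> int:
        size = 1
        for n in self.all_nodes():
            size *= n.max_level + 1
        return size

    @property
    def cytokinesis_node(self) -> str:
        return str(self.event_nodes["cytokinesis"])

    @property
    def mass_node(self) -> str:
        return str(self.event_nodes["mass"])

    @property
    def cytokinesis_level(self) -> int:
        return int(self.event_nodes["cytokinesis_level"])

    def module_names(self) -> tuple[str, ...]:
        return tuple(m.name for m in self.modules)

    # -- validation -------------------------------------------------------
    def validate_static(self) -> None:
        """Structural invariants that need no simulation."""
        names = [n.name for n in self.all_nodes()]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise SchemaError(f"duplicate node names: {sorted(dupes)}")
        levels = self.levels()

        all_rules = list(self.rules)
        for mod in self.modules:
            all_rules.extend(mod.rules)
        seen: set[tuple[str, int]] = set()
        for rule in all_rules:
            where = f"rule for {rule.target!r} level {rule.target_level}"
            if rule.target not in levels:
                raise SchemaError(f"{where}: undeclared target node {rule.target!r}")
            if not (1 <= rule.target_level <= levels[rule.target]):
                raise SchemaError(
                    f"{where}: target level out of range 1..{levels[rule.target]}"
                )
            key = (rule.target, rule.target_level)
            if key in seen:
                raise SchemaError(f"{where}: duplicate rule for this (target, level)")
            seen.add(key)
            validate_expr(rule.expr, levels, where)

        for sig in self.signatures:
            validate_expr(sig.expr, levels, f"signature {sig.phase}")
        if len({s.phase for s in self.signatures}) != len(self.signatures):
            raise SchemaError("duplicate phase signature")

        core = {n.name for n in self.nodes}
        missing = core - set(self.start_state)
        if missing:
            raise SchemaError(f"start_state missing nodes: {sorted(missing)}")
        for node, value in self.start_state.items():
            if node not in levels:
                raise SchemaError(f"start_state references undeclared node {node!r}")
            if not (0 <= int(value) <= levels[node]):
                raise SchemaError(f"start_state value for {node!r} out of range")

        if self.event_nodes:
            for key in ("cytokinesis", "mass", "cytokinesis_level"):
                if key not in self.event_nodes:
                    raise SchemaError(f"event_nodes missing key {key!r}")
            for key in ("cytokinesis", "mass"):
                if self.event_nodes[key] not in levels:
                    raise SchemaError(
                        f"event_nodes.{key} references undeclared node"
                        f" {self.event_nodes[key]!r}"
                    )
            if not (1 <= self.cytokinesis_level <= levels[self.cytokinesis_node]):
                raise SchemaError("cytokinesis completion level exceeds node range")

    def validate_dynamics(self, max_period: int = 512) -> int:
        """Simulate the unperturbed model and check periodicity + signatures.

        Returns the detected period (first return time of ``start_state``).
        Raises :class:`ValidationError` if the start state does not recur
        within ``max_period`` steps, or if any visited state is matched by
        zero or multiple phase signatures (models without signatures skip
        that part).
        """
        from .engine import deterministic_cycle  # local import: layering

        states = deterministic_cycle(self, max_period=max_period)
        if states is None:
            raise ValidationError(
                f"model {self.name!r}: start_state does not recur within "
                f"{max_period} steps under unperturbed dynamics"
            )
        if self.signatures:
            names = self.node_names()
            for t, vec in enumerate(states):
                lookup = dict(zip(names, vec))
                matches = [
                    s.phase for s in self.signatures
                    if eval_expr(s.expr, lookup.__getitem__)
                ]
                if len(matches) != 1:
                    raise ValidationError(
                        f"model {self.name!r}: step {t} of the unperturbed cycle "
                        f"matches signatures {matches} (need exactly one)"
                    )
        return len(states)


# ---------------------------------------------------------------------------
# serialisation
# ---------------------------------------------------------------------------

def model_to_dict(model: ModelDefinition) -> dict:
    d: dict = {
        "name": model.name,
        "nodes": [
            {"name": n.name, "max_level": n.max_level, "role": n.role}
            for n in model.nodes
        ],
        "rules": [
            {"target": r.target, "target_level": r.target_level,
             "expr": _canon_expr(r.expr)}
            for r in model.rules
        ],
        "signatures": {s.phase: _canon_expr(s.expr) for s in model.signatures},
        "start_state": {k: int(model.start_state[k]) for k in sorted(model.start_state)},
        "event_nodes": {
            k: model.event_nodes[k] for k in sorted(model.event_nodes)
        } if model.event_nodes else {},
        "modules": {
            m.name: {
                "nodes": [
                    {"name": n.name, "max_level": n.max_level, "role": n.role}
                    for n in m.nodes
                ],
                "rules": [
                    {"target": r.target, "target_level": r.target_level,
                     "expr": _canon_expr(r.expr)}
                    for r in m.rules
                ],
                "enabled": m.enabled,
            }
            for m in model.modules
        },
    }
    return d


def parse_model_dict(data: Mapping, *, check_dynamics: bool = True,
                     name: str | None = None) -> ModelDefinition:
    """Build and validate a :class:`ModelDefinition` from schema-shaped data."""
    try:
        nodes = tuple(
            NodeDef(str(n["name"]), int(n.get("max_level", 1)),
                    str(n.get("role", "gene")))
            for n in data["nodes"]
        )
        rules = tuple(
            RuleDef(str(r["target"]), int(r["target_level"]), r["expr"])
            for r in data["rules"]
        )
    except (KeyError, TypeError) as exc:
        raise SchemaError(f"malformed model file: {exc}") from exc
    signatures = tuple(
        PhaseSignature(phase, expr)
        for phase, expr in data.get("signatures", {}).items()
    )
    modules = tuple(
        ModuleBlock(
            name=str(mod_name),
            nodes=tuple(
                NodeDef(str(n["name"]), int(n.get("max_level", 1)),
                        str(n.get("role", "gene")))
                for n in blk.get("nodes", [])
            ),
            rules=tuple(
                RuleDef(str(r["target"]), int(r["target_level"]), r["expr"])
                for r in blk.get("rules", [])
            ),
            enabled=bool(blk.get("enabled", False)),
        )
        for mod_name, blk in data.get("modules", {}).items()
    )
    model = ModelDefinition(
        nodes=nodes,
        rules=rules,
        signatures=signatures,
        start_state=dict(data.get("start_state", {})),
        event_nodes=dict(data.get("event_nodes", {})),
        modules=modules,
        name=name or str(data.get("name", "model")),
    )
    model.validate_static()
    if check_dynamics:
        model.validate_dynamics()
    return model


def parse_model(path: str | Path, *, check_dynamics: bool = True) -> ModelDefinition:
    """Parse a model-definition JSON file and validate it."""
    path = Path(path)
    with open(path, "r", encoding="utf-8") as fh:
        try:
            data = json.load(fh)
        except json.JSONDecodeError as exc:
            raise SchemaError(f"{path}: not valid JSON: {exc}") from exc
    return parse_model_dict(data, check_dynamics=check_dynamics)


def write_model(model: ModelDefinition, path: str | Path) -> None:
    """Emit canonical, diff-stable JSON (two writes are byte-identical)."""
    payload = json.dumps(model_to_dict(model), indent=1, sort_keys=True,
                         ensure_ascii=False)
    Path(path).write_text(payload + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# module toggling
# ---------------------------------------------------------------------------

def toggle_module(model: ModelDefinition, name: str, on: bool) -> ModelDefinition:
    """Return a model with the named module block enabled or disabled.

    Disabled module nodes are clamped at 0 and their rules are ignored; core
    rules may still reference them (typically under NOT guards), which is how
    checkpoint blocks intercept transitions only when switched on.
    """
    if name not in model.module_names():
        raise KeyError(
            f"unknown module {name!r}; available: {list(model.module_names())}"
        )
    modules = tuple(
        replace(m, enabled=on) if m.name == name else m for m in model.modules
    )
    return replace(model, modules=modules)


# ---------------------------------------------------------------------------
# toy models
# ---------------------------------------------------------------------------

def make_toy_model(kind: str, size: int = 2) -> ModelDefinition:
    """Small models with analytically known behaviour, for tests and oracles.

    kind="toggle"
        ``size`` independent inverters (each node negates itself): a
        deterministic period-2 oscillator.  Cytokinesis can never complete.
    kind="ring-oscillator"
        A single pulse travelling around ``size`` nodes (period = size).  The
        cytokinesis node sits at level 2 while the pulse crosses three
        consecutive positions, so each lap is one division event.
    kind="arrester"
        A ring whose cytokinesis node can never reach its completion level:
        simulations arrest with zero events.
    """
    if kind == "toggle":
        n_state = size
        space = 2 ** n_state * 3 * 2  # state nodes x CYTO(0..2) x MASS(0..1)
        if space > ENUMERATION_BOUND:
            raise ValueError(
                f"toggle size {size} exceeds the enumeration bound {ENUMERATION_BOUND}"
            )
        nodes = [NodeDef(f"T{i}", 1, "state-variable") for i in range(n_state)]
        rules = [RuleDef(f"T{i}", 1, ("EQ", f"T{i}", 0)) for i in range(n_state)]
        nodes += [NodeDef("CYTO", 2, "event-marker"), NodeDef("MASS", 1, "event-marker")]
        # CYTO flickers to level 2 for single steps only: never a >2-step run.
        rules += [
            RuleDef("CYTO", 2, ("GE", "T0", 1)),
            RuleDef("MASS", 1, ("GE", "MASS", 0)),
        ]
        # start on the all-ones side: CYTO (which lags T0 by a step) is 0 there
        start = {f"T{i}": 1 for i in range(n_state)}
        start.update({"CYTO": 0, "MASS": 1})
        sigs = (
            PhaseSignature("G1", ("EQ", "T0", 0)),
            PhaseSignature("S_G2", ("EQ", "T0", 1)),
        )
        model = ModelDefinition(
            nodes=tuple(nodes), rules=tuple(rules), signatures=sigs,
            start_state=start,
            event_nodes={"cytokinesis": "CYTO", "mass": "MASS",
                         "cytokinesis_level": 2},
            name=f"toggle-{size}",
        )
    elif kind in ("ring-oscillator", "arrester"):
        if size < 4:
            raise ValueError("ring needs at least 4 nodes")
        space = 2 ** size * 3 * 2
        if space > ENUMERATION_BOUND:
            raise ValueError(
                f"ring size {size} exceeds the enumeration bound {ENUMERATION_BOUND}"
            )
        nodes = [NodeDef(f"R{i}", 1, "state-variable") for i in range(size)]
        rules = [
            RuleDef(f"R{i}", 1, ("GE", f"R{(i - 1) % size}", 1))
            for i in range(size)
        ]
        nodes += [NodeDef("CYTO", 2, "event-marker"), NodeDef("MASS", 1, "event-marker")]
        if kind == "ring-oscillator":
            # level 2 while the pulse crosses the last three ring positions
            window = ("OR",) + tuple(("GE", f"R{size - 3 + j}", 1) for j in range(3))
            rules.append(RuleDef("CYTO", 2, window))
        else:
            rules.append(RuleDef("CYTO", 1, ("GE", f"R{size - 1}", 1)))
        rules.append(RuleDef("MASS", 1, ("GE", "MASS", 0)))
        # pulse starts at R1: one step after the CYTO window has gone dark,
        # so the start state genuinely recurs every `size` steps
        start = {f"R{i}": 1 if i == 1 else 0 for i in range(size)}
        start.update({"CYTO": 0, "MASS": 1})
        half = size // 2
        sigs = (
            PhaseSignature("G1", ("OR",) + tuple(
                ("GE", f"R{i}", 1) for i in range(half))),
            PhaseSignature("S_G2", ("AND",
                ("NOT", ("OR",) + tuple(("GE", f"R{i}", 1) for i in range(half))),
            )),
        )
        model = ModelDefinition(
            nodes=tuple(nodes), rules=tuple(rules), signatures=sigs,
            start_state=start,
            event_nodes={"cytokinesis": "CYTO", "mass": "MASS",
                         "cytokinesis_level": 2},
            name=f"{kind}-{size}",
        )
    else:
        raise ValueError(f"unknown toy kind {kind!r}")
    model.validate_static()
    model.validate_dynamics(max_period=2 * ENUMERATION_BOUND)
    return model
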