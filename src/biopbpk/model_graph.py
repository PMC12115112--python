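"""In-memory representation of the graphical model-description language.

A :class:`ModelGraph` holds quantity nodes (species, parameters, compartments),
quantity-modifying nodes (reactions, initial/repeated assignments, dosing
plans), quantity lists, indices, and reusable subgraph definitions with their
instances.  Attaching an index with values ``A..D`` to a quantity ``P`` expands
it into the component array ``P_A .. P_D``; components are named by joining the
quantity name with the index values in declaration order, which makes component
names bit-compatible with VPop CSV column headers.

Subgraph definitions are blueprints whose bodies are nested ``ModelGraph``
objects.  Instances replicate the body under a name prefix; index-value
placeholders (e.g. ``thisOrgan``) declared in the body are bound per instance
and select elements of global parameter arrays via index specifiers such as
``V_va[organ=thisOrgan]``.  Instances may read, but never assign, quantities
defined outside their body.

Quantity lists group species so that a reaction connected to the list is
inherited by every member; lists may nest, and membership must stay acyclic.
"""

from __future__ import annotations

import copy
import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import yaml

from . import expr

__all__ = [
    "Index",
    "Quantity",
    "Reaction",
    "Assignment",
    "DosingPlan",
    "QuantityList",
    "Placeholder",
    "SubgraphDefinition",
    "SubgraphInstance",
    "ModelGraph",
    "Diagnostic",
    "ModelGraphError",
    "verify_graph",
    "expand_components",
]

QUANTITY_KINDS = ("species", "parameter", "compartment")


class ModelGraphError(ValueError):
    """Raised for structural errors while building a model graph."""


@dataclass
class Index:
    """Named, ordered set of index values (e.g. the organ labels)."""

    name: str
    values: list[str]

    def __post_init__(self):
        if not self.values:
            raise ModelGraphError(f"index {self.name!r} must have at least one value")
        if len(set(self.values)) != len(self.values):
            raise ModelGraphError(f"index {self.name!r} has duplicate values")


@dataclass
class Quantity:
    """A species, parameter, or compartment; possibly an indexed array.

    ``default`` is the fill value for every expanded component;
    ``default_values`` overrides individual components by full component name.
    For species the value is the initial amount (moles); for compartments it is
    the volume (litres).
    """

    name: str
    kind: str = "parameter"
    indices: list[str] = field(default_factory=list)
    default: float = 0.0
    default_values: dict[str, float] = field(default_factory=dict)
    container: str | None = None
    exposed: bool = False

    def __post_init__(self):
        if self.kind not in QUANTITY_KINDS:
            raise ModelGraphError(f"unknown quantity kind {self.kind!r}")
        if self.kind == "species" and not self.container:
            raise ModelGraphError(f"species {self.name!r} must reside in a compartment")
        if self.kind != "species" and self.container:
            raise ModelGraphError(f"{self.kind} {self.name!r} cannot have a container")


@dataclass
class Reaction:
    """ODE term: consumes substrates and produces products at ``rate``.

    ``substrates``/``products`` are (species-or-list name, stoichiometry)
    pairs.  ``indices`` names attached indices; the reaction is replicated for
    every combination of their values, with each value available as an ambient
    binding inside the rate expression.
    """

    name: str
    rate: str
    substrates: list[tuple[str, float]] = field(default_factory=list)
    products: list[tuple[str, float]] = field(default_factory=list)
    indices: list[str] = field(default_factory=list)


@dataclass
class Assignment:
    """Initial (once, at setup) or repeated (every solver step) assignment.

    ``target`` is a quantity reference, optionally with an index specifier
    (``V_va[organ=$ad]``).  ``indices`` replicate the assignment over attached
    index values, binding each value ambiently in target and expression.
    """

    name: str
    target: str
    expression: str
    kind: str = "initial"  # or "repeated"
    indices: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.kind not in ("initial", "repeated"):
            raise ModelGraphError(f"bad assignment kind {self.kind!r}")


@dataclass
class DosingPlan:
    """Bolus schedule for one species: list of (time, amount-expression)."""

    name: str
    target: str
    schedule: list[tuple[float, str]] = field(default_factory=list)

    def __post_init__(self):
        times = [t for t, _ in self.schedule]
        if any(t < 0 for t in times):
            raise ModelGraphError(f"dosing plan {self.name!r} has negative times")
        if times != sorted(times):
            raise ModelGraphError(f"dosing plan {self.name!r} times not sorted")


@dataclass
class QuantityList:
    """Ordered collection of species (or nested lists) sharing reactions.

    ``element_index`` pairs the flattened members positionally with the values
    of that index: member k corresponds to element_index.values[k], which is
    bound ambiently when a connected reaction is expanded.
    """

    name: str
    element_index: str
    members: list[str] = field(default_factory=list)
    exposed: bool = False


@dataclass
class Placeholder:
    """Index-value node: a per-instance binding slot over one index."""

    name: str
    index: str
    exposed: bool = True


@dataclass
class SubgraphDefinition:
    """Blueprint submodel; ``body`` is a nested ModelGraph."""

    name: str
    body: "ModelGraph"

    def exposed_nodes(self) -> set[str]:
        names = {q.name for q in self.body.quantities.values() if q.exposed}
        names |= {l.name for l in self.body.lists.values() if l.exposed}
        names |= {p.name for p in self.body.placeholders.values() if p.exposed}
        return names


@dataclass
class SubgraphInstance:
    """Placement of a definition with per-instance placeholder bindings.

    ``bindings`` maps placeholder name -> index value.  ``connections`` maps an
    exposed body node name -> an alias usable in the enclosing graph.
    """

    name: str
    definition: str
    bindings: dict[str, str] = field(default_factory=dict)
    connections: dict[str, str] = field(default_factory=dict)


@dataclass(frozen=True)
class Diagnostic:
    level: str  # "error" | "warning"
    code: str
    message: str

    def __str__(self):  # pragma: no cover - cosmetic
        return f"{self.level}[{self.code}]: {self.message}"


def expand_components(name: str, indices: Sequence[Index]) -> list[str]:
    """Expanded component names: cross-product of index values, declaration order."""
    if not indices:
        return [name]
    combos = itertools.product(*(ix.values for ix in indices))
    return [name + "".join(f"_{v}" for v in combo) for combo in combos]


def _check_name(name: str) -> str:
    if not name or "." in name or not name[0].isalpha() and name[0] != "_":
        raise ModelGraphError(f"invalid node name {name!r} (no dots, must be identifier-like)")
    return name


class ModelGraph:
    """Mutable container for one model (or one subgraph-definition body)."""

    def __init__(self, name: str = "model"):
        self.name = name
        self.indices: dict[str, Index] = {}
        self.quantities: dict[str, Quantity] = {}
        self.lists: dict[str, QuantityList] = {}
        self.reactions: dict[str, Reaction] = {}
        self.assignments: dict[str, Assignment] = {}
        self.dosing_plans: dict[str, DosingPlan] = {}
        self.placeholders: dict[str, Placeholder] = {}
        self.definitions: dict[str, SubgraphDefinition] = {}
        self.instances: dict[str, SubgraphInstance] = {}
        self.observers: dict[str, str] = {}

    # ------------------------------------------------------------- construction

    def add_index(self, name: str, values: Iterable[str]) -> Index:
        ix = Index(_check_name(name), list(values))
        if name in self.indices:
            raise ModelGraphError(f"duplicate index {name!r}")
        self.indices[name] = ix
        return ix

    def add_quantity(
        self,
        name: str,
        kind: str = "parameter",
        indices: Sequence[str] = (),
        default: float = 0.0,
        default_values: Mapping[str, float] | None = None,
        container: str | None = None,
        exposed: bool = False,
    ) -> Quantity:
        q = Quantity(
            _check_name(name),
            kind,
            list(indices),
            float(default),
            dict(default_values or {}),
            container,
            exposed,
        )
        if name in self.quantities:
            raise ModelGraphError(f"duplicate quantity {name!r}")
        # indices may be declared in an enclosing graph (subgraph bodies refer
        # to outer indices); existence is checked at verify/compile time
        self.quantities[name] = q
        return q

    # sugar used throughout the platform builders
    def add_parameter(self, name, **kw) -> Quantity:
        return self.add_quantity(name, "parameter", **kw)

    def add_species(self, name, container, **kw) -> Quantity:
        return self.add_quantity(name, "species", container=container, **kw)

    def add_compartment(self, name, volume: float = 1.0, **kw) -> Quantity:
        return self.add_quantity(name, "compartment", default=volume, **kw)

    def attach_index(self, quantity: str, index: str) -> Quantity:
        """Attach an index to a quantity; components become the cross-product."""
        q = self.quantities[quantity]
        if index not in self.indices:
            raise ModelGraphError(f"unknown index {index!r}")
        if index in q.indices:
            raise ModelGraphError(f"index {index!r} already attached to {quantity!r}")
        q.indices.append(index)
        return q

    def components(self, quantity: str) -> list[str]:
        q = self.quantities[quantity]
        return expand_components(q.name, [self.indices[i] for i in q.indices])

    def add_reaction(self, name, rate, substrates=(), products=(), indices=()) -> Reaction:
        rx = Reaction(
            _check_name(name),
            rate,
            [(s, float(c)) for s, c in substrates],
            [(s, float(c)) for s, c in products],
            list(indices),
        )
        if name in self.reactions:
            raise ModelGraphError(f"duplicate reaction {name!r}")
        self.reactions[name] = rx
        return rx

    def add_assignment(self, name, target, expression, kind="initial", indices=()) -> Assignment:
        a = Assignment(_check_name(name), target, expression, kind, list(indices))
        if name in self.assignments:
            raise ModelGraphError(f"duplicate assignment {name!r}")
        self.assignments[name] = a
        return a

    def add_dosing_plan(self, name, target, schedule) -> DosingPlan:
        d = DosingPlan(_check_name(name), target, [(float(t), a) for t, a in schedule])
        if name in self.dosing_plans:
            raise ModelGraphError(f"duplicate dosing plan {name!r}")
        self.dosing_plans[name] = d
        return d

    def add_list(self, name, element_index, members=(), exposed=False) -> QuantityList:
        # element_index may live in an enclosing graph; resolved at compile time
        lst = QuantityList(_check_name(name), element_index, list(members), exposed)
        if name in self.lists:
            raise ModelGraphError(f"duplicate list {name!r}")
        self.lists[name] = lst
        for m in lst.members:
            self._check_member(lst, m, adding=False)
        if self._membership_cycle():
            raise ModelGraphError(f"list {name!r} creates a membership cycle")
        return lst

    def _check_member(self, lst: QuantityList, member: str, adding: bool) -> None:
        if member in self.lists:
            return
        q = self.quantities.get(member)
        if q is None:
            raise ModelGraphError(f"list {lst.name!r}: unknown member {member!r}")
        if q.kind != "species":
            raise ModelGraphError(
                f"list {lst.name!r}: member {member!r} is a {q.kind}, not a species"
            )

    def add_list_member(self, list_name: str, member: str) -> QuantityList:
        """Append a member (species or nested list); rejects membership cycles."""
        lst = self.lists[list_name]
        self._check_member(lst, member, adding=True)
        lst.members.append(member)
        if self._membership_cycle():
            lst.members.pop()
            raise ModelGraphError(
                f"adding {member!r} to {list_name!r} creates a membership cycle"
            )
        return lst

    def _membership_cycle(self) -> list[str] | None:
        state: dict[str, int] = {}

        def visit(n: str, path: list[str]) -> list[str] | None:
            state[n] = 1
            for m in self.lists[n].members:
                if m in self.lists:
                    if state.get(m) == 1:
                        return path + [m]
                    if state.get(m) != 2:
                        cyc = visit(m, path + [m])
                        if cyc:
                            return cyc
            state[n] = 2
            return None

        for name in self.lists:
            if state.get(name) != 2:
                cyc = visit(name, [name])
                if cyc:
                    return cyc
        return None

    def add_placeholder(self, name, index, exposed=True) -> Placeholder:
        # the index may be declared in the enclosing graph of the instance
        ph = Placeholder(_check_name(name), index, exposed)
        if name in self.placeholders:
            raise ModelGraphError(f"duplicate placeholder {name!r}")
        self.placeholders[name] = ph
        return ph

    def define_subgraph(self, name: str, body: "ModelGraph") -> SubgraphDefinition:
        d = SubgraphDefinition(_check_name(name), body)
        if name in self.definitions:
            raise ModelGraphError(f"duplicate definition {name!r}")
        self.definitions[name] = d
        return d

    def instantiate_subgraph(
        self,
        name: str,
        definition: str,
        bindings: Mapping[str, str] | None = None,
        connections: Mapping[str, str] | None = None,
    ) -> SubgraphInstance:
        """Place an instance; every body placeholder must be bound exactly once."""
        if definition not in self.definitions:
            raise ModelGraphError(f"unknown definition {definition!r}")
        d = self.definitions[definition]
        bindings = dict(bindings or {})
        for ph in d.body.placeholders.values():
            if ph.name not in bindings:
                raise ModelGraphError(
                    f"instance {name!r}: unbound placeholder {ph.name!r}"
                )
            ix = self._find_index(ph.index, d.body)
            if bindings[ph.name] not in ix.values:
                raise ModelGraphError(
                    f"instance {name!r}: {bindings[ph.name]!r} is not a value of "
                    f"index {ph.index!r}"
                )
        for k in bindings:
            if k not in d.body.placeholders:
                raise ModelGraphError(f"instance {name!r}: unknown placeholder {k!r}")
        exposed = d.exposed_nodes()
        for node, alias in (connections or {}).items():
            if node not in exposed:
                raise ModelGraphError(
                    f"instance {name!r}: connection to non-exposed node {node!r}"
                )
            _check_name(alias)
        inst = SubgraphInstance(_check_name(name), definition, bindings, dict(connections or {}))
        if name in self.instances:
            raise ModelGraphError(f"duplicate instance {name!r}")
        self.instances[name] = inst
        return inst

    def _find_index(self, name: str, body: "ModelGraph") -> Index:
        if name in body.indices:
            return body.indices[name]
        if name in self.indices:
            return self.indices[name]
        raise ModelGraphError(f"unknown index {name!r}")

    def add_observer(self, name: str, expression: str) -> None:
        if name in self.observers:
            raise ModelGraphError(f"duplicate observer {name!r}")
        self.observers[name] = expression

    def copy(self) -> "ModelGraph":
        return copy.deepcopy(self)

    # ------------------------------------------------------------- verification

    def verify(self) -> list[Diagnostic]:
        return verify_graph(self)

    # ------------------------------------------------------------ serialization

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "indices": [{"name": i.name, "values": i.values} for i in self.indices.values()],
            "quantities": [
                {
                    "name": q.name,
                    "kind": q.kind,
                    "indices": q.indices,
                    "default": q.default,
                    "default_values": q.default_values,
                    "container": q.container,
                    "exposed": q.exposed,
                }
                for q in self.quantities.values()
            ],
            "lists": [
                {
                    "name": l.name,
                    "element_index": l.element_index,
                    "members": l.members,
                    "exposed": l.exposed,
                }
                for l in self.lists.values()
            ],
            "reactions": [
                {
                    "name": r.name,
                    "rate": r.rate,
                    "substrates": [list(s) for s in r.substrates],
                    "products": [list(p) for p in r.products],
                    "indices": r.indices,
                }
                for r in self.reactions.values()
            ],
            "assignments": [
                {
                    "name": a.name,
                    "target": a.target,
                    "expression": a.expression,
                    "kind": a.kind,
                    "indices": a.indices,
                }
                for a in self.assignments.values()
            ],
            "dosing_plans": [
                {"name": d.name, "target": d.target, "schedule": [list(s) for s in d.schedule]}
                for d in self.dosing_plans.values()
            ],
            "placeholders": [
                {"name": p.name, "index": p.index, "exposed": p.exposed}
                for p in self.placeholders.values()
            ],
            "definitions": [
                {"name": d.name, "body": d.body.to_dict()} for d in self.definitions.values()
            ],
            "instances": [
                {
                    "name": i.name,
                    "definition": i.definition,
                    "bindings": i.bindings,
                    "connections": i.connections,
                }
                for i in self.instances.values()
            ],
            "observers": dict(self.observers),
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "ModelGraph":
        g = cls(data.get("name", "model"))
        for i in data.get("indices", []):
            g.add_index(i["name"], i["values"])
        for d in data.get("definitions", []):
            g.define_subgraph(d["name"], cls.from_dict(d["body"]))
        for q in data.get("quantities", []):
            g.add_quantity(
                q["name"],
                q.get("kind", "parameter"),
                q.get("indices", []),
                q.get("default", 0.0),
                q.get("default_values", {}),
                q.get("container"),
                q.get("exposed", False),
            )
        for l in data.get("lists", []):
            g.add_list(l["name"], l["element_index"], l.get("members", []), l.get("exposed", False))
        for r in data.get("reactions", []):
            g.add_reaction(
                r["name"],
                r["rate"],
                [tuple(s) for s in r.get("substrates", [])],
                [tuple(p) for p in r.get("products", [])],
                r.get("indices", []),
            )
        for a in data.get("assignments", []):
            g.add_assignment(
                a["name"], a["target"], a["expression"], a.get("kind", "initial"), a.get("indices", [])
            )
        for d in data.get("dosing_plans", []):
            g.add_dosing_plan(d["name"], d["target"], [tuple(s) for s in d["schedule"]])
        for p in data.get("placeholders", []):
            g.add_placeholder(p["name"], p["index"], p.get("exposed", True))
        for i in data.get("instances", []):
            g.instantiate_subgraph(
                i["name"], i["definition"], i.get("bindings", {}), i.get("connections", {})
            )
        g.observers = dict(data.get("observers", {}))
        return g

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "ModelGraph":
        return cls.from_dict(yaml.safe_load(text))

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_yaml())

    @classmethod
    def load(cls, path) -> "ModelGraph":
        with open(path) as fh:
            return cls.from_yaml(fh.read())

    def __repr__(self):  # pragma: no cover - cosmetic
        return (
            f"<ModelGraph {self.name!r}: {len(self.quantities)} quantities, "
            f"{len(self.reactions)} reactions, {len(self.instances)} instances>"
        )


def verify_graph(graph: ModelGraph) -> list[Diagnostic]:
    """Run all consistency checks; returns diagnostics (never raises).

    An empty error set means the graph is compilable.  Checks: list-membership
    acyclicity, list/reaction index consistency, symbol resolution everywhere,
    no assignment inside an instance body targeting an outer (global) quantity,
    and a warning when overlapping list membership would duplicate an ODE term
    (double-counting is the modeller's responsibility, so it is not an error).
    """
    from . import compiler  # local import: compiler depends on this module

    diags: list[Diagnostic] = []
    cyc = graph._membership_cycle()
    if cyc:
        diags.append(Diagnostic("error", "list-cycle", " -> ".join(cyc)))
        return diags
    for d in graph.definitions.values():
        body_cyc = d.body._membership_cycle()
        if body_cyc:
            diags.append(
                Diagnostic("error", "list-cycle", f"{d.name}: " + " -> ".join(body_cyc))
            )
            return diags
    diags.extend(compiler.collect_diagnostics(graph))
    return diags
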