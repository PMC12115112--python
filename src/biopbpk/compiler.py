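"""Compile a model graph into an executable ODE system.

The compiler flattens a verified :class:`~biopbpk.model_graph.ModelGraph`:

1. subgraph instances are inlined under a ``"<instance>."`` name prefix with
   their index-value placeholders bound;
2. indexed quantities are expanded into named components (cross-product of
   index values, declaration order);
3. reactions are replicated over their attached indices and over the members
   of any connected quantity list (members are paired positionally with the
   list's element-index values, which become ambient bindings in the rate
   expression);
4. assignments are replicated likewise, ordered topologically, and split into
   an initial schedule (run once at setup) and a repeated schedule (evaluated
   inside the right-hand side at every solver step);
5. the right-hand side is generated as one Python function over the state
   (amounts, moles) and parameter vectors.

States are kept in amounts; concentrations are derived observers.  This makes
mass balance exact by construction: every reaction contributes ``-stoich*rate``
to its substrates and ``+stoich*rate`` to its products, so any closed reaction
set conserves the stoichiometry-weighted total exactly.
"""

from __future__ import annotations

import graphlib
import itertools
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from . import expr
from .model_graph import (
    Diagnostic,
    Index,
    ModelGraph,
    Quantity,
    QuantityList,
    expand_components,
)

__all__ = [
    "CompileError",
    "CompiledModel",
    "ConcreteReaction",
    "DoseEvent",
    "compile_graph",
    "resolve_specifier",
    "order_assignments",
    "collect_diagnostics",
]


class CompileError(ValueError):
    """Raised when a graph cannot be flattened into an executable system."""


# ---------------------------------------------------------------- flat records

@dataclass
class _FlatQuantity:
    full: str
    q: Quantity
    scope: "_Scope"
    index_objs: tuple[Index, ...]

    def components(self) -> list[str]:
        return [self.scope.prefix + c for c in expand_components(self.q.name, self.index_objs)]

    def component_defaults(self) -> dict[str, float]:
        out = {}
        for local in expand_components(self.q.name, self.index_objs):
            out[self.scope.prefix + local] = float(
                self.q.default_values.get(local, self.q.default)
            )
        return out


@dataclass
class _FlatList:
    full: str
    lst: QuantityList
    scope: "_Scope"


class _Scope:
    """One level of the instance-inlining hierarchy."""

    def __init__(self, graph: ModelGraph, prefix: str = "", parent: "_Scope | None" = None,
                 placeholder_values: dict[str, str] | None = None, label: str = "model"):
        self.graph = graph
        self.prefix = prefix
        self.parent = parent
        self.placeholder_values = placeholder_values or {}
        self.label = label
        # ambient index bindings contributed by this instance's placeholders
        self.ambient: dict[str, str] = {}
        for ph_name, value in self.placeholder_values.items():
            ph = graph.placeholders.get(ph_name)
            if ph is not None:
                self.ambient[ph.index] = value


@dataclass
class ConcreteReaction:
    name: str
    rate: object  # resolved expression AST
    substrates: list[tuple[str, float]]
    products: list[tuple[str, float]]


@dataclass(frozen=True)
class DoseEvent:
    time: float
    state: str
    amount: object  # expression AST, evaluated at initialization
    plan: str


# ------------------------------------------------------------------ flattener

class _Flattener:
    def __init__(self, graph: ModelGraph):
        self.root = graph
        self.quantities: dict[str, _FlatQuantity] = {}
        self.lists: dict[str, _FlatList] = {}
        self.aliases: dict[str, str] = {}
        self.modifiers: list[tuple[str, object, _Scope]] = []  # kind, obj, scope
        self.diagnostics: list[Diagnostic] = []
        self.collect = False

    # -- error handling -------------------------------------------------------

    def _fail(self, code: str, message: str):
        raise CompileError(f"[{code}] {message}")

    def _note(self, code: str, message: str, level: str = "error"):
        self.diagnostics.append(Diagnostic(level, code, message))

    # -- phase 1: registration ------------------------------------------------

    def register(self):
        self._walk(self.root, _Scope(self.root))

    def _walk(self, graph: ModelGraph, scope: _Scope):
        for q in graph.quantities.values():
            full = scope.prefix + q.name
            idx_objs = tuple(self._index(i, scope) for i in q.indices)
            self.quantities[full] = _FlatQuantity(full, q, scope, idx_objs)
        for lst in graph.lists.values():
            self.lists[scope.prefix + lst.name] = _FlatList(scope.prefix + lst.name, lst, scope)
        for rx in graph.reactions.values():
            self.modifiers.append(("reaction", rx, scope))
        for a in graph.assignments.values():
            self.modifiers.append(("assignment", a, scope))
        for d in graph.dosing_plans.values():
            self.modifiers.append(("dose", d, scope))
        for inst in graph.instances.values():
            defn = graph.definitions.get(inst.definition)
            if defn is None:
                self._fail("unknown-definition", f"instance {inst.name!r}: {inst.definition!r}")
            child = _Scope(
                defn.body,
                prefix=scope.prefix + inst.name + ".",
                parent=scope,
                placeholder_values=dict(inst.bindings),
                label=f"{scope.label}/{inst.name}",
            )
            for node, alias in inst.connections.items():
                self.aliases[scope.prefix + alias] = child.prefix + node
            self._walk(defn.body, child)

    def _index(self, name: str, scope: _Scope) -> Index:
        s = scope
        while s is not None:
            if name in s.graph.indices:
                return s.graph.indices[name]
            s = s.parent
        self._fail("unknown-index", f"index {name!r} not found (scope {scope.label})")

    # -- symbol lookup --------------------------------------------------------

    def _lookup(self, name: str, scope: _Scope, context: str,
                check_exposure: bool = True) -> tuple[str, str]:
        s = scope
        while s is not None:
            cand = s.prefix + name
            cand = self.aliases.get(cand, cand)
            kind = "quantity" if cand in self.quantities else (
                "list" if cand in self.lists else None)
            if kind is not None:
                if check_exposure:
                    self._check_exposure(cand, kind, scope, context)
                return kind, cand
            s = s.parent
        self._fail("unresolved-symbol", f"{context}: unknown symbol {name!r}")

    def _check_exposure(self, full: str, kind: str, scope: _Scope, context: str):
        # a reference reaching *into* a descendant instance must target an
        # exposed node (references outward to enclosing scopes are plain reads)
        if not full.startswith(scope.prefix):
            return
        rel = full[len(scope.prefix):]
        if "." not in rel:
            return
        node = self.quantities[full].q if kind == "quantity" else self.lists[full].lst
        if not node.exposed:
            self._fail(
                "not-exposed",
                f"{context}: {full!r} is not an exposed node of its definition",
            )

    def _placeholder_value(self, name: str, scope: _Scope, context: str) -> str:
        s = scope
        while s is not None:
            if name in s.placeholder_values:
                return s.placeholder_values[name]
            s = s.parent
        self._fail("unbound-placeholder", f"{context}: placeholder {name!r} is unbound")

    def _ambient_value(self, index: str, ambient: Mapping[str, str], scope: _Scope) -> str | None:
        if index in ambient:
            return ambient[index]
        s = scope
        while s is not None:
            if index in s.ambient:
                return s.ambient[index]
            s = s.parent
        return None

    def _component_of(self, full: str, spec: tuple, scope: _Scope,
                      ambient: Mapping[str, str], context: str) -> str:
        fq = self.quantities[full]
        spec_map: dict[str, str] = {}
        for iname, val, lit in spec:
            v = val if lit else self._placeholder_value(val, scope, context)
            spec_map[iname] = v
        for iname in spec_map:
            if iname not in fq.q.indices:
                self._fail(
                    "bad-specifier",
                    f"{context}: index {iname!r} is not attached to {full!r}",
                )
        suffix = []
        for ix, iname in zip(fq.index_objs, fq.q.indices):
            v = spec_map.get(iname)
            if v is None:
                v = self._ambient_value(iname, ambient, scope)
            if v is None:
                self._fail(
                    "unresolved-index",
                    f"{context}: index {iname!r} of {full!r} has no binding",
                )
            if v not in ix.values:
                self._fail(
                    "unknown-index-value",
                    f"{context}: {v!r} is not a value of index {iname!r}",
                )
            suffix.append(v)
        return full + "".join(f"_{v}" for v in suffix)

    def _resolve_expression(self, ast, scope: _Scope, ambient: Mapping[str, str],
                            listmap: Mapping[str, str], context: str,
                            check_exposure: bool = True):
        def sub(sym: expr.Sym):
            name = sym.name
            try:
                kind, full = self._lookup(name, scope, context, check_exposure)
            except CompileError:
                if name in expr.TIME_NAMES and not sym.spec:
                    return expr.Sym("t")
                raise
            if kind == "list":
                if full not in listmap:
                    self._fail(
                        "list-outside-loop",
                        f"{context}: list {full!r} referenced outside a list-"
                        "connected reaction",
                    )
                return expr.Sym(listmap[full])
            return expr.Sym(self._component_of(full, sym.spec, scope, ambient, context))

        return expr.map_symbols(ast, sub)

    # -- list flattening ------------------------------------------------------

    def _flatten_members(self, full: str, context: str, _seen=None) -> list[str]:
        fl = self.lists[full]
        out: list[str] = []
        for m in fl.lst.members:
            kind, mfull = self._lookup(m, fl.scope, context, check_exposure=False)
            if kind == "list":
                out.extend(self._flatten_members(mfull, context))
            else:
                out.append(mfull)
        return out

    # -- phase 2: expansion ---------------------------------------------------

    def expand(self):
        self.concrete_reactions: list[ConcreteReaction] = []
        self.initial: list[tuple[str, object, str]] = []  # target comp, ast, name
        self.repeated: list[tuple[str, object, str]] = []
        self.doses: list[DoseEvent] = []
        self.observers: list[tuple[str, object]] = []

        for kind, obj, scope in self.modifiers:
            if self.collect:
                try:
                    getattr(self, f"_expand_{kind}")(obj, scope)
                except CompileError as e:
                    code, _, msg = str(e).partition("] ")
                    self._note(code.strip("["), msg or str(e))
            else:
                getattr(self, f"_expand_{kind}")(obj, scope)

        for name, text in self.root.observers.items():
            ctx = f"observer {name!r}"
            if self.collect:
                try:
                    ast = self._resolve_expression(
                        expr.parse(text), _Scope(self.root), {}, {}, ctx, check_exposure=False
                    )
                except CompileError as e:
                    self._note("observer", str(e))
                    continue
            else:
                ast = self._resolve_expression(
                    expr.parse(text), _Scope(self.root), {}, {}, ctx, check_exposure=False
                )
            self.observers.append((name, ast))

    def _expand_reaction(self, rx, scope: _Scope):
        ctx = f"reaction {scope.prefix}{rx.name}"
        loop_objs = [self._index(i, scope) for i in rx.indices]
        rate_ast = expr.parse(rx.rate)

        # collect referenced lists from stoichiometry entries and rate symbols
        names = [n for n, _ in rx.substrates] + [n for n, _ in rx.products]
        names += [s.name for s in expr.symbols(rate_ast)]
        list_fulls: list[str] = []
        for n in names:
            try:
                kind, full = self._lookup(n, scope, ctx, check_exposure=False)
            except CompileError:
                continue
            if kind == "list" and full not in list_fulls:
                list_fulls.append(full)

        element: Index | None = None
        n_members: int | None = None
        members: dict[str, list[str]] = {}
        if list_fulls:
            for lf in list_fulls:
                fl = self.lists[lf]
                ei = self._index(fl.lst.element_index, fl.scope)
                if element is None:
                    element = ei
                elif ei.name != element.name or ei.values != element.values:
                    self._fail(
                        "list-index-mismatch",
                        f"{ctx}: lists use different element indices "
                        f"({element.name!r} vs {ei.name!r})",
                    )
                flat = self._flatten_members(lf, ctx)
                if len(flat) > len(element.values):
                    self._fail(
                        "list-arity",
                        f"{ctx}: list {lf!r} has {len(flat)} member species but "
                        f"index {element.name!r} has only {len(element.values)} values",
                    )
                if n_members is None:
                    n_members = len(flat)
                elif len(flat) != n_members:
                    self._fail(
                        "list-arity",
                        f"{ctx}: connected lists have differing member counts",
                    )
                if len(set(flat)) != len(flat):
                    self._note(
                        "duplicate-term",
                        f"{ctx}: list {lf!r} reaches the same species more than "
                        "once via overlapping membership; the resulting ODE terms "
                        "are duplicated",
                        level="warning",
                    )
                members[lf] = flat

        combos = itertools.product(*(ix.values for ix in loop_objs)) if loop_objs else [()]
        for combo in combos:
            base = dict(zip((ix.name for ix in loop_objs), combo))
            positions = range(n_members) if element is not None else [None]
            for k in positions:
                ambient = dict(base)
                listmap: dict[str, str] = {}
                suffix = "".join(f"_{v}" for v in combo)
                if k is not None:
                    ambient[element.name] = element.values[k]
                    suffix += f"_{element.values[k]}"
                    for lf, flat in members.items():
                        mfull = flat[k]
                        listmap[lf] = self._component_of(mfull, (), scope, ambient, ctx)
                subs = [
                    (self._stoich_ref(n, scope, ambient, listmap, ctx), c)
                    for n, c in rx.substrates
                ]
                prods = [
                    (self._stoich_ref(n, scope, ambient, listmap, ctx), c)
                    for n, c in rx.products
                ]
                rate = self._resolve_expression(rate_ast, scope, ambient, listmap, ctx)
                self.concrete_reactions.append(
                    ConcreteReaction(f"{scope.prefix}{rx.name}{suffix}", rate, subs, prods)
                )

    def _stoich_ref(self, name: str, scope: _Scope, ambient, listmap, ctx) -> str:
        kind, full = self._lookup(name, scope, ctx)
        if kind == "list":
            if full not in listmap:
                self._fail("list-outside-loop", f"{ctx}: list {full!r} has no member here")
            comp = listmap[full]
        else:
            comp = self._component_of(full, (), scope, ambient, ctx)
        root = comp if comp in self.quantities else None
        # component -> owning quantity kind check
        fq = self._owning_quantity(comp)
        if fq.q.kind != "species":
            self._fail("kind-mismatch", f"{ctx}: {comp!r} is a {fq.q.kind}, not a species")
        return comp

    def _owning_quantity(self, comp: str) -> _FlatQuantity:
        if comp in self.quantities:
            return self.quantities[comp]
        # strip index suffixes until the base quantity is found
        name = comp
        while "_" in name:
            name = name.rsplit("_", 1)[0]
            if name in self.quantities:
                return self.quantities[name]
        self._fail("unresolved-symbol", f"unknown component {comp!r}")

    def _expand_assignment(self, a, scope: _Scope):
        ctx = f"assignment {scope.prefix}{a.name}"
        loop_objs = [self._index(i, scope) for i in a.indices]
        target_ast = expr.parse(a.target)
        if not isinstance(target_ast, expr.Sym):
            self._fail("bad-target", f"{ctx}: target must be a single quantity reference")
        expr_ast = expr.parse(a.expression)
        combos = itertools.product(*(ix.values for ix in loop_objs)) if loop_objs else [()]
        for combo in combos:
            ambient = dict(zip((ix.name for ix in loop_objs), combo))
            kind, tfull = self._lookup(target_ast.name, scope, ctx)
            if kind == "list":
                self._fail("bad-target", f"{ctx}: cannot assign to a list")
            if scope.parent is not None and not tfull.startswith(scope.prefix):
                self._fail(
                    "illegal-global-write",
                    f"{ctx}: instances may read but not modify the outer "
                    f"quantity {tfull!r}",
                )
            tcomp = self._component_of(tfull, target_ast.spec, scope, ambient, ctx)
            tq = self._owning_quantity(tcomp)
            if tq.q.kind == "species" and a.kind == "repeated":
                self._fail(
                    "bad-target",
                    f"{ctx}: repeated assignments cannot target species states",
                )
            ast = self._resolve_expression(expr_ast, scope, ambient, {}, ctx)
            bucket = self.initial if a.kind == "initial" else self.repeated
            bucket.append((tcomp, ast, f"{scope.prefix}{a.name}"))

    def _expand_dose(self, d, scope: _Scope):
        ctx = f"dosing plan {scope.prefix}{d.name}"
        kind, tfull = self._lookup(d.target, scope, ctx)
        if kind == "list":
            self._fail("bad-target", f"{ctx}: dosing target must be a species")
        tcomp = self._component_of(tfull, (), scope, {}, ctx)
        if self._owning_quantity(tcomp).q.kind != "species":
            self._fail("bad-target", f"{ctx}: dosing target must be a species")
        for t, amount in d.schedule:
            ast = self._resolve_expression(expr.parse(amount), scope, {}, {}, ctx)
            self.doses.append(DoseEvent(float(t), tcomp, ast, f"{scope.prefix}{d.name}"))


# ------------------------------------------------------------- compiled model

@dataclass
class CompiledModel:
    """Flattened executable form of a model graph.

    The right-hand side operates on amounts; ``observe`` evaluates the named
    observers (typically concentrations and organ totals) at given states.
    """

    state_names: list[str]
    parameter_names: list[str]
    species_defaults: dict[str, float]
    param_defaults: dict[str, float]
    containers: dict[str, str]
    reactions: list[ConcreteReaction]
    initial_assignments: list[tuple[str, object, str]]
    repeated_assignments: list[tuple[str, object, str]]
    dose_events: list[DoseEvent]
    observer_names: list[str]
    assigned_targets: frozenset[str]
    rhs: Callable = field(repr=False, default=None)
    _obs_fn: Callable = field(repr=False, default=None)
    source: str = field(repr=False, default="")

    def __post_init__(self):
        self.state_index = {n: i for i, n in enumerate(self.state_names)}
        self.param_index = {n: i for i, n in enumerate(self.parameter_names)}

    @property
    def n_states(self) -> int:
        return len(self.state_names)

    def validate_overrides(self, overrides: Mapping[str, float]) -> None:
        for name in overrides:
            if name in self.assigned_targets:
                raise ValueError(
                    f"{name!r} is defined by an assignment node and cannot be "
                    "overridden through the VPop file"
                )
            if name not in self.state_index and name not in self.param_index:
                raise ValueError(f"unknown quantity {name!r}")

    def initialize(self, overrides: Mapping[str, float] | None = None):
        """Apply overrides, run initial assignments, evaluate dose amounts.

        Returns ``(y0, p, doses)`` with doses as (time, state index, amount).
        """
        overrides = dict(overrides or {})
        self.validate_overrides(overrides)
        env: dict[str, float] = {}
        env.update(self.param_defaults)
        env.update(self.species_defaults)
        env.update(overrides)
        for tcomp, ast, _name in self.initial_assignments:
            env[tcomp] = expr.evaluate(ast, env, t=0.0)
        y0 = np.array([env[s] for s in self.state_names], dtype=float)
        p = np.array([env[c] for c in self.parameter_names], dtype=float)
        doses = sorted(
            (
                (ev.time, self.state_index[ev.state], float(expr.evaluate(ev.amount, env, 0.0)))
                for ev in self.dose_events
            ),
            key=lambda x: x[0],
        )
        return y0, p, doses

    def observe(self, t: float, y: np.ndarray, p: np.ndarray) -> np.ndarray:
        if self._obs_fn is None or not self.observer_names:
            return np.empty(0)
        return np.asarray(self._obs_fn(t, y, p), dtype=float)

    def equations(self) -> str:
        """Human-readable dump of the flattened ODE system for audit."""
        terms: dict[str, list[str]] = {s: [] for s in self.state_names}
        for rx in self.reactions:
            rate = expr.unparse(rx.rate)
            for comp, c in rx.substrates:
                terms[comp].append(f"- {c}*[{rx.name}: {rate}]")
            for comp, c in rx.products:
                terms[comp].append(f"+ {c}*[{rx.name}: {rate}]")
        lines = []
        for tcomp, ast, name in self.initial_assignments:
            lines.append(f"init {tcomp} = {expr.unparse(ast)}    ({name})")
        for tcomp, ast, name in self.repeated_assignments:
            lines.append(f"every-step {tcomp} = {expr.unparse(ast)}    ({name})")
        for s in self.state_names:
            rhs = " ".join(terms[s]) if terms[s] else "0"
            lines.append(f"d({s})/dt = {rhs}")
        return "\n".join(lines)


# ----------------------------------------------------------------- public API

def order_assignments(assignments: Sequence[tuple[str, object]]):
    """Topologically order (target, expression-AST) pairs by dependency.

    Every assignment is evaluated after all assignments whose targets appear in
    its expression.  Raises :class:`CompileError` naming the cycle if circular.
    """
    targets = {}
    for tcomp, ast, *rest in assignments:
        if tcomp in targets:
            raise CompileError(f"[duplicate-target] {tcomp!r} assigned more than once")
        targets[tcomp] = (tcomp, ast, *rest)
    sorter = graphlib.TopologicalSorter()
    for tcomp, ast, *_ in targets.values():
        deps = [s.name for s in expr.symbols(ast) if s.name in targets and s.name != tcomp]
        sorter.add(tcomp, *deps)
    try:
        order = list(sorter.static_order())
    except graphlib.CycleError as e:
        cycle = " -> ".join(e.args[1])
        raise CompileError(f"[assignment-cycle] cyclic assignments: {cycle}") from None
    return [targets[t] for t in order]


def resolve_specifier(expression: str, bindings: Mapping[str, str],
                      graph: ModelGraph | None = None) -> str:
    """Rewrite index specifiers in an expression to concrete component names.

    Placeholder values come from ``bindings``; literal ``$`` values resolve
    directly.  With ``graph`` given, specifier values are ordered by the
    quantity's index declaration order; otherwise specifier order is used.
    """
    ast = expr.parse(expression)

    def sub(sym: expr.Sym):
        if not sym.spec:
            return sym
        resolved = {}
        for iname, val, lit in sym.spec:
            if lit:
                resolved[iname] = val
            else:
                if val not in bindings:
                    raise CompileError(f"[unbound-placeholder] {val!r} in {expression!r}")
                resolved[iname] = bindings[val]
        if graph is not None and sym.name in graph.quantities:
            order = [i for i in graph.quantities[sym.name].indices if i in resolved]
            leftover = [i for i in resolved if i not in order]
            order += leftover
            for iname, v in resolved.items():
                ix = graph.indices.get(iname)
                if ix is not None and v not in ix.values:
                    raise CompileError(
                        f"[unknown-index-value] {v!r} is not a value of {iname!r}"
                    )
        else:
            order = list(resolved)
        return expr.Sym(sym.name + "".join(f"_{resolved[i]}" for i in order))

    return expr.unparse(expr.map_symbols(ast, sub))


def collect_diagnostics(graph: ModelGraph) -> list[Diagnostic]:
    """Dry-run flattening, returning diagnostics instead of raising."""
    fl = _Flattener(graph)
    fl.collect = True
    try:
        fl.register()
    except CompileError as e:
        fl._note("registration", str(e))
        return fl.diagnostics
    fl.expand()
    try:
        order_assignments(fl.initial)
        order_assignments(fl.repeated)
    except CompileError as e:
        fl._note("assignment-order", str(e))
    return fl.diagnostics


def compile_graph(graph: ModelGraph, check: bool = True) -> CompiledModel:
    """Flatten and code-generate a model graph into a :class:`CompiledModel`.

    With ``check=True`` (default) the graph is verified first and compilation
    refuses to proceed on any error-level diagnostic.
    """
    if check:
        errors = [d for d in graph.verify() if d.level == "error"]
        if errors:
            msgs = "; ".join(str(d) for d in errors)
            raise CompileError(f"graph failed verification: {msgs}")
    fl = _Flattener(graph)
    fl.register()
    fl.expand()

    state_names: list[str] = []
    param_names: list[str] = []
    species_defaults: dict[str, float] = {}
    param_defaults: dict[str, float] = {}
    containers: dict[str, str] = {}
    for fq in fl.quantities.values():
        comps = fq.components()
        defaults = fq.component_defaults()
        if fq.q.kind == "species":
            state_names.extend(comps)
            species_defaults.update(defaults)
            ckind, cfull = fl._lookup(fq.q.container, fq.scope, f"species {fq.full!r}",
                                      check_exposure=False)
            cq = fl.quantities[cfull]
            if cq.q.kind != "compartment":
                raise CompileError(
                    f"[bad-container] species {fq.full!r} container {cfull!r} is a "
                    f"{cq.q.kind}"
                )
            if not cq.q.indices:
                for c in comps:
                    containers[c] = cfull
            elif cq.q.indices == fq.q.indices:
                for c, cc in zip(comps, cq.components()):
                    containers[c] = cc
            else:
                raise CompileError(
                    f"[bad-container] species {fq.full!r} and compartment {cfull!r} "
                    "must share the same attached indices"
                )
        else:
            param_names.extend(comps)
            param_defaults.update(defaults)

    initial = order_assignments(fl.initial)
    repeated = order_assignments(fl.repeated)
    assigned = frozenset(t for t, *_ in fl.initial) | frozenset(t for t, *_ in fl.repeated)

    state_index = {n: i for i, n in enumerate(state_names)}
    param_index = {n: i for i, n in enumerate(param_names)}

    # ---- code generation ----------------------------------------------------
    mangle: dict[str, str] = {}
    for n, i in state_index.items():
        mangle[n] = f"y[{i}]"
    for n, i in param_index.items():
        mangle[n] = f"p[{i}]"

    def to_code(node, table) -> str:
        if isinstance(node, expr.Num):
            return repr(node.value)
        if isinstance(node, expr.Sym):
            if node.name == "t":
                return "t"
            try:
                return table[node.name]
            except KeyError:
                raise CompileError(f"[codegen] unmapped symbol {node.name!r}") from None
        if isinstance(node, expr.Bin):
            op = "**" if node.op == "^" else node.op
            return f"({to_code(node.left, table)}{op}{to_code(node.right, table)})"
        if isinstance(node, expr.Neg):
            return f"(-{to_code(node.arg, table)})"
        if isinstance(node, expr.Call):
            return f"{node.fn}({', '.join(to_code(a, table) for a in node.args)})"
        raise CompileError(f"[codegen] bad node {node!r}")

    prelude: list[str] = []
    rtable = dict(mangle)
    for j, (tcomp, ast, _name) in enumerate(repeated):
        prelude.append(f"    ra{j} = {to_code(ast, rtable)}")
        rtable[tcomp] = f"ra{j}"

    lines = ["def _rhs(t, y, p):"]
    lines += prelude
    dterms: dict[int, list[str]] = {}
    for k, rx in enumerate(fl.concrete_reactions):
        lines.append(f"    r{k} = {to_code(rx.rate, rtable)}")
        for comp, c in rx.substrates:
            dterms.setdefault(state_index[comp], []).append(f"-{c!r}*r{k}")
        for comp, c in rx.products:
            dterms.setdefault(state_index[comp], []).append(f"+{c!r}*r{k}")
    lines.append(f"    dy = _zeros({len(state_names)})")
    for i, terms in dterms.items():
        lines.append(f"    dy[{i}] = " + " ".join(terms))
    lines.append("    return dy")

    obs_names = [n for n, _ in fl.observers]
    if fl.observers:
        lines.append("def _obs(t, y, p):")
        lines += prelude
        exprs = ", ".join(to_code(ast, rtable) for _, ast in fl.observers)
        lines.append(f"    return ({exprs},)")
    source = "\n".join(lines)

    ns: dict = {"_zeros": np.zeros}
    ns.update(expr.FUNCTIONS)
    exec(compile(source, f"<biopbpk:{graph.name}>", "exec"), ns)  # noqa: S102

    return CompiledModel(
        state_names=state_names,
        parameter_names=param_names,
        species_defaults=species_defaults,
        param_defaults=param_defaults,
        containers=containers,
        reactions=fl.concrete_reactions,
        initial_assignments=initial,
        repeated_assignments=repeated,
        dose_events=sorted(fl.doses, key=lambda d: d.time),
        observer_names=obs_names,
        assigned_targets=assigned,
        rhs=ns["_rhs"],
        _obs_fn=ns.get("_obs"),
        source=source,
    )
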