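"""Independent naive graph-walking interpreter used as a compiler oracle.

Computes per-component state derivatives directly from the *unflattened*
model graph by recursive enumeration: reactions are walked in place, index
loops and list memberships are expanded on the fly, and instance bodies are
entered with their placeholder bindings.  The structure is deliberately
different from the compiler (single-pass, object-based, no registries, no
code generation) so agreement between the two is meaningful.

Limitations (enough for the graphs it checks): no channel-connection
aliases (dotted references are supported instead), no repeated assignments.
"""

from __future__ import annotations

import itertools
from collections import defaultdict

from biopbpk import expr

# a frame is (graph, prefix, placeholder_values, ambient_index_bindings)


def _find_index(frames, name):
    for g, _, _, _ in reversed(frames):
        if name in g.indices:
            return g.indices[name]
    raise KeyError(f"index {name}")


def _lookup(frames, name):
    """Resolve a (possibly dotted) name to (kind, obj, owner_frames)."""
    for fi in range(len(frames) - 1, -1, -1):
        parts = name.split(".")
        cur_frames = list(frames[: fi + 1])
        g = cur_frames[-1][0]
        ok = True
        while len(parts) > 1:
            head = parts.pop(0)
            if head in g.instances:
                inst = g.instances[head]
                body = g.definitions[inst.definition].body
                amb = {
                    body.placeholders[ph].index: v
                    for ph, v in inst.bindings.items()
                    if ph in body.placeholders
                }
                cur_frames.append(
                    (body, cur_frames[-1][1] + head + ".", dict(inst.bindings), amb)
                )
                g = body
            else:
                ok = False
                break
        if not ok:
            continue
        leaf = parts[0]
        if leaf in g.quantities:
            return "q", g.quantities[leaf], cur_frames
        if leaf in g.lists:
            return "l", g.lists[leaf], cur_frames
    raise KeyError(name)


def _placeholder_value(frames, name):
    for _, _, ph, _ in reversed(frames):
        if name in ph:
            return ph[name]
    raise KeyError(f"placeholder {name}")


def _ambient(frames, index, loop):
    if index in loop:
        return loop[index]
    for _, _, _, amb in reversed(frames):
        if index in amb:
            return amb[index]
    raise KeyError(f"no binding for index {index}")


def _component(qobj, owner_frames, usage_frames, spec, loop):
    prefix = owner_frames[-1][1]
    chosen = {}
    for iname, val, lit in spec:
        chosen[iname] = val if lit else _placeholder_value(usage_frames, val)
    suffix = []
    for iname in qobj.indices:
        v = chosen.get(iname)
        if v is None:
            v = _ambient(usage_frames, iname, loop)
        suffix.append(v)
    return prefix + qobj.name + "".join(f"_{v}" for v in suffix)


def _flatten_members(lst, owner_frames):
    out = []
    for m in lst.members:
        kind, obj, frames = _lookup(owner_frames, m)
        if kind == "l":
            out.extend(_flatten_members(obj, frames))
        else:
            out.append((obj, frames))
    return out


def _rate_value(ast, frames, loop, listmap, env, t):
    def sub(sym):
        if sym.name in expr.TIME_NAMES:
            try:
                _lookup(frames, sym.name)
            except KeyError:
                return expr.Sym("t")
        kind, obj, owner = _lookup(frames, sym.name)
        if kind == "l":
            return expr.Sym(listmap[id(obj)])
        return expr.Sym(_component(obj, owner, frames, sym.spec, loop))

    return expr.evaluate(expr.map_symbols(ast, sub), env, t)


def derivatives(graph, env, t=0.0):
    """State derivatives (component name -> value) at one point."""
    dy = defaultdict(float)
    root = [(graph, "", {}, {})]
    _process(graph, root, dy, env, t)
    return dict(dy)


def _process(g, frames, dy, env, t):
    for rx in g.reactions.values():
        _expand(rx, frames, dy, env, t)
    for inst in g.instances.values():
        body = g.definitions[inst.definition].body
        amb = {
            body.placeholders[ph].index: v
            for ph, v in inst.bindings.items()
            if ph in body.placeholders
        }
        child = frames + [(body, frames[-1][1] + inst.name + ".", dict(inst.bindings), amb)]
        _process(body, child, dy, env, t)


def _expand(rx, frames, dy, env, t):
    ast = expr.parse(rx.rate)
    loops = [_find_index(frames, i) for i in rx.indices]
    names = [n for n, _ in rx.substrates] + [n for n, _ in rx.products]
    names += [s.name for s in expr.symbols(ast)]
    lists = []
    seen = set()
    for n in names:
        try:
            kind, obj, owner = _lookup(frames, n)
        except KeyError:
            continue
        if kind == "l" and id(obj) not in seen:
            seen.add(id(obj))
            lists.append((obj, owner))
    element = _find_index(lists[0][1], lists[0][0].element_index) if lists else None
    n_members = len(_flatten_members(*lists[0])) if lists else 0

    for combo in itertools.product(*(ix.values for ix in loops)) if loops else [()]:
        loop = dict(zip((ix.name for ix in loops), combo))
        for k in range(n_members) if element is not None else [None]:
            lmap = {}
            lp = dict(loop)
            if k is not None:
                lp[element.name] = element.values[k]
                for obj, owner in lists:
                    mobj, mframes = _flatten_members(obj, owner)[k]
                    lmap[id(obj)] = _component(mobj, mframes, mframes, (), lp)
            rate = _rate_value(ast, frames, lp, lmap, env, t)
            for name, stoich in rx.substrates:
                dy[_ref(name, frames, lp, lmap)] -= stoich * rate
            for name, stoich in rx.products:
                dy[_ref(name, frames, lp, lmap)] += stoich * rate


def _ref(name, frames, loop, listmap):
    kind, obj, owner = _lookup(frames, name)
    if kind == "l":
        return listmap[id(obj)]
    return _component(obj, owner, frames, (), loop)
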