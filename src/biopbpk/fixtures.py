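"""Seeded generators for every input the test-bench needs.

* :func:`toy_models` — four constructions of the same four-reaction,
  eight-state first-order system (manual, index-expanded, subgraph-based and
  list-based), all compiling to identical ODEs.
* :func:`table1_vpop` — the worked-example VPop table (four parameter sets
  overriding the A/B branches of the toy system).
* :func:`synth_physiology` — synthetic whole-body physiology tables for
  mouse, rat, monkey and human, allometrically scaled from a curated human
  reference (volumes scale with body weight, flows with body weight^0.75),
  plus the corresponding cross-species VPop table and optional log-normal
  inter-individual population sampling.

All outputs are deterministic for a given seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .engine import VPopRow, VPopTable
from .model_graph import ModelGraph

__all__ = [
    "FixtureSpec",
    "Physiology",
    "toy_models",
    "table1_vpop",
    "synth_physiology",
    "population_vpop",
    "ORGANS",
    "ORGAN_INDEX_VALUES",
    "SPECIES_BODY_WEIGHT",
]

# 21 whole-body organ labels (schematic organ set; "sc" is the subcutaneous
# injection-site tissue and "ot" the rest-of-body closure organ), plus the
# arterial and venous blood pools as extra organ-index values.
ORGANS = [
    "lu", "he", "ki", "li", "sp", "gu", "pa", "st", "mu", "sk", "ad",
    "bo", "bm", "br", "th", "ln", "ey", "te", "an", "sc", "ot",
]
ORGAN_INDEX_VALUES = ORGANS + ["ar", "ve"]

SPECIES_BODY_WEIGHT = {"mouse": 0.025, "rat": 0.25, "monkey": 3.5, "human": 70.0}


# ------------------------------------------------------------------ toy models

_TOY_INDEX = ["A", "B", "C", "D"]
_TOY_P = 1.0
_TOY_S1 = 10.0


def _toy_base(name: str) -> ModelGraph:
    g = ModelGraph(name)
    g.add_index("i", _TOY_INDEX)
    g.add_compartment("Main", volume=1.0)
    return g


def toy_models() -> dict[str, ModelGraph]:
    """Four equivalent constructions of dS1_i/dt = -P_i*S1_i, dS2_i/dt = +P_i*S1_i.

    Returns ``{"manual", "indexed", "subgraph", "list"}``; every graph expands
    to states S1_A..S2_D and parameters P_A..P_D, so their compiled systems
    can be compared component by component.
    """
    # manual: every species, parameter and reaction written out by hand
    manual = _toy_base("toy_manual")
    for v in _TOY_INDEX:
        manual.add_parameter(f"P_{v}", default=_TOY_P)
        manual.add_species(f"S1_{v}", "Main", default=_TOY_S1)
        manual.add_species(f"S2_{v}", "Main")
    for k, v in enumerate(_TOY_INDEX, start=1):
        manual.add_reaction(
            f"R{k}", f"P_{v}*S1_{v}", substrates=[(f"S1_{v}", 1)], products=[(f"S2_{v}", 1)]
        )

    # index-expanded: one reaction with the index attached
    indexed = _toy_base("toy_indexed")
    indexed.add_parameter("P", indices=["i"], default=_TOY_P)
    indexed.add_species("S1", "Main", indices=["i"], default=_TOY_S1)
    indexed.add_species("S2", "Main", indices=["i"])
    indexed.add_reaction(
        "R", "P*S1", substrates=[("S1", 1)], products=[("S2", 1)], indices=["i"]
    )

    # reusable subgraph: the reaction lives in a definition; four instances
    # bind the index-value node "thisInstance" to A..D
    subgraph = _toy_base("toy_subgraph")
    subgraph.add_parameter("P", indices=["i"], default=_TOY_P)
    subgraph.add_species("S1", "Main", indices=["i"], default=_TOY_S1)
    subgraph.add_species("S2", "Main", indices=["i"])
    body = ModelGraph("toy_reaction_block")
    body.add_placeholder("thisInstance", "i")
    body.add_reaction(
        "R", "P[i=thisInstance]*S1", substrates=[("S1", 1)], products=[("S2", 1)]
    )
    subgraph.define_subgraph("ReactionBlock", body)
    for v in _TOY_INDEX:
        subgraph.instantiate_subgraph(f"Inst{v}", "ReactionBlock", {"thisInstance": v})

    # quantity lists: species created individually, grouped into lists that
    # inherit one shared reaction
    listed = _toy_base("toy_list")
    listed.add_parameter("P", indices=["i"], default=_TOY_P)
    for v in _TOY_INDEX:
        listed.add_species(f"S1_{v}", "Main", default=_TOY_S1)
        listed.add_species(f"S2_{v}", "Main")
    listed.add_list("L1", "i", [f"S1_{v}" for v in _TOY_INDEX])
    listed.add_list("L2", "i", [f"S2_{v}" for v in _TOY_INDEX])
    listed.add_reaction("R", "P*L1", substrates=[("L1", 1)], products=[("L2", 1)])

    return {"manual": manual, "indexed": indexed, "subgraph": subgraph, "list": listed}


def table1_vpop() -> VPopTable:
    """The worked-example VPop file: four labelled override sets for the toy model."""
    rows = [
        (1, "Set 1", 0.647911, 6.422175, 76.44275, 2.585046, 15.34369, 4.826582),
        (2, "Set 2", 0.619675, 11.27114, 74.00611, 8.810178, 94.17874, 6.750496),
        (3, "Set 3", 0.447106, 10.09819, 49.51735, 5.76495, 59.79229, 1.762077),
        (4, "Set 4", 0.50173, 5.224387, 43.71762, 5.4861, 34.39141, 8.304497),
    ]
    cols = ["P_A", "P_B", "S1_A", "S1_B", "S2_A", "S2_B"]
    return VPopTable(
        [
            VPopRow(rid, label, dict(zip(cols, vals)))
            for rid, label, *vals in rows
        ]
    )


# ------------------------------------------------------------------ physiology

@dataclass
class FixtureSpec:
    """Controls the synthetic physiology generator.

    ``cv`` is the log-normal coefficient of variation used for population
    sampling (0 disables noise); ``lymph_fraction`` is the organ lymph flow as
    a fraction of its plasma flow.
    """

    seed: int = 0
    species: tuple[str, ...] = ("mouse", "rat", "monkey", "human")
    body_weight: dict[str, float] = field(default_factory=lambda: dict(SPECIES_BODY_WEIGHT))
    cardiac_output_human: float = 150.0  # plasma flow, L/h
    lymph_fraction: float = 0.002
    cv: float = 0.0

    def validate(self) -> None:
        unknown = set(self.species) - set(self.body_weight)
        if unknown:
            raise ValueError(f"unknown animal species {sorted(unknown)}")
        if not 0.0 < self.lymph_fraction < 1.0:
            raise ValueError("lymph fraction must be in (0, 1)")
        if self.cv < 0:
            raise ValueError("cv must be non-negative")


@dataclass
class Physiology:
    """One animal's organ table plus whole-body scalars.

    ``organs`` is indexed by organ label (including ``ar``/``ve`` rows for the
    blood pools) with columns V_va, V_en, V_is, V_ic (L), Q, L (L/h), rS, rL
    (nm), alphaL, A0dx (cm), FcRn0 (M), CLcat (L/h), sl, alb_ratio_is and
    Rabund (mol, receptor abundance for RME; zero by default).
    """

    name: str
    organs: pd.DataFrame
    tbw: float
    tbv: float
    gfr: float


# curated human reference: total organ volume (L), fraction of plasma cardiac
# output, and rough relative endosomal FcRn / catabolic weights
_HUMAN_ORGANS = {
    # organ: (V_total L, Q fraction of CO reaching it from the arterial pool)
    "lu": (1.0, 1.00),  # pulmonary flow = total cardiac output
    "he": (0.35, 0.04),
    "ki": (0.35, 0.19),
    "li": (1.8, 0.065),  # hepatic arterial
    "sp": (0.20, 0.03),
    "gu": (1.2, 0.16),
    "pa": (0.12, 0.01),
    "st": (0.16, 0.01),
    "mu": (29.0, 0.17),
    "sk": (3.4, 0.05),
    "ad": (13.0, 0.05),
    "bo": (5.5, 0.05),
    "bm": (3.0, 0.03),
    "br": (1.45, 0.12),
    "th": (0.03, 0.01),
    "ln": (0.30, 0.015),
    "ey": (0.015, 0.005),
    "te": (0.05, 0.005),
    "an": (0.015, 0.005),
    "sc": (0.5, 0.01),
    "ot": (2.0, 0.04),
}
# sub-compartment volume fractions (vascular, endosomal, interstitial, cellular)
_SUBFRACTIONS = (0.04, 0.005, 0.17, 0.785)
_BLOOD = {"ar": 1.0, "ve": 2.2}  # plasma volumes, L (human)
_HUMAN_GFR = 7.2  # L/h


def _one_species(name: str, spec: FixtureSpec, rng: np.random.Generator | None) -> Physiology:
    bw = spec.body_weight[name]
    vol_scale = bw / SPECIES_BODY_WEIGHT["human"]
    flow_scale = (bw / SPECIES_BODY_WEIGHT["human"]) ** 0.75
    co = spec.cardiac_output_human * flow_scale

    def noisy(x: float) -> float:
        if rng is None or spec.cv <= 0:
            return x
        sigma = np.sqrt(np.log(1.0 + spec.cv**2))
        return float(x * rng.lognormal(-0.5 * sigma**2, sigma))

    rows = {}
    for organ, (v_tot, q_frac) in _HUMAN_ORGANS.items():
        v = noisy(v_tot * vol_scale)
        q = noisy(q_frac * co)
        rows[organ] = {
            "V_va": v * _SUBFRACTIONS[0],
            "V_en": v * _SUBFRACTIONS[1],
            "V_is": v * _SUBFRACTIONS[2],
            "V_ic": v * _SUBFRACTIONS[3],
            "Q": q,
            "L": spec.lymph_fraction * q,
            "rS": 4.5,
            "rL": 25.0,
            "alphaL": 0.042,
            "A0dx": 5000.0 * v,  # exchange area scales with organ size
            "FcRn0": 4e-5,
            "CLcat": 20.0 * v * _SUBFRACTIONS[1],
            "sl": 0.2,
            "alb_ratio_is": 0.5,
            "Rabund": 0.0,
        }
    # rebalance so that sum of systemic flows equals pulmonary flow minus its
    # own lymph (flow balance at the arterial node)
    q_lu = rows["lu"]["Q"]
    l_lu = rows["lu"]["L"]
    systemic = [o for o in rows if o != "lu"]
    total = sum(rows[o]["Q"] for o in systemic)
    scale = (q_lu - l_lu) / total
    for o in systemic:
        rows[o]["Q"] *= scale
        rows[o]["L"] = spec.lymph_fraction * rows[o]["Q"]
    for organ, vol in _BLOOD.items():
        rows[organ] = {c: 0.0 for c in rows["lu"]}
        rows[organ]["V_va"] = noisy(vol * vol_scale)
        rows[organ]["rS"], rows[organ]["rL"] = 4.5, 25.0
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "organ"
    return Physiology(
        name=name,
        organs=df,
        tbw=bw,
        tbv=bw / 1.05,
        gfr=_HUMAN_GFR * flow_scale,
    )


_VPOP_SCALARS = ("tbw", "tbv", "GFR")
_VPOP_ORGAN_COLS = ("V_va", "V_en", "V_is", "V_ic", "Q", "L", "FcRn0", "CLcat")


def _vpop_overrides(phys: Physiology) -> dict[str, float]:
    out = {"tbw": phys.tbw, "tbv": phys.tbv, "GFR": phys.gfr}
    for organ, row in phys.organs.iterrows():
        for col in _VPOP_ORGAN_COLS:
            if organ == "ot" and col.startswith("V_"):
                continue  # closure-organ volumes are assignment-defined
            if organ in ("ar", "ve") and col != "V_va":
                continue
            out[f"{col}_{organ}"] = float(row[col])
    return out


def synth_physiology(spec: FixtureSpec | None = None) -> dict:
    """Per-species physiology tables plus the cross-species VPop table.

    Returns ``{"physiology": {species: Physiology}, "vpop": VPopTable}``.  The
    VPop rows carry the organ volumes, flows, FcRn abundances, catabolic
    clearances and whole-body scalars of each animal species, keyed by the
    expanded component names of the whole-body model, so the same compiled
    model simulates every species.
    """
    spec = spec or FixtureSpec()
    spec.validate()
    physiology = {name: _one_species(name, spec, None) for name in spec.species}
    rows = [
        VPopRow(i + 1, name, _vpop_overrides(physiology[name]))
        for i, name in enumerate(spec.species)
    ]
    return {"physiology": physiology, "vpop": VPopTable(rows)}


def population_vpop(spec: FixtureSpec, base_species: str = "human", n: int = 100) -> VPopTable:
    """Log-normal inter-individual population sample around one species.

    Each row is an individual with noisy organ volumes and flows at the
    requested coefficient of variation; flows are rebalanced per individual so
    the whole-body flow invariants keep holding.
    """
    spec.validate()
    if spec.cv <= 0:
        raise ValueError("population sampling needs cv > 0")
    rng = np.random.default_rng(spec.seed)
    rows = []
    for i in range(n):
        phys = _one_species(base_species, spec, rng)
        rows.append(VPopRow(i + 1, f"{base_species} {i + 1}", _vpop_overrides(phys)))
    return VPopTable(rows)
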