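"""Maternal-foetal IgG extension of the whole-body platform.

The base mAb model is extended with a feto-placental unit:

* a ``Placental_Tissue`` instance (``pl``) with a maternal vascular space, a
  shared endothelial-endosomal space, and a foetal vascular space — the
  interstitial compartment is omitted, since FcRn-mediated transcytosis
  across the shared endothelium is the transfer-limiting step and placental
  interstitial physiology is poorly characterized.  The FcRn salvage cycle is
  reused with a bidirectional recycling split: a fraction ``f_mat`` of the
  recycled complex releases drug on the maternal side, the rest on the
  foetal side;
* four foetal instances: arterial (``arF``) and venous (``veF``) blood pools,
  a lumped foetal body (``fe``) and a lumped foetal lymph node (``lnF``),
  both stamped from the generic tissue template and wired into a foetal
  circulation loop through the placenta's foetal vascular channel.

Gestational-age dependence: ``GA`` (weeks) advances with simulation time via
a repeated assignment, and any parameter component can be driven by a cubic
polynomial ``B0 + B1*GA + B2*GA^2 + B3*GA^3`` re-evaluated at every solver
step.  Organs without gestational dependence simply fix B1-B3 to zero, which
reduces the parameter to a constant.  Maternal endogenous IgG synthesis is a
zero-order production into the venous plasma whose rate ``ksynIgG`` may also
be GA-dependent.

Adding the placenta re-routes part of the (increased) maternal cardiac
output: pulmonary flow is raised by the maternal placental flow so the
arterial-node flow balance still holds.  With zero placental flow and
transfer, the extension leaves maternal kinetics exactly as in the base
model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from ..model_graph import ModelGraph, SubgraphDefinition
from .whole_body import ModelBuildError, _FLOW_TOL

__all__ = [
    "PregnancyPhysiology",
    "extend_pregnancy",
    "default_pregnancy_physiology",
    "FETAL_ORGANS",
]

FETAL_ORGANS = ["pl", "arF", "veF", "fe", "lnF"]


@dataclass
class PregnancyPhysiology:
    """Feto-placental physiology and gestational-age schedules.

    ``organs`` carries rows ``pl, arF, veF, fe, lnF`` with the same columns as
    the maternal organ table (the ``pl`` row describes the maternal-facing
    side; ``Q`` there is the maternal placental plasma flow).  ``ga_params``
    maps a tag to ``(target component expression, (B0, B1, B2, B3))``; each
    entry becomes a repeated assignment driving that component with a cubic
    polynomial in GA.  ``igg_syn`` are the B-coefficients of the maternal IgG
    synthesis rate (mol/h).
    """

    organs: pd.DataFrame
    ga0_weeks: float = 15.0
    v_vaF_pl: float = 0.08
    qcoF: float = 15.0
    q_plF: float = 6.0
    f_mat: float = 0.5
    kon_fcrn_pl: float | None = None
    ga_params: dict[str, tuple[str, tuple[float, float, float, float]]] = field(
        default_factory=dict
    )
    igg_syn: tuple[float, float, float, float] = (0.0, 0.0, 0.0, 0.0)

    def validate(self) -> None:
        if not 0.0 <= self.ga0_weeks <= 42.0:
            raise ModelBuildError("gestational age must be within 0-42 weeks")
        missing = [o for o in FETAL_ORGANS if o not in self.organs.index]
        if missing:
            raise ModelBuildError(f"pregnancy physiology missing rows {missing}")
        if not 0.0 <= self.f_mat <= 1.0:
            raise ModelBuildError("f_mat must be within [0, 1]")
        fetal_in = self.organs.loc["fe", "Q"] + self.organs.loc["lnF", "Q"] + self.q_plF
        if self.qcoF > 0 and abs(fetal_in - self.qcoF) > _FLOW_TOL * max(self.qcoF, 1.0):
            raise ModelBuildError(
                f"foetal flow imbalance: organ flows {fetal_in:g} vs cardiac "
                f"output {self.qcoF:g} L/h"
            )


def default_pregnancy_physiology(ga0_weeks: float = 15.0) -> PregnancyPhysiology:
    """Synthetic feto-placental parameter set (roughly a 30-week foetus)."""
    rows = {
        # V_total split below; Q is maternal placental plasma flow for "pl"
        "pl": dict(V=0.5, Q=25.0),
        "arF": dict(V=0.0, Q=0.0),
        "veF": dict(V=0.0, Q=0.0),
        "fe": dict(V=1.5, Q=8.6),
        "lnF": dict(V=0.02, Q=0.4),
    }
    sub = (0.04, 0.005, 0.17, 0.785)
    recs = {}
    for organ, r in rows.items():
        v, q = r["V"], r["Q"]
        recs[organ] = {
            "V_va": v * sub[0], "V_en": v * sub[1], "V_is": v * sub[2],
            "V_ic": v * sub[3], "Q": q, "L": 0.002 * q, "rS": 4.5, "rL": 25.0,
            "alphaL": 0.042, "A0dx": 5000.0 * v, "FcRn0": 4e-5,
            "CLcat": 20.0 * v * sub[1], "sl": 0.2, "alb_ratio_is": 0.5,
            "Rabund": 0.0,
        }
    recs["arF"]["V_va"] = 0.03
    recs["veF"]["V_va"] = 0.06
    df = pd.DataFrame.from_dict(recs, orient="index")
    df.index.name = "organ"
    return PregnancyPhysiology(organs=df, ga0_weeks=ga0_weeks, qcoF=15.0, q_plF=6.0)


def _build_placental_tissue() -> SubgraphDefinition:
    b = ModelGraph("Placental_Tissue_body")
    b.add_placeholder("thisOrgan", "organ")
    b.add_compartment("VasM")
    b.add_compartment("End")
    b.add_compartment("VasF")
    b.add_assignment("V1", "VasM", "V_va[organ=thisOrgan]", kind="initial")
    b.add_assignment("V2", "End", "V_en[organ=thisOrgan]", kind="initial")
    b.add_assignment("V3", "VasF", "V_vaF_pl", kind="initial")
    b.add_species("mAb_vaM", "VasM")
    b.add_species("mAb_vaF", "VasF")
    b.add_species("mAb_en", "End")
    b.add_species("FcRn_en", "End")
    b.add_species("FcRn_mAb_en", "End")
    b.add_species("degmAb_en", "End")
    b.add_assignment(
        "FA0", "FcRn_en", "FcRn0[organ=thisOrgan]*V_en[organ=thisOrgan]", kind="initial"
    )
    b.add_list("Circulating_vaM", "circulating", ["mAb_vaM"], exposed=True)
    b.add_list("Circulating_vaF", "circulating", ["mAb_vaF"], exposed=True)
    b.add_reaction("RuM", "Kup_va*mAb_vaM",
                   substrates=[("mAb_vaM", 1)], products=[("mAb_en", 1)])
    b.add_reaction("RuF", "Kup_va*mAb_vaF",
                   substrates=[("mAb_vaF", 1)], products=[("mAb_en", 1)])
    b.add_reaction(
        "Rcat",
        "CLcat[organ=thisOrgan]/V_en[organ=thisOrgan]*mAb_en",
        substrates=[("mAb_en", 1)],
        products=[("degmAb_en", 1)],
    )
    b.add_reaction(
        "Rbind",
        "konFcRn_pl*mAb_en*FcRn_en/V_en[organ=thisOrgan] - koffFcRn*FcRn_mAb_en",
        substrates=[("mAb_en", 1), ("FcRn_en", 1)],
        products=[("FcRn_mAb_en", 1)],
    )
    b.add_reaction(
        "RrecM",
        "f_mat*krec*FcRn_mAb_en",
        substrates=[("FcRn_mAb_en", 1)],
        products=[("mAb_vaM", 1), ("FcRn_en", 1)],
    )
    b.add_reaction(
        "RrecF",
        "(1-f_mat)*krec*FcRn_mAb_en",
        substrates=[("FcRn_mAb_en", 1)],
        products=[("mAb_vaF", 1), ("FcRn_en", 1)],
    )
    return SubgraphDefinition("Placental_Tissue", b)


def extend_pregnancy(graph: ModelGraph, preg: PregnancyPhysiology) -> ModelGraph:
    """Return a copy of the whole-body model extended with the feto-placental unit."""
    preg.validate()
    g = graph.copy()
    organ_index = g.indices["organ"]
    for o in FETAL_ORGANS:
        if o in organ_index.values:
            raise ModelBuildError(f"organ value {o!r} already present")
        organ_index.values.append(o)

    # fill the new organ entries of every organ-indexed input array
    for q in g.quantities.values():
        if "organ" in q.indices and q.name in preg.organs.columns:
            for o in FETAL_ORGANS:
                q.default_values[f"{q.name}_{o}"] = float(preg.organs.loc[o, q.name])

    # maternal cardiac output rises by the placental flow, keeping the
    # arterial-node balance intact
    q_pl = float(preg.organs.loc["pl", "Q"])
    qv = g.quantities["Q"].default_values
    qv["Q_lu"] = qv["Q_lu"] + q_pl

    kon_pl = preg.kon_fcrn_pl
    if kon_pl is None:
        kon_pl = g.quantities["konFcRn"].default
    g.add_parameter("konFcRn_pl", default=kon_pl)
    g.add_parameter("f_mat", default=preg.f_mat)
    g.add_parameter("V_vaF_pl", default=preg.v_vaF_pl)
    g.add_parameter("QcoF", default=preg.qcoF)
    g.add_parameter("Q_plF", default=preg.q_plF)
    g.add_parameter("ksynIgG", default=preg.igg_syn[0])

    placenta = _build_placental_tissue()
    g.define_subgraph(placenta.name, placenta.body)
    g.instantiate_subgraph("pl", placenta.name, {"thisOrgan": "pl"})

    # foetal blood pools and circulation loop
    g.add_compartment("ArtF")
    g.add_compartment("VenF")
    g.add_assignment("VA_arF", "ArtF", "V_va[organ=$arF]", kind="initial")
    g.add_assignment("VA_veF", "VenF", "V_va[organ=$veF]", kind="initial")
    g.add_species("mAb_arF", "ArtF")
    g.add_species("mAb_veF", "VenF")
    g.add_list("CircF_ar", "circulating", ["mAb_arF"])
    g.add_list("CircF_ve", "circulating", ["mAb_veF"])

    for organ in ("fe", "lnF"):
        g.instantiate_subgraph(organ, "Generic_Tissue", {"thisOrgan": organ})

    # maternal side of the placenta
    g.add_reaction(
        "Q_pl",
        "Q[organ=$pl]*Circ_ar/V_va[organ=$ar]",
        substrates=[("Circ_ar", 1)],
        products=[("pl.Circulating_vaM", 1)],
    )
    g.add_reaction(
        "QL_pl",
        "Q[organ=$pl]*pl.Circulating_vaM/V_va[organ=$pl]",
        substrates=[("pl.Circulating_vaM", 1)],
        products=[("Circ_ve", 1)],
    )
    # foetal heart/lung lump and organ flows
    g.add_reaction(
        "QF_heart",
        "QcoF*CircF_ve/V_va[organ=$veF]",
        substrates=[("CircF_ve", 1)],
        products=[("CircF_ar", 1)],
    )
    for organ in ("fe", "lnF"):
        g.add_reaction(
            f"QF_{organ}",
            f"Q[organ=${organ}]*CircF_ar/V_va[organ=$arF]",
            substrates=[("CircF_ar", 1)],
            products=[(f"{organ}.Circulating_va", 1)],
        )
        g.add_reaction(
            f"QLF_{organ}",
            f"(Q[organ=${organ}]-L[organ=${organ}])*{organ}.Circulating_va"
            f"/V_va[organ=${organ}]",
            substrates=[(f"{organ}.Circulating_va", 1)],
            products=[("CircF_ve", 1)],
        )
    g.add_reaction(
        "L_fe",
        "L[organ=$fe]*(1-sl[organ=$fe])*fe.Circulating_is/V_is[organ=$fe]",
        substrates=[("fe.Circulating_is", 1)],
        products=[("lnF.Circulating_is", 1)],
    )
    g.add_reaction(
        "L_lnF",
        "L[organ=$lnF]*(1-sl[organ=$lnF])*lnF.Circulating_is/V_is[organ=$lnF]",
        substrates=[("lnF.Circulating_is", 1)],
        products=[("CircF_ve", 1)],
    )
    # foetal side of the placenta
    g.add_reaction(
        "QF_pl",
        "Q_plF*CircF_ar/V_va[organ=$arF]",
        substrates=[("CircF_ar", 1)],
        products=[("pl.Circulating_vaF", 1)],
    )
    g.add_reaction(
        "QLF_pl",
        "Q_plF*pl.Circulating_vaF/V_vaF_pl",
        substrates=[("pl.Circulating_vaF", 1)],
        products=[("CircF_ve", 1)],
    )

    # maternal endogenous IgG synthesis into venous plasma
    g.add_reaction("IgG_syn", "ksynIgG", products=[("mAb_ve", 1)])

    # gestational-age machinery: GA advances with time (168 h per week)
    g.add_parameter("GA0", default=preg.ga0_weeks)
    g.add_parameter("GA", default=preg.ga0_weeks)
    g.add_assignment("RA_GA", "GA", "GA0 + time/168", kind="repeated")
    ga_entries = dict(preg.ga_params)
    b0, b1, b2, b3 = preg.igg_syn
    ga_entries.setdefault("ksynIgG", ("ksynIgG", (b0, b1, b2, b3)))
    for tag, (target, coefs) in ga_entries.items():
        cb0, cb1, cb2, cb3 = coefs
        for k, val in enumerate((cb0, cb1, cb2, cb3)):
            g.add_parameter(f"B{k}_{tag}", default=float(val))
        g.add_assignment(
            f"RA_{tag}",
            target,
            f"B0_{tag} + B1_{tag}*GA + B2_{tag}*GA^2 + B3_{tag}*GA^3",
            kind="repeated",
        )

    g.add_observer("mAb_plasma_fetal", "mAb_veF/V_va[organ=$veF]")
    g.add_observer("mAb_plasma_placF", "pl.mAb_vaF/V_vaF_pl")
    return g
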