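"""Targeted-oligonucleotide adaptation of the whole-body platform.

Oligonucleotides differ from mAbs in three ways that the adaptation encodes:

1. **Plasma protein binding.**  A ``pb`` index with values ``free``/``bound``
   is attached to the molecular weight and to every size-derived transport
   parameter (two-pore reflection/permeability/Peclet arrays and the
   glomerular sieving coefficient), so all transport properties are computed
   separately for the free oligonucleotide and its albumin complex
   (MW_bound = MW_free + 66.5 kDa).  Repeated assignments inside the tissue
   template compute the free and bound concentrations in the vascular and
   interstitial spaces at every solver step from ``fu_p`` and the
   organ-specific interstitial unbound fraction ``fu_is`` (single-site
   albumin binding; less albumin interstitially, so fu_is >= fu_p); the
   two-pore extravasation rate becomes the sum of the free and bound
   contributions.  The albumin complex is effectively excluded from
   glomerular filtration through its near-zero sieving coefficient.
2. **No FcRn salvage.**  Oligonucleotides lack an Fc domain; the FcRn
   association rate constant is set to zero, disabling the recycling pathway
   while leaving the graph structure untouched.
3. **Intracellular uptake.**  Non-specific macropinocytosis moves free
   interstitial drug into the intracellular space first-order in all
   tissues; receptor-mediated endocytosis (the GalNAc-ASGPR route) is added
   as a target-binding/internalization cycle whose receptor abundance is an
   organ-indexed parameter — zero outside expressing tissues, which switches
   the pathway off there.  Unconjugated oligonucleotides are the same model
   with the receptor association constant set to zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from ..mechanisms import BindingParams
from ..model_graph import ModelGraph
from .whole_body import TWO_PORE_OUTPUTS

__all__ = ["OligoUptakeParams", "adapt_oligonucleotide"]


@dataclass
class OligoUptakeParams:
    """Cellular uptake parameters of the oligonucleotide model.

    ``kmp``: macropinocytosis rate constant (1/h) on free interstitial drug;
    ``kon_r``/``koff_r``: receptor binding (1/(M*h), 1/h); ``kint_r``:
    internalization of the receptor complex (1/h); ``kdeg_r``: receptor
    turnover (1/h); ``receptor_abundance``: organ label -> receptor amount
    (mol), zero in non-expressing tissues.
    """

    kmp: float = 1e-3
    kon_r: float = 1e8
    koff_r: float = 10.0
    kint_r: float = 5.0
    kdeg_r: float = 0.1
    receptor_abundance: dict[str, float] = field(default_factory=dict)


_TWO_PORE_PB_RATE = (
    "(JS[organ=thisOrgan]*(1-sS[organ=thisOrgan,pb=$free])"
    " + JL[organ=thisOrgan]*(1-sL[organ=thisOrgan,pb=$free]))*free_va"
    " + (PSS[organ=thisOrgan,pb=$free]*pef(PeS[organ=thisOrgan,pb=$free])"
    " + PSL[organ=thisOrgan,pb=$free]*pef(PeL[organ=thisOrgan,pb=$free]))"
    "*(free_va - free_is)"
    " + (JS[organ=thisOrgan]*(1-sS[organ=thisOrgan,pb=$bound])"
    " + JL[organ=thisOrgan]*(1-sL[organ=thisOrgan,pb=$bound]))*bound_va"
    " + (PSS[organ=thisOrgan,pb=$bound]*pef(PeS[organ=thisOrgan,pb=$bound])"
    " + PSL[organ=thisOrgan,pb=$bound]*pef(PeL[organ=thisOrgan,pb=$bound]))"
    "*(bound_va - bound_is)"
)

_GFR_PB_RATE = (
    "(CLfilt[pb=$free]*fu_p + CLfilt[pb=$bound]*(1-fu_p))"
    "*ki.Soluble_va/V_va[organ=$ki]"
)


def adapt_oligonucleotide(
    graph: ModelGraph,
    binding: BindingParams | None = None,
    uptake: OligoUptakeParams | None = None,
) -> ModelGraph:
    """Return a copy of the whole-body model adapted for an oligonucleotide.

    The adaptation mutates the shared tissue template, so every organ
    instance picks up the changes on recompilation.
    """
    binding = binding or BindingParams()
    uptake = uptake or OligoUptakeParams()
    if not 0.0 < binding.fu_p <= 1.0:
        raise ValueError("fu_p must be in (0, 1]")
    g = graph.copy()

    # ---- pb index on MW and every size-derived transport parameter ----------
    g.add_index("pb", ["free", "bound"])
    mw = g.quantities["MWkDa"]
    mw.indices.append("pb")
    mw.default = binding.MW_free
    mw.default_values = {
        "MWkDa_mAb_free": binding.MW_free,
        "MWkDa_mAb_bound": binding.MW_bound,
    }
    pb_quantities = {name for name, _ in TWO_PORE_OUTPUTS}
    for name in pb_quantities:
        g.quantities[name].indices.append("pb")
    for a in g.assignments.values():
        target = a.target.split("[")[0]
        if target in pb_quantities:
            a.indices.append("pb")

    # ---- plasma and interstitial protein binding ----------------------------
    g.add_parameter("fu_p", default=binding.fu_p)
    ratios = binding.alb_ratio_is
    if not isinstance(ratios, dict):
        ratios = {o: float(ratios) for o in g.indices["organ"].values}
    g.quantities["alb_ratio_is"].default_values.update(
        {f"alb_ratio_is_{o}": v for o, v in ratios.items()}
    )
    g.add_parameter("fu_is", indices=["organ"])
    g.add_assignment(
        "A_fu_is", "fu_is", "1/(1 + alb_ratio_is*(1-fu_p)/fu_p)",
        kind="initial", indices=["organ"],
    )

    # ---- no FcRn salvage for oligonucleotides -------------------------------
    g.quantities["konFcRn"].default = 0.0

    # ---- uptake parameters --------------------------------------------------
    g.add_parameter("kmp", default=uptake.kmp)
    g.add_parameter("konR", default=uptake.kon_r)
    g.add_parameter("koffR", default=uptake.koff_r)
    g.add_parameter("kintR", default=uptake.kint_r)
    g.add_parameter("kdegR", default=uptake.kdeg_r)
    rab = g.quantities["Rabund"]
    rab.default = 0.0
    rab.default_values.update(
        {f"Rabund_{o}": float(v) for o, v in uptake.receptor_abundance.items()}
    )

    # ---- tissue-template edits (propagate to every organ instance) ----------
    body = g.definitions["Generic_Tissue"].body
    for name in ("free_va", "bound_va", "free_is", "bound_is"):
        body.add_parameter(name)
    body.add_assignment(
        "RA_free_va", "free_va", "fu_p*mAb_va/V_va[organ=thisOrgan]", kind="repeated"
    )
    body.add_assignment(
        "RA_bound_va", "bound_va", "(1-fu_p)*mAb_va/V_va[organ=thisOrgan]", kind="repeated"
    )
    body.add_assignment(
        "RA_free_is", "free_is",
        "fu_is[organ=thisOrgan]*mAb_is/V_is[organ=thisOrgan]", kind="repeated",
    )
    body.add_assignment(
        "RA_bound_is", "bound_is",
        "(1-fu_is[organ=thisOrgan])*mAb_is/V_is[organ=thisOrgan]", kind="repeated",
    )
    body.reactions["twoPore"].rate = _TWO_PORE_PB_RATE

    body.add_species("mAb_ic", "Cel")
    body.add_species("Rc", "Int")
    body.add_species("RcD", "Int")
    body.add_assignment("R0", "Rc", "Rabund[organ=thisOrgan]", kind="initial")
    body.add_reaction(
        "Rmp",
        "kmp*fu_is[organ=thisOrgan]*mAb_is",
        substrates=[("mAb_is", 1)],
        products=[("mAb_ic", 1)],
    )
    body.add_reaction("Rsyn", "kdegR*Rabund[organ=thisOrgan]", products=[("Rc", 1)])
    body.add_reaction("Rdeg", "kdegR*Rc", substrates=[("Rc", 1)])
    body.add_reaction(
        "RbindR",
        "konR*fu_is[organ=thisOrgan]*mAb_is*Rc/V_is[organ=thisOrgan] - koffR*RcD",
        substrates=[("mAb_is", 1), ("Rc", 1)],
        products=[("RcD", 1)],
    )
    body.add_reaction(
        "RintR", "kintR*RcD", substrates=[("RcD", 1)], products=[("mAb_ic", 1), ("Rc", 1)]
    )

    # ---- renal filtration of free vs albumin-bound drug ---------------------
    g.reactions["GFR_filtration"].rate = _GFR_PB_RATE

    # the administered dose is the free compound
    if "A_Dose" in g.assignments:
        g.assignments["A_Dose"].expression = (
            "Dose_mpk*tbw/(MWkDa[soluble=$mAb,pb=$free]*1e6)"
        )

    # ---- observers for the binding split ------------------------------------
    g.add_observer("C_free_plasma", "fu_p*mAb_ve/V_va[organ=$ve]")
    g.add_observer("C_bound_plasma", "(1-fu_p)*mAb_ve/V_va[organ=$ve]")
    g.add_observer("bound_va_li", "li.bound_va")
    g.add_observer("bound_is_li", "li.bound_is")
    g.add_observer("oligo_ic_li", "li.mAb_ic")
    return g
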