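"""The organ-level template of the whole-body biologics platform.

``build_generic_tissue`` returns the reusable subgraph definition that every
organ instance is stamped from.  The template contains:

* four sub-compartments (vascular, endothelial-endosomal, interstitial,
  intracellular) whose volumes are pulled from the organ-indexed global
  volume arrays via the exposed index-value node ``thisOrgan``;
* the drug species in the vascular, interstitial and endosomal spaces, the
  free FcRn pool, the drug-FcRn complex, and a degraded-drug bookkeeping
  species;
* the endosomal salvage reactions R1-R6 (fluid-phase uptake from both sides,
  catabolic degradation, reversible FcRn binding, recycling to the vascular
  and interstitial sides) and the two-pore extravasation reaction acting on
  the ``Soluble`` species lists;
* the dose chain DA1-DA3 routing the organ's element of the global
  ``Dose_mole`` array to the vascular (D1) and interstitial (D2) dosing
  plans.

The ``Circulating`` lists are exposed so that blood- and lymph-flow reactions
at the whole-body level connect to them as channels; the ``Soluble`` lists are
exposed for organ-specific extensions such as the kidney's filtration
reaction.  All rate expressions are in amount space (moles); concentrations
appear explicitly as ``amount / V_x[organ=thisOrgan]``.
"""

from __future__ import annotations

from ..model_graph import ModelGraph, SubgraphDefinition

__all__ = ["build_generic_tissue", "GENERIC_TISSUE_SPECIES", "GENERIC_TISSUE_COMPARTMENTS"]

GENERIC_TISSUE_COMPARTMENTS = ("Vas", "End", "Int", "Cel")
GENERIC_TISSUE_SPECIES = (
    "mAb_va",
    "mAb_is",
    "mAb_en",
    "FcRn_en",
    "FcRn_mAb_en",
    "degmAb_en",
)

# two-pore extravasation rate, amount space; the `soluble` index of the
# organ x solute parameter arrays is bound by the Soluble-list iteration
_TWO_PORE_RATE = (
    "(JS[organ=thisOrgan]*(1-sS[organ=thisOrgan])"
    " + JL[organ=thisOrgan]*(1-sL[organ=thisOrgan]))"
    "*Soluble_va/V_va[organ=thisOrgan]"
    " + (PSS[organ=thisOrgan]*pef(PeS[organ=thisOrgan])"
    " + PSL[organ=thisOrgan]*pef(PeL[organ=thisOrgan]))"
    "*(Soluble_va/V_va[organ=thisOrgan] - Soluble_is/V_is[organ=thisOrgan])"
)


def build_generic_tissue(with_dosing: bool = True) -> SubgraphDefinition:
    """Build the organ-level template as a reusable subgraph definition."""
    b = ModelGraph("Generic_Tissue_body")
    b.add_placeholder("thisOrgan", "organ")

    for comp, vol_array in zip(GENERIC_TISSUE_COMPARTMENTS, ("V_va", "V_en", "V_is", "V_ic")):
        b.add_compartment(comp)
    for n, (comp, vol_array) in enumerate(
        zip(GENERIC_TISSUE_COMPARTMENTS, ("V_va", "V_en", "V_is", "V_ic")), start=1
    ):
        b.add_assignment(f"V{n}", comp, f"{vol_array}[organ=thisOrgan]", kind="initial")

    b.add_species("mAb_va", "Vas")
    b.add_species("mAb_is", "Int")
    b.add_species("mAb_en", "End")
    b.add_species("FcRn_en", "End")
    b.add_species("FcRn_mAb_en", "End")
    b.add_species("degmAb_en", "End")
    b.add_assignment(
        "FA0", "FcRn_en", "FcRn0[organ=thisOrgan]*V_en[organ=thisOrgan]", kind="initial"
    )

    # species lists: soluble species inherit the two-pore reaction; nesting the
    # Soluble lists inside the exposed Circulating lists makes their members
    # inherit the blood/lymph flow reactions wired at the whole-body level
    b.add_list("Soluble_va", "soluble", ["mAb_va"], exposed=True)
    b.add_list("Soluble_is", "soluble", ["mAb_is"], exposed=True)
    b.add_list("Circulating_va", "circulating", ["Soluble_va"], exposed=True)
    b.add_list("Circulating_is", "circulating", ["Soluble_is"], exposed=True)

    # endosomal salvage cycle
    b.add_reaction(
        "R1", "Kup_va*mAb_va", substrates=[("mAb_va", 1)], products=[("mAb_en", 1)]
    )
    b.add_reaction(
        "R2", "Kup_is*mAb_is", substrates=[("mAb_is", 1)], products=[("mAb_en", 1)]
    )
    b.add_reaction(
        "R3",
        "CLcat[organ=thisOrgan]/V_en[organ=thisOrgan]*mAb_en",
        substrates=[("mAb_en", 1)],
        products=[("degmAb_en", 1)],
    )
    b.add_reaction(
        "R4",
        "konFcRn*mAb_en*FcRn_en/V_en[organ=thisOrgan] - koffFcRn*FcRn_mAb_en",
        substrates=[("mAb_en", 1), ("FcRn_en", 1)],
        products=[("FcRn_mAb_en", 1)],
    )
    b.add_reaction(
        "R5",
        "f_rec_va*krec*FcRn_mAb_en",
        substrates=[("FcRn_mAb_en", 1)],
        products=[("mAb_va", 1), ("FcRn_en", 1)],
    )
    b.add_reaction(
        "R6",
        "(1-f_rec_va)*krec*FcRn_mAb_en",
        substrates=[("FcRn_mAb_en", 1)],
        products=[("mAb_is", 1), ("FcRn_en", 1)],
    )
    b.add_reaction(
        "twoPore",
        _TWO_PORE_RATE,
        substrates=[("Soluble_va", 1)],
        products=[("Soluble_is", 1)],
    )

    if with_dosing:
        b.add_parameter("Dose_organ", indices=["doseTarget"])
        b.add_parameter("Dose_mAb_va")
        b.add_parameter("Dose_mAb_is")
        b.add_assignment(
            "DA1", "Dose_organ", "Dose_mole[organ=thisOrgan]",
            kind="initial", indices=["doseTarget"],
        )
        b.add_assignment("DA2", "Dose_mAb_va", "Dose_organ[doseTarget=$mAb_va]", kind="initial")
        b.add_assignment("DA3", "Dose_mAb_is", "Dose_organ[doseTarget=$mAb_is]", kind="initial")
        b.add_dosing_plan("D1", "mAb_va", [(0.0, "Dose_mAb_va")])
        b.add_dosing_plan("D2", "mAb_is", [(0.0, "Dose_mAb_is")])

    return SubgraphDefinition("Generic_Tissue", b)
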