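"""Whole-body assembly of the biologics PBPK platform (mAb base model).

The whole-body graph instantiates the :mod:`generic tissue
<biopbpk.platform.generic_tissue>` template once per organ and wires the
instances together with blood-flow (``Q_*``), venous-return (``QL_*``) and
lymph-flow (``L_*``) reactions through the exposed ``Circulating`` channels.
The organ index carries 21 organ values plus the arterial and venous blood
pools (23 values in total), so every organ-specific parameter is a
23-component array addressed with ``[organ=...]`` specifiers.

The parameters module computes the organ x solute two-pore transport
parameters (reflection coefficients, permeability-surface-area products,
Peclet numbers, pore-specific lymph flows) from the solute molecular weight
``MWkDa`` by initial assignments, and converts the ``Dose_mpk`` (mg/kg) array
into the ``Dose_mole`` array routed to the per-organ dose chains.  The kidney
is customized with a ``GFR`` filtration reaction into the lumped BCPTLH
compartment (Bowman's capsule / proximal tubules / loop of Henle) and a
``urine_flow`` reaction into a urine compartment.

Blood-flow topology: venous pool -> lung -> arterial pool -> systemic organs
-> venous pool, with interstitial lymph draining to the venous pool.  The
builder asserts Kirchhoff-style balance at the arterial node
(sum of systemic flows = pulmonary flow minus pulmonary lymph).
"""

from __future__ import annotations

from dataclasses import dataclass

from ..fixtures import ORGANS, ORGAN_INDEX_VALUES, Physiology
from ..model_graph import ModelGraph
from .generic_tissue import build_generic_tissue

__all__ = ["DrugParams", "build_whole_body", "ModelBuildError"]


class ModelBuildError(ValueError):
    """Raised when physiology inputs violate whole-body invariants."""


@dataclass
class DrugParams:
    """Drug-specific inputs of the platform model (defaults: a typical IgG mAb).

    Units: kDa, 1/h, 1/(M*h), L/h; ``f_rec_va`` is the vascular share of FcRn
    recycling; ``fup``/``freab`` parameterize net renal filtration.
    """

    mw_kda: float = 150.0
    kup_va: float = 0.02
    kup_is: float = 0.02
    kon_fcrn: float = 1e7
    koff_fcrn: float = 7.0
    krec: float = 5.0
    f_rec_va: float = 0.5
    fup: float = 1.0
    freab: float = 0.0
    glomerular_radius_nm: float = 4.5
    frac_area_small: float = 0.9
    k_urine: float = 2.0


# the derived two-pore quantities; oligonucleotide adaptation re-indexes these
TWO_PORE_OUTPUTS = [
    ("a_sol", ["soluble"]),
    ("D_sol", ["soluble"]),
    ("lamS", ["organ", "soluble"]),
    ("lamL", ["organ", "soluble"]),
    ("PhiS", ["organ", "soluble"]),
    ("PhiL", ["organ", "soluble"]),
    ("sS", ["organ", "soluble"]),
    ("sL", ["organ", "soluble"]),
    ("HS", ["organ", "soluble"]),
    ("HL", ["organ", "soluble"]),
    ("PSS", ["organ", "soluble"]),
    ("PSL", ["organ", "soluble"]),
    ("PeS", ["organ", "soluble"]),
    ("PeL", ["organ", "soluble"]),
    ("lamG", ["soluble"]),
    ("PhiG", ["soluble"]),
    ("theta", ["soluble"]),
    ("CLfilt", ["soluble"]),
]

_TWO_PORE_EXPRS = {
    # Stokes radius (nm) and free diffusivity (cm^2/h) from MW (kDa)
    "a_sol": "0.0483*(MWkDa*1000)^0.386",
    "D_sol": "0.0119/a_sol",
    # solute/pore radius ratios, capped at full exclusion
    "lamS": "min(a_sol/rS, 1)",
    "lamL": "min(a_sol/rL, 1)",
    # steric partition, reflection and Renkin diffusive hindrance per pore
    "PhiS": "(1-lamS)^2",
    "PhiL": "(1-lamL)^2",
    "sS": "1 - PhiS*(2-PhiS)*(1-lamS^2/3)",
    "sL": "1 - PhiL*(2-PhiL)*(1-lamL^2/3)",
    "HS": "PhiS*(1 - 2.104*lamS + 2.09*lamS^3 - 0.95*lamS^5)",
    "HL": "PhiL*(1 - 2.104*lamL + 2.09*lamL^3 - 0.95*lamL^5)",
    # permeability-surface-area products, cm^3/h -> L/h
    "PSS": "A0dx*fAs*D_sol*HS/1000",
    "PSL": "A0dx*(1-fAs)*D_sol*HL/1000",
    # per-pore Peclet numbers, guarded against full steric exclusion
    "PeS": "min(JS*(1-sS)/max(PSS, 1e-30), 50)",
    "PeL": "min(JL*(1-sL)/max(PSL, 1e-30), 50)",
    # glomerular sieving from the same size-transport relations
    "lamG": "min(a_sol/rG, 1)",
    "PhiG": "(1-lamG)^2",
    "theta": "PhiG*(2-PhiG)*(1-lamG^2/3)",
    "CLfilt": "GFR*theta*fup*(1-freab)",
}

_ORGAN_ARRAYS = ("V_va", "V_en", "V_is", "V_ic", "Q", "L", "rS", "rL", "alphaL",
                 "A0dx", "FcRn0", "CLcat", "sl", "alb_ratio_is", "Rabund")
_SUBVOL_ARRAYS = ("V_va", "V_en", "V_is", "V_ic")
_SUBVOL_FRACTIONS = (0.04, 0.005, 0.17, 0.785)
_FLOW_TOL = 1e-6


def _check_physiology(phys: Physiology) -> None:
    df = phys.organs
    missing = [o for o in ORGAN_INDEX_VALUES if o not in df.index]
    if missing:
        raise ModelBuildError(f"physiology is missing organ rows {missing}")
    for organ in ORGANS:
        row = df.loc[organ]
        if not row["L"] < row["Q"]:
            raise ModelBuildError(f"organ {organ!r}: lymph flow must be below blood flow")
        if min(row[list(_SUBVOL_ARRAYS)]) < 0:
            raise ModelBuildError(f"organ {organ!r}: negative sub-compartment volume")
    q_lu, l_lu = df.loc["lu", "Q"], df.loc["lu", "L"]
    systemic = sum(df.loc[o, "Q"] for o in ORGANS if o != "lu")
    if abs(systemic - (q_lu - l_lu)) > _FLOW_TOL * max(q_lu, 1.0):
        raise ModelBuildError(
            "flow imbalance at the arterial node: systemic flows "
            f"{systemic:g} L/h vs pulmonary return {q_lu - l_lu:g} L/h"
        )


def build_whole_body(
    physiology: Physiology,
    drug: DrugParams | None = None,
    with_dosing: bool = True,
    other_closure: bool = True,
) -> ModelGraph:
    """Assemble the whole-body mAb platform model for one animal's physiology.

    ``other_closure`` derives the rest-of-body ("ot") organ volumes by initial
    assignment as total body volume minus the explicitly modelled organs, so
    organ volumes always add up; being assignment-defined, those components
    cannot be overridden through VPop files.
    """
    drug = drug or DrugParams()
    _check_physiology(physiology)
    df = physiology.organs

    g = ModelGraph("mab_whole_body")
    g.add_index("organ", ORGAN_INDEX_VALUES)
    g.add_index("soluble", ["mAb"])
    g.add_index("circulating", ["mAb"])
    g.add_index("doseTarget", ["mAb_va", "mAb_is"])

    # ---- organ-indexed physiological arrays ---------------------------------
    for col in _ORGAN_ARRAYS:
        values = {f"{col}_{o}": float(df.loc[o, col]) for o in ORGAN_INDEX_VALUES}
        g.add_parameter(col, indices=["organ"], default_values=values)

    # ---- whole-body scalars and drug parameters -----------------------------
    g.add_parameter("tbw", default=physiology.tbw)
    g.add_parameter("tbv", default=physiology.tbv)
    g.add_parameter("GFR", default=physiology.gfr)
    g.add_parameter("MWkDa", indices=["soluble"], default=drug.mw_kda)
    g.add_parameter("Kup_va", default=drug.kup_va)
    g.add_parameter("Kup_is", default=drug.kup_is)
    g.add_parameter("konFcRn", default=drug.kon_fcrn)
    g.add_parameter("koffFcRn", default=drug.koff_fcrn)
    g.add_parameter("krec", default=drug.krec)
    g.add_parameter("f_rec_va", default=drug.f_rec_va)
    g.add_parameter("fup", default=drug.fup)
    g.add_parameter("freab", default=drug.freab)
    g.add_parameter("rG", default=drug.glomerular_radius_nm)
    g.add_parameter("fAs", default=drug.frac_area_small)
    g.add_parameter("k_urine", default=drug.k_urine)

    # ---- two-pore parameters module -----------------------------------------
    g.add_parameter("JS", indices=["organ"])
    g.add_parameter("JL", indices=["organ"])
    g.add_assignment("A_JS", "JS", "(1-alphaL)*L", kind="initial", indices=["organ"])
    g.add_assignment("A_JL", "JL", "alphaL*L", kind="initial", indices=["organ"])
    for name, indices in TWO_PORE_OUTPUTS:
        g.add_parameter(name, indices=indices)
        g.add_assignment(f"A_{name}", name, _TWO_PORE_EXPRS[name], kind="initial",
                         indices=indices)

    # ---- dose module --------------------------------------------------------
    if with_dosing:
        g.add_parameter("Dose_mpk", indices=["organ", "doseTarget"], default=0.0)
        g.add_parameter("Dose_mole", indices=["organ", "doseTarget"])
        g.add_assignment(
            "A_Dose",
            "Dose_mole",
            "Dose_mpk*tbw/(MWkDa[soluble=$mAb]*1e6)",
            kind="initial",
            indices=["organ", "doseTarget"],
        )

    # ---- blood pools, kidney filtrate and urine -----------------------------
    g.add_compartment("Art")
    g.add_compartment("Ven")
    g.add_compartment("BCPTLH", volume=0.2 * physiology.tbw / 70.0)
    g.add_compartment("Urine", volume=1.0)
    g.add_assignment("VA_ar", "Art", "V_va[organ=$ar]", kind="initial")
    g.add_assignment("VA_ve", "Ven", "V_va[organ=$ve]", kind="initial")
    g.add_species("mAb_ar", "Art")
    g.add_species("mAb_ve", "Ven")
    g.add_species("mAb_bcptlh", "BCPTLH")
    g.add_species("mAb_urine", "Urine")
    g.add_list("Circ_ar", "circulating", ["mAb_ar"])
    g.add_list("Circ_ve", "circulating", ["mAb_ve"])

    # ---- rest-of-body closure -----------------------------------------------
    if other_closure and "ot" in ORGANS:
        others = [o for o in ORGANS if o != "ot"]
        vol_terms = [
            f"V_va[organ=${o}]+V_en[organ=${o}]+V_is[organ=${o}]+V_ic[organ=${o}]"
            for o in others
        ]
        total = "+".join(vol_terms) + "+V_va[organ=$ar]+V_va[organ=$ve]"
        for col, frac in zip(_SUBVOL_ARRAYS, _SUBVOL_FRACTIONS):
            g.add_assignment(
                f"A_{col}_ot", f"{col}[organ=$ot]", f"{frac}*(tbv-({total}))",
                kind="initial",
            )

    # ---- organ instances ----------------------------------------------------
    tissue = build_generic_tissue(with_dosing=with_dosing)
    g.define_subgraph(tissue.name, tissue.body)
    for organ in ORGANS:
        g.instantiate_subgraph(organ, tissue.name, {"thisOrgan": organ})

    # ---- circulation --------------------------------------------------------
    g.add_reaction(
        "Q_lu",
        "Q[organ=$lu]*Circ_ve/V_va[organ=$ve]",
        substrates=[("Circ_ve", 1)],
        products=[("lu.Circulating_va", 1)],
    )
    g.add_reaction(
        "QL_lu",
        "(Q[organ=$lu]-L[organ=$lu])*lu.Circulating_va/V_va[organ=$lu]",
        substrates=[("lu.Circulating_va", 1)],
        products=[("Circ_ar", 1)],
    )
    for organ in ORGANS:
        if organ != "lu":
            g.add_reaction(
                f"Q_{organ}",
                f"Q[organ=${organ}]*Circ_ar/V_va[organ=$ar]",
                substrates=[("Circ_ar", 1)],
                products=[(f"{organ}.Circulating_va", 1)],
            )
            g.add_reaction(
                f"QL_{organ}",
                f"(Q[organ=${organ}]-L[organ=${organ}])*{organ}.Circulating_va"
                f"/V_va[organ=${organ}]",
                substrates=[(f"{organ}.Circulating_va", 1)],
                products=[("Circ_ve", 1)],
            )
        g.add_reaction(
            f"L_{organ}",
            f"L[organ=${organ}]*(1-sl[organ=${organ}])*{organ}.Circulating_is"
            f"/V_is[organ=${organ}]",
            substrates=[(f"{organ}.Circulating_is", 1)],
            products=[("Circ_ve", 1)],
        )

    # ---- kidney customization: glomerular filtration ------------------------
    g.add_reaction(
        "GFR_filtration",
        "CLfilt*ki.Soluble_va/V_va[organ=$ki]",
        substrates=[("ki.Soluble_va", 1)],
        products=[("mAb_bcptlh", 1)],
    )
    g.add_reaction(
        "urine_flow",
        "k_urine*mAb_bcptlh",
        substrates=[("mAb_bcptlh", 1)],
        products=[("mAb_urine", 1)],
    )

    # ---- intravenous dosing into the venous pool ----------------------------
    if with_dosing:
        g.add_dosing_plan(
            "D_iv", "mAb_ve", [(0.0, "Dose_mole[organ=$ve,doseTarget=$mAb_va]")]
        )

    # ---- observers ----------------------------------------------------------
    g.add_observer("mAb_plasma", "mAb_ve/V_va[organ=$ve]")
    for organ in ORGANS:
        g.add_observer(
            f"mAb_organTotal_{organ}",
            f"({organ}.mAb_va+{organ}.mAb_en+{organ}.mAb_is)"
            f"/(V_va[organ=${organ}]+V_en[organ=${organ}]"
            f"+V_is[organ=${organ}]+V_ic[organ=${organ}])",
        )
    return g
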