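"""Biologics disposition rate laws as pure, unit-consistent functions.

Conventions: time in hours, volumes in litres, amounts in moles,
concentrations in mol/L, molecular weight in kDa, pore radii in nm.

The module covers the mechanistic determinants of large-molecule PK:

* two-pore transcapillary transport — solute flux through small and large
  endothelial pores as the sum of a convective term ``L*(1 - sigma)`` and a
  hindered diffusive term ``PS * Pe/(e^Pe - 1) * (1 - C_is/C_v)``;
* size-based two-pore parameter prediction from molecular weight via a
  pluggable Stokes-radius / hindered-transport strategy;
* FcRn-mediated endosomal salvage — fluid-phase uptake, catabolic clearance,
  dynamic FcRn binding and recycling to the vascular/interstitial sides;
* renal filtration clearance ``GFR * theta * fup * (1 - freab)`` with a
  molecular-weight-dependent glomerular sieving coefficient;
* full TMDD (target synthesis/degradation, reversible binding, complex
  internalization), which doubles as the receptor-mediated endocytosis model;
* albumin-binding equilibria for the interstitial unbound fraction;
* mg/kg-to-moles dose conversion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

from .expr import pef as peclet_factor

__all__ = [
    "SizeTransportModel",
    "TwoPoreParams",
    "FcRnParams",
    "RenalParams",
    "TMDDParams",
    "BindingParams",
    "compute_two_pore_params",
    "two_pore_clearance",
    "two_pore_rate",
    "fcrn_rhs",
    "renal_filtration_cl",
    "gsc_from_mw",
    "tmdd_rhs",
    "fraction_unbound_interstitial",
    "dose_to_moles",
    "peclet_factor",
    "tmdd_subgraph",
]


# ----------------------------------------------------------- size/pore strategy

@dataclass(frozen=True)
class SizeTransportModel:
    """Pluggable MW -> (radius, hindrance) strategy for pore transport.

    Defaults use an empirical power law for the Stokes-Einstein radius of
    globular proteins, ``a_nm = 0.0483 * MW_Da^0.386``, the steric partition
    coefficient ``Phi = (1 - lam)^2`` for a solute/pore radius ratio ``lam``,
    the Renkin diffusive hindrance polynomial, and the convective sieving
    factor ``W = Phi*(2 - Phi)*(1 - lam^2/3)`` with ``sigma = 1 - W``.  Free
    diffusivity follows Stokes-Einstein at 37 C in water.  Any component can
    be replaced to match a specific literature parameterization.
    """

    radius_coeff: float = 0.0483
    radius_exponent: float = 0.386
    diffusivity_coeff: float = 0.0119  # cm^2 * nm / h (Stokes-Einstein, 37 C)

    def stokes_radius_nm(self, mw_kda: float) -> float:
        if mw_kda <= 0:
            raise ValueError("molecular weight must be positive")
        return self.radius_coeff * (mw_kda * 1000.0) ** self.radius_exponent

    def free_diffusivity(self, mw_kda: float) -> float:
        """Aqueous diffusion coefficient, cm^2/h."""
        return self.diffusivity_coeff / self.stokes_radius_nm(mw_kda)

    @staticmethod
    def partition(lam: float) -> float:
        lam = min(lam, 1.0)
        return (1.0 - lam) ** 2

    def reflection(self, lam: float) -> float:
        """Vascular reflection coefficient sigma in [0, 1]."""
        phi = self.partition(lam)
        w = phi * (2.0 - phi) * (1.0 - min(lam, 1.0) ** 2 / 3.0)
        return min(max(1.0 - w, 0.0), 1.0)

    def diffusive_hindrance(self, lam: float) -> float:
        """Renkin hindrance for diffusion through a cylindrical pore."""
        lam = min(lam, 1.0)
        phi = self.partition(lam)
        poly = 1.0 - 2.104 * lam + 2.09 * lam**3 - 0.95 * lam**5
        return max(phi * poly, 0.0)


DEFAULT_TRANSPORT = SizeTransportModel()


# -------------------------------------------------------------- param records

@dataclass
class TwoPoreParams:
    """Per organ x solute two-pore transport parameters.

    ``L_S``/``L_L`` (== ``J_S``/``J_L``) are the lymph-flow components routed
    through small and large pores (L/h); ``sigma`` the vascular reflection
    coefficients; ``PS`` the permeability-surface-area products (L/h); ``Pe``
    the Peclet numbers; ``sl`` the lymphatic reflection coefficient; ``rS``
    and ``rL`` the pore radii (nm).
    """

    L_S: float
    L_L: float
    sigma_S: float
    sigma_L: float
    PS_S: float
    PS_L: float
    Pe_S: float
    Pe_L: float
    sl: float = 0.2
    rS: float = 4.5
    rL: float = 25.0

    @property
    def J_S(self) -> float:
        return self.L_S

    @property
    def J_L(self) -> float:
        return self.L_L

    def validate(self) -> None:
        if not (0.0 <= self.sigma_S <= 1.0 and 0.0 <= self.sigma_L <= 1.0):
            raise ValueError("reflection coefficients must be within [0, 1]")
        if self.PS_S < 0 or self.PS_L < 0 or self.Pe_S < 0 or self.Pe_L < 0:
            raise ValueError("PS and Pe must be non-negative")


@dataclass
class FcRnParams:
    """Endosomal FcRn salvage parameters.

    ``Kup_va``/``Kup_is``: fluid-phase endocytosis rate constants (1/h) acting
    on the source-compartment amount; ``CLcat``: catabolic clearance (L/h);
    ``kon``/``koff``: FcRn binding (1/(M*h), 1/h); ``krec``: recycling rate of
    the drug-FcRn complex (1/h); ``f_rec_va``: fraction of recycled complex
    released on the vascular side.
    """

    Kup_va: float = 0.03
    Kup_is: float = 0.03
    CLcat: float = 1e-3
    kon: float = 1e7
    koff: float = 7.0
    krec: float = 5.0
    f_rec_va: float = 0.5

    def validate(self) -> None:
        vals = (self.Kup_va, self.Kup_is, self.CLcat, self.kon, self.koff, self.krec)
        if any(v < 0 for v in vals):
            raise ValueError("FcRn parameters must be non-negative")
        if not 0.0 <= self.f_rec_va <= 1.0:
            raise ValueError("f_rec_va must be within [0, 1]")


@dataclass
class RenalParams:
    """Net glomerular filtration clearance parameters."""

    GFR: float = 7.2  # L/h
    theta: float = 1.0  # glomerular sieving coefficient
    fup: float = 1.0  # fraction unbound in plasma
    freab: float = 0.0  # fraction reabsorbed intact

    def validate(self) -> None:
        for name in ("theta", "fup", "freab"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be within [0, 1]")
        if self.GFR < 0:
            raise ValueError("GFR must be non-negative")


@dataclass
class TMDDParams:
    """Full target-mediated drug disposition parameters (amount space).

    The target is synthesized at the zero-order rate ``ksyn`` (mol/h) and
    degraded first-order at ``kdeg`` (1/h), giving the pre-dose baseline
    ``R0 = ksyn/kdeg``.  Complex internalization defaults to the receptor
    degradation rate for membrane targets and to the drug's elimination rate
    ``kel_drug`` for soluble targets.
    """

    ksyn: float
    kdeg: float
    kon: float  # 1/(M*h) if concentrations are used; 1/(mol*h) in amount space
    koff: float
    kint: float | None = None
    target_kind: str = "membrane"  # or "soluble"
    kel_drug: float = 0.0

    def internalization_rate(self) -> float:
        if self.kint is not None:
            return self.kint
        return self.kdeg if self.target_kind == "membrane" else self.kel_drug

    @property
    def baseline(self) -> float:
        if self.kdeg <= 0:
            raise ValueError("baseline undefined for kdeg <= 0")
        return self.ksyn / self.kdeg


@dataclass
class BindingParams:
    """Single-site albumin binding of a solute (e.g. an oligonucleotide)."""

    fu_p: float = 0.05
    alb_ratio_is: float | Mapping[str, float] = 0.5
    MW_free: float = 7.0
    MW_albumin: float = 66.5

    @property
    def MW_bound(self) -> float:
        return self.MW_free + self.MW_albumin


# ------------------------------------------------------------------- two pore

def compute_two_pore_params(
    mw_kda: float,
    lymph_flow: float,
    rS: float = 4.5,
    rL: float = 25.0,
    alpha_L: float = 0.042,
    A0dx: float = 1.0,
    frac_A_small: float = 0.9,
    sl: float = 0.2,
    transport: SizeTransportModel = DEFAULT_TRANSPORT,
) -> TwoPoreParams:
    """Predict organ x solute two-pore parameters from molecular size.

    ``lymph_flow`` (L/h) is split ``(1 - alpha_L)`` / ``alpha_L`` between
    small and large pores; ``A0dx`` is the total exchange area over diffusion
    distance (cm) and ``frac_A_small`` its small-pore share.  PS is
    ``(A/dx) * D_free * H(lam)`` converted to L/h, and the Peclet number is
    the standard per-pore ratio ``Pe = J*(1 - sigma)/PS``.  Sigma is
    non-decreasing and PS non-increasing in MW; a solute radius at or above a
    pore radius gives complete steric exclusion (sigma = 1, PS = 0).
    """
    if mw_kda <= 0:
        raise ValueError("molecular weight must be positive")
    if not rS < rL:
        raise ValueError("small-pore radius must be below large-pore radius")
    a = transport.stokes_radius_nm(mw_kda)
    D = transport.free_diffusivity(mw_kda)  # cm^2/h
    J_S = (1.0 - alpha_L) * lymph_flow
    J_L = alpha_L * lymph_flow
    out = {}
    for tag, r, frac, J in (("S", rS, frac_A_small, J_S), ("L", rL, 1 - frac_A_small, J_L)):
        lam = a / r
        sigma = 1.0 if lam >= 1.0 else transport.reflection(lam)
        H = 0.0 if lam >= 1.0 else transport.diffusive_hindrance(lam)
        PS = A0dx * frac * D * H / 1000.0  # cm^3/h -> L/h
        Pe = J * (1.0 - sigma) / PS if PS > 0 else 0.0
        out[tag] = (sigma, PS, Pe)
    return TwoPoreParams(
        L_S=J_S,
        L_L=J_L,
        sigma_S=out["S"][0],
        sigma_L=out["L"][0],
        PS_S=out["S"][1],
        PS_L=out["L"][1],
        Pe_S=out["S"][2],
        Pe_L=out["L"][2],
        sl=sl,
        rS=rS,
        rL=rL,
    )


def two_pore_rate(params: TwoPoreParams, C_is: float, C_v: float) -> float:
    """Net extravasation rate (mol/h per unit... strictly amount/time when
    concentrations are mol/L and flows L/h): convection on ``C_v`` plus
    hindered diffusion on the concentration difference.

    This difference form is algebraically identical to the clearance form
    ``(CL_S + CL_L) * C_v`` but remains well defined at ``C_v = 0``.
    """
    conv = (params.L_S * (1 - params.sigma_S) + params.L_L * (1 - params.sigma_L)) * C_v
    diff = (
        params.PS_S * peclet_factor(params.Pe_S) + params.PS_L * peclet_factor(params.Pe_L)
    ) * (C_v - C_is)
    return conv + diff


def two_pore_clearance(params: TwoPoreParams, C_is: float, C_v: float) -> tuple[float, float]:
    """Per-pore transcapillary clearances (L/h).

    ``CL = L*(1 - sigma) + PS * Pe/(e^Pe - 1) * (1 - C_is/C_v)`` for each pore
    class; the net extravasation rate is ``(CL_S + CL_L) * C_v``.  At
    ``C_v = 0`` the concentration-ratio factor is undefined, so the diffusive
    term falls back to the concentration-difference form (zero convection
    reference); use :func:`two_pore_rate` when a rate is what is needed.
    """
    params.validate()
    if C_v > 0:
        grad = 1.0 - C_is / C_v
    else:
        grad = -C_is  # difference form per unit C_v fallback; rate users: two_pore_rate
    cl_s = params.L_S * (1 - params.sigma_S) + params.PS_S * peclet_factor(params.Pe_S) * grad
    cl_l = params.L_L * (1 - params.sigma_L) + params.PS_L * peclet_factor(params.Pe_L) * grad
    return cl_s, cl_l


# ------------------------------------------------------------------------ FcRn

def fcrn_rhs(
    a_va: float,
    a_is: float,
    a_en: float,
    a_fcrn: float,
    a_complex: float,
    params: FcRnParams,
    v_en: float,
) -> tuple[float, float, float, float, float, float]:
    """Amount-space derivatives of the endosomal FcRn salvage cycle.

    Returns ``(d_va, d_is, d_en, d_fcrn, d_complex, d_deg)`` for the vascular
    and interstitial drug amounts, free endosomal drug, free FcRn, drug-FcRn
    complex, and the degraded-drug bookkeeping pool.  Uptake is first order on
    the source amounts; binding is bimolecular in the endosomal volume; the
    recycled complex releases drug to the vascular side with probability
    ``f_rec_va`` and to the interstitial side otherwise, returning the
    receptor to the free endosomal pool in both cases, so total FcRn
    (free + complex) is conserved exactly.
    """
    params.validate()
    up_va = params.Kup_va * a_va
    up_is = params.Kup_is * a_is
    cat = params.CLcat / v_en * a_en if v_en > 0 else 0.0
    bind = params.kon * a_en * a_fcrn / v_en if v_en > 0 else 0.0
    unbind = params.koff * a_complex
    rec = params.krec * a_complex
    d_va = -up_va + params.f_rec_va * rec
    d_is = -up_is + (1.0 - params.f_rec_va) * rec
    d_en = up_va + up_is - cat - bind + unbind
    d_fcrn = -bind + unbind + rec
    d_complex = bind - unbind - rec
    d_deg = cat
    return d_va, d_is, d_en, d_fcrn, d_complex, d_deg


# ----------------------------------------------------------------------- renal

def renal_filtration_cl(params: RenalParams) -> float:
    """Net filtration clearance ``GFR * theta * fup * (1 - freab)`` (L/h)."""
    params.validate()
    return params.GFR * params.theta * params.fup * (1.0 - params.freab)


def gsc_from_mw(
    mw_kda: float,
    pore_radius_nm: float = 4.5,
    transport: SizeTransportModel = DEFAULT_TRANSPORT,
) -> float:
    """Glomerular sieving coefficient from molecular weight.

    Uses the convective sieving factor of the size-transport strategy at the
    glomerular small-pore radius: theta -> 1 as MW -> 0 (filtered like water)
    and theta -> 0 once the solute radius reaches the pore radius, so
    filtration is negligible for large proteins.
    """
    if mw_kda <= 0:
        raise ValueError("molecular weight must be positive")
    lam = transport.stokes_radius_nm(mw_kda) / pore_radius_nm
    if lam >= 1.0:
        return 0.0
    return 1.0 - transport.reflection(lam)


# ------------------------------------------------------------------------ TMDD

def tmdd_rhs(
    drug: float,
    target: float,
    cplx: float,
    params: TMDDParams,
) -> tuple[float, float, float]:
    """Full-TMDD derivatives ``(d_drug, d_target, d_complex)`` (amount space).

    Target turnover is zero-order synthesis / first-order degradation; the
    drug binds the target reversibly; the complex internalizes first-order at
    :meth:`TMDDParams.internalization_rate`.  With ``kdeg = 0`` and
    ``ksyn > 0`` the baseline is unbounded — allowed but the caller is
    expected to know what they are doing.
    """
    bind = params.kon * drug * target
    unbind = params.koff * cplx
    kint = params.internalization_rate()
    d_drug = -bind + unbind
    d_target = params.ksyn - params.kdeg * target - bind + unbind
    d_cplx = bind - unbind - kint * cplx
    return d_drug, d_target, d_cplx


def tmdd_subgraph(params: TMDDParams, volume: float = 1.0):
    """Full-TMDD model fragment as a standalone model graph.

    Species ``Drug``, ``Target`` and ``Complex`` live in one compartment;
    the graph is ready to compile on its own or to embed as a subgraph
    definition body.  ``Target`` starts at its turnover baseline.
    """
    from .model_graph import ModelGraph

    g = ModelGraph("tmdd")
    g.add_compartment("Cell", volume=volume)
    g.add_parameter("ksyn", default=params.ksyn)
    g.add_parameter("kdeg", default=params.kdeg)
    g.add_parameter("kon", default=params.kon)
    g.add_parameter("koff", default=params.koff)
    g.add_parameter("kint", default=params.internalization_rate())
    g.add_species("Drug", "Cell")
    g.add_species("Target", "Cell")
    g.add_species("Complex", "Cell")
    g.add_assignment("T0", "Target", "ksyn/kdeg", kind="initial")
    g.add_reaction("syn", "ksyn", products=[("Target", 1)])
    g.add_reaction("deg", "kdeg*Target", substrates=[("Target", 1)])
    g.add_reaction(
        "bind",
        "kon*Drug*Target - koff*Complex",
        substrates=[("Drug", 1), ("Target", 1)],
        products=[("Complex", 1)],
    )
    g.add_reaction("internalize", "kint*Complex", substrates=[("Complex", 1)])
    return g


# --------------------------------------------------------------------- binding

def fraction_unbound_interstitial(params: BindingParams, organ: str | None = None) -> float:
    """Interstitial unbound fraction from the plasma unbound fraction.

    With linear single-site albumin binding, ``fu = 1/(1 + [Alb]/Kd)``; the
    albumin-to-Kd ratio implied by ``fu_p`` is scaled by the organ's
    interstitial-to-plasma albumin ratio, giving
    ``fu_is = 1 / (1 + R * (1 - fu_p)/fu_p)``.  Since ``R <= 1``,
    ``fu_is >= fu_p`` always.
    """
    fu_p = params.fu_p
    if not 0.0 < fu_p <= 1.0:
        raise ValueError("fu_p must be in (0, 1]")
    ratio = params.alb_ratio_is
    if isinstance(ratio, Mapping):
        if organ is None:
            raise ValueError("organ required for per-organ albumin ratios")
        ratio = ratio[organ]
    if not 0.0 < ratio <= 1.0:
        raise ValueError("alb_ratio_is must be in (0, 1]")
    return 1.0 / (1.0 + ratio * (1.0 - fu_p) / fu_p)


# ------------------------------------------------------------------------ dose

def dose_to_moles(dose_mpk: float, tbw: float, mw_kda: float) -> float:
    """Convert a mg/kg dose to moles: ``dose * tbw / (MW_kDa * 1e6)``.

    A molar mass of MW kDa is MW * 1e6 mg/mol.  Zero dose is allowed; zero or
    negative body weight / molecular weight is not.
    """
    if dose_mpk < 0:
        raise ValueError("dose must be non-negative")
    if tbw <= 0 or mw_kda <= 0:
        raise ValueError("body weight and molecular weight must be positive")
    return dose_mpk * tbw / (mw_kda * 1e6)
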