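# Methods

This note documents the modelling language semantics, the mechanistic
equations, the parameter conventions, and the numerical choices implemented
in `biopbpk`, together with what the synthetic fixtures do and do not
represent.

## Units and state convention

Time is in hours, volumes in litres, amounts in **moles**, concentrations in
mol/L, molecular weight in kDa, pore radii in nm.  The compiled state vector
holds amounts; concentrations are derived observers (`amount / volume`).
Working in amount space makes mass balance exact by construction — every
reaction subtracts `stoich × rate` from its substrates and adds it to its
products, so any closed reaction set conserves the stoichiometry-weighted
total to machine precision, and multistep integrators preserve that linear
invariant up to round-off.  It also fixes an explicit convention for the
endosomal uptake terms: an uptake rate constant `Kup` (1/h) acts on the
*amount* in the source compartment, i.e. rate (mol/h) = `Kup × A_source`.
Whether such rate constants are defined per source or per endosomal volume
is a modelling convention; ours is stated here and used consistently, so a
user porting literature values should check which convention those values
assume.

## Model-description language

* **Components.**  Attaching indices `i1, i2, …` to a quantity `Q` expands it
  into the cross-product of index values; components are named
  `Q_<v1>_<v2>…` in index **declaration order**.  This naming is the contract
  with VPop CSV headers (`Dose_mpk_sc_mAb_is` is the subcutaneous-organ,
  interstitial-target element of the dose array).
* **Expressions** support `+ − * / ^`, parentheses, `exp`, `expm1`, `log`,
  `sqrt`, `abs`, `min`, `max`, and `pef(x) = x/(e^x − 1)` (continuous value 1
  at 0).  There are no conditionals; the only place one would be needed —
  the two-pore diffusive factor when a pore class fully excludes the solute —
  is covered by `pef` and the guards described below.  An index specifier
  `Q[i=$A]` selects a component literally; `Q[i=name]` looks `name` up among
  the index-value placeholders in scope.  An index left unbound by a
  specifier must be bound ambiently — by the reaction's attached index loop,
  by the iteration index of a connected quantity list, or by the enclosing
  instance's bindings; v1 requires every index to be resolvable one of these
  ways (no partially-bound arrays inside list reactions).
* **Subgraphs.**  A definition is a blueprint; instances inline its body
  under a `<instance>.` name prefix with the placeholder bindings applied, so
  editing a definition re-shapes all instances at the next compile.  Bodies
  may *read* outer quantities (falling back through the scope chain) but an
  assignment inside a body targeting an outer quantity is rejected — global
  parameters stay consistent across instances.  Outer modifiers may reach
  into an instance only through nodes the definition exposes (dotted
  references or channel aliases).
* **Quantity lists** pair their flattened members positionally with the
  values of their element index; a reaction connected to lists replicates
  once per member, with the element-index value bound ambiently in the rate.
  Nested lists flatten; connected lists must agree in length; an empty list
  yields zero reaction instances.  A species may sit in several lists: when
  that routes the *same* reaction to the same species twice the verifier
  emits a **warning**, not an error — de-duplication is deliberately the
  modeller's responsibility, and the check only detects syntactic
  duplication (one list reaching a species along two membership paths).
* **Verification** runs five checks (membership acyclicity, list/reaction
  index consistency, symbol resolution everywhere, no instance writes to
  outer quantities, duplicate-term warning).  This is the implemented check
  set; a tool-specific GUI layer would add more.  `verify_graph` is pure: it
  returns diagnostics and never mutates the graph.
* **Compilation** orders initial assignments topologically (cycles are
  reported by name), generates one Python function for the right-hand side
  with repeated assignments evaluated at the top of every call, and keeps
  state ordering deterministic (declaration order through the instance
  walk), so identical graphs give bit-identical compiled systems.

## Mechanisms

**Two-pore transcapillary transport.**  Per pore class (small/large),
clearance is `L_pore(1−σ) + PS·Pe/(e^Pe−1)·(1−C_is/C_v)`; numerically the
diffusive part is evaluated on the concentration difference
`PS·pef(Pe)·(C_v−C_is)`, which is the same algebra but well-defined at
`C_v = 0`.  Size dependence is a pluggable strategy with documented
defaults: Stokes radius `a = 0.0483·MW_Da^0.386` nm, steric partition
`Φ = (1−λ)²` at radius ratio `λ = a/r`, convective sieving
`W = Φ(2−Φ)(1−λ²/3)` with `σ = 1−W`, Renkin diffusive hindrance
`H = Φ(1 − 2.104λ + 2.09λ³ − 0.95λ⁵)`, Stokes–Einstein free diffusivity at
37 °C, and `PS = (A₀/Δx)·frac·D·H`.  Lymph flow splits
`J_S = (1−α_L)L`, `J_L = α_L L` (α_L = 0.042 hydraulic large-pore share) and
`Pe = J(1−σ)/PS` per pore.  Any of these pieces can be replaced to match a
specific literature parameterization.  In the platform graph the same
formulas are initial assignments; `Pe` is computed as
`min(J(1−σ)/max(PS,1e−30), 50)` so complete steric exclusion (σ=1, PS=0)
stays finite, and the pure-Python calculator (no guards needed) is
cross-checked against the compiled values in the tests.  A solute radius at
or above a pore radius gives σ = 1 and PS = 0 exactly.

**Lymphatic drainage** from the interstitial space uses `L(1−sl)·C_is` with
the organ's lymphatic reflection coefficient `sl` (input parameter, default
0.2); no independent equation for the lymph flux is available, so this
standard convective form is the package's choice.

**FcRn salvage.**  Endosomal drug is taken up first-order from the vascular
and interstitial sides, degraded at `CLcat/V_en`, and binds free FcRn
bimolecularly (`kon·A_drug·A_FcRn/V_en`, `koff` dissociation).  The complex
recycles at `krec`, releasing drug to the vascular side with probability
`f_rec_va` and to the interstitial side otherwise (default 0.5: both routes
are drawn without a published ratio, so the split is symmetric and
user-adjustable).  **Receptor conservation:**
recycling returns FcRn to the free endosomal pool, so total FcRn
(free + complex) is a strict invariant; FcRn synthesis/degradation is not
modelled, which is the simplest closure consistent with a fixed endosomal
receptor level.

**Renal filtration.**  `CL_filt = GFR·θ·fu_p·(1−f_reab)`, applied as a
first-order transfer from the kidney vascular compartment into the lumped
BCPTLH filtrate compartment and onward to urine.  θ(MW) is the convective
sieving factor at a glomerular pore radius of 4.5 nm: θ→1 as MW→0, strictly
non-increasing, and ≈0 above ~60 kDa, so a mAb is essentially unfiltered
while a 10 kDa protein clears renally.  A "partition ratio" sometimes listed
alongside these symbols has no defining equation and is not implemented;
charge selectivity of the barrier is likewise out of scope.

**TMDD / RME.**  Full model: target synthesized at zero order `ksyn`,
degraded at `kdeg` (baseline `R0 = ksyn/kdeg`), reversible binding
(`kon`, `koff`), first-order complex internalization `kint`.  Default
`kint`: the receptor degradation rate for membrane targets, the drug's
elimination rate for soluble targets.  Receptor-mediated endocytosis uses
the same mathematics with the internalized drug *released* intracellularly
(and the receptor recycled) instead of degraded — that is how the
oligonucleotide adaptation uses it.

**Protein binding.**  Linear single-site albumin binding:
`fu = 1/(1+[Alb]/Kd)`, so the interstitial unbound fraction follows from the
plasma one and the organ's interstitial/plasma albumin ratio `R ≤ 1`:
`fu_is = 1/(1 + R(1−fu_p)/fu_p) ≥ fu_p`.

**Dose conversion.**  `amount [mol] = Dose_mpk [mg/kg] × tbw [kg] /
(MW_kDa × 10⁶ mg/mol)`, routed through the organ × doseTarget `Dose_mpk`
array: exactly one component nonzero selects route and site (venous `mAb_va`
for IV, `sc` organ `mAb_is` for subcutaneous).

## Whole-body platform

21 organ labels (lung, heart, kidney, liver, spleen, gut, pancreas, stomach,
muscle, skin, adipose, bone, bone marrow, brain, thymus, lymph node, eye,
testes, adrenal, a subcutaneous injection-site tissue `sc`, and a
rest-of-body closure organ `ot`) plus arterial and venous blood pools give
the 23-valued organ index.  The label set is a package assumption drawn from
the standard whole-body schematic; no canonical list is published with the
method.  Circulation: venous → lung → arterial → systemic organs → venous,
lymph draining interstitial → venous; the builder asserts Kirchhoff balance
at the arterial node (Σ systemic Q = Q_lung − L_lung) and `L < Q` per organ.
The `ot` organ's sub-compartment volumes are *initial assignments* (total
body volume minus all modelled organs, split by standard sub-compartment
fractions), so organ volumes always sum correctly and those components are
structurally non-overridable from VPop files — the worked mechanism for
encoding inter-parameter constraints.

**Pregnancy.**  The feto-placental unit adds 5 organ-index values: a
placenta instance (maternal vascular + shared endothelium + foetal vascular;
no interstitial space, as transcytosis across the shared endothelium is
transfer-limiting and placental interstitial physiology is not
characterized), foetal arterial/venous pools, a lumped foetal body and a
foetal lymph node, wired into a foetal circulation loop.  Placental FcRn
transfer reuses the salvage cycle with a maternal/foetal recycling split
`f_mat`.  Gestational age `GA = GA0 + t/168` (weeks) drives any parameter
component through `B0 + B1·GA + B2·GA² + B3·GA³` as a repeated assignment —
a cubic because exactly four empirical constants parameterize each schedule;
non-GA-dependent parameters fix B1–B3 = 0 and reduce to constants.  The
placental FcRn schedule is applied to the placental association rate
constant (`konFcRn_pl`): with a fixed endosomal receptor pool, a time-varying
abundance and a time-varying association capacity are not distinguishable,
so the capacity form is used and stated.  Maternal cardiac output is raised
by the placental flow so the arterial flow balance still holds (cardiac
output does rise in pregnancy); with zero placental flow the extension
leaves maternal kinetics exactly unchanged, which is the reduction test.
Maternal endogenous IgG synthesis is zero-order production into venous
plasma with a GA-drivable rate.  Parameter estimation against clinical data
is out of scope; all pregnancy parameters here are synthetic.

**Oligonucleotides.**  A `pb` index (`free`/`bound`) doubles the molecular
weight and every size-derived transport array; the albumin complex uses
`MW_bound = MW_free + 66.5` kDa, which drives its sieving coefficient to ~0
(bound drug is effectively not filtered).  Binding is treated as an
instantaneous equilibrium: repeated assignments compute free/bound
concentrations in the vascular and interstitial spaces every solver step
from `fu_p` and `fu_is`, and the two-pore rate sums the free and bound
contributions.  FcRn association is set to zero.  Macropinocytosis is
first-order uptake of free interstitial drug into the intracellular space in
all tissues; RME adds receptor binding/internalization with an organ-indexed
receptor abundance — zero outside expressing tissues — and an unconjugated
compound is the same model with the receptor association constant zero.

## Numerics

LSODA by default (BDF available), rtol 1e−8, atol 1e−12 — tight absolute
tolerance because amounts in moles are small; all configurable per run.
Bolus doses are integration restarts at the dose times (exact
discontinuities), not forcing functions; infusions can be expressed as
zero-order production reactions.  Repeated assignments execute inside the
generated RHS, i.e. at every internal solver step.  States are never clipped
inside the solver; small negative amounts are clipped to zero only in
reported trajectories, and negativity beyond 100×atol is flagged in the run
diagnostics.  Non-finite parameters or RHS values abort with the offending
component named.  Model-property checks that compare two trajectories
(linearity, reduction tests) tighten tolerances to rtol 1e−10–1e−11 so
solver error does not mask structural agreement.

## Synthetic fixtures

The physiology generator produces a curated human organ table (plausible
volumes, plasma flows summing to a 150 L/h plasma cardiac output, lymph at
0.2 % of plasma flow, GFR 7.2 L/h) scaled allometrically — volumes ∝ BW¹,
flows and GFR ∝ BW^0.75 — to mouse (25 g), rat (250 g) and monkey (3.5 kg),
with flows rebalanced per individual/species so the whole-body invariants
hold by construction.  Population mode draws log-normal multiplicative
variability at a specified CV.  The drug defaults describe a typical IgG1
(150 kDa, FcRn KD ≈ 0.7 µM at endosomal pH, endosomal catabolic clearance
set so the human terminal half-life comes out ≈ 22 days).  These are
*synthetic study conditions*: they are internally consistent and
physiologically plausible, but they are not literature-sourced per-organ
measurements, they contain no measurement error or covariance structure,
and passing tests against them demonstrates the correctness of the model
assembly and simulation machinery — not predictive accuracy for any real
compound.  Case-study fits to in-vivo datasets are correspondingly out of
scope.

Problem sizes used by the test-bench and the acceptance script: the toy
system (8 states), the whole-body mAb model (130 states, 212 reactions;
1000–2000 h horizons), the pregnancy extension (150 states) and the
oligonucleotide adaptation (193 states), with VPop batches of 4–500 rows —
sizes at which every check runs in seconds while exercising the full
machinery.

## Known limitations

* No SBML import/export; the serialization format is the package's own YAML
  schema (lossless round-trip).
* No conditionals or piecewise expressions in the language (v1).
* Equilibrium (not kinetic) plasma-protein binding for oligonucleotides.
* Single-pH FcRn binding (no endosomal pH cycling), no FcRn turnover.
* No charge selectivity in glomerular filtration; no redistribution
  pathway beyond the implemented uptake/recycling routes.
* Parameter estimation is out of scope; the package simulates.
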