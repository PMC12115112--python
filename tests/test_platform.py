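"""Whole-body platform model, pregnancy extension, oligonucleotide adaptation."""

import numpy as np
import pytest

from biopbpk import compiler, engine, fixtures, mechanisms as mech
from biopbpk.engine import SolverOptions, run_vpop, simulate
from biopbpk.model_graph import ModelGraph
from biopbpk.platform import (
    FETAL_ORGANS,
    GENERIC_TISSUE_COMPARTMENTS,
    GENERIC_TISSUE_SPECIES,
    ModelBuildError,
    OligoUptakeParams,
    adapt_oligonucleotide,
    build_generic_tissue,
    build_whole_body,
    default_pregnancy_physiology,
    extend_pregnancy,
)

IV_DOSE = {"Dose_mpk_ve_mAb_va": 1.0}


def _zero_clearance_overrides():
    ov = {"GFR": 0.0}
    ov.update({f"CLcat_{o}": 0.0 for o in fixtures.ORGANS})
    return ov


def drug_states(model):
    """States carrying drug mass (free FcRn excluded; complex counts once)."""
    return [s for s in model.state_names if not s.endswith(".FcRn_en")]


class TestGenericTissue:
    def test_template_structure(self):
        defn = build_generic_tissue()
        body = defn.body
        comps = [q for q in body.quantities.values() if q.kind == "compartment"]
        assert len(comps) == len(GENERIC_TISSUE_COMPARTMENTS) == 4
        assert {q.name for q in body.quantities.values() if q.kind == "species"} == set(
            GENERIC_TISSUE_SPECIES
        )
        assert {"R1", "R2", "R3", "R4", "R5", "R6", "twoPore"} <= set(body.reactions)

    def test_single_instance_has_six_states_plus_dose_chain(self, human_physiology):
        """One organ instance contributes exactly the six template species."""
        defn = build_generic_tissue(with_dosing=False)
        g = _single_organ_graph(human_physiology, defn)
        model = compiler.compile_graph(g)
        assert model.n_states == 6

    def test_everything_degrades_without_recycling(self, whole_body_model):
        """With krec = 0 all drug ends up in the degraded pools."""
        ov = {**IV_DOSE, "krec": 0.0}
        res = simulate(whole_body_model, 20000.0, overrides=ov,
                       output_times=np.linspace(0.0, 20000.0, 51))
        deg = [s for s in whole_body_model.state_names if s.endswith("degmAb_en")]
        urine = res.state("mAb_urine")[-1]
        total = res.total_amount(drug_states(whole_body_model))[0]
        assert (res.states[deg].to_numpy()[-1].sum() + urine) / total > 0.99

    def test_organ_total_observer_is_amount_over_volume(self, whole_body_model):
        res = simulate(whole_body_model, 24.0, overrides=IV_DOSE,
                       output_times=np.linspace(0, 24, 5))
        _, p, _ = whole_body_model.initialize(IV_DOSE)
        pv = dict(zip(whole_body_model.parameter_names, p))
        vols = sum(pv[f"V_{c}_he"] for c in ("va", "en", "is", "ic"))
        amounts = (
            res.state("he.mAb_va") + res.state("he.mAb_en") + res.state("he.mAb_is")
        )
        np.testing.assert_allclose(
            res.observer("mAb_organTotal_he"), amounts / vols, rtol=1e-12
        )


def _single_organ_graph(phys, defn):
    g = ModelGraph("single")
    g.add_index("organ", ["he"])
    g.add_index("soluble", ["mAb"])
    g.add_index("circulating", ["mAb"])
    row = phys.organs.loc["he"]
    for col in ("V_va", "V_en", "V_is", "V_ic", "CLcat", "FcRn0"):
        g.add_parameter(col, indices=["organ"], default_values={f"{col}_he": row[col]})
    for name, val in [("Kup_va", 0.02), ("Kup_is", 0.02), ("konFcRn", 1e7),
                      ("koffFcRn", 7.0), ("krec", 5.0), ("f_rec_va", 0.5)]:
        g.add_parameter(name, default=val)
    for name in ("JS", "JL", "sS", "sL", "PSS", "PSL", "PeS", "PeL"):
        idx = ["organ"] if name in ("JS", "JL") else ["organ", "soluble"]
        g.add_parameter(name, indices=idx, default=0.0 if name[0] in "Js" else 0.1)
    g.define_subgraph(defn.name, defn.body)
    g.instantiate_subgraph("he", defn.name, {"thisOrgan": "he"})
    return g


class TestWholeBody:
    def test_organ_index_cardinality(self, whole_body_graph):
        """21 organs plus arterial and venous pools -> 23 index values."""
        assert len(whole_body_graph.indices["organ"].values) == 23

    def test_flow_imbalance_rejected(self, human_physiology):
        bad = fixtures.Physiology(
            name="bad",
            organs=human_physiology.organs.copy(),
            tbw=human_physiology.tbw,
            tbv=human_physiology.tbv,
            gfr=human_physiology.gfr,
        )
        bad.organs.loc["he", "Q"] *= 3.0
        with pytest.raises(ModelBuildError, match="flow imbalance"):
            build_whole_body(bad)

    def test_missing_organ_rejected(self, human_physiology):
        bad = fixtures.Physiology(
            name="bad",
            organs=human_physiology.organs.drop(index="he"),
            tbw=human_physiology.tbw,
            tbv=human_physiology.tbv,
            gfr=human_physiology.gfr,
        )
        with pytest.raises(ModelBuildError, match="missing organ"):
            build_whole_body(bad)

    def test_iv_bolus_mass_conserved_without_clearance(self, whole_body_model):
        ov = {**IV_DOSE, **_zero_clearance_overrides()}
        res = simulate(whole_body_model, 500.0, overrides=ov)
        total = res.total_amount(drug_states(whole_body_model))
        assert np.max(np.abs(total - total[0]) / total[0]) < 1e-8

    def test_plasma_profile_is_biphasic(self, whole_body_model):
        """Distribution then elimination: the terminal slope is the shallower one."""
        t = np.linspace(0.0, 2000.0, 201)
        res = simulate(whole_body_model, 2000.0, output_times=t, overrides=IV_DOSE)
        logc = np.log(res.observer("mAb_plasma"))
        early = np.polyfit(t[(t >= 5) & (t <= 100)], logc[(t >= 5) & (t <= 100)], 1)[0]
        late = np.polyfit(t[t >= 1000], logc[t >= 1000], 1)[0]
        assert early < late < 0.0  # both decaying; terminal is slower

    def test_small_solutes_are_renally_filtered(self, whole_body_model):
        """A 10 kDa protein passes the glomerular barrier; a mAb does not."""
        small = simulate(whole_body_model, 100.0,
                         overrides={**IV_DOSE, "MWkDa_mAb": 10.0})
        big = simulate(whole_body_model, 100.0, overrides=IV_DOSE)
        total = small.total_amount(drug_states(whole_body_model))[0]
        assert small.state("mAb_urine")[-1] / total > 0.05
        assert big.state("mAb_urine")[-1] / total < 1e-4

    def test_graph_two_pore_parameters_match_mechanism_module(
        self, whole_body_graph, whole_body_model
    ):
        """Dual route: compiled initial assignments vs the pure-Python calculator."""
        _, p, _ = whole_body_model.initialize()
        pv = dict(zip(whole_body_model.parameter_names, p))
        row = None
        for organ in ("he", "li", "mu"):
            src = whole_body_graph.quantities
            ref = mech.compute_two_pore_params(
                mw_kda=pv["MWkDa_mAb"],
                lymph_flow=pv[f"L_{organ}"],
                rS=pv[f"rS_{organ}"],
                rL=pv[f"rL_{organ}"],
                alpha_L=pv[f"alphaL_{organ}"],
                A0dx=pv[f"A0dx_{organ}"],
                frac_A_small=pv["fAs"],
            )
            assert pv[f"sS_{organ}_mAb"] == pytest.approx(ref.sigma_S, rel=1e-12)
            assert pv[f"sL_{organ}_mAb"] == pytest.approx(ref.sigma_L, rel=1e-12)
            assert pv[f"PSS_{organ}_mAb"] == pytest.approx(ref.PS_S, rel=1e-12, abs=1e-30)
            assert pv[f"PSL_{organ}_mAb"] == pytest.approx(ref.PS_L, rel=1e-12)
            assert pv[f"PeL_{organ}_mAb"] == pytest.approx(ref.Pe_L, rel=1e-12)
        assert pv["theta_mAb"] == pytest.approx(
            mech.gsc_from_mw(pv["MWkDa_mAb"], pore_radius_nm=pv["rG"]), abs=1e-12
        )

    def test_adding_an_instance_leaves_existing_organs_untouched(
        self, whole_body_graph, whole_body_model, rng
    ):
        """Locality: a new unwired organ instance changes no existing equations."""
        extended = whole_body_graph.copy()
        extended.instantiate_subgraph("he2", "Generic_Tissue", {"thisOrgan": "he"})
        m2 = compiler.compile_graph(extended, check=False)
        y1 = rng.uniform(0, 1e-6, whole_body_model.n_states)
        _, p1, _ = whole_body_model.initialize()
        _, p2, _ = m2.initialize()
        y2 = np.zeros(m2.n_states)
        for name, v in zip(whole_body_model.state_names, y1):
            y2[m2.state_index[name]] = v
        d1 = dict(zip(whole_body_model.state_names, whole_body_model.rhs(0, y1, p1)))
        d2 = dict(zip(m2.state_names, m2.rhs(0, y2, p2)))
        for s in whole_body_model.state_names:
            assert d1[s] == pytest.approx(d2[s], rel=1e-12, abs=1e-30)

    def test_cross_species_vpop_runs_and_fcrn_protection_slows_decay(
        self, whole_body_model
    ):
        bundle = fixtures.synth_physiology()
        t = np.linspace(0.0, 1000.0, 51)
        results = run_vpop(whole_body_model, bundle["vpop"], 1000.0,
                           output_times=t, base_overrides=IV_DOSE)
        assert [r.label for r in results] == ["mouse", "rat", "monkey", "human"]
        for res in results:
            dtot = res.total_amount(drug_states(whole_body_model))
            deg = [s for s in whole_body_model.state_names
                   if s.endswith("degmAb_en")]
            cleared = res.states[deg].to_numpy()[-1].sum() + res.state("mAb_urine")[-1]
            # mass balance: initial total = remaining + cleared (all tracked)
            assert dtot[-1] == pytest.approx(dtot[0], rel=1e-6)
        # directional: disabling FcRn binding (no protected recycling) speeds decay
        tt = np.linspace(0.0, 400.0, 41)
        protected = simulate(whole_body_model, 400.0, overrides=IV_DOSE,
                             output_times=tt)
        naked = simulate(whole_body_model, 400.0,
                         overrides={**IV_DOSE, "konFcRn": 0.0}, output_times=tt)
        slope = lambda r: np.polyfit(
            r.times[10:], np.log(r.observer("mAb_plasma")[10:]), 1
        )[0]
        assert slope(naked) < slope(protected)


class TestPregnancy:
    def test_five_fetoplacental_units_added(self, whole_body_graph):
        g = extend_pregnancy(whole_body_graph, default_pregnancy_physiology())
        assert len(FETAL_ORGANS) == 5
        assert len(g.indices["organ"].values) == 28
        assert {"pl", "fe", "lnF"} <= set(g.instances)
        assert {"mAb_arF", "mAb_veF"} <= set(g.quantities)

    def test_ga_outside_range_rejected(self, whole_body_graph):
        with pytest.raises(ModelBuildError, match="gestational age"):
            extend_pregnancy(
                whole_body_graph, default_pregnancy_physiology(ga0_weeks=50.0)
            )

    def test_zero_polynomial_terms_give_constant_parameter(self, whole_body_graph):
        """B1=B2=B3=0 reduces a GA-driven parameter to its constant B0."""
        preg = default_pregnancy_physiology()
        preg.ga_params["kup"] = ("Kup_va", (0.02, 0.0, 0.0, 0.0))
        g = extend_pregnancy(whole_body_graph, preg)
        model = compiler.compile_graph(g, check=False)
        reps = {name: ast for _, ast, name in model.repeated_assignments}
        from biopbpk import expr

        _, p, _ = model.initialize()
        env = dict(zip(model.parameter_names, p))
        assert expr.evaluate(reps["RA_kup"], env, t=0.0) == 0.02
        assert expr.evaluate(reps["RA_kup"], env, t=5000.0) == 0.02

    def test_zero_transfer_extension_reproduces_maternal_base_model(
        self, whole_body_graph, whole_body_model
    ):
        preg = default_pregnancy_physiology()
        preg.organs.loc["pl", "Q"] = 0.0
        g = extend_pregnancy(whole_body_graph, preg)
        model = compiler.compile_graph(g, check=False)
        t = np.linspace(0.0, 500.0, 26)
        opts = SolverOptions(rtol=1e-10, atol=1e-20)
        base = simulate(whole_body_model, 500.0, output_times=t,
                        overrides=IV_DOSE, options=opts)
        ext = simulate(model, 500.0, output_times=t, overrides=IV_DOSE, options=opts)
        a, b = base.observer("mAb_plasma"), ext.observer("mAb_plasma")
        assert np.max(np.abs(a - b)) / np.max(a) < 1e-6

    def test_fetal_igg_rises_through_late_gestation(self, whole_body_graph):
        """Steady maternal IgG + rising placental FcRn -> monotone fetal rise."""
        preg = default_pregnancy_physiology(ga0_weeks=26.0)
        preg.igg_syn = (2e-7, 0.0, 0.0, 0.0)  # constant maternal synthesis
        preg.ga_params["konpl"] = ("konFcRn_pl", (0.0, 2.5e5, 0.0, 0.0))
        g = extend_pregnancy(whole_body_graph, preg)
        model = compiler.compile_graph(g, check=False)
        res = simulate(model, 12 * 168.0, output_times=np.linspace(0, 12 * 168, 49))
        fetal = res.observer("mAb_plasma_fetal")
        assert fetal[-1] > 0
        assert np.all(np.diff(fetal[4:]) > 0)


@pytest.fixture(scope="module")
def oligo_model(whole_body_graph):
    g = adapt_oligonucleotide(
        whole_body_graph,
        mech.BindingParams(fu_p=0.05, MW_free=7.0),
        OligoUptakeParams(receptor_abundance={"li": 1e-9}),
    )
    return compiler.compile_graph(g)


class TestOligonucleotide:
    def test_two_pore_arrays_double_in_solute_dimension(
        self, whole_body_graph, oligo_model
    ):
        g = adapt_oligonucleotide(whole_body_graph, mech.BindingParams())
        assert len(g.components("sS")) == 2 * len(whole_body_graph.components("sS"))
        assert "MWkDa_mAb_free" in g.components("MWkDa")
        assert oligo_model.param_defaults["MWkDa_mAb_bound"] == pytest.approx(73.5)

    def test_interstitial_unbound_fraction_exceeds_plasma(self, oligo_model):
        _, p, _ = oligo_model.initialize()
        pv = dict(zip(oligo_model.parameter_names, p))
        for organ in ("he", "li", "mu"):
            assert pv[f"fu_is_{organ}"] >= pv["fu_p"]
        assert pv["fu_is_he"] == pytest.approx(
            mech.fraction_unbound_interstitial(
                mech.BindingParams(fu_p=0.05, alb_ratio_is=0.5)
            )
        )

    def test_fcrn_pathway_disabled(self, oligo_model):
        assert oligo_model.param_defaults["konFcRn"] == 0.0

    def test_macropinocytosis_fills_intracellular_space(self, oligo_model):
        res = simulate(oligo_model, 168.0, overrides=IV_DOSE)
        assert res.state("mu.mAb_ic")[-1] > 0  # non-expressing tissue, kmp only

    def test_unbound_drug_only_when_fu_p_is_one(self, whole_body_graph):
        g = adapt_oligonucleotide(
            whole_body_graph, mech.BindingParams(fu_p=1.0),
            OligoUptakeParams(receptor_abundance={"li": 1e-9}),
        )
        model = compiler.compile_graph(g)
        res = simulate(model, 72.0, overrides=IV_DOSE)
        assert np.all(res.observer("C_bound_plasma") == 0.0)
        assert np.all(res.observer("bound_va_li") == 0.0)
        assert np.all(res.observer("bound_is_li") == 0.0)

    def test_no_receptor_anywhere_makes_conjugation_irrelevant(self, whole_body_graph):
        ga = adapt_oligonucleotide(whole_body_graph, mech.BindingParams(fu_p=0.05),
                                   OligoUptakeParams())
        gu = adapt_oligonucleotide(whole_body_graph, mech.BindingParams(fu_p=0.05),
                                   OligoUptakeParams(kon_r=0.0))
        ma, mu_ = compiler.compile_graph(ga), compiler.compile_graph(gu)
        t = np.linspace(0.0, 168.0, 29)
        ra = simulate(ma, 168.0, output_times=t, overrides=IV_DOSE)
        rb = simulate(mu_, 168.0, output_times=t, overrides=IV_DOSE)
        assert np.max(np.abs(ra.states.to_numpy() - rb.states.to_numpy())) <= 1e-10

    def test_receptor_route_targets_expressing_tissue(self, oligo_model, whole_body_graph):
        """GalNAc-style conjugation boosts liver intracellular exposure only."""
        unconj = compiler.compile_graph(
            adapt_oligonucleotide(
                whole_body_graph, mech.BindingParams(fu_p=0.05),
                OligoUptakeParams(kon_r=0.0, receptor_abundance={"li": 1e-9}),
            )
        )
        t = np.linspace(0.0, 168.0, 29)
        conj = simulate(oligo_model, 168.0, output_times=t, overrides=IV_DOSE)
        plain = simulate(unconj, 168.0, output_times=t, overrides=IV_DOSE)
        assert conj.state("li.mAb_ic")[-1] > 2 * plain.state("li.mAb_ic")[-1]
        assert conj.state("mu.mAb_ic")[-1] == pytest.approx(
            plain.state("mu.mAb_ic")[-1], rel=1e-4
        )
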