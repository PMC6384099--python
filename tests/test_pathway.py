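"""Cofactor ledger, branch equations, and ATP yields."""

import pytest

import fermbalance as fb
from fermbalance.accounting import NetChange, NetChangeTable
from fermbalance.pathway import BUILTIN_PATHWAY_IDS, PathwayError, pathway_from_yaml


def test_builtin_pathways_are_carbon_balanced(registry):
    for name in BUILTIN_PATHWAY_IDS:
        pw = fb.builtin_pathway(name, registry)
        for rxn in pw.reactions:
            assert abs(rxn.carbon_imbalance(registry)) < 1e-9, rxn.name


def test_unbalanced_reaction_rejected(registry):
    rxn = fb.Reaction("broken", {"glucose": -1, "acetate": 1})  # 6 C -> 2 C
    with pytest.raises(PathwayError):
        rxn.check_carbon_balance(registry)


def test_branch_equations_match_reported_coefficients(nets):
    # basis 44.3 mM = 46.4 mM rhamnose consumed - 2.1 mM biomass drain
    eqs = fb.branch_equations(nets["rhamnose"])
    lact, dhap = eqs["lactaldehyde"], eqs["DHAP"]
    assert lact.basis_mM == pytest.approx(44.3)
    assert round(lact.coefficients["1,2-propanediol"], 2) == 0.39
    assert round(lact.coefficients["propanol"], 2) == 0.41
    assert round(lact.coefficients["propionate"], 2) == 0.18
    assert round(dhap.coefficients["acetate"], 2) == 0.43
    assert round(dhap.coefficients["butyrate"], 2) == 0.26


def test_branch_equations_round_trip(nets):
    net = nets["rhamnose"]
    for eq in fb.branch_equations(net).values():
        for product, amount in eq.regenerate().items():
            assert amount == pytest.approx(net.products[product], rel=1e-12)


def test_branch_carbon_closure(nets):
    # acetyl-CoA units (acetate + 2*butyrate) cannot exceed pyruvate available
    dhap = fb.branch_equations(nets["rhamnose"])["DHAP"]
    acetyl = dhap.coefficients["acetate"] + 2 * dhap.coefficients["butyrate"]
    assert acetyl <= 1.0 + 1e-9
    assert acetyl == pytest.approx(42.6 / 44.3, rel=1e-9)
    # the 0.26 butyrate is condensed from 0.52 acetyl-CoA
    assert 2 * round(dhap.coefficients["butyrate"], 2) == pytest.approx(0.52)


def test_branch_equations_from_generator_round_trip():
    spec = fb.SimulationSpec(
        substrates={"rhamnose": 100.0},
        fraction_consumed={"rhamnose": 0.5},
        product_coefficients={
            "rhamnose": {"1,2-propanediol": 0.5, "propanol": 0.3, "propionate": 0.2}
        },
        noise_sd=0.0,
        seed=11,
    )
    ds, _ = fb.simulate_fermentation(spec)
    net = fb.net_changes(ds)
    eq = fb.branch_equations(net, biomass_mM=0.0)["lactaldehyde"]
    assert eq.coefficients["1,2-propanediol"] == pytest.approx(0.5, abs=1e-12)
    assert eq.coefficients["propanol"] == pytest.approx(0.3, abs=1e-12)
    assert eq.coefficients["propionate"] == pytest.approx(0.2, abs=1e-12)


def test_branch_equations_require_consumed_sugar(rhamnose_pathway):
    net = NetChangeTable("demo", (NetChange("glucose", 10.0, "substrate"),))
    with pytest.raises(PathwayError):
        fb.branch_equations(net, pathway=rhamnose_pathway)


def test_reference_ledger_reproduces_total_nadh(nets, rhamnose_pathway):
    # with the branch input taken as sugar consumed (46.4 mM), glycolysis and
    # full ferredoxin transhydrogenation supply 92.8 mM NADH
    ledger = fb.nadh_ledger(nets["rhamnose"], rhamnose_pathway, convention="reference")
    assert ledger.dhap_mM == pytest.approx(46.4)
    assert ledger.nadh_available == pytest.approx(92.8)


def test_measured_ledger_gross_terms(nets, rhamnose_pathway):
    ledger = fb.nadh_ledger(nets["rhamnose"], rhamnose_pathway, convention="measured")
    # all 43.2 mM of diol-branch products pass through 1,2-propanediol
    assert ledger.nadh_consumed["pdo_oxidoreductase"] == pytest.approx(43.2)
    assert ledger.nadh_consumed["propanol_dehydrogenase"] == pytest.approx(18.2)
    # C4 branch: one NADH each at the hydroxybutyryl and butyryl steps
    assert ledger.nadh_consumed["hydroxybutyryl_dehydrogenase"] == pytest.approx(11.7)
    assert ledger.nadh_consumed["butyryl_dehydrogenase"] == pytest.approx(11.7)
    # sources: glycolytic NADH at measured pyruvate flux + propionaldehyde oxidation
    assert ledger.nadh_produced["emp_lower"] == pytest.approx(42.6)
    assert ledger.nadh_produced["propionaldehyde_dehydrogenase"] == pytest.approx(7.8)
    assert ledger.nadh_deficit == pytest.approx(34.4)
    assert ledger.fd_red_produced == pytest.approx(42.6)
    # DHAP-equivalents consumed: 19.2 acetate + 2 x 11.7 butyrate
    assert ledger.dhap_mM == pytest.approx(42.6)
    assert ledger.lactaldehyde_mM == pytest.approx(43.2)


def test_empty_culture_gives_zero_ledger(rhamnose_pathway):
    net = NetChangeTable("demo", (NetChange("rhamnose", 10.0, "substrate"),))
    ledger = fb.nadh_ledger(net, rhamnose_pathway)
    assert ledger.nadh_consumed == {}
    assert ledger.fd_red_produced == 0.0
    assert ledger.nadh_deficit == 0.0


def test_ledger_linearity(nets, rhamnose_pathway):
    net = nets["rhamnose"]
    one = fb.nadh_ledger(net, rhamnose_pathway)
    two = fb.nadh_ledger(net.scaled(2.0), rhamnose_pathway)
    assert two.fd_red_produced == pytest.approx(2 * one.fd_red_produced)
    assert two.nadh_deficit == pytest.approx(2 * one.nadh_deficit)
    for key, value in one.nadh_consumed.items():
        assert two.nadh_consumed[key] == pytest.approx(2 * value)


def test_atp_yield_rhamnose(nets, rhamnose_pathway):
    # -1 uptake -1 rhamnulokinase +2 EMP +0.87 acid kinases = 0.87 -> 0.9
    atp = fb.atp_yield(nets["rhamnose"], rhamnose_pathway)
    assert atp == pytest.approx(0.873, abs=0.001)
    assert round(atp, 1) == 0.9


def test_atp_yield_glucose(nets, glucose_pathway):
    atp = fb.atp_yield(nets["glucose"], glucose_pathway)
    assert atp == pytest.approx(2.0, abs=0.05)


def test_atp_ratio_rhamnose_vs_glucose(nets, rhamnose_pathway, glucose_pathway):
    ratio = fb.atp_yield(nets["rhamnose"], rhamnose_pathway) / fb.atp_yield(
        nets["glucose"], glucose_pathway
    )
    assert ratio < 0.5  # less than half the energy per mol sugar


def test_atp_yield_zero_acid_rhamnose_culture(rhamnose_pathway):
    # -1 uptake -1 kinase +2 EMP and no acid kinases -> exactly 0
    net = NetChangeTable(
        "demo",
        (
            NetChange("rhamnose", 10.0, "substrate"),
            NetChange("1,2-propanediol", 5.0, "product"),
        ),
    )
    assert fb.atp_yield(net, rhamnose_pathway) == pytest.approx(0.0, abs=1e-12)


def test_atp_yield_requires_sugar(rhamnose_pathway):
    net = NetChangeTable("demo", (NetChange("butanol", 5.0, "product"),))
    with pytest.raises(PathwayError):
        fb.atp_yield(net, rhamnose_pathway)


def test_pathway_yaml_round_trip(tmp_path, registry, nets):
    cfg = tmp_path / "pw.yaml"
    cfg.write_text(
        """
name: mini
sugar: glucose
uptake_atp: 0
priming_atp: 2
pyruvate_per_sugar: 2
reactions:
  - name: glycolysis_upper
    stoichiometry: {glucose: -1, triose-P: 2}
    cofactors: {ATP: -2}
  - name: emp_lower
    stoichiometry: {triose-P: -1, pyruvate: 1}
    cofactors: {NADH: 1, ATP: 2}
  - name: pyruvate_oxidation
    stoichiometry: {pyruvate: -1, acetyl-CoA: 1, CO2: 1}
    cofactors: {Fd_red: 1}
  - name: acetate_kinase
    stoichiometry: {acetyl-CoA: -1, acetate: 1}
    cofactors: {ATP: 1}
routes:
  acetate: {emp_lower: 1, pyruvate_oxidation: 1, acetate_kinase: 1}
"""
    )
    pw = pathway_from_yaml(cfg, registry)
    net = NetChangeTable(
        "homoacetate",
        (NetChange("glucose", 10.0, "substrate"), NetChange("acetate", 20.0, "product")),
    )
    assert fb.estimate_h2(net, pw) == pytest.approx(40.0)


def test_route_with_unknown_reaction_rejected():
    with pytest.raises(PathwayError):
        fb.Pathway(
            name="bad",
            sugar="glucose",
            reactions=(),
            routes={"acetate": {"nope": 1}},
            uptake_atp=0,
            priming_atp=0,
            pyruvate_per_sugar=2,
        )
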