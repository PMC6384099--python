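"""Cofactor ledger and branch equations of the l-rhamnose fermentation.

Rhamnose catabolism splits at the aldolase into a lactaldehyde branch
(1,2-propanediol, propanol, propionate) and a DHAP branch (acetate,
butyrate via the EMP pathway and acetyl-CoA). This example prints the
NADH/ferredoxin ledger under the measured (gross-flux) and reference
(full-conversion) conventions, the normalized branch equations on the
biomass-corrected basis, and the net ATP yield per mol sugar.
"""

import fermbalance as fb

net = fb.net_changes(fb.load_culture("rhamnose"))
pathway = fb.builtin_pathway("rhamnose")

measured = fb.nadh_ledger(net, pathway, convention="measured")
print("measured-flux ledger:")
print(f"  DHAP-equivalents consumed: {measured.dhap_mM:.1f} mM")
print(f"  lactaldehyde-branch products: {measured.lactaldehyde_mM:.1f} mM")
print(f"  NADH sinks: {sum(measured.nadh_consumed.values()):.1f} mM, "
      f"sources: {sum(measured.nadh_produced.values()):.1f} mM "
      f"(deficit {measured.nadh_deficit:.1f} mM)")
print(f"  reduced ferredoxin from pyruvate oxidation: {measured.fd_red_produced:.1f} mM")
print(f"  -> H2 by redox closure: {fb.estimate_h2(net, pathway):.1f} mM")

reference = fb.nadh_ledger(net, pathway, convention="reference")
print(f"\nreference ledger (full sugar conversion): "
      f"{reference.nadh_available:.1f} mM NADH available in total")

print("\nbranch equations (basis = sugar consumed - biomass drain):")
for name, eq in fb.branch_equations(net).items():
    terms = " + ".join(f"{c:.2f} {p}" for p, c in eq.coefficients.items())
    print(f"  1 {name} ({eq.basis_mM:.1f} mM) -> {terms}")

atp = fb.atp_yield(net, pathway)
print(f"\nnet ATP yield: {atp:.2f} mol/mol rhamnose "
      "(uptake -1, rhamnulokinase -1, EMP +2, acid kinases per mol acid)")
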