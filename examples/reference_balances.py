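"""Carbon and electron balances of the three packaged reference cultures.

Loads the endpoint data of C. beijerinckii DSM 6423 batch fermentations on
d-glucose, l-rhamnose, and their mixture, and prints molar yields and the
carbon/electron recoveries with the stoichiometric CO2 estimate and the H2
redox-closure estimate. A recovery near 100% means the measured products,
biomass, and estimated gases account for essentially all consumed substrate
carbon (or electrons); the gap is unmeasured product, gas, or analytical
error.
"""

import fermbalance as fb

for cid in fb.BUILTIN_CULTURE_IDS:
    report = fb.build_report(fb.load_culture(cid))
    bal = report.balance
    print(f"\n=== {cid} culture ===")
    for key, value in sorted(report.yield_table.rounded(3).items()):
        print(f"  yield {key}: {value}")
    print(f"  estimated CO2: {bal.co2_C:.1f} mM")
    print(f"  estimated H2 (redox closure): {bal.h2_estimate:.1f} mM")
    print(f"  carbon recovery:   {bal.carbon_recovery:5.1f} %")
    print(f"  electron recovery: {bal.electron_recovery:5.1f} % "
          f"({bal.electron_recovery_no_h2:.1f} % without H2)")
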