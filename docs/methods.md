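# Methods

This note documents the accounting model, its conventions and parameters,
the synthetic-data generator, and the design choices made where the design
was genuinely open. Numbers quoted here are computed by the test suite and
the examples; nothing is asserted that the code does not reproduce.

## Scope and assumptions

The package performs *endpoint stoichiometric accounting* for anaerobic
batch cultures: given extracellular concentrations (mM) at the start and end
of a fermentation, it closes carbon and electron balances and budgets
cofactors over a declared pathway. It deliberately does **not** fit
kinetics, estimate fluxes by optimization (no FBA/LP), model thermodynamics,
charge balance, or acid speciation, and it does not integrate measured
off-gas data. All concentrations are mM and times are hours throughout; no
unit conversion is attempted.

Key assumptions:

* A compound is a *substrate* over the interval if its final concentration
  is below its initial one, otherwise a *product*. This handles dosed
  acetate cleanly: it is a net substrate in the glucose and mixed cultures
  and a net product (+19.2 mM) in the rhamnose culture. Compounds with zero
  net change are omitted.
* Missing cells are "not measured", never zero. "Not detected" is encoded
  as 0 mM with a below-detection flag preserved through I/O.
* End-of-fermentation is the last time point unless truncated explicitly
  (`FermentationDataset.with_end_time`).

## Degree of reduction and the compound registry

γ = 4C + H − 2O − 3N electrons/mol, the linear rule with CO₂, H₂O and NH₃ as
zero-electron references. γ is linear in element counts, so any reaction
balanced in C/H/O/N conserves total γ — the property test for the balance
machinery. Two registry conventions matter:

* **Acids are undissociated** (acetic acid C₂H₄O₂, butyric C₄H₈O₂, lactic
  C₃H₆O₃, propionic C₃H₆O₂). Only then does the linear rule give the
  conventional fermentation-balance values (acetate 8, butyrate 20, lactate
  12, propionate 14). Charge/pH speciation is out of scope.
* **Biomass is a 5-C-mol unit** C₅H₉O₂.₅N (123.1 g/mol from standard atomic
  weights), i.e. 5 × CH₁.₈O₀.₅N₀.₂, giving 21 e⁻/mol and 5 C-mol/mol. The
  unit size is a modeling choice, not a measurable: it is fixed by requiring
  the conventional "21 electrons per mole" figure (5 × 4.2 e⁻ per C-mol) and
  it reproduces the packaged cultures' biomass concentrations (e.g. OD 11.1
  → 3.24 g/L → 26.3 mM, against the reported 26.6 mM) and their carbon
  recoveries. Users preferring a 1-C-mol basis can pass their own
  `BiomassUnit`.

The registry is user-extensible via YAML (`name: formula` or a mapping with
`formula`, `co2_class`, `role_hint`); unknown compounds raise rather than
being skipped, because a silently dropped column corrupts a recovery.

## CO₂ and biomass conversion

CO₂ is not measured in these fermentations. It is reconstructed per mol of
product from the pathway origin of each compound: 1 CO₂ per acetate or
ethanol (one pyruvate decarboxylation), 2 per butyrate or butanol (two), 3
per acetone or isopropanol (two plus acetoacetate decarboxylation); all
other products (lactate, 1,2-propanediol, propanol, propionate) release
none. Consumed acids never generate CO₂.

Biomass observation routes, in order of preference: a reported endpoint mM
value; a measured cell dry weight (g/L) divided by the 123.1 g/mol unit; an
OD₆₀₀ reading through the linear calibration cdw = 0.28·OD + 0.13 g/L. The
calibration was established on glucose-grown cells and is *not* valid for
rhamnose-grown cultures (different morphology); datasets for such cultures
should carry a measured dry weight or mM value, which always wins.

## H₂ redox closure

H₂ is likewise unmeasured and is estimated by closing the ferredoxin/NADH
budget of the pathway ledger at **measured gross fluxes**: every mol of
product is routed through its full reaction chain (all lactaldehyde-branch
products pass through 1,2-propanediol; butyrate passes both C₄ reduction
steps), NADH sources are glycolytic GAPDH flux plus oxidative steps
(propionaldehyde dehydrogenase), and one reduced ferredoxin arises per
pyruvate oxidized. Ferredoxin not needed to cover the NADH deficit leaves as
H₂:

    H₂ = max(0, Fd_red − (NADH consumed − NADH produced)).

A negative deficit (NADH surplus, e.g. a homoacetate fermentation) adds to
H₂, reproducing the textbook glucose → 2 acetate + 2 CO₂ + 4 H₂. Acetate
consumed from the medium re-enters as acetyl-CoA via the CoA transferase and
offsets glycolysis and pyruvate oxidation 1:1; it carries γ = 8 and 2 C in
the denominators and never generates CO₂. Electron-bifurcating butyryl-CoA
dehydrogenase and NADH-dependent ferredoxin reduction beyond deficit
coverage are deliberately not modeled; this convention closes the rhamnose
culture at 8.2 mM H₂ and an electron recovery of 96%.

For the glucose IBE culture the same closure yields ~161 mM H₂ and an
electron recovery of ~93%, which is *lower* than solvent fermentations
usually report; the H₂ physiology of solventogenic cells (bifurcation,
NADH-fed hydrogenase) is not identified by endpoint data alone. The balance
report therefore always carries three diagnostics instead of one number:
the closure estimate, the recovery without any H₂, and the H₂ that would be
required for 100% closure. The mixed-sugar culture shares this caveat.

## Rounding

Yields are stored at full precision and displayed at two decimals (three
where convention reports three); recoveries are reported both at full
precision and rounded to integer percent. One packaged-data wrinkle: the
mixed-culture carbon recovery computes to 88.7% from the tabulated endpoint
concentrations (themselves rounded to 0.1 mM), so its integer rendering is
89 while the originally reported value is 88; the rhamnose (96) and glucose
(95) columns reproduce exactly. The test suite records this discrepancy
rather than hiding it.

## Pathway ledger conventions

Reactions are declarative (signed species stoichiometry, checked for carbon
balance, plus NADH/Fd_red/ATP coefficients), and each measurable product has
an explicit route — the multiset of reactions it fires per mol. Three ledger
conventions are exposed because endpoint data support several consistent
readings:

* `measured` — all fluxes from measured products (used for H₂ closure).
* `reference` — sources idealized to full sugar conversion: NADH available
  = sugar consumed (glycolytic) + sugar consumed (ferredoxin
  transhydrogenation), i.e. 2 × 46.4 = 92.8 mM for the rhamnose culture;
  sinks stay measured. This reading explains why no solvents appear on
  rhamnose: the diol and C₄ branches absorb essentially the whole supply.
* `biomass-corrected` — branch input = sugar consumed − biomass drain
  (mole-for-mole in 5-C units), the basis of the normalized branch
  equations: 46.4 − 2.1 = 44.3 mM gives 1 lactaldehyde → 0.39
  1,2-propanediol + 0.41 propanol + 0.18 propionate and 1 DHAP → 0.43
  acetate + 0.26 butyrate. The gross ledger reports propanol's NADH
  consumption (18.2 mM) and propionaldehyde oxidation's production (7.8 mM)
  separately rather than netting them.

Further conventions, each a documented switch: isopropanol formation is
charged 1 NADH (no NADPH distinction); propionate phosphorylation is
credited +1 ATP (the moonlighting butyrate-kinase route); microcompartment
shell synthesis costs are not quantified.

**ATP yield.** The `reference` convention prices a mol of sugar as −uptake
− priming kinases + 2 ATP per glycolytic pyruvate at full conversion, plus
1 ATP per mol of acid (acetate, butyrate, propionate) normalized on the
biomass-corrected basis: rhamnose (uptake 1, rhamnulokinase 1, 1 pyruvate
per sugar) gives −1 − 1 + 2 + 38.7/44.3 = 0.87 ≈ 0.9 mol ATP/mol; glucose
(priming 2, 2 pyruvates) gives ≈ 2.0. A `measured` convention (ATP
coefficients over measured fluxes, 0.67 for the rhamnose culture) is
available for sensitivity checks; the difference quantifies how much the
idealized EMP term matters.

## Synthetic-data generator

The generator emulates a batch culture in which products accumulate in fixed
molar proportion to substrate consumed: consumption follows a normalized
logistic curve (midpoint 20 h, rate 0.2 h⁻¹ by default over 56 h, 9
sampling points), biomass grows with a fixed molar yield, and per-substrate
CO₂ and H₂ coefficients are *solved* from the carbon and γ balances of the
declared split, so a noiseless run closes both recoveries at exactly 100%
— splits that cannot close with non-negative CO₂/H₂ are rejected at
specification time. Noise is additive Gaussian per concentration
measurement (HPLC-like), applied to levels rather than deltas; negative
values are clipped to 0 (detection limit) and counted. A seed fixes the
trajectory bit-for-bit.

Defaults mirror the packaged rhamnose bioreactor culture: 243.4 mM initial
rhamnose of which 46.4 mM is consumed, branch splits 0.39/0.41/0.18 and
0.43/0.26, biomass yield 0.045, and 1 mM noise where noise is enabled.

What the generator does *not* emulate — and hence what passing tests do not
show about real data: growth-rate kinetics (no Monod), pH dynamics and
growth cessation, product inhibition, reassimilation dynamics,
heteroscedastic or compound-specific analytical error, and sampling-volume
effects. Tests against it validate the accounting algebra and estimator
behavior under idealized noise, not instrument realism.

**Parameter recovery.** Branch coefficients are recovered by through-origin
least squares of each product's concentration rise against substrate
consumed, pooling all time points — the natural estimator for a
fixed-proportion trajectory, with roughly a third the error of an
endpoint-ratio estimate at these settings. Over 100 replicates at 1 mM
noise the mean absolute error is ~0.01 (asserted < 0.02).

## Numerical choices and degenerate inputs

Tolerances: carbon-balance checks of pathway reactions at 1e-9 C-mol;
generator closure at 1e-9 relative; exact-identity claims (round trips,
regenerated branch products) at 1e-12 relative. Ties: a compound with
exactly zero net change is omitted from the accounting; H₂ closure clamps
at zero rather than reporting negative hydrogen. Degenerate inputs raise
typed errors: empty tables, single-point series, negative concentrations,
non-monotone time, unknown compounds, zero yield denominators, cultures with
no consumed substrate, biomass drain exceeding sugar consumption.

## Problem sizes

All computations are closed-form over at most a dozen compounds; the test
suite's heaviest item is the 2 × 100-replicate parameter-recovery study
(9-point trajectories), and the whole suite plus the acceptance script runs
in a few seconds on one CPU.
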