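"""Carbon recovery, CO2 estimation, H2 redox closure, and electron recovery.

Carbon recovery divides the carbon found in products, biomass and estimated
CO2 by the carbon of the consumed substrates. CO2 is not measured in these
fermentations; it is reconstructed from product stoichiometry: 1 mol CO2 per
mol of acetate or ethanol, 2 per butyrate or butanol, 3 per acetone or
isopropanol (pyruvate decarboxylation plus, for the C3 solvents,
acetoacetate decarboxylation).

Electron recovery does the same with degree-of-reduction weights (gamma,
electrons/mol), with biomass at 21 e-/mol (5-C unit) and H2 at 2 e-/mol.
H2 is likewise not measured; it is estimated by redox closure of the
pathway ledger: pyruvate oxidation produces one reduced ferredoxin per
acetyl-CoA, ferredoxin not needed to cover the ledger's NADH deficit leaves
as H2 via hydrogenase,

    H2 = max(0, Fd_red_produced - (NADH consumed - NADH produced)).

Electron-bifurcating butyryl-CoA dehydrogenase is deliberately not modeled;
the ferredoxin pool sees only pyruvate oxidation and transhydrogenation.
CO2 carries zero electrons, so electron recovery is independent of the CO2
estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from .accounting import NetChangeTable
from .compounds import BIOMASS_UNIT, BiomassUnit, Registry, default_registry
from .pathway import Pathway, nadh_ledger

__all__ = [
    "BalanceReport",
    "estimate_co2",
    "carbon_recovery",
    "estimate_h2",
    "electron_recovery",
    "balance_report",
]


class BalanceError(ValueError):
    """Raised when a recovery is undefined (e.g. no consumed substrate)."""


def estimate_co2(net: NetChangeTable, registry: Registry | None = None) -> float:
    """Estimated CO2 release (mM) from the per-product CO2 classes.

    Only compounds with role=product contribute; a consumed acid never
    generates CO2.
    """
    registry = registry or default_registry()
    return sum(
        registry.co2_per_mole(name) * amount for name, amount in net.products.items()
    )


def _carbon_terms(
    net: NetChangeTable,
    biomass_mM: float,
    registry: Registry,
    unit: BiomassUnit,
    co2_mM: float | None,
):
    if co2_mM is None:
        co2_mM = estimate_co2(net, registry)
    substrate_C = sum(registry.carbon(n) * a for n, a in net.substrates.items())
    product_terms = {n: registry.carbon(n) * a for n, a in net.products.items()}
    biomass_C = unit.carbon * biomass_mM
    product_C = sum(product_terms.values()) + biomass_C + co2_mM
    return substrate_C, product_C, product_terms, biomass_C, co2_mM


def carbon_recovery(
    net: NetChangeTable,
    biomass_mM: float | None = None,
    registry: Registry | None = None,
    *,
    co2_mM: float | None = None,
    biomass_unit: BiomassUnit = BIOMASS_UNIT,
) -> float:
    """Percent of substrate carbon recovered in products + biomass + CO2.

    ``co2_mM`` overrides the stoichiometric CO2 estimate (e.g. with a
    measured or simulated value).
    """
    registry = registry or default_registry()
    if biomass_mM is None:
        biomass_mM = net.biomass_produced
    substrate_C, product_C, *_ = _carbon_terms(net, biomass_mM, registry, biomass_unit, co2_mM)
    if substrate_C <= 0:
        raise BalanceError(f"{net.culture_id}: no consumed substrate carbon")
    return 100.0 * product_C / substrate_C


def estimate_h2(net: NetChangeTable, pathway: Pathway) -> float:
    """H2 (mM) from ferredoxin/NADH redox closure of the measured fluxes."""
    ledger = nadh_ledger(net, pathway, convention="measured")
    return max(0.0, ledger.fd_red_produced - ledger.nadh_deficit)


def electron_recovery(
    net: NetChangeTable,
    biomass_mM: float | None = None,
    h2_mM: float = 0.0,
    registry: Registry | None = None,
    *,
    biomass_unit: BiomassUnit = BIOMASS_UNIT,
) -> float:
    """Percent of substrate electrons recovered in gamma-weighted products.

    Numerator: gamma-weighted products + 21 e-/mol biomass + 2 e-/mol H2.
    Denominator: gamma-weighted consumed substrates.
    """
    registry = registry or default_registry()
    if biomass_mM is None:
        biomass_mM = net.biomass_produced
    substrate_e = sum(registry.gamma(n) * a for n, a in net.substrates.items())
    if substrate_e <= 0:
        raise BalanceError(f"{net.culture_id}: no consumed substrate electrons")
    product_e = (
        sum(registry.gamma(n) * a for n, a in net.products.items())
        + biomass_unit.gamma * biomass_mM
        + 2.0 * h2_mM
    )
    return 100.0 * product_e / substrate_e


@dataclass(frozen=True)
class BalanceReport:
    """All terms of the carbon and electron balance for one culture."""

    culture_id: str
    substrate_C: float  # C-mmol/L consumed
    product_C: float  # C-mmol/L recovered incl. biomass and CO2
    co2_C: float
    biomass_C: float
    carbon_recovery: float  # %
    substrate_e: float  # e-mmol/L consumed
    product_e: float  # e-mmol/L recovered incl. biomass and H2
    h2_estimate: float  # mM, redox closure
    h2_for_full_closure: float  # mM H2 that would close electrons to 100%
    electron_recovery: float  # % with the closure H2
    electron_recovery_no_h2: float  # % ignoring H2
    carbon_terms: Mapping[str, float] = field(default_factory=dict)
    electron_terms: Mapping[str, float] = field(default_factory=dict)

    def as_dict(self) -> dict:
        d = {
            "culture_id": self.culture_id,
            "substrate_C_mmol_per_L": self.substrate_C,
            "product_C_mmol_per_L": self.product_C,
            "co2_C_mmol_per_L": self.co2_C,
            "biomass_C_mmol_per_L": self.biomass_C,
            "carbon_recovery_pct": self.carbon_recovery,
            "carbon_recovery_pct_rounded": round(self.carbon_recovery),
            "substrate_e_mmol_per_L": self.substrate_e,
            "product_e_mmol_per_L": self.product_e,
            "h2_estimate_mM": self.h2_estimate,
            "h2_for_full_closure_mM": self.h2_for_full_closure,
            "electron_recovery_pct": self.electron_recovery,
            "electron_recovery_pct_rounded": round(self.electron_recovery),
            "electron_recovery_no_h2_pct": self.electron_recovery_no_h2,
            "carbon_terms_mmol_per_L": dict(self.carbon_terms),
            "electron_terms_mmol_per_L": dict(self.electron_terms),
        }
        return d


def balance_report(
    net: NetChangeTable,
    pathway: Pathway | None = None,
    registry: Registry | None = None,
    *,
    biomass_mM: float | None = None,
    co2_mM: float | None = None,
    h2_mM: float | None = None,
    biomass_unit: BiomassUnit = BIOMASS_UNIT,
) -> BalanceReport:
    """Full carbon/electron balance with every intermediate term.

    ``h2_mM`` defaults to the pathway redox closure (0 if no pathway is
    given); ``co2_mM`` defaults to the stoichiometric estimate. The report
    also carries the H2 that *would* be needed to close the electron balance
    at 100%, a useful diagnostic when the closure convention under-predicts
    hydrogen for a culture.
    """
    registry = registry or default_registry()
    if biomass_mM is None:
        biomass_mM = net.biomass_produced
    substrate_C, product_C, c_terms, biomass_C, co2_used = _carbon_terms(
        net, biomass_mM, registry, biomass_unit, co2_mM
    )
    if substrate_C <= 0:
        raise BalanceError(f"{net.culture_id}: no consumed substrate carbon")
    if h2_mM is None:
        h2_mM = estimate_h2(net, pathway) if pathway is not None else 0.0
    substrate_e = sum(registry.gamma(n) * a for n, a in net.substrates.items())
    e_terms = {n: registry.gamma(n) * a for n, a in net.products.items()}
    product_e_no_h2 = sum(e_terms.values()) + biomass_unit.gamma * biomass_mM
    h2_full = max(0.0, (substrate_e - product_e_no_h2) / 2.0)
    return BalanceReport(
        culture_id=net.culture_id,
        substrate_C=substrate_C,
        product_C=product_C,
        co2_C=co2_used,
        biomass_C=biomass_C,
        carbon_recovery=100.0 * product_C / substrate_C,
        substrate_e=substrate_e,
        product_e=product_e_no_h2 + 2.0 * h2_mM,
        h2_estimate=h2_mM,
        h2_for_full_closure=h2_full,
        electron_recovery=100.0 * (product_e_no_h2 + 2.0 * h2_mM) / substrate_e,
        electron_recovery_no_h2=100.0 * product_e_no_h2 / substrate_e,
        carbon_terms={**c_terms, "biomass": biomass_C, "CO2": co2_used},
        electron_terms={**e_terms, "biomass": biomass_unit.gamma * biomass_mM, "H2": 2.0 * h2_mM},
    )
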