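"""Stoichiometric cofactor ledger over reconstructed fermentation pathways.

The ledger maps measured net product amounts back onto the reactions of a
declared pathway and totals the cofactor turnover (NADH, reduced ferredoxin,
ATP) those fluxes imply. Two pathways ship with the package:

``rhamnose``
    L-rhamnose is isomerized, phosphorylated (rhamnulokinase, 1 ATP) and
    split by the aldolase into lactaldehyde and dihydroxyacetone phosphate
    (DHAP). The *lactaldehyde branch* reduces lactaldehyde to
    1,2-propanediol (1 NADH), which a B12-independent diol dehydratase
    converts to propionaldehyde inside a bacterial microcompartment;
    propionaldehyde is either reduced to n-propanol (1 NADH) or oxidized to
    propionyl-CoA (yields 1 NADH) and phosphorylated to propionate (1 ATP,
    via a moonlighting butyrate kinase). The *DHAP branch* runs the lower
    EMP pathway to pyruvate (1 NADH, 2 ATP), then
    pyruvate:ferredoxin-oxidoreductase to acetyl-CoA (1 reduced ferredoxin,
    1 CO2), ending in acetate (1 ATP) or butyrate (2 acetyl-CoA, 2 NADH,
    1 ATP).

``glucose``
    The IBE (isopropanol/butanol/ethanol) fermentation: upper glycolysis
    (2 ATP invested), lower EMP per triose, pyruvate to acetyl-CoA or
    lactate, and the solventogenic branches (ethanol 2 NADH, butanol 4 NADH
    per mol, isopropanol 1 NADH after acetoacetate decarboxylation).
    Acetate taken up from the medium re-enters as acetyl-CoA through the
    CoA transferase and offsets pyruvate oxidation 1:1.

Ledger conventions
------------------
``measured``
    All fluxes derive from measured net product amounts (gross routing: a
    mol of propanol counts the NADH of the 1,2-propanediol it passed
    through). This is the convention behind the H2 redox-closure estimate.
``reference``
    Sources are idealized to full sugar conversion (1 DHAP and 1
    lactaldehyde per rhamnose): NADH available = sugar consumed (glycolytic)
    + sugar consumed (ferredoxin transhydrogenation). Sinks stay measured.
``biomass-corrected``
    Like ``reference`` but the branch input is sugar consumed minus the
    biomass drain (in 5-C units), the basis used for the normalized branch
    equations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import yaml

from .accounting import NetChangeTable
from .compounds import Registry, default_registry, normalize_name

__all__ = [
    "Reaction",
    "Pathway",
    "PathwayLedger",
    "BranchEquation",
    "builtin_pathway",
    "branch_equations",
    "nadh_ledger",
    "atp_yield",
    "BUILTIN_PATHWAY_IDS",
]

# carbon counts of pathway intermediates not tracked in the compound registry
_INTERMEDIATE_C: dict[str, float] = {
    "rhamnulose": 6,
    "rhamnulose-1P": 6,
    "lactaldehyde": 3,
    "DHAP": 3,
    "triose-P": 3,
    "pyruvate": 3,
    "acetyl-CoA": 2,
    "acetoacetyl-CoA": 4,
    "acetoacetate": 4,
    "3-hydroxybutyryl-CoA": 4,
    "crotonyl-CoA": 4,
    "butyryl-CoA": 4,
    "butyraldehyde": 4,
    "propionaldehyde": 3,
    "propionyl-CoA": 3,
}


class PathwayError(ValueError):
    """Raised for ill-formed pathway definitions or inapplicable ledgers."""


@dataclass(frozen=True)
class Reaction:
    """One pathway step: signed species stoichiometry plus cofactor turnover.

    ``stoichiometry`` maps carbon species (registry compounds or
    intermediates) to signed coefficients; ``cofactors`` maps
    NADH / Fd_red / ATP to signed coefficients (positive = produced).
    """

    name: str
    stoichiometry: Mapping[str, float]
    cofactors: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for k, v in {**self.stoichiometry, **self.cofactors}.items():
            if not math.isfinite(v):
                raise PathwayError(f"{self.name}: non-finite coefficient for {k}")
        bad = set(self.cofactors) - {"NADH", "Fd_red", "ATP"}
        if bad:
            raise PathwayError(f"{self.name}: unknown cofactors {sorted(bad)}")

    def carbon_imbalance(self, registry: Registry) -> float:
        total = 0.0
        for species, coeff in self.stoichiometry.items():
            if species in _INTERMEDIATE_C:
                c = _INTERMEDIATE_C[species]
            elif species == "H2O":
                c = 0.0
            else:
                c = registry.carbon(species)
            total += coeff * c
        return total

    def check_carbon_balance(self, registry: Registry, tol: float = 1e-9) -> None:
        imbalance = self.carbon_imbalance(registry)
        if abs(imbalance) > tol:
            raise PathwayError(f"{self.name}: carbon imbalance of {imbalance} C-mol")


@dataclass(frozen=True)
class Pathway:
    """A reaction set plus per-product routes and per-sugar constants.

    ``routes`` gives, for each measurable end product, the multiplicity with
    which each reaction fires per mol of product (counted from the branch
    entry points; sugar uptake/priming steps are per-sugar, not per-product).
    """

    name: str
    sugar: str
    reactions: tuple[Reaction, ...]
    routes: Mapping[str, Mapping[str, float]]
    uptake_atp: float  # ATP per mol sugar imported
    priming_atp: float  # ATP invested in kinase steps per mol sugar
    pyruvate_per_sugar: float  # glycolytic pyruvate at full conversion
    lactaldehyde_products: frozenset = frozenset()
    acetate_reassimilation: bool = True

    def __post_init__(self) -> None:
        names = {r.name for r in self.reactions}
        for product, route in self.routes.items():
            missing = set(route) - names
            if missing:
                raise PathwayError(f"route for {product} uses unknown reactions {sorted(missing)}")

    def reaction(self, name: str) -> Reaction:
        for r in self.reactions:
            if r.name == name:
                return r
        raise PathwayError(f"no reaction named {name!r}")

    def check(self, registry: Registry | None = None) -> "Pathway":
        registry = registry or default_registry()
        for r in self.reactions:
            r.check_carbon_balance(registry)
        return self

    def fluxes(self, net: NetChangeTable) -> dict[str, float]:
        """Reaction flux (mM) implied by the measured net product amounts."""
        flux: dict[str, float] = {r.name: 0.0 for r in self.reactions}
        for product, amount in net.products.items():
            route = self.routes.get(product)
            if route is None:
                continue
            for rxn, mult in route.items():
                flux[rxn] += mult * amount
        if self.acetate_reassimilation:
            # acetate consumed from the medium re-enters as acetyl-CoA via the
            # CoA transferase, displacing glycolysis and pyruvate oxidation 1:1
            credit = net.amount("acetate", "substrate")
            for rxn in ("pyruvate_oxidation", "emp_lower"):
                if rxn in flux:
                    flux[rxn] = max(0.0, flux[rxn] - credit)
        return flux


@dataclass(frozen=True)
class PathwayLedger:
    """Cofactor totals (mM) implied by a culture's product profile."""

    pathway: str
    convention: str
    sugar_consumed: float
    dhap_mM: float  # DHAP-branch input (glycolytic C3 units)
    lactaldehyde_mM: float  # lactaldehyde-branch input
    nadh_produced: Mapping[str, float]  # by source
    nadh_consumed: Mapping[str, float]  # by sink
    fd_red_produced: float
    atp_produced: Mapping[str, float]
    atp_consumed: Mapping[str, float]

    @property
    def nadh_available(self) -> float:
        """Total NADH supply, counting full ferredoxin->NAD transhydrogenation."""
        return sum(self.nadh_produced.values()) + self.fd_red_produced

    @property
    def nadh_deficit(self) -> float:
        """NADH sinks minus non-ferredoxin NADH sources (may be negative)."""
        return sum(self.nadh_consumed.values()) - sum(self.nadh_produced.values())

    @property
    def atp_net(self) -> float:
        return sum(self.atp_produced.values()) - sum(self.atp_consumed.values())

    def as_dict(self) -> dict:
        return {
            "pathway": self.pathway,
            "convention": self.convention,
            "sugar_consumed_mM": self.sugar_consumed,
            "dhap_mM": self.dhap_mM,
            "lactaldehyde_mM": self.lactaldehyde_mM,
            "nadh_produced_mM": dict(self.nadh_produced),
            "nadh_consumed_mM": dict(self.nadh_consumed),
            "nadh_available_mM": self.nadh_available,
            "nadh_deficit_mM": self.nadh_deficit,
            "fd_red_produced_mM": self.fd_red_produced,
            "atp_produced_mM": dict(self.atp_produced),
            "atp_consumed_mM": dict(self.atp_consumed),
            "atp_net_mM": self.atp_net,
        }


@dataclass(frozen=True)
class BranchEquation:
    """Products formed per 1 mol of branch input (lactaldehyde or DHAP)."""

    basis: str
    basis_mM: float
    coefficients: Mapping[str, float]

    def regenerate(self) -> dict[str, float]:
        """Forward application: coefficient * basis = product amount (mM)."""
        return {p: c * self.basis_mM for p, c in self.coefficients.items()}

    def as_dict(self) -> dict:
        return {
            "basis": self.basis,
            "basis_mM": self.basis_mM,
            "coefficients": dict(self.coefficients),
        }


def _rhamnose_pathway() -> Pathway:
    rxns = (
        Reaction("rhamnose_uptake", {"rhamnose": -1, "rhamnulose": 1}, {"ATP": -1}),
        Reaction("rhamnulokinase", {"rhamnulose": -1, "rhamnulose-1P": 1}, {"ATP": -1}),
        Reaction("aldolase", {"rhamnulose-1P": -1, "lactaldehyde": 1, "DHAP": 1}),
        Reaction("pdo_oxidoreductase", {"lactaldehyde": -1, "1,2-propanediol": 1}, {"NADH": -1}),
        Reaction("pdo_dehydratase", {"1,2-propanediol": -1, "propionaldehyde": 1, "H2O": 1}),
        Reaction("propanol_dehydrogenase", {"propionaldehyde": -1, "propanol": 1}, {"NADH": -1}),
        Reaction(
            "propionaldehyde_dehydrogenase",
            {"propionaldehyde": -1, "propionyl-CoA": 1},
            {"NADH": 1},
        ),
        Reaction("propionate_kinase", {"propionyl-CoA": -1, "propionate": 1}, {"ATP": 1}),
        Reaction("emp_lower", {"DHAP": -1, "pyruvate": 1}, {"NADH": 1, "ATP": 2}),
        Reaction(
            "pyruvate_oxidation",
            {"pyruvate": -1, "acetyl-CoA": 1, "CO2": 1},
            {"Fd_red": 1},
        ),
        Reaction("acetate_kinase", {"acetyl-CoA": -1, "acetate": 1}, {"ATP": 1}),
        Reaction("thiolase", {"acetyl-CoA": -2, "acetoacetyl-CoA": 1}),
        Reaction(
            "hydroxybutyryl_dehydrogenase",
            {"acetoacetyl-CoA": -1, "3-hydroxybutyryl-CoA": 1},
            {"NADH": -1},
        ),
        Reaction("crotonase", {"3-hydroxybutyryl-CoA": -1, "crotonyl-CoA": 1, "H2O": 1}),
        Reaction(
            "butyryl_dehydrogenase", {"crotonyl-CoA": -1, "butyryl-CoA": 1}, {"NADH": -1}
        ),
        Reaction("butyrate_kinase", {"butyryl-CoA": -1, "butyrate": 1}, {"ATP": 1}),
    )
    routes = {
        "1,2-propanediol": {"pdo_oxidoreductase": 1},
        "propanol": {"pdo_oxidoreductase": 1, "pdo_dehydratase": 1, "propanol_dehydrogenase": 1},
        "propionate": {
            "pdo_oxidoreductase": 1,
            "pdo_dehydratase": 1,
            "propionaldehyde_dehydrogenase": 1,
            "propionate_kinase": 1,
        },
        "acetate": {"emp_lower": 1, "pyruvate_oxidation": 1, "acetate_kinase": 1},
        "butyrate": {
            "emp_lower": 2,
            "pyruvate_oxidation": 2,
            "thiolase": 1,
            "hydroxybutyryl_dehydrogenase": 1,
            "crotonase": 1,
            "butyryl_dehydrogenase": 1,
            "butyrate_kinase": 1,
        },
    }
    return Pathway(
        name="rhamnose",
        sugar="rhamnose",
        reactions=rxns,
        routes=routes,
        uptake_atp=1.0,  # 1 ATP per mol sugar assumed for rhamnose import
        priming_atp=1.0,  # rhamnulokinase
        pyruvate_per_sugar=1.0,  # one DHAP per rhamnose at full conversion
        lactaldehyde_products=frozenset({"1,2-propanediol", "propanol", "propionate"}),
    )


def _glucose_pathway() -> Pathway:
    rxns = (
        Reaction("glycolysis_upper", {"glucose": -1, "triose-P": 2}, {"ATP": -2}),
        Reaction("emp_lower", {"triose-P": -1, "pyruvate": 1}, {"NADH": 1, "ATP": 2}),
        Reaction("lactate_dehydrogenase", {"pyruvate": -1, "lactate": 1}, {"NADH": -1}),
        Reaction(
            "pyruvate_oxidation",
            {"pyruvate": -1, "acetyl-CoA": 1, "CO2": 1},
            {"Fd_red": 1},
        ),
        Reaction("acetate_kinase", {"acetyl-CoA": -1, "acetate": 1}, {"ATP": 1}),
        Reaction(
            "ethanol_dehydrogenase", {"acetyl-CoA": -1, "ethanol": 1}, {"NADH": -2}
        ),
        Reaction("thiolase", {"acetyl-CoA": -2, "acetoacetyl-CoA": 1}),
        Reaction(
            "hydroxybutyryl_dehydrogenase",
            {"acetoacetyl-CoA": -1, "3-hydroxybutyryl-CoA": 1},
            {"NADH": -1},
        ),
        Reaction("crotonase", {"3-hydroxybutyryl-CoA": -1, "crotonyl-CoA": 1, "H2O": 1}),
        Reaction(
            "butyryl_dehydrogenase", {"crotonyl-CoA": -1, "butyryl-CoA": 1}, {"NADH": -1}
        ),
        Reaction("butyrate_kinase", {"butyryl-CoA": -1, "butyrate": 1}, {"ATP": 1}),
        Reaction(
            "butanol_dehydrogenase", {"butyryl-CoA": -1, "butanol": 1}, {"NADH": -2}
        ),
        Reaction("coa_transferase", {"acetoacetyl-CoA": -1, "acetoacetate": 1}),
        Reaction(
            "acetoacetate_decarboxylase", {"acetoacetate": -1, "acetone": 1, "CO2": 1}
        ),
        Reaction(
            "isopropanol_dehydrogenase", {"acetone": -1, "isopropanol": 1}, {"NADH": -1}
        ),
    )
    c4 = {
        "emp_lower": 2,
        "pyruvate_oxidation": 2,
        "thiolase": 1,
        "hydroxybutyryl_dehydrogenase": 1,
        "crotonase": 1,
        "butyryl_dehydrogenase": 1,
    }
    acetone_route = {
        "emp_lower": 2,
        "pyruvate_oxidation": 2,
        "thiolase": 1,
        "coa_transferase": 1,
        "acetoacetate_decarboxylase": 1,
    }
    routes = {
        "lactate": {"emp_lower": 1, "lactate_dehydrogenase": 1},
        "acetate": {"emp_lower": 1, "pyruvate_oxidation": 1, "acetate_kinase": 1},
        "ethanol": {"emp_lower": 1, "pyruvate_oxidation": 1, "ethanol_dehydrogenase": 1},
        "butyrate": {**c4, "butyrate_kinase": 1},
        "butanol": {**c4, "butanol_dehydrogenase": 1},
        "acetone": acetone_route,
        "isopropanol": {**acetone_route, "isopropanol_dehydrogenase": 1},
    }
    return Pathway(
        name="glucose",
        sugar="glucose",
        reactions=rxns,
        routes=routes,
        uptake_atp=0.0,
        priming_atp=2.0,  # hexokinase + phosphofructokinase
        pyruvate_per_sugar=2.0,
        lactaldehyde_products=frozenset(),
    )


_BUILTINS = {"rhamnose": _rhamnose_pathway, "glucose": _glucose_pathway}
BUILTIN_PATHWAY_IDS = tuple(_BUILTINS)


def builtin_pathway(name: str, registry: Registry | None = None) -> Pathway:
    """A packaged, carbon-checked pathway definition (``rhamnose`` or ``glucose``)."""
    if name not in _BUILTINS:
        raise PathwayError(f"unknown pathway {name!r}; choose from {sorted(_BUILTINS)}")
    return _BUILTINS[name]().check(registry)


def pathway_from_yaml(path, registry: Registry | None = None) -> Pathway:
    """Load a user pathway definition (same structure as the built-ins)."""
    with open(path) as fh:
        spec = yaml.safe_load(fh)
    rxns = tuple(
        Reaction(
            name=r["name"],
            stoichiometry={k: float(v) for k, v in r.get("stoichiometry", {}).items()},
            cofactors={k: float(v) for k, v in r.get("cofactors", {}).items()},
        )
        for r in spec["reactions"]
    )
    return Pathway(
        name=spec["name"],
        sugar=normalize_name(spec["sugar"]),
        reactions=rxns,
        routes={normalize_name(p): dict(r) for p, r in spec["routes"].items()},
        uptake_atp=float(spec.get("uptake_atp", 0.0)),
        priming_atp=float(spec.get("priming_atp", 0.0)),
        pyruvate_per_sugar=float(spec.get("pyruvate_per_sugar", 1.0)),
        lactaldehyde_products=frozenset(
            normalize_name(p) for p in spec.get("lactaldehyde_products", [])
        ),
        acetate_reassimilation=bool(spec.get("acetate_reassimilation", True)),
    ).check(registry)


def _cofactor_totals(pathway: Pathway, flux: Mapping[str, float]):
    nadh_prod: dict[str, float] = {}
    nadh_cons: dict[str, float] = {}
    atp_prod: dict[str, float] = {}
    atp_cons: dict[str, float] = {}
    fd = 0.0
    for rxn in pathway.reactions:
        f = flux.get(rxn.name, 0.0)
        if f == 0.0:
            continue
        nadh = rxn.cofactors.get("NADH", 0.0) * f
        atp = rxn.cofactors.get("ATP", 0.0) * f
        fd += rxn.cofactors.get("Fd_red", 0.0) * f
        if nadh > 0:
            nadh_prod[rxn.name] = nadh_prod.get(rxn.name, 0.0) + nadh
        elif nadh < 0:
            nadh_cons[rxn.name] = nadh_cons.get(rxn.name, 0.0) - nadh
        if atp > 0:
            atp_prod[rxn.name] = atp_prod.get(rxn.name, 0.0) + atp
        elif atp < 0:
            atp_cons[rxn.name] = atp_cons.get(rxn.name, 0.0) - atp
    return nadh_prod, nadh_cons, atp_prod, atp_cons, fd


def nadh_ledger(
    net: NetChangeTable,
    pathway: Pathway,
    *,
    convention: str = "measured",
) -> PathwayLedger:
    """Cofactor ledger for a culture under one of the three conventions."""
    if convention not in ("measured", "reference", "biomass-corrected"):
        raise PathwayError(f"unknown ledger convention {convention!r}")
    sugar_consumed = net.amount(pathway.sugar, "substrate")
    flux = pathway.fluxes(net)
    nadh_prod, nadh_cons, atp_prod, atp_cons, fd = _cofactor_totals(pathway, flux)
    lact = sum(net.products.get(p, 0.0) for p in pathway.lactaldehyde_products)
    dhap = flux.get("emp_lower", 0.0)

    if convention in ("reference", "biomass-corrected"):
        # idealized sources: full conversion of sugar into branch inputs
        basis = sugar_consumed
        if convention == "biomass-corrected":
            basis = sugar_consumed - net.biomass_produced
        dhap = basis * pathway.pyruvate_per_sugar
        lact = basis if pathway.lactaldehyde_products else 0.0
        # idealized NADH supply: glycolysis plus full Fd->NAD transfer only
        nadh_prod = {"emp_lower": dhap}  # 1 NADH per glycolytic C3 unit
        fd = dhap  # 1 Fd_red per pyruvate oxidized

    # per-sugar uptake/priming ATP costs
    if sugar_consumed > 0:
        if pathway.uptake_atp:
            atp_cons["uptake"] = atp_cons.get("uptake", 0.0) + pathway.uptake_atp * sugar_consumed
        if pathway.priming_atp:
            atp_cons["priming_kinases"] = (
                atp_cons.get("priming_kinases", 0.0) + pathway.priming_atp * sugar_consumed
            )

    return PathwayLedger(
        pathway=pathway.name,
        convention=convention,
        sugar_consumed=sugar_consumed,
        dhap_mM=dhap,
        lactaldehyde_mM=lact,
        nadh_produced=nadh_prod,
        nadh_consumed=nadh_cons,
        fd_red_produced=fd,
        atp_produced=atp_prod,
        atp_consumed=atp_cons,
    )


def branch_equations(
    net: NetChangeTable,
    biomass_mM: float | None = None,
    *,
    pathway: Pathway | None = None,
) -> dict[str, BranchEquation]:
    """Normalized branch equations on the biomass-corrected basis.

    The basis is sugar consumed minus the biomass drain (mM of 5-C units):
    each mol of sugar that is not incorporated into cells delivers one
    lactaldehyde and one DHAP, so each product coefficient is its net amount
    divided by that basis.
    """
    pathway = pathway or builtin_pathway("rhamnose")
    sugar = net.amount(pathway.sugar, "substrate")
    if sugar <= 0:
        raise PathwayError(f"{pathway.sugar} was not consumed; no branch basis")
    if biomass_mM is None:
        biomass_mM = net.biomass_produced
    basis = sugar - biomass_mM
    if basis <= 0:
        raise PathwayError("biomass drain exceeds sugar consumption; zero branch basis")
    lact_products = pathway.lactaldehyde_products
    dhap_products = [p for p in pathway.routes if p not in lact_products]
    lact_eq = BranchEquation(
        basis="lactaldehyde",
        basis_mM=basis,
        coefficients={
            p: net.products.get(p, 0.0) / basis
            for p in sorted(lact_products)
            if net.products.get(p, 0.0) > 0
        },
    )
    dhap_eq = BranchEquation(
        basis="DHAP",
        basis_mM=basis,
        coefficients={
            p: net.products.get(p, 0.0) / basis
            for p in sorted(dhap_products)
            if net.products.get(p, 0.0) > 0
        },
    )
    return {"lactaldehyde": lact_eq, "DHAP": dhap_eq}


# acid products whose kinase step yields 1 ATP/mol
_ACID_KINASE_PRODUCTS = ("acetate", "butyrate", "propionate")


def atp_yield(
    net: NetChangeTable,
    pathway: Pathway,
    *,
    biomass_mM: float | None = None,
    convention: str = "reference",
) -> float:
    """Net mol ATP per mol sugar consumed.

    ``reference`` (default): uptake and priming costs plus 2 ATP of
    substrate-level phosphorylation per glycolytic pyruvate at full sugar
    conversion, plus 1 ATP per mol of acid formed, with acid amounts
    normalized on the biomass-corrected branch basis. ``measured`` totals the
    ATP coefficients over the fluxes implied by the measured products.
    """
    sugar = net.amount(pathway.sugar, "substrate")
    if sugar <= 0:
        raise PathwayError(f"{pathway.sugar} was not consumed; ATP yield undefined")
    if convention == "measured":
        ledger = nadh_ledger(net, pathway, convention="measured")
        return ledger.atp_net / sugar
    if convention != "reference":
        raise PathwayError(f"unknown ATP convention {convention!r}")
    if biomass_mM is None:
        biomass_mM = net.biomass_produced
    basis = sugar - biomass_mM
    if basis <= 0:
        raise PathwayError("biomass drain exceeds sugar consumption")
    acid_atp = sum(net.products.get(p, 0.0) for p in _ACID_KINASE_PRODUCTS) / basis
    return (
        -pathway.uptake_atp
        - pathway.priming_atp
        + 2.0 * pathway.pyruvate_per_sugar
        + acid_atp
    )
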