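"""Net consumption/production accounting and molar yields.

Between the first and last time point of a culture, every compound with a
nonzero concentration change is assigned exactly one role: *substrate* if
its final concentration is below the initial one, *product* otherwise. This
convention matters for acetate, which is typically dosed in the medium and
can end up on either side of the balance depending on the culture.

Biomass is converted to mM of 5-carbon formula units (C5H9O2.5N). Three
observation routes are supported, in order of preference: a directly
reported endpoint biomass concentration, an endpoint cell dry weight (g/L),
or an OD600 reading through the linear calibration

    cdw [g/L] = 0.28 * OD600 + 0.13

which was established for d-glucose-grown cells and must not be applied to
cultures with a different morphology (rhamnose-grown cells); those should
carry a measured dry weight instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping

import pandas as pd

from .compounds import BIOMASS_UNIT, BiomassUnit, normalize_name
from .dataset import FermentationDataset, ValidationError

__all__ = [
    "NetChange",
    "NetChangeTable",
    "YieldTable",
    "net_changes",
    "biomass_from_od",
    "biomass_millimolar",
    "resolve_biomass_mM",
    "yields",
]

OD_SLOPE = 0.28  # g cdw per L per OD600 unit, d-glucose calibration
OD_INTERCEPT = 0.13  # g/L

Role = Literal["substrate", "product"]


@dataclass(frozen=True)
class NetChange:
    compound: str
    net_amount: float  # mM, always >= 0
    role: Role


@dataclass(frozen=True)
class NetChangeTable:
    """Per-compound net amounts between t0 and t_end, with role assignment."""

    culture_id: str
    entries: tuple[NetChange, ...]
    biomass_produced: float = 0.0  # mM of 5-C units
    reference_substrates: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        names = [e.compound for e in self.entries]
        if len(names) != len(set(names)):
            raise ValidationError("a compound may appear with exactly one role")

    def amount(self, compound: str, role: Role | None = None) -> float:
        key = normalize_name(compound)
        for e in self.entries:
            if e.compound == key and (role is None or e.role == role):
                return e.net_amount
        return 0.0

    def by_role(self, role: Role) -> dict[str, float]:
        return {e.compound: e.net_amount for e in self.entries if e.role == role}

    @property
    def substrates(self) -> dict[str, float]:
        return self.by_role("substrate")

    @property
    def products(self) -> dict[str, float]:
        return self.by_role("product")

    def scaled(self, factor: float) -> "NetChangeTable":
        return NetChangeTable(
            culture_id=self.culture_id,
            entries=tuple(
                NetChange(e.compound, e.net_amount * factor, e.role) for e in self.entries
            ),
            biomass_produced=self.biomass_produced * factor,
            reference_substrates=self.reference_substrates,
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"compound": e.compound, "net_mM": e.net_amount, "role": e.role}
            for e in self.entries
        ]
        rows.append(
            {"compound": "biomass", "net_mM": self.biomass_produced, "role": "product"}
        )
        return pd.DataFrame(rows)


def biomass_from_od(od600: float) -> float:
    """Cell dry weight (g/L) from OD600 via the d-glucose calibration line."""
    if od600 < 0:
        raise ValueError(f"OD600 must be non-negative, got {od600}")
    return OD_SLOPE * od600 + OD_INTERCEPT


def biomass_millimolar(cdw: float, unit: BiomassUnit = BIOMASS_UNIT) -> float:
    """mM of biomass formula units from a dry weight in g/L."""
    if cdw < 0:
        raise ValueError(f"cdw must be non-negative, got {cdw}")
    return cdw / unit.molar_mass * 1000.0


def resolve_biomass_mM(
    dataset: FermentationDataset, unit: BiomassUnit = BIOMASS_UNIT
) -> float:
    """Endpoint biomass in mM of 5-C units, using the best available observation.

    Preference order: reported biomass_end_mM > measured cdw_end > OD600
    calibration (d-glucose cultures only; the caller is trusted on
    applicability when only OD is available).
    """
    if dataset.biomass_end_mM is not None:
        return float(dataset.biomass_end_mM)
    if dataset.cdw_end is not None:
        return biomass_millimolar(dataset.cdw_end, unit)
    if dataset.od600 is not None and len(dataset.od600) > 0:
        return biomass_millimolar(biomass_from_od(float(dataset.od600.iloc[-1])), unit)
    return 0.0


def net_changes(
    dataset: FermentationDataset,
    *,
    biomass_unit: BiomassUnit = BIOMASS_UNIT,
    atol: float = 0.0,
) -> NetChangeTable:
    """Fold end-minus-start concentration deltas into (net_amount, role) entries.

    Compounds whose |delta| <= ``atol`` (default: exactly zero) are omitted.
    A compound series needs at least two measured values.
    """
    entries: list[NetChange] = []
    for name in dataset.compounds:
        series = dataset.concentrations[name].dropna()
        if series.empty:
            continue
        if len(series) < 2:
            raise ValidationError(
                f"{dataset.culture_id}:{name}: a single time point cannot define a net change"
            )
        delta = float(series.iloc[-1] - series.iloc[0])
        if abs(delta) <= atol:
            continue
        role: Role = "substrate" if delta < 0 else "product"
        entries.append(NetChange(compound=name, net_amount=abs(delta), role=role))
    return NetChangeTable(
        culture_id=dataset.culture_id,
        entries=tuple(entries),
        biomass_produced=resolve_biomass_mM(dataset, biomass_unit),
        reference_substrates=tuple(sorted(dataset.substrate_labels)),
    )


SUGARS = ("glucose", "rhamnose")


@dataclass(frozen=True)
class YieldTable:
    """(product, substrate-basis) -> mol/mol molar yields, stored at full precision."""

    yields: Mapping[tuple[str, str], float] = field(default_factory=dict)

    def get(self, product: str, basis: str) -> float:
        return self.yields[(normalize_name(product), basis)]

    def rounded(self, ndigits: int = 2) -> dict[str, float]:
        return {
            f"{product}/{basis}": round(value, ndigits)
            for (product, basis), value in sorted(self.yields.items())
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"product": p, "basis": b, "mol_per_mol": v}
                for (p, b), v in sorted(self.yields.items())
            ]
        )


def yields(
    net: NetChangeTable,
    bases: Iterable[str] | None = None,
    *,
    include_biomass: bool = True,
) -> YieldTable:
    """Molar product yields on each basis substrate.

    ``bases`` defaults to the culture's reference substrates. The special
    basis ``"sugar"`` (always included when any sugar was consumed) sums the
    consumption of all sugars and is the denominator for the biomass yield,
    matching how growth yields are reported for mixed-sugar cultures.
    """
    bases = list(bases) if bases is not None else list(net.reference_substrates)
    substrates = net.substrates
    table: dict[tuple[str, str], float] = {}
    for basis in bases:
        key = normalize_name(basis)
        denom = substrates.get(key, 0.0)
        if denom <= 0:
            raise ZeroDivisionError(f"basis substrate {basis!r} has no net consumption")
        for product, amount in net.products.items():
            table[(product, key)] = amount / denom
    sugar_total = sum(v for k, v in substrates.items() if k in SUGARS)
    if include_biomass and sugar_total > 0:
        table[("biomass", "sugar")] = net.biomass_produced / sugar_total
    return YieldTable(yields=table)
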