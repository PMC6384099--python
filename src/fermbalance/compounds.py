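"""Compound registry and elemental chemistry.

Every quantity in the balance calculations reduces to two numbers per
compound: its carbon content (C-mol per mol) and its degree of reduction
gamma (electrons liberated per mol on full oxidation to CO2, H2O and NH3),

    gamma = 4*C + 1*H - 2*O - 3*N.

Acids are registered as the undissociated species (acetic acid C2H4O2,
butyric acid C4H8O2, ...) so that gamma matches the values conventionally
used in fermentation balances (acetate 8, butyrate 20, propionate 14,
lactate 12).

Biomass is carried as a 5-carbon formula unit C5H9O2.5N, i.e. five times the
standard elemental composition CH1.8O0.5N0.2, which puts its degree of
reduction at 21 electrons per mole and its carbon content at 5 C-mol/mol.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import yaml

__all__ = [
    "ElementalFormula",
    "Compound",
    "BiomassUnit",
    "Registry",
    "degree_of_reduction",
    "carbon_count",
    "co2_per_mole",
    "default_registry",
    "BIOMASS_UNIT",
    "normalize_name",
]

ATOMIC_MASS = {"C": 12.011, "H": 1.008, "O": 15.999, "N": 14.007}

_FORMULA_TOKEN = re.compile(r"([CHON])(\d+(?:\.\d+)?)?")


class FormulaError(ValueError):
    """Raised for malformed or physically invalid elemental formulas."""


@dataclass(frozen=True)
class ElementalFormula:
    """CHON composition; fractional subscripts allowed (biomass-type formulas)."""

    c: float = 0.0
    h: float = 0.0
    o: float = 0.0
    n: float = 0.0

    def __post_init__(self) -> None:
        for element, count in self.as_dict().items():
            if not math.isfinite(count):
                raise FormulaError(f"non-finite {element} count: {count}")
            if count < 0:
                raise FormulaError(f"negative {element} count: {count}")
        if all(v == 0 for v in self.as_dict().values()):
            raise FormulaError("formula must contain at least one atom")

    def as_dict(self) -> dict[str, float]:
        return {"C": self.c, "H": self.h, "O": self.o, "N": self.n}

    @property
    def gamma(self) -> float:
        """Degree of reduction, electrons per mole."""
        return 4.0 * self.c + 1.0 * self.h - 2.0 * self.o - 3.0 * self.n

    @property
    def carbon(self) -> float:
        return self.c

    @property
    def molar_mass(self) -> float:
        """g/mol from standard atomic weights."""
        return sum(ATOMIC_MASS[el] * cnt for el, cnt in self.as_dict().items())

    @classmethod
    def parse(cls, text: str) -> "ElementalFormula":
        """Parse Hill-like CHON strings, e.g. ``C6H12O6`` or ``C1H1.8O0.5N0.2``."""
        s = text.strip()
        if not s:
            raise FormulaError("empty formula string")
        counts: dict[str, float] = {"C": 0.0, "H": 0.0, "O": 0.0, "N": 0.0}
        pos = 0
        for m in _FORMULA_TOKEN.finditer(s):
            if m.start() != pos:
                raise FormulaError(f"unparseable formula {text!r}")
            counts[m.group(1)] += float(m.group(2) or 1.0)
            pos = m.end()
        if pos != len(s):
            raise FormulaError(f"unparseable formula {text!r}")
        return cls(c=counts["C"], h=counts["H"], o=counts["O"], n=counts["N"])


def degree_of_reduction(formula: ElementalFormula) -> float:
    """Electrons per mole released on full oxidation (gamma = 4C + H - 2O - 3N)."""
    return formula.gamma


def carbon_count(formula: ElementalFormula) -> float:
    """C-mol per mol."""
    return formula.carbon


# mol CO2 released per mol of product formed, by fermentative origin:
# 1 for C2 products from one acetyl-CoA (pyruvate decarboxylation),
# 2 for C4 products from two acetyl-CoA,
# 3 for C3 solvents from two acetyl-CoA plus acetoacetate decarboxylation.
CO2_CLASS: dict[str, int] = {
    "acetate": 1,
    "ethanol": 1,
    "butyrate": 2,
    "butanol": 2,
    "acetone": 3,
    "isopropanol": 3,
}


@dataclass(frozen=True)
class Compound:
    name: str
    formula: ElementalFormula
    co2_class: int = 0
    role_hint: str = "either"  # substrate | product | either

    def __post_init__(self) -> None:
        if self.co2_class not in (0, 1, 2, 3):
            raise FormulaError(f"{self.name}: co2_class must be 0..3")
        if self.role_hint not in ("substrate", "product", "either"):
            raise FormulaError(f"{self.name}: bad role_hint {self.role_hint!r}")
        if self.formula.gamma < 0:
            raise FormulaError(f"{self.name}: negative degree of reduction")

    @property
    def gamma(self) -> float:
        return self.formula.gamma

    @property
    def carbon(self) -> float:
        return self.formula.carbon


def co2_per_mole(compound: Compound) -> int:
    """mol CO2 released per mol of this product formed."""
    return compound.co2_class


@dataclass(frozen=True)
class BiomassUnit:
    """Biomass formula unit: 5 C-mol of CH1.8O0.5N0.2, i.e. C5H9O2.5N."""

    formula: ElementalFormula = field(
        default_factory=lambda: ElementalFormula(c=5.0, h=9.0, o=2.5, n=1.0)
    )

    def __post_init__(self) -> None:
        if not math.isclose(self.formula.gamma, round(self.formula.gamma), abs_tol=1e-9):
            # fractional gammas are fine in general; nothing to enforce here
            pass

    @property
    def gamma(self) -> float:
        return self.formula.gamma

    @property
    def carbon(self) -> float:
        return self.formula.carbon

    @property
    def molar_mass(self) -> float:
        return self.formula.molar_mass


BIOMASS_UNIT = BiomassUnit()

_ALIASES = {
    "d-glucose": "glucose",
    "l-rhamnose": "rhamnose",
    "1,2-propanediol": "1,2-propanediol",
    "12-propanediol": "1,2-propanediol",
    "propanediol": "1,2-propanediol",
    "n-propanol": "propanol",
    "acetic acid": "acetate",
    "butyric acid": "butyrate",
    "propionic acid": "propionate",
    "lactic acid": "lactate",
    "hydrogen": "H2",
    "carbon dioxide": "CO2",
}


def normalize_name(name: str) -> str:
    """Canonical registry key for a compound name (case/stereo-prefix tolerant)."""
    key = name.strip().lower()
    if key in ("h2", "co2"):
        return key.upper()
    if key.startswith(("d-", "l-")) and key not in _ALIASES:
        key = key[2:]
    return _ALIASES.get(key, key)


_DEFAULTS: list[tuple[str, str, str]] = [
    # name, formula, role hint
    ("glucose", "C6H12O6", "substrate"),
    ("rhamnose", "C6H12O5", "substrate"),
    ("acetate", "C2H4O2", "either"),
    ("lactate", "C3H6O3", "product"),
    ("butyrate", "C4H8O2", "either"),
    ("acetone", "C3H6O", "product"),
    ("isopropanol", "C3H8O", "product"),
    ("ethanol", "C2H6O", "product"),
    ("butanol", "C4H10O", "product"),
    ("1,2-propanediol", "C3H8O2", "product"),
    ("propanol", "C3H8O", "product"),
    ("propionate", "C3H6O2", "product"),
    ("H2", "H2", "product"),
    ("CO2", "CO2", "product"),
    ("H2O", "H2O", "either"),
]


class RegistryError(KeyError):
    """Raised when a compound cannot be resolved in the registry."""


class Registry:
    """Name -> :class:`Compound` lookup with alias normalization.

    User registries extend (or override) the defaults via a YAML mapping of
    ``name: {formula: "...", co2_class: 0..3, role_hint: ...}`` or the
    shorthand ``name: "C3H8O2"``.
    """

    def __init__(self, compounds: Iterable[Compound] = ()):
        self._compounds: dict[str, Compound] = {}
        for c in compounds:
            self.add(c)

    def add(self, compound: Compound) -> None:
        self._compounds[normalize_name(compound.name)] = compound

    def __contains__(self, name: str) -> bool:
        return normalize_name(name) in self._compounds

    def __iter__(self):
        return iter(self._compounds.values())

    def __len__(self) -> int:
        return len(self._compounds)

    def get(self, name: str) -> Compound:
        key = normalize_name(name)
        if key not in self._compounds:
            raise RegistryError(
                f"unknown compound {name!r}; add it to the registry with an "
                f"elemental formula before using it"
            )
        return self._compounds[key]

    def gamma(self, name: str) -> float:
        return self.get(name).gamma

    def carbon(self, name: str) -> float:
        return self.get(name).carbon

    def co2_per_mole(self, name: str) -> int:
        return self.get(name).co2_class

    def extended(self, entries: Mapping[str, object]) -> "Registry":
        """New registry with ``entries`` merged on top of this one."""
        reg = Registry(self._compounds.values())
        for name, value in entries.items():
            if isinstance(value, str):
                spec: dict = {"formula": value}
            elif isinstance(value, Mapping):
                spec = dict(value)
            else:
                raise FormulaError(f"{name}: registry entry must be a formula string or mapping")
            if "formula" not in spec:
                raise FormulaError(f"{name}: registry entry lacks an elemental formula")
            reg.add(
                Compound(
                    name=name,
                    formula=ElementalFormula.parse(str(spec["formula"])),
                    co2_class=int(spec.get("co2_class", CO2_CLASS.get(normalize_name(name), 0))),
                    role_hint=str(spec.get("role_hint", "either")),
                )
            )
        return reg

    @classmethod
    def from_yaml(cls, path, base: "Registry | None" = None) -> "Registry":
        with open(path) as fh:
            entries = yaml.safe_load(fh) or {}
        if not isinstance(entries, Mapping):
            raise FormulaError(f"{path}: registry file must be a mapping")
        return (base or default_registry()).extended(entries)


def default_registry() -> Registry:
    """Registry of the compounds measured in clostridial ABE/IBE fermentations."""
    reg = Registry()
    for name, formula, hint in _DEFAULTS:
        reg.add(
            Compound(
                name=name,
                formula=ElementalFormula.parse(formula),
                co2_class=CO2_CLASS.get(name, 0),
                role_hint=hint,
            )
        )
    return reg
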