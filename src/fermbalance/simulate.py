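"""Synthetic batch-fermentation time courses with known ground truth.

The generator emulates a batch culture in which products accumulate in fixed
stoichiometric proportion to substrate consumed: substrate depletion follows
a normalized logistic curve (slow onset, fast mid-fermentation, plateau),
each product rises as ``coefficient x substrate consumed``, and biomass
grows with a fixed molar yield (5-C units per mol sugar). Elemental closure
is enforced at specification time: for each substrate, the CO2 and H2
coefficients are solved from the carbon and degree-of-reduction balances of
the declared product split, so a noiseless simulation recovers exactly 100%
carbon and electron recovery when its own CO2/H2 are supplied to the
balance functions. A split that cannot be closed with non-negative CO2 and
H2 is rejected.

Measurement noise is additive Gaussian per observation (HPLC-like), applied
to concentrations, never to deltas; negative noisy values are clipped at 0
(detection limit) and the clipping events are counted in the ground truth.
A fixed seed makes the whole trajectory reproducible bit for bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .compounds import BIOMASS_UNIT, BiomassUnit, Registry, default_registry, normalize_name
from .dataset import FermentationDataset, load_culture

__all__ = [
    "SimulationSpec",
    "GroundTruth",
    "simulate_fermentation",
    "recover_coefficients",
    "replay_culture",
    "rhamnose_like_spec",
]


class SimulationSpecError(ValueError):
    """Raised for stoichiometrically inconsistent or invalid specifications."""


@dataclass(frozen=True)
class SimulationSpec:
    """Ground-truth stoichiometry and sampling plan for one synthetic culture.

    ``product_coefficients`` maps each substrate to its product split in
    mol product per mol substrate consumed; ``biomass_yield`` is in 5-C
    units per mol substrate. ``fraction_consumed`` sets how much of the
    initial substrate is gone at the end of the run.
    """

    substrates: Mapping[str, float]  # initial mM per substrate
    product_coefficients: Mapping[str, Mapping[str, float]]
    biomass_yield: Mapping[str, float] = field(default_factory=dict)
    fraction_consumed: Mapping[str, float] = field(default_factory=dict)
    duration_h: float = 56.0
    n_points: int = 9
    logistic_midpoint_h: float = 20.0
    logistic_rate: float = 0.2  # 1/h
    noise_sd: float = 0.0  # mM, additive Gaussian per measurement
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise SimulationSpecError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.n_points < 2:
            raise SimulationSpecError("need at least two time points")
        if self.duration_h <= 0:
            raise SimulationSpecError("duration must be positive")
        for sub, c0 in self.substrates.items():
            if c0 <= 0:
                raise SimulationSpecError(f"{sub}: initial concentration must be > 0")
            f = self.fraction_consumed.get(sub, 1.0)
            if not 0 < f <= 1:
                raise SimulationSpecError(f"{sub}: fraction_consumed must be in (0, 1]")
        for sub, coeffs in self.product_coefficients.items():
            if sub not in self.substrates:
                raise SimulationSpecError(f"coefficients given for undosed substrate {sub!r}")
            if any(v < 0 for v in coeffs.values()):
                raise SimulationSpecError(f"{sub}: negative product coefficient")


@dataclass(frozen=True)
class GroundTruth:
    """What the generator actually did, for scoring estimators against."""

    spec: SimulationSpec
    consumed_mM: Mapping[str, float]
    co2_per_substrate: Mapping[str, float]  # mol CO2 per mol substrate
    h2_per_substrate: Mapping[str, float]  # mol H2 per mol substrate
    co2_mM: float
    h2_mM: float
    biomass_mM: float
    n_clipped: int = 0


def _closure_coefficients(
    spec: SimulationSpec, registry: Registry, unit: BiomassUnit, tol: float = 1e-9
) -> tuple[dict[str, float], dict[str, float]]:
    """Solve per-substrate CO2 and H2 coefficients from C and gamma balances."""
    co2c: dict[str, float] = {}
    h2c: dict[str, float] = {}
    for sub, coeffs in spec.product_coefficients.items():
        bio = spec.biomass_yield.get(sub, 0.0)
        c_sub = registry.carbon(sub)
        c_products = sum(registry.carbon(p) * v for p, v in coeffs.items())
        co2 = c_sub - c_products - unit.carbon * bio
        if co2 < -tol:
            raise SimulationSpecError(
                f"{sub}: product split over-consumes carbon by {-co2:.3g} C-mol/mol"
            )
        co2 = max(0.0, co2)
        g_sub = registry.gamma(sub)
        g_products = sum(registry.gamma(p) * v for p, v in coeffs.items())
        h2 = (g_sub - g_products - unit.gamma * bio) / 2.0  # CO2 carries 0 electrons
        if h2 < -tol:
            raise SimulationSpecError(
                f"{sub}: product split over-consumes electrons by {-2 * h2:.3g} e-mol/mol"
            )
        co2c[sub] = co2
        h2c[sub] = max(0.0, h2)
    return co2c, h2c


def _progress(times: np.ndarray, spec: SimulationSpec) -> np.ndarray:
    """Normalized logistic consumption curve: 0 at t0, 1 at t_end."""
    f = 1.0 / (1.0 + np.exp(-spec.logistic_rate * (times - spec.logistic_midpoint_h)))
    return (f - f[0]) / (f[-1] - f[0])


def simulate_fermentation(
    spec: SimulationSpec,
    registry: Registry | None = None,
    *,
    biomass_unit: BiomassUnit = BIOMASS_UNIT,
) -> tuple[FermentationDataset, GroundTruth]:
    """Generate one culture and its ground-truth record."""
    registry = registry or default_registry()
    for sub in spec.substrates:
        registry.get(sub)
    for coeffs in spec.product_coefficients.values():
        for p in coeffs:
            registry.get(p)
    co2c, h2c = _closure_coefficients(spec, registry, biomass_unit)

    times = np.linspace(0.0, spec.duration_h, spec.n_points)
    s = _progress(times, spec)
    columns: dict[str, np.ndarray] = {}
    consumed_end: dict[str, float] = {}
    biomass = np.zeros_like(times)
    co2_total = 0.0
    h2_total = 0.0
    for sub, c0 in spec.substrates.items():
        key = normalize_name(sub)
        total = c0 * spec.fraction_consumed.get(sub, 1.0)
        consumed = total * s
        consumed_end[key] = total
        columns[key] = c0 - consumed
        for p, coeff in spec.product_coefficients.get(sub, {}).items():
            pk = normalize_name(p)
            columns[pk] = columns.get(pk, np.zeros_like(times)) + coeff * consumed
        biomass += spec.biomass_yield.get(sub, 0.0) * consumed
        co2_total += co2c.get(sub, 0.0) * total
        h2_total += h2c.get(sub, 0.0) * total

    rng = np.random.default_rng(spec.seed)
    n_clipped = 0
    if spec.noise_sd > 0:
        for key in sorted(columns):
            noisy = columns[key] + rng.normal(0.0, spec.noise_sd, size=times.shape)
            n_clipped += int((noisy < 0).sum())
            columns[key] = np.clip(noisy, 0.0, None)

    df = pd.DataFrame(columns, index=pd.Index(times, name="time_h"))
    dataset = FermentationDataset(
        culture_id=f"synthetic-seed{spec.seed}",
        substrate_labels=frozenset(normalize_name(sub) for sub in spec.substrates),
        concentrations=df,
        biomass_end_mM=float(biomass[-1]),
    )
    truth = GroundTruth(
        spec=spec,
        consumed_mM=consumed_end,
        co2_per_substrate=co2c,
        h2_per_substrate=h2c,
        co2_mM=co2_total,
        h2_mM=h2_total,
        biomass_mM=float(biomass[-1]),
        n_clipped=n_clipped,
    )
    return dataset, truth


def recover_coefficients(
    dataset: FermentationDataset, substrate: str, products: list[str] | None = None
) -> dict[str, float]:
    """Estimate mol/mol product coefficients from a (possibly noisy) time course.

    Through-origin least squares of product concentration rise against
    substrate consumed, pooling all time points; with endpoint-only data this
    degenerates to the net-change ratio.
    """
    sub = dataset.series(substrate).dropna()
    consumed = (sub.iloc[0] - sub).to_numpy(dtype=float)
    denom = float(consumed @ consumed)
    if denom <= 0:
        raise ValueError(f"{substrate}: no consumption to regress against")
    if products is None:
        products = [c for c in dataset.compounds if c != normalize_name(substrate)]
    out: dict[str, float] = {}
    for p in products:
        series = dataset.series(p).dropna()
        rise = (series - series.iloc[0]).to_numpy(dtype=float)
        out[normalize_name(p)] = float(consumed @ rise) / denom
    return out


def rhamnose_like_spec(*, noise_sd: float = 0.0, seed: int = 0) -> SimulationSpec:
    """A specification mirroring the packaged l-rhamnose bioreactor culture.

    243.4 mM initial rhamnose of which 46.4 mM is consumed over 56 h; branch
    splits 0.39/0.41/0.18 (lactaldehyde) and 0.43/0.26 (DHAP) in mol per mol
    sugar net of a 0.045 biomass yield.
    """
    return SimulationSpec(
        substrates={"rhamnose": 243.4},
        fraction_consumed={"rhamnose": 46.4 / 243.4},
        product_coefficients={
            "rhamnose": {
                "1,2-propanediol": 0.39,
                "propanol": 0.41,
                "propionate": 0.18,
                "acetate": 0.43,
                "butyrate": 0.26,
            }
        },
        biomass_yield={"rhamnose": 0.045},
        duration_h=56.0,
        noise_sd=noise_sd,
        seed=seed,
    )


def replay_culture(culture_id: str) -> FermentationDataset:
    """Pass-through to the packaged reference cultures (endpoint datasets)."""
    return load_culture(culture_id)
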