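"""Fermentation time-series container, CSV I/O, and packaged reference cultures.

A :class:`FermentationDataset` holds extracellular concentrations (mM) per
compound over time (h) for one batch culture, plus whatever biomass
observation the experiment produced (an OD600 series, an endpoint cell dry
weight in g/L, or an endpoint biomass concentration already expressed in mM
of 5-carbon formula units).

The on-disk format is a plain CSV with a ``time_h`` column and one column
per compound; culture metadata travels in ``# key: json`` comment lines at
the top of the file, so a dataset round-trips through a single text file.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .compounds import Registry, default_registry, normalize_name

__all__ = [
    "FermentationDataset",
    "ValidationError",
    "read_dataset",
    "write_dataset",
    "builtin_cultures",
    "load_culture",
    "BUILTIN_CULTURE_IDS",
]

_META_KEYS = ("culture_id", "substrate_labels", "cdw_end", "biomass_end_mM", "below_detection")


class ValidationError(ValueError):
    """Raised when a dataset violates its structural invariants."""


@dataclass(frozen=True)
class FermentationDataset:
    """Concentration time courses for one batch culture.

    Attributes
    ----------
    culture_id:
        Identifier of the culture.
    substrate_labels:
        Compound names dosed at t0 (yield denominators by default).
    concentrations:
        DataFrame indexed by time (h), one column per compound (mM). NaN
        cells are "not measured"; they are never treated as zero.
    od600:
        Optional OD600 series indexed by time (h).
    cdw_end:
        Optional endpoint cell dry weight, g/L.
    biomass_end_mM:
        Optional endpoint biomass, mM of 5-C formula units.
    below_detection:
        Compounds reported as below the detection limit; their stored
        concentration is 0 mM but the flag is preserved.
    """

    culture_id: str
    substrate_labels: frozenset = frozenset()
    concentrations: pd.DataFrame = field(default_factory=pd.DataFrame)
    od600: pd.Series | None = None
    cdw_end: float | None = None
    biomass_end_mM: float | None = None
    below_detection: frozenset = frozenset()

    def __post_init__(self) -> None:
        df = self.concentrations
        if df.empty or len(df.index) == 0 or len(df.columns) == 0:
            raise ValidationError(f"{self.culture_id}: dataset has no measurements")
        times = np.asarray(df.index, dtype=float)
        if not np.all(np.isfinite(times)):
            raise ValidationError(f"{self.culture_id}: non-finite time points")
        if not np.all(np.diff(times) > 0):
            raise ValidationError(f"{self.culture_id}: time points must be strictly increasing")
        values = df.to_numpy(dtype=float)
        if (values[np.isfinite(values)] < 0).any():
            raise ValidationError(f"{self.culture_id}: negative concentration")

    @property
    def t0(self) -> float:
        return float(self.concentrations.index[0])

    @property
    def t_end(self) -> float:
        return float(self.concentrations.index[-1])

    @property
    def compounds(self) -> list[str]:
        return list(self.concentrations.columns)

    def series(self, name: str) -> pd.Series:
        return self.concentrations[normalize_name(name)]

    def validate_against(self, registry: Registry) -> "FermentationDataset":
        for name in self.concentrations.columns:
            registry.get(name)  # raises RegistryError on a miss
        return self

    def with_end_time(self, t_end: float) -> "FermentationDataset":
        """Truncate the series at ``t_end`` (config override of end-of-fermentation)."""
        df = self.concentrations.loc[self.concentrations.index <= t_end]
        od = None if self.od600 is None else self.od600.loc[self.od600.index <= t_end]
        return replace(self, concentrations=df, od600=od)


def _normalize_columns(df: pd.DataFrame) -> pd.DataFrame:
    return df.rename(columns={c: normalize_name(c) for c in df.columns})


def read_dataset(
    path,
    registry: Registry | None = None,
    *,
    culture_id: str | None = None,
    substrate_labels=None,
    cdw_end: float | None = None,
    biomass_end_mM: float | None = None,
) -> FermentationDataset:
    """Read a delimited-text fermentation table.

    The file must have a ``time_h`` column; every other column is either a
    registry compound, ``od600``, or ``biomass_mM``. ``# key: json`` header
    comments carry metadata; keyword arguments override it. Missing cells
    stay missing (NaN) rather than becoming zeros.
    """
    path = Path(path)
    registry = registry or default_registry()
    meta: dict = {}
    body_lines: list[str] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                key, _, value = line.lstrip("# ").partition(":")
                key = key.strip()
                if key in _META_KEYS:
                    meta[key] = json.loads(value.strip())
            elif line.strip():
                body_lines.append(line)
    if not body_lines:
        raise ValidationError(f"{path}: empty table")
    sep = "\t" if "\t" in body_lines[0] else ","
    df = pd.read_csv(pd.io.common.StringIO("".join(body_lines)), sep=sep)
    if "time_h" not in df.columns:
        raise ValidationError(f"{path}: missing time_h column")
    df = df.set_index("time_h")
    df = _normalize_columns(df)
    od = None
    if "od600" in df.columns:
        od = df.pop("od600").dropna()
    biomass_col = df.pop("biomass_mm") if "biomass_mm" in df.columns else None
    if df.shape[1] == 0:
        raise ValidationError(f"{path}: no compound columns")

    labels = substrate_labels if substrate_labels is not None else meta.get("substrate_labels", [])
    bd = frozenset(normalize_name(n) for n in meta.get("below_detection", []))
    if biomass_end_mM is None:
        biomass_end_mM = meta.get("biomass_end_mM")
    if biomass_end_mM is None and biomass_col is not None and biomass_col.notna().any():
        biomass_end_mM = float(biomass_col.dropna().iloc[-1])
    ds = FermentationDataset(
        culture_id=culture_id or meta.get("culture_id", path.stem),
        substrate_labels=frozenset(normalize_name(n) for n in labels),
        concentrations=df,
        od600=od,
        cdw_end=cdw_end if cdw_end is not None else meta.get("cdw_end"),
        biomass_end_mM=biomass_end_mM,
        below_detection=bd,
    )
    return ds.validate_against(registry)


def write_dataset(dataset: FermentationDataset, path) -> Path:
    """Serialize a dataset to the CSV dialect :func:`read_dataset` reads."""
    path = Path(path)
    df = dataset.concentrations.copy()
    if dataset.od600 is not None:
        df["od600"] = dataset.od600.reindex(df.index)
    meta = {
        "culture_id": dataset.culture_id,
        "substrate_labels": sorted(dataset.substrate_labels),
        "cdw_end": dataset.cdw_end,
        "biomass_end_mM": dataset.biomass_end_mM,
        "below_detection": sorted(dataset.below_detection),
    }
    with open(path, "w") as fh:
        for key, value in meta.items():
            if value not in (None, []):
                fh.write(f"# {key}: {json.dumps(value)}\n")
        df.reset_index(names="time_h").to_csv(fh, index=False)
    return path


# ---------------------------------------------------------------------------
# Packaged reference cultures: endpoint data of C. beijerinckii DSM 6423
# batch fermentations on d-glucose (56 h), l-rhamnose (56 h) and a
# d-glucose/l-rhamnose mixture (72 h). Concentrations in mM; biomass in mM of
# 5-C formula units; 0.0 with a below-detection flag encodes "not detected".
# ---------------------------------------------------------------------------

_REFERENCE_CULTURES: dict[str, dict] = {
    "glucose": {
        "duration_h": 56.0,
        "substrates": ["glucose"],
        "start": {"glucose": 224.8, "acetate": 39.5},
        "end": {
            "glucose": 224.8 - 215.3,  # 215.3 mM consumed
            "acetate": 8.8,
            "lactate": 7.5,
            "butyrate": 2.1,
            "acetone": 3.2,
            "isopropanol": 68.5,
            "ethanol": 6.0,
            "butanol": 111.8,
            "1,2-propanediol": 0.0,
            "propanol": 0.0,
            "propionate": 0.0,
        },
        "below_detection": ["1,2-propanediol", "propanol", "propionate"],
        "biomass_end_mM": 26.6,
        "od600_end": 11.1,
    },
    "rhamnose": {
        "duration_h": 56.0,
        "substrates": ["rhamnose"],
        "start": {"rhamnose": 243.4, "acetate": 38.3},
        "end": {
            "rhamnose": 243.4 - 46.4,  # 46.4 mM consumed
            "acetate": 57.5,
            "lactate": 0.0,
            "butyrate": 11.7,
            "acetone": 0.0,
            "isopropanol": 0.0,
            "ethanol": 0.0,
            "butanol": 0.0,
            "1,2-propanediol": 17.2,
            "propanol": 18.2,
            "propionate": 7.8,
        },
        "below_detection": ["lactate", "acetone", "isopropanol", "ethanol", "butanol"],
        "biomass_end_mM": 2.1,
        "od600_end": 2.8,
    },
    "mixture": {
        "duration_h": 72.0,
        "substrates": ["glucose", "rhamnose"],
        "start": {"glucose": 111.2, "rhamnose": 129.3, "acetate": 37.3},
        "end": {
            "glucose": 0.0,  # fully consumed
            "rhamnose": 129.3 - 86.7,  # 86.7 mM consumed
            "acetate": 36.2,
            "lactate": 2.4,
            "butyrate": 25.9,
            "acetone": 7.9,
            "isopropanol": 31.9,
            "ethanol": 1.1,
            "butanol": 59.4,
            "1,2-propanediol": 78.4,
            "propanol": 0.0,
            "propionate": 0.0,
        },
        "below_detection": ["propanol", "propionate"],
        "biomass_end_mM": 11.7,
        "od600_end": 6.8,
    },
}

BUILTIN_CULTURE_IDS = tuple(_REFERENCE_CULTURES)


def load_culture(culture_id: str) -> FermentationDataset:
    """One packaged reference culture as a two-point (t0, t_end) dataset."""
    if culture_id not in _REFERENCE_CULTURES:
        raise KeyError(
            f"unknown culture {culture_id!r}; choose from {sorted(_REFERENCE_CULTURES)}"
        )
    spec = _REFERENCE_CULTURES[culture_id]
    compounds = sorted(set(spec["start"]) | set(spec["end"]))
    start = {c: spec["start"].get(c, 0.0) for c in compounds}
    end = {c: spec["end"].get(c, start[c]) for c in compounds}
    df = pd.DataFrame(
        [start, end], index=pd.Index([0.0, spec["duration_h"]], name="time_h")
    )[compounds]
    od = pd.Series(
        [math.nan, spec["od600_end"]], index=df.index, name="od600"
    ).dropna()
    return FermentationDataset(
        culture_id=culture_id,
        substrate_labels=frozenset(spec["substrates"]),
        concentrations=df,
        od600=od,
        biomass_end_mM=spec["biomass_end_mM"],
        below_detection=frozenset(spec["below_detection"]),
    )


def builtin_cultures() -> dict[str, FermentationDataset]:
    """The three packaged reference cultures (glucose, rhamnose, mixture)."""
    return {cid: load_culture(cid) for cid in BUILTIN_CULTURE_IDS}
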