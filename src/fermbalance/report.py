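"""Assembly and serialization of full culture reports.

A report bundles the net-change table, molar yields, the carbon/electron
balance, the cofactor ledger and (for rhamnose-consuming cultures) the
normalized branch equations, and serializes deterministically to JSON, a
Markdown table, or TSV.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Mapping

from .accounting import NetChangeTable, YieldTable, net_changes, yields
from .balances import BalanceReport, balance_report
from .compounds import Registry, default_registry
from .dataset import FermentationDataset
from .pathway import (
    BranchEquation,
    Pathway,
    PathwayError,
    atp_yield,
    branch_equations,
    builtin_pathway,
    nadh_ledger,
    PathwayLedger,
)

__all__ = ["CultureReport", "build_report"]


@dataclass(frozen=True)
class CultureReport:
    culture_id: str
    net: NetChangeTable
    yield_table: YieldTable
    balance: BalanceReport
    ledger: PathwayLedger | None = None
    reference_ledger: PathwayLedger | None = None
    branches: Mapping[str, BranchEquation] | None = None
    atp_per_sugar: float | None = None
    conventions: Mapping[str, str] | None = None

    def as_dict(self) -> dict:
        d: dict = {
            "culture_id": self.culture_id,
            "net_changes_mM": {
                e.compound: {"net_mM": e.net_amount, "role": e.role}
                for e in self.net.entries
            },
            "biomass_mM": self.net.biomass_produced,
            "yields_mol_per_mol": {
                f"{p}/{b}": v for (p, b), v in sorted(self.yield_table.yields.items())
            },
            "balance": self.balance.as_dict(),
        }
        if self.ledger is not None:
            d["ledger"] = self.ledger.as_dict()
        if self.reference_ledger is not None:
            d["reference_ledger"] = self.reference_ledger.as_dict()
        if self.branches is not None:
            d["branch_equations"] = {k: v.as_dict() for k, v in self.branches.items()}
        if self.atp_per_sugar is not None:
            d["atp_per_mol_sugar"] = self.atp_per_sugar
        if self.conventions:
            d["conventions"] = dict(self.conventions)
        return d

    def to_json(self) -> str:
        return json.dumps(self.as_dict(), indent=2, sort_keys=True) + "\n"

    def to_markdown(self) -> str:
        """Human-readable yields-and-recovery block."""
        lines = [
            f"## Culture {self.culture_id}",
            "",
            "| quantity | value |",
            "| --- | --- |",
        ]
        for (p, b), v in sorted(self.yield_table.yields.items()):
            lines.append(f"| yield {p} (mol/mol {b}) | {v:.3f} |")
        bal = self.balance
        lines += [
            f"| carbon recovery (%) | {bal.carbon_recovery:.1f} (reported {round(bal.carbon_recovery)}) |",
            f"| electron recovery (%) | {bal.electron_recovery:.1f} (reported {round(bal.electron_recovery)}) |",
            f"| electron recovery without H2 (%) | {bal.electron_recovery_no_h2:.1f} |",
            f"| estimated CO2 (mM) | {bal.co2_C:.1f} |",
            f"| estimated H2, redox closure (mM) | {bal.h2_estimate:.1f} |",
            f"| H2 required for 100% electron closure (mM) | {bal.h2_for_full_closure:.1f} |",
        ]
        if self.atp_per_sugar is not None:
            lines.append(f"| ATP per mol sugar | {self.atp_per_sugar:.2f} |")
        if self.branches:
            for name, eq in self.branches.items():
                coeffs = " + ".join(f"{c:.2f} {p}" for p, c in eq.coefficients.items())
                lines.append(f"| branch 1 {name} -> | {coeffs} |")
        return "\n".join(lines) + "\n"

    def to_tsv(self) -> str:
        rows = [("section", "key", "value")]
        for (p, b), v in sorted(self.yield_table.yields.items()):
            rows.append(("yield", f"{p}/{b}", f"{v:.6g}"))
        for key, value in self.balance.as_dict().items():
            if isinstance(value, (int, float)):
                rows.append(("balance", key, f"{value:.6g}"))
        if self.atp_per_sugar is not None:
            rows.append(("ledger", "atp_per_mol_sugar", f"{self.atp_per_sugar:.6g}"))
        return "\n".join("\t".join(r) for r in rows) + "\n"


def build_report(
    dataset: FermentationDataset,
    pathway: Pathway | str | None = None,
    registry: Registry | None = None,
    *,
    ledger_convention: str = "measured",
    h2_closure: bool = True,
) -> CultureReport:
    """End-to-end analysis of one culture.

    The pathway defaults to ``rhamnose`` if the culture consumed rhamnose,
    else ``glucose``. With ``h2_closure=False`` the electron recovery is
    reported without an H2 term (the closure diagnostic still appears).
    """
    registry = registry or default_registry()
    dataset.validate_against(registry)
    net = net_changes(dataset)
    if pathway is None:
        pathway = "rhamnose" if "rhamnose" in net.substrates else "glucose"
    if isinstance(pathway, str):
        pathway = builtin_pathway(pathway, registry)
    yt = yields(net)
    balance = balance_report(
        net,
        pathway,
        registry,
        h2_mM=None if h2_closure else 0.0,
    )
    ledger = nadh_ledger(net, pathway, convention=ledger_convention)
    reference_ledger = None
    branches = None
    atp = None
    try:
        atp = atp_yield(net, pathway)
    except PathwayError:
        pass
    if pathway.sugar in net.substrates:
        reference_ledger = nadh_ledger(net, pathway, convention="reference")
        if pathway.lactaldehyde_products:
            try:
                branches = branch_equations(net, pathway=pathway)
            except PathwayError:
                branches = None
    return CultureReport(
        culture_id=dataset.culture_id,
        net=net,
        yield_table=yt,
        balance=balance,
        ledger=ledger,
        reference_ledger=reference_ledger,
        branches=branches,
        atp_per_sugar=atp,
        conventions={
            "ledger": ledger_convention,
            "h2_closure": "on" if h2_closure else "off",
        },
    )
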