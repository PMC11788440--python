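"""Scenario-based life-cycle impact characterization.

A deliberately generic midpoint engine: inventories are flow -> amount
vectors per functional unit (1 m3 of product water over the plant's
operating horizon), characterization factors are user-supplied (none are
bundled), and impact scores are the linear map ``score_c = sum_f amount_f *
factor_{f,c}``.  On top of that sit two scenario operations used for
treatment-system comparison: re-expressing grid electricity through a
country-specific generation mix, and mitigation levers (membrane-lifespan
extension, brine energy recovery at the high-pressure pumps, transport mode
swaps).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

__all__ = [
    "DEFAULT_CATEGORIES",
    "Inventory",
    "CharacterizationSet",
    "ElectricityMix",
    "ScenarioSpec",
    "characterize",
    "apply_electricity_mix",
    "apply_scenario",
    "percent_change",
]

#: Ten midpoint impact categories commonly reported for urban water systems.
DEFAULT_CATEGORIES = (
    "global_warming",
    "ozone_depletion",
    "terrestrial_acidification",
    "freshwater_eutrophication",
    "marine_eutrophication",
    "terrestrial_ecotoxicity",
    "freshwater_ecotoxicity",
    "marine_ecotoxicity",
    "mineral_consumption",
    "fossil_fuel_depletion",
)

ELECTRICITY_FLOW = "electricity"
MEMBRANE_FLOW = "membrane"
TRANSPORT_PREFIX = "transport_"


@dataclass(frozen=True)
class Inventory:
    """Foreground flows per functional unit (amounts >= 0, ids unique)."""

    flows: Mapping[str, float]

    def __post_init__(self) -> None:
        for fid, amount in self.flows.items():
            if not (math.isfinite(amount) and amount >= 0):
                raise ValueError(f"flow {fid!r}: amount must be finite and >= 0")

    def as_series(self) -> pd.Series:
        return pd.Series(dict(self.flows), dtype=float)

    def __add__(self, other: "Inventory") -> "Inventory":
        merged = dict(self.flows)
        for fid, amount in other.flows.items():
            merged[fid] = merged.get(fid, 0.0) + amount
        return Inventory(merged)

    def scaled(self, factor: float) -> "Inventory":
        return Inventory({fid: a * factor for fid, a in self.flows.items()})


@dataclass(frozen=True)
class CharacterizationSet:
    """Factor matrix flow_id x category_id (category unit per flow unit)."""

    factors: pd.DataFrame  # index: flow_id, columns: category_id

    def __post_init__(self) -> None:
        if self.factors.columns.duplicated().any() or self.factors.index.duplicated().any():
            raise ValueError("duplicate flow or category ids in factor matrix")
        if not self.factors.map(math.isfinite).all().all():
            raise ValueError("characterization factors must be finite")

    @property
    def categories(self) -> list[str]:
        return list(self.factors.columns)

    def merged_with(self, other: "CharacterizationSet") -> "CharacterizationSet":
        return CharacterizationSet(pd.concat([self.factors, other.factors]))


class CharacterizationError(KeyError):
    """An inventory flow has no factor row."""


def characterize(inv: Inventory, cs: CharacterizationSet) -> pd.Series:
    """Impact scores per category: the factor-weighted sum over flows."""
    amounts = inv.as_series()
    missing = sorted(set(amounts.index) - set(cs.factors.index))
    if missing:
        raise CharacterizationError(f"no characterization factors for flows: {missing}")
    if amounts.empty:
        return pd.Series(0.0, index=cs.categories)
    mat = cs.factors.loc[amounts.index]
    return mat.mul(amounts, axis=0).sum(axis=0)


@dataclass(frozen=True)
class ElectricityMix:
    """Per-country generation shares plus per-source impact factors per kWh."""

    country_id: str
    shares: Mapping[str, float]
    source_factors: pd.DataFrame  # index: source_id, columns: category_id

    def __post_init__(self) -> None:
        total = sum(self.shares.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"mix {self.country_id}: shares sum to {total}, not 1")
        for src, s in self.shares.items():
            if s < 0:
                raise ValueError(f"mix {self.country_id}: negative share for {src}")
            if src not in self.source_factors.index:
                raise ValueError(f"mix {self.country_id}: no factors for source {src}")


def source_flow_id(source_id: str) -> str:
    return f"{ELECTRICITY_FLOW}_{source_id}"


def apply_electricity_mix(
    inv: Inventory,
    mix: ElectricityMix,
    flow_id: str = ELECTRICITY_FLOW,
) -> tuple[Inventory, CharacterizationSet]:
    """Resolve a grid-electricity flow into source-specific flows.

    The aggregate kWh amount is split across generation sources by the mix
    shares (total kWh preserved); the returned factor set carries one row
    per source flow so the resolved inventory can be characterized.
    """
    if flow_id not in inv.flows:
        raise KeyError(f"inventory has no {flow_id!r} flow")
    kwh = inv.flows[flow_id]
    flows = {f: a for f, a in inv.flows.items() if f != flow_id}
    for src, share in mix.shares.items():
        flows[source_flow_id(src)] = flows.get(source_flow_id(src), 0.0) + share * kwh
    factors = mix.source_factors.copy()
    factors.index = [source_flow_id(s) for s in factors.index]
    return Inventory(flows), CharacterizationSet(factors)


@dataclass(frozen=True)
class ScenarioSpec:
    """Mitigation levers applied to an inventory.

    ``membrane_life_multiplier`` divides the membrane-replacement flow
    (doubling the lifespan halves the replacement demand);
    ``energy_recovery_fraction`` of the high-pressure-pump electricity share
    ``hp_pump_share`` is recovered from the pressurized brine; transport
    amounts can be moved between mode-specific flows.
    """

    membrane_life_multiplier: float = 1.0
    energy_recovery_fraction: float = 0.0
    hp_pump_share: float = 0.0
    transport_mode_swap: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.membrane_life_multiplier < 1.0:
            raise ValueError("membrane_life_multiplier must be >= 1")
        if not 0.0 <= self.energy_recovery_fraction < 1.0:
            raise ValueError("energy_recovery_fraction must lie in [0, 1)")
        if not 0.0 <= self.hp_pump_share <= 1.0:
            raise ValueError("hp_pump_share must lie in [0, 1]")


def apply_scenario(inv: Inventory, s: ScenarioSpec) -> Inventory:
    """Apply mitigation levers; the identity spec is a bit-exact no-op."""
    flows = dict(inv.flows)
    if s.membrane_life_multiplier != 1.0:
        if MEMBRANE_FLOW not in flows:
            raise KeyError(f"inventory has no {MEMBRANE_FLOW!r} flow")
        flows[MEMBRANE_FLOW] = flows[MEMBRANE_FLOW] / s.membrane_life_multiplier
    reduction = s.hp_pump_share * s.energy_recovery_fraction
    if reduction != 0.0:
        if ELECTRICITY_FLOW not in flows:
            raise KeyError(f"inventory has no {ELECTRICITY_FLOW!r} flow")
        flows[ELECTRICITY_FLOW] = flows[ELECTRICITY_FLOW] * (1.0 - reduction)
    for src_mode, dst_mode in s.transport_mode_swap.items():
        src, dst = TRANSPORT_PREFIX + src_mode, TRANSPORT_PREFIX + dst_mode
        if src not in flows:
            raise KeyError(f"inventory has no transport flow {src!r}")
        if dst not in flows:
            raise KeyError(f"unknown destination transport mode {dst_mode!r}")
        flows[dst] = flows[dst] + flows[src]
        flows[src] = 0.0
    return Inventory(flows)


def percent_change(base: pd.Series, alt: pd.Series) -> pd.Series:
    """100 * (alt - base) / base per category; NaN where base is zero."""
    base, alt = base.align(alt)
    out = 100.0 * (alt - base) / base
    out[base == 0.0] = float("nan")
    return out


# ---------------------------------------------------------------------------
# file formats: inventory.csv, factors.csv, mixes.csv, scenario.json


def load_inventory(path) -> Inventory:
    """inventory.csv: flow_id, amount[, unit]."""
    df = pd.read_csv(path)
    return Inventory(dict(zip(df["flow_id"].astype(str), df["amount"].astype(float))))


def write_inventory(inv: Inventory, path, units: Mapping[str, str] | None = None) -> None:
    rows = [
        {"flow_id": fid, "amount": amount, "unit": (units or {}).get(fid, "")}
        for fid, amount in inv.flows.items()
    ]
    pd.DataFrame(rows, columns=["flow_id", "amount", "unit"]).to_csv(path, index=False)


def load_factors(path) -> CharacterizationSet:
    """factors.csv: flow_id, category_id, factor (long format)."""
    df = pd.read_csv(path)
    mat = df.pivot(index="flow_id", columns="category_id", values="factor").fillna(0.0)
    mat.index.name = None
    mat.columns.name = None
    return CharacterizationSet(mat)


def write_factors(cs: CharacterizationSet, path) -> None:
    long = cs.factors.stack().rename("factor").reset_index()
    long.columns = ["flow_id", "category_id", "factor"]
    long.to_csv(path, index=False)


def load_mixes(mixes_path, source_factors_path) -> dict[str, ElectricityMix]:
    """mixes.csv: country_id, source_id, share; factors in long format."""
    shares_df = pd.read_csv(mixes_path)
    src = pd.read_csv(source_factors_path)
    factors = src.pivot(index="source_id", columns="category_id", values="factor").fillna(0.0)
    factors.index.name = None
    factors.columns.name = None
    mixes = {}
    for country, grp in shares_df.groupby("country_id"):
        shares = dict(zip(grp["source_id"].astype(str), grp["share"].astype(float)))
        mixes[str(country)] = ElectricityMix(
            country_id=str(country), shares=shares, source_factors=factors
        )
    return mixes


def write_mixes(mixes: Mapping[str, ElectricityMix], mixes_path, source_factors_path) -> None:
    rows = [
        {"country_id": m.country_id, "source_id": src, "share": share}
        for m in mixes.values()
        for src, share in m.shares.items()
    ]
    pd.DataFrame(rows, columns=["country_id", "source_id", "share"]).to_csv(
        mixes_path, index=False
    )
    any_mix = next(iter(mixes.values()))
    long = any_mix.source_factors.stack().rename("factor").reset_index()
    long.columns = ["source_id", "category_id", "factor"]
    long.to_csv(source_factors_path, index=False)


def load_scenario(path) -> ScenarioSpec:
    import json

    with open(path, encoding="utf-8") as fh:
        obj = json.load(fh)
    return ScenarioSpec(**obj)
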