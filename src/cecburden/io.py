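"""Tabular input/output and data-preparation rules.

File schemas (comma-delimited, UTF-8, header mandatory, "." decimal):

``cec_table.csv``
    cec_id,name,category,conc_low,conc_mode,conc_high,lod,loq,ef_cancer,ef_noncancer
    Concentrations and limits in ng/L, effect factors in cases/kg; blank
    cells mean "absent".  A row with all three concentration cells blank is
    a non-detect and is censored to half its LOD (or LOQ; LOD wins when
    both are present).

``removal_table.csv``
    train_id,unit_id,cec_id,r_low,r_mode,r_high  (fractions in [0, 1])

``train.json``
    {"train_id": ..., "units": [{"unit_id": ..., "name": ...}, ...]}  in
    treatment order.

``context.json``
    {"sp", "ir_daily", "years", "df_cancer", "df_noncancer", "threshold"}

Missing (unit, chemical) removal entries are imputed with the
parameter-wise mean over same-category chemicals in the same unit.
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .distributions import DistributionSpec
from .risk import CATEGORIES, CECRecord, ExposureContext, TreatmentTrain, TreatmentUnit

__all__ = [
    "CEC_COLUMNS",
    "REMOVAL_COLUMNS",
    "LoadError",
    "ImputationError",
    "apply_censoring",
    "load_cec_table",
    "write_cec_table",
    "load_removal_table",
    "write_removal_table",
    "load_train",
    "write_train",
    "load_context",
    "write_context",
    "impute_removal",
    "build_train",
]

log = logging.getLogger(__name__)

CEC_COLUMNS = [
    "cec_id",
    "name",
    "category",
    "conc_low",
    "conc_mode",
    "conc_high",
    "lod",
    "loq",
    "ef_cancer",
    "ef_noncancer",
]
REMOVAL_COLUMNS = ["train_id", "unit_id", "cec_id", "r_low", "r_mode", "r_high"]


class LoadError(ValueError):
    """A file failed schema or invariant validation."""


class ImputationError(ValueError):
    """No same-category data available to impute a missing removal entry."""


def apply_censoring(value: float | None, limit: float | None) -> float:
    """Half-of-limit substitution for non-detects.

    A detected ``value`` passes through unchanged; a below-limit entry
    (``value is None``) becomes ``0.5 * limit``.  Idempotent: censored
    values are ordinary detected values on re-application.
    """
    if value is not None:
        if value < 0:
            raise LoadError("detected concentration must be non-negative")
        return float(value)
    if limit is None or not limit > 0:
        raise LoadError("below-limit entry with no positive LOD/LOQ available")
    return 0.5 * float(limit)


def _opt(row, col) -> float | None:
    v = row[col]
    return None if pd.isna(v) else float(v)


def _spec_from_params(low: float, mode: float, high: float) -> DistributionSpec:
    if low == mode == high:
        return DistributionSpec.point(mode)
    return DistributionSpec.triangular(low, mode, high)


def load_cec_table(path: str | Path) -> list[CECRecord]:
    """Read and validate a chemical table; apply censoring rules.

    Raises :class:`LoadError` naming the offending row on any invariant
    breach (unknown category, negative concentration, low > high,
    duplicate id, non-detect with no limit).
    """
    df = pd.read_csv(path)
    missing = [c for c in CEC_COLUMNS if c not in df.columns]
    if missing:
        raise LoadError(f"{path}: missing columns {missing}")
    records: list[CECRecord] = []
    seen: set[str] = set()
    for idx, row in df.iterrows():
        rowno = idx + 2  # header is line 1
        cec_id = str(row["cec_id"])
        if cec_id in seen:
            raise LoadError(f"{path} row {rowno}: duplicate cec_id {cec_id!r}")
        seen.add(cec_id)
        category = str(row["category"])
        if category not in CATEGORIES:
            raise LoadError(f"{path} row {rowno}: unknown category {category!r}")
        lod, loq = _opt(row, "lod"), _opt(row, "loq")
        low, mode, high = (_opt(row, c) for c in ("conc_low", "conc_mode", "conc_high"))
        try:
            if mode is None and low is None and high is None:
                limit = lod if lod is not None else loq
                cs = DistributionSpec.point(apply_censoring(None, limit))
                censored = True
            else:
                if mode is None:
                    raise LoadError("conc_mode missing on a detected row")
                low = mode if low is None else low
                high = mode if high is None else high
                if low < 0:
                    raise LoadError("negative concentration")
                cs = _spec_from_params(low, mode, high)
                censored = False
            records.append(
                CECRecord(
                    cec_id=cec_id,
                    name=str(row["name"]),
                    category=category,
                    cs=cs,
                    ef_cancer=_opt(row, "ef_cancer"),
                    ef_noncancer=_opt(row, "ef_noncancer"),
                    lod=lod,
                    censored=censored,
                )
            )
        except (ValueError, LoadError) as exc:
            raise LoadError(f"{path} row {rowno}: {exc}") from exc
    counts = Counter(r.category for r in records)
    log.info("loaded %d CECs from %s: %s", len(records), path, dict(counts))
    return records


def write_cec_table(records: Sequence[CECRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        if r.censored:
            conc = {"conc_low": None, "conc_mode": None, "conc_high": None}
        else:
            conc = {"conc_low": r.cs.low, "conc_mode": r.cs.mode, "conc_high": r.cs.high}
        rows.append(
            {
                "cec_id": r.cec_id,
                "name": r.name,
                "category": r.category,
                **conc,
                "lod": r.lod,
                "loq": None,
                "ef_cancer": r.ef_cancer,
                "ef_noncancer": r.ef_noncancer,
            }
        )
    pd.DataFrame(rows, columns=CEC_COLUMNS).to_csv(path, index=False)


@dataclass
class RemovalTable:
    """Long-format removal-rate distributions keyed by (train, unit, cec)."""

    df: pd.DataFrame

    def lookup(self, train_id: str, unit_id: str, cec_id: str) -> DistributionSpec | None:
        sel = self.df[
            (self.df["train_id"] == train_id)
            & (self.df["unit_id"] == unit_id)
            & (self.df["cec_id"] == cec_id)
        ]
        if sel.empty:
            return None
        row = sel.iloc[0]
        return _spec_from_params(row["r_low"], row["r_mode"], row["r_high"])


def load_removal_table(path: str | Path) -> RemovalTable:
    df = pd.read_csv(path)
    missing = [c for c in REMOVAL_COLUMNS if c not in df.columns]
    if missing:
        raise LoadError(f"{path}: missing columns {missing}")
    for idx, row in df.iterrows():
        rowno = idx + 2
        lo, mo, hi = row["r_low"], row["r_mode"], row["r_high"]
        if not (0.0 <= lo <= mo <= hi <= 1.0):
            raise LoadError(
                f"{path} row {rowno}: removal parameters ({lo}, {mo}, {hi}) "
                "must satisfy 0 <= low <= mode <= high <= 1"
            )
    dup = df.duplicated(subset=["train_id", "unit_id", "cec_id"])
    if dup.any():
        raise LoadError(f"{path} row {dup.idxmax() + 2}: duplicate (train, unit, cec)")
    return RemovalTable(df)


def write_removal_table(table: RemovalTable, path: str | Path) -> None:
    table.df.to_csv(path, index=False, columns=REMOVAL_COLUMNS)


@dataclass(frozen=True)
class TrainDefinition:
    """Ordered unit list for one train; removal data lives in RemovalTable."""

    train_id: str
    units: tuple[tuple[str, str], ...]  # (unit_id, name) in treatment order


def load_train(path: str | Path) -> TrainDefinition:
    with open(path, encoding="utf-8") as fh:
        obj = json.load(fh)
    units = tuple((u["unit_id"], u.get("name", u["unit_id"])) for u in obj["units"])
    if len({u[0] for u in units}) != len(units):
        raise LoadError(f"{path}: duplicate unit ids")
    return TrainDefinition(train_id=obj["train_id"], units=units)


def write_train(train: TrainDefinition, path: str | Path) -> None:
    obj = {
        "train_id": train.train_id,
        "units": [{"unit_id": uid, "name": name} for uid, name in train.units],
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2)
        fh.write("\n")


def load_context(path: str | Path) -> ExposureContext:
    with open(path, encoding="utf-8") as fh:
        obj = json.load(fh)
    return ExposureContext(**obj)


def write_context(ctx: ExposureContext, path: str | Path) -> None:
    obj = {
        "sp": ctx.sp,
        "ir_daily": ctx.ir_daily,
        "years": ctx.years,
        "df_cancer": ctx.df_cancer,
        "df_noncancer": ctx.df_noncancer,
        "threshold": ctx.threshold,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2)
        fh.write("\n")


def impute_removal(
    train_id: str,
    unit_id: str,
    cec: CECRecord,
    cecs: Sequence[CECRecord],
    table: RemovalTable,
) -> DistributionSpec:
    """Category-mean imputation of a missing removal distribution.

    Takes the element-wise mean of (low, mode, high) over all same-category
    chemicals with data for this unit.
    """
    peers = {c.cec_id for c in cecs if c.category == cec.category and c.cec_id != cec.cec_id}
    sel = table.df[
        (table.df["train_id"] == train_id)
        & (table.df["unit_id"] == unit_id)
        & (table.df["cec_id"].isin(peers))
    ]
    if sel.empty:
        raise ImputationError(
            f"no {cec.category} removal data in unit {unit_id} (train {train_id}) "
            f"to impute {cec.cec_id}"
        )
    lo = float(sel["r_low"].mean())
    mo = float(sel["r_mode"].mean())
    hi = float(sel["r_high"].mean())
    return _spec_from_params(lo, mo, hi)


def build_train(
    definition: TrainDefinition,
    table: RemovalTable,
    cecs: Sequence[CECRecord],
) -> TreatmentTrain:
    """Assemble a fully specified train, imputing missing removal entries."""
    units = []
    n_imputed = 0
    for unit_id, name in definition.units:
        removal: dict[str, DistributionSpec] = {}
        for cec in cecs:
            spec = table.lookup(definition.train_id, unit_id, cec.cec_id)
            if spec is None:
                spec = impute_removal(definition.train_id, unit_id, cec, cecs, table)
                n_imputed += 1
            removal[cec.cec_id] = spec
        units.append(TreatmentUnit(unit_id=unit_id, name=name, removal=removal))
    if n_imputed:
        log.info("train %s: imputed %d removal entries", definition.train_id, n_imputed)
    return TreatmentTrain(train_id=definition.train_id, units=tuple(units))
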