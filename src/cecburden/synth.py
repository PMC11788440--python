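"""Seeded synthetic study inputs.

Three generators cover the pipeline's input surface:

* :func:`generate_cec_dataset` — a study-scale chemical table (93 chemicals
  across six categories by default), with triangular concentration and
  effect-factor uncertainty, LOD-censored non-detects, and two treatment
  trains (a 6-unit membrane train and a 7-unit conventional extended train)
  whose removal tables contain deliberate gaps to exercise imputation.
* :func:`generate_two_system_benchmark` — a small paired-train scenario with
  planted stochastic dominance and analytically known expected burdens, for
  parameter-recovery testing.
* :func:`generate_lci_fixture` — synthetic inventories, characterization
  factors and electricity mixes for the impact engine (stand-ins for
  proprietary background databases; all values are invented).

Every artifact draws from a named sub-stream of one global seed, so adding
an output never shifts the draws of existing ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .distributions import DistributionSpec, substream
from .io import REMOVAL_COLUMNS, RemovalTable, TrainDefinition
from .lca import DEFAULT_CATEGORIES, CharacterizationSet, ElectricityMix, Inventory
from .risk import CECRecord, ExposureContext, TreatmentTrain, TreatmentUnit

__all__ = [
    "DEFAULT_CATEGORY_COUNTS",
    "RO_TRAIN_UNITS",
    "ET_TRAIN_UNITS",
    "SynthConfig",
    "CECDataset",
    "generate_cec_dataset",
    "BenchmarkBundle",
    "generate_two_system_benchmark",
    "LCIFixture",
    "generate_lci_fixture",
]

DEFAULT_CATEGORY_COUNTS = {
    "pesticide": 41,
    "industrial": 19,
    "pharmaceutical": 17,
    "antibiotic": 7,
    "DBP": 5,
    "PCP": 4,
}

#: 6-unit membrane train: bank filtration, reverse osmosis, polishing steps.
RO_TRAIN_UNITS = (
    ("rbf", "riverbank filtration"),
    ("ro", "reverse osmosis"),
    ("ion_exchange", "ion exchange"),
    ("remineralization", "remineralization"),
    ("oxygenation", "oxygenation"),
    ("degasification", "degasification"),
)

#: 7-unit conventional extended train.
ET_TRAIN_UNITS = (
    ("rbf", "riverbank filtration"),
    ("dry_filtration", "biological iron removal / dry filtration"),
    ("pellet_softening", "pellet softening"),
    ("carryover_filtration", "carry-over filtering"),
    ("ion_exchange", "ion exchange"),
    ("gac", "granular activated carbon"),
    ("uv", "UV disinfection"),
)

#: Removal-fraction mode ranges per unit class, loosely typical of each
#: process class (membranes strong, polishing steps weak).
DEFAULT_REMOVAL_PROFILES = {
    "rbf": (0.20, 0.60),
    "ro": (0.85, 0.99),
    "ion_exchange": (0.00, 0.30),
    "remineralization": (0.00, 0.05),
    "oxygenation": (0.00, 0.10),
    "degasification": (0.00, 0.10),
    "dry_filtration": (0.10, 0.40),
    "pellet_softening": (0.00, 0.20),
    "carryover_filtration": (0.05, 0.30),
    "gac": (0.30, 0.80),
    "uv": (0.00, 0.30),
}


@dataclass(frozen=True)
class SynthConfig:
    """Knobs of the study-scale generator.

    Concentration modes are log-uniform over ``10**conc_log10_range`` ng/L
    (sub-ng/L to low-ug/L), effect factors log-uniform over
    ``10**ef_log10_range`` cases/kg spanning roughly four orders of
    magnitude, with the DBP category drawn from the top half of that range
    (high-toxicity byproducts).  ``rel_half_width`` sets the triangular
    spread around each mode; ``missing_removal_frac`` and ``censored_frac``
    control the deliberate data gaps.
    """

    category_counts: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_COUNTS)
    )
    conc_log10_range: tuple[float, float] = (0.0, 3.0)
    ef_log10_range: tuple[float, float] = (-3.0, 1.1)
    removal_profiles: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_REMOVAL_PROFILES)
    )
    removal_half_width: float = 0.05
    missing_removal_frac: float = 0.10
    censored_frac: float = 0.10
    cancer_ef_prob: float = 0.80
    rel_half_width: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.category_counts.values()):
            raise ValueError("category counts must be >= 0")
        if sum(self.category_counts.values()) == 0:
            raise ValueError("at least one chemical must be generated")
        for name in ("missing_removal_frac", "censored_frac", "cancer_ef_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        for rng_name in ("conc_log10_range", "ef_log10_range"):
            lo, hi = getattr(self, rng_name)
            if lo > hi:
                raise ValueError(f"{rng_name} must be ordered")


@dataclass
class CECDataset:
    """Generator output: chemical records, removal table, train definitions."""

    cecs: list[CECRecord]
    removal_table: RemovalTable
    trains: list[TrainDefinition]
    ctx: ExposureContext


def _triangular_around(mode: float, rel_half_width: float) -> DistributionSpec:
    low = mode * (1.0 - rel_half_width)
    high = mode * (1.0 + rel_half_width)
    if low == high:
        return DistributionSpec.point(mode)
    return DistributionSpec.triangular(low, mode, high)


def generate_cec_dataset(cfg: SynthConfig) -> CECDataset:
    """Generate a full study-scale input bundle (seeded, reproducible)."""
    rng_conc = substream(cfg.seed, "cec/concentration")
    rng_ef = substream(cfg.seed, "cec/effect-factor")
    rng_cens = substream(cfg.seed, "cec/censoring")
    rng_rem = substream(cfg.seed, "removal/modes")
    rng_gap = substream(cfg.seed, "removal/gaps")

    lo_c, hi_c = cfg.conc_log10_range
    lo_e, hi_e = cfg.ef_log10_range
    cecs: list[CECRecord] = []
    n = 0
    for category in sorted(cfg.category_counts):
        for j in range(cfg.category_counts[category]):
            n += 1
            cec_id = f"cec{n:03d}"
            mode = 10.0 ** rng_conc.uniform(lo_c, hi_c)
            censored = bool(rng_cens.random() < cfg.censored_frac)
            if category == "DBP":
                # byproducts sit in the high-toxicity tail
                ef_nc = 10.0 ** rng_ef.uniform(0.5 * (lo_e + hi_e), hi_e)
                ef_ca = 10.0 ** rng_ef.uniform(0.5 * (lo_e + hi_e), hi_e)
                has_cancer = True
            else:
                ef_nc = 10.0 ** rng_ef.uniform(lo_e, hi_e)
                ef_ca = 10.0 ** rng_ef.uniform(lo_e, hi_e)
                has_cancer = bool(rng_ef.random() < cfg.cancer_ef_prob)
            if censored:
                cs = DistributionSpec.point(0.5 * mode)
                lod: float | None = mode
            else:
                cs = _triangular_around(mode, cfg.rel_half_width)
                lod = None
            cecs.append(
                CECRecord(
                    cec_id=cec_id,
                    name=f"{category} {j + 1}",
                    category=category,
                    cs=cs,
                    ef_cancer=ef_ca if has_cancer else None,
                    ef_noncancer=ef_nc,
                    lod=lod,
                    censored=censored,
                )
            )

    trains = [
        TrainDefinition("rbf_ro", RO_TRAIN_UNITS),
        TrainDefinition("rbf_et", ET_TRAIN_UNITS),
    ]
    rows = []
    for train in trains:
        for unit_id, _name in train.units:
            rmin, rmax = cfg.removal_profiles[unit_id]
            for cec in cecs:
                mode = rng_rem.uniform(rmin, rmax)
                if rng_gap.random() < cfg.missing_removal_frac:
                    continue  # deliberate gap: exercised by imputation
                low = max(0.0, mode - cfg.removal_half_width)
                high = min(1.0, mode + cfg.removal_half_width)
                rows.append(
                    {
                        "train_id": train.train_id,
                        "unit_id": unit_id,
                        "cec_id": cec.cec_id,
                        "r_low": low,
                        "r_mode": mode,
                        "r_high": high,
                    }
                )
    table = RemovalTable(pd.DataFrame(rows, columns=REMOVAL_COLUMNS))
    return CECDataset(cecs=cecs, removal_table=table, trains=trains, ctx=ExposureContext())


@dataclass
class BenchmarkBundle:
    """Paired-train scenario with analytically known expected burdens.

    The membrane-style train stochastically dominates the conventional
    train on removal for every chemical (disjoint residual-fraction
    supports), so with shared source-water draws every iteration favours
    it.  ``expected`` maps (train_id, endpoint) to the exact expected
    additive annual burden.
    """

    cecs: list[CECRecord]
    ref_train: TreatmentTrain  # conventional
    alt_train: TreatmentTrain  # membrane-style, dominating
    ctx: ExposureContext
    expected: dict[tuple[str, str], float]


def _expected_total(
    cecs: Sequence[CECRecord], train: TreatmentTrain, ctx: ExposureContext, endpoint: str
) -> float:
    """E[additive total] under independent triangular draws (exact)."""
    intake_l = ctx.ir_daily * 365.0 * ctx.years
    total = 0.0
    for cec in cecs:
        ef = cec.effect_factor(endpoint)
        if ef is None:
            continue
        resid = 1.0
        for unit in train.units:
            resid *= 1.0 - unit.removal[cec.cec_id].mean()
        he = ef * ctx.damage_factor(endpoint) * ctx.sp * intake_l * cec.cs.mean() * resid * 1e-12
        total += he / (ctx.sp * ctx.years)
    return total


def generate_two_system_benchmark(seed: int) -> BenchmarkBundle:
    """Six-chemical paired scenario with planted dominance.

    Conventional-train removals stay below 0.25 per unit (residual fraction
    >= 0.75**7 ~ 0.133 over 7 units) while the membrane train carries one
    0.90-0.99 unit (residual fraction <= 0.10), so the membrane train's
    residual concentration is lower for every possible draw.
    """
    rng = substream(seed, "benchmark/cs")
    rng_r = substream(seed, "benchmark/removal")
    ctx = ExposureContext()
    cecs = []
    for i, category in enumerate(
        ("pesticide", "industrial", "pharmaceutical", "antibiotic", "DBP", "PCP")
    ):
        mode = 10.0 ** rng.uniform(1.0, 2.5)
        cecs.append(
            CECRecord(
                cec_id=f"bench{i + 1}",
                name=f"benchmark {category}",
                category=category,
                cs=DistributionSpec.triangular(0.5 * mode, mode, 1.5 * mode),
                ef_cancer=10.0 ** rng.uniform(-2.0, 1.0),
                ef_noncancer=10.0 ** rng.uniform(-2.0, 1.0),
            )
        )

    def unit(unit_id: str, name: str, lo_mode: float, hi_mode: float, hw: float) -> TreatmentUnit:
        removal = {}
        for cec in cecs:
            m = rng_r.uniform(lo_mode, hi_mode)
            removal[cec.cec_id] = DistributionSpec.triangular(m - hw, m, m + hw)
        return TreatmentUnit(unit_id=unit_id, name=name, removal=removal)

    ref_units = tuple(
        unit(uid, name, 0.10, 0.20, 0.05) for uid, name in ET_TRAIN_UNITS
    )
    alt_units = []
    for uid, name in RO_TRAIN_UNITS:
        if uid == "ro":
            alt_units.append(unit(uid, name, 0.945, 0.945, 0.045))  # modes 0.945, range [0.90, 0.99]
        else:
            alt_units.append(unit(uid, name, 0.02, 0.08, 0.02))
    ref_train = TreatmentTrain("bench_et", ref_units)
    alt_train = TreatmentTrain("bench_ro", tuple(alt_units))
    expected = {
        (train.train_id, endpoint): _expected_total(cecs, train, ctx, endpoint)
        for train in (ref_train, alt_train)
        for endpoint in ("cancer", "noncancer")
    }
    return BenchmarkBundle(cecs, ref_train, alt_train, ctx, expected)


ELECTRICITY_SOURCES = ("coal", "lignite", "gas", "nuclear", "hydro", "wind", "solar")

#: Planted per-kWh global-warming ordering (fossil sources dirtiest).
_GW_PER_KWH = {
    "coal": 1.05,
    "lignite": 1.20,
    "gas": 0.50,
    "nuclear": 0.012,
    "hydro": 0.004,
    "wind": 0.011,
    "solar": 0.045,
}

_COUNTRY_MIXES = {
    "coaland": {"coal": 0.65, "lignite": 0.15, "gas": 0.15, "hydro": 0.05},
    "hydroland": {"hydro": 0.75, "wind": 0.15, "gas": 0.10},
    "mixland": {"coal": 0.25, "gas": 0.30, "nuclear": 0.20, "hydro": 0.15, "wind": 0.10},
}


@dataclass
class LCIFixture:
    """Synthetic impact-engine inputs (all values invented stand-ins)."""

    inventories: dict[str, Inventory]
    factors: CharacterizationSet
    mixes: dict[str, ElectricityMix]


def generate_lci_fixture(seed: int) -> LCIFixture:
    """Two system inventories, a 10-category factor matrix, country mixes."""
    rng = substream(seed, "lci/factors")
    flows = [
        "electricity",
        "membrane",
        "antiscalant",
        "coagulant",
        "activated_carbon",
        "softening_pellets",
        "sludge_disposal",
        "transport_truck",
        "transport_ship",
    ]
    factors = pd.DataFrame(
        10.0 ** rng.uniform(-3.0, 0.0, size=(len(flows), len(DEFAULT_CATEGORIES))),
        index=flows,
        columns=list(DEFAULT_CATEGORIES),
    )
    inventories = {
        # membrane train: power- and membrane-intensive, few chemicals
        "rbf_ro": Inventory(
            {
                "electricity": float(rng.uniform(0.8, 1.2)),
                "membrane": float(rng.uniform(0.001, 0.003)),
                "antiscalant": float(rng.uniform(0.005, 0.02)),
                "sludge_disposal": float(rng.uniform(0.01, 0.03)),
                "transport_truck": float(rng.uniform(0.05, 0.15)),
                "transport_ship": 0.0,
            }
        ),
        # conventional train: chemical-intensive, moderate power
        "rbf_et": Inventory(
            {
                "electricity": float(rng.uniform(0.4, 0.7)),
                "coagulant": float(rng.uniform(0.02, 0.08)),
                "activated_carbon": float(rng.uniform(0.01, 0.05)),
                "softening_pellets": float(rng.uniform(0.02, 0.06)),
                "sludge_disposal": float(rng.uniform(0.02, 0.06)),
                "transport_truck": float(rng.uniform(0.05, 0.15)),
                "transport_ship": 0.0,
            }
        ),
    }
    src = pd.DataFrame(
        10.0 ** rng.uniform(-4.0, -1.0, size=(len(ELECTRICITY_SOURCES), len(DEFAULT_CATEGORIES))),
        index=list(ELECTRICITY_SOURCES),
        columns=list(DEFAULT_CATEGORIES),
    )
    src["global_warming"] = pd.Series(_GW_PER_KWH)  # planted ordering
    mixes = {
        country: ElectricityMix(country_id=country, shares=shares, source_factors=src)
        for country, shares in _COUNTRY_MIXES.items()
    }
    return LCIFixture(
        inventories=inventories,
        factors=CharacterizationSet(factors),
        mixes=mixes,
    )
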