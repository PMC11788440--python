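"""Monte Carlo propagation of input uncertainty to disease burdens.

Each iteration draws one source-water concentration per chemical — shared
across treatment trains, since both systems treat the same source water —
and independent removal fractions per (train, unit, chemical).  Burdens are
evaluated with the deterministic chain of :mod:`cecburden.risk` and
aggregated per endpoint, per category and per chemical.  Every draw comes
from a named sub-stream of one global seed keyed by (chemical) or (train,
unit, chemical), so results are reproducible and adding a unit never
perturbs other draws.

Summaries report the median with 5th/95th percentile variability and the
mean with a 95% percentile interval of the simulated distribution;
threshold compliance uses an inclusive comparison against the tolerable
burden.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .distributions import DistributionSpec, substream
from .risk import ENDPOINTS, CECRecord, ExposureContext, TreatmentTrain

__all__ = [
    "MCResult",
    "SummaryStats",
    "sample",
    "run_mc",
    "cpdf",
    "compliance_fraction",
    "paired_benefit",
    "summarize",
    "convergence_check",
]


def sample(spec: DistributionSpec, u):
    """Inverse-CDF transform of uniform variates through a spec."""
    return spec.ppf(u)


@dataclass
class MCResult:
    """Simulation output for one train (or the raw source water).

    ``totals`` maps endpoint -> (n_iter,) mixture totals in DALYs per
    person per year; ``per_cec`` maps endpoint -> DataFrame (iteration x
    chemical) of additive per-chemical burdens.  ``inputs`` holds recorded
    input draws (``cs:<cec>``, ``r:<unit>:<cec>``) when requested, for
    rank-correlation sensitivity analysis.
    """

    train_id: str
    n_iter: int
    seed: int
    mixture_mode: str
    totals: dict[str, np.ndarray]
    per_cec: dict[str, pd.DataFrame]
    categories: dict[str, str]  # cec_id -> category
    inputs: dict[str, np.ndarray] = field(default_factory=dict)
    sampled_params: tuple[str, ...] = ()

    def category_totals(self, endpoint: str) -> pd.DataFrame:
        """Additive per-category burdens, iteration x category."""
        df = self.per_cec[endpoint]
        return df.T.groupby(self.categories).sum().T


@dataclass(frozen=True)
class SummaryStats:
    """Central tendency and variability of a simulated burden."""

    median: float
    p5: float
    p95: float
    mean: float
    interval95: tuple[float, float]

    def as_dict(self) -> dict:
        return {
            "median": self.median,
            "p5": self.p5,
            "p95": self.p95,
            "mean": self.mean,
            "interval95": list(self.interval95),
        }


def _aggregate_matrix(
    burdens: np.ndarray, mode: str, df_: float, years: float
) -> np.ndarray:
    """Vectorised mixture aggregation over an (iteration x chemical) matrix."""
    if burdens.shape[1] == 0:
        return np.zeros(burdens.shape[0])
    if mode == "additive":
        return burdens.sum(axis=1)
    if mode == "dominant":
        return burdens.max(axis=1)
    if mode == "multiplicative":
        p = burdens * years / df_
        if np.any(p >= 1.0):
            raise ValueError("per-chemical case probability >= 1 in multiplicative mode")
        combined = -np.expm1(np.sum(np.log1p(-p), axis=1))
        return combined * df_ / years
    raise ValueError(f"unknown mixture mode {mode!r}")


def run_mc(
    cecs: Sequence[CECRecord],
    trains: Sequence[TreatmentTrain | None],
    ctx: ExposureContext,
    n_iter: int = 10_000,
    seed: int = 0,
    mixture_mode: str = "additive",
    record_inputs: bool = False,
    shared_cs: bool = True,
) -> dict[str, MCResult]:
    """Propagate input distributions through each train.

    ``trains`` may contain ``None`` for the untreated source water (keyed
    ``"source"`` in the result).  With ``shared_cs`` (default) the same
    source-concentration draws feed every train per iteration, making
    paired differencing well-defined; removal draws are always independent
    per train and unit.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    if not cecs:
        raise ValueError("run_mc requires at least one chemical")
    cec_ids = [c.cec_id for c in cecs]
    categories = {c.cec_id: c.category for c in cecs}
    intake_l = ctx.ir_daily * 365.0 * ctx.years
    # per-person annual burden per unit residual concentration (ng/L)
    unit_burden = {
        ep: {
            c.cec_id: (
                0.0
                if c.effect_factor(ep) is None
                else c.effect_factor(ep) * ctx.damage_factor(ep) * intake_l * 1e-12 / ctx.years
            )
            for c in cecs
        }
        for ep in ENDPOINTS
    }

    shared_cs_draws = {
        c.cec_id: sample(c.cs, substream(seed, f"cs/{c.cec_id}").random(n_iter))
        for c in cecs
    } if shared_cs else None

    results: dict[str, MCResult] = {}
    for train in trains:
        train_key = "source" if train is None else train.train_id
        inputs: dict[str, np.ndarray] = {}
        sampled: list[str] = []
        if shared_cs:
            cs_draws = shared_cs_draws
        else:
            cs_draws = {
                c.cec_id: sample(
                    c.cs, substream(seed, f"cs/{train_key}/{c.cec_id}").random(n_iter)
                )
                for c in cecs
            }
        resid = np.ones((n_iter, len(cecs)))
        if train is not None:
            for unit in train.units:
                for j, cec in enumerate(cecs):
                    spec = unit.removal[cec.cec_id]
                    u = substream(seed, f"r/{train_key}/{unit.unit_id}/{cec.cec_id}").random(
                        n_iter
                    )
                    r = sample(spec, u)
                    resid[:, j] *= 1.0 - r
                    name = f"r:{unit.unit_id}:{cec.cec_id}"
                    sampled.append(name)
                    if record_inputs:
                        inputs[name] = r
        cs_mat = np.column_stack([cs_draws[cid] for cid in cec_ids])
        ce = cs_mat * resid  # residual concentrations, iteration x chemical
        for cid in cec_ids:
            sampled.append(f"cs:{cid}")
        if record_inputs:
            for j, cid in enumerate(cec_ids):
                inputs[f"cs:{cid}"] = cs_mat[:, j]
        totals: dict[str, np.ndarray] = {}
        per_cec: dict[str, pd.DataFrame] = {}
        for ep in ENDPOINTS:
            w = np.array([unit_burden[ep][cid] for cid in cec_ids])
            burdens = ce * w  # zero columns where the endpoint EF is absent
            keep = [j for j, c in enumerate(cecs) if c.effect_factor(ep) is not None]
            per_cec[ep] = pd.DataFrame(
                burdens[:, keep], columns=[cec_ids[j] for j in keep]
            )
            totals[ep] = _aggregate_matrix(
                burdens[:, keep], mixture_mode, ctx.damage_factor(ep), ctx.years
            )
        results[train_key] = MCResult(
            train_id=train_key,
            n_iter=n_iter,
            seed=seed,
            mixture_mode=mixture_mode,
            totals=totals,
            per_cec=per_cec,
            categories=categories,
            inputs=inputs,
            sampled_params=tuple(sampled),
        )
    return results


def cpdf(samples) -> list[tuple[float, float]]:
    """Empirical CDF points: P(X <= x) = rank/n at each sorted sample."""
    x = np.sort(np.asarray(samples, dtype=float))
    if x.size == 0:
        raise ValueError("cpdf requires at least one sample")
    n = x.size
    return [(float(v), float(k + 1) / n) for k, v in enumerate(x)]


def compliance_fraction(samples, threshold: float) -> float:
    """Percent of iterations at or below the tolerable burden (inclusive)."""
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    x = np.asarray(samples, dtype=float)
    return 100.0 * float(np.count_nonzero(x <= threshold)) / x.size


def paired_benefit(
    mc_ref: MCResult, mc_alt: MCResult, endpoint: str
) -> tuple[np.ndarray, float]:
    """Per-iteration burden differences alt - ref and the benefit percent.

    Negative differences are health benefits of switching from the
    reference to the alternative train; the benefit percent counts strictly
    negative differences.
    """
    if mc_ref.n_iter != mc_alt.n_iter:
        raise ValueError("paired_benefit requires equal iteration counts")
    if mc_ref.seed != mc_alt.seed:
        raise ValueError("paired_benefit requires a shared seed lineage")
    diff = mc_alt.totals[endpoint] - mc_ref.totals[endpoint]
    benefit = 100.0 * float(np.count_nonzero(diff < 0.0)) / mc_ref.n_iter
    return diff, benefit


def summarize(samples) -> SummaryStats:
    """Median, 5th/95th percentiles, mean and 95% percentile interval.

    Quantiles use linear interpolation between order statistics (the
    type-7 convention).
    """
    x = np.asarray(samples, dtype=float)
    if x.size < 2:
        raise ValueError("summarize requires at least 2 samples")
    p5, p50, p95 = np.percentile(x, [5.0, 50.0, 95.0])
    lo, hi = np.percentile(x, [2.5, 97.5])
    return SummaryStats(
        median=float(p50),
        p5=float(p5),
        p95=float(p95),
        mean=float(x.mean()),
        interval95=(float(lo), float(hi)),
    )


def convergence_check(
    run_a: MCResult, run_b: MCResult, tol: float = 0.05, eps: float = 1e-30
) -> tuple[float, bool]:
    """Max relative deviation of summary statistics between two seeds.

    Used to verify that the iteration count is adequate: two runs of the
    same configuration under different seeds should agree to within ``tol``
    on every summary statistic of every endpoint total.
    """
    if run_a.seed == run_b.seed:
        raise ValueError("convergence check requires different seeds")
    if run_a.n_iter != run_b.n_iter:
        raise ValueError("convergence check requires equal iteration counts")
    worst = 0.0
    for ep in run_a.totals:
        sa, sb = summarize(run_a.totals[ep]), summarize(run_b.totals[ep])
        for name in ("median", "p5", "p95", "mean"):
            a, b = getattr(sa, name), getattr(sb, name)
            worst = max(worst, abs(a - b) / max(abs(a), abs(b), eps))
    return worst, worst <= tol
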