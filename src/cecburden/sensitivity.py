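"""Sensitivity analysis: rank correlation over MC draws and ±20% OAT.

Two complementary views of what drives the modelled burdens:

* :func:`mc_sensitivity` computes Spearman rank correlations between the
  recorded Monte Carlo input draws (source concentrations, unit removal
  fractions) and the endpoint burden totals, identifying the chemicals and
  units the burden is most sensitive to.
* :func:`oat_sensitivity` perturbs one scalar model input at a time by a
  relative ``delta`` (20% by default) and reports the sensitivity
  coefficient — relative output change over relative input change — for
  each direction and their mean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Mapping

import numpy as np
from scipy import stats

from .mc import MCResult

__all__ = [
    "SensitivityReport",
    "spearman_rho",
    "mc_sensitivity",
    "oat_sensitivity",
]


def spearman_rho(x, y) -> float:
    """Spearman rank correlation (tie-aware, average ranks).

    Returns NaN for constant input vectors, where the correlation is
    undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    if x.size < 3:
        raise ValueError("spearman_rho requires at least 3 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan")
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


def mc_sensitivity(mc: MCResult, endpoint: str) -> dict[str, float]:
    """Rank correlation of every recorded input draw with the burden total.

    Requires ``run_mc(..., record_inputs=True)``; point (constant) inputs
    yield NaN.
    """
    if not mc.inputs:
        raise ValueError(
            "no input draws recorded; rerun the simulation with record_inputs=True"
        )
    out = mc.totals[endpoint]
    return {name: spearman_rho(draws, out) for name, draws in mc.inputs.items()}


@dataclass(frozen=True)
class SensitivityReport:
    """Spearman coefficients per endpoint plus OAT coefficients per metric."""

    spearman: Mapping[str, Mapping[str, float]]  # endpoint -> param -> rho
    oat: Mapping[str, Mapping[str, float]]  # param -> {sc_plus, sc_minus, sc_mean}


def oat_sensitivity(
    model: Callable[[float], float], base: float, delta: float = 0.20
) -> dict[str, float]:
    """One-factor-at-a-time sensitivity coefficient at ``base ± delta``.

    ``sc_± = ((model(base·(1±δ)) − model(base)) / model(base)) / (±δ)``;
    the headline value is the mean of the two one-sided coefficients.
    A zero base output makes the coefficient undefined (all NaN).
    """
    if not 0.0 < delta < 1.0:
        raise ValueError("delta must lie in (0, 1)")
    out0 = model(base)
    if out0 == 0.0 or not math.isfinite(out0):
        return {"sc_plus": float("nan"), "sc_minus": float("nan"), "sc_mean": float("nan")}
    sc_plus = ((model(base * (1.0 + delta)) - out0) / out0) / delta
    sc_minus = ((model(base * (1.0 - delta)) - out0) / out0) / (-delta)
    return {
        "sc_plus": float(sc_plus),
        "sc_minus": float(sc_minus),
        "sc_mean": float(0.5 * (sc_plus + sc_minus)),
    }
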