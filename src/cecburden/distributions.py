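"""Scalar uncertainty descriptions used for every stochastic model input.

Concentrations, removal rates and (optionally) toxicity factors are carried
around as min/mode/max triangular specifications, with point (degenerate) and
uniform specs as special cases.  Sampling goes through the inverse CDF so that
a single uniform stream drives every draw reproducibly.
"""

from __future__ import annotations

from dataclasses import dataclass
from zlib import crc32

import numpy as np

__all__ = ["DistributionSpec", "substream"]


@dataclass(frozen=True)
class DistributionSpec:
    """A point, triangular or uniform distribution on a scalar input.

    Parameters
    ----------
    kind:
        One of ``"point"``, ``"triangular"``, ``"uniform"``.
    low, mode, high:
        Minimum, mode and maximum.  A point spec requires all three equal;
        a uniform spec ignores ``mode`` for sampling but still requires
        ``low <= mode <= high``.
    """

    kind: str
    low: float
    mode: float
    high: float

    def __post_init__(self) -> None:
        if self.kind not in ("point", "triangular", "uniform"):
            raise ValueError(f"unknown distribution kind {self.kind!r}")
        for v in (self.low, self.mode, self.high):
            if not np.isfinite(v):
                raise ValueError("distribution parameters must be finite")
        if not (self.low <= self.mode <= self.high):
            raise ValueError(
                f"require low <= mode <= high, got ({self.low}, {self.mode}, {self.high})"
            )
        if self.kind == "point" and not (self.low == self.mode == self.high):
            raise ValueError("point distribution requires low = mode = high")

    @classmethod
    def point(cls, value: float) -> "DistributionSpec":
        return cls("point", value, value, value)

    @classmethod
    def triangular(cls, low: float, mode: float, high: float) -> "DistributionSpec":
        return cls("triangular", low, mode, high)

    @classmethod
    def uniform(cls, low: float, high: float) -> "DistributionSpec":
        return cls("uniform", low, 0.5 * (low + high), high)

    @property
    def is_degenerate(self) -> bool:
        return self.low == self.high

    def mean(self) -> float:
        if self.kind == "point" or self.is_degenerate:
            return self.mode
        if self.kind == "triangular":
            return (self.low + self.mode + self.high) / 3.0
        return 0.5 * (self.low + self.high)

    def var(self) -> float:
        if self.kind == "point" or self.is_degenerate:
            return 0.0
        a, c, b = self.low, self.mode, self.high
        if self.kind == "triangular":
            return (a * a + b * b + c * c - a * b - a * c - b * c) / 18.0
        return (b - a) ** 2 / 12.0

    def ppf(self, u):
        """Inverse CDF, vectorised over ``u`` in [0, 1]."""
        u = np.asarray(u, dtype=float)
        if np.any((u < 0.0) | (u > 1.0)):
            raise ValueError("u must lie in [0, 1]")
        if self.kind == "point" or self.is_degenerate:
            return np.full_like(u, self.mode)
        a, c, b = self.low, self.mode, self.high
        if self.kind == "uniform":
            return a + u * (b - a)
        # triangular: piecewise square-root inverse
        fc = (c - a) / (b - a)
        left = a + np.sqrt(u * (b - a) * (c - a))
        right = b - np.sqrt((1.0 - u) * (b - a) * (b - c))
        if c == a:
            return right
        if c == b:
            return left
        return np.where(u <= fc, left, right)

    def sample(self, rng: np.random.Generator, size=None):
        return self.ppf(rng.random(size))


def substream(seed: int, name: str) -> np.random.Generator:
    """A named, independent random sub-stream derived from one global seed.

    Each (seed, name) pair yields a fixed generator regardless of how many
    other streams exist, so adding a new sampled artifact never perturbs
    existing draws.
    """
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) % (2**31), crc32(name.encode("utf-8"))])
    )
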