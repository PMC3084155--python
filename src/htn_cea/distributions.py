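"""Sampling distributions attached to model parameters.

Every scalar input of the decision model carries both a base-case value
(used for deterministic runs) and a sampling law (used by the
probabilistic sensitivity analysis).  Four laws are supported:

* ``uniform(p1, p2)`` — lower / upper bound,
* ``lognormal(p1, p2)`` — mean and sd of the natural logarithm,
* ``normal(p1, p2)`` — mean and sd,
* ``fixed`` — never resampled.

Normal draws for probabilities and hazard ratios are truncated to their
valid range by resampling; at the sd values used here truncation is
astronomically rare, but the sampler is total regardless.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

__all__ = ["DistributionSpec", "ValidationError", "fixed", "uniform", "lognormal", "normal"]

_KINDS = ("uniform", "lognormal", "normal", "fixed")


class ValidationError(ValueError):
    """An input value violates a model-parameter constraint."""


@dataclass(frozen=True)
class DistributionSpec:
    """A base-case value together with its sampling law.

    Parameters
    ----------
    kind:
        One of ``uniform``, ``lognormal``, ``normal``, ``fixed``.
    base:
        Base-case scalar used in deterministic evaluations.
    p1, p2:
        Law parameters (see module docstring); ignored for ``fixed``.
    lower, upper:
        Optional truncation bounds enforced by resampling.
    integer:
        If true, draws are floored to whole numbers (used for the
        starting age, which enters the model in whole years).
    """

    kind: str
    base: float
    p1: float = 0.0
    p2: float = 0.0
    lower: Optional[float] = None
    upper: Optional[float] = None
    integer: bool = False

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValidationError(f"unknown distribution kind {self.kind!r}")
        if self.kind == "uniform":
            if not (self.p1 <= self.base <= self.p2):
                raise ValidationError(
                    f"uniform base {self.base} outside [{self.p1}, {self.p2}]"
                )
        elif self.kind == "lognormal":
            if self.p2 <= 0:
                raise ValidationError("lognormal sd of log must be > 0")
        elif self.kind == "normal":
            if self.p2 < 0:
                raise ValidationError("normal sd must be >= 0")

    # ------------------------------------------------------------------
    @property
    def is_fixed(self) -> bool:
        return self.kind == "fixed"

    def mean(self) -> float:
        """Analytic mean of the (untruncated) law."""
        if self.kind == "uniform":
            return 0.5 * (self.p1 + self.p2)
        if self.kind == "lognormal":
            return math.exp(self.p1 + self.p2 ** 2 / 2.0)
        if self.kind == "normal":
            return self.p1
        return self.base

    def percentile(self, q: float) -> float:
        """Quantile of the untruncated law (used for tornado bounds)."""
        if self.kind == "uniform":
            return self.p1 + q * (self.p2 - self.p1)
        if self.kind == "lognormal":
            return float(stats.lognorm.ppf(q, s=self.p2, scale=math.exp(self.p1)))
        if self.kind == "normal":
            return float(stats.norm.ppf(q, loc=self.p1, scale=self.p2))
        return self.base

    def bounds(self) -> Optional[tuple[float, float]]:
        """Finite sweep bounds: uniform endpoints, else 2.5/97.5 percentiles."""
        if self.kind == "fixed":
            return None
        if self.kind == "uniform":
            return (self.p1, self.p2)
        return (self.percentile(0.025), self.percentile(0.975))

    def sample(self, rng: np.random.Generator, size: int = 1) -> np.ndarray:
        """Draw ``size`` values, enforcing truncation bounds by resampling."""
        if self.kind == "fixed":
            out = np.full(size, self.base, dtype=float)
            return out
        out = self._draw(rng, size)
        if self.lower is not None or self.upper is not None:
            # open lower bound, closed upper bound: hr in (0, 1.5]
            lo = -np.inf if self.lower is None else self.lower
            hi = np.inf if self.upper is None else self.upper
            bad = (out <= lo) | (out > hi)
            while bad.any():
                out[bad] = self._draw(rng, int(bad.sum()))
                bad = (out <= lo) | (out > hi)
        if self.integer:
            out = np.floor(out)
        return out

    def _draw(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.kind == "uniform":
            return rng.uniform(self.p1, self.p2, size)
        if self.kind == "lognormal":
            return rng.lognormal(self.p1, self.p2, size)
        return rng.normal(self.p1, self.p2, size)

    def with_base(self, value: float) -> "DistributionSpec":
        """Copy of this spec collapsed to a fixed value (used by one-way sweeps)."""
        return DistributionSpec(kind="fixed", base=float(value))


# Convenience constructors -------------------------------------------------

def fixed(base: float) -> DistributionSpec:
    return DistributionSpec("fixed", base=base)


def uniform(p1: float, p2: float, base: Optional[float] = None, **kw) -> DistributionSpec:
    if base is None:
        base = 0.5 * (p1 + p2)
    return DistributionSpec("uniform", base=base, p1=p1, p2=p2, **kw)


def lognormal(mu: float, sigma: float, base: float, **kw) -> DistributionSpec:
    return DistributionSpec("lognormal", base=base, p1=mu, p2=sigma, **kw)


def normal(m: float, sd: float, base: Optional[float] = None, **kw) -> DistributionSpec:
    if base is None:
        base = m
    return DistributionSpec("normal", base=base, p1=m, p2=sd, **kw)
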