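"""Inbreeding-purging (IP) model algebra.

Connects the inbreeding load delta (lethal equivalents), the purging
coefficient d, inbreeding F / purged inbreeding g, and expected fitness:

* load over loci:             delta = sum 2 d_locus q (1 - q)
* expected fitness:           E(W)  = E(W0) exp(-delta * g)
* expected individual
  log-fitness on F (or g):    E[ln W] = E[ln W0] + [ln(1 - 2d)/(2d)] delta F

The bracketed slope tends to -delta as d -> 0 and diverges at d = 0.5,
so -b from a log-fitness regression is an upwardly biased estimate of
delta unless d is small; ``load_from_slope`` inverts the relation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "IPParameters",
    "inbreeding_load",
    "slope_from_load",
    "load_from_slope",
    "predict_fitness",
    "predict_log_fitness",
]


@dataclass
class IPParameters:
    """Parameters of the IP fitness model.

    delta : inbreeding load in lethal equivalents (>= 0)
    d     : purging coefficient in [0, 0.5]
    W0    : expected fitness of the noninbred base (> 0), or give lnW0
    betas : coefficients for extra covariates (multiplicative on log scale)
    """

    delta: float
    d: float
    W0: float | None = None
    lnW0: float | None = None
    betas: tuple[float, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.delta < 0:
            raise ValueError("inbreeding load delta must be >= 0")
        if not (0.0 <= self.d <= 0.5):
            raise ValueError("purging coefficient d must lie in [0, 0.5]")
        if self.W0 is None and self.lnW0 is None:
            self.W0 = 1.0
        if self.W0 is None:
            self.W0 = float(np.exp(self.lnW0))
        if self.lnW0 is None:
            if self.W0 <= 0:
                raise ValueError("W0 must be > 0")
            self.lnW0 = float(np.log(self.W0))


def inbreeding_load(loci) -> float:
    """Inbreeding load delta = sum over loci of 2 d q (1 - q).

    ``loci`` is a sequence of (d_locus, q) pairs; d_locus = s(1/2 - h) is
    the per-locus purging coefficient and q the deleterious frequency.
    """
    loci = list(loci)
    if not loci:
        return 0.0
    arr = np.asarray(loci, dtype=float)
    d, q = arr[:, 0], arr[:, 1]
    if np.any(q < 0) or np.any(q > 1):
        raise ValueError("allele frequencies must lie in [0, 1]")
    if np.any(d < 0):
        raise ValueError("per-locus purging coefficients must be >= 0")
    return float(np.sum(2.0 * d * q * (1.0 - q)))


def _slope_factor(d: float) -> float:
    """ln(1 - 2d)/(2d), with its limit -1 at d = 0 and -inf at d = 0.5."""
    d = float(d)
    if d < 0 or d > 0.5:
        raise ValueError("purging coefficient d must lie in [0, 0.5]")
    if d == 0.5:
        warnings.warn(
            "slope factor diverges at d = 0.5 (recessive lethals); returning -inf",
            RuntimeWarning,
            stacklevel=3,
        )
        return -np.inf
    if d < 1e-8:
        # series ln(1-2d)/(2d) = -(1 + d + 4d^2/3 + ...), exact limit at 0
        return -(1.0 + d)
    return float(np.log1p(-2.0 * d) / (2.0 * d))


def slope_from_load(delta: float, d: float) -> float:
    """Expected slope of individual log-fitness on inbreeding.

    b = delta * ln(1 - 2d)/(2d); b = -delta in the d -> 0 limit.  |b| >=
    delta always, which is why -b overestimates the load.
    """
    if delta < 0:
        raise ValueError("inbreeding load delta must be >= 0")
    if delta == 0.0:
        return 0.0
    return float(delta) * _slope_factor(d)


def load_from_slope(b: float, d: float) -> float:
    """Inbreeding load implied by a log-fitness regression slope.

    delta = b * 2d / ln(1 - 2d); delta = -b in the d -> 0 limit.
    """
    fac = _slope_factor(d)
    return float(b) / fac


def predict_fitness(params: IPParameters, g, covariates=None):
    """Expected fitness E(W) = W0 exp(-delta g + sum beta_j x_j).

    ``g`` may be scalar or array (purged inbreeding, or plain F for the
    no-purging d = 0 case); ``covariates`` has one column per beta.
    """
    g = np.asarray(g, dtype=float)
    expo = -params.delta * g
    if covariates is not None and len(params.betas):
        X = np.atleast_2d(np.asarray(covariates, dtype=float))
        expo = expo + X @ np.asarray(params.betas)
    return params.W0 * np.exp(expo)


def predict_log_fitness(params: IPParameters, F_or_g, covariates=None):
    """Expected individual log-fitness.

    E[ln W] = ln W0 + slope_from_load(delta, d) * F; lies below
    ln(predict_fitness) whenever d > 0 and F > 0 (Jensen's inequality).
    """
    F = np.asarray(F_or_g, dtype=float)
    out = params.lnW0 + slope_from_load(params.delta, params.d) * F
    if covariates is not None and len(params.betas):
        X = np.atleast_2d(np.asarray(covariates, dtype=float))
        out = out + X @ np.asarray(params.betas)
    return out
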