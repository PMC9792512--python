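"""First-order protein turnover under partial synthesis suppression.

The model: protein synthesis is a zero-order reaction (constant rate
``alpha``) and degradation a first-order reaction with rate constant
``beta = ln 2 / t_half`` (equivalently time constant ``tau = 1/beta =
t_half/ln 2``, commonly quoted as ``1.44 * t_half``).  A protein-synthesis
inhibitor (PSI) reduces the synthesis rate to a fraction ``k = alpha_i /
alpha`` of its nominal value while leaving degradation untouched.  Starting
from steady state, the residual abundance relative to time-matched controls
is

    C'(t) = (1 - k) * exp(-beta * t) + k

so ``C'(0) = 1`` and ``C'`` relaxes to the new steady state ``C'(inf) = k``.
In a dynamic-SILAC experiment ``C'`` is what the (reference-normalized) H/M
ratio estimates, and ``log2 C'`` is the expected log2(H/M).

Units: half-lives are given in **days** (the unit half-life tables use),
elapsed PSI exposure in **hours**.  Conversions use the exact ``1/ln 2``,
not the rounded 1.44.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

__all__ = [
    "HOURS_PER_DAY",
    "KineticParams",
    "KEstimate",
    "tau_from_halflife",
    "beta_per_hour",
    "residual_fraction",
    "expected_log2_ratio",
    "k_from_fold_suppression",
    "estimate_k",
]

HOURS_PER_DAY = 24.0
_LN2 = np.log(2.0)


def _check_t_half(t_half_days) -> None:
    if np.any(np.asarray(t_half_days, dtype=float) <= 0):
        raise ValueError("half-life must be positive (np.inf allowed)")


def _check_k(k) -> None:
    k = np.asarray(k, dtype=float)
    if np.any((k < 0) | (k > 1)):
        raise ValueError("fractional synthesis rate k must lie in [0, 1]")


def tau_from_halflife(t_half_days):
    """Degradation time constant tau = t_half / ln 2, in days.

    ``tau/t_half = 1/ln 2 = 1.4427...`` (1.44 at 3 significant figures).
    Accepts scalars or arrays; an infinite half-life (no degradation) gives
    an infinite time constant.
    """
    _check_t_half(t_half_days)
    tau = np.asarray(t_half_days, dtype=float) / _LN2
    return float(tau) if np.isscalar(t_half_days) else tau


def beta_per_hour(t_half_days):
    """First-order degradation rate constant, per hour."""
    _check_t_half(t_half_days)
    beta = _LN2 / (np.asarray(t_half_days, dtype=float) * HOURS_PER_DAY)
    return float(beta) if np.isscalar(t_half_days) else beta


@dataclass(frozen=True)
class KineticParams:
    """Kinetic parameters of one protein under a PSI.

    Parameters
    ----------
    t_half_days:
        Protein half-life in days, > 0 (``np.inf`` = effectively
        non-degrading).
    k:
        Fractional synthesis rate in the presence of the inhibitor,
        ``k = alpha_i/alpha`` in [0, 1].  ``k = 0`` is complete shutdown,
        ``k = 1`` no inhibition.
    """

    t_half_days: float
    k: float = 0.0

    def __post_init__(self):
        _check_t_half(self.t_half_days)
        _check_k(self.k)

    @property
    def tau_days(self) -> float:
        return tau_from_halflife(self.t_half_days)

    @property
    def tau_hours(self) -> float:
        return self.tau_days * HOURS_PER_DAY

    @property
    def beta_per_hour(self) -> float:
        return beta_per_hour(self.t_half_days)

    def residual_fraction(self, t_hours):
        return residual_fraction(t_hours, self.t_half_days, self.k)

    def expected_log2_ratio(self, t_hours):
        return expected_log2_ratio(t_hours, self.t_half_days, self.k)


def residual_fraction(t_hours, t_half_days, k):
    """Residual fraction C'(t) = (1-k) exp(-beta t) + k.

    All arguments broadcast; ``t_hours`` must be >= 0.  Monotone
    non-increasing in t, non-decreasing in k and in t_half.
    """
    _check_t_half(t_half_days)
    _check_k(k)
    t = np.asarray(t_hours, dtype=float)
    if np.any(t < 0):
        raise ValueError("elapsed time must be non-negative")
    scalar = np.isscalar(t_hours) and np.isscalar(t_half_days) and np.isscalar(k)
    beta = _LN2 / (np.asarray(t_half_days, dtype=float) * HOURS_PER_DAY)
    with np.errstate(invalid="ignore"):
        decay = np.exp(-beta * t)
    # beta = 0 (infinite half-life) with t = inf gives nan from 0*inf; no decay.
    decay = np.where(np.isnan(decay), 1.0, decay)
    c = (1.0 - np.asarray(k, dtype=float)) * decay + np.asarray(k, dtype=float)
    return float(c) if scalar else c


def expected_log2_ratio(t_hours, t_half_days, k):
    """Expected log2(H/M) = log2 C'(t).

    Zero at t = 0 and -> log2(k) as t -> inf; for k = 0 the limit is -inf
    (returned as ``-np.inf``, not an error).
    """
    c = residual_fraction(t_hours, t_half_days, k)
    with np.errstate(divide="ignore"):
        out = np.log2(c)
    return float(out) if np.isscalar(c) else out


def k_from_fold_suppression(fold):
    """Fractional synthesis rate from a measured fold suppression: k = 1/fold.

    E.g. the ~40-fold (39.2) suppression measured for cycloheximide gives
    k = 0.0255; no suppression (fold = 1) gives k = 1.
    """
    f = np.asarray(fold, dtype=float)
    if np.any(f < 1):
        raise ValueError("fold suppression must be >= 1")
    k = 1.0 / f
    return float(k) if np.isscalar(fold) else k


@dataclass(frozen=True)
class KEstimate:
    """Least-squares estimate of the fractional synthesis rate k."""

    k: float
    rss: float
    n_obs: int


def estimate_k(t_half_days, t_hours, log2_ratio) -> KEstimate:
    """Least-squares fit of k in [0, 1] to measured log2(H/M) values.

    Parameters are parallel arrays: per measurement a known half-life
    (days), exposure time (hours) and the measured log2 ratio.  Minimizes
    the residual sum of squares of measured minus model-expected log2
    ratios over k.  Measurements at t = 0 carry no information on k; an
    input with no t > 0 measurement raises.
    """
    t_half = np.asarray(t_half_days, dtype=float)
    t = np.asarray(t_hours, dtype=float)
    y = np.asarray(log2_ratio, dtype=float)
    if not (t_half.shape == t.shape == y.shape):
        raise ValueError("t_half_days, t_hours and log2_ratio must align")
    mask = np.isfinite(y) & np.isfinite(t_half) & (t >= 0)
    t_half, t, y = t_half[mask], t[mask], y[mask]
    if t_half.size < 2:
        raise ValueError("need at least 2 finite measurements to estimate k")
    if not np.any(t > 0):
        raise ValueError("k is unidentifiable: all measurements are at t = 0")
    _check_t_half(t_half)

    decay = np.exp(-_LN2 * t / (t_half * HOURS_PER_DAY))

    def rss(k: float) -> float:
        with np.errstate(divide="ignore"):
            expected = np.log2((1.0 - k) * decay + k)
        r = y - expected
        r = r[np.isfinite(r)]
        return float(np.dot(r, r))

    res = minimize_scalar(rss, bounds=(0.0, 1.0), method="bounded",
                          options={"xatol": 1e-10})
    return KEstimate(k=float(res.x), rss=rss(float(res.x)), n_obs=int(y.size))
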