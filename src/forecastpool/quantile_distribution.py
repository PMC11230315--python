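"""Reconstruct a predictive distribution from (quantile level, value) pairs.

The interior of the CDF is a shape-preserving monotone cubic (PCHIP)
interpolant of level as a function of value; each tail is a location-scale
member of a chosen family (normal, lognormal, Cauchy) matched exactly to
the two most extreme pairs on that side.  Quasi-random samples are the
quantiles at the midpoint grid (k - 0.5)/n.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.stats import cauchy as _cauchy
from scipy.stats import norm as _norm

from .errors import (
    DegenerateQuantilesError,
    DomainError,
    InsufficientDataError,
    SupportError,
)

TAIL_FAMILIES = ("normal", "lognormal", "cauchy")
#: accepted aliases (CLI uses the short R-style names)
_TAIL_ALIASES = {
    "norm": "normal",
    "normal": "normal",
    "lnorm": "lognormal",
    "lognormal": "lognormal",
    "cauchy": "cauchy",
}

_ROOT_TOL = 1e-10


def canonical_tail(name: str) -> str:
    try:
        return _TAIL_ALIASES[name]
    except KeyError:
        raise DomainError(
            f"unknown tail family {name!r}; expected one of {sorted(_TAIL_ALIASES)}"
        ) from None


@dataclass(frozen=True)
class _Tail:
    """Location-scale tail: F(x) = base.cdf((t(x) - loc)/scale) with
    t = log for lognormal, identity otherwise."""

    family: str
    loc: float
    scale: float

    def _transform(self, x):
        return np.log(x) if self.family == "lognormal" else x

    def _base(self):
        return _cauchy if self.family == "cauchy" else _norm

    def cdf(self, x):
        x = np.asarray(x, dtype=float)
        if self.family == "lognormal":
            out = np.zeros_like(x)
            pos = x > 0
            out[pos] = self._base().cdf((np.log(x[pos]) - self.loc) / self.scale)
            return out
        return self._base().cdf((x - self.loc) / self.scale)

    def quantile(self, theta):
        z = self._base().ppf(theta)
        t = self.loc + self.scale * z
        return np.exp(t) if self.family == "lognormal" else t


def _fit_tail(family: str, th1: float, x1: float, th2: float, x2: float) -> _Tail:
    """Location-scale member through two (level, value) points."""
    base = _cauchy if family == "cauchy" else _norm
    if family == "lognormal":
        if x1 <= 0 or x2 <= 0:
            raise SupportError("lognormal tails require strictly positive values")
        t1, t2 = np.log(x1), np.log(x2)
    else:
        t1, t2 = x1, x2
    z1, z2 = base.ppf(th1), base.ppf(th2)
    if z2 == z1 or t2 == t1:
        # flat or degenerate pair: fall back to a tiny-scale point mass at x1
        return _Tail(family, (t1 + t2) / 2.0, 1e-12)
    scale = (t2 - t1) / (z2 - z1)
    loc = t1 - scale * z1
    return _Tail(family, float(loc), float(scale))


@dataclass(frozen=True)
class DistributionEstimate:
    """A CDF reconstructed from quantile pairs; see :func:`fit_distribution`."""

    levels: np.ndarray
    values: np.ndarray
    tail_family: str
    _interior: PchipInterpolator
    _lower: _Tail
    _upper: _Tail

    def cdf(self, x) -> np.ndarray:
        """Evaluate the reconstructed CDF; a total function on the reals."""
        x = np.asarray(x, dtype=float)
        scalar = x.ndim == 0
        x = np.atleast_1d(x)
        lo, hi = self.values[0], self.values[-1]
        out = np.empty_like(x)
        below = x < lo
        above = x > hi
        mid = ~(below | above)
        out[below] = self._lower.cdf(x[below])
        out[above] = self._upper.cdf(x[above])
        out[mid] = np.clip(self._interior(x[mid]), 0.0, 1.0)
        out[np.isneginf(x)] = 0.0
        out[np.isposinf(x)] = 1.0
        return out[0] if scalar else out

    def quantile(self, theta) -> np.ndarray:
        """Generalized inverse of :meth:`cdf` for theta in (0, 1)."""
        theta = np.asarray(theta, dtype=float)
        scalar = theta.ndim == 0
        theta = np.atleast_1d(theta)
        if ((theta <= 0.0) | (theta >= 1.0)).any():
            raise DomainError("quantile levels must lie strictly in (0, 1)")
        out = np.empty_like(theta)
        lo = theta <= self.levels[0]
        hi = theta >= self.levels[-1]
        mid = ~(lo | hi)
        if lo.any():
            out[lo] = self._lower.quantile(theta[lo])
        if hi.any():
            out[hi] = self._upper.quantile(theta[hi])
        if mid.any():
            out[mid] = self._invert_interior(theta[mid])
        return out[0] if scalar else out

    def _invert_interior(self, th: np.ndarray) -> np.ndarray:
        """Vectorized safeguarded Newton/bisection inversion of the
        monotone interior interpolant, to ``_ROOT_TOL`` on theta."""
        j = np.searchsorted(self.levels, th)
        a = self.values[j - 1].astype(float)
        b = self.values[j].astype(float)
        th_a = self.levels[j - 1]
        th_b = self.levels[j]
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(th_b > th_a, (th - th_a) / (th_b - th_a), 0.5)
        x = a + frac * (b - a)
        lo, hi = a.copy(), b.copy()
        deriv = self._interior.derivative()
        for _ in range(100):
            fx = self._interior(x) - th
            done = np.abs(fx) <= _ROOT_TOL
            if done.all():
                break
            hi = np.where(fx > 0, x, hi)
            lo = np.where(fx <= 0, x, lo)
            d = deriv(x)
            with np.errstate(invalid="ignore", divide="ignore"):
                newton = x - fx / d
            ok = (d > 0) & (newton > lo) & (newton < hi)
            x = np.where(done, x, np.where(ok, newton, 0.5 * (lo + hi)))
        return np.clip(x, a, b)

    def quasi_random_samples(self, n: int) -> np.ndarray:
        """Deterministic samples: quantiles at theta_k = (k - 0.5)/n."""
        if n < 1:
            raise DomainError("n must be a positive integer")
        grid = (np.arange(1, n + 1) - 0.5) / n
        return self.quantile(grid)


def fit_distribution(
    levels,
    values,
    tail_dist: str = "normal",
) -> DistributionEstimate:
    """Fit a :class:`DistributionEstimate` to (level, value) pairs.

    Parameters
    ----------
    levels : array-like of float
        Quantile levels in (0, 1), strictly increasing.
    values : array-like of float
        Corresponding quantile values, nondecreasing.
    tail_dist : str
        Tail family: ``normal`` (default), ``lognormal``/``lnorm``, or
        ``cauchy``.

    Notes
    -----
    Ties in ``values`` across distinct levels are collapsed to a single
    node at the mean of their levels (with a warning); if fewer than two
    distinct values remain, a :class:`DegenerateQuantilesError` is raised.
    """
    family = canonical_tail(tail_dist)
    levels = np.asarray(levels, dtype=float)
    values = np.asarray(values, dtype=float)
    if levels.shape != values.shape or levels.ndim != 1:
        raise DomainError("levels and values must be 1-D arrays of equal length")
    if len(levels) < 2:
        raise InsufficientDataError("at least 2 quantile pairs are required")
    if not np.isfinite(levels).all() or not np.isfinite(values).all():
        raise DomainError("levels and values must be finite")
    if ((levels <= 0) | (levels >= 1)).any():
        raise DomainError("levels must lie strictly in (0, 1)")
    if (np.diff(levels) <= 0).any():
        raise DomainError("levels must be strictly increasing")
    if (np.diff(values) < 0).any():
        raise DomainError("values must be nondecreasing")

    # collapse exact value ties (flat CDF region) to one node
    if (np.diff(values) == 0).any():
        uvals, inverse = np.unique(values, return_inverse=True)
        ulevels = np.array(
            [levels[inverse == k].mean() for k in range(len(uvals))]
        )
        if len(uvals) < 2:
            raise DegenerateQuantilesError(
                "all quantile values identical; cannot fit a distribution"
            )
        warnings.warn(
            "tied quantile values collapsed to single CDF nodes", stacklevel=2
        )
        values, levels = uvals, ulevels

    if family == "lognormal" and (values <= 0).any():
        raise SupportError("lognormal tails require all values > 0")

    interior = PchipInterpolator(values, levels, extrapolate=False)
    lower = _fit_tail(family, levels[0], values[0], levels[1], values[1])
    upper = _fit_tail(family, levels[-2], values[-2], levels[-1], values[-1])
    return DistributionEstimate(
        levels=levels,
        values=values,
        tail_family=family,
        _interior=interior,
        _lower=lower,
        _upper=upper,
    )
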