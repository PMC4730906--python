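"""Circular (von Mises) primitives: density, sampling, summaries, ML fitting.

The von Mises distribution

    f(theta; mu, kappa) = exp(kappa * cos(theta - mu)) / (2 * pi * I0(kappa))

is the circular analogue of the normal distribution: ``mu`` is the mean
direction and ``kappa`` >= 0 the concentration (kappa = 0 is uniform on the
circle; large kappa concentrates mass tightly around mu).  Everything else in
this package — the state-space smoother, the sliding-window baseline, the
synthetic generator — is built on the functions in this module.

Angles are canonically stored in the half-open interval [-pi, pi).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import i0e

__all__ = [
    "KAPPA_MAX",
    "VonMisesParams",
    "CircularSummary",
    "wrap_angle",
    "vonmises_pdf",
    "sample_vonmises",
    "circular_summary",
    "ml_fit_vonmises",
    "read_phase_series",
    "write_phase_series",
]

#: Concentration cap: exp(kappa) overflows float64 near 709, and no phase
#: data set distinguishes kappa = 700 from a point mass.
KAPPA_MAX = 700.0


@dataclass(frozen=True)
class VonMisesParams:
    """Mean direction ``mu`` in [-pi, pi) and concentration ``kappa`` >= 0."""

    mu: float
    kappa: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.mu) or not np.isfinite(self.kappa):
            raise ValueError("mu and kappa must be finite")
        if self.kappa < 0:
            raise ValueError(f"kappa must be nonnegative, got {self.kappa}")
        object.__setattr__(self, "mu", float(wrap_angle(self.mu)))
        object.__setattr__(self, "kappa", float(self.kappa))


@dataclass(frozen=True)
class CircularSummary:
    """First trigonometric moment of a circular sample.

    ``resultant_length`` is the modulus of the average unit vector: 1 for
    identical angles, 0 for perfectly balanced dispersion.  When it is zero
    the mean direction is undefined (``mean_direction`` is NaN and
    ``mean_defined`` is False).
    """

    mean_direction: float
    resultant_length: float
    n: int

    @property
    def mean_defined(self) -> bool:
        return bool(np.isfinite(self.mean_direction))


def wrap_angle(x):
    """Map any finite real angle(s) to the canonical interval [-pi, pi).

    The boundary pi itself maps to -pi, so the interval is genuinely
    half-open and wrapping is idempotent.
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("angles must be finite")
    wrapped = np.mod(x + np.pi, 2.0 * np.pi) - np.pi
    return wrapped if wrapped.ndim else float(wrapped)


def vonmises_pdf(theta, params: VonMisesParams):
    """Density of the von Mises law at ``theta`` (scalar or array).

    Evaluated in exponentially scaled form,
    ``exp(kappa * (cos(theta - mu) - 1)) / (2 pi i0e(kappa))``, which stays
    finite for concentrations all the way up to :data:`KAPPA_MAX`.
    """
    theta = np.asarray(theta, dtype=float)
    if not np.all(np.isfinite(theta)):
        raise ValueError("theta must be finite")
    kappa = params.kappa
    out = np.exp(kappa * (np.cos(theta - params.mu) - 1.0)) / (
        2.0 * np.pi * i0e(kappa)
    )
    return out if out.ndim else float(out)


def sample_vonmises(n: int, params: VonMisesParams, rng: np.random.Generator):
    """Draw ``n`` i.i.d. angles, wrapped to [-pi, pi).

    Uses the Best–Fisher rejection sampler (numpy's generator method).
    Reproducible: the same ``rng`` state yields bit-identical draws.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if params.kappa == 0.0:
        draws = rng.uniform(-np.pi, np.pi, size=n)
    else:
        draws = rng.vonmises(params.mu, params.kappa, size=n)
    return wrap_angle(draws)


def circular_summary(angles) -> CircularSummary:
    """Mean direction and resultant length of a sample of angles.

    mean_direction = atan2(mean sin, mean cos); resultant_length is the
    modulus of the mean unit vector.  An exactly balanced sample (resultant
    length 0, e.g. an antipodal pair) has no defined mean direction.
    """
    angles = np.atleast_1d(np.asarray(angles, dtype=float))
    if angles.size == 0:
        raise ValueError("need at least one angle")
    c = np.cos(angles).mean()
    s = np.sin(angles).mean()
    r = float(np.hypot(c, s))
    if r < 1e-12:
        return CircularSummary(float("nan"), 0.0, angles.size)
    return CircularSummary(float(np.arctan2(s, c)), min(r, 1.0), angles.size)


def _a_inv(rbar: float) -> float:
    # Fisher's three-branch rational approximation of the inverse of
    # A(kappa) = I1(kappa)/I0(kappa) (Fisher 1993, eq. 4.40/4.41):
    #   rbar < 0.53          : 2r + r^3 + 5 r^5 / 6
    #   0.53 <= rbar < 0.85  : -0.4 + 1.39 r + 0.43 / (1 - r)
    #   rbar >= 0.85         : 1 / (r^3 - 4 r^2 + 3 r)
    if rbar < 0.53:
        return 2.0 * rbar + rbar**3 + 5.0 * rbar**5 / 6.0
    if rbar < 0.85:
        return -0.4 + 1.39 * rbar + 0.43 / (1.0 - rbar)
    return 1.0 / (rbar**3 - 4.0 * rbar**2 + 3.0 * rbar)


def ml_fit_vonmises(angles) -> VonMisesParams:
    """Maximum-likelihood von Mises fit.

    mu-hat is the sample mean direction; kappa-hat inverts the resultant
    length through Fisher's piecewise rational approximation, capped at
    :data:`KAPPA_MAX`.  A degenerate sample (resultant length 1, e.g. all
    angles equal) yields the cap with a warning rather than an exception.
    """
    angles = np.atleast_1d(np.asarray(angles, dtype=float))
    if angles.size < 2:
        raise ValueError("ML fit needs at least two angles")
    summ = circular_summary(angles)
    mu = summ.mean_direction if summ.mean_defined else 0.0
    if summ.resultant_length >= 1.0 - 1e-12:
        warnings.warn(
            "resultant length is 1 (degenerate sample); kappa capped",
            RuntimeWarning,
            stacklevel=2,
        )
        return VonMisesParams(mu, KAPPA_MAX)
    kappa = min(_a_inv(summ.resultant_length), KAPPA_MAX)
    return VonMisesParams(mu, max(kappa, 0.0))


def read_phase_series(path) -> np.ndarray:
    """Load a phase series: plain text, one radian value per line.

    A single non-numeric header line is tolerated.  All values are wrapped
    to [-pi, pi) on load.
    """
    try:
        values = np.loadtxt(path, dtype=float, ndmin=1)
    except ValueError:
        values = np.loadtxt(path, dtype=float, ndmin=1, skiprows=1)
    return wrap_angle(values)


def write_phase_series(path, angles) -> None:
    np.savetxt(path, wrap_angle(np.asarray(angles, dtype=float)), fmt="%.12g")
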