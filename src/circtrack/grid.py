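"""Discrete (mu, kappa) state grid and the transition matrices on it.

The hidden state of the smoother is the pair S_t = (mu_t, kappa_t) of von
Mises parameters, represented on a finite grid: m mean directions uniformly
spaced on the circle, and m concentration values on [0, ell].  The state
evolves under independent random-walk priors — a von Mises step of
concentration K for the mean, a Gaussian step of variance sigma2 for the
concentration — each discretized by evaluating the kernel at the grid nodes
and normalizing rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "StateGrid",
    "TransitionPrior",
    "build_grid",
    "mu_transition_matrix",
    "kappa_transition_matrix",
]

#: Default uniform mixing floor for transition rows.  The discretized
#: Gaussian kernel underflows to exactly zero between distant kappa nodes,
#: which disconnects the chain (a change in the data can then never move the
#: posterior, and the forward recursion can hit an all-zero belief).  Mixing
#: in a tiny uniform component keeps every state reachable while leaving the
#: short-range dynamics untouched.
DEFAULT_MIXING_FLOOR = 1e-5


@dataclass(frozen=True)
class StateGrid:
    """Supports R_mu (mean directions) and R_kappa (concentrations).

    ``mu_values``: m angles uniformly spaced over [-pi, pi), endpoint
    excluded.  ``kappa_values``: m strictly increasing values with
    ``kappa_values[0] == 0`` and ``kappa_values[-1] == ell``; either
    log-spaced (a zero node followed by a geometric ladder) or uniformly
    spaced.
    """

    mu_values: np.ndarray
    kappa_values: np.ndarray
    m: int
    ell: float

    def __post_init__(self) -> None:
        mu = np.asarray(self.mu_values, float)
        kv = np.asarray(self.kappa_values, float)
        if np.any(np.diff(mu) <= 0) or np.any(np.diff(kv) <= 0):
            raise ValueError("grid values must be strictly increasing")
        if kv[0] != 0.0 or not np.isclose(kv[-1], self.ell):
            raise ValueError("kappa grid must run from 0 to ell")

    def to_dict(self) -> dict:
        return {"m": self.m, "ell": self.ell,
                "kappa_values": [float(k) for k in self.kappa_values]}


def build_grid(
    m: int,
    ell: float,
    kappa_spacing: str = "log",
    kappa_min: float | None = None,
) -> StateGrid:
    """Construct an m-by-m state grid with kappa upper bound ``ell``.

    mu nodes: ``linspace(-pi, pi, m, endpoint=False)`` (spacing 2*pi/m).

    kappa nodes, ``kappa_spacing="log"``: a zero node (uniform phase must be
    representable) followed by m-1 geometrically spaced points from
    ``kappa_min`` (default ell / 2**(m-2)) up to ell.

    kappa nodes, ``kappa_spacing="linear"``: ``linspace(0, ell, m)``.
    Uniform spacing keeps the discretized Gaussian transition kernel
    homogeneous across the grid — on a log grid the sparse high-kappa nodes
    acquire much larger self-transition weight than the dense low-kappa
    nodes, which biases long smoothing runs toward high concentration.
    """
    if m < 2:
        raise ValueError("m must be >= 2")
    if ell <= 0:
        raise ValueError("ell must be positive")
    mu = np.linspace(-np.pi, np.pi, m, endpoint=False)
    if kappa_spacing == "log":
        if kappa_min is None:
            kappa_min = ell / 2.0 ** (m - 2)
        if not 0 < kappa_min <= ell:
            raise ValueError("kappa_min must lie in (0, ell]")
        kv = np.concatenate(([0.0], np.geomspace(kappa_min, ell, m - 1)))
    elif kappa_spacing == "linear":
        kv = np.linspace(0.0, ell, m)
    else:
        raise ValueError(f"unknown kappa_spacing {kappa_spacing!r}")
    return StateGrid(mu_values=mu, kappa_values=kv, m=m, ell=float(ell))


def mu_transition_matrix(
    grid: StateGrid, K: float, mixing_floor: float = DEFAULT_MIXING_FLOOR
) -> np.ndarray:
    """Row-stochastic transition matrix for the mean-direction chain.

    Entry (i, j) is proportional to exp(K * cos(u_j - u_i)): a von Mises
    step centred on the previous mean with concentration K, evaluated at
    the grid nodes and row-normalized.  K = 0 gives uniform transitions;
    large K freezes the chain.
    """
    if K < 0:
        raise ValueError("K must be nonnegative")
    u = grid.mu_values
    # subtract the row max (cos <= 1) before exponentiating so large K is safe
    kernel = np.exp(K * (np.cos(u[None, :] - u[:, None]) - 1.0))
    return _normalize(kernel, mixing_floor)


def kappa_transition_matrix(
    grid: StateGrid, sigma2: float, mixing_floor: float = DEFAULT_MIXING_FLOOR
) -> np.ndarray:
    """Row-stochastic transition matrix for the concentration chain.

    Entry (i, j) is proportional to exp(-(k_j - k_i)^2 / (2 sigma2)): a
    Gaussian step evaluated at the grid nodes, implicitly truncated to
    [0, ell] by row normalization.  No cell-width weighting is applied —
    the kernel is evaluated and normalized exactly as stated.
    """
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    k = grid.kappa_values
    kernel = np.exp(-((k[None, :] - k[:, None]) ** 2) / (2.0 * sigma2))
    return _normalize(kernel, mixing_floor)


def _normalize(kernel: np.ndarray, mixing_floor: float) -> np.ndarray:
    if not 0 <= mixing_floor < 1:
        raise ValueError("mixing_floor must be in [0, 1)")
    rows = kernel / kernel.sum(axis=1, keepdims=True)
    if mixing_floor:
        rows = (1.0 - mixing_floor) * rows + mixing_floor / kernel.shape[1]
    return rows


@dataclass(frozen=True)
class TransitionPrior:
    """Hyperparameters (K, sigma2) plus the matrices they induce on a grid.

    K is the von Mises concentration of the mean-direction random walk
    (large K = the mean barely moves between trials); sigma2 the Gaussian
    variance of the concentration random walk (small sigma2 = kappa changes
    slowly).  The joint transition factorizes:
    p((mu', k') | (mu, k)) = mu_transition[mu, mu'] * kappa_transition[k, k'].
    """

    K: float
    sigma2: float
    mu_transition: np.ndarray = field(repr=False)
    kappa_transition: np.ndarray = field(repr=False)
    mixing_floor: float = DEFAULT_MIXING_FLOOR

    @classmethod
    def from_grid(
        cls,
        grid: StateGrid,
        K: float,
        sigma2: float,
        mixing_floor: float = DEFAULT_MIXING_FLOOR,
    ) -> "TransitionPrior":
        return cls(
            K=float(K),
            sigma2=float(sigma2),
            mu_transition=mu_transition_matrix(grid, K, mixing_floor),
            kappa_transition=kappa_transition_matrix(grid, sigma2, mixing_floor),
            mixing_floor=mixing_floor,
        )

    def to_dict(self) -> dict:
        return {"K": self.K, "sigma2": self.sigma2,
                "mixing_floor": self.mixing_floor}
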