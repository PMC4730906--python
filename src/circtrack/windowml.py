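"""Sliding-window maximum-likelihood baseline.

The pre-Bayesian way to track a drifting phase distribution: slide a window
of G trials (with overlap g) along the series and fit a von Mises law to
each window by ML.  Small windows are noisy; large windows smear change
points — the trade-off the state-space smoother is designed to escape.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .circular import VonMisesParams, ml_fit_vonmises, sample_vonmises

__all__ = ["WindowSpec", "WindowTrack", "sliding_ml_track"]


@dataclass(frozen=True)
class WindowSpec:
    """Window length G (trials), overlap g, and edge padding.

    ``overlap`` may be given as a count of trials (int, 0 <= g < G) or as a
    fraction in [0, 1) (float, e.g. 0.98).  ``padding`` is the number of
    synthetic trials appended to *each* end before windowing so that every
    original trial receives an estimate; None means G // 2.
    """

    G: int
    overlap: float = 0.0
    padding: int | None = None

    def __post_init__(self) -> None:
        if self.G < 1:
            raise ValueError("G must be >= 1")
        if isinstance(self.overlap, float) and 0 <= self.overlap < 1:
            pass
        elif isinstance(self.overlap, (int, np.integer)) and 0 <= self.overlap < self.G:
            pass
        else:
            raise ValueError("overlap must be a fraction in [0,1) or a count < G")
        if self.padding is not None and self.padding < 0:
            raise ValueError("padding must be nonnegative")

    @property
    def overlap_fraction(self) -> float:
        if isinstance(self.overlap, float) and self.overlap < 1:
            return float(self.overlap)
        return float(self.overlap) / self.G

    @property
    def stride(self) -> int:
        # overlap is stated as a percentage; round the implied stride and
        # never let it fall below one trial
        return max(1, round(self.G * (1.0 - self.overlap_fraction)))

    @property
    def pad(self) -> int:
        return self.G // 2 if self.padding is None else self.padding


@dataclass(frozen=True)
class WindowTrack:
    """Per-trial ML estimates: arrays ``mu`` and ``kappa`` of length N."""

    mu: np.ndarray
    kappa: np.ndarray
    spec: WindowSpec
    centers: np.ndarray


def sliding_ml_track(
    theta: np.ndarray,
    spec: WindowSpec,
    rng: np.random.Generator | None = None,
    edge_params: tuple[VonMisesParams, VonMisesParams] | None = None,
) -> WindowTrack:
    """Per-trial von Mises estimates from overlapping-window ML fits.

    Each window's fit is assigned to its center trial; trials between
    centers take the nearest center's estimate.  To give edge trials a
    centred window, the series is first extended by ``spec.pad`` samples on
    each side, drawn from the first/last distribution: the true segment
    laws when ``edge_params`` is supplied (the synthetic harness does
    this), otherwise the ML fit of the first/last window.  Padding draws
    require ``rng``; with ``pad=0`` no randomness is used.
    """
    theta = np.atleast_1d(np.asarray(theta, float))
    n = theta.size
    if spec.G > n:
        raise ValueError(f"window G={spec.G} exceeds series length {n}")
    pad = spec.pad
    if pad > 0:
        if edge_params is None:
            first = ml_fit_vonmises(theta[: spec.G])
            last = ml_fit_vonmises(theta[-spec.G:])
        else:
            first, last = edge_params
        if rng is None:
            raise ValueError("padding requires rng for the resampled edges")
        left = sample_vonmises(pad, first, rng)
        right = sample_vonmises(pad, last, rng)
        extended = np.concatenate([left, theta, right])
    else:
        extended = theta
    offset = pad  # index of original trial 0 in the extended series

    starts = np.arange(0, extended.size - spec.G + 1, spec.stride)
    centers = starts + spec.G // 2 - offset  # in original trial coordinates
    mus = np.empty(starts.size)
    kappas = np.empty(starts.size)
    for w, s in enumerate(starts):
        fit = ml_fit_vonmises(extended[s: s + spec.G])
        mus[w] = fit.mu
        kappas[w] = fit.kappa

    # nearest-center assignment for every original trial
    idx = np.clip(np.searchsorted(centers, np.arange(n)), 0, centers.size - 1)
    left_ok = idx > 0
    use_left = np.zeros(n, bool)
    use_left[left_ok] = (
        np.arange(n)[left_ok] - centers[idx[left_ok] - 1]
        <= centers[idx[left_ok]] - np.arange(n)[left_ok]
    )
    idx[use_left] -= 1
    return WindowTrack(mu=mus[idx], kappa=kappas[idx], spec=spec, centers=centers)
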