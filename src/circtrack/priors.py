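"""Selection of the transition hyperparameters (K, sigma2).

Rather than maximizing data likelihood (which overfits each series and does
not help separate experimental conditions), the hyperparameters are chosen
on a finite candidate grid to maximize

    rho = between-group variance of the E'(kappa_t) summaries
          / average within-group variance,

where each series is reduced to a scalar summary (the mean of its
normalized expected-concentration trajectory) and series are grouped by
condition (e.g. stimulus level).  Large rho means the chosen prior makes
conditions maximally distinguishable relative to within-condition scatter.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .grid import StateGrid, TransitionPrior
from .smoother import concentration_track, three_sweep_smooth

__all__ = ["PriorSearchResult", "rho_criterion", "grid_search_priors"]


def rho_criterion(series_by_group: Mapping[object, Sequence[float]]) -> float:
    """Between-group over average within-group variance of scalar summaries.

    Sample variances (ddof=1) throughout: the unweighted variance of the
    group means, divided by the mean of the per-group variances.  Requires
    at least two groups of at least two values.  If every group has zero
    internal variance the ratio is flagged as ``inf`` (degenerate, excluded
    from grid-search argmax); if additionally the group means coincide the
    result is 0.
    """
    groups = [np.asarray(v, float) for v in series_by_group.values()]
    if len(groups) < 2 or any(g.size < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 series each")
    means = np.array([g.mean() for g in groups])
    between = means.var(ddof=1)
    within = float(np.mean([g.var(ddof=1) for g in groups]))
    if within == 0.0:
        return 0.0 if between == 0.0 else float("inf")
    return float(between / within)


@dataclass(frozen=True)
class PriorSearchResult:
    candidate_K: tuple[float, ...]
    candidate_sigma2: tuple[float, ...]
    rho_surface: np.ndarray  # (len(K), len(sigma2)); NaN marks failed cells
    best_pair: tuple[float, float]
    group_summaries: dict  # best pair's per-group scalar summaries

    def best_prior(self, grid: StateGrid) -> TransitionPrior:
        return TransitionPrior.from_grid(grid, *self.best_pair)


def grid_search_priors(
    datasets: Sequence[tuple[np.ndarray, object]],
    candidate_K: Sequence[float],
    candidate_sigma2: Sequence[float],
    grid: StateGrid,
    tail: int = 50,
) -> PriorSearchResult:
    """Exhaustive rho maximization over the candidate (K, sigma2) pairs.

    ``datasets`` is a list of (phase series, group label) pairs.  For every
    candidate pair the smoother runs on every series, each E'(kappa_t)
    trajectory is reduced to its mean over trials, and rho is evaluated on
    the grouped summaries.  A failed smoothing run invalidates that cell
    (NaN) instead of aborting the search.  Ties (and infinite-rho
    degenerate cells) resolve toward smaller sigma2, then smaller K —
    preferring the peakiest transition priors consistent with the data.
    """
    if not candidate_K or not candidate_sigma2:
        raise ValueError("candidate lists must be non-empty")
    if not datasets:
        raise ValueError("need at least one dataset")
    surface = np.full((len(candidate_K), len(candidate_sigma2)), np.nan)
    summaries_by_cell: dict[tuple[int, int], dict] = {}
    for i, K in enumerate(candidate_K):
        for j, s2 in enumerate(candidate_sigma2):
            prior = TransitionPrior.from_grid(grid, K, s2)
            by_group: dict[object, list[float]] = {}
            try:
                for theta, label in datasets:
                    track = three_sweep_smooth(np.asarray(theta, float), grid, prior)
                    ctrack = concentration_track(track, grid, tail=tail)
                    by_group.setdefault(label, []).append(
                        float(ctrack.normalized_expected_kappa.mean())
                    )
                surface[i, j] = rho_criterion(by_group)
                summaries_by_cell[(i, j)] = by_group
            except (FloatingPointError, ValueError):
                continue

    finite = np.isfinite(surface)
    if not finite.any():
        raise RuntimeError("no candidate pair produced a finite rho")
    best_rho = surface[finite].max()
    # tie-break: among maximal finite cells prefer small sigma2, then small K
    order_s2 = np.argsort(candidate_sigma2, kind="stable")
    order_K = np.argsort(candidate_K, kind="stable")
    best_ij = None
    for j in order_s2:
        for i in order_K:
            if finite[i, j] and surface[i, j] == best_rho:
                best_ij = (i, j)
                break
        if best_ij:
            break
    i, j = best_ij
    return PriorSearchResult(
        candidate_K=tuple(float(k) for k in candidate_K),
        candidate_sigma2=tuple(float(s) for s in candidate_sigma2),
        rho_surface=surface,
        best_pair=(float(candidate_K[i]), float(candidate_sigma2[j])),
        group_summaries=summaries_by_cell.get((i, j), {}),
    )
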