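"""Brute-force oracles used by the smoother tests.

Exact smoothed marginals of the discrete state-space model by literal
enumeration of every state path — exponential in the series length, usable
only for tiny grids and a handful of trials, and deliberately independent
of the recursive implementation it validates.
"""

from itertools import product

import numpy as np

from circtrack.smoother import likelihood_table


def enumerate_smoothed(theta, grid, prior):
    """Exact per-trial smoothed marginals under a uniform prior on the
    initial state, by summing the joint weight of every state path."""
    n_mu = grid.mu_values.size
    n_k = grid.kappa_values.size
    states = list(product(range(n_mu), range(n_k)))
    L = likelihood_table(np.asarray(theta, float), grid)
    n = L.shape[0]
    post = np.zeros((n, n_mu, n_k))
    total = 0.0
    for path in product(states, repeat=n):
        w = (1.0 / len(states)) * L[0][path[0]]
        for t in range(1, n):
            w *= (
                prior.mu_transition[path[t - 1][0], path[t][0]]
                * prior.kappa_transition[path[t - 1][1], path[t][1]]
                * L[t][path[t]]
            )
        total += w
        for t in range(n):
            post[t][path[t]] += w
    return post / total
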