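"""Independent reference implementations used to validate the package.

Everything here is deliberately written from the mathematical definition
(enumeration, generic numerical optimization) rather than reusing the
package's own algorithms.
"""

from __future__ import annotations

from math import comb

import numpy as np
from scipy.optimize import minimize

from igwas.pweight import PriorSpec, expected_rejections


def brute_force_prune(ranked_ids, r2_lookup, r2_max, exclude_index=None):
    """Literal execution of the greedy pruning definition on explicit sets."""
    remaining = list(ranked_ids)
    if exclude_index is not None:
        remaining = [
            s for s in remaining
            if s != exclude_index and r2_lookup(s, exclude_index) <= r2_max
        ]
    kept = []
    while remaining:
        head, rest = remaining[0], remaining[1:]
        kept.append(head)
        remaining = [s for s in rest if r2_lookup(head, s) <= r2_max]
    return kept


def hypergeom_upper_tail(population, successes, draws, observed):
    """P[X >= observed] by exact enumeration of the hypergeometric mass."""
    total = comb(population, draws)
    upper = 0
    for x in range(observed, min(successes, draws) + 1):
        if draws - x > population - successes:
            continue
        upper += comb(successes, x) * comb(population - successes, draws - x)
    return upper / total


def numerical_weights(eta, sigma, q, n_starts=8, seed=0):
    """Constrained numerical maximizer of the expected-rejections objective.

    Multi-start SLSQP over {w >= 0, mean(w) = 1, q*w <= 1}; returns
    (weights, objective) of the best run. Independent of the package's
    closed-form solution path.
    """
    eta = np.asarray(eta, dtype=float)
    n = eta.size
    prior = PriorSpec(eta=eta, sigma=sigma, q=q)
    rng = np.random.default_rng(seed)

    def negative(w):
        return -expected_rejections(np.maximum(w, 0.0), prior)

    starts = [np.ones(n)]
    starts += [rng.dirichlet(np.ones(n)) * n for _ in range(n_starts - 1)]
    best = None
    for x0 in starts:
        res = minimize(
            negative,
            x0,
            method="SLSQP",
            constraints=[{"type": "eq", "fun": lambda w: np.mean(w) - 1.0}],
            bounds=[(0.0, 1.0 / q)] * n,
            options={"maxiter": 1000, "ftol": 1e-14},
        )
        if res.success and (best is None or res.fun < best.fun):
            best = res
    assert best is not None, "SLSQP failed on every start"
    return best.x, -best.fun
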