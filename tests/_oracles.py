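"""Independent test oracles, kept separate from the implementation under test.

The occupancy equilibrium oracle integrates the (linear) mass-action rate
equations of the five-state scheme to steady state by matrix-exponential
propagation with time doubling; it shares no code with the closed-form
solution in the package.
"""

import numpy as np

# state order: Free, 12, 12*, 12.6, 12.6*
FREE, B12, A12, B126, A126 = range(5)


def rate_matrix(params, fkbp12, fkbp12_6):
    """Generator matrix Q (row = from, column = to) of the occupancy chain."""
    Q = np.zeros((5, 5))
    edges = [
        (FREE, B12, params.k1 * fkbp12),
        (B12, FREE, params.k_m1),
        (B12, A12, params.k2),
        (A12, B12, params.k_m2),
        (FREE, B126, params.k3 * fkbp12_6),
        (B126, FREE, params.k_m3),
        (B126, A126, params.k4),
        (A126, B126, params.k_m4),
    ]
    for i, j, r in edges:
        Q[i, j] += r
        Q[i, i] -= r
    return Q


def occupancy_by_ode(params, fkbp12, fkbp12_6, x0=None):
    """Steady-state occupancy by long-time integration of dx/dt = x Q."""
    Q = rate_matrix(params, fkbp12, fkbp12_6)
    # the slowest *individual* transition bounds the relaxation time (it can be
    # buried inside a faster exit-rate sum, e.g. slow unbinding next to a fast
    # conformational step)
    off = Q[~np.eye(5, dtype=bool)]
    pos = off[off > 0]
    if len(pos) == 0:  # no transitions at all: distribution is frozen
        return np.array([1.0, 0, 0, 0, 0]) if x0 is None else np.asarray(x0)
    x = np.array([1.0, 0, 0, 0, 0]) if x0 is None else np.asarray(x0, dtype=float)
    # propagate x(t) = x expm(Q t), doubling t until the distribution stops
    # moving; relaxation can be slower than the slowest single rate when the
    # exchange bottleneck runs through a barely occupied intermediate state.
    # The short-time propagator is built by uniformization (Poisson-weighted
    # powers of a substochastic matrix: all-non-negative arithmetic), which
    # stays accurate for the very small components that direct expm() of a
    # stiff generator loses.
    lam = float((-np.diag(Q)).max())
    S = np.eye(5) + Q / lam  # stochastic
    propagator = np.zeros((5, 5))
    term = np.exp(-1.0) * np.eye(5)  # Poisson(1; 0) * S^0, with lam*t0 = 1
    for k in range(1, 40):
        propagator += term
        term = term @ S / k
    propagator += term
    propagator /= propagator.sum(axis=1, keepdims=True)
    for _ in range(100):
        x_new = x @ propagator
        x_new = np.maximum(x_new, 0.0)
        x_new = x_new / x_new.sum()
        if np.max(np.abs(x_new - x)) < 1e-13:
            x = x_new
            break
        x = x_new
        propagator = propagator @ propagator
        # the propagator is row-stochastic; renormalising fights roundoff
        # accumulation across repeated squarings
        propagator = np.maximum(propagator, 0.0)
        propagator /= propagator.sum(axis=1, keepdims=True)
    return x
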