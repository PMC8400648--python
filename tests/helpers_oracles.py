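"""Independent brute-force oracles shared across test modules."""

import numpy as np


def brute_force_breakpoint(x, y, weights=None, step=0.1,
                           min_points_per_side=3):
    """Exhaustive hinge-model knot search on a fixed fine grid.

    Solves the 3-parameter weighted least squares exactly at every
    candidate knot on a ``step``-resolution grid spanning the admissible
    interior, and returns the knot with the smallest weighted SSR (ties
    toward lower x).  Deliberately simple and independent of the
    package's profiled search-and-refine implementation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    order = np.argsort(x)
    x, y = x[order], y[order]
    w = np.ones_like(x) if weights is None else \
        np.asarray(weights, dtype=float)[order]
    m = min_points_per_side
    candidates = np.arange(x[m - 1] + step, x[-m] + 1e-9, step)
    best_ssr, best_xb = np.inf, None
    for xb in candidates:
        d = x - xb
        A = np.column_stack([np.ones_like(x), np.minimum(d, 0.0),
                             np.maximum(d, 0.0)])
        Aw = A * w[:, None]
        beta = np.linalg.solve(Aw.T @ A, Aw.T @ y)
        r = y - A @ beta
        ssr = float(r @ (w * r))
        if ssr < best_ssr - 1e-15:
            best_ssr, best_xb = ssr, float(xb)
    return best_xb


def brute_force_msd(pos):
    """O(T^2) direct all-origin MSD of an (T, n, 3) position array."""
    T = pos.shape[0]
    out = np.zeros(T)
    for lag in range(1, T):
        d = pos[lag:] - pos[:-lag]
        out[lag] = (d ** 2).sum(axis=2).mean()
    return out
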