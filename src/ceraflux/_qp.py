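"""Exact solver for the closest-flux quadratic program.

    min ||v - p||^2   s.t.  C v = d,  v >= 0

solved by a primal active-set method with KKT solves on the free set and
multiplier-based release, so the unique optimum is found to machine
precision (a soft-penalty least-squares formulation is not accurate
enough near active bounds, and the baseline flux profile must be
bit-reproducible across call sites).
"""

from __future__ import annotations

import numpy as np


def closest_nonneg_lsq(
    C: np.ndarray,
    d: np.ndarray,
    p: np.ndarray,
    tol: float = 1e-11,
    max_iter: int = 500,
) -> np.ndarray:
    """Flux vector closest to the prior ``p`` satisfying C v = d, v >= 0.

    Raises ``RuntimeError`` if the equality constraints cannot be met on
    the nonnegative orthant (checked by the caller against its own
    tolerance via the residual).
    """
    n = p.size
    active = np.zeros(n, dtype=bool)
    v = np.zeros(n)
    lam = np.zeros(C.shape[0])
    for _ in range(max_iter):
        free = ~active
        Cf = C[:, free]
        pf = p[free]
        # v_f = p_f - Cf' lam with (Cf Cf') lam = Cf p_f - d  (min-norm lam)
        M = Cf @ Cf.T
        rhs_ = Cf @ pf - d
        lam, *_ = np.linalg.lstsq(M, rhs_, rcond=None)
        vf = pf - Cf.T @ lam
        v = np.zeros(n)
        v[free] = vf
        if vf.size and vf.min() < -tol:
            # fix the most violated variable at its bound
            idx = np.nonzero(free)[0][np.argmin(vf)]
            active[idx] = True
            continue
        v = np.maximum(v, 0.0)
        if not active.any():
            return v
        # multipliers of the active bounds: release if any is negative
        mu = 2.0 * (C.T @ lam - p)[active]
        if mu.min() >= -tol:
            return v
        idx = np.nonzero(active)[0][np.argmin(mu)]
        active[idx] = False
    return v  # safeguarded; caller validates the residual
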