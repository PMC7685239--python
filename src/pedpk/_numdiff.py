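"""Central finite-difference derivatives used by the Laplace machinery."""

from __future__ import annotations

from typing import Callable

import numpy as np


def approx_gradient(f: Callable, x: np.ndarray, rel_step: float = 1e-6) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    g = np.zeros_like(x)
    for i in range(x.size):
        h = rel_step * max(abs(x[i]), 1.0)
        xp, xm = x.copy(), x.copy()
        xp[i] += h
        xm[i] -= h
        g[i] = (f(xp) - f(xm)) / (2 * h)
    return g


def approx_hessian(f: Callable, x: np.ndarray, rel_step: float = 1e-4) -> np.ndarray:
    """Central-difference Hessian; symmetric by construction."""
    x = np.asarray(x, dtype=float)
    n = x.size
    h = np.array([rel_step * max(abs(xi), 1.0) for xi in x])
    hess = np.empty((n, n))
    f0 = f(x)
    # diagonal
    for i in range(n):
        xp, xm = x.copy(), x.copy()
        xp[i] += h[i]
        xm[i] -= h[i]
        hess[i, i] = (f(xp) - 2 * f0 + f(xm)) / h[i] ** 2
    # off-diagonal
    for i in range(n):
        for j in range(i + 1, n):
            xpp, xpm, xmp, xmm = x.copy(), x.copy(), x.copy(), x.copy()
            xpp[[i, j]] += [h[i], h[j]]
            xpm[i] += h[i]
            xpm[j] -= h[j]
            xmp[i] -= h[i]
            xmp[j] += h[j]
            xmm[[i, j]] -= [h[i], h[j]]
            hess[i, j] = hess[j, i] = (f(xpp) - f(xpm) - f(xmp) + f(xmm)) / (
                4 * h[i] * h[j]
            )
    return hess
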