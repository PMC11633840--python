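"""Central-difference Hessian for observed-information standard errors."""

from __future__ import annotations

import numpy as np


def hessian(f, x: np.ndarray, rel_step: float = 1e-5) -> np.ndarray:
    """Symmetric central-difference Hessian of a scalar function.

    Step size h_i = rel_step * max(1, |x_i|) per coordinate.
    """
    x = np.asarray(x, dtype=float)
    p = x.size
    h = rel_step * np.maximum(1.0, np.abs(x))
    H = np.empty((p, p))
    f0 = f(x)

    def at(**shifts):
        xx = x.copy()
        for i, s in shifts.items():
            xx[int(i)] += s
        return f(xx)

    for i in range(p):
        e = np.zeros(p)
        e[i] = h[i]
        H[i, i] = (f(x + e) - 2.0 * f0 + f(x - e)) / h[i] ** 2
    for i in range(p):
        for j in range(i + 1, p):
            ei = np.zeros(p); ei[i] = h[i]
            ej = np.zeros(p); ej[j] = h[j]
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4.0 * h[i] * h[j])
    return H
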