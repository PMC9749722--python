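"""Natural cubic spline basis on follow-up time.

The truncated-power natural cubic basis (linear beyond the boundary
knots): with knots ξ1 < … < ξK the K−1 columns are

    N1(x) = x,   N_{k+1}(x) = d_k(x) − d_{K−1}(x),   k = 1..K−2,
    d_k(x) = [(x−ξ_k)₊³ − (x−ξ_K)₊³] / (ξ_K − ξ_k).

Cubic columns are rescaled by the squared knot span so all columns are
O(x), which keeps the logistic fits well conditioned.
"""

from __future__ import annotations

import numpy as np


def natural_cubic_basis(x, knots) -> np.ndarray:
    """Basis matrix with ``len(knots) - 1`` columns."""
    x = np.asarray(x, dtype=float)
    k = np.asarray(knots, dtype=float)
    if k.ndim != 1 or len(k) < 3:
        raise ValueError("need at least 3 strictly increasing knots")
    if np.any(np.diff(k) <= 0):
        raise ValueError("knots must be strictly increasing")
    span2 = (k[-1] - k[0]) ** 2

    def d(j):
        return (np.clip(x - k[j], 0, None) ** 3
                - np.clip(x - k[-1], 0, None) ** 3) / ((k[-1] - k[j]) * span2)

    cols = [x]
    d_last = d(len(k) - 2)
    for j in range(len(k) - 2):
        cols.append(d(j) - d_last)
    return np.column_stack(cols)
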