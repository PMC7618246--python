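"""Natural cubic spline utilities.

A natural cubic spline with knots xi_1 < ... < xi_K spans a K-dimensional
function space that is cubic between knots, has continuous second derivatives,
and is linear beyond the boundary knots.  The basis used here is the classical
truncated-power construction:

    N_1(x) = 1,  N_2(x) = x,
    N_{k+2}(x) = d_k(x) - d_{K-1}(x),   k = 1..K-2,
    d_k(x) = [ (x - xi_k)_+^3 - (x - xi_K)_+^3 ] / (xi_K - xi_k).

The constant function is in the span (N_1), which matters for the lag basis: a
flat lag-response curve must be representable.
"""

from __future__ import annotations

import numpy as np

__all__ = ["natural_spline_basis", "natural_spline_interpolate"]


def natural_spline_basis(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Evaluate the K-column natural cubic spline basis at points ``x``.

    Parameters
    ----------
    x : array of evaluation points.
    knots : strictly increasing array of K >= 2 knots (boundary knots included).

    Returns
    -------
    (len(x), K) basis matrix whose first column is constant 1.
    """
    x = np.asarray(x, dtype=float)
    knots = np.asarray(knots, dtype=float)
    if knots.ndim != 1 or knots.size < 2:
        raise ValueError("need at least two knots")
    if np.any(np.diff(knots) <= 0):
        raise ValueError("knots must be strictly increasing")
    K = knots.size
    cols = [np.ones_like(x), x]

    def d(k: int) -> np.ndarray:
        return (
            np.clip(x - knots[k], 0.0, None) ** 3
            - np.clip(x - knots[K - 1], 0.0, None) ** 3
        ) / (knots[K - 1] - knots[k])

    dKm2 = d(K - 2)
    for k in range(K - 2):
        cols.append(d(k) - dKm2)
    return np.column_stack(cols)


def natural_spline_interpolate(
    x_obs: np.ndarray, y_obs: np.ndarray, x_new: np.ndarray | float
) -> np.ndarray | float:
    """Natural cubic spline through (x_obs, y_obs), evaluated at ``x_new``.

    Inside the data range this is ordinary natural-spline interpolation
    (zero second derivative at the end points).  Beyond the range the natural
    tail is linear, so extrapolation continues the boundary tangent line.
    """
    from scipy.interpolate import CubicSpline

    x_obs = np.asarray(x_obs, dtype=float)
    y_obs = np.asarray(y_obs, dtype=float)
    order = np.argsort(x_obs)
    x_obs, y_obs = x_obs[order], y_obs[order]
    cs = CubicSpline(x_obs, y_obs, bc_type="natural")
    scalar = np.isscalar(x_new)
    xq = np.atleast_1d(np.asarray(x_new, dtype=float))
    out = cs(xq)
    der = cs.derivative()
    lo, hi = x_obs[0], x_obs[-1]
    below, above = xq < lo, xq > hi
    if below.any():
        out[below] = y_obs[0] + der(lo) * (xq[below] - lo)
    if above.any():
        out[above] = y_obs[-1] + der(hi) * (xq[above] - hi)
    return float(out[0]) if scalar else out
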