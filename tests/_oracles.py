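"""Independent brute-force oracles used to validate the fitting code.

These deliberately avoid the package's optimizer path: the hyperbola
oracle is a zooming dense grid search, the regression oracles are the
closed-form normal equations.
"""

import numpy as np


def grid_search_hyperbola_rss(
    x, y, y0_bounds=(0.0, 10.0), beta_bounds=(-0.01, 0.2), n=121, zooms=6
):
    """Best RSS of y0/(1+beta x) over a zooming dense (y0, beta) grid."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    y0_lo, y0_hi = y0_bounds
    b_lo, b_hi = beta_bounds
    best = np.inf
    for _ in range(zooms):
        y0g = np.linspace(y0_lo, y0_hi, n)
        bg = np.linspace(b_lo, b_hi, n)
        denom = 1.0 + bg[:, None] * x[None, :]  # (n, nx)
        pred = y0g[:, None, None] / denom[None, :, :]  # (ny0, nbeta, nx)
        rss = ((y[None, None, :] - pred) ** 2).sum(axis=-1)
        i, j = np.unravel_index(np.argmin(rss), rss.shape)
        best = float(rss[i, j])
        dy = (y0_hi - y0_lo) / (n - 1)
        db = (b_hi - b_lo) / (n - 1)
        y0_lo, y0_hi = y0g[i] - 2 * dy, y0g[i] + 2 * dy
        b_lo, b_hi = bg[j] - 2 * db, bg[j] + 2 * db
    return best


def normal_equation_coefs(design, y):
    """OLS coefficients from the normal equations X'X b = X'y."""
    design = np.asarray(design, float)
    y = np.asarray(y, float)
    return np.linalg.solve(design.T @ design, design.T @ y)
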