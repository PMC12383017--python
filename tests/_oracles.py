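"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's closed forms: the yield oracle
integrates the underlying age-structured catch equation numerically, and
the argmax oracles use dense grids.
"""

import numpy as np
from scipy.integrate import quad


def integral_ypr(E, c, m_ratio):
    """Relative yield per recruit by numerical integration.

    Age-structured catch equation with knife-edge selection: recruits at
    t0 with unit abundance, natural mortality M until the capture age tc
    (where mean length crosses Lc), then total mortality Z = F + M, cubic
    weight-at-length.  Time units are chosen so k = 1; the result depends
    only on (E, c, M/k) and is normalised by the asymptotic weight.
    """
    k = 1.0
    M = m_ratio * k
    F = M * E / (1.0 - E)
    Z = F + M
    t0 = 0.0
    tc = t0 - np.log(1.0 - c) / k  # length reaches Lc = c * L_inf

    def integrand(t):
        survival = np.exp(-M * (tc - t0)) * np.exp(-Z * (t - tc))
        weight = (1.0 - np.exp(-k * (t - t0))) ** 3
        return F * survival * weight

    val, _ = quad(integrand, tc, tc + 60.0 / Z, limit=200)
    return val


def grid_argmax_e(fun, step=1e-4):
    """Brute-force argmax of fun over E in (0, 1) on a regular grid."""
    grid = np.arange(step, 1.0, step)
    vals = np.array([fun(e) for e in grid])
    return float(grid[int(np.argmax(vals))])
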