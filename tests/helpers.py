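"""Shared independent oracles for the test suite."""

import numpy as np
from scipy import integrate


def quad_log_normalization(c: float, d: float, j_nu: float) -> float:
    """Adaptive-quadrature oracle for the 1-D Landau log-normalization.

    Integrates the density exponent directly, factoring out the peak value
    so nothing overflows even for strongly bistable shapes; independent of
    the Bessel closed form it is used to check.
    """
    peak = 0.0 if c >= 0 else c * c / (4.0 * d)
    f = lambda y: np.exp(
        -(c / 2.0) * j_nu * y * y - (d / 4.0) * j_nu**2 * y**4 - peak
    )
    # finite range holding all mass above exp(-800) of the peak, with
    # breakpoints at the density maxima so quad never misses the spikes
    a = (d / 4.0) * j_nu**2
    b = (c / 2.0) * j_nu
    l2 = (-b + np.sqrt(b * b + 4.0 * a * (peak + 800.0))) / (2.0 * a)
    lim = float(np.sqrt(l2))
    pts = [-np.sqrt(-c / (d * j_nu)), np.sqrt(-c / (d * j_nu))] if c < 0 else None
    val, _ = integrate.quad(
        f, -lim, lim, points=pts, epsabs=1e-300, epsrel=1e-13, limit=200
    )
    return float(np.log(val) + peak)
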