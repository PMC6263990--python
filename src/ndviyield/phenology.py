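"""Phenological characteristics of a fitted NDVI curve.

Three characteristic points of the seasonal curve are extracted: the left
inflection (time of maximum growth rate), the seasonal maximum, and the
right inflection (time of maximum withering rate), together with the NDVI
value at each.

Closed forms
------------
Writing the curve as ``f(t) = a + (b/k) * C_k * n * (1+n)^(-q)`` with
``n = exp[(t + d ln k - c)/d]``, ``q = (k+1)/k`` and ``C_k = (k+1)^q``:

* ``f'(t) = 0``  at ``n = k``, i.e. ``t_max = c`` and ``f(t_max) = a + b``.
* ``f''(t) = 0`` where ``n^2 - k(k+3) n + k^2 = 0``, giving
  ``n± = (k/2) [ (k+3) ± sqrt((k+3)^2 - 4) ]`` and
  ``t = c - d ln k + d ln n±``.

Both results are validated against numeric optimisation / root-finding in
:func:`numeric_phenology`, which is kept as an independent cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .curve import CurveParams, evaluate_curve

__all__ = ["PhenoFeatures", "extract_phenology", "numeric_phenology"]


@dataclass(frozen=True)
class PhenoFeatures:
    """Times (DOY) and NDVI values of the three characteristic points."""

    t_inf_1: float
    t_inf_2: float
    t_max: float
    ndvi_inf_1: float
    ndvi_inf_2: float
    ndvi_max: float

    def __post_init__(self) -> None:
        if not (self.t_inf_1 < self.t_max < self.t_inf_2):
            raise ValueError("inflection times must bracket the peak time")

    def as_dict(self) -> dict[str, float]:
        return {
            "t_inf_1": self.t_inf_1,
            "t_inf_2": self.t_inf_2,
            "t_max": self.t_max,
            "ndvi_inf_1": self.ndvi_inf_1,
            "ndvi_inf_2": self.ndvi_inf_2,
            "ndvi_max": self.ndvi_max,
        }


def extract_phenology(params: CurveParams) -> PhenoFeatures:
    """Closed-form characteristic points of the fitted curve."""
    k, c, d = params.k, params.c, params.d
    s = k + 3.0
    root = np.sqrt(s * s - 4.0)
    n_lo = 0.5 * k * (s - root)
    n_hi = 0.5 * k * (s + root)
    t1 = c - d * np.log(k) + d * np.log(n_lo)
    t2 = c - d * np.log(k) + d * np.log(n_hi)
    return PhenoFeatures(
        t_inf_1=float(t1),
        t_inf_2=float(t2),
        t_max=float(c),
        ndvi_inf_1=float(evaluate_curve(params, t1)),
        ndvi_inf_2=float(evaluate_curve(params, t2)),
        ndvi_max=params.a + params.b,
    )


def numeric_phenology(params: CurveParams, span: float = 12.0) -> PhenoFeatures:
    """Characteristic points by numeric optimisation and root-finding.

    Independent of the closed forms: the peak and the inflections are located
    with Brent root-finding on numerical first and second derivatives. The
    first derivative uses the complex-step formula ``Im f(t + ih)/h``, which
    has no subtractive cancellation and is exact to machine precision; the
    second derivative is a central difference of the complex-step first
    derivative. (Direct minimisation of ``-f`` or plain finite differences
    of function values resolve the roots only to ~1e-5 days; the curve is
    locally flat on those scales.) ``span`` sets the search window
    ``[c - span*d, c + span*d]``.
    """
    a, b, c, d, k = params.a, params.b, params.c, params.d, params.k
    lo, hi = c - span * d, c + span * d
    q = (k + 1.0) / k

    def f_complex(t):
        z = (t + d * np.log(k) - c) / d
        return a + (b / k) * (k + 1.0) ** q * np.exp(z - q * np.log(1.0 + np.exp(z)))

    hc = 1e-100  # complex-step size; derivative scales linearly, no cancellation

    def f1(t):
        return f_complex(complex(t, hc)).imag / hc

    h = 5e-6 * d  # central-difference step on the (exact) first derivative

    def f2(t):
        return (f1(t + h) - f1(t - h)) / (2.0 * h)

    grid = np.linspace(lo, hi, 400)
    coarse = grid[int(np.argmax([evaluate_curve(params, t) for t in grid]))]
    t_max = float(brentq(f1, coarse - 2.0 * d, coarse + 2.0 * d, xtol=1e-10))

    def bracket_root(t_from, t_to, n_grid=400):
        ts = np.linspace(t_from, t_to, n_grid)
        vals = np.array([f2(t) for t in ts])
        sign = np.sign(vals)
        idx = np.nonzero(np.diff(sign) != 0)[0]
        if len(idx) == 0:
            raise RuntimeError("no curvature sign change in bracket")
        i = idx[0]
        return brentq(f2, ts[i], ts[i + 1], xtol=1e-9)

    t1 = bracket_root(lo, t_max)
    t2 = bracket_root(t_max, hi)
    return PhenoFeatures(
        t_inf_1=float(t1),
        t_inf_2=float(t2),
        t_max=t_max,
        ndvi_inf_1=float(evaluate_curve(params, t1)),
        ndvi_inf_2=float(evaluate_curve(params, t2)),
        ndvi_max=float(evaluate_curve(params, t_max)),
    )
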