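"""Asymmetric logistic NDVI curve: evaluation and bounded least-squares fitting.

A pixel's seasonal NDVI trajectory is modelled with the five-parameter
unimodal curve

    NDVI(t) = a + (b/k) * (1 + n)^(-(k+1)/k) * n * (k+1)^((k+1)/k)
    n(t)    = exp[(t + d*ln(k) - c) / d]

where ``t`` is day of year (DOY). The parameterisation is chosen so that the
curve peaks exactly at ``t = c`` with peak value ``a + b``: substituting
``t = c`` gives ``n = k``, and the normalising factor ``(k+1)^((k+1)/k)``
makes the peak term equal one. ``a`` is the off-season baseline NDVI, ``b``
the seasonal amplitude, ``d`` a time scale (days) and ``k`` a dimensionless
asymmetry (``k = 1`` gives a symmetric bell; ``k != 1`` skews green-up
versus senescence).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "CurveParams",
    "NdviSeries",
    "AsymmetricLogisticModel",
    "ndvi",
    "evaluate_curve",
    "fit_curve",
    "daily_ndvi",
    "CurveFitError",
]

# Physical/seasonal bounds on (a, b, c, d, k); c bounds are widened to the
# observation window +/- 30 days at fit time.
BOUND_A = (-0.5, 0.5)
BOUND_B = (1e-6, 1.5)
BOUND_D = (2.0, 60.0)
BOUND_K = (0.05, 20.0)
MIN_OBSERVATIONS = 8
MIN_SPAN_DAYS = 60.0


class CurveFitError(RuntimeError):
    """Raised when a per-pixel curve fit cannot be performed or fails."""


@dataclass(frozen=True)
class CurveParams:
    """Fitted parameters of the asymmetric logistic curve plus diagnostics."""

    a: float
    b: float
    c: float
    d: float
    k: float
    rss: float = float("nan")
    converged: bool = True

    def __post_init__(self) -> None:
        if not (self.b > 0 and self.d > 0 and self.k > 0):
            raise ValueError(f"b, d, k must be positive (got b={self.b}, d={self.d}, k={self.k})")
        if not (BOUND_A[0] <= self.a <= BOUND_A[1]):
            raise ValueError(f"baseline a={self.a} outside physical range {BOUND_A}")

    def as_array(self) -> np.ndarray:
        return np.array([self.a, self.b, self.c, self.d, self.k])


@dataclass(frozen=True)
class NdviSeries:
    """One pixel's irregular (DOY, NDVI) observations for one season."""

    pixel_id: int
    t: np.ndarray
    ndvi: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        v = np.asarray(self.ndvi, dtype=float)
        if t.shape != v.shape or t.ndim != 1:
            raise ValueError("t and ndvi must be matching 1-D arrays")
        if len(t) and not np.all(np.diff(t) > 0):
            raise ValueError("observation DOYs must be strictly increasing")
        if len(t) and (t.min() < 1 or t.max() > 366):
            raise ValueError("DOY must lie in [1, 366]")
        if len(v) and (v.min() < -1 or v.max() > 1):
            raise ValueError("NDVI must lie in [-1, 1]")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "ndvi", v)

    def __len__(self) -> int:
        return len(self.t)


def ndvi(red, nir):
    """Normalized Difference Vegetation Index, (NIR - red) / (NIR + red).

    Computed from red and near-infrared surface reflectances in [0, 1].
    Raises ``ValueError`` on a zero denominator (no signal in either band).
    """
    red = np.asarray(red, dtype=float)
    nir = np.asarray(nir, dtype=float)
    if np.any(red < 0) or np.any(red > 1) or np.any(nir < 0) or np.any(nir > 1):
        raise ValueError("reflectances must lie in [0, 1]")
    denom = nir + red
    if np.any(denom == 0):
        raise ValueError("NDVI undefined where nir + red == 0")
    out = (nir - red) / denom
    return float(out) if out.ndim == 0 else out


def _evaluate(t, a, b, c, d, k):
    # log-space evaluation: z = ln n grows linearly in t, so the peak term
    # exp(z - ((k+1)/k) * ln(1+e^z)) stays finite for |t - c| >> d.
    t = np.asarray(t, dtype=float)
    z = (t + d * np.log(k) - c) / d
    q = (k + 1.0) / k
    log_term = z - q * np.logaddexp(0.0, z)
    return a + (b / k) * (k + 1.0) ** q * np.exp(log_term)


def evaluate_curve(params: CurveParams, t):
    """Evaluate the curve at DOY ``t`` (scalar or array).

    Tends to the baseline ``a`` as ``t -> +/-inf`` and attains its maximum
    ``a + b`` at ``t = c``.
    """
    out = _evaluate(t, params.a, params.b, params.c, params.d, params.k)
    return float(out) if np.ndim(out) == 0 else out


def daily_ndvi(params: CurveParams, start: int, end: int) -> np.ndarray:
    """Reconstructed daily NDVI at every integer DOY in [start, end]."""
    start, end = int(start), int(end)
    if start > end:
        raise ValueError(f"invalid DOY range [{start}, {end}]")
    return evaluate_curve(params, np.arange(start, end + 1, dtype=float))


class AsymmetricLogisticModel(RegressorMixin, BaseEstimator):
    """Bounded nonlinear least-squares fit of the asymmetric logistic curve.

    scikit-learn style estimator: ``fit(X, y)`` takes DOYs as a column vector
    (or 1-D array) ``X`` and NDVI values ``y``; ``predict(X)`` evaluates the
    fitted curve. The underlying solver is the trust-region reflective method
    with box constraints on all five parameters.

    Initialisation uses data moments: the parameterisation makes ``c`` the
    peak time and ``a + b`` the peak value, so the DOY of the observed
    maximum, the observed min and the observed range give strong starting
    values. On non-convergence the fit restarts from ``k0 in {0.5, 1, 2}``.

    Parameters
    ----------
    max_nfev : int
        Function-evaluation budget per restart.
    xtol, ftol : float
        Solver tolerances.

    Attributes
    ----------
    params_ : CurveParams
        Fitted parameters with residual sum of squares and convergence flag.
    """

    def __init__(self, max_nfev: int = 2000, xtol: float = 1e-12, ftol: float = 1e-12):
        self.max_nfev = max_nfev
        self.xtol = xtol
        self.ftol = ftol

    def fit(self, X, y):
        t = np.asarray(X, dtype=float).reshape(-1)
        v = np.asarray(y, dtype=float).reshape(-1)
        if t.shape != v.shape:
            raise ValueError("X and y must have the same length")
        order = np.argsort(t)
        t, v = t[order], v[order]
        if len(t) < MIN_OBSERVATIONS:
            raise CurveFitError(
                f"need >= {MIN_OBSERVATIONS} observations for a 5-parameter fit, got {len(t)}"
            )
        if t[-1] - t[0] < MIN_SPAN_DAYS:
            raise CurveFitError(
                f"observations span {t[-1] - t[0]:.0f} days; need >= {MIN_SPAN_DAYS:.0f}"
            )
        if np.ptp(v) < 1e-8:
            raise CurveFitError("degenerate (constant) NDVI series")

        lo = np.array([BOUND_A[0], BOUND_B[0], t[0] - 30.0, BOUND_D[0], BOUND_K[0]])
        hi = np.array([BOUND_A[1], BOUND_B[1], t[-1] + 30.0, BOUND_D[1], BOUND_K[1]])

        a0 = float(np.clip(v.min(), *BOUND_A))
        b0 = float(np.clip(np.ptp(v), BOUND_B[0] * 10, BOUND_B[1]))
        c0 = float(t[np.argmax(v)])
        d0 = float(np.clip((t[-1] - t[0]) / 6.0, *BOUND_D))

        def residuals(x):
            return _evaluate(t, *x) - v

        best = None
        for k0 in (1.0, 0.5, 2.0):
            x0 = np.clip(np.array([a0, b0, c0, d0, k0]), lo, hi)
            res = least_squares(
                residuals, x0, bounds=(lo, hi), method="trf",
                max_nfev=self.max_nfev, xtol=self.xtol, ftol=self.ftol,
            )
            rss = float(res.cost * 2.0)
            if res.success and (best is None or rss < best[1]):
                best = (res.x, rss)
                if rss < 1e-10 * max(1.0, len(t)):
                    break  # essentially exact; restarts cannot improve
        if best is None:
            raise CurveFitError("curve fit did not converge after restarts")

        x, rss = best
        self.params_ = CurveParams(
            a=float(x[0]), b=float(x[1]), c=float(x[2]), d=float(x[3]), k=float(x[4]),
            rss=rss, converged=True,
        )
        self.n_observations_ = len(t)
        return self

    def predict(self, X):
        check_is_fitted(self, "params_")
        t = np.asarray(X, dtype=float).reshape(-1)
        return evaluate_curve(self.params_, t)


def fit_curve(series: NdviSeries) -> CurveParams:
    """Fit the asymmetric logistic curve to one pixel's NDVI series.

    Thin functional wrapper over :class:`AsymmetricLogisticModel`. Raises
    :class:`CurveFitError` for degenerate or insufficient series and on
    non-convergence; callers typically drop (and log) such pixels.
    """
    model = AsymmetricLogisticModel().fit(series.t, series.ndvi)
    return model.params_
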