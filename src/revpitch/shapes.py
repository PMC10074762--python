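"""Polynomial shape models for temporal kernels.

Kernels are fit by ordinary least squares with polynomials of degree
1-4 on the normalized time axis t_k = (k-1)/(K-1).  Nested models are
compared with the OLS F-test (the likelihood-ratio test for Gaussian
errors), and the selection ladder walks up the degrees sequentially:
linear vs quadratic first; when that is not significant, linear vs
cubic; a significant cubic is then challenged by the quartic; when
linear vs cubic is also not significant, linear vs quartic decides.
The fitted curve yields two shape parameters: the y-intercept b0 = p(0)
and the analytic tangent slope at the midpoint p'(0.5).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "ShapeFit",
    "NestedTestResult",
    "ShapeParams",
    "fit_polynomial",
    "nested_f_test",
    "select_shape",
    "shape_params",
    "normalized_grid",
]

ALPHA = 0.05


@dataclass
class ShapeFit:
    """OLS polynomial fit of kernel values against normalized time."""

    degree: int
    coefficients: np.ndarray  # power basis, ascending: c0 + c1 t + ...
    sse: float
    r_squared: float
    n_points: int
    t: np.ndarray = field(repr=False, default=None)
    y: np.ndarray = field(repr=False, default=None)

    def predict(self, t) -> np.ndarray:
        return np.polynomial.polynomial.polyval(np.asarray(t, dtype=float),
                                                self.coefficients)


@dataclass
class NestedTestResult:
    comparison: str
    df_num: int
    df_den: int
    f_stat: float
    p_value: float
    winner: int  # degree of the favoured model
    significant: bool


@dataclass
class ShapeParams:
    b0: float
    midpoint_slope: float
    midpoint: float = 0.5


def normalized_grid(n_points: int) -> np.ndarray:
    """Breakpoint time grid t_k = (k-1)/(K-1) on [0, 1]."""
    return np.arange(n_points) / (n_points - 1)


def fit_polynomial(y, degree: int, t=None) -> ShapeFit:
    """Least-squares polynomial fit of degree 1-4.

    ``t`` defaults to the normalized grid for ``len(y)`` points; pass an
    explicit grid to pool several participants' kernels (repeated time
    values are fine for OLS).
    """
    y = np.asarray(y, dtype=float)
    if not 1 <= degree <= 4:
        raise ValueError("degree must be in 1..4")
    t = normalized_grid(len(y)) if t is None else np.asarray(t, dtype=float)
    if len(t) != len(y):
        raise ValueError("t and y lengths differ")
    n = len(y)
    if degree + 1 > n:
        raise ValueError("degree too high for the number of points")
    X = np.vander(t, degree + 1, increasing=True)
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < degree + 1:
        raise ValueError("rank-deficient design (too few distinct time points)")
    resid = y - X @ coef
    sse = float(resid @ resid)
    sst = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 if sst == 0 else max(0.0, 1.0 - sse / sst)
    return ShapeFit(degree=degree, coefficients=coef, sse=sse, r_squared=r2,
                    n_points=n, t=t, y=y)


def nested_f_test(fit_small: ShapeFit, fit_big: ShapeFit,
                  alpha: float = ALPHA) -> NestedTestResult:
    """OLS F-test between nested polynomial fits of the same data.

    F = ((SSE_s - SSE_b)/df_num) / (SSE_b/df_den), df_num the degree
    difference, df_den = n - (degree_big + 1).  Equivalent to the
    Gaussian likelihood-ratio test.
    """
    if fit_big.degree <= fit_small.degree:
        raise ValueError("fit_big must have the higher degree")
    if fit_big.n_points != fit_small.n_points:
        raise ValueError("fits must share the same data")
    if fit_big.sse <= 0:
        raise ValueError("degenerate test: the larger model fits perfectly")
    df_num = fit_big.degree - fit_small.degree
    df_den = fit_big.n_points - (fit_big.degree + 1)
    if df_den <= 0:
        raise ValueError("no residual degrees of freedom for the larger model")
    delta = max(fit_small.sse - fit_big.sse, 0.0)
    f = (delta / df_num) / (fit_big.sse / df_den)
    p = float(stats.f.sf(f, df_num, df_den)) if f > 0 else 1.0
    significant = p < alpha
    winner = fit_big.degree if significant else fit_small.degree
    names = {1: "Linear", 2: "Quadratic", 3: "Cubic", 4: "Quartic"}
    return NestedTestResult(
        comparison=f"{names[fit_small.degree]} and {names[fit_big.degree]}",
        df_num=df_num, df_den=df_den, f_stat=float(f), p_value=p,
        winner=winner, significant=significant,
    )


def select_shape(y, t=None, alpha: float = ALPHA,
                 ) -> tuple[int, list[NestedTestResult]]:
    """Sequential nested-model selection over degrees 1-4.

    Ladder: linear vs quadratic; if not significant, linear vs cubic;
    a winning cubic is challenged by the quartic; if linear vs cubic is
    also not significant, linear vs quartic decides.  (When linear vs
    quadratic is significant the same logic continues upward from the
    quadratic.)  Returns the winning degree and the full ladder.
    """
    fits = {d: fit_polynomial(y, d, t=t) for d in (1, 2, 3, 4)}
    ladder: list[NestedTestResult] = []
    current = 1
    test = nested_f_test(fits[1], fits[2], alpha=alpha)
    ladder.append(test)
    if test.significant:
        current = 2
        test = nested_f_test(fits[2], fits[3], alpha=alpha)
        ladder.append(test)
        if test.significant:
            current = 3
            test = nested_f_test(fits[3], fits[4], alpha=alpha)
            ladder.append(test)
            if test.significant:
                current = 4
        else:
            test = nested_f_test(fits[2], fits[4], alpha=alpha)
            ladder.append(test)
            if test.significant:
                current = 4
        return current, ladder
    test = nested_f_test(fits[1], fits[3], alpha=alpha)
    ladder.append(test)
    if test.significant:
        current = 3
        test = nested_f_test(fits[3], fits[4], alpha=alpha)
        ladder.append(test)
        if test.significant:
            current = 4
    else:
        test = nested_f_test(fits[1], fits[4], alpha=alpha)
        ladder.append(test)
        if test.significant:
            current = 4
    return current, ladder


def shape_params(fit: ShapeFit, midpoint: float = 0.5) -> ShapeParams:
    """y-intercept and analytic tangent slope at the midpoint."""
    b0 = float(fit.predict(0.0))
    deriv = np.polynomial.polynomial.polyder(fit.coefficients)
    slope = float(np.polynomial.polynomial.polyval(midpoint, deriv))
    return ShapeParams(b0=b0, midpoint_slope=slope, midpoint=midpoint)
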