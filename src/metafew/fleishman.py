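"""Fleishman power-method generation of non-normal variates.

The power method represents a zero-mean, unit-variance variable with target
skewness g1 and excess kurtosis g2 as a cubic of a standard normal variate,

    Y = a + b*Z + c*Z^2 + d*Z^3,   a = -c.

The coefficients solve the classical three-moment system

    b^2 + 6*b*d + 2*c^2 + 15*d^2                       = 1
    2*c*(b^2 + 24*b*d + 105*d^2 + 2)                   = g1
    24*[b*d + c^2*(1 + b^2 + 28*b*d)
        + d^2*(12 + 48*b*d + 141*c^2 + 225*d^2)]       = g2

A solution exists only inside the feasible region
g2 >= -1.2264489 + 1.6410373 * g1^2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize

__all__ = ["FleishmanCoeffs", "solve_fleishman", "sample_fleishman", "fleishman_moments"]

_FEAS_A = -1.2264489
_FEAS_B = 1.6410373


@dataclass(frozen=True)
class FleishmanCoeffs:
    a: float
    b: float
    c: float
    d: float

    def transform(self, z: np.ndarray) -> np.ndarray:
        z = np.asarray(z, dtype=float)
        return self.a + z * (self.b + z * (self.c + z * self.d))

    def is_monotone(self, z_max: float = 6.0) -> bool:
        """Whether the cubic is increasing on |z| <= z_max (quantile identity)."""
        z = np.linspace(-z_max, z_max, 2001)
        deriv = self.b + 2 * self.c * z + 3 * self.d * z**2
        return bool(np.all(deriv > 0))


def _system(x, skew, exkurt):
    b, c, d = x
    f1 = b**2 + 6 * b * d + 2 * c**2 + 15 * d**2 - 1.0
    f2 = 2 * c * (b**2 + 24 * b * d + 105 * d**2 + 2.0) - skew
    f3 = (
        24.0
        * (
            b * d
            + c**2 * (1.0 + b**2 + 28 * b * d)
            + d**2 * (12.0 + 48 * b * d + 141 * c**2 + 225 * d**2)
        )
        - exkurt
    )
    return [f1, f2, f3]


def fleishman_moments(coeffs: FleishmanCoeffs) -> tuple[float, float, float, float]:
    """Exact (mean, variance, skewness, excess kurtosis) of the cubic of Z."""
    b, c, d = coeffs.b, coeffs.c, coeffs.d
    var = b**2 + 6 * b * d + 2 * c**2 + 15 * d**2
    skew = 2 * c * (b**2 + 24 * b * d + 105 * d**2 + 2.0)
    exkurt = 24.0 * (
        b * d
        + c**2 * (1.0 + b**2 + 28 * b * d)
        + d**2 * (12.0 + 48 * b * d + 141 * c**2 + 225 * d**2)
    )
    mean = coeffs.a + c
    return mean, var, skew, exkurt


def solve_fleishman(skew: float, excess_kurt: float, tol: float = 1e-10) -> FleishmanCoeffs:
    """Coefficients of the zero-mean, unit-variance Fleishman cubic.

    Multi-start Newton (scipy hybr) from the near-normal start (1, 0, 0) and
    a few perturbed starts.  Raises ``ValueError`` for targets outside the
    feasible region.  The quadratic boundary excess_kurt >= -1.2264489 +
    1.6410373 * skew^2 is a fitted approximation that can be slightly
    conservative, so a solve is always attempted first and the boundary is
    reported only when no solution exists.
    """
    starts = [
        (1.0, 0.0, 0.0),
        (0.9, 0.1 * math.copysign(1.0, skew or 1.0), 0.0),
        (0.9, 0.15 * math.copysign(1.0, skew or 1.0), 0.05),
        (0.8, 0.2 * math.copysign(1.0, skew or 1.0), -0.05),
    ]
    best = None
    for x0 in starts:
        sol = optimize.root(_system, x0, args=(skew, excess_kurt), method="hybr", tol=tol)
        resid = float(np.max(np.abs(_system(sol.x, skew, excess_kurt))))
        if resid < 1e-8 and sol.x[0] > 0:
            best = sol.x
            break
        if best is None or resid < float(np.max(np.abs(_system(best, skew, excess_kurt)))):
            best = sol.x
    resid = float(np.max(np.abs(_system(best, skew, excess_kurt))))
    if resid > 1e-6:
        boundary = _FEAS_A + _FEAS_B * skew**2
        if excess_kurt < boundary:
            raise ValueError(
                f"(skew={skew}, excess_kurt={excess_kurt}) is outside the "
                f"Fleishman feasible region: excess kurtosis must be >= "
                f"{boundary:.6f} (= {_FEAS_A} + {_FEAS_B} * skew^2)"
            )
        raise ValueError(
            f"Fleishman system did not converge for (skew={skew}, "
            f"excess_kurt={excess_kurt}); max residual {resid:.2e}"
        )
    b, c, d = (float(v) for v in best)
    return FleishmanCoeffs(a=-c, b=b, c=c, d=d)


def sample_fleishman(
    n: int,
    mean: float,
    sd: float,
    skew: float,
    excess_kurt: float,
    rng: np.random.Generator,
    coeffs: FleishmanCoeffs | None = None,
) -> np.ndarray:
    """n draws of mean + sd * (a + b Z + c Z^2 + d Z^3), Z standard normal."""
    if sd <= 0:
        raise ValueError("sd must be positive")
    if coeffs is None:
        coeffs = solve_fleishman(skew, excess_kurt)
    z = rng.standard_normal(n)
    return mean + sd * coeffs.transform(z)
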