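"""No-intercept least squares for difference equations, with test battery.

The coupled logistic model is fit by differential regression: the ODE is
discretised to a daily difference equation whose increment is linear in the
lagged regressors, so parameter estimation reduces to ordinary least squares
without a constant term.  A fit passes the three-part battery when

* **structural** — every coefficient strictly matches its expected sign,
* **correlation** — R² exceeds a threshold (default 0.9), and
* **significance** — every coefficient's two-sided t-test p-value is below
  a threshold (default 0.05).

Because the model has no intercept, the default R² convention is uncentered
(``1 - RSS / Σy²``); the centered convention is available for sensitivity
analysis with an intercept.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg
from scipy.special import stdtr

__all__ = [
    "CollinearityError",
    "InsufficientDataError",
    "RegressionResult",
    "LogisticFit",
    "TestOutcome",
    "ols_no_intercept",
    "ols",
    "build_logistic_design",
    "fit_logistic",
    "evaluate_tests",
]


class CollinearityError(ValueError):
    """Design matrix is rank deficient."""


class InsufficientDataError(ValueError):
    """Too few observations for the requested fit."""


@dataclass
class RegressionResult:
    coefficients: np.ndarray
    std_errors: np.ndarray
    p_values: np.ndarray
    r_squared: float
    n_obs: int
    dof: int


@dataclass
class LogisticFit:
    """Logistic parameters recovered from a difference-equation regression.

    ``K`` is defined only when the coefficient on x² is strictly negative
    (the raw coefficients remain available in ``regression`` otherwise).
    """

    r: float
    K: float | None
    regression: RegressionResult


@dataclass(frozen=True)
class TestOutcome:
    structural_pass: bool
    correlation_pass: bool
    significance_pass: bool

    @property
    def overall_pass(self) -> bool:
        return self.structural_pass and self.correlation_pass and self.significance_pass


def _pvalues_from_t(coefficients, std_errors, dof):
    """Two-sided t-test p-values against zero; exact-fit conventions.

    With a zero standard error the statistic degenerates: a nonzero
    coefficient is taken as infinitely significant (p = 0), a zero
    coefficient as maximally insignificant (p = 1).
    """
    p = np.empty_like(np.asarray(coefficients, dtype=float))
    for j, (c, se) in enumerate(zip(coefficients, std_errors)):
        if se > 0 and np.isfinite(se):
            p[j] = 2.0 * stdtr(dof, -abs(c / se))
        else:
            p[j] = 0.0 if c != 0 else 1.0
    return p


def ols_no_intercept(design, response, r2_convention: str = "uncentered") -> RegressionResult:
    """Least squares through the origin with classical t inference.

    Columns are rescaled to unit norm internally for numerical stability
    (the polynomial regressors of the cumulative model span many orders of
    magnitude); estimates are reported on the original scale.
    """
    X = np.asarray(design, dtype=float)
    y = np.asarray(response, dtype=float)
    if X.ndim != 2 or y.ndim != 1 or X.shape[0] != len(y):
        raise ValueError("design must be 2-D and match the response length")
    n_obs, k = X.shape
    dof = n_obs - k
    if dof < 1:
        raise InsufficientDataError(f"{n_obs} observations cannot support {k} regressors with dof >= 1")

    norms = np.linalg.norm(X, axis=0)
    if np.any(norms == 0):
        dead = [int(j) for j in np.flatnonzero(norms == 0)]
        raise CollinearityError(f"design columns {dead} are identically zero")
    Xs = X / norms
    # rank check via pivoted QR; name the dependent columns
    _, R, piv = scipy.linalg.qr(Xs, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag[0] * max(n_obs, k) * np.finfo(float).eps if diag[0] > 0 else 0.0
    rank = int(np.sum(diag > tol))
    if rank < k:
        dependent = sorted(int(j) for j in piv[rank:])
        raise CollinearityError(f"design columns {dependent} are linearly dependent on the others")

    beta_s, *_ = np.linalg.lstsq(Xs, y, rcond=None)
    resid = y - Xs @ beta_s
    rss = float(resid @ resid)
    G = Xs.T @ Xs
    inv_diag = np.diag(np.linalg.inv(G))
    s2 = rss / dof
    se_s = np.sqrt(np.maximum(s2 * inv_diag, 0.0))
    p = _pvalues_from_t(beta_s, se_s, dof)

    yy = float(y @ y)
    if r2_convention == "uncentered":
        r2 = 1.0 - rss / yy if yy > 0 else np.nan
    elif r2_convention == "centered":
        tss = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 - rss / tss if tss > 0 else np.nan
    else:
        raise ValueError(f"unknown r2_convention {r2_convention!r}")

    return RegressionResult(
        coefficients=beta_s / norms,
        std_errors=se_s / norms,
        p_values=p,
        r_squared=r2,
        n_obs=n_obs,
        dof=dof,
    )


def ols(design, response, intercept: bool = False, r2_convention: str | None = None) -> RegressionResult:
    """OLS with an optional constant term (sensitivity escape hatch).

    The difference equations have no constant, so ``intercept=False`` is
    the modelling default.  With ``intercept=True`` a column of ones is
    prepended (its coefficient comes first) and R² switches to the
    centered convention unless overridden.
    """
    if not intercept:
        return ols_no_intercept(design, response, r2_convention or "uncentered")
    X = np.column_stack([np.ones(len(response)), np.asarray(design, dtype=float)])
    return ols_no_intercept(X, response, r2_convention or "centered")


def build_logistic_design(x) -> tuple[np.ndarray, np.ndarray]:
    """Design/response for the discrete logistic equation.

    For ``n = 2..len(x)`` the response row is the increment ``x(n) - x(n-1)``
    and the regressor row is ``(x(n-1), x(n-1)²)`` — the lagged-state
    convention shared with the simulator.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or len(x) < 3:
        raise InsufficientDataError("need a cumulative sequence of at least 3 days")
    lag = x[:-1]
    return np.column_stack([lag, lag**2]), np.diff(x)


def fit_logistic(x, r2_convention: str = "uncentered") -> LogisticFit:
    """Recover (r, K) of the logistic model from a cumulative trajectory."""
    x = np.asarray(x, dtype=float)
    if len(x) < 4:
        raise InsufficientDataError("need at least 4 days so the residual dof is >= 1")
    design, response = build_logistic_design(x)
    res = ols_no_intercept(design, response, r2_convention=r2_convention)
    r = float(res.coefficients[0])
    c2 = float(res.coefficients[1])
    K = -r / c2 if c2 < 0 else None
    return LogisticFit(r=r, K=K, regression=res)


def decide_tests(
    coefficients, p_values, r_squared, expected_signs, r2_min: float, alpha: float
) -> TestOutcome:
    """Three-part battery on raw fit quantities (shared fast path)."""
    signs = np.asarray(expected_signs, dtype=float)
    coef = np.asarray(coefficients, dtype=float)
    structural = bool(np.all(signs * coef > 0))  # strict: zero coefficient fails
    r2 = float(r_squared)
    correlation = bool(np.isfinite(r2) and r2 > r2_min)
    p = np.asarray(p_values, dtype=float)
    significance = bool(np.all(np.isfinite(p)) and np.all(p < alpha))
    return TestOutcome(structural, correlation, significance)


def evaluate_tests(
    result: RegressionResult, expected_signs, r2_min: float = 0.9, alpha: float = 0.05
) -> TestOutcome:
    """Apply the structural / correlation / significance battery to a fit."""
    if len(expected_signs) != len(result.coefficients):
        raise ValueError("expected_signs must give one sign per regressor")
    return decide_tests(
        result.coefficients, result.p_values, result.r_squared, expected_signs, r2_min, alpha
    )
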