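"""Maximum-likelihood cointegration rank test for bivariate systems.

The vector error correction model (VECM) form of a VAR(K) process,

    dy_t = Pi y_{t-1} + Gamma_1 dy_{t-1} + ... + Gamma_{K-1} dy_{t-K+1} + u_t,

links the system type to the rank of Pi = alpha beta': for a bivariate
system, rk(Pi) = 2 means both series are stationary (I(0)), rk(Pi) = 1
means cointegration (CI(1)) with cointegrating vector beta = (1, beta0)',
and rk(Pi) = 0 means two integrated series without a common trend (I(1)).

The rank is estimated by reduced-rank regression: partial out the lagged
differences from both dy_t and y_{t-1}, form the residual product-moment
matrices S00, S01, S11, and solve the generalized eigenproblem

    |lambda S11 - S10 S00^{-1} S01| = 0.

The eigenvalues are the squared canonical correlations between the two
residual sets; the trace statistic for H0: rk(Pi) <= j is
-T_eff * sum_{i>j} ln(1 - lambda_i).  The rank decision is sequential:
test r = 0 first, then r <= 1, stopping at the first hypothesis not
rejected.

No deterministic term enters the cointegrating relation, but an
unrestricted intercept is part of the short-run dynamics (the standard
default of VECM software: both dy_t and y_{t-1} are demeaned along with
the lagged differences).  The critical values below are the matching
trace-table entries for that case — note 8.18 and 11.65 are the squares of
the demeaned Dickey-Fuller quantiles, as they must be for n - r = 1.
Levels enter at lag 1 (the "transitory" specification); this yields the
same eigenvalues and statistics as the long-run form, since the regressor
spans coincide.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg
from sklearn.base import BaseEstimator

from .series import BivariateSeries

#: Trace-statistic critical values (Osterwald-Lenum 1992) for the case with
#: an unrestricted intercept in the short-run dynamics and no deterministic
#: term in the cointegrating relation.  Keyed by n - r (number of common
#: trends under H0), columns at the 10%, 5% and 1% levels.
TRACE_CRITICAL_VALUES = {
    1: {0.10: 6.50, 0.05: 8.18, 0.01: 11.65},
    2: {0.10: 15.66, 0.05: 17.95, 0.01: 23.52},
}

LEVELS = (0.10, 0.05, 0.01)

#: |first eigenvector component| below this means (1, beta0)' normalization
#: is undefined for that replication.
NORMALIZE_TOL = 1e-10


class DegenerateInputError(ValueError):
    """Moment matrices are singular (e.g. a constant series after degradation)."""


def critical_value(n_minus_r: int, level: float) -> float:
    """Trace-test critical value for H0: rank <= n - (n - r).

    ``n_minus_r`` is the number of common trends under the null (1 or 2 for
    a bivariate system); ``level`` one of 0.10, 0.05, 0.01.
    """
    if n_minus_r not in TRACE_CRITICAL_VALUES:
        raise ValueError(f"n_minus_r must be 1 or 2, got {n_minus_r}")
    if level not in TRACE_CRITICAL_VALUES[n_minus_r]:
        raise ValueError(f"level must be one of {LEVELS}, got {level}")
    return TRACE_CRITICAL_VALUES[n_minus_r][level]


@dataclass
class VECMFit:
    """Reduced-rank regression ingredients for a bivariate VECM."""

    lag_diffs: int
    T_eff: int
    S00: np.ndarray
    S01: np.ndarray
    S11: np.ndarray
    eigenvalues: np.ndarray  # descending, in [0, 1)
    eigenvectors: np.ndarray  # columns are beta candidates, normalized b'S11b = I
    gamma: np.ndarray  # short-run coefficients, shape (2, 2*lag_diffs)
    residuals_d: np.ndarray  # dy_t partialled on lagged differences
    residuals_l: np.ndarray  # y_{t-1} partialled on lagged differences

    @property
    def beta_raw(self) -> np.ndarray:
        return self.eigenvectors

    def alpha(self, rank: int) -> np.ndarray:
        """Loading matrix for the first ``rank`` cointegrating vectors."""
        b = self.eigenvectors[:, :rank]
        # eigenvectors satisfy b' S11 b = I, so alpha = S01 b
        return self.S01 @ b

    def beta0_hat(self) -> float:
        """Second component of the leading vector normalized to (1, beta0)'.

        Recorded for every replication regardless of the rank decision;
        raises when the first component is numerically zero.
        """
        v = self.eigenvectors[:, 0]
        if abs(v[0]) < NORMALIZE_TOL:
            raise DegenerateInputError("leading eigenvector has ~0 first component")
        return float(v[1] / v[0])


@dataclass
class JohansenResult:
    """Sequential trace-test outcome."""

    trace_stats: np.ndarray  # statistics for H0 r = 0 and H0 r <= 1
    crit_values: dict  # {n_minus_r: {level: cv}}
    level: float
    rank: int
    beta0_hat: float | None
    alpha_hat: np.ndarray
    eigenvalues: np.ndarray

    @property
    def classification(self) -> str:
        return {0: "I1", 1: "CI1", 2: "I0"}[self.rank]

    def to_dict(self) -> dict:
        return {
            "eigenvalues": list(map(float, self.eigenvalues)),
            "trace_stats": {
                "r=0": float(self.trace_stats[0]),
                "r<=1": float(self.trace_stats[1]),
            },
            "crit_values": {
                "r=0": {f"{int(100 * p)}%": critical_value(2, p) for p in LEVELS},
                "r<=1": {f"{int(100 * p)}%": critical_value(1, p) for p in LEVELS},
            },
            "level": self.level,
            "rank": self.rank,
            "classification": self.classification,
            "beta0_hat": self.beta0_hat,
            "alpha_hat": np.asarray(self.alpha_hat).tolist(),
        }


def _as_levels(series) -> np.ndarray:
    if isinstance(series, BivariateSeries):
        if not series.observed.all():
            raise ValueError("series has unobserved points; call drop_missing first")
        return series.to_array()
    y = np.asarray(series, dtype=float)
    if y.ndim != 2 or y.shape[1] != 2:
        raise ValueError(f"expected (T, 2) data, got shape {y.shape}")
    return y


def fit_vecm(series, lag_diffs: int = 1, intercept: bool = True) -> VECMFit:
    """Reduced-rank regression of a bivariate VECM with ``lag_diffs`` lags.

    Regresses dy_t and y_{t-1} each on (dy_{t-1}, ..., dy_{t-lag_diffs}) —
    plus an unrestricted intercept unless ``intercept=False`` — by least
    squares, forms the residual product-moment matrices and solves the
    generalized eigenproblem.  The embedded critical values belong to the
    intercept case; disabling it is for diagnostics only.
    """
    if lag_diffs < 1:
        raise ValueError("lag_diffs must be >= 1")
    y = _as_levels(series)
    T = len(y)
    p = lag_diffs
    T_eff = T - 1 - p
    if T_eff < 20:
        raise ValueError(f"effective sample after lagging is {T_eff} (< 20)")

    dy = np.diff(y, axis=0)  # dy[t] = y[t+1] - y[t]
    Z0 = dy[p:]  # dy_t
    Z1 = y[p:-1]  # y_{t-1} (transitory form: levels at lag 1)
    Z2 = np.hstack([dy[p - j - 1 : T - 2 - j] for j in range(p)])  # lagged diffs
    if intercept:
        Z2 = np.hstack([Z2, np.ones((T_eff, 1))])

    # partial out the short-run dynamics
    coef, *_ = np.linalg.lstsq(Z2, np.hstack([Z0, Z1]), rcond=None)
    resid = np.hstack([Z0, Z1]) - Z2 @ coef
    R0, R1 = resid[:, :2], resid[:, 2:]

    S00 = R0.T @ R0 / T_eff
    S01 = R0.T @ R1 / T_eff
    S11 = R1.T @ R1 / T_eff

    # guard against numerically singular moment matrices
    for name, S in (("S00", S00), ("S11", S11)):
        if np.linalg.cond(S) > 1e12 or np.linalg.det(S) <= 0:
            raise DegenerateInputError(f"{name} is singular; degraded series degenerate")

    A = S01.T @ np.linalg.solve(S00, S01)  # S10 S00^{-1} S01, symmetric PSD
    try:
        eigvals, eigvecs = scipy.linalg.eigh((A + A.T) / 2, S11)
    except scipy.linalg.LinAlgError as exc:  # pragma: no cover
        raise DegenerateInputError(f"generalized eigenproblem failed: {exc}") from exc
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, 1.0 - 1e-15)
    eigvecs = eigvecs[:, order]  # scipy returns b' S11 b = I normalization

    return VECMFit(
        lag_diffs=p,
        T_eff=T_eff,
        S00=S00,
        S01=S01,
        S11=S11,
        eigenvalues=eigvals,
        eigenvectors=eigvecs,
        gamma=coef[: 2 * p, :2].T,  # intercept row excluded
        residuals_d=R0,
        residuals_l=R1,
    )


def trace_stats_from_eigenvalues(eigenvalues: np.ndarray, T_eff: int) -> np.ndarray:
    """Trace statistics [H0: r = 0, H0: r <= 1] from sorted eigenvalues."""
    lam = np.asarray(eigenvalues, dtype=float)
    log1m = np.log(1.0 - lam)
    return np.array([-T_eff * log1m.sum(), -T_eff * log1m[1:].sum()])


def sequential_rank(trace_stats, level: float = 0.01, n: int = 2) -> int:
    """Sequential rank decision from trace statistics.

    Tests H0: r = 0 first; if rejected, H0: r <= 1; the estimated rank is
    the first hypothesis not rejected (n if all are rejected).
    """
    for r, stat in enumerate(trace_stats):
        if stat <= critical_value(n - r, level):
            return r
    return n


def trace_test(fit: VECMFit, level: float = 0.01, T_eff: int | None = None) -> JohansenResult:
    """Sequential trace test on a fitted VECM.

    ``T_eff`` defaults to the fit's usable-row count (never the intended
    series length).
    """
    if level not in LEVELS:
        raise ValueError(f"level must be one of {LEVELS}")
    T_eff = fit.T_eff if T_eff is None else T_eff
    stats = trace_stats_from_eigenvalues(fit.eigenvalues, T_eff)
    rank = sequential_rank(stats, level)
    try:
        beta0 = fit.beta0_hat()
    except DegenerateInputError:
        beta0 = None
    return JohansenResult(
        trace_stats=stats,
        crit_values=TRACE_CRITICAL_VALUES,
        level=level,
        rank=rank,
        beta0_hat=beta0,
        alpha_hat=fit.alpha(max(rank, 1)),
        eigenvalues=fit.eigenvalues,
    )


def johansen_test(series, lag_diffs: int = 1, level: float = 0.01,
                  intercept: bool = True) -> JohansenResult:
    """Convenience wrapper: fit the VECM and run the sequential trace test."""
    return trace_test(fit_vecm(series, lag_diffs=lag_diffs, intercept=intercept),
                      level=level)


class JohansenTraceTest(BaseEstimator):
    """Cointegration-rank estimator with a scikit-learn interface.

    Parameters
    ----------
    lag_diffs : int
        Number of lagged-difference terms (K - 1 for a VAR(K)).  One lag is
        the minimal admissible choice for the VAR(1) generators used here.
    level : float
        Significance level of the sequential trace test (0.10, 0.05, 0.01).

    Attributes
    ----------
    eigenvalues_ : ndarray of shape (2,)
        Squared canonical correlations, descending.
    trace_stats_ : ndarray of shape (2,)
        Statistics for H0 r = 0 and H0 r <= 1.
    rank_ : int
        Estimated cointegration rank in {0, 1, 2}.
    classification_ : str
        "I1", "CI1" or "I0" per the rank.
    beta0_hat_ : float or None
        Second component of the leading eigenvector normalized to
        (1, beta0)'; None when normalization is undefined.
    alpha_ : ndarray
        Adjustment loadings for the leading relation(s).
    """

    def __init__(self, lag_diffs: int = 1, level: float = 0.01, intercept: bool = True):
        self.lag_diffs = lag_diffs
        self.level = level
        self.intercept = intercept

    def fit(self, X, y=None):
        """Run the test on (T, 2) level data (or a BivariateSeries)."""
        fit = fit_vecm(X, lag_diffs=self.lag_diffs, intercept=self.intercept)
        res = trace_test(fit, level=self.level)
        self.vecm_fit_ = fit
        self.result_ = res
        self.eigenvalues_ = res.eigenvalues
        self.trace_stats_ = res.trace_stats
        self.rank_ = res.rank
        self.classification_ = res.classification
        self.beta0_hat_ = res.beta0_hat
        self.alpha_ = res.alpha_hat
        return self

    def predict(self, X=None) -> str:
        """Classification of the fitted system ("I0", "I1" or "CI1")."""
        if not hasattr(self, "result_"):
            raise RuntimeError("call fit first")
        return self.classification_
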