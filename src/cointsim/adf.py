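"""Augmented Dickey-Fuller unit-root test.

Testing equation (most general form, "trend" spec):

    dy_t = c + tau * t + rho * y_{t-1} + sum_j phi_j dy_{t-j} + a_t

H0: rho = 0 (a unit root, i.e. the AR coefficient beta = 1) against
rho < 0 (stationarity).  The studentized statistic of rho does not follow
a t distribution under H0; p-values are obtained by bilinear interpolation
in the classic Dickey-Fuller tau quantile tables (Fuller 1976; the same
finite-sample tables interpolated by R's tseries::adf.test) and clipped to
[0.01, 0.99] as is common practice.

Defaults — spec="trend" and lags = floor((T - 1)^(1/3)) — reproduce the
standard applied diagnostic workflow.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

SPECS = ("none", "drift", "trend")

_TABLE_T = np.array([25, 50, 100, 250, 500, 100000])
_TABLE_P = np.array([0.01, 0.025, 0.05, 0.10, 0.90, 0.95, 0.975, 0.99])

# Finite-sample quantiles of the tau statistic under H0, rows = probs,
# cols = sample sizes (last column = asymptotic).
_DF_TABLES = {
    "none": np.array(
        [
            [-2.66, -2.62, -2.60, -2.58, -2.58, -2.58],
            [-2.26, -2.25, -2.24, -2.23, -2.23, -2.23],
            [-1.95, -1.95, -1.95, -1.95, -1.95, -1.95],
            [-1.60, -1.61, -1.61, -1.62, -1.62, -1.62],
            [0.92, 0.91, 0.90, 0.89, 0.89, 0.89],
            [1.33, 1.31, 1.29, 1.29, 1.28, 1.28],
            [1.70, 1.66, 1.64, 1.63, 1.62, 1.62],
            [2.16, 2.08, 2.03, 2.01, 2.00, 2.00],
        ]
    ),
    "drift": np.array(
        [
            [-3.75, -3.58, -3.51, -3.46, -3.44, -3.43],
            [-3.33, -3.22, -3.17, -3.14, -3.13, -3.12],
            [-3.00, -2.93, -2.89, -2.88, -2.87, -2.86],
            [-2.62, -2.60, -2.58, -2.57, -2.57, -2.57],
            [-0.37, -0.40, -0.42, -0.42, -0.43, -0.44],
            [0.00, -0.03, -0.05, -0.06, -0.07, -0.07],
            [0.34, 0.29, 0.26, 0.24, 0.24, 0.23],
            [0.72, 0.66, 0.63, 0.62, 0.61, 0.60],
        ]
    ),
    "trend": np.array(
        [
            [-4.38, -4.15, -4.04, -3.99, -3.98, -3.96],
            [-3.95, -3.80, -3.73, -3.69, -3.68, -3.66],
            [-3.60, -3.50, -3.45, -3.43, -3.42, -3.41],
            [-3.24, -3.18, -3.15, -3.13, -3.13, -3.12],
            [-1.14, -1.19, -1.22, -1.23, -1.24, -1.25],
            [-0.80, -0.87, -0.90, -0.92, -0.93, -0.94],
            [-0.50, -0.58, -0.62, -0.64, -0.65, -0.66],
            [-0.15, -0.24, -0.28, -0.31, -0.32, -0.33],
        ]
    ),
}


@dataclass
class ADFResult:
    """Outcome of one ADF regression."""

    rho_hat: float
    t_stat: float
    p_value: float
    spec: str
    lags: int
    n_obs: int

    def to_dict(self) -> dict:
        return {
            "rho_hat": self.rho_hat,
            "t_stat": self.t_stat,
            "p_value": self.p_value,
            "spec": self.spec,
            "lags": self.lags,
            "n_obs": self.n_obs,
        }


def default_lags(T: int) -> int:
    """Rule-of-thumb lag order floor((T - 1)^(1/3))."""
    return int(np.floor((T - 1) ** (1 / 3)))


def df_pvalue(t_stat: float, T: int, spec: str) -> float:
    """Interpolated Dickey-Fuller p-value, clipped to [0.01, 0.99]."""
    table = _DF_TABLES[spec]
    # quantile row at this sample size (linear in T, flat beyond the grid)
    quantiles = np.array(
        [np.interp(T, _TABLE_T, table[i]) for i in range(len(_TABLE_P))]
    )
    p = np.interp(t_stat, quantiles, _TABLE_P)
    return float(np.clip(p, 0.01, 0.99))


def adf_test(x, spec: str = "trend", lags: int | None = None) -> ADFResult:
    """ADF regression with ``lags`` lagged differences; one-sided test of rho = 0.

    Parameters
    ----------
    x : array-like, shape (T,)
    spec : {"none", "drift", "trend"}
        Deterministic terms: nothing, intercept, or intercept + linear trend.
    lags : int, optional
        Lagged differences of the dependent variable; defaults to
        floor((T - 1)^(1/3)).
    """
    if spec not in SPECS:
        raise ValueError(f"spec must be one of {SPECS}, got {spec!r}")
    x = np.asarray(x, dtype=float).ravel()
    T = len(x)
    if lags is None:
        lags = default_lags(T)
    if lags < 0:
        raise ValueError("lags must be non-negative")
    if T < lags + 10:
        raise ValueError(f"series too short: length {T} < lags + 10")
    if np.ptp(x) == 0:
        raise ValueError("constant input: ADF regression undefined")

    dx = np.diff(x)
    # rows are t = lags+1 .. T-1 in differenced time
    yvar = dx[lags:]
    cols = [x[lags:-1]]  # y_{t-1}
    for j in range(1, lags + 1):
        cols.append(dx[lags - j : len(dx) - j])
    n = len(yvar)
    if spec in ("drift", "trend"):
        cols.insert(0, np.ones(n))
    if spec == "trend":
        cols.insert(1, np.arange(1, n + 1, dtype=float))
    X = np.column_stack(cols)
    rho_idx = {"none": 0, "drift": 1, "trend": 2}[spec]

    coef, _, rank, _ = np.linalg.lstsq(X, yvar, rcond=None)
    if rank < X.shape[1]:
        raise ValueError("singular ADF design matrix")
    resid = yvar - X @ coef
    dof = n - X.shape[1]
    s2 = resid @ resid / dof
    XtX_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(s2 * XtX_inv[rho_idx, rho_idx])
    rho_hat = coef[rho_idx]
    t_stat = rho_hat / se
    return ADFResult(
        rho_hat=float(rho_hat),
        t_stat=float(t_stat),
        p_value=df_pvalue(float(t_stat), n, spec),
        spec=spec,
        lags=lags,
        n_obs=n,
    )


class ADFTest:
    """Estimator-style wrapper around :func:`adf_test`.

    Fitted attributes: ``rho_hat_``, ``t_stat_``, ``p_value_``, ``result_``.
    """

    def __init__(self, spec: str = "trend", lags: int | None = None):
        self.spec = spec
        self.lags = lags

    def get_params(self, deep: bool = True) -> dict:
        return {"spec": self.spec, "lags": self.lags}

    def set_params(self, **params):
        for k, v in params.items():
            if k not in ("spec", "lags"):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X, y=None):
        res = adf_test(np.asarray(X, dtype=float).ravel(), spec=self.spec, lags=self.lags)
        self.result_ = res
        self.rho_hat_ = res.rho_hat
        self.t_stat_ = res.t_stat
        self.p_value_ = res.p_value
        return self
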