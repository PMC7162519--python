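"""Bivariate data-generating processes: stationary, integrated, cointegrated.

Three system types drive the whole simulation study:

* ``I0`` — two independent stationary AR(1) series, y_t = beta * y_{t-1} + u_t
  with |beta| < 1;
* ``I1`` — two integrated series without a common trend, built with the
  same measurement construction as the cointegrated case but with
  *independent* unit random walks x1_t, x2_t: y1 = b1 * x1 + u1,
  y2 = b2 * x2 + u2 (unequal loadings b1 != b2 give the components unequal
  variances);
* ``CI1`` — a cointegrated pair sharing a single unit-root common trend x_t
  (a random walk): y1 = b1 * x + u1, y2 = b2 * x + u2 with stationary noise
  u1, u2.  The linear combination y1 - (b1/b2) * y2 = u1 - (b1/b2) * u2 is
  stationary, so the cointegrating vector is (1, beta0)' with
  beta0 = -b1/b2.

The I1 and CI1 systems are thus identical apart from whether the trend is
shared: a questionnaire observes a latent trending process through loading
b plus measurement noise either way.  Innovations are i.i.d. standard
normal throughout.  One master seed spawns independent child streams per
replication via :func:`numpy.random.SeedSequence.spawn`, so replications
are independent and individually reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Iterator

import numpy as np

from .series import BivariateSeries

#: burn-in used for stationary AR(1) components; random walks start at 0
#: with no burn-in (they have no stationary distribution to reach).
DEFAULT_BURN_IN = 50

#: default trend loadings for the integrated system (matching the
#: cointegrated system's beta0 = -1 parameterization, but on independent
#: random walks).
DEFAULT_I1_LOADINGS = (1.0, 1.0)

#: default AR coefficients for the stationary system.
DEFAULT_I0_BETAS = (-0.5, -0.2)

KINDS = ("I0", "I1", "CI1")


@dataclass
class DGPSpec:
    """Specification of one bivariate system with known ground truth.

    Parameters
    ----------
    kind : {"I0", "I1", "CI1"}
        System type: stationary, integrated (no common trend), cointegrated.
    T : int
        Intended series length (>= 10).
    params : dict
        Kind-specific parameters.  I0: ``beta1``, ``beta2`` with |beta| < 1.
        I1: ``b1``, ``b2`` != 0 (loadings on two independent random walks).
        CI1: ``b1``, ``b2`` (common-trend loadings, b2 != 0).
    seed : int or numpy.random.SeedSequence
        Seeds the innovation stream.
    burn_in : int
        Initial values discarded from stationary components.
    """

    kind: str
    T: int = 100
    params: dict[str, float] = field(default_factory=dict)
    seed: Any = 0
    burn_in: int = DEFAULT_BURN_IN

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown system kind {self.kind!r}; expected one of {KINDS}")
        if self.T < 10:
            raise ValueError(f"T must be >= 10, got {self.T}")
        if self.burn_in < 0:
            raise ValueError("burn_in must be non-negative")
        defaults = {
            "I0": {"beta1": DEFAULT_I0_BETAS[0], "beta2": DEFAULT_I0_BETAS[1]},
            "I1": {"b1": DEFAULT_I1_LOADINGS[0], "b2": DEFAULT_I1_LOADINGS[1]},
            "CI1": {"b1": 1.0, "b2": 1.0},
        }[self.kind]
        self.params = {**defaults, **self.params}
        if self.kind == "I0":
            for key in ("beta1", "beta2"):
                if abs(self.params[key]) >= 1:
                    raise ValueError(f"I0 requires |{key}| < 1, got {self.params[key]}")
        elif self.kind == "I1":
            for key in ("b1", "b2"):
                if self.params[key] == 0:
                    raise ValueError(f"I1 requires {key} != 0")
        elif self.kind == "CI1":
            if self.params["b2"] == 0:
                raise ValueError("CI1 requires b2 != 0 (beta0 = -b1/b2 must be finite)")


def true_beta0(spec: DGPSpec) -> float:
    """Ground-truth cointegrating parameter of the system.

    ``-b1/b2`` for cointegrated systems; 0 for stationary and integrated
    systems (where no equilibrium relation exists).
    """
    if spec.kind == "CI1":
        return -spec.params["b1"] / spec.params["b2"]
    return 0.0


def _rng(seed: Any) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_ar1(
    beta: float,
    T: int,
    seed: Any,
    burn_in: int = DEFAULT_BURN_IN,
    sigma: float = 1.0,
) -> np.ndarray:
    """Simulate y_t = beta * y_{t-1} + u_t with standard-normal innovations.

    The recursion starts at 0 and the first ``burn_in`` values are
    discarded.  ``beta = 1`` gives a random walk; explosive processes
    (|beta| > 1) are rejected.
    """
    if abs(beta) > 1:
        raise ValueError(f"|beta| > 1 (explosive process) not supported, got {beta}")
    if T < 1:
        raise ValueError("T must be positive")
    rng = _rng(seed)
    u = sigma * rng.standard_normal(T + burn_in)
    if beta == 1.0:
        y = np.cumsum(u)
    elif beta == 0.0:
        y = u
    else:
        # scipy.signal.lfilter would also do; the explicit loop keeps the
        # initial-state convention (y_0 driven from state 0) unambiguous.
        y = np.empty(T + burn_in)
        prev = 0.0
        for t in range(T + burn_in):
            prev = beta * prev + u[t]
            y[t] = prev
    return y[burn_in:]


def simulate_system(spec: DGPSpec, return_innovations: bool = False):
    """Generate one bivariate system according to ``spec``.

    Deterministic given the spec (including its seed).  With
    ``return_innovations=True`` also returns the stationary noise pair
    (u1, u2) for CI1 systems, which makes the cointegration identity
    y1 - (b1/b2) y2 == u1 - (b1/b2) u2 testable to machine precision.
    """
    rng = _rng(spec.seed)
    p = spec.params
    innovations = None
    if spec.kind == "I0":
        y1 = simulate_ar1(p["beta1"], spec.T, rng, burn_in=spec.burn_in)
        y2 = simulate_ar1(p["beta2"], spec.T, rng, burn_in=spec.burn_in)
    elif spec.kind == "I1":
        x1 = np.cumsum(rng.standard_normal(spec.T))
        x2 = np.cumsum(rng.standard_normal(spec.T))
        u1 = rng.standard_normal(spec.T)
        u2 = rng.standard_normal(spec.T)
        y1 = p["b1"] * x1 + u1
        y2 = p["b2"] * x2 + u2
        innovations = (u1, u2)
    else:  # CI1
        x = np.cumsum(rng.standard_normal(spec.T))
        u1 = rng.standard_normal(spec.T)
        u2 = rng.standard_normal(spec.T)
        y1 = p["b1"] * x + u1
        y2 = p["b2"] * x + u2
        innovations = (u1, u2)
    series = BivariateSeries(
        y1,
        y2,
        meta={
            "spec": {"kind": spec.kind, "T": spec.T, "params": dict(p)},
            "true_beta0": true_beta0(spec),
            "transforms": [],
        },
    )
    if return_innovations:
        return series, innovations
    return series


def spawn_specs(
    kind: str,
    n_reps: int,
    master_seed: Any,
    T: int = 100,
    params: dict[str, float] | None = None,
    burn_in: int = DEFAULT_BURN_IN,
) -> Iterator[DGPSpec]:
    """Yield ``n_reps`` independent replication specs from one master seed."""
    ss = (
        master_seed
        if isinstance(master_seed, np.random.SeedSequence)
        else np.random.SeedSequence(master_seed)
    )
    for child in ss.spawn(n_reps):
        yield DGPSpec(kind=kind, T=T, params=dict(params or {}), seed=child, burn_in=burn_in)
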