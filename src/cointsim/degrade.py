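"""Psychometric degradation operators.

Continuous series become questionnaire-like data in three ways, mirroring
how longitudinal psychological measurements actually lose information:

* **scaling** — mapping onto a k-point interval scale (equal-width bins) or
  a k-point ordinal scale (unequally spaced category boundaries, four
  spacing schemes);
* **missingness** — regular (every k-th measurement occasion skipped, e.g.
  weekends) or random omissions; both components of a bivariate system are
  missing at the same occasions, and listwise deletion then destroys
  equidistance;
* **bounding** — ceiling/floor effects, modelled by collapsing marginal
  categories of a 10-point scale until a target fraction of observations
  piles up at the boundary.

All scale maps are monotone: they never invert the order of two values.
Bins are anchored on the realized range of the data, the way a
questionnaire spans the observed phenomenon (random walks have unbounded
support, so no fixed theoretical range could cover them).  When a
bivariate system is degraded as a whole, both components share one
instrument: the cut points are anchored on the pooled range of the two
series (pass ``anchor`` explicitly to override).

The classes follow the scikit-learn transformer protocol on (T, 2) arrays;
the module-level functions are the one-shot equivalents used throughout the
Monte Carlo pipeline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Any

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .series import BivariateSeries

ORDINAL_SCHEMES = (
    "random",
    "increasing_from_median",
    "decreasing_from_median",
    "monotone_increasing",
)

#: total spacing inequality of the deterministic ordinal schemes, held
#: fixed across scale sizes so that adding points refines resolution
#: without changing the instrument's overall nonlinearity:
#: extreme-to-middle width ratio for the from-median schemes, end-to-end
#: width ratio for the monotone scheme.  Concrete instantiations of the
#: four qualitative unequal-spacing designs; the constants are package
#: defaults exposed here for overriding.
MEDIAN_SCHEME_TOTAL_RATIO = 8.0
MONOTONE_TOTAL_RATIO = 12.0
RANDOM_SPACING_LOW, RANDOM_SPACING_HIGH = 0.5, 1.5


@dataclass
class ScaleSpec:
    """A k-point interval or ordinal scale."""

    kind: str  # "interval" or "ordinal"
    points: int
    ordinal_scheme: str | None = None
    seed: Any = 0  # used only by the random ordinal scheme

    def __post_init__(self) -> None:
        if self.kind not in ("interval", "ordinal"):
            raise ValueError(f"scale kind must be 'interval' or 'ordinal', got {self.kind!r}")
        if not 3 <= self.points <= 10:
            raise ValueError(f"points must be in [3, 10], got {self.points}")
        if self.kind == "ordinal":
            if self.ordinal_scheme not in ORDINAL_SCHEMES:
                raise ValueError(
                    f"ordinal_scheme must be one of {ORDINAL_SCHEMES}, got {self.ordinal_scheme!r}"
                )
        elif self.ordinal_scheme is not None:
            raise ValueError("ordinal_scheme is only valid for ordinal scales")


@dataclass
class MissingSpec:
    """Regular (every k-th occasion) or random missingness."""

    mode: str  # "regular" or "random"
    every_k: int | None = None
    pct: float | None = None
    seed: Any = 0

    def __post_init__(self) -> None:
        if self.mode == "regular":
            if self.every_k is None or self.pct is not None:
                raise ValueError("regular mode requires every_k (and no pct)")
            if self.every_k < 2:
                raise ValueError("every_k must be >= 2")
        elif self.mode == "random":
            if self.pct is None or self.every_k is not None:
                raise ValueError("random mode requires pct (and no every_k)")
            if not 0 < self.pct < 0.5:
                raise ValueError("pct must be in (0, 0.5)")
        else:
            raise ValueError(f"mode must be 'regular' or 'random', got {self.mode!r}")


@dataclass
class BoundSpec:
    """Ceiling/floor effect: collapse marginal categories of a 10-point scale."""

    side: str  # "above", "below" or "both"
    merged_fraction: float

    def __post_init__(self) -> None:
        if self.side not in ("above", "below", "both"):
            raise ValueError(f"side must be 'above', 'below' or 'both', got {self.side!r}")
        if not 0 < self.merged_fraction <= 0.6:
            raise ValueError("merged_fraction must be in (0, 0.6]")


# ---------------------------------------------------------------------------
# scale maps


def _bin_by_cuts(x: np.ndarray, cuts: np.ndarray) -> np.ndarray:
    """Map values to categories 1..len(cuts)+1 via half-open bins.

    Values below the first cut map to 1, values >= the last cut to the top
    category; the top bin is closed above by construction.
    """
    return np.digitize(x, cuts, right=False) + 1


def _check_scalable(x: np.ndarray, points: int) -> bool:
    """Return False (with a warning) if x is constant and cannot be binned."""
    if np.ptp(x) == 0:
        warnings.warn("constant input: all values map to scale point 1", stacklevel=3)
        return False
    return True


def to_interval_scale(
    x: np.ndarray, points: int, anchor: tuple[float, float] | None = None
) -> np.ndarray:
    """Equal-width k-point interval scale anchored on the realized range.

    Partitions [lo, hi] — the realized range of ``x`` unless ``anchor``
    supplies the instrument's span (e.g. the pooled range of a bivariate
    system) — into ``points`` equal-width half-open bins (the last closed
    above) and returns bin indices 1..points.
    """
    if points < 2:
        raise ValueError("points must be >= 2")
    x = np.asarray(x, dtype=float)
    lo, hi = anchor if anchor is not None else (x.min(), x.max())
    if hi <= lo:
        if not _check_scalable(x, points):
            return np.ones(len(x), dtype=int)
    cuts = np.linspace(lo, hi, points + 1)[1:-1]
    return _bin_by_cuts(x, cuts)


def ordinal_spacings(points: int, scheme: str, rng: np.random.Generator | None = None) -> np.ndarray:
    """Relative widths of the ``points`` ordinal bins under a spacing scheme.

    random
        i.i.d. uniform(0.5, 1.5) widths.
    increasing_from_median / decreasing_from_median
        widths symmetric about the middle, growing / shrinking geometrically
        outward from the median category, with the extreme-to-middle width
        ratio fixed at :data:`MEDIAN_SCHEME_TOTAL_RATIO` whatever the number
        of points.
    monotone_increasing
        widths form a geometric sequence left to right with end-to-end
        ratio :data:`MONOTONE_TOTAL_RATIO`.

    Returned widths are normalized to sum to 1; the caller rescales them to
    the data range.
    """
    if scheme == "random":
        if rng is None:
            raise ValueError("the random scheme needs an rng")
        w = rng.uniform(RANDOM_SPACING_LOW, RANDOM_SPACING_HIGH, size=points)
    elif scheme in ("increasing_from_median", "decreasing_from_median"):
        dist = np.abs(np.arange(points) - (points - 1) / 2)
        d_max = (points - 1) / 2
        sign = 1.0 if scheme == "increasing_from_median" else -1.0
        w = MEDIAN_SCHEME_TOTAL_RATIO ** (sign * dist / d_max)
    elif scheme == "monotone_increasing":
        w = MONOTONE_TOTAL_RATIO ** (np.arange(points) / (points - 1))
    else:
        raise ValueError(f"unknown ordinal scheme {scheme!r}")
    return w / w.sum()


def to_ordinal_scale(
    x: np.ndarray, spec: ScaleSpec, anchor: tuple[float, float] | None = None
) -> np.ndarray:
    """k-point ordinal scale with unequally spaced category boundaries.

    Constructs ``points - 1`` cut points spanning the realized range (or
    the ``anchor`` span) whose consecutive spacings follow
    ``spec.ordinal_scheme``, then assigns each value its category
    1..points.  The mapping is monotone.
    """
    if spec.kind != "ordinal":
        raise ValueError("spec.kind must be 'ordinal'")
    x = np.asarray(x, dtype=float)
    lo, hi = anchor if anchor is not None else (x.min(), x.max())
    if hi <= lo:
        if not _check_scalable(x, spec.points):
            return np.ones(len(x), dtype=int)
    rng = np.random.default_rng(spec.seed) if spec.ordinal_scheme == "random" else None
    widths = ordinal_spacings(spec.points, spec.ordinal_scheme, rng)
    cuts = lo + (hi - lo) * np.cumsum(widths)[:-1]
    return _bin_by_cuts(x, cuts)


def round_to_integers(x: np.ndarray) -> np.ndarray:
    """Discretize by rounding to the nearest whole number.

    Emulates instruments that record only integer values while keeping the
    original numeric range (no k-point compression).
    """
    return np.round(np.asarray(x, dtype=float))


def apply_bounds(x: np.ndarray, spec: BoundSpec) -> np.ndarray:
    """Impose a ceiling and/or floor on a 10-point scale.

    ``merged_fraction`` is the proportion of the scale's 10 points drawn
    into each merge — a property of the instrument, not of any particular
    sample.  A 40% ceiling summarizes the four values 7, 8, 9 and 10 into
    7; a 50% ceiling maps everything at or above 6 to 6; a 30% floor maps
    everything at or below 3 to 3.  ``side='both'`` applies half the
    fraction to each tail.

    The mapping is monotone and data-independent; a trending series that
    lives entirely in the merged zone becomes constant, which is precisely
    the ceiling-effect pathology under study (such replications are counted
    as failures downstream).
    """
    x = np.asarray(x)
    if x.size and (x.min() < 1 or x.max() > 10 or not np.allclose(x, np.round(x))):
        raise ValueError("apply_bounds expects integer values on a 1..10 scale")
    out = x.astype(int).copy()
    frac = spec.merged_fraction / 2 if spec.side == "both" else spec.merged_fraction
    k = int(round(10 * frac))  # scale points participating in each merge
    if k > 1:
        if spec.side in ("above", "both"):
            out = np.minimum(out, 11 - k)
        if spec.side in ("below", "both"):
            out = np.maximum(out, k)
    return out


# ---------------------------------------------------------------------------
# missingness


def inject_missing(series: BivariateSeries, spec: MissingSpec) -> BivariateSeries:
    """Mark time points unobserved in *both* components.

    Regular mode clears every k-th measurement occasion (occasions k, 2k,
    ... counting from 1); random mode clears a simple random sample of
    ``floor(pct * T)`` occasions.  Observed values are left bit-identical.
    A skipped occasion affects both series — the diary was not filled in
    that day.
    """
    T = len(series)
    if spec.mode == "regular":
        idx = np.arange(spec.every_k, T + 1, spec.every_k) - 1
    else:
        n_miss = int(np.floor(spec.pct * T))
        rng = np.random.default_rng(spec.seed)
        idx = rng.choice(T, size=n_miss, replace=False)
    mask = series.observed.copy()
    mask[idx] = False
    if mask.sum() < 20:
        raise ValueError(
            f"only {int(mask.sum())} observations would remain (< 20); refusing to inject"
        )
    out = series.with_transform(
        "inject_missing", mode=spec.mode, every_k=spec.every_k, pct=spec.pct
    )
    out.observed = mask
    return out


def drop_missing(series: BivariateSeries) -> BivariateSeries:
    """Listwise deletion: remove unobserved occasions and close the gaps.

    The result is treated as equidistant by downstream tests — this is
    exactly the equidistance distortion under study, not a bug.
    """
    keep = series.observed
    out = BivariateSeries(
        series.y1[keep],
        series.y2[keep],
        meta=dict(series.meta),
    )
    return out.with_transform("drop_missing", n_dropped=int((~keep).sum()))


# ---------------------------------------------------------------------------
# sklearn-style transformers


class _PairTransformer(TransformerMixin, BaseEstimator):
    """Base for column-wise degradation transforms on (T, 2) arrays."""

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("expected a 2-D array of shape (T, n_series)")
        self.n_features_in_ = X.shape[1]
        return self

    def _transform_column(self, x: np.ndarray, col: int) -> np.ndarray:
        raise NotImplementedError

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("column count changed between fit and transform")
        return np.column_stack(
            [self._transform_column(X[:, j], j) for j in range(X.shape[1])]
        )


class IntervalScaler(_PairTransformer):
    """Map each column onto a k-point equal-width interval scale."""

    def __init__(self, points: int = 10):
        self.points = points

    def _transform_column(self, x, col):
        return to_interval_scale(x, self.points)


class OrdinalScaler(_PairTransformer):
    """Map each column onto a k-point ordinal scale with unequal spacings."""

    def __init__(self, points: int = 7, scheme: str = "random", seed: Any = 0):
        self.points = points
        self.scheme = scheme
        self.seed = seed

    def _transform_column(self, x, col):
        # independent cut-point draws per column under the random scheme
        spec = ScaleSpec(
            kind="ordinal",
            points=self.points,
            ordinal_scheme=self.scheme,
            seed=np.random.SeedSequence([int(self.seed), col])
            if np.isscalar(self.seed)
            else self.seed,
        )
        return to_ordinal_scale(x, spec)


class BoundedScale(_PairTransformer):
    """Ceiling/floor effect on a 10-point scale."""

    def __init__(self, side: str = "above", merged_fraction: float = 0.3):
        self.side = side
        self.merged_fraction = merged_fraction

    def _transform_column(self, x, col):
        return apply_bounds(x, BoundSpec(self.side, self.merged_fraction))


class MissingInjector(_PairTransformer):
    """Replace skipped occasions with NaN in every column (same occasions)."""

    def __init__(self, mode: str = "random", every_k: int | None = None,
                 pct: float | None = None, seed: Any = 0):
        self.mode = mode
        self.every_k = every_k
        self.pct = pct
        self.seed = seed

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        spec = MissingSpec(self.mode, every_k=self.every_k, pct=self.pct, seed=self.seed)
        series = BivariateSeries(X[:, 0], X[:, 1] if X.shape[1] > 1 else X[:, 0])
        masked = inject_missing(series, spec)
        out = X.copy()
        out[~masked.observed] = np.nan
        return out
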