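"""Bivariate time-series container shared by all modules.

A :class:`BivariateSeries` holds two aligned numeric sequences plus an
``observed`` mask.  Positions flagged unobserved are treated as absent by
every consumer; generation always produces a fully observed series and
degradation operators may clear mask entries later.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np


@dataclass
class BivariateSeries:
    """Two aligned series ``y1``, ``y2`` with an observation mask.

    Parameters
    ----------
    y1, y2 : array-like of float, shape (T,)
        The two component series.
    observed : array-like of bool, shape (T,), optional
        True where the time point was actually measured.  Defaults to all
        True.
    meta : dict
        Provenance record: the generating spec and every transform applied,
        appended in order.
    """

    y1: np.ndarray
    y2: np.ndarray
    observed: np.ndarray | None = None
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.y1 = np.asarray(self.y1, dtype=float)
        self.y2 = np.asarray(self.y2, dtype=float)
        if self.y1.ndim != 1 or self.y2.ndim != 1:
            raise ValueError("y1 and y2 must be one-dimensional")
        if self.y1.shape != self.y2.shape:
            raise ValueError(
                f"y1 and y2 must have equal length, got {len(self.y1)} and {len(self.y2)}"
            )
        if self.observed is None:
            self.observed = np.ones(len(self.y1), dtype=bool)
        else:
            self.observed = np.asarray(self.observed, dtype=bool)
            if self.observed.shape != self.y1.shape:
                raise ValueError("observed mask must match series length")

    def __len__(self) -> int:
        return len(self.y1)

    @property
    def n_observed(self) -> int:
        return int(self.observed.sum())

    def to_array(self) -> np.ndarray:
        """Stack into a (T, 2) array (ignores the mask)."""
        return np.column_stack([self.y1, self.y2])

    @classmethod
    def from_array(cls, X: np.ndarray, **meta: Any) -> "BivariateSeries":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError(f"expected a (T, 2) array, got shape {X.shape}")
        return cls(X[:, 0], X[:, 1], meta=dict(meta))

    def copy(self) -> "BivariateSeries":
        return BivariateSeries(
            self.y1.copy(), self.y2.copy(), self.observed.copy(), dict(self.meta)
        )

    def with_transform(self, name: str, **params: Any) -> "BivariateSeries":
        """Return a copy with ``name`` appended to the transform provenance."""
        out = self.copy()
        out.meta.setdefault("transforms", [])
        out.meta["transforms"] = list(out.meta["transforms"]) + [
            {"name": name, **params}
        ]
        return out
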