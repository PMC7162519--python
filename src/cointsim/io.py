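"""Readers/writers and small descriptive utilities.

Series travel as two-column CSV (header ``y1,y2``, empty field = missing
value, period decimal separator).  Files from other tools may use ``;`` or
tab delimiters; the reader sniffs among ``,;\\t``.
"""

from __future__ import annotations

import csv
import io as _io
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .series import BivariateSeries


@dataclass
class EmpiricalDataset:
    """Two observed series read from disk, optionally z-standardized."""

    y1: np.ndarray
    y2: np.ndarray
    standardized: bool
    source: str = ""

    def to_series(self) -> BivariateSeries:
        observed = ~(np.isnan(self.y1) | np.isnan(self.y2))
        return BivariateSeries(self.y1, self.y2, observed,
                               meta={"source": self.source,
                                     "standardized": self.standardized,
                                     "transforms": []})


def _sniff_delimiter(sample: str) -> str:
    try:
        return csv.Sniffer().sniff(sample, delimiters=",;\t").delimiter
    except csv.Error:
        return ","


def read_series_csv(path, standardize: bool = False) -> EmpiricalDataset:
    """Read the first two numeric columns of a delimited text file.

    Header row optional; empty cells become NaN (missing).  With
    ``standardize=True`` each column is z-scored using its observed values
    only.  Files with fewer than 20 rows or non-numeric content are
    rejected.
    """
    path = Path(path)
    sample = path.read_text(encoding="utf-8")
    delim = _sniff_delimiter(sample[:4096])
    first = sample.splitlines()[0] if sample.splitlines() else ""

    def _numeric(tok: str) -> bool:
        try:
            float(tok)
            return True
        except ValueError:
            return tok.strip() == ""

    has_header = not all(_numeric(t) for t in first.split(delim))
    df = pd.read_csv(_io.StringIO(sample), sep=delim,
                     header=0 if has_header else None,
                     float_precision="round_trip")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    # a numeric column: everything parses except genuinely empty cells
    good = [c for c in df.columns
            if numeric[c].notna().sum() > 0
            and (numeric[c].notna() | df[c].isna()
                 | (df[c].astype(str).str.strip() == "")).all()]
    if len(good) < 2:
        raise ValueError(f"{path}: need at least 2 numeric columns, found {len(good)}")
    if len(df) < 20:
        raise ValueError(f"{path}: need at least 20 rows, found {len(df)}")
    y1 = numeric[good[0]].to_numpy(dtype=float)
    y2 = numeric[good[1]].to_numpy(dtype=float)
    if standardize:
        y1, y2 = _zscore(y1), _zscore(y2)
    return EmpiricalDataset(y1, y2, standardized=standardize, source=str(path))


def _zscore(x: np.ndarray) -> np.ndarray:
    obs = ~np.isnan(x)
    mu, sd = x[obs].mean(), x[obs].std(ddof=1)
    if sd == 0:
        raise ValueError("cannot standardize a constant column")
    return (x - mu) / sd


def write_series_csv(series: BivariateSeries, path) -> None:
    """Write ``y1,y2`` CSV; unobserved points become empty fields."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        fh.write("y1,y2\n")
        for v1, v2, obs in zip(series.y1, series.y2, series.observed):
            if obs and not (np.isnan(v1) or np.isnan(v2)):
                fh.write(f"{float(v1)!r},{float(v2)!r}\n")
            else:
                fh.write(",\n")


def acf(x, max_lag: int) -> np.ndarray:
    """Sample autocorrelation function at lags 0..max_lag (lag 0 = 1).

    Uses the standard biased covariance estimator c_k / c_0 with the
    overall sample mean removed.
    """
    x = np.asarray(x, dtype=float).ravel()
    n = len(x)
    if max_lag >= n / 2:
        raise ValueError("max_lag must be < length/2")
    if np.ptp(x) == 0:
        raise ValueError("constant series has undefined autocorrelation")
    xc = x - x.mean()
    c0 = xc @ xc / n
    out = np.empty(max_lag + 1)
    for k in range(max_lag + 1):
        out[k] = (xc[k:] @ xc[: n - k]) / n / c0
    return out
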