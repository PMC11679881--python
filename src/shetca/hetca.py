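"""Heterocovariance association of compound abundance with bioactivity.

For each compound x (a column of the integration matrix) and the bioactivity
vector y (% radical scavenging per fraction) the sample covariance and the
Pearson correlation

    cov(x, y) = sum_i (x_i - mean(x)) (y_i - mean(y)) / (N - 1)
    rho(x, y) = cov(x, y) / (s_x * s_y)

are computed over a set of fractions.  The two engines differ only in that
set:

* ``hetca_full`` uses ALL fractions of the zero-imputed matrix; a compound
  is called ACTIVE when its correlation with the activity is positive.
* ``shetca`` (sparse heterocovariance) first drops fractions below an
  activity threshold (default < 5 % scavenging) and then, per compound,
  uses only the fractions where the compound was actually detected; the
  compound is ACTIVE when correlation AND covariance are both positive.

Zero imputation can flip the verdict for a compound confined to a few
fractions: zeros in the many fractions where other compounds drive the
activity drag the full-matrix correlation negative even when abundance
tracks activity perfectly inside the detection window.  sHetCA is immune
to that artefact by construction.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ACTIVITY_THRESHOLD_PCT = 5.0
MIN_FRACTIONS = 3  # correlation over 2 points is always +/-1


class Classification(enum.Enum):
    ACTIVE = "ACTIVE"
    INACTIVE = "INACTIVE"
    EXCLUDED = "EXCLUDED"


class Method(enum.Enum):
    HETCA_FULL = "HETCA_FULL"
    SHETCA = "SHETCA"


def covariance(x: np.ndarray, y: np.ndarray) -> float:
    """Sample covariance with N-1 denominator."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 observations")
    return float(np.sum((x - x.mean()) * (y - y.mean())) / (n - 1))


def correlation(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation using sample (N-1) standard deviations."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    sx = float(np.std(x, ddof=1))
    sy = float(np.std(y, ddof=1))
    if sx == 0.0 or sy == 0.0:
        raise ZeroDivisionError("correlation undefined for a constant vector")
    return covariance(x, y) / (sx * sy)


@dataclass(frozen=True)
class FractionFilter:
    """Fractions excluded from sHetCA for negligible bioactivity."""

    activity_threshold_pct: float = ACTIVITY_THRESHOLD_PCT
    excluded: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not 0 <= self.activity_threshold_pct <= 100:
            raise ValueError("activity threshold must be in [0, 100]")


def build_fraction_filter(
    activity: pd.Series, threshold_pct: float = ACTIVITY_THRESHOLD_PCT
) -> FractionFilter:
    """Exclude every fraction whose activity is below ``threshold_pct``."""
    _check_activity(activity)
    excluded = frozenset(activity.index[activity < threshold_pct])
    return FractionFilter(activity_threshold_pct=threshold_pct, excluded=excluded)


def _check_activity(activity: pd.Series) -> None:
    vals = np.asarray(activity, dtype=float)
    if np.any(vals < 0) or np.any(vals > 100):
        raise ValueError("activity values must be percentages in [0, 100]")


def _check_alignment(matrix: pd.DataFrame, activity: pd.Series) -> None:
    if list(matrix.index) != list(activity.index):
        raise ValueError("fraction ids of the matrix and activity vector differ")


def _record(compound, method, n_used, cov, corr, classification) -> dict:
    return {
        "compound": compound,
        "method": method.value,
        "n_used": int(n_used),
        "covariance": cov,
        "correlation": corr,
        "classification": classification.value,
    }


def hetca_full(matrix0: pd.DataFrame, activity: pd.Series) -> pd.DataFrame:
    """Heterocovariance over all fractions of the zero-imputed matrix.

    ACTIVE iff correlation > 0 (strict).  Compounds with zero variance
    (e.g. an all-zero column) are EXCLUDED.
    """
    _check_activity(activity)
    _check_alignment(matrix0, activity)
    if matrix0.isna().any().any():
        raise ValueError("hetca_full expects the zero-imputed matrix (no NaN)")
    y = np.asarray(activity, dtype=float)
    records = []
    for compound in matrix0.columns:
        x = matrix0[compound].to_numpy(dtype=float)
        try:
            corr = correlation(x, y)
        except ZeroDivisionError:
            records.append(
                _record(compound, Method.HETCA_FULL, x.size, np.nan, np.nan,
                        Classification.EXCLUDED)
            )
            continue
        cov = covariance(x, y)
        cls = Classification.ACTIVE if corr > 0 else Classification.INACTIVE
        records.append(_record(compound, Method.HETCA_FULL, x.size, cov, corr, cls))
    return pd.DataFrame(records).set_index("compound")


def shetca(
    matrix: pd.DataFrame,
    activity: pd.Series,
    fraction_filter: FractionFilter | None = None,
    min_fractions: int = MIN_FRACTIONS,
) -> pd.DataFrame:
    """Sparse heterocovariance over detected fractions only.

    Low-activity fractions are dropped first, then each compound is
    evaluated on the fractions where its cell is present (not NaN).
    ACTIVE iff correlation > 0 AND covariance > 0, both strict.  Compounds
    with fewer than ``min_fractions`` usable fractions, or with zero
    variance in either vector, are EXCLUDED.
    """
    _check_activity(activity)
    _check_alignment(matrix, activity)
    if fraction_filter is None:
        fraction_filter = FractionFilter(excluded=frozenset())
    retained = [f for f in matrix.index if f not in fraction_filter.excluded]
    sub = matrix.loc[retained]
    y_all = activity.loc[retained].to_numpy(dtype=float)

    records = []
    for compound in matrix.columns:
        col = sub[compound].to_numpy(dtype=float)
        present = ~np.isnan(col)
        n_used = int(present.sum())
        if n_used < min_fractions:
            records.append(
                _record(compound, Method.SHETCA, n_used, np.nan, np.nan,
                        Classification.EXCLUDED)
            )
            continue
        x = col[present]
        y = y_all[present]
        try:
            corr = correlation(x, y)
        except ZeroDivisionError:
            records.append(
                _record(compound, Method.SHETCA, n_used, np.nan, np.nan,
                        Classification.EXCLUDED)
            )
            continue
        cov = covariance(x, y)
        cls = (
            Classification.ACTIVE
            if corr > 0 and cov > 0
            else Classification.INACTIVE
        )
        records.append(_record(compound, Method.SHETCA, n_used, cov, corr, cls))
    return pd.DataFrame(records).set_index("compound")


def hetca_plot_data(records: pd.DataFrame, rf_positions: dict | None = None) -> pd.DataFrame:
    """Covariance-vs-compound table (colour = correlation) mirroring the
    classic heterocovariance visualisation; optional Rf x-axis."""
    out = records[["covariance", "correlation", "classification"]].copy()
    if rf_positions is not None:
        out.insert(0, "rf", [rf_positions.get(c, np.nan) for c in out.index])
    return out
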