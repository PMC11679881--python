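"""Baseline correction, negative-peak rectification and profile binning.

Baselines are cubic splines through automatically chosen anchor points --
a deterministic surrogate for manual spline anchoring.  The profile is
split into windows of 5 % of the Rf range; a robust line through the
window medians absorbs slow drift, and each window contributes an anchor
at its "quiet" points (within three noise scales of the line).  Windows
dominated by a peak of either sign contribute no anchor, so the spline
interpolates across both ordinary bands and negative-going bands.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from shetca.densitometry import Densitogram

WINDOW_FRACTION = 0.05
QUIET_SIGMAS = 3.0
MIN_ANCHORS = 4


@dataclass
class BaselineModel:
    """Cubic-spline (or fallback linear) baseline for one densitogram."""

    anchor_rf: np.ndarray
    anchor_intensity: np.ndarray
    is_linear: bool = False

    def __post_init__(self) -> None:
        self.anchor_rf = np.asarray(self.anchor_rf, dtype=float)
        self.anchor_intensity = np.asarray(self.anchor_intensity, dtype=float)
        if np.any(np.diff(self.anchor_rf) <= 0):
            raise ValueError("anchors must be strictly increasing in rf")
        if self.is_linear:
            self._coef = np.polyfit(self.anchor_rf, self.anchor_intensity, 1)
            self._spline = None
        else:
            if self.anchor_rf.size < MIN_ANCHORS:
                raise ValueError(f"need at least {MIN_ANCHORS} anchors for a spline")
            self._spline = CubicSpline(
                self.anchor_rf, self.anchor_intensity, bc_type="natural"
            )

    def __call__(self, rf: np.ndarray) -> np.ndarray:
        rf = np.asarray(rf, dtype=float)
        if self.is_linear:
            return np.polyval(self._coef, rf)
        # linear continuation outside the anchor range (the end cubic of a
        # natural spline would diverge; clamping would ignore any drift)
        lo, hi = self.anchor_rf[0], self.anchor_rf[-1]
        out = self._spline(np.clip(rf, lo, hi))
        below, above = rf < lo, rf > hi
        if np.any(below):
            out = out + np.where(below, self._spline(lo, 1) * (rf - lo), 0.0)
        if np.any(above):
            out = out + np.where(above, self._spline(hi, 1) * (rf - hi), 0.0)
        return out


def _windows(rf: np.ndarray):
    span = rf[-1] - rf[0]
    width = WINDOW_FRACTION * span
    n_windows = max(int(round(1.0 / WINDOW_FRACTION)), 1)
    for w in range(n_windows):
        lo = rf[0] + w * width
        hi = lo + width if w < n_windows - 1 else rf[-1] + 1e-12
        mask = (rf >= lo) & (rf < hi)
        if mask.any():
            yield np.flatnonzero(mask)


def _robust_line(rf: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Line through the window medians, refitted on the closer half so
    windows dominated by a peak (of either sign) do not tilt it."""
    wrf = np.array([rf[idx].mean() for idx in _windows(rf)])
    wmed = np.array([np.median(y[idx]) for idx in _windows(rf)])
    coef = np.polyfit(wrf, wmed, 1)
    resid = np.abs(wmed - np.polyval(coef, wrf))
    close = resid <= np.median(resid) + 1e-12
    if close.sum() >= 2:
        coef = np.polyfit(wrf[close], wmed[close], 1)
    return coef


def fit_baseline(densitogram: Densitogram) -> BaselineModel:
    """Fit a cubic-spline baseline through automatically chosen anchors.

    Per 5 %-of-range window, the anchor sits at the window's "quiet"
    points: those within three noise scales of a robust linear trend.
    Peaks of either sign (a band the colour of the background produces a
    negative peak) leave no quiet points, so their windows contribute no
    anchor and the spline interpolates across them.  Falls back to a
    linear baseline (``is_linear=True``) when fewer than four anchors
    survive.
    """
    rf, y = densitogram.rf, densitogram.intensity
    if rf.size < 8:
        raise ValueError("need at least 8 points to fit a baseline")
    coef = _robust_line(rf, y)
    detrended = y - np.polyval(coef, rf)
    scale = 1.4826 * np.median(np.abs(detrended))  # MAD noise estimate
    threshold = QUIET_SIGMAS * scale + 1e-12 + 1e-9 * (np.std(y) + 1.0)

    anchor_rf, anchor_y = [], []
    for idx in _windows(rf):
        quiet = idx[np.abs(detrended[idx]) <= threshold]
        if quiet.size < max(idx.size // 5, 2):
            continue
        a_rf = rf[quiet].mean()
        anchor_rf.append(a_rf)
        anchor_y.append(np.polyval(coef, a_rf) + np.median(detrended[quiet]))
    anchor_rf = np.asarray(anchor_rf)
    anchor_y = np.asarray(anchor_y)

    if anchor_rf.size < MIN_ANCHORS:
        if anchor_rf.size < 2:
            anchor_rf = rf[[0, -1]]
            anchor_y = np.polyval(coef, anchor_rf)
        return BaselineModel(anchor_rf, anchor_y, is_linear=True)
    return BaselineModel(anchor_rf, anchor_y)


def subtract_baseline(densitogram: Densitogram, baseline: BaselineModel) -> Densitogram:
    """Pointwise difference signal - baseline; metadata preserved."""
    return densitogram.with_intensity(
        densitogram.intensity - baseline(densitogram.rf)
    )


def correct_baseline(densitogram: Densitogram) -> Densitogram:
    """Convenience: fit and subtract in one step."""
    return subtract_baseline(densitogram, fit_baseline(densitogram))


def rectify_negative_peaks(densitogram: Densitogram) -> Densitogram:
    """Flip negative excursions positive by multiplying them by -1.

    A spot the same colour as the plate background produces a negative
    peak after polarity orientation; once the baseline is corrected the
    inverted peak is a genuine band and is rectified here.  Idempotent.
    """
    return densitogram.with_intensity(np.abs(densitogram.intensity))


def bin_profiles(densitograms: list[Densitogram], bin_width: int = 1) -> pd.DataFrame:
    """Stack corrected profiles into a samples x Rf-bin matrix.

    With ``bin_width=1`` every retained Rf point is its own bin (the
    "blind" method's default); larger widths merge adjacent points by
    mean, dropping a trailing remainder.
    """
    if not densitograms:
        raise ValueError("no densitograms given")
    rf0 = densitograms[0].rf
    for d in densitograms[1:]:
        if d.rf.size != rf0.size or not np.allclose(d.rf, rf0):
            raise ValueError("densitograms are on different rf grids")
    values = np.vstack([d.intensity for d in densitograms])
    rf = rf0
    if bin_width > 1:
        n_bins = values.shape[1] // bin_width
        trimmed = values[:, : n_bins * bin_width]
        values = trimmed.reshape(values.shape[0], n_bins, bin_width).mean(axis=2)
        rf = rf0[: n_bins * bin_width].reshape(n_bins, bin_width).mean(axis=1)
    index = [d.sample_id or f"track{i:02d}" for i, d in enumerate(densitograms)]
    return pd.DataFrame(values, index=index, columns=np.round(rf, 6))
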