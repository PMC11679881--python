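"""Gaussian peak integration, deconvolution and the integration matrix.

Peaks are modelled with the area-parameterised Gaussian

    f(rf) = area / (hwhm * sqrt(pi / ln 2)) * exp(-ln 2 * ((rf - c) / hwhm)^2)

whose integral over the whole axis is exactly ``area`` (hwhm = half-width
at half-maximum).  Overlapping bands are deconvolved by fitting a sum of
such components inside an Rf window.

The fraction x compound integration matrix keeps an explicit distinction
between a measured area (possibly 0.0) and a compound that was simply not
detected in a fraction (NaN).  That distinction is the whole point of the
sparse heterocovariance method and is preserved through CSV round trips.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.signal import find_peaks

from shetca.densitometry import Densitogram

_LN2 = math.log(2.0)
#: f(center) = area / (hwhm * _HEIGHT_FACTOR)
_HEIGHT_FACTOR = math.sqrt(math.pi / _LN2)

MAX_ITER = 500
COST_TOL = 1e-8


def gaussian_a(area: float, center: float, hwhm: float, rf: np.ndarray) -> np.ndarray:
    """Area-parameterised Gaussian evaluated at ``rf``."""
    if np.any(np.asarray(hwhm) <= 0):
        raise ValueError("hwhm must be positive")
    rf = np.asarray(rf, dtype=float)
    height = area / (hwhm * _HEIGHT_FACTOR)
    return height * np.exp(-_LN2 * ((rf - center) / hwhm) ** 2)


@dataclass(frozen=True)
class PeakComponent:
    area: float
    center_rf: float
    hwhm: float

    def __post_init__(self) -> None:
        if self.hwhm <= 0:
            raise ValueError("hwhm must be positive")

    def __call__(self, rf: np.ndarray) -> np.ndarray:
        return gaussian_a(self.area, self.center_rf, self.hwhm, rf)


@dataclass
class PeakFit:
    components: list[PeakComponent]
    window: tuple[float, float]
    residual_rmse: float
    converged: bool
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.components = sorted(self.components, key=lambda c: c.center_rf)

    def predict(self, rf: np.ndarray) -> np.ndarray:
        rf = np.asarray(rf, dtype=float)
        out = np.zeros_like(rf)
        for c in self.components:
            out += c(rf)
        return out


def _initial_guess(
    rf: np.ndarray, y: np.ndarray, k: int, window: tuple[float, float]
) -> np.ndarray:
    """Centres at the k strongest local maxima, trapezoid areas, equal widths."""
    lo, hi = window
    width = hi - lo
    hwhm0 = width / (4 * k)
    peaks_idx, props = find_peaks(y, height=0)
    if peaks_idx.size >= k:
        order = np.argsort(props["peak_heights"])[::-1][:k]
        centers = np.sort(rf[peaks_idx[order]])
    else:  # spread any shortfall evenly over the window
        centers = list(rf[peaks_idx])
        n_missing = k - len(centers)
        centers += list(lo + (np.arange(n_missing) + 0.5) * width / n_missing)
        centers = np.sort(np.asarray(centers))
    total_area = max(float(np.trapezoid(np.clip(y, 0, None), rf)), 1e-12)
    params = []
    for c in centers:
        params.extend([total_area / k, float(c), hwhm0])
    return np.asarray(params)


def fit_peaks(
    densitogram: Densitogram,
    window: tuple[float, float],
    k: int = 1,
    init: np.ndarray | None = None,
) -> PeakFit:
    """Least-squares fit of ``k`` area-parameterised Gaussians in a window.

    Components are constrained to the window (centres inside, widths at
    most the window span, areas nonnegative).  On non-convergence the
    best-so-far parameters are returned with ``converged=False``.
    """
    lo, hi = float(window[0]), float(window[1])
    if hi <= lo:
        raise ValueError("window must be a nonempty rf interval")
    if k < 1:
        raise ValueError("k must be at least 1")
    mask = (densitogram.rf >= lo) & (densitogram.rf <= hi)
    rf, y = densitogram.rf[mask], densitogram.intensity[mask]
    if rf.size < 3 * k:
        raise ValueError(
            f"window holds {rf.size} points, need at least {3 * k} for k={k}"
        )
    x0 = np.asarray(init, dtype=float) if init is not None else _initial_guess(rf, y, k, (lo, hi))
    width = hi - lo
    lower = np.tile([0.0, lo, width * 1e-4], k)
    upper = np.tile([np.inf, hi, width], k)
    x0 = np.clip(x0, lower + 1e-12, np.where(np.isfinite(upper), upper - 1e-12, x0))

    def residuals(p: np.ndarray) -> np.ndarray:
        model = np.zeros_like(rf)
        for j in range(k):
            a, c, h = p[3 * j : 3 * j + 3]
            model += gaussian_a(a, c, h, rf)
        return model - y

    result = least_squares(
        residuals,
        x0,
        bounds=(lower, upper),
        ftol=COST_TOL,
        xtol=1e-12,
        gtol=1e-12,
        max_nfev=MAX_ITER * (3 * k + 1),
    )
    comps = [
        PeakComponent(*result.x[3 * j : 3 * j + 3]) for j in range(k)
    ]
    rmse = float(np.sqrt(np.mean(result.fun**2)))
    return PeakFit(
        components=comps,
        window=(lo, hi),
        residual_rmse=rmse,
        converged=bool(result.status > 0),
        meta={"cost": float(result.cost), "nfev": int(result.nfev)},
    )


def integrate_component(fit: PeakFit, index: int) -> float:
    """The fitted area (AUC) of one component."""
    return fit.components[index].area


def noise_equivalent_area(fit: PeakFit, index: int) -> float:
    """Area of a hypothetical peak with height = residual RMSE and the
    component's width; used by the detection criterion."""
    comp = fit.components[index]
    return fit.residual_rmse * comp.hwhm * _HEIGHT_FACTOR


def is_detected(fit: PeakFit, index: int, snr_factor: float = 3.0) -> bool:
    """A component counts as detected when its area exceeds ``snr_factor``
    times the residual-noise-equivalent area (surrogate for visual
    inspection of the chromatogram)."""
    return integrate_component(fit, index) > snr_factor * noise_equivalent_area(fit, index)


def assemble_integration_matrix(
    assignments: list[tuple[str, str, float | None]],
    fractions: list[str] | None = None,
    compounds: list[str] | None = None,
) -> pd.DataFrame:
    """Build the fraction x compound matrix from per-fraction assignments.

    Each assignment is ``(fraction, compound, area)`` with ``area=None``
    meaning not detected (stored as NaN).  Duplicate (fraction, compound)
    pairs are rejected.
    """
    seen: set[tuple[str, str]] = set()
    for frac, comp, _ in assignments:
        if (frac, comp) in seen:
            raise ValueError(f"duplicate assignment for ({frac}, {comp})")
        seen.add((frac, comp))
    if fractions is None:
        fractions = list(dict.fromkeys(f for f, _, _ in assignments))
    if compounds is None:
        compounds = list(dict.fromkeys(c for _, c, _ in assignments))
    matrix = pd.DataFrame(np.nan, index=list(fractions), columns=list(compounds))
    for frac, comp, area in assignments:
        if area is not None:
            if area < 0:
                raise ValueError(f"negative area for ({frac}, {comp})")
            matrix.loc[frac, comp] = float(area)
    matrix.index.name = "fraction"
    return matrix


def impute_zeros(matrix: pd.DataFrame) -> pd.DataFrame:
    """Zero-imputed twin of the integration matrix (NaN -> 0)."""
    return matrix.fillna(0.0)


# ---------------------------------------------------------------------------
# Profile -> integration-matrix pipeline


def _cluster_windows(windows: list[tuple[str, float, float, float, float]]):
    """Merge compounds whose Rf windows overlap into joint fit clusters.

    ``windows`` holds (compound, lo, hi, center, hwhm) tuples of one
    measurement mode, and overlapping bands must be deconvolved together.
    """
    ordered = sorted(windows, key=lambda w: w[3])
    clusters: list[list[tuple]] = []
    for w in ordered:
        if clusters and w[1] <= clusters[-1][-1][2]:
            clusters[-1].append(w)
        else:
            clusters.append([w])
    return clusters


def integrate_profiles(
    densitograms_by_mode: dict[str, list[Densitogram]],
    windows: dict[str, tuple[str, float, float, float, float]],
    snr_factor: float = 3.0,
    preprocess: bool = True,
) -> pd.DataFrame:
    """Fit every compound's band in every fraction and assemble the matrix.

    ``windows`` maps compound -> (mode, lo, hi, center, hwhm); compounds
    with overlapping windows in the same mode are deconvolved jointly
    (k = cluster size) with centres initialised at the assigned positions.
    Cells fall back to NaN (not detected) when the fitted area fails the
    ``snr_factor`` x noise-equivalent-area criterion.

    With ``preprocess=True`` each profile is baseline-corrected and
    negative peaks are rectified before fitting.
    """
    from shetca.preprocess import correct_baseline, rectify_negative_peaks

    fractions: list[str] = []
    for mode, tracks in densitograms_by_mode.items():
        ids = [d.sample_id for d in tracks]
        if not fractions:
            fractions = ids
        elif ids != fractions:
            raise ValueError(f"fraction ids of mode {mode} disagree with the others")
    compounds = list(windows)
    matrix = pd.DataFrame(np.nan, index=fractions, columns=compounds)
    matrix.index.name = "fraction"

    by_mode: dict[str, list[tuple]] = {}
    for compound, (mode, lo, hi, center, hwhm) in windows.items():
        by_mode.setdefault(mode, []).append((compound, lo, hi, center, hwhm))

    for mode, wins in by_mode.items():
        if mode not in densitograms_by_mode:
            raise KeyError(f"no densitograms for mode {mode}")
        clusters = _cluster_windows(wins)
        for d in densitograms_by_mode[mode]:
            profile = d
            if preprocess:
                profile = rectify_negative_peaks(correct_baseline(profile))
            for cluster in clusters:
                k = len(cluster)
                lo = min(w[1] for w in cluster)
                hi = max(w[2] for w in cluster)
                init = []
                mask = (profile.rf >= lo) & (profile.rf <= hi)
                rf_w, y_w = profile.rf[mask], profile.intensity[mask]
                for _, _, _, center, hwhm in cluster:
                    local = np.abs(rf_w - center) <= 2 * hwhm
                    a0 = float(np.trapezoid(np.clip(y_w[local], 0, None), rf_w[local])) if local.any() else 0.0
                    init.extend([max(a0, 1e-9), center, hwhm])
                fit = fit_peaks(profile, (lo, hi), k=k, init=np.asarray(init))
                # components and cluster entries are both centre-ordered
                for j, (compound, _, _, center, hwhm) in enumerate(
                    sorted(cluster, key=lambda w: w[3])
                ):
                    comp = fit.components[j]
                    # identification: the fitted band must appear at the
                    # compound's Rf with a plausible band width
                    if abs(comp.center_rf - center) > 2.0 * hwhm:
                        continue
                    if comp.hwhm > 2.5 * hwhm:
                        continue
                    # detection: area above snr_factor x the noise-equivalent
                    # area of a band no narrower than the assigned width
                    floor = snr_factor * fit.residual_rmse * max(comp.hwhm, hwhm) * _HEIGHT_FACTOR
                    if comp.area > floor:
                        matrix.loc[profile.sample_id, compound] = comp.area
    return matrix
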