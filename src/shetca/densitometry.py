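"""Plate-photograph densitometry.

An HPTLC plate photographed under UV 254 nm, UV 366 nm or white light is a
height x width x 3 RGB array.  Each applied sample occupies a vertical track;
averaging one colour channel across the track width at every vertical
position yields a densitogram: intensity versus retention factor (Rf).

Conventions fixed here (documented, since image origin is ambiguous):
row index 0 is the TOP of the plate; Rf increases upward, so profiles are
reported bottom -> top.  Point ``i`` of an ``n_points`` profile sits at the
bin centre ``(i + 0.5) / n_points`` of the plate height.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np


class Illumination(enum.Enum):
    UV254 = "UV254"
    UV366 = "UV366"
    WHITE_PRE_DERIV = "WHITE_PRE_DERIV"
    WHITE_POST_DERIV = "WHITE_POST_DERIV"


class Phase(enum.Enum):
    NP = "NP"  # normal phase (silica)
    RP = "RP"  # reversed phase (C18)


class Channel(enum.Enum):
    R = "R"
    G = "G"
    B = "B"
    GRAY = "GRAY"


#: Illumination modes in which spots absorb (dark/coloured on a bright
#: background) as opposed to emitting on a dark background (366 nm).
_ABSORBANCE_MODES = {
    Illumination.UV254,
    Illumination.WHITE_PRE_DERIV,
    Illumination.WHITE_POST_DERIV,
}


@dataclass(frozen=True)
class TrackGeometry:
    """Physical layout of sample tracks on the plate.

    Distances are in mm from the lower plate edge; ``track_center_x_mm``
    lists the horizontal centre of each applied band.  ``plate_height_mm``
    together with ``pixels_per_mm`` fixes the pixel <-> mm mapping.
    """

    track_center_x_mm: Sequence[float]
    application_distance_mm: float = 8.0
    solvent_front_mm: float = 75.0
    band_width_mm: float = 7.0
    edge_trim_mm: float = 1.0
    pixels_per_mm: float = 10.2543
    plate_height_mm: float = 97.52

    def __post_init__(self) -> None:
        if not 0 < self.application_distance_mm < self.solvent_front_mm:
            raise ValueError(
                "application distance must lie strictly between 0 and the "
                f"solvent front ({self.application_distance_mm} vs "
                f"{self.solvent_front_mm})"
            )
        if self.band_width_mm <= 2 * self.edge_trim_mm:
            raise ValueError("band width must exceed twice the edge trim")
        if self.pixels_per_mm <= 0 or self.plate_height_mm <= 0:
            raise ValueError("pixel scale and plate height must be positive")


def default_geometry(n_tracks: int = 17) -> TrackGeometry:
    """Calibrated default: 20 cm plate, 17 tracks, 97.52 mm imaged height.

    With a 1000-point vertical profile, application at 8 mm and front at
    75 mm this retains exactly 687 Rf points after cropping.
    """
    # tracks evenly spaced with 12 mm margins on a 200 mm wide plate
    span = 200.0 - 2 * 12.0
    step = span / max(n_tracks - 1, 1)
    centers = [12.0 + i * step for i in range(n_tracks)]
    return TrackGeometry(track_center_x_mm=centers)


@dataclass
class Densitogram:
    """Intensity versus retention factor for one track."""

    rf: np.ndarray
    intensity: np.ndarray
    sample_id: str = ""
    channel_used: Channel | None = None
    illumination: Illumination | None = None
    phase: Phase | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.rf = np.asarray(self.rf, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.rf.shape != self.intensity.shape:
            raise ValueError("rf and intensity must have the same length")
        if self.rf.ndim != 1:
            raise ValueError("rf must be one-dimensional")
        if np.any(np.diff(self.rf) <= 0):
            raise ValueError("rf must be strictly increasing")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("intensities must be finite")

    @property
    def n_points(self) -> int:
        return self.rf.size

    def with_intensity(self, intensity: np.ndarray) -> "Densitogram":
        return replace(self, intensity=np.asarray(intensity, dtype=float))


def select_channel(illumination: Illumination, phase: Phase) -> Channel:
    """Channel rule used to extract densitograms from plate photographs.

    254 nm plates fluoresce green in normal phase (the green channel tracks
    absorbing spots best) and appear blue in reversed phase; at 366 nm most
    spots emit blue; white-light images before/after derivatization are read
    in grayscale because spot colours vary.
    """
    illumination = Illumination(illumination)
    phase = Phase(phase)
    if illumination is Illumination.UV254:
        return Channel.G if phase is Phase.NP else Channel.B
    if illumination is Illumination.UV366:
        return Channel.B
    return Channel.GRAY


def _channel_plane(pixels: np.ndarray, channel: Channel) -> np.ndarray:
    if channel is Channel.GRAY:
        return pixels.mean(axis=2)
    idx = {Channel.R: 0, Channel.G: 1, Channel.B: 2}[channel]
    return pixels[:, :, idx].astype(float)


def _as_8bit(pixels: np.ndarray) -> np.ndarray:
    pixels = np.asarray(pixels)
    if pixels.ndim != 3 or pixels.shape[2] != 3:
        raise ValueError("plate image must be height x width x 3")
    if pixels.dtype == np.uint16:
        return pixels.astype(float) * (255.0 / 65535.0)
    return pixels.astype(float)


def image_to_profile(
    pixels: np.ndarray,
    geometry: TrackGeometry,
    track_index: int,
    channel: Channel,
    n_points: int = 1000,
) -> np.ndarray:
    """Average ``channel`` across one track's trimmed width, bottom -> top.

    Returns an ``n_points`` profile; point ``i`` is the channel mean over
    the trimmed band at plate height ``(i + 0.5) / n_points`` (linear
    interpolation between pixel-row centres).
    """
    pixels = _as_8bit(pixels)
    height, width = pixels.shape[:2]
    center_px = geometry.track_center_x_mm[track_index] * geometry.pixels_per_mm
    half_px = (geometry.band_width_mm / 2 - geometry.edge_trim_mm) * geometry.pixels_per_mm
    lo = int(np.ceil(center_px - half_px))
    hi = int(np.floor(center_px + half_px))
    if lo < 0 or hi > width:
        raise ValueError(
            f"track {track_index} spans columns [{lo}, {hi}) outside the "
            f"image width {width}"
        )
    if hi <= lo:
        raise ValueError("trimmed band width is zero pixels")
    plane = _channel_plane(pixels, Channel(channel))
    rows = plane[:, lo:hi].mean(axis=1)  # top -> bottom
    rows_bottom_up = rows[::-1]
    # pixel-row bin centres and profile bin centres, both on [0, 1]
    src = (np.arange(height) + 0.5) / height
    dst = (np.arange(n_points) + 0.5) / n_points
    return np.interp(dst, src, rows_bottom_up)


def orient_polarity(profile: np.ndarray, illumination: Illumination) -> np.ndarray:
    """Orient a raw profile so chromatographic peaks point up.

    Under 254 nm and white light the background is bright and spots absorb,
    so peaks are dips: return ``background - profile``.  At 366 nm the
    background is dark and spots emit: return ``profile - background``.
    The background level is estimated as the per-track median, which is
    robust to a handful of bands.
    """
    profile = np.asarray(profile, dtype=float)
    if not np.all(np.isfinite(profile)):
        raise ValueError("profile must be finite")
    background = float(np.median(profile))
    if Illumination(illumination) in _ABSORBANCE_MODES:
        return background - profile
    return profile - background


def crop_to_rf(
    profile: np.ndarray,
    geometry: TrackGeometry,
    sample_id: str = "",
    channel: Channel | None = None,
    illumination: Illumination | None = None,
    phase: Phase | None = None,
) -> Densitogram:
    """Crop a full-height profile to the chromatographically meaningful span.

    Points below the application line (Rf = 0) or above the solvent front
    (Rf = 1) are discarded; the retained points get a linear Rf axis.  With
    the calibrated default geometry a 1000-point profile retains 687 points.
    """
    profile = np.asarray(profile, dtype=float)
    n = profile.size
    heights = (np.arange(n) + 0.5) / n * geometry.plate_height_mm
    app, front = geometry.application_distance_mm, geometry.solvent_front_mm
    if front <= app:
        raise ValueError("solvent front must exceed the application distance")
    if heights[0] > app or heights[-1] < front:
        raise ValueError("application line or solvent front falls outside the profile")
    keep = (heights >= app) & (heights <= front)
    kept = profile[keep]
    rf = (heights[keep] - app) / (front - app)
    # normalise the retained axis to exactly [0, 1]
    rf = (rf - rf[0]) / (rf[-1] - rf[0])
    return Densitogram(
        rf=rf,
        intensity=kept,
        sample_id=sample_id,
        channel_used=channel,
        illumination=illumination,
        phase=phase,
    )
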