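"""Seeded synthetic fractionation studies.

Emulates a centrifugal-partition-chromatography run of an artificial
mixture: each compound elutes as a Gaussian bump over the ordered fraction
series, per-fraction radical-scavenging activity follows a saturating
cumulative dose model, and each fraction's HPTLC densitograms (and
optionally rendered plate photographs) are synthesised from the compound
concentrations via the same area-parameterised Gaussian band model the
peak-analysis stage fits.

The default study plants the failure modes that make bioactivity
association hard in practice:

* an inactive "shadow" compound eluting in lockstep with an active one
  (false-positive mechanism; profile correlation >= 0.95);
* a low-abundance active eluting in the dip between two dominant actives,
  so the activity it does contribute is overshadowed (false-negative
  mechanism);
* an inactive spread thinly over many fractions;
* a low-activity leading region containing only inactive compounds, which
  the sparse-heterocovariance activity filter removes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from shetca.densitometry import (
    Channel,
    Densitogram,
    Illumination,
    Phase,
    TrackGeometry,
    default_geometry,
    select_channel,
)
from shetca.peaks import gaussian_a

#: measurement modes available to the simulator, as "PHASE:ILLUMINATION"
MODES = ("NP:UV254", "NP:UV366", "RP:UV254", "RP:WHITE_POST_DERIV")


def parse_mode(mode: str) -> tuple[Phase, Illumination]:
    phase, illum = mode.split(":")
    return Phase(phase), Illumination(illum)


@dataclass(frozen=True)
class CompoundSpec:
    """One compound of the artificial mixture."""

    id: str
    elution_center: float          # fractional index into the fraction series
    elution_spread: float          # Gaussian sigma, in fractions
    total_amount: float            # arbitrary units, conserved over fractions
    rf_position: float             # band position on the plate, in [0, 1]
    band_hwhm_rf: float            # chromatographic band half-width
    mode: str                      # measurement mode used for integration
    response_factor: float         # signal per unit concentration (may be < 0:
                                   # a band coloured like the background)
    is_active: bool
    potency: float                 # 0 iff inactive

    def __post_init__(self) -> None:
        if self.elution_spread <= 0:
            raise ValueError("elution spread must be positive")
        if self.potency < 0:
            raise ValueError("potency must be nonnegative")
        if self.is_active != (self.potency > 0):
            raise ValueError("potency must be 0 iff inactive")


@dataclass(frozen=True)
class SimulationConfig:
    n_fractions: int = 69
    first_fraction: int = 2        # ids Fr02 .. Fr70
    noise_sd: float = 0.05         # multiplicative log-normal abundance noise
    densitogram_noise_sd: float = 0.3
    baseline_amplitude: float = 5.0
    n_rf_points: int = 687
    tracks_per_plate: int = 17
    detection_limit_fraction: float = 0.01  # of the study's largest concentration
    activity_target_median: float = 0.75    # median activity of dosed fractions
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_fractions < 3:
            raise ValueError("need at least 3 fractions")

    def fraction_ids(self) -> list[str]:
        return [f"Fr{self.first_fraction + i:02d}" for i in range(self.n_fractions)]


def simulate_elution(
    specs: list[CompoundSpec],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Fraction x compound concentration matrix.

    Each compound's total amount is distributed over fractions following a
    normalised Gaussian on the fraction index, then perturbed by
    multiplicative log-normal noise (sd from config; exact conservation at
    zero noise).
    """
    idx = np.arange(config.n_fractions, dtype=float)
    cols = {}
    for spec in specs:
        shape = np.exp(-0.5 * ((idx - spec.elution_center) / spec.elution_spread) ** 2)
        profile = spec.total_amount * shape / shape.sum()
        if config.noise_sd > 0:
            sigma = np.sqrt(np.log(1 + config.noise_sd**2))
            noise = rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=idx.size)
            profile = profile * noise
        cols[spec.id] = profile
    out = pd.DataFrame(cols, index=config.fraction_ids())
    out.index.name = "fraction"
    return out


def simulate_activity(
    concentrations: pd.DataFrame,
    specs: list[CompoundSpec],
    scale: float,
) -> pd.Series:
    """% scavenging per fraction: 100 * (1 - exp(-scale * total potency dose)).

    The saturating cumulative model reproduces the masking phenomena seen
    in pooled-activity assays: a dominant active flattens the contribution
    of co-eluting minor actives.
    """
    potency = np.array([s.potency for s in specs])
    if np.any(potency < 0):
        raise ValueError("potencies must be nonnegative")
    order = [s.id for s in specs]
    dose = concentrations[order].to_numpy() @ potency
    activity = 100.0 * (1.0 - np.exp(-scale * dose))
    return pd.Series(activity, index=concentrations.index, name="activity")


def calibrate_activity_scale(
    concentrations: pd.DataFrame,
    specs: list[CompoundSpec],
    target_median: float = 0.75,
) -> float:
    """Scale such that the median dosed fraction reaches ``target_median``
    fractional activity (deterministic calibration, part of the design)."""
    potency = np.array([s.potency for s in specs])
    dose = concentrations[[s.id for s in specs]].to_numpy() @ potency
    dosed = dose[dose > 1e-6 * max(dose.max(), 1e-300)]
    if dosed.size == 0:
        return 1.0
    return float(-np.log(1.0 - target_median) / np.median(dosed))


def detection_mask(concentrations: pd.DataFrame, config: SimulationConfig) -> pd.DataFrame:
    """True where a compound is detectable (concentration >= limit)."""
    limit = config.detection_limit_fraction * concentrations.to_numpy().max()
    return concentrations >= limit


def masked_matrix(concentrations: pd.DataFrame, config: SimulationConfig) -> pd.DataFrame:
    """Concentration matrix with sub-detection cells set to NaN (MISSING)."""
    return concentrations.where(detection_mask(concentrations, config))


def render_densitograms(
    concentrations: pd.DataFrame,
    specs: list[CompoundSpec],
    mode: str,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> list[Densitogram]:
    """Per-fraction densitograms for one (phase, illumination) mode.

    Each compound assigned to the mode contributes an area-parameterised
    Gaussian band with area = response_factor x concentration; a slow
    sinusoidal baseline drift and additive Gaussian noise are superposed.
    """
    phase, illumination = parse_mode(mode)
    rf = np.linspace(0.0, 1.0, config.n_rf_points)
    in_mode = [s for s in specs if s.mode == mode]
    out = []
    for fraction in concentrations.index:
        signal = np.zeros_like(rf)
        for spec in in_mode:
            conc = float(concentrations.loc[fraction, spec.id])
            area = spec.response_factor * conc
            if area != 0.0:
                signal += gaussian_a(area, spec.rf_position, spec.band_hwhm_rf, rf)
        if config.baseline_amplitude > 0:
            phase_shift = rng.uniform(0, 2 * np.pi)
            signal += config.baseline_amplitude * (
                0.5 + 0.5 * np.sin(2 * np.pi * 1.5 * rf + phase_shift)
            )
        if config.densitogram_noise_sd > 0:
            signal += rng.normal(0, config.densitogram_noise_sd, rf.size)
        out.append(
            Densitogram(
                rf=rf.copy(),
                intensity=signal,
                sample_id=str(fraction),
                channel_used=select_channel(illumination, phase),
                illumination=illumination,
                phase=phase,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Plate-image rendering (inverse of the densitometry stage)

_BACKGROUNDS = {
    Illumination.UV254: {Phase.NP: (70, 190, 110), Phase.RP: (70, 110, 200)},
    Illumination.UV366: {Phase.NP: (15, 15, 35), Phase.RP: (15, 15, 35)},
    Illumination.WHITE_PRE_DERIV: {Phase.NP: (235, 235, 230), Phase.RP: (235, 235, 230)},
    Illumination.WHITE_POST_DERIV: {Phase.NP: (230, 228, 220), Phase.RP: (230, 228, 220)},
}
#: how strongly the non-selected channels respond relative to the selected one
_OFF_CHANNEL_FACTOR = 0.35


def render_plate_image(
    densitograms: list[Densitogram],
    geometry: TrackGeometry | None = None,
    illumination: Illumination = Illumination.UV254,
    phase: Phase = Phase.NP,
    tracks_per_plate: int = 17,
    sensor_noise: float = 0.5,
    seed: int = 0,
) -> np.ndarray:
    """Synthesise an RGB plate photograph from per-track densitograms.

    Bands attenuate the background under 254 nm / white light and emit on
    the dark background at 366 nm; a densitogram with negative intensity
    renders a band *brighter* than the 254 nm background (a spot coloured
    like the plate), reproducing the negative-peak failure mode.

    ``sensor_noise`` (8-bit units, per pixel) emulates camera shot noise;
    besides realism it dithers the quantisation, so averaging across a
    track's width recovers intensity differences finer than one grey
    level.  Deterministic for a fixed ``seed``.
    """
    if geometry is None:
        geometry = default_geometry(tracks_per_plate)
    if len(densitograms) > len(geometry.track_center_x_mm):
        raise ValueError(
            f"{len(densitograms)} tracks exceed the plate capacity "
            f"{len(geometry.track_center_x_mm)}"
        )
    height = int(round(geometry.plate_height_mm * geometry.pixels_per_mm))
    width = int(round(200.0 * geometry.pixels_per_mm))
    bg = np.array(_BACKGROUNDS[Illumination(illumination)][Phase(phase)], dtype=float)
    image = np.tile(bg, (height, width, 1))

    selected = select_channel(illumination, phase)
    if selected is Channel.GRAY:
        weights = np.array([1.0, 1.0, 1.0])
    else:
        weights = np.full(3, _OFF_CHANNEL_FACTOR)
        weights[{Channel.R: 0, Channel.G: 1, Channel.B: 2}[selected]] = 1.0

    peak = max(float(np.abs(d.intensity).max()) for d in densitograms) or 1.0
    gain = 170.0 / peak
    emissive = Illumination(illumination) is Illumination.UV366

    rows = np.arange(height)
    heights_mm = (height - rows - 0.5) / geometry.pixels_per_mm
    rf_rows = (heights_mm - geometry.application_distance_mm) / (
        geometry.solvent_front_mm - geometry.application_distance_mm
    )
    visible = (rf_rows >= 0.0) & (rf_rows <= 1.0)

    for track, d in enumerate(densitograms):
        center_px = geometry.track_center_x_mm[track] * geometry.pixels_per_mm
        half_px = geometry.band_width_mm / 2 * geometry.pixels_per_mm
        lo = max(int(np.ceil(center_px - half_px)), 0)
        hi = min(int(np.floor(center_px + half_px)), width)
        band = np.zeros(height)
        band[visible] = np.interp(rf_rows[visible], d.rf, d.intensity)
        delta = gain * band[:, None] * weights[None, :]
        if emissive:
            image[:, lo:hi, :] += delta[:, None, :]
        else:
            image[:, lo:hi, :] -= delta[:, None, :]
    if sensor_noise > 0:
        rng = np.random.default_rng(seed)
        image += rng.normal(0.0, sensor_noise, size=image.shape)
    return np.clip(np.round(image), 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# The default study


@dataclass
class SyntheticStudy:
    config: SimulationConfig
    specs: list[CompoundSpec]
    concentrations: pd.DataFrame
    matrix: pd.DataFrame            # NaN where below the detection limit
    matrix0: pd.DataFrame           # zero-imputed twin
    activity: pd.Series
    activity_scale: float
    ground_truth: pd.DataFrame
    densitograms: dict[str, list[Densitogram]] = field(default_factory=dict)
    #: planted-scenario compound ids
    planted: dict[str, str] = field(default_factory=dict)

    @property
    def windows(self) -> dict[str, tuple[str, float, float, float, float]]:
        """compound -> (mode, window_lo, window_hi, center, hwhm)."""
        out = {}
        for s in self.specs:
            half = 2.5 * s.band_hwhm_rf
            out[s.id] = (
                s.mode,
                max(s.rf_position - half, 0.0),
                min(s.rf_position + half, 1.0),
                s.rf_position,
                s.band_hwhm_rf,
            )
        return out


def _default_specs(rng: np.random.Generator) -> tuple[list[CompoundSpec], dict[str, str]]:
    """43 compounds (14 active) with the planted scenarios."""
    specs: list[CompoundSpec] = []
    planted: dict[str, str] = {}

    # 13 regular actives marching across the series at 4-fraction spacing
    # (each dominates its own detection window), then the masked one.
    active_centers = [19.0 + 4.0 * k for k in range(13)]   # 19 .. 67
    active_amounts = [8.0, 12.0, 7.0, 10.0, 6.0, 11.0, 9.0, 7.5, 12.0, 8.5, 10.5, 6.5, 9.5]
    entries: list[dict] = []
    for k, (c, amt) in enumerate(zip(active_centers, active_amounts)):
        entries.append(dict(center=c, spread=0.8, amount=amt, active=True, potency=1.0))
    # masked low-abundance active in the dip between the actives at 47 and 51
    entries.append(dict(center=49.0, spread=0.9, amount=0.8, active=True, potency=0.8))
    planted["masked_active"] = f"C{len(entries):02d}"

    # inactive shadow co-eluting with the active at 23
    entries.append(dict(center=23.0, spread=0.8, amount=5.0, active=False, potency=0.0))
    planted["shadow_inactive"] = f"C{len(entries):02d}"
    planted["shadow_partner"] = "C02"

    # inactive spread thinly over many fractions
    entries.append(dict(center=40.0, spread=10.0, amount=2.0, active=False, potency=0.0))
    planted["thin_inactive"] = f"C{len(entries):02d}"

    # 8 head inactives in the low-activity leading fractions
    for c in [2.0, 4.0, 6.0, 8.0, 10.0, 12.0, 14.0, 16.0]:
        entries.append(dict(center=c, spread=1.0, amount=4.0 + 0.5 * (c % 3), active=False, potency=0.0))

    # 19 mid inactives in the activity valleys between consecutive actives
    # (some valleys hold two co-eluting inactives at different Rf)
    mid_centers = [21.0 + 4.0 * k for k in range(12)]      # 21 .. 65
    mid_centers += [21.0, 29.0, 37.0, 45.0, 53.0, 61.0, 65.0]
    for c in mid_centers:
        entries.append(dict(center=c, spread=1.0, amount=2.5 + (c % 2.0), active=False, potency=0.0))

    # assign measurement modes and rf positions: cycle modes, evenly spaced
    # rf slots within each mode, small seeded jitter
    per_mode_counter = {m: 0 for m in MODES}
    for i, e in enumerate(entries):
        cid = f"C{i + 1:02d}"
        mode = MODES[i % len(MODES)]
        slot = per_mode_counter[mode]
        per_mode_counter[mode] += 1
        rf_pos = 0.08 + 0.075 * slot + rng.uniform(-0.004, 0.004)
        response = float(rng.uniform(0.6, 1.8))
        specs.append(
            CompoundSpec(
                id=cid,
                elution_center=e["center"],
                elution_spread=e["spread"],
                total_amount=e["amount"],
                rf_position=min(rf_pos, 0.95),
                band_hwhm_rf=0.01,
                mode=mode,
                response_factor=response,
                is_active=e["active"],
                potency=e["potency"],
            )
        )

    # planted chromatographic scenarios: one deliberately overlapping band
    # pair for the deconvolution path, and one background-coloured band
    i_pair = specs.index(next(s for s in specs if s.id == planted["thin_inactive"]))
    partner = specs[2]  # C03: same-mode neighbour exists by construction
    specs[i_pair] = CompoundSpec(
        **{
            **_spec_dict(specs[i_pair]),
            "mode": partner.mode,
            "rf_position": partner.rf_position + 0.012,
        }
    )
    planted["overlap_pair"] = f"{partner.id}+{specs[i_pair].id}"

    i_neg = specs.index(next(s for s in specs if not s.is_active and s.elution_center == 53.0))
    specs[i_neg] = CompoundSpec(
        **{**_spec_dict(specs[i_neg]), "response_factor": -abs(specs[i_neg].response_factor)}
    )
    planted["background_coloured"] = specs[i_neg].id
    return specs, planted


def _spec_dict(s: CompoundSpec) -> dict:
    return {
        "id": s.id,
        "elution_center": s.elution_center,
        "elution_spread": s.elution_spread,
        "total_amount": s.total_amount,
        "rf_position": s.rf_position,
        "band_hwhm_rf": s.band_hwhm_rf,
        "mode": s.mode,
        "response_factor": s.response_factor,
        "is_active": s.is_active,
        "potency": s.potency,
    }


def default_study(
    seed: int = 1,
    config: SimulationConfig | None = None,
    render: bool = True,
) -> SyntheticStudy:
    """Generate the default 69-fraction, 43-compound (14 active) study.

    Fully deterministic under a fixed seed.  ``render=False`` skips the
    densitogram synthesis when only matrices are needed.
    """
    if config is None:
        config = SimulationConfig(seed=seed)
    rng = np.random.default_rng(config.seed if config.seed else seed)
    specs, planted = _default_specs(rng)
    conc = simulate_elution(specs, config, rng)
    scale = calibrate_activity_scale(conc, specs, config.activity_target_median)
    activity = simulate_activity(conc, specs, scale)
    matrix = masked_matrix(conc, config)
    matrix0 = matrix.fillna(0.0)

    # generator self-checks for the planted scenarios
    shadow = planted["shadow_inactive"]
    partner = planted["shadow_partner"]
    r = np.corrcoef(conc[shadow], conc[partner])[0, 1]
    if r < 0.95:
        raise AssertionError(f"shadow profile correlation {r:.3f} below 0.95")

    truth = pd.DataFrame(
        {
            "is_active": [s.is_active for s in specs],
            "potency": [s.potency for s in specs],
        },
        index=pd.Index([s.id for s in specs], name="compound"),
    )
    densitograms = {}
    if render:
        for mode in MODES:
            densitograms[mode] = render_densitograms(conc, specs, mode, config, rng)
    return SyntheticStudy(
        config=config,
        specs=specs,
        concentrations=conc,
        matrix=matrix,
        matrix0=matrix0,
        activity=activity,
        activity_scale=scale,
        ground_truth=truth,
        densitograms=densitograms,
        planted=planted,
    )
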