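"""Core optical data model for transillumination microscopy and spectroscopy.

Everything downstream of the cameras and the spectrometer is expressed in
terms of optical density (OD).  For light transmitted through an absorber,

    OD = log10(I_incident / I_transmitted) = eps(lambda) * L * C

(Beer-Lambert), with ``eps`` the hemoglobin extinction coefficient
(per mM per cm), ``L`` the optical path length (cm) and ``C`` the hemoglobin
concentration (mM).  At an isosbestic wavelength the oxy- and deoxyhemoglobin
extinction coefficients coincide, so OD changes there reflect changes in
hemoglobin *content* only, independent of oxygen saturation.  Red-cell
oxygen saturation (SO2) is instead read from the ratio of ODs at an
O2-dependent wavelength (438 nm) to the isosbestic 450 nm.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

#: Isosbestic wavelengths of hemoglobin in the visible spectrum (nm).
ISOSBESTIC_WAVELENGTHS_NM: tuple[float, ...] = (452.0, 500.0, 530.0, 545.0, 570.0, 584.0)

#: Half-width of the spectral band averaged around each isosbestic
#: wavelength (nm); a 2-nm bandpass realised as lambda +/- 1 nm inclusive.
ISOSBESTIC_BANDPASS_HALF_NM: float = 1.0


@dataclass(frozen=True)
class HemoglobinSpectrum:
    """Extinction coefficients of hemoglobin at one wavelength.

    Units are per mM per cm.  ``is_isosbestic`` marks wavelengths where the
    oxy and deoxy coefficients are equal.
    """

    wavelength: float
    eps_oxy: float
    eps_deoxy: float
    is_isosbestic: bool = False

    def __post_init__(self) -> None:
        if self.eps_oxy <= 0 or self.eps_deoxy <= 0:
            raise ValueError("extinction coefficients must be positive")
        if self.is_isosbestic and self.eps_oxy != self.eps_deoxy:
            raise ValueError(
                f"isosbestic wavelength {self.wavelength} nm requires eps_oxy == eps_deoxy"
            )

    def eps_at_so2(self, so2: float) -> float:
        """Effective extinction coefficient at fractional saturation ``so2``."""
        return so2 * self.eps_oxy + (1.0 - so2) * self.eps_deoxy


def default_extinction_table() -> dict[float, HemoglobinSpectrum]:
    """Bundled hemoglobin extinction coefficients (per mM per cm).

    Approximate values at the working wavelengths, on the scale of standard
    visible-spectrum hemoglobin compilations.  The 438-nm entries are chosen
    so that the 438/450 OD-ratio endpoints equal the default
    :class:`CalibrationConstants`; all values are configurable by passing a
    replacement table wherever one is consumed.
    """
    eps450 = 62.8
    table = [
        HemoglobinSpectrum(438.0, eps_oxy=1.2 * eps450, eps_deoxy=0.6 * eps450),
        HemoglobinSpectrum(450.0, eps450, eps450, is_isosbestic=True),
        HemoglobinSpectrum(452.0, 60.0, 60.0, is_isosbestic=True),
        HemoglobinSpectrum(500.0, 20.9, 20.9, is_isosbestic=True),
        HemoglobinSpectrum(530.0, 39.0, 39.0, is_isosbestic=True),
        HemoglobinSpectrum(545.0, 51.5, 51.5, is_isosbestic=True),
        HemoglobinSpectrum(570.0, 44.8, 44.8, is_isosbestic=True),
        HemoglobinSpectrum(584.0, 33.4, 33.4, is_isosbestic=True),
    ]
    return {row.wavelength: row for row in table}


@dataclass(frozen=True)
class CalibrationConstants:
    """In vivo calibration endpoints of the 438/450 nm OD ratio.

    ``ratio_oxy`` is the OD ratio of a fully oxygenated red cell and
    ``ratio_deoxy`` that of a fully deoxygenated one.  Saturation is affine
    in the ratio between the two endpoints.  The defaults are package
    placeholders used symmetrically by the forward simulator and the
    analysis; replace them with instrument-specific calibration values for
    real recordings.
    """

    ratio_oxy: float = 1.2
    ratio_deoxy: float = 0.6

    def __post_init__(self) -> None:
        if self.ratio_oxy <= 0 or self.ratio_deoxy <= 0:
            raise ValueError("calibration ratios must be positive")
        if self.ratio_oxy == self.ratio_deoxy:
            raise ValueError("calibration ratios must differ")

    def ratio_at_so2(self, so2) -> np.ndarray | float:
        """Forward map: OD ratio produced by saturation ``so2``."""
        return self.ratio_deoxy + np.asarray(so2, dtype=float) * (
            self.ratio_oxy - self.ratio_deoxy
        )


@dataclass
class FrameSequence:
    """A timed dual-wavelength image stack with pixel calibration.

    ``frames`` maps wavelength (nm) to an array of shape
    ``(n_frames, height, width)`` of linear camera counts.  All wavelengths
    share frame geometry and timestamps (simultaneous dual-camera capture).
    """

    frames: dict[float, np.ndarray]
    timestamps: np.ndarray
    pixel_size: float
    bit_depth: int = 12
    fov_id: str = "fov0"
    group_label: str = "control"
    imaging_period: int = 1

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if self.timestamps.ndim != 1:
            raise ValueError("timestamps must be 1-D")
        if np.any(np.diff(self.timestamps) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        shapes = {wl: arr.shape for wl, arr in self.frames.items()}
        if len({s for s in shapes.values()}) > 1:
            raise ValueError(f"frame shapes differ across wavelengths: {shapes}")
        full_scale = 2 ** self.bit_depth
        for wl, arr in self.frames.items():
            if arr.ndim != 3 or arr.shape[0] != self.timestamps.size:
                raise ValueError(
                    f"{wl} nm stack shape {arr.shape} inconsistent with "
                    f"{self.timestamps.size} timestamps"
                )
            if arr.min() < 0 or arr.max() >= full_scale:
                raise ValueError(
                    f"{wl} nm intensities outside [0, 2^{self.bit_depth})"
                )

    @property
    def wavelengths(self) -> list[float]:
        return sorted(self.frames)

    @property
    def frame_shape(self) -> tuple[int, int]:
        arr = next(iter(self.frames.values()))
        return arr.shape[1], arr.shape[2]

    @property
    def frame_rate(self) -> float:
        return 1.0 / float(np.median(np.diff(self.timestamps)))


@dataclass
class SpectralRecording:
    """Continuous-wave spectroscopy: wavelength x time intensity matrix."""

    wavelengths: np.ndarray
    timestamps: np.ndarray
    intensities: np.ndarray
    fov_id: str = "fov0"
    group_label: str = "control"
    imaging_period: int = 1

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if np.any(np.diff(self.timestamps) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if self.intensities.shape != (self.wavelengths.size, self.timestamps.size):
            raise ValueError(
                "intensities must be (n_wavelengths, n_times); got "
                f"{self.intensities.shape}"
            )
        if self.intensities.min() < 0:
            raise ValueError("intensities must be nonnegative")

    @property
    def mean_rate(self) -> float:
        span = self.timestamps[-1] - self.timestamps[0]
        return (self.timestamps.size - 1) / span


@dataclass
class ODTimeSeries:
    """Change in optical density relative to the first sample.

    ``source`` tags provenance: ``"MFI"`` (mean frame intensity of the video)
    or ``"CWS"`` (spectrometer).
    """

    timestamps: np.ndarray
    delta_od: np.ndarray
    source: str = "MFI"
    wavelength_set: tuple[float, ...] = (450.0,)
    fov_id: str = "fov0"
    group_label: str = "control"
    imaging_period: int = 1

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.delta_od = np.asarray(self.delta_od, dtype=float)
        if self.timestamps.shape != self.delta_od.shape:
            raise ValueError("timestamps and delta_od must align")
        if not np.all(np.isfinite(self.delta_od)):
            raise ValueError("delta_od must be finite")
        if abs(self.delta_od[0]) > 1e-12:
            raise ValueError("delta_od must be 0 at the first sample")

    def is_uniform(self, rtol: float = 1e-6) -> bool:
        dt = np.diff(self.timestamps)
        return bool(np.allclose(dt, dt[0], rtol=rtol, atol=1e-12))


def beer_lambert_od(eps: float, path_length: float, concentration: float) -> float:
    """Optical density of an absorber: ``eps * L * C``.

    Parameters are the extinction coefficient (per mM per cm), the optical
    path length (cm) and the absorber concentration (mM).  The implied
    transmitted fraction is ``10**(-OD)``.
    """
    eps = np.asarray(eps, dtype=float)
    path_length = np.asarray(path_length, dtype=float)
    concentration = np.asarray(concentration, dtype=float)
    if np.any(eps < 0) or np.any(path_length < 0) or np.any(concentration < 0):
        raise ValueError("beer_lambert_od arguments must be nonnegative")
    out = eps * path_length * concentration
    return float(out) if out.ndim == 0 else out


def delta_od_series(
    timestamps,
    intensities,
    *,
    source: str = "MFI",
    wavelength_set: tuple[float, ...] = (450.0,),
    fov_id: str = "fov0",
    group_label: str = "control",
    imaging_period: int = 1,
) -> ODTimeSeries:
    """ODTimeSeries from a transmitted-intensity trace.

    ``dOD(t) = log10(I(0) / I(t))`` so a fall in transmitted intensity
    (more absorbing hemoglobin in the light path) gives a *rise* in dOD.
    """
    intensities = np.asarray(intensities, dtype=float)
    bad = np.flatnonzero(intensities <= 0)
    if bad.size:
        raise ValueError(
            f"nonpositive intensity at index {bad[0]} (value {intensities[bad[0]]})"
        )
    dod = np.log10(intensities[0] / intensities)
    dod[0] = 0.0
    return ODTimeSeries(
        timestamps=np.asarray(timestamps, dtype=float),
        delta_od=dod,
        source=source,
        wavelength_set=tuple(wavelength_set),
        fov_id=fov_id,
        group_label=group_label,
        imaging_period=imaging_period,
    )


def mean_frame_intensity(
    seq: FrameSequence, wavelength: float, *, exclude_saturated: bool = True
) -> np.ndarray:
    """Per-frame mean pixel intensity at one wavelength.

    Saturated pixels (at or above full scale minus one for the sequence bit
    depth) are excluded from the mean; their count is logged.
    """
    if wavelength not in seq.frames:
        raise KeyError(
            f"wavelength {wavelength} nm not in sequence (has {seq.wavelengths})"
        )
    stack = seq.frames[wavelength].astype(float)
    if not exclude_saturated:
        return stack.mean(axis=(1, 2))
    sat_level = 2 ** seq.bit_depth - 1
    saturated = stack >= sat_level
    n_sat = int(saturated.sum())
    if n_sat:
        logger.info(
            "mean_frame_intensity: excluding %d saturated pixels at %s nm (fov %s)",
            n_sat,
            wavelength,
            seq.fov_id,
        )
        masked = np.where(saturated, np.nan, stack)
        return np.nanmean(masked, axis=(1, 2))
    return stack.mean(axis=(1, 2))


def rbc_so2(od_438, od_450, calib: CalibrationConstants | None = None):
    """Red-cell oxygen saturation from the 438/450 nm OD ratio.

    ``SO2 = (R - ratio_deoxy) / (ratio_oxy - ratio_deoxy)`` with
    ``R = OD438/OD450``, clipped to [0, 1].  Accepts scalars or arrays.
    """
    calib = calib or CalibrationConstants()
    od_438 = np.asarray(od_438, dtype=float)
    od_450 = np.asarray(od_450, dtype=float)
    if np.any(od_450 <= 0):
        raise ValueError("od_450 must be positive (no red-cell signal otherwise)")
    ratio = od_438 / od_450
    so2 = (ratio - calib.ratio_deoxy) / (calib.ratio_oxy - calib.ratio_deoxy)
    so2 = np.clip(so2, 0.0, 1.0)
    return float(so2) if so2.ndim == 0 else so2


def isosbestic_average(
    rec: SpectralRecording,
    *,
    isosbestic_nm: tuple[float, ...] = ISOSBESTIC_WAVELENGTHS_NM,
    half_band_nm: float = ISOSBESTIC_BANDPASS_HALF_NM,
) -> ODTimeSeries:
    """Mean dOD over the six isosbestic wavelengths of a CWS recording.

    For each isosbestic wavelength the intensities within +/- ``half_band_nm``
    (inclusive) are averaged into one band intensity, converted to a dOD
    series, and the six dOD series are averaged without weighting.  At these
    wavelengths the extinction coefficients are saturation-independent, so
    the average tracks microvascular hemoglobin content; averaging reduces
    uncorrelated per-wavelength noise by ~sqrt(6).
    """
    missing = []
    band_dods = []
    for wl in isosbestic_nm:
        in_band = np.abs(rec.wavelengths - wl) <= half_band_nm + 1e-9
        if not np.any(in_band):
            missing.append(wl)
            continue
        band_intensity = rec.intensities[in_band].mean(axis=0)
        if np.any(band_intensity <= 0):
            raise ValueError(f"nonpositive band intensity at {wl} nm")
        band_dods.append(np.log10(band_intensity[0] / band_intensity))
    if missing:
        raise ValueError(
            f"spectral coverage missing isosbestic wavelengths: {missing}"
        )
    mean_dod = np.mean(band_dods, axis=0)
    mean_dod[0] = 0.0
    return ODTimeSeries(
        timestamps=rec.timestamps,
        delta_od=mean_dod,
        source="CWS",
        wavelength_set=tuple(isosbestic_nm),
        fov_id=rec.fov_id,
        group_label=rec.group_label,
        imaging_period=rec.imaging_period,
    )


def resample_uniform(timestamps, values, rate: float) -> tuple[np.ndarray, np.ndarray]:
    """Linear interpolation onto a uniform grid at ``rate`` Hz.

    The grid runs from the first to the last timestamp; no extrapolation.
    Returns ``(grid_timestamps, grid_values)``.
    """
    timestamps = np.asarray(timestamps, dtype=float)
    values = np.asarray(values, dtype=float)
    if timestamps.size < 2:
        raise ValueError("need at least 2 samples to resample")
    if np.any(np.diff(timestamps) <= 0):
        raise ValueError("timestamps must be strictly increasing")
    if rate <= 0:
        raise ValueError("rate must be positive")
    span = timestamps[-1] - timestamps[0]
    n = int(np.floor(span * rate)) + 1
    grid = timestamps[0] + np.arange(n) / rate
    return grid, np.interp(grid, timestamps, values)


def resample_od_series(series: ODTimeSeries, rate: float = 10.5) -> ODTimeSeries:
    """Resample an ODTimeSeries onto a uniform grid (default 10.5 Hz)."""
    grid, vals = resample_uniform(series.timestamps, series.delta_od, rate)
    vals = vals - vals[0]
    return ODTimeSeries(
        timestamps=grid,
        delta_od=vals,
        source=series.source,
        wavelength_set=series.wavelength_set,
        fov_id=series.fov_id,
        group_label=series.group_label,
        imaging_period=series.imaging_period,
    )
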