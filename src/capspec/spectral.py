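"""Fourier power analysis of hemoglobin dOD series in the vasomotion band.

The power spectrum is the squared one-sided amplitude spectrum of the
mean-removed series: ``A_k = 2 |X_k| / N`` (DC and Nyquist not doubled), so
a pure sinusoid of amplitude A lands ``A**2`` of Power in its bin.  The
vasomotion band is 0.03-0.06 Hz (periods 16-32 s); the band peak is the
maximum Power over bins inside the band, inclusive of both edges.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .imaging import ODTimeSeries

logger = logging.getLogger(__name__)

VASOMOTION_BAND_HZ: tuple[float, float] = (0.03, 0.06)


@dataclass
class PowerSpectrum:
    frequencies: np.ndarray
    power: np.ndarray  # amplitude^2, one-sided
    series_source: str = "MFI"
    fov_id: str = "fov0"
    group_label: str = "control"
    imaging_period: int = 1

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if np.any(self.frequencies < 0) or np.any(self.power < 0):
            raise ValueError("frequencies and power must be nonnegative")


@dataclass
class BandPeak:
    peak_power: float
    peak_frequency: float
    peak_period: float
    band: tuple[float, float] = VASOMOTION_BAND_HZ
    source: str = "MFI"
    fov_id: str = "fov0"
    group_label: str = "control"
    imaging_period: int = 1

    def __post_init__(self) -> None:
        lo, hi = self.band
        if not (lo <= self.peak_frequency <= hi):
            raise ValueError("peak frequency outside band")


def power_spectrum(
    series: ODTimeSeries,
    *,
    detrend: str = "mean",
    taper: bool = False,
    min_samples: int = 64,
) -> PowerSpectrum:
    """One-sided FFT power (amplitude squared) of a uniformly sampled series.

    Only the mean is removed by default; no taper window and no zero padding
    (a plain FFT).  Non-uniform timestamps are rejected -- resample first
    (see :func:`capspec.imaging.resample_uniform`).
    """
    if not series.is_uniform():
        raise ValueError(
            "series is not uniformly sampled; apply resample_uniform first"
        )
    x = series.delta_od.astype(float)
    n = x.size
    if n < min_samples:
        raise ValueError(f"need at least {min_samples} samples, got {n}")
    if detrend == "mean":
        x = x - x.mean()
    elif detrend == "linear":
        t = np.arange(n)
        x = x - np.polyval(np.polyfit(t, x, 1), t)
    elif detrend not in (None, "none"):
        raise ValueError(f"unknown detrend {detrend!r}")
    if taper:
        x = x * np.hanning(n)
    dt = float(series.timestamps[1] - series.timestamps[0])
    spec = np.fft.rfft(x)
    amplitude = 2.0 * np.abs(spec) / n
    amplitude[0] /= 2.0
    if n % 2 == 0:
        amplitude[-1] /= 2.0
    freqs = np.fft.rfftfreq(n, d=dt)
    return PowerSpectrum(
        frequencies=freqs,
        power=amplitude**2,
        series_source=series.source,
        fov_id=series.fov_id,
        group_label=series.group_label,
        imaging_period=series.imaging_period,
    )


def peak_power_in_band(
    spec: PowerSpectrum, band: tuple[float, float] = VASOMOTION_BAND_HZ
) -> BandPeak:
    """Maximum Power over frequency bins inside ``band`` (edges inclusive).

    Ties go to the lowest frequency.  Raises if the spectrum has no bin in
    the band (series too short), stating the minimum duration required.
    """
    lo, hi = band
    sel = (spec.frequencies >= lo) & (spec.frequencies <= hi)
    if not np.any(sel):
        raise ValueError(
            f"no frequency bins inside [{lo}, {hi}] Hz; the series must span "
            f"at least {1.0 / lo:.0f} s for one bin in the band"
        )
    freqs = spec.frequencies[sel]
    power = spec.power[sel]
    k = int(np.argmax(power))  # argmax returns the first (lowest-frequency) tie
    return BandPeak(
        peak_power=float(power[k]),
        peak_frequency=float(freqs[k]),
        peak_period=float(1.0 / freqs[k]),
        band=band,
        source=spec.series_source,
        fov_id=spec.fov_id,
        group_label=spec.group_label,
        imaging_period=spec.imaging_period,
    )


def band_peak_for_fov(
    mfi_series: ODTimeSeries | None,
    cws_series: ODTimeSeries | None,
    *,
    band: tuple[float, float] = VASOMOTION_BAND_HZ,
) -> dict[str, BandPeak]:
    """Paired MFI- and CWS-derived band peaks for one field of view.

    Each available modality is analyzed at its native length and sampling;
    a missing modality yields a partial record with a log message.
    """
    out: dict[str, BandPeak] = {}
    for name, series in (("MFI", mfi_series), ("CWS", cws_series)):
        if series is None:
            logger.info("band_peak_for_fov: %s series missing", name)
            continue
        peak = peak_power_in_band(power_spectrum(series), band)
        peak.source = name
        out[name] = peak
    return out
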