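"""Forward simulator for dual-wavelength capillary video and CW spectroscopy.

The generator renders what the two instruments would record from a thin,
transilluminated skeletal muscle: discrete red blood cells (dark elongated
absorbers) moving single-file along capillary centerlines separated by
bright plasma gaps, on top of a tissue background whose hemoglobin content
may oscillate slowly (vasomotion).  Attenuation everywhere follows
Beer-Lambert; the O2-dependent 438-nm wavelength uses a saturation-dependent
extinction for the red cells while the isosbestic 450-nm wavelength does
not.  Every simulated quantity (per-frame velocity, lineal density, supply
rate, SO2, hemoglobin concentration trace) is returned as ground truth so
that the analysis pipeline can be validated closed-loop.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
from scipy.spatial import cKDTree

from .imaging import (
    CalibrationConstants,
    FrameSequence,
    HemoglobinSpectrum,
    SpectralRecording,
    beer_lambert_od,
    default_extinction_table,
)

Profile = float | Callable[[np.ndarray], np.ndarray]


def _eval_profile(profile: Profile, t: np.ndarray) -> np.ndarray:
    if callable(profile):
        return np.asarray(profile(t), dtype=float)
    return np.full_like(t, float(profile))


@dataclass(frozen=True)
class VasomotionParams:
    """Low-frequency oscillation of microvascular hemoglobin and flow.

    When enabled, the tissue hemoglobin concentration is modulated as
    ``C(t) = C0 * (1 + m sin(2 pi t / T + phi))`` with period ``T`` of the
    order of 30 s (about 2 cycles/min) and fractional depth ``m``.  By
    default capillary velocity is modulated with the same phase, mirroring
    the synchrony of hemoglobin and flow oscillations; set
    ``couple_velocity=False`` to decouple.
    """

    enabled: bool = False
    period_s: float = 28.8
    modulation_depth: float = 0.05
    phase_rad: float = 0.0
    couple_velocity: bool = True

    def __post_init__(self) -> None:
        if self.period_s <= 0:
            raise ValueError("period must be positive")
        if not (0.0 <= self.modulation_depth < 1.0):
            raise ValueError("modulation depth must be in [0, 1)")

    def factor(self, t: np.ndarray) -> np.ndarray:
        """Multiplicative modulation factor at times ``t`` (1.0 if disabled)."""
        t = np.asarray(t, dtype=float)
        if not self.enabled:
            return np.ones_like(t)
        return 1.0 + self.modulation_depth * np.sin(
            2.0 * np.pi * t / self.period_s + self.phase_rad
        )


@dataclass
class CapillaryProgram:
    """Ground-truth kinematics of one simulated capillary.

    ``centerline`` is an ordered pixel polyline, arteriolar end first;
    positive velocity is arteriolar-to-venular.  ``velocity`` and ``so2``
    may be constants or callables of time (s).  ``rbc_spacing_um`` is the
    mean center-to-center spacing of consecutive red cells.
    """

    centerline: np.ndarray
    velocity: Profile = 200.0
    so2: Profile = 0.8
    rbc_spacing_um: float = 20.0
    flow_state_truth: str = "continuous"
    capillary_id: str = "cap0"

    def __post_init__(self) -> None:
        self.centerline = np.asarray(self.centerline, dtype=float)
        if self.centerline.ndim != 2 or self.centerline.shape[0] < 2:
            raise ValueError("centerline needs >= 2 (x, y) points")
        if self.flow_state_truth not in ("continuous", "intermittent", "stopped"):
            raise ValueError(f"unknown flow state {self.flow_state_truth!r}")


def steady_program(centerline, velocity_um_s=200.0, **kw) -> CapillaryProgram:
    return CapillaryProgram(
        centerline, velocity=velocity_um_s, flow_state_truth="continuous", **kw
    )


def intermittent_program(
    centerline,
    velocity_um_s: float = 200.0,
    stop_s: float = 4.0,
    cycle_s: float = 12.0,
    **kw,
) -> CapillaryProgram:
    """Velocity gated by a square wave with full stops of ``stop_s`` seconds.

    The default 4-s stop satisfies the ">3 s at least once" intermittency
    rule used by the flow classifier.
    """
    if stop_s >= cycle_s:
        raise ValueError("stop interval must be shorter than the cycle")

    def v(t: np.ndarray) -> np.ndarray:
        return np.where((t % cycle_s) < stop_s, 0.0, velocity_um_s)

    return CapillaryProgram(centerline, velocity=v, flow_state_truth="intermittent", **kw)


def reversed_program(
    centerline, velocity_um_s: float = 200.0, epoch_s: float = 5.0, **kw
) -> CapillaryProgram:
    """Flow direction alternates every ``epoch_s`` seconds (reversal epochs)."""

    def v(t: np.ndarray) -> np.ndarray:
        return np.where((t % (2.0 * epoch_s)) < epoch_s, velocity_um_s, -velocity_um_s)

    return CapillaryProgram(centerline, velocity=v, flow_state_truth="intermittent", **kw)


def stopped_program(centerline, **kw) -> CapillaryProgram:
    return CapillaryProgram(centerline, velocity=0.0, flow_state_truth="stopped", **kw)


@dataclass
class SimulationConfig:
    """All knobs of the forward model, with acquisition-matched defaults.

    Video defaults mirror the acquisition: 696 x 520 px at 0.6466 um/px
    (450 um across 696 px), 12-bit counts, 21 frames/s for 60 s at 438 and
    450 nm.  Spectroscopy defaults: 450-650 nm, ~10.5 recordings/s for
    120 s.  ``noise_sigma`` is additive Gaussian camera noise in counts
    (default ~1% of the tissue background); CWS noise is shot-like,
    proportional to intensity.
    """

    frame_shape: tuple[int, int] = (520, 696)
    pixel_size: float = 0.6466
    frame_rate: float = 21.0
    duration: float = 60.0
    wavelengths: tuple[float, ...] = (438.0, 450.0)
    bit_depth: int = 12
    incident_counts: float = 3000.0
    noise_sigma: float = 7.0
    tissue_hb_mm: float = 0.1
    tissue_path_cm: float = 0.1
    tissue_so2: float = 0.7
    rbc_length_um: float = 6.0
    rbc_width_um: float = 5.0
    rbc_path_um: float = 5.0
    rbc_hb_mm: float = 11.1
    seed: int = 0
    capillary_programs: list[CapillaryProgram] = field(default_factory=list)
    vasomotion: VasomotionParams = field(default_factory=VasomotionParams)
    cws_rate: float = 10.5
    cws_duration: float = 120.0
    cws_noise_frac: float = 0.005
    cws_wavelength_step: float = 1.0
    cws_jitter_s: float = 0.02
    calibration: CalibrationConstants = field(default_factory=CalibrationConstants)

    def __post_init__(self) -> None:
        if self.frame_rate <= 0 or self.duration <= 0:
            raise ValueError("frame_rate and duration must be positive")
        if self.cws_rate <= 0 or self.cws_duration <= 0:
            raise ValueError("cws_rate and cws_duration must be positive")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def rbc_od450(self) -> float:
        """Optical density of one red cell at 450 nm from its Beer-Lambert terms."""
        eps450 = default_extinction_table()[450.0].eps_oxy
        return beer_lambert_od(eps450, self.rbc_path_um * 1e-4, self.rbc_hb_mm)


@dataclass
class CapillaryTruth:
    """Per-frame ground truth for one capillary."""

    capillary_id: str
    flow_state: str
    length_um: float
    velocity: np.ndarray
    lineal_density: np.ndarray
    supply_rate: np.ndarray
    so2: np.ndarray
    od450: float
    n_inside_start: int = 0
    n_inside_end: int = 0
    n_entered_upstream: int = 0
    n_exited_downstream: int = 0
    n_midpoint_crossings: int = 0


@dataclass
class VideoTruth:
    timestamps: np.ndarray
    tissue_concentration: np.ndarray
    background_counts: dict[float, np.ndarray]
    capillaries: dict[str, CapillaryTruth]
    vasomotion: VasomotionParams


@dataclass
class CwsTruth:
    timestamps: np.ndarray
    concentration: np.ndarray
    period_s: float | None
    modulation_depth: float
    od450_baseline: float


def _arc_coordinates(centerline: np.ndarray, pixel_size: float, step_px: float = 0.25):
    """Densify a polyline; return fine points (px) and their arc lengths (um)."""
    seg = np.diff(centerline, axis=0)
    seg_len = np.hypot(seg[:, 0], seg[:, 1])
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    total = cum[-1]
    n = max(int(np.ceil(total / step_px)) + 1, 2)
    s_px = np.linspace(0.0, total, n)
    x = np.interp(s_px, cum, centerline[:, 0])
    y = np.interp(s_px, cum, centerline[:, 1])
    return np.column_stack([x, y]), s_px * pixel_size, total * pixel_size


def _rasterize_capillary(
    program: CapillaryProgram, config: SimulationConfig, feather_px: float = 1.0
):
    """Pixels covered by the capillary lumen with arc position and coverage.

    Returns (rows, cols, s_um, lateral_coverage, length_um).
    """
    h, w = config.frame_shape
    cl = program.centerline
    if (
        cl[:, 0].min() < 0
        or cl[:, 0].max() > w - 1
        or cl[:, 1].min() < 0
        or cl[:, 1].max() > h - 1
    ):
        raise ValueError(
            f"capillary {program.capillary_id} centerline outside frame bounds"
        )
    fine, s_um, length_um = _arc_coordinates(cl, config.pixel_size)
    half_w_px = 0.5 * config.rbc_width_um / config.pixel_size
    pad = int(np.ceil(half_w_px + feather_px)) + 1
    x0 = max(int(cl[:, 0].min()) - pad, 0)
    x1 = min(int(cl[:, 0].max()) + pad + 1, w)
    y0 = max(int(cl[:, 1].min()) - pad, 0)
    y1 = min(int(cl[:, 1].max()) + pad + 1, h)
    ys, xs = np.mgrid[y0:y1, x0:x1]
    pts = np.column_stack([xs.ravel(), ys.ravel()]).astype(float)
    tree = cKDTree(fine)
    dist_px, idx = tree.query(pts, k=1)
    cov = np.clip((half_w_px + feather_px / 2.0 - dist_px) / feather_px, 0.0, 1.0)
    keep = cov > 0
    return (
        pts[keep, 1].astype(int),
        pts[keep, 0].astype(int),
        s_um[idx[keep]],
        cov[keep],
        length_um,
    )


def _rbc_offsets(
    rng: np.random.Generator,
    spacing_um: float,
    rbc_length_um: float,
    lo: float,
    hi: float,
) -> np.ndarray:
    """Center-to-center RBC offsets covering [lo, hi] um with jittered spacing."""
    min_spacing = 1.2 * rbc_length_um
    if spacing_um <= min_spacing:
        raise ValueError("rbc spacing must exceed the RBC length")
    n = int(np.ceil((hi - lo) / (0.5 * spacing_um))) + 4
    draws = rng.normal(spacing_um, 0.15 * spacing_um, size=n)
    draws = np.clip(draws, min_spacing, None)
    offsets = lo + rng.uniform(0.0, spacing_um) + np.concatenate([[0.0], np.cumsum(draws)])
    return offsets[offsets <= hi]


def _count_crossings(offsets: np.ndarray, disp: np.ndarray, boundary: float) -> int:
    """Total boundary crossings over the run, summed across RBCs."""
    if offsets.size == 0:
        return 0
    pos = offsets[:, None] + disp[None, :]
    above = pos > boundary
    return int(np.abs(np.diff(above.astype(np.int8), axis=1)).sum())


def generate_capillary_video(
    config: SimulationConfig,
) -> tuple[FrameSequence, VideoTruth]:
    """Render a dual-wavelength frame stack plus complete ground truth.

    Identical configs (including seed) produce bit-identical stacks.
    """
    rng = np.random.default_rng([config.seed, 1])
    n_frames = int(round(config.duration * config.frame_rate))
    t = np.arange(n_frames) / config.frame_rate
    dt = 1.0 / config.frame_rate

    table = default_extinction_table()
    conc = config.tissue_hb_mm * config.vasomotion.factor(t)

    background: dict[float, np.ndarray] = {}
    for wl in config.wavelengths:
        if wl not in table:
            raise ValueError(f"no extinction entry for {wl} nm")
        eps = table[wl].eps_at_so2(config.tissue_so2)
        od = beer_lambert_od(eps, config.tissue_path_cm, conc)
        background[wl] = config.incident_counts * 10.0 ** (-od)

    od450_rbc = config.rbc_od450
    full_scale = 2 ** config.bit_depth - 1

    # Paint capillary pixels on top of the background, per frame.
    cap_pixels = []
    truths: dict[str, CapillaryTruth] = {}
    for prog in config.capillary_programs:
        rows, cols, s_um, cov_lat, length_um = _rasterize_capillary(prog, config)
        v = _eval_profile(prog.velocity, t)
        if config.vasomotion.enabled and config.vasomotion.couple_velocity:
            v = v * config.vasomotion.factor(t)
        disp = np.concatenate([[0.0], np.cumsum(v[:-1] * dt)])
        lo = -max(disp.max(), 0.0) - 2.0 * config.rbc_length_um
        hi = length_um - min(disp.min(), 0.0) + 2.0 * config.rbc_length_um
        offsets = _rbc_offsets(rng, prog.rbc_spacing_um, config.rbc_length_um, lo, hi)
        so2 = np.clip(_eval_profile(prog.so2, t), 0.0, 1.0)
        od_by_wl = {}
        for wl in config.wavelengths:
            if wl == 438.0:
                od_by_wl[wl] = od450_rbc * config.calibration.ratio_at_so2(so2)
            else:
                od_by_wl[wl] = np.full(n_frames, od450_rbc * table[wl].eps_oxy / table[450.0].eps_oxy)
        cap_pixels.append((rows, cols, s_um, cov_lat, offsets, disp, od_by_wl))

        pos0 = offsets + disp[0]
        pos1 = offsets + disp[-1]
        inside = (
            (offsets[:, None] + disp[None, :] >= 0.0)
            & (offsets[:, None] + disp[None, :] <= length_um)
        ).sum(axis=0)
        ld = inside / (length_um / 1000.0)
        sr = np.abs(v) * ld / 1000.0
        sr[v == 0.0] = 0.0
        truths[prog.capillary_id] = CapillaryTruth(
            capillary_id=prog.capillary_id,
            flow_state=prog.flow_state_truth,
            length_um=length_um,
            velocity=v,
            lineal_density=ld,
            supply_rate=sr,
            so2=so2,
            od450=od450_rbc,
            n_inside_start=int(((pos0 >= 0.0) & (pos0 <= length_um)).sum()),
            n_inside_end=int(((pos1 >= 0.0) & (pos1 <= length_um)).sum()),
            n_entered_upstream=_count_crossings(offsets, disp, 0.0),
            n_exited_downstream=_count_crossings(offsets, disp, length_um),
            n_midpoint_crossings=_count_crossings(offsets, disp, length_um / 2.0),
        )

    h, w = config.frame_shape
    feather_um = 1.0 * config.pixel_size
    frames: dict[float, np.ndarray] = {}
    for wl in sorted(config.wavelengths):
        out = np.empty((n_frames, h, w), dtype=np.uint16)
        bg = background[wl]
        for k in range(n_frames):
            frame = np.full((h, w), bg[k], dtype=np.float64)
            for rows, cols, s_um, cov_lat, offsets, disp, od_by_wl in cap_pixels:
                u = s_um - disp[k]
                idx = np.searchsorted(offsets, u)
                left = offsets[np.clip(idx - 1, 0, offsets.size - 1)]
                right = offsets[np.clip(idx, 0, offsets.size - 1)]
                dist = np.minimum(np.abs(u - left), np.abs(u - right))
                cov_ax = np.clip(
                    (config.rbc_length_um / 2.0 + feather_um / 2.0 - dist) / feather_um,
                    0.0,
                    1.0,
                )
                alpha = cov_lat * cov_ax
                transmit = 10.0 ** (-np.asarray(od_by_wl[wl])[k])
                frame[rows, cols] = bg[k] * (1.0 - alpha * (1.0 - transmit))
            frame += rng.normal(0.0, config.noise_sigma, size=(h, w))
            np.clip(frame, 0.0, full_scale, out=frame)
            out[k] = np.round(frame).astype(np.uint16)
        frames[wl] = out

    seq = FrameSequence(
        frames=frames,
        timestamps=t,
        pixel_size=config.pixel_size,
        bit_depth=config.bit_depth,
    )
    truth = VideoTruth(
        timestamps=t,
        tissue_concentration=conc,
        background_counts=background,
        capillaries=truths,
        vasomotion=config.vasomotion,
    )
    return seq, truth


def generate_cws_recording(
    config: SimulationConfig,
) -> tuple[SpectralRecording, CwsTruth]:
    """Simulate a continuous-wave spectroscopy acquisition (450-650 nm).

    The hemoglobin concentration trace follows the vasomotion program;
    intensities obey Beer-Lambert with extinction coefficients interpolated
    between the isosbestic anchor points; shot-like noise is added with
    standard deviation proportional to intensity; timestamps are jittered
    around the nominal recording rate.
    """
    rng = np.random.default_rng([config.seed, 2])
    n = int(round(config.cws_duration * config.cws_rate))
    base = np.arange(n) / config.cws_rate
    jitter = rng.uniform(-config.cws_jitter_s, config.cws_jitter_s, size=n)
    jitter[0] = 0.0
    # jitter bounded well below half the sampling interval keeps order strict
    timestamps = base + np.clip(jitter, -0.4 / config.cws_rate, 0.4 / config.cws_rate)

    step = config.cws_wavelength_step
    wavelengths = np.arange(450.0, 650.0 + step / 2.0, step)
    table = default_extinction_table()
    anchors = sorted(wl for wl, row in table.items() if row.is_isosbestic)
    eps_anchor = np.array([table[wl].eps_oxy for wl in anchors])
    eps = np.interp(wavelengths, anchors, eps_anchor)

    conc = config.tissue_hb_mm * config.vasomotion.factor(timestamps)
    od = eps[:, None] * config.tissue_path_cm * conc[None, :]
    clean = config.incident_counts * 10.0 ** (-od)
    noisy = clean + rng.normal(0.0, 1.0, size=clean.shape) * (
        config.cws_noise_frac * clean
    )
    noisy = np.clip(noisy, 0.0, None)

    rec = SpectralRecording(
        wavelengths=wavelengths, timestamps=timestamps, intensities=noisy
    )
    truth = CwsTruth(
        timestamps=timestamps,
        concentration=conc,
        period_s=config.vasomotion.period_s if config.vasomotion.enabled else None,
        modulation_depth=(
            config.vasomotion.modulation_depth if config.vasomotion.enabled else 0.0
        ),
        od450_baseline=beer_lambert_od(
            table[450.0].eps_oxy, config.tissue_path_cm, config.tissue_hb_mm
        ),
    )
    return rec, truth


@dataclass
class CohortRecord:
    """One field of view at one imaging period of the simulated cohort."""

    group_label: str
    animal_id: str
    fov_id: str
    imaging_period: int
    spectral: SpectralRecording
    spectral_truth: CwsTruth
    video: FrameSequence | None = None
    video_truth: VideoTruth | None = None
    oscillatory: bool = False
    vasomotion_period_s: float | None = None


def generate_cohort(
    n_per_group: int = 5,
    fovs_per_animal: int = 8,
    seed: int = 0,
    *,
    template: SimulationConfig | None = None,
    include_video: bool = False,
    video_template: SimulationConfig | None = None,
    nonoscillatory_fraction: float = 0.25,
    period_range_s: tuple[float, float] = (16.0, 32.0),
    modulation_depth: float = 0.05,
) -> list[CohortRecord]:
    """Simulate a two-group, three-period imaging study.

    Control fields of view never oscillate.  In the peritonitis (FIP) group,
    vasomotion switches on from imaging period 2 onward with a per-FOV
    period drawn uniformly in ``period_range_s``; a fraction of FIP fields
    is left non-oscillatory, matching the observed spatial heterogeneity of
    microvascular dysfunction.  Videos are optional because spectroscopy
    alone carries the hemoglobin-oscillation endpoint and is far cheaper to
    render.
    """
    if n_per_group < 1 or fovs_per_animal < 1:
        raise ValueError("counts must be >= 1")
    template = template or SimulationConfig()
    rng = np.random.default_rng([seed, 99])
    records: list[CohortRecord] = []
    for group in ("control", "FIP"):
        for a in range(1, n_per_group + 1):
            animal_id = f"{group}_rat{a}"
            for f in range(1, fovs_per_animal + 1):
                fov_id = f"{animal_id}_fov{f}"
                oscillatory = group == "FIP" and rng.random() >= nonoscillatory_fraction
                period = float(rng.uniform(*period_range_s))
                phase = float(rng.uniform(0.0, 2.0 * np.pi))
                for imaging_period in (1, 2, 3):
                    child_seed = int(rng.integers(0, 2**31 - 1))
                    vaso = VasomotionParams(
                        enabled=oscillatory and imaging_period >= 2,
                        period_s=period,
                        modulation_depth=modulation_depth,
                        phase_rad=phase,
                    )
                    cfg = replace(template, seed=child_seed, vasomotion=vaso)
                    rec, truth = generate_cws_recording(cfg)
                    rec.fov_id = fov_id
                    rec.group_label = group
                    rec.imaging_period = imaging_period
                    video = video_truth = None
                    if include_video:
                        vcfg = replace(
                            video_template or template, seed=child_seed, vasomotion=vaso
                        )
                        video, video_truth = generate_capillary_video(vcfg)
                        video.fov_id = fov_id
                        video.group_label = group
                        video.imaging_period = imaging_period
                    records.append(
                        CohortRecord(
                            group_label=group,
                            animal_id=animal_id,
                            fov_id=fov_id,
                            imaging_period=imaging_period,
                            spectral=rec,
                            spectral_truth=truth,
                            video=video,
                            video_truth=video_truth,
                            oscillatory=oscillatory,
                            vasomotion_period_s=period if oscillatory else None,
                        )
                    )
    return records
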