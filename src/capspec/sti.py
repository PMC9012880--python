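"""Space-time image (kymograph) analysis of capillary red-cell flow.

A space-time image (STI) is built by sampling the video intensity along a
capillary centerline at equal arc-length steps, one column per frame.
Moving red cells appear as dark sloped tracts against the bright plasma
gaps; the tract slope encodes velocity, the tract count per column encodes
lineal density, and the tract optical density at the two wavelengths gives
the red cell's oxygen saturation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label

from .imaging import CalibrationConstants, FrameSequence, rbc_so2

logger = logging.getLogger(__name__)


@dataclass
class CapillarySegment:
    """An ordered centerline polyline, arteriolar end first (pixel coords)."""

    capillary_id: str
    centerline: np.ndarray
    fov_id: str = "fov0"

    def __post_init__(self) -> None:
        self.centerline = np.asarray(self.centerline, dtype=float)
        if self.centerline.ndim != 2 or self.centerline.shape[0] < 2:
            raise ValueError("centerline needs >= 2 points")

    def arc_length_px(self) -> float:
        seg = np.diff(self.centerline, axis=0)
        return float(np.hypot(seg[:, 0], seg[:, 1]).sum())

    def length_um(self, pixel_size: float) -> float:
        return self.arc_length_px() * pixel_size


@dataclass
class SpaceTimeImage:
    """Position x time intensity matrix for one capillary at one wavelength."""

    matrix: np.ndarray
    position_step: float  # um per row
    time_step: float  # s per column
    wavelength: float
    capillary_id: str = "cap0"
    fov_id: str = "fov0"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("STI matrix must be 2-D (position x time)")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("STI matrix must be finite")

    @property
    def n_positions(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_frames(self) -> int:
        return self.matrix.shape[1]


@dataclass
class TractSegmentation:
    """Binary tract mask, connected-component labels and incident surface."""

    mask: np.ndarray
    labels: np.ndarray
    incident: np.ndarray
    n_tracts: int


@dataclass
class CapillaryDynamics:
    """Per-frame hemodynamics of one capillary plus per-tract saturations."""

    timestamps: np.ndarray
    velocity: np.ndarray  # um/s, signed, 0 = stopped
    lineal_density: np.ndarray  # RBC/mm
    hematocrit: np.ndarray  # %
    supply_rate: np.ndarray  # RBC/s
    tracts: pd.DataFrame = field(default_factory=pd.DataFrame)
    capillary_id: str = "cap0"
    fov_id: str = "fov0"


def build_sti(
    seq: FrameSequence,
    segment: CapillarySegment,
    wavelength: float,
    position_step: float | None = None,
) -> SpaceTimeImage:
    """Sample the frame stack along the centerline into an STI.

    Each column is the bilinear interpolation of one frame at equal
    arc-length steps along the centerline (default step = one pixel);
    position 0 is the arteriolar end.
    """
    if wavelength not in seq.frames:
        raise KeyError(f"wavelength {wavelength} nm not in sequence")
    stack = seq.frames[wavelength]
    _, h, w = stack.shape
    cl = segment.centerline
    if cl[:, 0].min() < 0 or cl[:, 0].max() > w - 1 or cl[:, 1].min() < 0 or cl[:, 1].max() > h - 1:
        raise ValueError(f"centerline of {segment.capillary_id} outside frame bounds")

    step = position_step if position_step is not None else seq.pixel_size
    length_um = segment.length_um(seq.pixel_size)
    n_rows = int(np.ceil(length_um / step))

    seg_vec = np.diff(cl, axis=0)
    seg_len = np.hypot(seg_vec[:, 0], seg_vec[:, 1])
    cum_um = np.concatenate([[0.0], np.cumsum(seg_len)]) * seq.pixel_size
    s = np.arange(n_rows) * step
    xs = np.interp(s, cum_um, cl[:, 0])
    ys = np.interp(s, cum_um, cl[:, 1])

    n_frames = stack.shape[0]
    t_idx = np.repeat(np.arange(n_frames), n_rows)
    coords = np.stack(
        [t_idx, np.tile(ys, n_frames), np.tile(xs, n_frames)], axis=0
    )
    sampled = ndi.map_coordinates(
        stack.astype(np.float64), coords, order=1, mode="nearest"
    ).reshape(n_frames, n_rows)

    return SpaceTimeImage(
        matrix=sampled.T,
        position_step=step,
        time_step=float(np.median(np.diff(seq.timestamps))),
        wavelength=wavelength,
        capillary_id=segment.capillary_id,
        fov_id=segment.fov_id,
    )


def _block_percentile_surface(
    matrix: np.ndarray, block_rows: int, block_cols: int, q: float
) -> np.ndarray:
    """Percentile of non-overlapping blocks, bilinearly interpolated back."""
    p, t = matrix.shape
    br = max(min(block_rows, p), 1)
    bc = max(min(block_cols, t), 1)
    n_br = int(np.ceil(p / br))
    n_bc = int(np.ceil(t / bc))
    pad_r = n_br * br - p
    pad_c = n_bc * bc - t
    padded = np.pad(matrix, ((0, pad_r), (0, pad_c)), mode="edge")
    blocks = padded.reshape(n_br, br, n_bc, bc)
    coarse = np.percentile(blocks, q, axis=(1, 3))
    # block-center coordinates, then separable linear interpolation
    rc = (np.arange(n_br) + 0.5) * br - 0.5
    cc = (np.arange(n_bc) + 0.5) * bc - 0.5
    rows = np.arange(p)
    cols = np.arange(t)
    tmp = np.empty((n_br, t))
    for i in range(n_br):
        tmp[i] = np.interp(cols, cc, coarse[i])
    out = np.empty((p, t))
    for j in range(t):
        out[:, j] = np.interp(rows, rc, tmp[:, j])
    return out


def segment_tracts(
    sti: SpaceTimeImage,
    *,
    incident_percentile: float = 90.0,
    incident_window_s: float = 1.0,
    incident_window_um: float = 10.0,
    min_contrast: float = 0.03,
    min_tract_px: int = 5,
) -> TractSegmentation:
    """Separate dark red-cell tracts from bright plasma gaps.

    The incident intensity surface I0 is estimated as a high percentile of
    the local intensity (plasma gaps are the brightest structures within a
    ~1 s x ~10 um neighborhood); the STI is divided by I0 and thresholded
    with Otsu's method.  Low-contrast STIs (no discernible tracts) yield an
    empty mask with a warning.
    """
    if sti.n_frames < 10:
        raise ValueError("STI must have at least 10 columns (frames)")
    block_rows = max(int(round(incident_window_um / sti.position_step)), 1)
    block_cols = max(int(round(incident_window_s / sti.time_step)), 1)
    incident = _block_percentile_surface(
        sti.matrix, block_rows, block_cols, incident_percentile
    )
    incident = np.clip(incident, 1e-9, None)
    ratio = sti.matrix / incident

    lo, hi = np.percentile(ratio, [1, 99])
    if hi - lo < min_contrast:
        warnings.warn(
            "STI has no intensity contrast: no tracts segmented", stacklevel=2
        )
        mask = np.zeros_like(ratio, dtype=bool)
        return TractSegmentation(mask, np.zeros_like(ratio, dtype=int), incident, 0)

    thr = threshold_otsu(ratio)
    mask = ratio < thr
    if min_tract_px > 1:
        lab = cc_label(mask, connectivity=2)
        areas = np.bincount(lab.ravel())
        mask &= areas[lab] >= min_tract_px
    if mask.all():
        warnings.warn("STI is entirely dark: full tract mask", stacklevel=2)
    labels = cc_label(mask, connectivity=2)
    return TractSegmentation(mask, labels, incident, int(labels.max()))


def label_tracts(
    mask: np.ndarray, displacement_px: np.ndarray | None = None
) -> tuple[np.ndarray, int]:
    """Connected-component tract labels, compensating for red-cell motion.

    A red cell moving faster than one position step per frame leaves mask
    segments that are disconnected between columns.  Shearing each column by
    the integrated displacement (rounded to pixels) makes each cell's tract
    approximately horizontal, where plain connectivity links it; labels are
    then mapped back to STI coordinates.  With no displacement given the
    mask is labelled as-is.
    """
    if displacement_px is None or mask.size == 0 or not mask.any():
        labels = cc_label(mask, connectivity=2)
        return labels, int(labels.max())
    p, t = mask.shape
    shift = np.round(np.asarray(displacement_px, dtype=float)).astype(int)
    if shift.size != t:
        raise ValueError("displacement must have one value per STI column")
    pad = int(np.abs(shift).max()) + 1
    sheared = np.zeros((p + 2 * pad, t), dtype=bool)
    rows = np.arange(p)
    for j in range(t):
        sheared[rows - shift[j] + pad, j] = mask[:, j]
    lab_sheared = cc_label(sheared, connectivity=2)
    labels = np.zeros_like(mask, dtype=int)
    for j in range(t):
        labels[:, j] = lab_sheared[rows - shift[j] + pad, j]
    # relabel contiguously
    uniq = np.unique(labels)
    remap = np.zeros(uniq.max() + 1, dtype=int)
    remap[uniq[uniq > 0]] = np.arange(1, (uniq > 0).sum() + 1)
    return remap[labels], int((uniq > 0).sum())


def tract_od(sti: SpaceTimeImage, seg: TractSegmentation) -> pd.DataFrame:
    """Optical density of each tract: ``OD = log10(I0 / I_RBC)``.

    ``I_RBC`` is the mean intensity over the tract pixels and ``I0`` the
    mean incident (plasma-gap) intensity over the same pixels.  Returns a
    DataFrame with one row per tract: tract_id, time_s, position_um, od.
    """
    if seg.n_tracts == 0:
        raise ValueError("tract mask is empty")
    if np.any(sti.matrix[seg.mask] <= 0):
        raise ValueError("nonpositive tract intensities")
    rows = []
    cols_idx = np.arange(sti.n_frames)
    pos_idx = np.arange(sti.n_positions)
    for lab in range(1, seg.n_tracts + 1):
        m = seg.labels == lab
        i_rbc = sti.matrix[m].mean()
        i_0 = seg.incident[m].mean()
        t_center = (m.sum(axis=0) * cols_idx).sum() / m.sum()
        p_center = (m.sum(axis=1) * pos_idx).sum() / m.sum()
        rows.append(
            {
                "tract_id": lab,
                "time_s": t_center * sti.time_step,
                "position_um": p_center * sti.position_step,
                "od": float(np.log10(i_0 / i_rbc)),
                "n_px": int(m.sum()),
            }
        )
    return pd.DataFrame(rows)


def _shear_scores(window: np.ndarray, slopes: np.ndarray) -> np.ndarray:
    """Variance of the shear projection for each candidate slope.

    ``window`` is (positions x frames); slope is in rows per column.  For
    the true tract slope, shearing aligns the tract into few projection
    bins, maximizing the variance of the projected profile.
    """
    p, t = window.shape
    jc = np.arange(t) - (t - 1) / 2.0
    shifts = slopes[:, None] * jc[None, :]  # (A, T)
    pos = np.arange(p)[None, :, None] + shifts[:, None, :]  # (A, P, T)
    base = np.floor(pos).astype(np.int64)
    frac = pos - base
    w0 = np.where((base >= 0) & (base < p), 1.0 - frac, 0.0)
    w1 = np.where((base + 1 >= 0) & (base + 1 < p), frac, 0.0)
    b0 = np.clip(base, 0, p - 1)
    b1 = np.clip(base + 1, 0, p - 1)
    cols = np.broadcast_to(np.arange(t)[None, None, :], pos.shape)
    proj_sum = (window[b0, cols] * w0 + window[b1, cols] * w1).sum(axis=2)  # (A, P)
    count = (w0 + w1).sum(axis=2)  # (A, P) in-bounds weight per projection bin
    # count-weighted variance of the mean projection: removes the bias of
    # zero padding against steep slopes, where most samples leave the window
    ok = count > 0.5
    mean_bin = np.where(ok, proj_sum / np.maximum(count, 1e-12), 0.0)
    wsum = np.where(ok, count, 0.0)
    total_w = wsum.sum(axis=1)
    grand = (wsum * mean_bin).sum(axis=1) / np.maximum(total_w, 1e-12)
    var_w = (wsum * (mean_bin - grand[:, None]) ** 2).sum(axis=1) / np.maximum(
        total_w, 1e-12
    )
    return var_w


def _xcorr_displacement(window: np.ndarray) -> float:
    """Mean column-to-column displacement (rows per column) by cross-correlation.

    Cross-correlations of all adjacent column pairs are accumulated in the
    Fourier domain (zero-padded, so no circular wrap) and the peak of the
    summed correlogram gives the dominant per-frame displacement, with
    parabolic sub-pixel interpolation.  Ties prefer the smaller |shift|.
    """
    p, t = window.shape
    cols = window - window.mean(axis=0, keepdims=True)
    n = 2 * p
    spec = np.fft.rfft(cols, n=n, axis=0)
    cross = (spec[:, 1:] * np.conj(spec[:, :-1])).sum(axis=1)
    corr = np.fft.irfft(cross, n=n)
    # lag d means column j+1 is column j shifted by +d rows
    lags = np.concatenate([np.arange(0, p), np.arange(-p, 0)])
    order = np.argsort(lags)
    lags = lags[order]
    corr = corr[order]
    peak_val = corr.max()
    candidates = np.flatnonzero(corr >= peak_val * (1.0 - 1e-12))
    k = candidates[np.argmin(np.abs(lags[candidates]))]
    d = float(lags[k])
    if 0 < k < corr.size - 1:
        denom = corr[k - 1] - 2.0 * corr[k] + corr[k + 1]
        if denom < 0:
            d += 0.5 * float(corr[k - 1] - corr[k + 1]) / float(denom)
    return d


def estimate_velocity(
    sti: SpaceTimeImage,
    seg: TractSegmentation,
    *,
    window_s: float = 0.5,
    refine: bool = True,
    refine_halfwidth_px: float = 0.5,
    refine_points: int = 21,
    stop_threshold_um_s: float = 10.0,
    stop_displacement_px: float = 2.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Signed red-cell velocity per analysis window (um/s).

    The dominant tract orientation in each non-overlapping window of the
    masked absorbance STI is found in two stages: adjacent-column
    cross-correlation gives the displacement in rows per column at sub-pixel
    precision, then (optionally) a narrow orientation search maximizing the
    variance of the shear projection (Radon-style) refines it.  The slope
    converts to velocity via position_step / time_step.  Positive velocity
    is arteriolar-to-venular; windows with no tracts, or sub-threshold speed
    with no tract displacement, are assigned exactly 0 (stopped).  Returns
    ``(window_center_times, velocities)``.
    """
    n_t = max(int(round(window_s / sti.time_step)), 3)
    if sti.n_frames < n_t:
        raise ValueError("STI shorter than one analysis window")
    absorb = np.clip(1.0 - sti.matrix / seg.incident, 0.0, None) * seg.mask

    px_per_frame_to_um_s = sti.position_step / sti.time_step

    centers, vels = [], []
    for start in range(0, sti.n_frames - n_t + 1, n_t):
        win = absorb[:, start : start + n_t]
        centers.append((start + (n_t - 1) / 2.0) * sti.time_step)
        if not np.any(win > 0):
            vels.append(0.0)
            continue
        d = _xcorr_displacement(win)
        if refine:
            slopes = d + np.linspace(
                -refine_halfwidth_px, refine_halfwidth_px, refine_points
            )
            scores = _shear_scores(win, slopes)
            top = scores.max()
            near = np.flatnonzero(scores >= top * (1.0 - 1e-12))
            d = float(slopes[near[np.argmin(np.abs(slopes[near]))]])
        v = float(d * px_per_frame_to_um_s)
        if abs(v) < stop_threshold_um_s:
            third = max(n_t // 3, 1)
            w_first = win[:, :third].sum(axis=1)
            w_last = win[:, -third:].sum(axis=1)
            pos = np.arange(sti.n_positions)
            if w_first.sum() > 0 and w_last.sum() > 0:
                c0 = (pos * w_first).sum() / w_first.sum()
                c1 = (pos * w_last).sum() / w_last.sum()
                if abs(c1 - c0) < stop_displacement_px:
                    v = 0.0
            else:
                v = 0.0
        vels.append(v)
    return np.asarray(centers), np.asarray(vels)


def window_series_to_frames(
    centers: np.ndarray, values: np.ndarray, timestamps: np.ndarray
) -> np.ndarray:
    """Expand per-window values to per-frame by nearest-window assignment."""
    centers = np.asarray(centers, dtype=float)
    values = np.asarray(values, dtype=float)
    t = np.asarray(timestamps, dtype=float) - timestamps[0]
    idx = np.clip(np.searchsorted(centers, t), 1, centers.size - 1)
    nearer_left = np.abs(t - centers[idx - 1]) <= np.abs(t - centers[idx])
    idx = np.where(nearer_left, idx - 1, idx)
    return values[idx]


def lineal_density(seg: TractSegmentation, segment_length_mm: float) -> np.ndarray:
    """Red cells per mm of capillary, per time column.

    Each maximal vertical run of masked pixels in a column is one red cell
    crossing that instant (partial tracts at the segment ends count).
    """
    if segment_length_mm <= 0:
        raise ValueError("segment length must be positive")
    mask = seg.mask
    rising = mask & ~np.vstack([np.zeros((1, mask.shape[1]), dtype=bool), mask[:-1]])
    return rising.sum(axis=0) / segment_length_mm


def hematocrit_from_density(
    ld, rbc_volume_fl: float = 55.0, capillary_diameter_um: float = 5.0
):
    """Tube hematocrit (%) from lineal density.

    ``Hct = 100 * LD(RBC/mm) * V_rbc(um^3) / (pi (d/2)^2 * 1000 um)`` -- the
    red-cell volume per mm of vessel over the lumen volume per mm.  Defaults
    (rat red-cell volume 55 fL, 5-um capillary) are configurable.
    """
    if capillary_diameter_um <= 0:
        raise ValueError("capillary diameter must be positive")
    ld = np.asarray(ld, dtype=float)
    lumen_um3_per_mm = np.pi * (capillary_diameter_um / 2.0) ** 2 * 1000.0
    out = 100.0 * ld * rbc_volume_fl / lumen_um3_per_mm
    return float(out) if out.ndim == 0 else out


def supply_rate(velocity, ld):
    """Red-cell supply rate (RBC/s) = |v| x lineal density / 1000; 0 if stopped."""
    velocity = np.asarray(velocity, dtype=float)
    ld = np.asarray(ld, dtype=float)
    sr = np.abs(velocity) * ld / 1000.0
    sr = np.where(velocity == 0.0, 0.0, sr)
    return float(sr) if sr.ndim == 0 else sr


def tract_so2(
    od438: pd.DataFrame,
    od450: pd.DataFrame,
    calib: CalibrationConstants | None = None,
) -> pd.DataFrame:
    """Per-tract oxygen saturation from ODs at the two wavelengths.

    Tracts are matched by tract_id (the two STIs share the 450-nm tract
    mask, so labels coincide); unmatched or zero-OD tracts are skipped with
    a log message.
    """
    calib = calib or CalibrationConstants()
    merged = od438.merge(od450, on="tract_id", suffixes=("_438", "_450"))
    skipped = len(od438) + len(od450) - 2 * len(merged)
    if skipped:
        logger.info("tract_so2: %d unmatched tracts skipped", skipped)
    ok = merged["od_450"] > 0
    if (~ok).any():
        logger.info("tract_so2: %d tracts with nonpositive 450-nm OD skipped", int((~ok).sum()))
        merged = merged[ok]
    so2 = rbc_so2(merged["od_438"].to_numpy(), merged["od_450"].to_numpy(), calib)
    return pd.DataFrame(
        {
            "tract_id": merged["tract_id"].to_numpy(),
            "time_s": merged["time_s_450"].to_numpy(),
            "so2": np.atleast_1d(so2),
        }
    )


def analyze_capillary(
    seq: FrameSequence,
    segment: CapillarySegment,
    *,
    calib: CalibrationConstants | None = None,
    window_s: float = 0.5,
    oxy_wavelength: float = 438.0,
    iso_wavelength: float = 450.0,
    rbc_volume_fl: float = 55.0,
    capillary_diameter_um: float = 5.0,
) -> CapillaryDynamics:
    """Full per-capillary pipeline: STI -> tracts -> v, LD, Hct, SR, SO2."""
    sti450 = build_sti(seq, segment, iso_wavelength)
    seg450 = segment_tracts(sti450)
    length_mm = segment.length_um(seq.pixel_size) / 1000.0

    centers, v_win = estimate_velocity(sti450, seg450, window_s=window_s)
    v = window_series_to_frames(centers, v_win, seq.timestamps)
    ld = lineal_density(seg450, length_mm)
    hct = hematocrit_from_density(ld, rbc_volume_fl, capillary_diameter_um)
    sr = supply_rate(v, ld)

    # relabel tracts compensating for the estimated motion
    dt = float(np.median(np.diff(seq.timestamps)))
    disp_px = np.concatenate([[0.0], np.cumsum(v[:-1] * dt)]) / sti450.position_step
    labels, n_tracts = label_tracts(seg450.mask, disp_px)
    seg450 = TractSegmentation(seg450.mask, labels, seg450.incident, n_tracts)

    tracts = pd.DataFrame()
    if seg450.n_tracts > 0 and oxy_wavelength in seq.frames:
        sti438 = build_sti(seq, segment, oxy_wavelength)
        seg438_on450 = TractSegmentation(
            mask=seg450.mask,
            labels=seg450.labels,
            incident=_block_percentile_surface(
                sti438.matrix,
                max(int(round(10.0 / sti438.position_step)), 1),
                max(int(round(1.0 / sti438.time_step)), 1),
                90.0,
            ),
            n_tracts=seg450.n_tracts,
        )
        od450_df = tract_od(sti450, seg450)
        od438_df = tract_od(sti438, seg438_on450)
        tracts = tract_so2(od438_df, od450_df, calib)

    return CapillaryDynamics(
        timestamps=seq.timestamps,
        velocity=v,
        lineal_density=ld,
        hematocrit=hct,
        supply_rate=sr,
        tracts=tracts,
        capillary_id=segment.capillary_id,
        fov_id=segment.fov_id,
    )
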