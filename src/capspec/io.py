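"""Readers and writers for the on-disk interchange formats.

Frame input is either a directory of per-frame PNG files (one file per frame
per wavelength, ``<fov>_<wavelength>nm_<frameindex>.png`` with a zero-padded
0-based index) plus a small YAML sidecar with the acquisition metadata, or a
multi-page TIFF per wavelength.  Spectroscopy tables are CSV with a
``time_s`` column and one column per wavelength in nm.  Centerlines are a
JSON list of ``{capillary_id, points: [[x, y], ...]}`` per field of view.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
import yaml

from .imaging import FrameSequence, ODTimeSeries, SpectralRecording
from .sti import CapillaryDynamics, CapillarySegment

_PNG_RE = re.compile(r"^(?P<fov>.+)_(?P<wl>[0-9.]+)nm_(?P<idx>\d+)\.png$")


def write_frames_png(seq: FrameSequence, directory: str | Path) -> Path:
    """Write one 16-bit PNG per frame per wavelength plus a metadata sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    n = seq.timestamps.size
    width = max(len(str(n - 1)), 4)
    for wl, stack in seq.frames.items():
        for k in range(n):
            name = f"{seq.fov_id}_{wl:g}nm_{k:0{width}d}.png"
            iio.imwrite(directory / name, stack[k].astype(np.uint16))
    meta = {
        "fov_id": seq.fov_id,
        "pixel_size_um": float(seq.pixel_size),
        "bit_depth": int(seq.bit_depth),
        "frame_rate_hz": float(seq.frame_rate),
        "group_label": seq.group_label,
        "imaging_period": int(seq.imaging_period),
        "n_frames": int(n),
        "wavelengths_nm": [float(w) for w in seq.wavelengths],
    }
    (directory / f"{seq.fov_id}_meta.yaml").write_text(yaml.safe_dump(meta))
    return directory


def read_frames_png(directory: str | Path, fov_id: str | None = None) -> FrameSequence:
    """Rebuild a FrameSequence from a per-frame PNG directory."""
    directory = Path(directory)
    metas = sorted(directory.glob("*_meta.yaml"))
    if not metas:
        raise FileNotFoundError(f"no *_meta.yaml sidecar in {directory}")
    if fov_id is not None:
        metas = [m for m in metas if m.name == f"{fov_id}_meta.yaml"]
        if not metas:
            raise FileNotFoundError(f"no metadata for fov {fov_id!r}")
    meta = yaml.safe_load(metas[0].read_text())
    fov = meta["fov_id"]

    by_wl: dict[float, dict[int, Path]] = {}
    for f in directory.glob(f"{fov}_*nm_*.png"):
        m = _PNG_RE.match(f.name)
        if not m or m.group("fov") != fov:
            continue
        by_wl.setdefault(float(m.group("wl")), {})[int(m.group("idx"))] = f
    if not by_wl:
        raise FileNotFoundError(f"no frames for fov {fov!r} in {directory}")
    frames = {}
    for wl, files in by_wl.items():
        idxs = sorted(files)
        if idxs != list(range(len(idxs))):
            raise ValueError(f"frame indices for {wl} nm are not contiguous from 0")
        frames[wl] = np.stack([iio.imread(files[i]) for i in idxs])
    n = meta["n_frames"]
    timestamps = np.arange(n) / meta["frame_rate_hz"]
    return FrameSequence(
        frames=frames,
        timestamps=timestamps,
        pixel_size=meta["pixel_size_um"],
        bit_depth=meta["bit_depth"],
        fov_id=fov,
        group_label=meta.get("group_label", "control"),
        imaging_period=meta.get("imaging_period", 1),
    )


def write_frames_tiff(seq: FrameSequence, directory: str | Path) -> Path:
    """One multi-page TIFF per wavelength plus the YAML sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for wl, stack in seq.frames.items():
        tifffile.imwrite(
            directory / f"{seq.fov_id}_{wl:g}nm.tiff", stack.astype(np.uint16)
        )
    meta = {
        "fov_id": seq.fov_id,
        "pixel_size_um": float(seq.pixel_size),
        "bit_depth": int(seq.bit_depth),
        "frame_rate_hz": float(seq.frame_rate),
        "group_label": seq.group_label,
        "imaging_period": int(seq.imaging_period),
        "n_frames": int(seq.timestamps.size),
        "wavelengths_nm": [float(w) for w in seq.wavelengths],
    }
    (directory / f"{seq.fov_id}_meta.yaml").write_text(yaml.safe_dump(meta))
    return directory


def read_frames_tiff(directory: str | Path, fov_id: str | None = None) -> FrameSequence:
    directory = Path(directory)
    metas = sorted(directory.glob("*_meta.yaml"))
    if fov_id is not None:
        metas = [m for m in metas if m.name == f"{fov_id}_meta.yaml"]
    if not metas:
        raise FileNotFoundError(f"no metadata sidecar in {directory}")
    meta = yaml.safe_load(metas[0].read_text())
    fov = meta["fov_id"]
    frames = {}
    for wl in meta["wavelengths_nm"]:
        frames[float(wl)] = tifffile.imread(directory / f"{fov}_{wl:g}nm.tiff")
    timestamps = np.arange(meta["n_frames"]) / meta["frame_rate_hz"]
    return FrameSequence(
        frames=frames,
        timestamps=timestamps,
        pixel_size=meta["pixel_size_um"],
        bit_depth=meta["bit_depth"],
        fov_id=fov,
        group_label=meta.get("group_label", "control"),
        imaging_period=meta.get("imaging_period", 1),
    )


def write_spectral_csv(rec: SpectralRecording, path: str | Path) -> Path:
    """CSV: first column time_s, remaining columns named by wavelength (nm)."""
    path = Path(path)
    df = pd.DataFrame(rec.intensities.T, columns=[f"{w:.1f}" for w in rec.wavelengths])
    df.insert(0, "time_s", rec.timestamps)
    df.to_csv(path, index=False)
    return path


def read_spectral_csv(
    path: str | Path,
    fov_id: str = "fov0",
    group_label: str = "control",
    imaging_period: int = 1,
) -> SpectralRecording:
    df = pd.read_csv(path)
    if df.columns[0] != "time_s":
        raise ValueError("first column of a spectral CSV must be time_s")
    wavelengths = np.array([float(c) for c in df.columns[1:]])
    return SpectralRecording(
        wavelengths=wavelengths,
        timestamps=df["time_s"].to_numpy(),
        intensities=df.iloc[:, 1:].to_numpy().T,
        fov_id=fov_id,
        group_label=group_label,
        imaging_period=imaging_period,
    )


def write_od_csv(series: ODTimeSeries, path: str | Path) -> Path:
    pd.DataFrame(
        {
            "time_s": series.timestamps,
            "delta_od": series.delta_od,
            "source": series.source,
            "fov_id": series.fov_id,
        }
    ).to_csv(path, index=False)
    return Path(path)


def write_centerlines_json(segments: list[CapillarySegment], path: str | Path) -> Path:
    payload = [
        {"capillary_id": s.capillary_id, "points": s.centerline.tolist()}
        for s in segments
    ]
    Path(path).write_text(json.dumps(payload, indent=1))
    return Path(path)


def read_centerlines_json(path: str | Path, fov_id: str = "fov0") -> list[CapillarySegment]:
    payload = json.loads(Path(path).read_text())
    return [
        CapillarySegment(
            capillary_id=item["capillary_id"],
            centerline=np.asarray(item["points"], dtype=float),
            fov_id=fov_id,
        )
        for item in payload
    ]


def write_dynamics_csv(dyn: CapillaryDynamics, path: str | Path) -> Path:
    pd.DataFrame(
        {
            "time_s": dyn.timestamps,
            "velocity_um_s": dyn.velocity,
            "lineal_density_rbc_mm": dyn.lineal_density,
            "hematocrit_pct": dyn.hematocrit,
            "supply_rate_rbc_s": dyn.supply_rate,
        }
    ).to_csv(path, index=False)
    return Path(path)


def write_tract_so2_csv(dyn: CapillaryDynamics, path: str | Path) -> Path:
    cols = ["tract_id", "time_s", "so2"]
    df = dyn.tracts[cols] if len(dyn.tracts) else pd.DataFrame(columns=cols)
    df.to_csv(path, index=False)
    return Path(path)
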