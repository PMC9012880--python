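"""Capillary flow-state classification and functional capillary density.

Flow through each capillary is classified over a 30-s window as continuous,
intermittent (at least one stop strictly longer than 3 s, or a reversal) or
completely stopped.  Functional capillary density (FCD) counts perfused
capillaries crossing three horizontal test lines across the field of view,
normalized by line length.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .sti import CapillaryDynamics


@dataclass(frozen=True)
class FlowState:
    value: str  # continuous | intermittent | stopped
    window_start: float
    window_length: float = 30.0
    capillary_id: str = "cap0"

    def __post_init__(self) -> None:
        if self.value not in ("continuous", "intermittent", "stopped"):
            raise ValueError(f"unknown flow state {self.value!r}")


@dataclass
class FieldOfViewMetrics:
    fov_id: str
    fcd_per_mm: float
    n_continuous: int
    n_intermittent: int
    n_stopped: int
    group_label: str = "control"
    imaging_period: int = 1


def _zero_runs(v: np.ndarray, t: np.ndarray) -> list[float]:
    """Durations (s) of maximal runs of exactly-zero velocity, linear time."""
    zero = v == 0.0
    runs = []
    start = None
    dt = np.median(np.diff(t)) if t.size > 1 else 0.0
    for i, z in enumerate(zero):
        if z and start is None:
            start = i
        elif not z and start is not None:
            runs.append(t[i] - t[start])
            start = None
    if start is not None:
        runs.append(t[-1] - t[start] + dt)
    return runs


def _has_sustained_reversal(v: np.ndarray, t: np.ndarray, min_duration: float) -> bool:
    """True if both flow signs are sustained for at least ``min_duration``."""

    def longest_run(sign: int) -> float:
        m = np.sign(v) == sign
        best = 0.0
        start = None
        dt = np.median(np.diff(t)) if t.size > 1 else 0.0
        for i, z in enumerate(m):
            if z and start is None:
                start = i
            elif not z and start is not None:
                best = max(best, t[i] - t[start])
                start = None
        if start is not None:
            best = max(best, t[-1] - t[start] + dt)
        return best

    return longest_run(1) >= min_duration and longest_run(-1) >= min_duration


def classify_flow(
    dynamics: CapillaryDynamics,
    window_start: float = 0.0,
    *,
    window_length: float = 30.0,
    stop_rule_s: float = 3.0,
    reversal_min_s: float = 0.5,
) -> FlowState:
    """Classify flow within ``[window_start, window_start + window_length]``.

    Stopped: velocity is 0 for the whole window.  Intermittent: at least one
    maximal zero-velocity run strictly longer than ``stop_rule_s`` (an exact
    3.0-s stop does not qualify), or a reversal in which each flow direction
    is sustained for at least ``reversal_min_s``.  Otherwise continuous.
    """
    t = dynamics.timestamps
    v = dynamics.velocity
    end = window_start + window_length
    eps = 1e-9
    if t[0] > window_start + eps or t[-1] < end - 1.0 / max(len(t), 1) - eps:
        raise ValueError(
            f"dynamics cover [{t[0]:.2f}, {t[-1]:.2f}] s, not the requested "
            f"[{window_start:.2f}, {end:.2f}] s window"
        )
    sel = (t >= window_start - eps) & (t <= end + eps)
    tw, vw = t[sel], v[sel]

    if np.all(vw == 0.0):
        return FlowState("stopped", window_start, window_length, dynamics.capillary_id)
    if any(run > stop_rule_s for run in _zero_runs(vw, tw)):
        return FlowState(
            "intermittent", window_start, window_length, dynamics.capillary_id
        )
    if _has_sustained_reversal(vw, tw, reversal_min_s):
        return FlowState(
            "intermittent", window_start, window_length, dynamics.capillary_id
        )
    return FlowState("continuous", window_start, window_length, dynamics.capillary_id)


def functional_capillary_density(crossings: int, fov_width_um: float = 450.0) -> float:
    """Capillaries per mm from test-line crossing counts.

    ``FCD = crossings / (3 * fov_width_mm)`` -- three horizontal lines, each
    spanning the full field-of-view width; a capillary crossing two lines
    contributes two crossings.
    """
    if fov_width_um <= 0:
        raise ValueError("field-of-view width must be positive")
    if crossings < 0:
        raise ValueError("crossing count must be nonnegative")
    return crossings / (3.0 * fov_width_um / 1000.0)


def count_line_crossings(
    centerlines: list[np.ndarray],
    frame_shape: tuple[int, int],
    *,
    line_fractions: tuple[float, ...] = (0.25, 0.5, 0.75),
) -> int:
    """Count capillaries crossing horizontal test lines.

    Lines sit at the given fractions of frame height (defaults: quarter,
    half, three-quarter).  Each capillary counts at most once per line,
    regardless of how many times its polyline wiggles across it.
    """
    h, _ = frame_shape
    total = 0
    for frac in line_fractions:
        y_line = frac * (h - 1)
        for cl in centerlines:
            y = np.asarray(cl, dtype=float)[:, 1]
            if np.any((y[:-1] - y_line) * (y[1:] - y_line) <= 0) and y.min() != y.max():
                total += 1
    return total


def fov_metrics(
    fov_id: str,
    states: list[FlowState],
    crossings: int,
    *,
    fov_width_um: float = 450.0,
    group_label: str = "control",
    imaging_period: int = 1,
) -> FieldOfViewMetrics:
    """Bundle flow-state counts and FCD for one field of view."""
    counts = {"continuous": 0, "intermittent": 0, "stopped": 0}
    for s in states:
        counts[s.value] += 1
    return FieldOfViewMetrics(
        fov_id=fov_id,
        fcd_per_mm=functional_capillary_density(crossings, fov_width_um),
        n_continuous=counts["continuous"],
        n_intermittent=counts["intermittent"],
        n_stopped=counts["stopped"],
        group_label=group_label,
        imaging_period=imaging_period,
    )
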