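"""Pulsed-fluorescence trace preprocessing.

A pulsed-ultrasound release experiment records fluorescence intensity while
sonication alternates ON and OFF; after release saturates, detergent (Triton
X-100) lysis frees all remaining dye, establishing the 100%-release intensity.
This module turns such a raw trace into a continuous cumulative-fractional-
release (CFR) profile:

1. normalize intensity between the pre-sonication baseline mean ``Io`` and the
   post-lysis plateau mean ``I_inf``:  CFR = (It - Io) / (I_inf - Io);
2. "de-step" the pulsed profile by discarding all OFF segments and remapping
   each retained sample to cumulative ultrasound-ON time.

The OFF segments exist only to suppress acoustic heating of the cuvette; the
kinetic models apply to insonation time, so trimming OFF time yields the
continuous curve the fits require.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .exceptions import (
    DegenerateNormalizationError,
    EmptyProfileError,
    MissingBaselineError,
    PlateauNotFoundError,
)

__all__ = [
    "FluorescenceTrace",
    "ReleaseProfile",
    "compute_cfr",
    "detect_plateau",
    "destep",
    "preprocess_trace",
]

_log = logging.getLogger(__name__)

#: Plateau-detection defaults: rolling window (s) and absolute slope
#: tolerance (1/s) on range-normalized intensity.
PLATEAU_WINDOW = 10.0
PLATEAU_SLOPE_TOL = 1e-4


@dataclass
class FluorescenceTrace:
    """Raw timestamped fluorescence intensity from one release run.

    ``cycles`` lists the sonication ON intervals ``(on_start, on_end)`` in
    seconds; everything between consecutive intervals is OFF.  The baseline
    window precedes the first cycle and ``lysis_time`` (Triton addition)
    follows the last.
    """

    time: np.ndarray  # seconds, strictly increasing
    intensity: np.ndarray  # arbitrary fluorescence units
    baseline_window: tuple[float, float]
    cycles: list[tuple[float, float]]
    lysis_time: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.time.shape != self.intensity.shape:
            raise ValueError("time and intensity must have the same length")
        if self.time.size and np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("intensity must be finite everywhere")
        self.cycles = [(float(a), float(b)) for a, b in self.cycles]
        for (a, b) in self.cycles:
            if b <= a:
                raise ValueError(f"empty or inverted cycle ({a}, {b})")
        for (_, b0), (a1, _) in zip(self.cycles, self.cycles[1:]):
            if a1 < b0:
                raise ValueError("cycles must be disjoint and ordered")
        if self.cycles:
            if self.baseline_window[1] > self.cycles[0][0]:
                raise ValueError("baseline window must precede the first cycle")
            if self.lysis_time < self.cycles[-1][1]:
                raise ValueError("lysis must follow the last cycle")


@dataclass
class ReleaseProfile:
    """Continuous CFR versus cumulative ultrasound-ON time for one run."""

    t_us: np.ndarray  # cumulative insonation time, seconds, starts at 0
    cfr: np.ndarray  # dimensionless
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t_us = np.asarray(self.t_us, dtype=float)
        self.cfr = np.asarray(self.cfr, dtype=float)
        if self.t_us.shape != self.cfr.shape:
            raise ValueError("t_us and cfr must have the same length")
        if self.t_us.size and np.any(np.diff(self.t_us) <= 0):
            raise ValueError("t_us must be strictly increasing")

    @property
    def n_points(self) -> int:
        return int(self.t_us.size)


def detect_plateau(
    trace: FluorescenceTrace,
    window: float = PLATEAU_WINDOW,
    slope_tol: float = PLATEAU_SLOPE_TOL,
) -> tuple[float, float]:
    """Find the earliest maximal flat interval after lysis.

    Intensity is range-normalized over the whole trace and a least-squares
    slope is computed in a rolling window of ``window`` seconds starting at
    each post-lysis sample; the plateau is the earliest run of consecutive
    windows whose absolute slope stays below ``slope_tol`` (units 1/s),
    extended to the end of the last flat window.

    Raises :class:`PlateauNotFoundError` when no window qualifies.
    """
    t, y = trace.time, trace.intensity
    if t[-1] - t[0] <= window:
        raise PlateauNotFoundError("trace shorter than the plateau window")
    rng = np.ptp(y)
    y_norm = y / rng if rng > 0 else np.zeros_like(y)

    start_idx = np.searchsorted(t, trace.lysis_time, side="left")
    flat_starts: list[int] = []
    flat_ends: list[int] = []
    for i in range(start_idx, t.size):
        j = np.searchsorted(t, t[i] + window, side="right")
        if j - i < 2:
            break
        if j > t.size:
            break
        tt, yy = t[i:j], y_norm[i:j]
        if tt[-1] - tt[0] < 0.5 * window:
            break  # window runs off the end of the trace
        slope = np.polyfit(tt, yy, 1)[0]
        if abs(slope) < slope_tol:
            flat_starts.append(i)
            flat_ends.append(j - 1)
        elif flat_starts:
            break  # earliest maximal run found
    if not flat_starts:
        raise PlateauNotFoundError(
            f"no post-lysis window of {window} s with |slope| < {slope_tol}/s"
        )
    return float(t[flat_starts[0]]), float(t[flat_ends[-1]])


def compute_cfr(
    trace: FluorescenceTrace,
    baseline_min_samples: int = 5,
    plateau_window: float = PLATEAU_WINDOW,
    plateau_slope_tol: float = PLATEAU_SLOPE_TOL,
    despike: bool = False,
    despike_kernel: int = 5,
) -> np.ndarray:
    """Normalize a trace to CFR on its original time axis.

    ``Io`` is the mean intensity over the baseline window and ``I_inf`` the
    mean over the detected post-lysis plateau (falling back to the final
    ``plateau_window`` seconds with a warning if detection fails).  No
    clipping to [0, 1] is applied; with noise, CFR may slightly exceed those
    bounds and downstream fits decide how to handle that.

    ``despike`` applies an optional moving-median filter (odd ``despike_kernel``
    samples) to intensity before normalization; off by default.
    """
    t, y = trace.time, trace.intensity.copy()
    if despike:
        from scipy.ndimage import median_filter

        y = median_filter(y, size=despike_kernel, mode="nearest")

    # half-open like the ON intervals: a sample at the exact baseline end
    # (typically the first ON transition) is not part of the baseline
    b0, b1 = trace.baseline_window
    base = (t >= b0) & (t < b1)
    if base.sum() < baseline_min_samples:
        raise MissingBaselineError(
            f"baseline window [{b0}, {b1}] holds {base.sum()} samples; "
            f"need >= {baseline_min_samples}"
        )
    io = float(y[base].mean())

    try:
        p0, p1 = detect_plateau(trace, plateau_window, plateau_slope_tol)
    except PlateauNotFoundError:
        _log.warning(
            "post-lysis plateau not detected; using the final %g s of the "
            "trace for I_inf",
            plateau_window,
        )
        p0, p1 = float(t[-1] - plateau_window), float(t[-1])
    tail = (t >= p0) & (t <= p1)
    if tail.sum() < 5:
        raise PlateauNotFoundError("post-lysis plateau holds fewer than 5 samples")
    i_inf = float(y[tail].mean())

    if i_inf <= io:
        raise DegenerateNormalizationError(
            f"I_inf ({i_inf:.4g}) must exceed Io ({io:.4g}); lysis step absent?"
        )
    return (y - io) / (i_inf - io)


def destep(
    time: Sequence[float],
    cfr: Sequence[float],
    cycles: Sequence[tuple[float, float]],
    provenance: Optional[dict] = None,
) -> ReleaseProfile:
    """Trim OFF segments and remap time to cumulative insonation time.

    ON intervals are half-open ``[on_start, on_end)``: a sample exactly at the
    OFF transition belongs to OFF and is discarded.  A retained sample at time
    ``t`` in cycle ``i`` maps to ``sum(earlier ON durations) + (t - on_start_i)``,
    so ordering is preserved and no ON time is double counted.
    """
    time = np.asarray(time, dtype=float)
    cfr = np.asarray(cfr, dtype=float)
    if not cycles:
        raise EmptyProfileError("no sonication cycles supplied")
    t_out: list[np.ndarray] = []
    c_out: list[np.ndarray] = []
    elapsed_on = 0.0
    for on_start, on_end in cycles:
        mask = (time >= on_start) & (time < on_end)
        t_out.append(elapsed_on + (time[mask] - on_start))
        c_out.append(cfr[mask])
        elapsed_on += on_end - on_start
    t_us = np.concatenate(t_out)
    if t_us.size == 0:
        raise EmptyProfileError("no samples fall inside any ON interval")
    prov = dict(provenance or {})
    prov.setdefault("total_on_duration", elapsed_on)
    return ReleaseProfile(t_us=t_us, cfr=np.concatenate(c_out), provenance=prov)


def preprocess_trace(trace: FluorescenceTrace, **cfr_kwargs) -> ReleaseProfile:
    """Full preprocessing: CFR normalization followed by de-stepping."""
    cfr = compute_cfr(trace, **cfr_kwargs)
    prov = dict(trace.meta)
    return destep(trace.time, cfr, trace.cycles, provenance=prov)
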