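"""Oscillation cycle detection and phase landmarking on a GAW.

A cycle runs from one opening instant to the next (half-open in time).  Each
cycle is subdivided into the open phase (opening limb up to the area peak,
then the closing limb) and the closed phase (frames at or below the closure
level).  The closure level is

    c = baseline + closure_threshold_rel * (cycle-local max - baseline)

with baseline the global minimum area of the recording.  With the default
``closure_threshold_rel = 0`` no frame is classified closed (closure would
require dropping strictly below the global baseline), so the open quotient
is identically 1 — the regime of a glottis with a posterior gap that never
fully closes.  Thresholds of 0.01 or 0.05 reproduce the literature's 1%/5%
closure conventions.

Boundary detection is two-stage so it stays robust down to ~4 samples per
cycle: candidate cycles are bracketed by upward crossings of the mid-level
(baseline + half the global range), then each boundary is refined to the
takeoff frame — the last closure-level sample before the rise (the opening
instant falls between it and the next frame) — when closure-level samples
exist, else to the last minimal sample in the bracket.  Placing the boundary
on the takeoff frame makes the opening limb carry its sub-threshold portion
just as the closing limb does, so opening/closing durations are unbiased.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .synth import GAWRecord

__all__ = ["Cycle", "CycleSet", "NoOscillationError", "detect_cycles", "estimate_f0"]

DEFAULT_MAX_CYCLES = 106


class NoOscillationError(ValueError):
    """The signal contains no detectable oscillation (constant or < 2 cycles)."""


@dataclass
class Cycle:
    """One oscillation cycle with its phase landmarks (times in seconds)."""

    t_start: float
    t_end: float
    open_s: float
    closed_s: float
    opening_s: float
    closing_s: float
    peak_time: float
    peak_area: float
    min_area: float
    i_start: int
    i_end: int
    t_M_left: float | None = None
    t_M_right: float | None = None

    @property
    def T(self) -> float:
        return self.t_end - self.t_start

    @property
    def dyn_range(self) -> float:
        return self.peak_area - self.min_area


@dataclass
class CycleSet:
    """Ordered, contiguous cycles detected in one GAW."""

    cycles: list[Cycle]
    fs_fps: float
    n_used: int

    @property
    def used(self) -> list[Cycle]:
        return self.cycles[: self.n_used]

    @property
    def f0_hz(self) -> float:
        return estimate_f0(self)

    def periods(self) -> np.ndarray:
        return np.array([c.T for c in self.used])

    def dyn_ranges(self) -> np.ndarray:
        return np.array([c.dyn_range for c in self.used])

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for c in self.used:
            rows.append(
                {
                    "t_start": c.t_start, "t_end": c.t_end, "T": c.T,
                    "open_s": c.open_s, "closed_s": c.closed_s,
                    "opening_s": c.opening_s, "closing_s": c.closing_s,
                    "peak_time": c.peak_time, "peak_area": c.peak_area,
                    "min_area": c.min_area, "dyn_range": c.dyn_range,
                    "t_M_left": c.t_M_left, "t_M_right": c.t_M_right,
                }
            )
        return pd.DataFrame(rows)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "fs_fps": self.fs_fps,
                    "n_used": self.n_used,
                    "cycles": self.to_dataframe().to_dict(orient="records"),
                },
                indent=1,
            )
        )


def _boundaries(
    a: np.ndarray, closure_threshold_rel: float
) -> np.ndarray:
    baseline = float(a.min())
    gmax = float(a.max())
    if gmax - baseline <= 0:
        raise NoOscillationError("no oscillation: constant signal")
    mid = baseline + 0.5 * (gmax - baseline)
    above = a > mid
    ups = np.flatnonzero(~above[:-1] & above[1:]) + 1
    if ups.size < 2:
        raise NoOscillationError("no oscillation: fewer than 2 complete cycles")
    c = baseline + closure_threshold_rel * (gmax - baseline)

    bounds = []
    prev = 0
    for k in ups:
        window = np.arange(prev, k + 1) if k > prev else np.array([k])
        vals = a[window]
        below = np.flatnonzero(vals <= c)
        if below.size:
            b = window[below[-1]]  # takeoff: last closure-level frame before the rise
        else:
            mins = np.flatnonzero(vals == vals.min())
            b = window[mins[-1]]
        bounds.append(min(b, k))
        prev = k
    bounds = np.unique(np.asarray(bounds, dtype=int))
    if bounds.size < 3:
        raise NoOscillationError("no oscillation: fewer than 2 complete cycles")
    return bounds


def detect_cycles(
    gaw: GAWRecord,
    closure_threshold_rel: float = 0.0,
    max_cycles: int = DEFAULT_MAX_CYCLES,
) -> CycleSet:
    """Detect cycles and their phase landmarks.

    Partial first/last cycles are discarded; at most ``max_cycles`` cycles
    from the start are retained for analysis.  Raises
    :class:`NoOscillationError` on constant input or fewer than 2 complete
    cycles.
    """
    if not (0.0 <= closure_threshold_rel < 1.0):
        raise ValueError("closure_threshold_rel must be in [0, 1)")
    a = gaw.total_area
    fs = gaw.fs_fps
    bounds = _boundaries(a, closure_threshold_rel)
    baseline = float(a.min())

    cycles: list[Cycle] = []
    for b0, b1 in zip(bounds[:-1], bounds[1:]):
        seg = a[b0:b1]
        # same arithmetic as the Cycle.T property, so open/T == 1.0 exactly
        # when no frame is closed (rank tests must not see ulp noise)
        T = b1 / fs - b0 / fs
        peak_rel = int(np.argmax(seg))  # earliest tie
        peak_idx = b0 + peak_rel
        cyc_max = float(seg.max())
        cyc_min = float(seg.min())
        c = baseline + closure_threshold_rel * (cyc_max - baseline)
        if closure_threshold_rel > 0:
            closed_mask = seg <= c
            closed_mask[0] = False  # the takeoff frame opens the cycle
        else:
            closed_mask = seg < baseline  # never: closure needs a positive threshold
        closed_s = int(closed_mask.sum()) / fs
        open_s = T - closed_s
        opening_s = (peak_idx - b0) / fs
        after_peak = np.flatnonzero(closed_mask & (np.arange(seg.size) > peak_rel))
        if after_peak.size:
            closing_s = (after_peak[0] - peak_rel) / fs
        else:
            closing_s = (b1 - peak_idx) / fs

        t_M_left = t_M_right = None
        if gaw.has_halves:
            t_M_left = (b0 + int(np.argmax(gaw.left_area[b0:b1]))) / fs
            t_M_right = (b0 + int(np.argmax(gaw.right_area[b0:b1]))) / fs

        cycles.append(
            Cycle(
                t_start=b0 / fs, t_end=b1 / fs,
                open_s=open_s, closed_s=closed_s,
                opening_s=opening_s, closing_s=closing_s,
                peak_time=peak_idx / fs, peak_area=cyc_max, min_area=cyc_min,
                i_start=int(b0), i_end=int(b1),
                t_M_left=t_M_left, t_M_right=t_M_right,
            )
        )
    return CycleSet(cycles=cycles, fs_fps=fs, n_used=min(max_cycles, len(cycles)))


def estimate_f0(cycles: CycleSet) -> float:
    """Fundamental frequency as 1 / mean cycle period over used cycles."""
    if cycles.n_used < 2:
        raise ValueError("need at least 2 cycles to estimate F0")
    return 1.0 / float(np.mean(cycles.periods()))
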