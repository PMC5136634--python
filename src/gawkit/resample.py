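"""Frame-rate decimation: emulating slower cameras from a master recording.

A camera running at a lower rate captures a subset of the instants the
master camera saw; it does not low-pass the scene.  Decimation therefore
selects, for output frame j at the target rate, the nearest preceding master
frame: index floor(j * master_fps / target_fps).  Non-integer rate ratios
(e.g. 15000 -> 14000 fps) are handled by the same floor map.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np

from .synth import GAWRecord

__all__ = ["RateSweepPlan", "decimate_to_rate", "build_sweep", "sample_indices"]


@dataclass(frozen=True)
class RateSweepPlan:
    """A set of target frame rates to emulate from one master rate.

    Defaults reproduce a 15-step sweep, 1000..15000 fps in 1000 fps steps.
    """

    master_fps: float = 15000.0
    target_fps_list: tuple[float, ...] = field(
        default_factory=lambda: tuple(range(1000, 15001, 1000))
    )

    def __post_init__(self) -> None:
        targets = tuple(self.target_fps_list)
        object.__setattr__(self, "target_fps_list", targets)
        if len(targets) == 0:
            raise ValueError("target_fps_list must be non-empty")
        if any(t <= 0 for t in targets):
            raise ValueError("target rates must be strictly positive")
        if any(t > self.master_fps for t in targets):
            raise ValueError("target rates must not exceed the master rate")
        if len(set(targets)) != len(targets):
            raise ValueError("target rates must be unique")
        if list(targets) != sorted(targets):
            raise ValueError("target rates must be sorted ascending")


def sample_indices(n_master: int, master_fps: float, target_fps: float) -> np.ndarray:
    """Master-frame indices selected for each output frame (floor map)."""
    ratio = Fraction(master_fps).limit_denominator(10**9) / Fraction(
        target_fps
    ).limit_denominator(10**9)
    n_out = int(n_master / ratio)  # floor(duration_s * target_fps)
    j = np.arange(n_out, dtype=np.int64)
    return (j * ratio.numerator) // ratio.denominator


def decimate_to_rate(gaw: GAWRecord, target_fps: float) -> GAWRecord:
    """Resample a GAW to a lower frame rate by nearest-preceding-frame selection.

    Output length is floor(duration_s * target_fps); the total duration is
    preserved within one master frame.  Left/right halves use the identical
    index map.  ``target_fps == fs_fps`` returns an identity copy.
    """
    if target_fps <= 0:
        raise ValueError("target_fps must be positive")
    if target_fps > gaw.fs_fps:
        raise ValueError("target_fps exceeds the master rate")
    idx = sample_indices(gaw.n_frames, gaw.fs_fps, target_fps)
    if idx.size < 2:
        raise ValueError("decimated GAW would have fewer than 2 frames")
    return GAWRecord(
        fs_fps=target_fps,
        total_area=gaw.total_area[idx],
        left_area=gaw.left_area[idx] if gaw.has_halves else None,
        right_area=gaw.right_area[idx] if gaw.has_halves else None,
        provenance=f"{gaw.provenance} | decimated {gaw.fs_fps:g}->{target_fps:g} fps",
    )


def build_sweep(
    recordings: list[GAWRecord] | dict[str, GAWRecord],
    plan: RateSweepPlan,
) -> list[tuple[str, float, GAWRecord]]:
    """Cartesian product of recordings and target rates.

    Returns ``n_recordings * n_targets`` entries ``(recording_id, fps, gaw)``.
    Recording ids come from dict keys, or are rec00, rec01, ... for a list.
    """
    if isinstance(recordings, dict):
        items = list(recordings.items())
    else:
        items = [(f"rec{i:02d}", g) for i, g in enumerate(recordings)]
    if not items:
        raise ValueError("no recordings given")
    for _, g in items:
        if plan.master_fps != g.fs_fps:
            raise ValueError("plan master_fps must match each recording's rate")
    out = []
    for rec_id, g in items:
        for fps in plan.target_fps_list:
            out.append((rec_id, float(fps), decimate_to_rate(g, fps)))
    return out
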