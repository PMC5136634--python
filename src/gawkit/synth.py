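"""Synthetic glottal area waveform (GAW) generation.

Produces ground-truth-annotated GAWs that emulate sustained phonation as
captured by laryngeal high-speed videoendoscopy: a quasi-periodic pulse
train of glottal area values (pixels) at a kilohertz frame rate, with a
posterior glottal gap (the glottis never fully closes), small left-right
phase asymmetry, and controllable cycle-to-cycle period (jitter) and
amplitude (shimmer) perturbations.

The per-cycle pulse is piecewise smooth: a raised-cosine opening limb and a
raised-cosine closing limb, joined at the peak, sitting on a constant area
floor that models the posterior chink.  Opening and closing durations are in
the ratio of the programmed speed quotient.  Left and right half waveforms
are each half the pulse, time-shifted in opposite directions by half the
programmed phase asymmetry, so the normalized left-right peak-time offset
equals the programmed value exactly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import imageio.v3 as imageio
import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "KinematicParams",
    "GAWRecord",
    "GroundTruth",
    "UnresolvablePulseError",
    "CanvasOverflowError",
    "generate_gaw",
    "render_frames",
    "write_stack",
    "read_stack",
    "write_gaw_csv",
    "read_gaw_csv",
    "write_ground_truth",
    "read_ground_truth",
]


class UnresolvablePulseError(ValueError):
    """Open phase shorter than two frame intervals: the pulse cannot be sampled."""


class CanvasOverflowError(ValueError):
    """Requested glottis area exceeds what the image canvas can hold."""


# Mean absolute first difference of an i.i.d. N(0, sigma^2) sequence is
# 2*sigma/sqrt(pi); invert to scale perturbations to a requested mean |delta|.
_MAD1_FACTOR = 2.0 / np.sqrt(np.pi)


@dataclass(frozen=True)
class KinematicParams:
    """Ground-truth kinematics of a synthetic phonation recording.

    Defaults emulate a vocally healthy adult female during sustained
    phonation: F0 near 176 Hz, a 15 kfps master frame rate, at least 106
    oscillation cycles, a small posterior glottal gap, near-perfect
    left-right symmetry and low jitter/shimmer.
    """

    f0_hz: float = 176.0
    fs_fps: float = 15000.0
    n_cycles: int = 110
    open_quotient: float = 0.9
    speed_quotient: float = 1.25
    gap_fraction: float = 0.06
    phase_asym: float = -0.02
    jitter_ms: float = 0.30
    shimmer_db: float = 0.20
    noise_sd: float = 2.0
    peak_area_px: float = 4000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.open_quotient <= 1.0):
            raise ValueError("open_quotient must be in [0, 1]")
        if self.speed_quotient <= 0.0:
            raise ValueError("speed_quotient must be > 0")
        if not (0.0 <= self.gap_fraction < 1.0):
            raise ValueError("gap_fraction must be in [0, 1)")
        if not (-1.0 < self.phase_asym < 1.0):
            raise ValueError("phase_asym must be in (-1, 1)")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        if self.f0_hz <= 0 or self.fs_fps <= 0:
            raise ValueError("f0_hz and fs_fps must be positive")
        if self.fs_fps / self.f0_hz < 4.0:
            raise ValueError("need at least 4 samples per cycle (fs/f0 >= 4)")
        if self.jitter_ms < 0 or self.shimmer_db < 0 or self.noise_sd < 0:
            raise ValueError("perturbation magnitudes must be non-negative")
        if self.peak_area_px <= 0:
            raise ValueError("peak_area_px must be positive")


@dataclass
class GAWRecord:
    """A sampled glottal area waveform at a stated frame rate.

    ``total_area`` holds one area value (pixels) per video frame; frame k
    corresponds to time k / fs_fps (0-based).  Optional ``left_area`` and
    ``right_area`` partition the total by the glottal midline.
    """

    fs_fps: float
    total_area: np.ndarray
    left_area: np.ndarray | None = None
    right_area: np.ndarray | None = None
    provenance: str = ""

    def __post_init__(self) -> None:
        self.total_area = np.asarray(self.total_area, dtype=float)
        if self.total_area.ndim != 1 or self.total_area.size < 2:
            raise ValueError("total_area must be a 1-D sequence of length >= 2")
        if np.any(self.total_area < 0):
            raise ValueError("areas must be non-negative")
        if (self.left_area is None) != (self.right_area is None):
            raise ValueError("left_area and right_area must be given together")
        if self.left_area is not None:
            self.left_area = np.asarray(self.left_area, dtype=float)
            self.right_area = np.asarray(self.right_area, dtype=float)
            if self.left_area.shape != self.total_area.shape or (
                self.right_area.shape != self.total_area.shape
            ):
                raise ValueError("half waveforms must match total_area in length")
            if np.any(self.left_area < 0) or np.any(self.right_area < 0):
                raise ValueError("areas must be non-negative")
            resid = np.abs(self.left_area + self.right_area - self.total_area)
            if np.max(resid) > 1e-6 * max(1.0, float(np.max(self.total_area))):
                raise ValueError("left + right must equal total per frame")

    @property
    def n_frames(self) -> int:
        return int(self.total_area.size)

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.fs_fps

    @property
    def has_halves(self) -> bool:
        return self.left_area is not None

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.fs_fps


@dataclass
class GroundTruth:
    """Generator bookkeeping for one synthetic recording.

    ``periods_s`` and ``peaks_px`` are the realized per-cycle periods and
    peak areas, from which the realized jitter/shimmer are computed without
    going through the analysis pipeline.
    """

    params: KinematicParams
    periods_s: np.ndarray
    peaks_px: np.ndarray
    cycle_starts_s: np.ndarray
    floor_px: float

    @property
    def realized_jitter_ms(self) -> float:
        return float(np.mean(np.abs(np.diff(self.periods_s)))) * 1000.0

    @property
    def realized_shimmer_db(self) -> float:
        db = 20.0 * np.log10(self.peaks_px)
        return float(np.mean(np.abs(np.diff(db))))

    @property
    def gap_fraction_realized(self) -> float:
        return float(self.floor_px / np.max(self.peaks_px))


def _limb(tau: np.ndarray, t_opening: float, t_closing: float) -> np.ndarray:
    """Unit-amplitude open-phase pulse: raised-cosine up then down, 0 outside."""
    out = np.zeros_like(tau)
    if t_opening > 0:
        m = (tau >= 0) & (tau < t_opening)
        out[m] = 0.5 * (1.0 - np.cos(np.pi * tau[m] / t_opening))
    m = (tau >= t_opening) & (tau < t_opening + t_closing)
    if t_closing > 0:
        out[m] = 0.5 * (1.0 + np.cos(np.pi * (tau[m] - t_opening) / t_closing))
    return out


def generate_gaw(params: KinematicParams) -> tuple[GAWRecord, GroundTruth]:
    """Generate a synthetic GAW and its ground-truth record.

    Identical ``params`` (including seed) give bit-identical output.  Raises
    :class:`UnresolvablePulseError` when the open phase of any cycle spans
    fewer than two frame intervals at the master rate.
    """
    rng = np.random.default_rng(params.seed)
    p = params
    t_nom = 1.0 / p.f0_hz

    # i.i.d. Gaussian on log-period, scaled so mean |T_{i+1}-T_i| ~= jitter_ms
    if p.jitter_ms > 0:
        sigma_log = (p.jitter_ms / 1000.0) / t_nom / _MAD1_FACTOR
        periods = t_nom * np.exp(rng.normal(0.0, sigma_log, p.n_cycles))
    else:
        periods = np.full(p.n_cycles, t_nom)

    # i.i.d. Gaussian on dB peak amplitude, scaled the same way
    if p.shimmer_db > 0:
        sigma_db = p.shimmer_db / _MAD1_FACTOR
        peaks = p.peak_area_px * 10.0 ** (rng.normal(0.0, sigma_db, p.n_cycles) / 20.0)
    else:
        peaks = np.full(p.n_cycles, p.peak_area_px)

    floor = p.gap_fraction * p.peak_area_px
    pulse_amp = peaks - floor
    if np.any(pulse_amp <= 0):
        raise ValueError("shimmer drove a cycle peak below the area floor")

    t_open = p.open_quotient * periods
    if np.any(t_open < 2.0 / p.fs_fps):
        raise UnresolvablePulseError(
            "unresolvable pulse: open phase shorter than 2 frames at the master rate"
        )
    sq = p.speed_quotient
    t_opening = t_open * sq / (sq + 1.0)
    t_closing = t_open / (sq + 1.0)

    starts = np.concatenate([[0.0], np.cumsum(periods)])
    total_dur = starts[-1]
    n_frames = int(np.floor(total_dur * p.fs_fps))
    t = np.arange(n_frames) / p.fs_fps

    cyc = np.searchsorted(starts, t, side="right") - 1
    cyc = np.clip(cyc, 0, p.n_cycles - 1)
    tau = t - starts[cyc]

    shift = p.phase_asym * periods / 2.0  # left peaks later by +shift, right by -shift
    left = np.empty(n_frames)
    right = np.empty(n_frames)
    for i in range(p.n_cycles):
        m = cyc == i
        if not np.any(m):
            continue
        half = 0.5 * pulse_amp[i]
        left[m] = floor / 2.0 + half * _limb(tau[m] - shift[i], t_opening[i], t_closing[i])
        right[m] = floor / 2.0 + half * _limb(tau[m] + shift[i], t_opening[i], t_closing[i])

    if p.noise_sd > 0:
        eps = rng.normal(0.0, p.noise_sd, n_frames)
        left = left + eps / 2.0
        right = right + eps / 2.0
    left = np.maximum(left, 0.0)
    right = np.maximum(right, 0.0)
    total = left + right

    gaw = GAWRecord(
        fs_fps=p.fs_fps,
        total_area=total,
        left_area=left,
        right_area=right,
        provenance=f"synthetic f0={p.f0_hz:g}Hz seed={p.seed}",
    )
    truth = GroundTruth(
        params=p,
        periods_s=periods,
        peaks_px=peaks,
        cycle_starts_s=starts[:-1],
        floor_px=floor,
    )
    return gaw, truth


# ---------------------------------------------------------------------------
# Frame rendering: endoscopy-like grayscale stacks
# ---------------------------------------------------------------------------

_GLOTTIS_GRAY = 25
_BACKGROUND_GRAY = 230


def _half_lens_count(
    half_width: float, cols_rel: np.ndarray, rows_rel2: np.ndarray
) -> np.ndarray:
    """Boolean mask of one half-ellipse with the given half width."""
    if half_width <= 0:
        return np.zeros((rows_rel2.size, cols_rel.size), dtype=bool)
    return (cols_rel[None, :] / half_width) ** 2 + rows_rel2[:, None] <= 1.0


def _fit_half(target: float, cols_rel: np.ndarray, rows_rel2: np.ndarray, w_max: float) -> np.ndarray:
    """Binary-search the half-ellipse width whose pixel count best matches target."""
    target_n = int(round(target))
    if target_n <= 0:
        return np.zeros((rows_rel2.size, cols_rel.size), dtype=bool)
    lo, hi = 0.0, w_max
    if int(_half_lens_count(hi, cols_rel, rows_rel2).sum()) < target_n:
        raise CanvasOverflowError("canvas overflow: area exceeds image capacity")
    best = None
    best_err = np.inf
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        mask = _half_lens_count(mid, cols_rel, rows_rel2)
        n = int(mask.sum())
        err = abs(n - target_n)
        if err < best_err:
            best, best_err = mask, err
        if n < target_n:
            lo = mid
        else:
            hi = mid
        if err == 0:
            break
    return best


def render_frames(
    gaw: GAWRecord,
    image_size: tuple[int, int] = (64, 96),
    axis_fraction: float = 0.8,
) -> np.ndarray:
    """Render a GAW as a stack of endoscopy-like 8-bit grayscale frames.

    Each frame shows a dark, vertically oriented lens (the glottis) centered
    on a bright background; the number of dark pixels matches the frame's
    area value within rasterization error.  The anterior-posterior midline is
    the vertical line between the two center columns, so the left half of the
    lens carries ``left_area`` and the right half ``right_area``.

    Returns an array of shape ``(n_frames, height, width)`` dtype uint8.
    """
    h, w = image_size
    if h < 8 or w < 8:
        raise ValueError("image too small")
    length = axis_fraction * h  # major (vertical) axis of the lens
    # quarter-pixel vertical offset de-degenerates symmetric row pairs, so
    # boundary pixels enter one at a time (finer area granularity)
    cy = (h - 1) / 2.0 + 0.25
    rows = np.arange(h, dtype=float)
    rows_rel2 = ((rows - cy) / (length / 2.0)) ** 2

    # midline between columns w//2 - 1 and w//2
    mid = w / 2.0 - 0.5
    cols = np.arange(w, dtype=float)
    left_cols = cols[cols < mid] - mid   # negative offsets
    right_cols = cols[cols > mid] - mid  # positive offsets
    w_max = mid - 0.5

    if gaw.has_halves:
        left_t, right_t = gaw.left_area, gaw.right_area
    else:
        left_t = right_t = gaw.total_area / 2.0

    stack = np.full((gaw.n_frames, h, w), _BACKGROUND_GRAY, dtype=np.uint8)
    for k in range(gaw.n_frames):
        lm = _fit_half(left_t[k], np.abs(left_cols), rows_rel2, w_max)
        # fit the right half against the residual so the total pixel count
        # tracks total_area despite rasterization granularity
        residual = max(left_t[k] + right_t[k] - int(lm.sum()), 0.0)
        rm = _fit_half(residual, right_cols, rows_rel2, w_max)
        frame = stack[k]
        frame[:, : left_cols.size][lm] = _GLOTTIS_GRAY
        frame[:, w - right_cols.size :][rm] = _GLOTTIS_GRAY
    return stack


def write_stack(stack: np.ndarray, path: str | Path) -> None:
    """Write a frame stack as a multi-page TIFF (or one PNG per frame if
    ``path`` is a directory)."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        tifffile.imwrite(path, np.asarray(stack, dtype=np.uint8))
    else:
        path.mkdir(parents=True, exist_ok=True)
        for k, frame in enumerate(stack):
            imageio.imwrite(path / f"frame{k:05d}.png", frame.astype(np.uint8))


def read_stack(path: str | Path) -> np.ndarray:
    """Read a stack written by :func:`write_stack`."""
    path = Path(path)
    if path.is_dir():
        frames = [imageio.imread(p) for p in sorted(path.glob("frame*.png"))]
        return np.stack(frames)
    return np.asarray(tifffile.imread(path))


# ---------------------------------------------------------------------------
# Plain-text I/O
# ---------------------------------------------------------------------------

def write_gaw_csv(gaw: GAWRecord, path: str | Path) -> None:
    """Write a GAW as CSV with header frame,time_s,total_area,left_area,right_area."""
    n = gaw.n_frames
    df = pd.DataFrame(
        {
            "frame": np.arange(n),
            "time_s": gaw.times_s,
            "total_area": gaw.total_area,
            "left_area": gaw.left_area if gaw.has_halves else np.full(n, np.nan),
            "right_area": gaw.right_area if gaw.has_halves else np.full(n, np.nan),
        }
    )
    with open(path, "w") as fh:
        fh.write(f"# fs_fps={gaw.fs_fps:g} provenance={gaw.provenance}\n")
        df.to_csv(fh, index=False)


def read_gaw_csv(path: str | Path) -> GAWRecord:
    """Read a GAW written by :func:`write_gaw_csv`."""
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("#"):
            raise ValueError("missing GAW CSV metadata line")
        meta = dict(
            item.split("=", 1) for item in header[1:].strip().split(" ", 1) if "=" in item
        )
        fs = float(meta["fs_fps"])
        prov = header.split("provenance=", 1)[1].strip() if "provenance=" in header else ""
        df = pd.read_csv(fh)
    halves = not df["left_area"].isna().all()
    return GAWRecord(
        fs_fps=fs,
        total_area=df["total_area"].to_numpy(),
        left_area=df["left_area"].to_numpy() if halves else None,
        right_area=df["right_area"].to_numpy() if halves else None,
        provenance=prov,
    )


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    payload = {
        "params": dataclasses.asdict(truth.params),
        "periods_s": truth.periods_s.tolist(),
        "peaks_px": truth.peaks_px.tolist(),
        "cycle_starts_s": truth.cycle_starts_s.tolist(),
        "floor_px": truth.floor_px,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_ground_truth(path: str | Path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    return GroundTruth(
        params=KinematicParams(**payload["params"]),
        periods_s=np.asarray(payload["periods_s"]),
        peaks_px=np.asarray(payload["peaks_px"]),
        cycle_starts_s=np.asarray(payload["cycle_starts_s"]),
        floor_px=float(payload["floor_px"]),
    )
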