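"""Glottis segmentation on grayscale frame stacks.

The glottis appears as a dark region between the two (brighter) vocal folds.
Segmentation is a fixed global intensity threshold followed by a
largest-connected-component rule (4-connectivity), optionally restricted to a
rectangular region of interest.  Per-frame areas form the glottal area
waveform; the left/right split uses the principal axis of the time-union
glottis mask, which stays defined even in frames where the glottis closes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .synth import GAWRecord

__all__ = ["SegmentationConfig", "segment_frame", "extract_gaw"]


@dataclass(frozen=True)
class SegmentationConfig:
    """Segmentation settings.

    intensity_threshold
        Pixels with grayscale value <= threshold are glottis candidates.
    roi
        Optional (row0, col0, row1, col1) rectangle, 0-based, half-open.
    min_component_px
        Components smaller than this count as noise (area 0).
    """

    intensity_threshold: int = 128
    roi: tuple[int, int, int, int] | None = None
    min_component_px: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.intensity_threshold <= 255):
            raise ValueError("intensity_threshold must be in [0, 255]")
        if self.min_component_px < 0:
            raise ValueError("min_component_px must be >= 0")
        if self.roi is not None:
            r0, c0, r1, c1 = self.roi
            if r1 <= r0 or c1 <= c0:
                raise ValueError("empty roi")


_FOUR_CONN = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])


def segment_frame(
    frame: np.ndarray, cfg: SegmentationConfig
) -> tuple[np.ndarray, int]:
    """Segment one frame; return (full-frame boolean glottis mask, area in px).

    The glottis is the largest dark (<= threshold) 4-connected component
    inside the roi; area is 0 when no component reaches ``min_component_px``.
    """
    frame = np.asarray(frame)
    if frame.ndim != 2:
        raise ValueError("frame must be single-channel (2-D)")
    if cfg.roi is not None:
        r0, c0, r1, c1 = cfg.roi
        if r0 < 0 or c0 < 0 or r1 > frame.shape[0] or c1 > frame.shape[1]:
            raise ValueError("roi outside frame")
        view = frame[r0:r1, c0:c1]
    else:
        r0 = c0 = 0
        view = frame

    dark = view <= cfg.intensity_threshold
    mask = np.zeros(frame.shape, dtype=bool)
    if not dark.any():
        return mask, 0
    labels, n = ndimage.label(dark, structure=_FOUR_CONN)
    sizes = np.bincount(labels.ravel())[1:]
    best = int(np.argmax(sizes)) + 1
    area = int(sizes[best - 1])
    if area < cfg.min_component_px:
        return mask, 0
    sub = labels == best
    mask[r0 : r0 + sub.shape[0], c0 : c0 + sub.shape[1]] = sub
    return mask, area


def extract_gaw(stack: np.ndarray, cfg: SegmentationConfig) -> GAWRecord:
    """Segment every frame of a stack into a GAWRecord with left/right halves.

    The glottal midline is the major principal axis of the union of all
    per-frame glottis masks; a pixel's side is the sign of its offset from
    the axis along the minor direction (on-axis pixels count as left), so
    left_area + right_area == total_area exactly.

    ``fs_fps`` is not knowable from pixels alone and must be set by the
    caller; it defaults to 1.0 (times in frames).
    """
    stack = np.asarray(stack)
    if stack.ndim != 3 or stack.shape[0] == 0:
        raise ValueError("stack must be (n_frames, h, w) with n_frames >= 1")

    masks = []
    for k in range(stack.shape[0]):
        mask, _ = segment_frame(stack[k], cfg)
        masks.append(mask)
    union = np.logical_or.reduce(masks)

    n = stack.shape[0]
    if not union.any():
        warnings.warn("no glottis found in any frame; GAW is all-zero", stacklevel=2)
        zero = np.zeros(n)
        return GAWRecord(
            fs_fps=1.0, total_area=zero, left_area=zero.copy(),
            right_area=zero.copy(), provenance="segmentation (empty)",
        )

    rr, cc = np.nonzero(union)
    r_mean, c_mean = rr.mean(), cc.mean()
    # principal (major) axis of the union mask from second central moments
    mu_rr = np.mean((rr - r_mean) ** 2)
    mu_cc = np.mean((cc - c_mean) ** 2)
    mu_rc = np.mean((rr - r_mean) * (cc - c_mean))
    cov = np.array([[mu_rr, mu_rc], [mu_rc, mu_cc]])
    evals, evecs = np.linalg.eigh(cov)
    major = evecs[:, int(np.argmax(evals))]  # (d_row, d_col) of the midline
    # normal points toward increasing column for a vertical (row-aligned) axis
    normal = np.array([-major[1], major[0]])
    if normal[1] < 0 or (normal[1] == 0 and normal[0] < 0):
        normal = -normal

    total = np.empty(n)
    left = np.empty(n)
    right = np.empty(n)
    for k, mask in enumerate(masks):
        a = int(mask.sum())
        total[k] = a
        if a == 0:
            left[k] = right[k] = 0.0
            continue
        mr, mc = np.nonzero(mask)
        side = (mr - r_mean) * normal[0] + (mc - c_mean) * normal[1]
        n_right = int(np.count_nonzero(side > 0))
        right[k] = n_right
        left[k] = a - n_right
    return GAWRecord(
        fs_fps=1.0, total_area=total, left_area=left, right_area=right,
        provenance="segmentation",
    )
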