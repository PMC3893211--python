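"""Larva detection and best-focus compositing.

The imaging program this module reproduces works on a per-well z-stack:
the larva body is recognised by its fluorescence intensity (EGFP body
channel), the field of view is centred on the body's centre of brightness,
and a single in-focus image is composited from the z-slices before any
tumor quantification.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.filters import threshold_otsu

__all__ = [
    "ZStack",
    "BodyDetection",
    "CompositeImage",
    "body_centroid",
    "focus_score",
    "best_focus_composite",
    "crop_fov",
]


@dataclass
class ZStack:
    """An ordered stack of z-slices for one channel of one well.

    Parameters
    ----------
    slices : ndarray, shape (n_slices, rows, cols)
        Intensity images ordered by acquisition depth.
    z_step_um : float
        Axial distance between consecutive slices, in micrometres.
    pixel_size_um : float
        Lateral pixel size, in micrometres per pixel.
    channel : {"body", "tumor"}
    """

    slices: np.ndarray
    z_step_um: float
    pixel_size_um: float
    channel: str = "body"

    def __post_init__(self) -> None:
        self.slices = np.asarray(self.slices, dtype=float)
        if self.slices.ndim != 3 or self.slices.shape[0] < 1:
            raise ValueError("slices must be a (n_slices, rows, cols) array with n_slices >= 1")
        if self.z_step_um <= 0:
            raise ValueError("z_step_um must be positive")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.channel not in ("body", "tumor"):
            raise ValueError("channel must be 'body' or 'tumor'")

    @property
    def n_slices(self) -> int:
        return self.slices.shape[0]


@dataclass
class BodyDetection:
    """Result of intensity-based body detection on a single image."""

    centroid_um: tuple[float, float] | None
    mask: np.ndarray
    total_intensity: float
    ok: bool
    reason: str = ""


@dataclass
class CompositeImage:
    """Best-focus composite of a z-stack.

    In ``global`` mode the composite is exactly one input slice and
    ``source_index`` is that slice's index; in ``tile`` mode
    ``source_index`` is a 2-D map giving the winning slice per tile.
    """

    image: np.ndarray
    source_index: int | np.ndarray
    focus_scores: np.ndarray = field(default_factory=lambda: np.empty(0))


def _round_half_toward_zero(x: float) -> int:
    """Round to nearest integer, ties toward zero."""
    return int(np.sign(x) * np.ceil(abs(x) - 0.5))


def body_centroid(
    image: np.ndarray,
    threshold_mode: str = "otsu",
    k: float = 3.0,
    pixel_size_um: float = 1.0,
    min_area_px: int = 10,
) -> BodyDetection:
    """Detect the larva body and locate its centre of brightness.

    The mask is the set of pixels above an automatic threshold (Otsu by
    default; ``k_sigma`` uses mean + k*SD for low-contrast images) and the
    centroid is the intensity-weighted mean pixel position of the mask,
    converted to micrometres.  Detection failure (constant image, or fewer
    than ``min_area_px`` masked pixels) is flagged, never raised.
    """
    image = np.asarray(image, dtype=float)
    if image.size == 0:
        raise ValueError("image is empty")

    if threshold_mode == "otsu":
        try:
            thresh = threshold_otsu(image)
        except ValueError:  # constant image
            return BodyDetection(None, np.zeros(image.shape, bool), 0.0, False, "constant_image")
    elif threshold_mode == "k_sigma":
        thresh = image.mean() + k * image.std()
    else:
        raise ValueError(f"unknown threshold_mode {threshold_mode!r}")

    mask = image > thresh
    if mask.sum() < min_area_px:
        return BodyDetection(None, mask, 0.0, False, "mask_below_min_area")

    w = image[mask]
    rows, cols = np.nonzero(mask)
    total = float(w.sum())
    cx = float((w * cols).sum() / total) * pixel_size_um
    cy = float((w * rows).sum() / total) * pixel_size_um
    return BodyDetection((cx, cy), mask, total, True)


def focus_score(image: np.ndarray) -> float:
    """Tenengrad sharpness: mean squared gradient magnitude.

    Invariant to adding a constant offset; scales as c**2 when intensities
    are scaled by c; zero for a constant image.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2 or min(image.shape) < 3:
        raise ValueError("image must be 2-D and at least 3x3")
    gy, gx = np.gradient(image)
    return float(np.mean(gx * gx + gy * gy))


def best_focus_composite(stack: ZStack, mode: str = "global", tile_px: int = 64) -> CompositeImage:
    """Build the best-focus composite of a z-stack.

    ``global`` mode returns the single slice with the highest focus score
    (ties broken toward the lowest index).  ``tile`` mode partitions the
    field into ``tile_px`` squares and assembles each tile from the slice
    that is sharpest over that tile, for specimens thicker than the depth
    of field.
    """
    scores = np.array([focus_score(s) for s in stack.slices])
    if mode == "global":
        idx = int(np.argmax(scores))
        return CompositeImage(stack.slices[idx].copy(), idx, scores)
    if mode != "tile":
        raise ValueError(f"unknown mode {mode!r}")
    if tile_px < 1:
        raise ValueError("tile_px must be positive")

    n, rows, cols = stack.slices.shape
    out = np.zeros((rows, cols))
    n_tr = -(-rows // tile_px)
    n_tc = -(-cols // tile_px)
    index_map = np.zeros((n_tr, n_tc), dtype=int)
    for ti in range(n_tr):
        for tj in range(n_tc):
            rs = slice(ti * tile_px, min((ti + 1) * tile_px, rows))
            cs = slice(tj * tile_px, min((tj + 1) * tile_px, cols))
            tile_scores = [
                focus_score(s[rs, cs]) if min(s[rs, cs].shape) >= 3 else float(np.var(s[rs, cs]))
                for s in stack.slices
            ]
            best = int(np.argmax(tile_scores))
            index_map[ti, tj] = best
            out[rs, cs] = stack.slices[best, rs, cs]
    return CompositeImage(out, index_map, scores)


def crop_fov(
    image: np.ndarray,
    center_um: tuple[float, float],
    size_px: tuple[int, int],
    pixel_size_um: float = 1.0,
) -> np.ndarray:
    """Extract a window of ``size_px`` (rows, cols) centred on ``center_um``.

    The centre is rounded to the nearest pixel (ties toward zero); regions
    outside the image are zero-padded, emulating re-centring the stage on
    the centre of brightness.
    """
    image = np.asarray(image, dtype=float)
    out_r, out_c = int(size_px[0]), int(size_px[1])
    if out_r < 1 or out_c < 1:
        raise ValueError("size_px must be positive")
    cx = _round_half_toward_zero(center_um[0] / pixel_size_um)
    cy = _round_half_toward_zero(center_um[1] / pixel_size_um)
    out = np.zeros((out_r, out_c), dtype=image.dtype)
    r0 = cy - out_r // 2
    c0 = cx - out_c // 2
    src_r0, src_r1 = max(r0, 0), min(r0 + out_r, image.shape[0])
    src_c0, src_c1 = max(c0, 0), min(c0 + out_c, image.shape[1])
    if src_r0 < src_r1 and src_c0 < src_c1:
        out[src_r0 - r0 : src_r1 - r0, src_c0 - c0 : src_c1 - c0] = image[src_r0:src_r1, src_c0:src_c1]
    return out
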