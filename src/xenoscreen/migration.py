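"""Concentric-ring migration statistics.

Migration is scored by drawing concentric circles of 150, 300 and 450 µm
around the centre of brightness of the main tumor and counting non-main
foci (with their summed areas) in the distance bins [0,150), [150,300),
[300,450) and [450,inf) µm.  Bins are half-open and lower-inclusive; a
focus is assigned by its centroid alone and is never split across rings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .segmentation import SegmentationResult, TumorFocus

__all__ = ["DEFAULT_RADII_UM", "RingBins", "ring_assign", "summarize_migration"]

DEFAULT_RADII_UM = (150.0, 300.0, 450.0)


@dataclass
class RingBins:
    """Counts and summed areas of migration foci per distance bin."""

    radii_um: tuple[float, ...]
    counts: np.ndarray
    areas_um2: np.ndarray
    center_um: tuple[float, float]

    @property
    def n_bins(self) -> int:
        return len(self.radii_um) + 1

    @property
    def total_count(self) -> int:
        return int(self.counts.sum())


def _check_radii(radii_um) -> np.ndarray:
    radii = np.asarray(radii_um, dtype=float)
    if radii.size == 0 or radii[0] <= 0 or np.any(np.diff(radii) <= 0):
        raise ValueError("ring radii must be positive and strictly increasing")
    return radii


def ring_assign(
    focus_centroid_um: tuple[float, float],
    center_um: tuple[float, float],
    radii_um=DEFAULT_RADII_UM,
) -> int:
    """Bin index of a focus by Euclidean distance from the ring centre.

    Bin ``i`` covers [r_i, r_{i+1}) with r_0 = 0 and the last bin open to
    infinity, so a focus exactly on a circle falls in the outer bin.
    """
    radii = _check_radii(radii_um)
    d = float(np.hypot(focus_centroid_um[0] - center_um[0], focus_centroid_um[1] - center_um[1]))
    return int(np.searchsorted(radii, d, side="right"))


def summarize_migration(
    result: SegmentationResult,
    main: TumorFocus,
    radii_um=DEFAULT_RADII_UM,
    center_um: tuple[float, float] | None = None,
) -> RingBins:
    """Ring-bin counts and areas of all non-main foci.

    The ring origin defaults to the main tumor's intensity-weighted
    centroid; pass ``center_um`` to use a different centre of brightness
    (e.g. the whole-channel centroid).
    """
    radii = _check_radii(radii_um)
    if main not in result.foci:
        raise ValueError("main focus does not belong to this segmentation result")
    center = main.centroid_um if center_um is None else center_um
    counts = np.zeros(radii.size + 1, dtype=int)
    areas = np.zeros(radii.size + 1, dtype=float)
    for f in result.foci:
        if f is main:
            continue
        b = ring_assign(f.centroid_um, center, radii)
        counts[b] += 1
        areas[b] += f.area_um2
    return RingBins(tuple(radii.tolist()), counts, areas, tuple(center))
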