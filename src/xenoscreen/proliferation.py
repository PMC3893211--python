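"""Per-fish tumor proliferation across the two imaging timepoints.

Each fish is imaged at 72 hpf (before treatment) and 120 hpf (48 h after);
the proliferation index is the ratio of integrated tumor fluorescence
I(120)/I(72) for the same well.  Fish whose baseline signal is too weak
(transplant failure) are excluded with a recorded reason rather than
producing unstable ratios.  Cohort bookkeeping (transplant success and
survival percentages) lives here as well.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .migration import RingBins

__all__ = [
    "FishRecord",
    "ProliferationResult",
    "match_timepoints",
    "proliferation_ratio",
    "cohort_rates",
]

TIMEPOINTS_HPF = (72, 120)


@dataclass
class FishRecord:
    """Measurements for one fish at one timepoint."""

    well: str
    group: str
    tp: int  # hours post-fertilization, 72 or 120
    integrated_intensity: float
    ring_bins: RingBins | None = None
    qc_flags: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.tp not in TIMEPOINTS_HPF:
            raise ValueError(f"tp must be one of {TIMEPOINTS_HPF}")
        if self.integrated_intensity < 0:
            raise ValueError("integrated_intensity must be >= 0")


@dataclass
class ProliferationResult:
    well: str
    group: str
    ratio: float | None
    included: bool
    reason: str = ""


def match_timepoints(
    records: list[FishRecord],
) -> tuple[list[tuple[FishRecord, FishRecord]], list[FishRecord]]:
    """Pair records sharing a well into (72 hpf, 120 hpf) tuples.

    Returns (pairs, unpaired); wells missing either timepoint are reported
    unpaired.  A duplicate (well, timepoint) is an error.
    """
    by_well: dict[str, dict[int, FishRecord]] = {}
    for r in records:
        slot = by_well.setdefault(r.well, {})
        if r.tp in slot:
            raise ValueError(f"duplicate record for well {r.well} at {r.tp} hpf")
        slot[r.tp] = r
    pairs, unpaired = [], []
    for well in sorted(by_well):
        slot = by_well[well]
        if len(slot) == 2:
            pairs.append((slot[72], slot[120]))
        else:
            unpaired.extend(slot.values())
    return pairs, unpaired


def proliferation_ratio(
    i_120: float, i_72: float, min_baseline: float = 0.0, well: str = "", group: str = ""
) -> ProliferationResult:
    """I(120)/I(72) with a baseline quality gate.

    A 72-hpf intensity below ``min_baseline`` marks the fish as excluded
    (reason ``baseline_below_minimum``) instead of raising: low-baseline
    fish are transplant failures, not analysis errors.
    """
    if i_120 < 0 or i_72 < 0:
        raise ValueError("intensities must be >= 0")
    if i_72 < min_baseline or i_72 == 0:
        return ProliferationResult(well, group, None, False, "baseline_below_minimum")
    return ProliferationResult(well, group, i_120 / i_72, True)


def cohort_rates(n_injected: int, n_success: int, n_alive: int) -> tuple[float, float]:
    """Transplant success and survival percentages of an injected cohort."""
    if n_injected <= 0:
        raise ValueError("n_injected must be positive")
    if not 0 <= n_success <= n_injected or not 0 <= n_alive <= n_injected:
        raise ValueError("counts must lie in [0, n_injected]")
    return 100.0 * n_success / n_injected, 100.0 * n_alive / n_injected
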