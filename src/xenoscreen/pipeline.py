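"""End-to-end plate analysis: images in, per-fish metrics and group statistics out.

For every well and timepoint the pipeline builds the best-focus composite
of each channel, detects the larva body, segments tumor foci, identifies
the main tumor, computes the integrated tumor fluorescence and the
concentric-ring migration bins, then pairs timepoints into proliferation
ratios and runs the group statistics (ANOVA + Dunnett vs the designated
control).  Every exclusion is logged with its reason; a fish is never
silently dropped.

Outputs are plain CSV: ``fish_metrics.csv`` (one row per well per
timepoint, carrying qc flags), ``ratios.csv``, ``group_stats.csv`` and,
for toxicity tables, ``ld50_brackets.csv``.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .acquisition import ZStack, best_focus_composite, body_centroid
from .migration import DEFAULT_RADII_UM, summarize_migration
from .proliferation import FishRecord, match_timepoints, proliferation_ratio
from .screening_stats import ToxicityTable, anova_dunnett, ld50_bracket, max_safe_concentration
from .segmentation import NoTumorError, identify_main_tumor, integrated_fluorescence, segment_tumors

__all__ = ["AnalysisConfig", "PlateLayout", "PlateAnalysis", "analyze_plate", "run_toxicity"]

_TP_CODE = {1: 72, 2: 120}  # acquisition pass -> hours post-fertilization


@dataclass
class AnalysisConfig:
    """Tunable analysis settings, JSON-serializable for provenance.

    ``min_baseline_frac`` gates proliferation ratios: fish whose 72-hpf
    integrated intensity falls below this fraction of the plate median are
    excluded as transplant failures.
    """

    pixel_size_um: float = 3.25
    ring_radii_um: tuple[float, ...] = DEFAULT_RADII_UM
    threshold_mode: str = "k_sigma"  # tumor channel
    k: float = 3.0
    body_threshold_mode: str = "otsu"
    min_area_um2: float = 50.0
    focus_mode: str = "global"
    tile_px: int = 64
    min_baseline_frac: float = 0.01
    alpha: float = 0.05
    seed: int = 0
    control_group: str | None = None

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0 or self.min_area_um2 < 0 or self.tile_px < 1:
            raise ValueError("numeric config fields must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        radii = np.asarray(self.ring_radii_um, dtype=float)
        if radii.size == 0 or radii[0] <= 0 or np.any(np.diff(radii) <= 0):
            raise ValueError("ring radii must be positive and strictly increasing")

    @classmethod
    def from_json(cls, path) -> "AnalysisConfig":
        data = json.loads(Path(path).read_text())
        if "ring_radii_um" in data:
            data["ring_radii_um"] = tuple(data["ring_radii_um"])
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["ring_radii_um"] = list(d["ring_radii_um"])
        return d


@dataclass
class PlateLayout:
    """Well -> fish/group mapping with the control designated explicitly."""

    table: pd.DataFrame  # columns: well, fish_id, group, concentration_um[, role]

    def __post_init__(self) -> None:
        required = {"well", "fish_id", "group"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"layout is missing columns: {sorted(missing)}")
        if self.table["well"].duplicated().any():
            dups = self.table.loc[self.table["well"].duplicated(), "well"].tolist()
            raise ValueError(f"duplicate wells in layout: {dups}")

    @classmethod
    def from_csv(cls, path) -> "PlateLayout":
        return cls(pd.read_csv(path, keep_default_na=False))

    def control_group(self, fallback: str | None = None) -> str:
        """The control group: from the layout's ``role`` column, else the
        explicitly supplied fallback.  Never inferred from group names."""
        if "role" in self.table.columns:
            controls = self.table.loc[self.table["role"] == "control", "group"].unique()
            if len(controls) > 1:
                raise ValueError(f"multiple control groups designated: {controls.tolist()}")
            if len(controls) == 1:
                return str(controls[0])
        if fallback is None:
            raise ValueError("no control group designated in layout and none supplied")
        if fallback not in set(self.table["group"]):
            raise ValueError(f"control group {fallback!r} not present in layout")
        return fallback


@dataclass
class PlateAnalysis:
    """All pipeline outputs for one plate."""

    fish_metrics: pd.DataFrame
    ratios: pd.DataFrame
    group_stats: pd.DataFrame
    anova: dict
    log: list[str] = field(default_factory=list)


def _read_stack(path: Path, config: AnalysisConfig, channel: str) -> ZStack:
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        arr = arr[None]
    return ZStack(arr.astype(float), z_step_um=1.0, pixel_size_um=config.pixel_size_um, channel=channel)


def _empty_metrics_row(well: str, meta: pd.Series, hpf: int, n_rings: int) -> dict:
    row = {
        "well": well,
        "fish_id": meta["fish_id"],
        "group": meta["group"],
        "concentration_um": meta.get("concentration_um", 0.0),
        "tp_hpf": hpf,
        "body_cx_um": np.nan,
        "body_cy_um": np.nan,
        "integrated_intensity": 0.0,
        "n_foci": 0,
        "main_cx_um": np.nan,
        "main_cy_um": np.nan,
        "main_area_um2": np.nan,
        "main_mean_radius_um": np.nan,
    }
    for b in range(n_rings + 1):
        row[f"ring{b}_count"] = 0
        row[f"ring{b}_area_um2"] = 0.0
    row["qc_flags"] = ""
    return row


def analyze_plate(
    layout: PlateLayout | str | Path,
    config: AnalysisConfig,
    image_dir: str | Path,
    out_dir: str | Path | None = None,
    control: str | None = None,
) -> PlateAnalysis:
    """Run the full quantification pipeline over one plate.

    The control group must be resolvable (layout ``role`` column or the
    ``control`` argument / config) before any image is read.  Unreadable
    stacks are recorded as per-well failures and the run continues.
    Deterministic given the config: rerunning writes byte-identical CSVs.
    """
    if not isinstance(layout, PlateLayout):
        layout = PlateLayout.from_csv(layout)
    control_name = layout.control_group(control or config.control_group)
    image_dir = Path(image_dir)
    n_rings = len(config.ring_radii_um)
    log: list[str] = [f"control group: {control_name}"]

    rows = []
    records: list[FishRecord] = []
    for _, meta in layout.table.iterrows():
        well = meta["well"]
        for tp_code, hpf in _TP_CODE.items():
            row = _empty_metrics_row(well, meta, hpf, n_rings)
            qc: set[str] = set()
            try:
                body_stack = _read_stack(image_dir / f"{well}_body_{tp_code}.tif", config, "body")
                tumor_stack = _read_stack(image_dir / f"{well}_tumor_{tp_code}.tif", config, "tumor")
            except (FileNotFoundError, OSError, ValueError) as e:
                qc.add("unreadable_image")
                log.append(f"{well} tp{tp_code}: unreadable image ({e})")
                row["qc_flags"] = ";".join(sorted(qc))
                rows.append(row)
                records.append(FishRecord(well, meta["group"], hpf, 0.0, None, qc))
                continue

            body = best_focus_composite(body_stack, config.focus_mode, config.tile_px)
            detection = body_centroid(
                body.image,
                threshold_mode=config.body_threshold_mode,
                k=config.k,
                pixel_size_um=config.pixel_size_um,
            )
            if detection.ok:
                row["body_cx_um"], row["body_cy_um"] = detection.centroid_um
            else:
                qc.add("detection_failed")
            log.append(f"{well} tp{tp_code}: body detection ok={detection.ok}")

            tumor = best_focus_composite(tumor_stack, config.focus_mode, config.tile_px)
            seg = segment_tumors(
                tumor.image,
                pixel_size_um=config.pixel_size_um,
                threshold_mode=config.threshold_mode,
                k=config.k,
                min_area_um2=config.min_area_um2,
            )
            row["n_foci"] = seg.n_foci
            intensity = integrated_fluorescence(seg)
            row["integrated_intensity"] = intensity
            ring_bins = None
            try:
                main = identify_main_tumor(seg)
                row["main_cx_um"], row["main_cy_um"] = main.centroid_um
                row["main_area_um2"] = main.area_um2
                row["main_mean_radius_um"] = main.mean_radius_um
                ring_bins = summarize_migration(seg, main, config.ring_radii_um)
                for b in range(n_rings + 1):
                    row[f"ring{b}_count"] = int(ring_bins.counts[b])
                    row[f"ring{b}_area_um2"] = float(ring_bins.areas_um2[b])
            except NoTumorError:
                qc.add("no_tumor")
            log.append(f"{well} tp{tp_code}: segmentation foci={seg.n_foci} intensity={intensity:.1f}")

            row["qc_flags"] = ";".join(sorted(qc))
            rows.append(row)
            records.append(FishRecord(well, meta["group"], hpf, intensity, ring_bins, qc))

    fish_metrics = pd.DataFrame(rows)

    pairs, unpaired = match_timepoints(records)
    for r in unpaired:
        log.append(f"{r.well}: unpaired timepoint ({r.tp} hpf)")
    baselines = [
        r72.integrated_intensity for r72, _ in pairs if "no_tumor" not in r72.qc_flags
    ]
    min_baseline = config.min_baseline_frac * float(np.median(baselines)) if baselines else 0.0
    log.append(f"baseline gate: {min_baseline:.2f}")

    ratio_rows = []
    for r72, r120 in pairs:
        flags = r72.qc_flags | r120.qc_flags
        if flags & {"no_tumor", "dead", "unreadable_image"}:
            result_reason = ";".join(sorted(flags & {"no_tumor", "dead", "unreadable_image"}))
            ratio_rows.append(
                {"well": r72.well, "group": r72.group, "ratio": np.nan,
                 "included": False, "reason": result_reason}
            )
            log.append(f"{r72.well}: excluded from ratios ({result_reason})")
            continue
        res = proliferation_ratio(
            r120.integrated_intensity, r72.integrated_intensity, min_baseline, r72.well, r72.group
        )
        ratio_rows.append(
            {"well": res.well, "group": res.group,
             "ratio": res.ratio if res.included else np.nan,
             "included": res.included, "reason": res.reason}
        )
        if not res.included:
            log.append(f"{res.well}: excluded from ratios ({res.reason})")
    ratios = pd.DataFrame(ratio_rows)

    included = ratios[ratios["included"]]
    groups = {
        g: sub["ratio"].to_numpy() for g, sub in included.groupby("group") if len(sub) >= 2
    }
    anova_info: dict = {}
    if control_name in groups and len(groups) >= 2:
        comparison = anova_dunnett(groups, control_name, config.alpha, seed=config.seed)
        group_stats = comparison.summary()
        anova_info = {"F": comparison.statistic, "p": comparison.p, "control": control_name}
        log.append(f"ANOVA: F={comparison.statistic:.4g} p={comparison.p:.4g}")
    else:
        stats_rows = []
        for g, v in groups.items():
            mean = float(np.mean(v))
            sem = float(np.std(v, ddof=1) / math.sqrt(len(v))) if len(v) > 1 else np.nan
            stats_rows.append({"group": g, "n": len(v), "mean": mean, "sem": sem})
        group_stats = pd.DataFrame(stats_rows)
        log.append("group statistics: not enough groups/samples for ANOVA; summary only")

    analysis = PlateAnalysis(fish_metrics, ratios, group_stats, anova_info, log)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        fish_metrics.to_csv(out_dir / "fish_metrics.csv", index=False)
        ratios.to_csv(out_dir / "ratios.csv", index=False)
        group_stats.to_csv(out_dir / "group_stats.csv", index=False)
        (out_dir / "config_echo.json").write_text(json.dumps(config.to_dict(), indent=2, sort_keys=True))
        (out_dir / "run.log").write_text("\n".join(log) + "\n")
    return analysis


def run_toxicity(
    table_csv: str | Path | ToxicityTable, out_dir: str | Path | None = None
) -> tuple[pd.DataFrame, float]:
    """LD50 brackets for every compound plus the working concentration.

    Returns (brackets table, max safe concentration in µM) and optionally
    writes ``ld50_brackets.csv``; the upper edge of an uncrossed bracket is
    reported as ``inf``.
    """
    table = table_csv if isinstance(table_csv, ToxicityTable) else ToxicityTable.from_csv(table_csv)
    rows = []
    for compound in table.compounds:
        br = ld50_bracket(compound, table.concentrations_um, table.row(compound))
        rows.append({"compound": compound, "ld50_lower_um": br.lower_um, "ld50_upper_um": br.upper_um})
    brackets = pd.DataFrame(rows).sort_values("compound", kind="stable").reset_index(drop=True)
    safe = max_safe_concentration(table)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        brackets.to_csv(out_dir / "ld50_brackets.csv", index=False)
        (out_dir / "working_concentration.json").write_text(
            json.dumps({"max_safe_concentration_um": safe})
        )
    return brackets, safe
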