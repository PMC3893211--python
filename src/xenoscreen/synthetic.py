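"""Ground-truthed synthetic plates for the xenograft screening pipeline.

Real screens image each well of a 96-well plate twice (72 and 120 hpf),
acquiring a defocused z-stack per channel: an EGFP body channel showing the
larva and a Kusabira-orange (TRITC-range) tumor channel showing the
implanted cells.  No public image data accompanies the assay, so every
downstream stage is exercised against scenes generated here, where the body
position, every tumor focus (centre, radius, peak), and the per-group tumor
growth factor are known exactly.

Scenes are rendered as: an elongated body (intensity ellipse with a tapered
tail) in the body channel; one main tumor mass near the yolk position plus
0-20 smaller migration foci at controlled distances in the tumor channel,
each an isotropic Gaussian profile whose *radius* is the half-width at half
maximum.  Z-stacks apply a Gaussian defocus blur growing linearly with
distance from the focal slice, then an additive background, optional Poisson
shot noise and Gaussian read noise.  All randomness is seeded; identical
seeds give byte-identical images.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy.ndimage import gaussian_filter

from .acquisition import ZStack

__all__ = [
    "AcquisitionParams",
    "GroundTruthFocus",
    "SyntheticScene",
    "SyntheticPlate",
    "generate_scene",
    "render_ideal",
    "render_zstack",
    "generate_plate",
]

# HWHM-to-sigma conversion for a Gaussian profile: I(r) = peak/2 at r = HWHM
_HWHM_TO_SIGMA = 1.0 / np.sqrt(2.0 * np.log(2.0))

_CHANNELS = ("body", "tumor")
_CHANNEL_CODE = {"body": 1, "tumor": 2}


@dataclass(frozen=True)
class AcquisitionParams:
    """Imaging geometry and noise settings for synthetic acquisition.

    Defaults mirror the low-magnification pass of the assay: five z-slices
    stepped 40 µm with the middle slice in focus.  ``blur_per_um`` is the
    Gaussian blur sigma (µm of lateral blur) added per µm of defocus;
    ``pixel_size_um`` has no stated experimental value and simply calibrates
    all geometry, which is computed in µm throughout.
    """

    pixel_size_um: float = 3.25
    n_slices: int = 5
    z_step_um: float = 40.0
    focus_index: int = 2
    blur_per_um: float = 0.05
    background_level: float = 100.0
    shot_noise: bool = True
    read_noise_sd: float = 2.0
    image_shape: tuple[int, int] = (256, 256)

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.n_slices < 1:
            raise ValueError("n_slices must be >= 1")
        if not 0 <= self.focus_index < self.n_slices:
            raise ValueError("focus_index must lie in [0, n_slices)")
        if self.z_step_um <= 0:
            raise ValueError("z_step_um must be positive")
        if self.blur_per_um < 0 or self.background_level < 0 or self.read_noise_sd < 0:
            raise ValueError("blur_per_um, background_level, read_noise_sd must be >= 0")
        if len(self.image_shape) != 2 or min(self.image_shape) < 8:
            raise ValueError("image_shape must be (rows, cols) with both >= 8")

    @property
    def field_um(self) -> tuple[float, float]:
        """Field of view (width, height) in µm."""
        return (self.image_shape[1] * self.pixel_size_um, self.image_shape[0] * self.pixel_size_um)


@dataclass
class GroundTruthFocus:
    """A single tumor focus as planted in a synthetic scene."""

    center_um: tuple[float, float]
    radius_um: float
    peak_intensity: float
    is_main: bool = False

    def __post_init__(self) -> None:
        if self.radius_um <= 0:
            raise ValueError("radius_um must be positive")

    @property
    def sigma_um(self) -> float:
        return self.radius_um * _HWHM_TO_SIGMA

    def total_intensity(self) -> float:
        """Analytic integral of the Gaussian profile over the plane, per µm²."""
        return 2.0 * np.pi * self.sigma_um**2 * self.peak_intensity


@dataclass
class SyntheticScene:
    """Ground truth for one fish: body geometry plus planted tumor foci.

    ``body_center_um`` is the intensity-weighted centroid of the ideal
    (noise- and blur-free) body image, i.e. the centre of brightness a
    perfect detector would report; the ellipse centre is kept separately
    because the tapered tail skews the centroid tailward.
    """

    body_center_um: tuple[float, float]
    body_axes_um: tuple[float, float]
    body_intensity: float
    foci: list[GroundTruthFocus]
    growth_factor: float
    seed: int
    ellipse_center_um: tuple[float, float] = (0.0, 0.0)
    tail_length_um: float = 0.0

    def __post_init__(self) -> None:
        if self.growth_factor < 0:
            raise ValueError("growth_factor must be >= 0")
        if sum(f.is_main for f in self.foci) != 1:
            raise ValueError("exactly one focus must be the main tumor")

    @property
    def main_focus(self) -> GroundTruthFocus:
        return next(f for f in self.foci if f.is_main)

    def migration_distances_um(self) -> np.ndarray:
        """Euclidean distances of non-main foci from the main focus centre."""
        mx, my = self.main_focus.center_um
        return np.array(
            [np.hypot(f.center_um[0] - mx, f.center_um[1] - my) for f in self.foci if not f.is_main]
        )


def _grid_um(params: AcquisitionParams) -> tuple[np.ndarray, np.ndarray]:
    """Pixel-centre coordinates in µm (x = column, y = row, origin top-left)."""
    rows, cols = params.image_shape
    y = np.arange(rows)[:, None] * params.pixel_size_um
    x = np.arange(cols)[None, :] * params.pixel_size_um
    return x, y


def _ideal_body(scene: SyntheticScene, params: AcquisitionParams) -> np.ndarray:
    x, y = _grid_um(params)
    cx, cy = scene.ellipse_center_um
    a, b = scene.body_axes_um
    img = np.zeros(params.image_shape)
    inside = ((x - cx) / a) ** 2 + ((y - cy) / b) ** 2 <= 1.0
    img[inside] = scene.body_intensity
    # tapered tail: half-height and intensity both shrink linearly over tail_length
    if scene.tail_length_um > 0:
        u = (x - (cx + a)) / scene.tail_length_um
        in_tail = (u >= 0) & (u <= 1) & (np.abs(y - cy) <= 0.5 * b * (1.0 - u))
        tail_val = scene.body_intensity * (1.0 - 0.7 * u)
        img = np.where(in_tail & ~inside, tail_val, img)
    return img


def _ideal_tumor(scene: SyntheticScene, params: AcquisitionParams) -> np.ndarray:
    x, y = _grid_um(params)
    img = np.zeros(params.image_shape)
    for f in scene.foci:
        r2 = (x - f.center_um[0]) ** 2 + (y - f.center_um[1]) ** 2
        img += f.peak_intensity * np.exp(-r2 / (2.0 * f.sigma_um**2))
    return img


def render_ideal(
    scene: SyntheticScene, params: AcquisitionParams, channel: str, timepoint: int = 1
) -> np.ndarray:
    """Noise- and blur-free image of one channel, without background.

    At the second timepoint the tumor channel is scaled by the scene's
    growth factor; the body channel does not change between timepoints.
    """
    if channel not in _CHANNELS:
        raise ValueError("channel must be 'body' or 'tumor'")
    if timepoint not in (1, 2):
        raise ValueError("timepoint must be 1 or 2")
    if channel == "body":
        return _ideal_body(scene, params)
    img = _ideal_tumor(scene, params)
    if timepoint == 2:
        img = img * scene.growth_factor
    return img


def generate_scene(
    params: AcquisitionParams,
    n_migration_foci: int,
    distance_spec: list[float],
    growth_factor: float,
    seed: int,
    *,
    main_radius_um: float = 40.0,
    main_peak: float = 3000.0,
    migration_radius_range_um: tuple[float, float] = (8.0, 16.0),
    migration_peak: float = 1200.0,
    body_intensity: float = 1000.0,
) -> SyntheticScene:
    """Build a ground-truth scene with controlled migration distances.

    One main focus is planted near the yolk position (anterior-ventral to
    the body centre); each requested migration focus is placed at exactly
    its ``distance_spec`` entry (in µm) from the main focus centre, at a
    seeded random angle biased toward the tail.  A distance that cannot be
    placed inside the image bounds raises a ``ValueError`` naming the focus
    index.  Identical arguments and seed reproduce the scene bit-for-bit.
    """
    if len(distance_spec) != n_migration_foci:
        raise ValueError("distance_spec length must equal n_migration_foci")
    if any(d < 0 for d in distance_spec):
        raise ValueError("migration distances must be >= 0")

    rng = np.random.default_rng(seed)
    w_um, h_um = params.field_um

    # body: horizontal ellipse, slightly jittered, tail toward +x
    ecx = 0.42 * w_um + rng.uniform(-0.03, 0.03) * w_um
    ecy = 0.50 * h_um + rng.uniform(-0.04, 0.04) * h_um
    a = 0.28 * w_um
    b = 0.10 * h_um
    tail_len = 0.22 * w_um

    # main tumor near the yolk: anterior-ventral of the body centre
    main_center = (ecx - 0.45 * a, ecy + 0.55 * b)
    main = GroundTruthFocus(
        center_um=main_center,
        radius_um=main_radius_um * rng.uniform(0.9, 1.1),
        peak_intensity=main_peak * rng.uniform(0.9, 1.1),
        is_main=True,
    )
    foci = [main]
    for i, dist in enumerate(distance_spec):
        radius = rng.uniform(*migration_radius_range_um)
        margin = 2.0 * radius + 2.0 * params.pixel_size_um
        placed = False
        for _ in range(256):
            # bias toward the tail (+x) where migration is scored in vivo
            theta = rng.uniform(-75.0, 75.0) * np.pi / 180.0
            cx = main_center[0] + dist * np.cos(theta)
            cy = main_center[1] + dist * np.sin(theta)
            if margin <= cx <= w_um - margin and margin <= cy <= h_um - margin:
                foci.append(
                    GroundTruthFocus(
                        center_um=(cx, cy),
                        radius_um=radius,
                        peak_intensity=migration_peak * rng.uniform(0.8, 1.2),
                        is_main=False,
                    )
                )
                placed = True
                break
        if not placed:
            raise ValueError(
                f"migration focus {i}: distance {dist} um cannot fit inside the image bounds"
            )

    scene = SyntheticScene(
        body_center_um=(0.0, 0.0),
        body_axes_um=(a, b),
        body_intensity=body_intensity,
        foci=foci,
        growth_factor=growth_factor,
        seed=int(seed),
        ellipse_center_um=(ecx, ecy),
        tail_length_um=tail_len,
    )
    # record the centre of brightness of the ideal body image as the truth
    body = _ideal_body(scene, params)
    total = body.sum()
    x, y = _grid_um(params)
    scene.body_center_um = (float((body * x).sum() / total), float((body * y).sum() / total))
    return scene


def render_zstack(
    scene: SyntheticScene, params: AcquisitionParams, channel: str, timepoint: int = 1
) -> ZStack:
    """Render the defocused z-stack of one channel at one timepoint.

    Slice ``i`` is the ideal image convolved with a normalized Gaussian
    kernel of sigma ``blur_per_um * |i - focus_index| * z_step_um`` (in µm,
    converted to pixels), plus the background offset and, when enabled,
    Poisson shot noise and Gaussian read noise.  With noise off, the
    focal slice equals the ideal image plus background exactly.
    """
    ideal = render_ideal(scene, params, channel, timepoint)
    slices = np.empty((params.n_slices,) + tuple(params.image_shape))
    for i in range(params.n_slices):
        defocus_um = abs(i - params.focus_index) * params.z_step_um
        sigma_px = params.blur_per_um * defocus_um / params.pixel_size_um
        img = gaussian_filter(ideal, sigma_px, mode="nearest") if sigma_px > 0 else ideal.copy()
        img = img + params.background_level
        if params.shot_noise or params.read_noise_sd > 0:
            ss = np.random.SeedSequence(
                [scene.seed, _CHANNEL_CODE[channel], timepoint, i]
            )
            rng = np.random.default_rng(ss)
            if params.shot_noise:
                img = rng.poisson(np.clip(img, 0, None)).astype(float)
            if params.read_noise_sd > 0:
                img = img + rng.normal(0.0, params.read_noise_sd, img.shape)
        slices[i] = np.clip(img, 0.0, None)
    return ZStack(
        slices=slices,
        z_step_um=params.z_step_um,
        pixel_size_um=params.pixel_size_um,
        channel=channel,
    )


def _well_name(index: int) -> str:
    row, col = divmod(index, 12)
    return f"{chr(ord('A') + row)}{col + 1:02d}"


def _to_uint16(stack: np.ndarray) -> np.ndarray:
    return np.clip(np.rint(stack), 0, 65535).astype(np.uint16)


@dataclass
class SyntheticPlate:
    """Handle onto a generated plate directory and its ground truth."""

    directory: Path
    layout: pd.DataFrame
    truth_scenes: pd.DataFrame
    truth_foci: pd.DataFrame
    scenes: dict[str, SyntheticScene] = field(default_factory=dict)


def generate_plate(
    out_dir: str | Path,
    n_fish_per_group: int,
    group_effects: dict[str, float],
    params: AcquisitionParams,
    seed: int,
    *,
    group_concentrations: dict[str, float] | None = None,
    n_migration_range: tuple[int, int] = (0, 5),
    distance_range_um: tuple[float, float] = (100.0, 500.0),
    control_group: str | None = None,
) -> SyntheticPlate:
    """Write a full synthetic plate: TIFF stacks, layout and truth tables.

    For every fish, one multi-page 16-bit TIFF per channel per timepoint is
    written as ``{well}_{channel}_{tp}.tif``, together with ``layout.csv``
    (well → fish, group, concentration, optional control role),
    ``truth_scenes.csv`` / ``truth_foci.csv`` (per-scene and per-focus
    ground truth) and a ``params.json`` sidecar echoing every generation
    parameter.  Wells are filled row-major (A01, A02, ...).
    """
    out_dir = Path(out_dir)
    n_wells = n_fish_per_group * len(group_effects)
    if n_wells > 96:
        raise ValueError(f"{n_wells} wells requested; a plate has 96")
    if n_migration_range[0] < 0 or n_migration_range[1] < n_migration_range[0]:
        raise ValueError("invalid n_migration_range")
    out_dir.mkdir(parents=True, exist_ok=True)

    rng = np.random.default_rng(seed)
    group_concentrations = group_concentrations or {}

    layout_rows, scene_rows, focus_rows = [], [], []
    scenes: dict[str, SyntheticScene] = {}
    idx = 0
    for group, growth in group_effects.items():
        for _ in range(n_fish_per_group):
            well = _well_name(idx)
            fish_id = f"F{idx + 1:03d}"
            scene_seed = int(rng.integers(2**31))
            n_mig = int(rng.integers(n_migration_range[0], n_migration_range[1] + 1))
            scene = None
            for _attempt in range(20):
                distances = rng.uniform(*distance_range_um, size=n_mig).tolist()
                try:
                    scene = generate_scene(params, n_mig, distances, growth, scene_seed)
                    break
                except ValueError:
                    continue
            if scene is None:
                raise RuntimeError(f"could not place migration foci for well {well}")
            scenes[well] = scene

            for channel in _CHANNELS:
                for tp in (1, 2):
                    stack = render_zstack(scene, params, channel, tp)
                    tifffile.imwrite(
                        out_dir / f"{well}_{channel}_{tp}.tif",
                        _to_uint16(stack.slices),
                        photometric="minisblack",
                    )

            role = "control" if group == control_group else ""
            layout_rows.append(
                {
                    "well": well,
                    "fish_id": fish_id,
                    "group": group,
                    "concentration_um": group_concentrations.get(group, 0.0),
                    "role": role,
                }
            )
            scene_rows.append(
                {
                    "well": well,
                    "fish_id": fish_id,
                    "group": group,
                    "growth_factor": growth,
                    "scene_seed": scene.seed,
                    "body_cx_um": scene.body_center_um[0],
                    "body_cy_um": scene.body_center_um[1],
                    "n_migration_foci": n_mig,
                }
            )
            for j, f in enumerate(scene.foci):
                mx, my = scene.main_focus.center_um
                focus_rows.append(
                    {
                        "well": well,
                        "focus_index": j,
                        "center_x_um": f.center_um[0],
                        "center_y_um": f.center_um[1],
                        "radius_um": f.radius_um,
                        "peak_intensity": f.peak_intensity,
                        "is_main": f.is_main,
                        "distance_um": float(np.hypot(f.center_um[0] - mx, f.center_um[1] - my)),
                    }
                )
            idx += 1

    layout = pd.DataFrame(layout_rows)
    truth_scenes = pd.DataFrame(scene_rows)
    truth_foci = pd.DataFrame(focus_rows)
    layout.to_csv(out_dir / "layout.csv", index=False)
    truth_scenes.to_csv(out_dir / "truth_scenes.csv", index=False)
    truth_foci.to_csv(out_dir / "truth_foci.csv", index=False)
    sidecar = {
        "params": asdict(params),
        "n_fish_per_group": n_fish_per_group,
        "group_effects": group_effects,
        "group_concentrations": group_concentrations,
        "n_migration_range": list(n_migration_range),
        "distance_range_um": list(distance_range_um),
        "seed": int(seed),
    }
    (out_dir / "params.json").write_text(json.dumps(sidecar, indent=2, sort_keys=True))
    return SyntheticPlate(out_dir, layout, truth_scenes, truth_foci, scenes)
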