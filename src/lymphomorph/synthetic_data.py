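"""Synthetic ground-truth generators for every pipeline input.

No raw microscopy or behavioral data ship with this package, so each stage
is validated by parameter recovery on simulated data: tubular vessels with a
known diameter profile, labeled brain volumes seeded with spherical plaques
at known per-region burden, two-group studies with a specified reduction
effect, correlated-random-walk swim trajectories, Beta-distributed object
exploration, and first-order-exponential temperature traces.

Every generator is a pure function of its parameters and a seed, and every
dataset ships with a :class:`SyntheticTruth` sidecar recording the true
generating parameters; recovery tests read truth only from the sidecar.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Callable

import numpy as np
from scipy import ndimage

from .behavior_metrics import ExplorationRecord, Trajectory
from .imaging_io import BrainVolume, LabelVolume, VesselImage
from .physiology_kinetics import ProtocolSchedule, TemperatureTrace


class GeneratorError(ValueError):
    pass


@dataclasses.dataclass
class SyntheticTruth:
    """Generating parameters attached to every simulated dataset."""

    generator: str
    seed: int
    params: dict

    def to_json(self, path: str | Path) -> None:
        def _default(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (np.integer, np.floating)):
                return o.item()
            raise TypeError(type(o))

        Path(path).write_text(
            json.dumps(dataclasses.asdict(self), indent=2, default=_default)
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        data = json.loads(Path(path).read_text())
        return cls(**data)


# ---------------------------------------------------------------------------
# vessel images
# ---------------------------------------------------------------------------


def gen_vessel_image(
    length_px: int = 200,
    diameter_px: float | Callable[[np.ndarray], np.ndarray] = 7.0,
    orientation_deg: float = 0.0,
    contrast: float = 100.0,
    background: float = 0.0,
    noise_sigma: float = 0.0,
    psf_sigma_px: float = 0.0,
    spacing_um: float = 1.0,
    margin_px: int = 12,
    seed: int = 0,
) -> tuple[VesselImage, SyntheticTruth]:
    """Rasterize a straight tube of known width profile at a given angle.

    ``diameter_px`` is either a constant or a function of arclength (px).
    The tube is rendered analytically in the rotated frame (foreground where
    the perpendicular distance to the midline is below half the local
    width), then blurred with a Gaussian PSF and degraded with additive
    Gaussian noise. Same seed ⇒ bit-identical output.
    """
    s_grid = np.arange(0.0, length_px + 1.0)
    if callable(diameter_px):
        widths = np.asarray([float(diameter_px(s)) for s in s_grid])
    else:
        widths = np.full_like(s_grid, float(diameter_px))
    if widths.min() < 3:
        raise GeneratorError("diameter below 3 px is under the measurable resolution")

    max_w = float(widths.max())
    theta = np.deg2rad(orientation_deg)
    side = int(
        np.ceil(
            length_px * max(abs(np.cos(theta)), abs(np.sin(theta)))
            + max_w
            + 2 * margin_px
        )
    )
    yy, xx = np.mgrid[0:side, 0:side].astype(np.float64)
    # quarter-pixel midline offset: an exactly lattice-aligned midline is a
    # measure-zero configuration in real acquisitions and maximizes
    # rasterization quantization at 0/45 degrees
    cy = (side - 1) / 2.0 - 0.15
    cx = (side - 1) / 2.0 + 0.15
    # coordinates in the tube frame: s along the midline, d across it
    s = np.cos(theta) * (xx - cx) + np.sin(theta) * (yy - cy) + length_px / 2.0
    d = -np.sin(theta) * (xx - cx) + np.cos(theta) * (yy - cy)
    w_local = np.interp(np.clip(s, 0, length_px), s_grid, widths)
    fg = (s >= 0) & (s <= length_px) & (np.abs(d) <= w_local / 2.0)

    img = background + contrast * fg.astype(np.float64)
    if psf_sigma_px > 0:
        img = ndimage.gaussian_filter(img, psf_sigma_px)
    rng = np.random.default_rng(seed)
    if noise_sigma > 0:
        img = img + rng.normal(0.0, noise_sigma, img.shape)
    truth = SyntheticTruth(
        generator="gen_vessel_image",
        seed=seed,
        params={
            "length_px": length_px,
            "orientation_deg": orientation_deg,
            "contrast": contrast,
            "background": background,
            "noise_sigma": noise_sigma,
            "psf_sigma_px": psf_sigma_px,
            "spacing_um": spacing_um,
            "diameter_px_profile": widths,
            "mean_diameter_px": float(widths.mean()),
            "mean_diameter_um": float(widths.mean() * spacing_um),
        },
    )
    return VesselImage(img, spacing_um, name=f"synthetic_vessel_{seed}"), truth


# ---------------------------------------------------------------------------
# label volumes and plaque fields
# ---------------------------------------------------------------------------


def gen_label_volume(
    shape: tuple[int, int, int],
    region_spec: list[tuple[int, str, dict]],
) -> LabelVolume:
    """Build a label volume from disjoint box or sphere regions.

    Each region is ``(label, acronym, geometry)`` where geometry is either
    ``{"box": ((z0, z1), (y0, y1), (x0, x1))}`` (half-open bounds) or
    ``{"sphere": (center_zyx, radius_vox)}``. Overlapping regions are an
    error; an empty spec yields an all-background volume.
    """
    labels = np.zeros(shape, dtype=np.int32)
    names: dict[int, str] = {}
    for label, acronym, geom in region_spec:
        if label <= 0:
            raise GeneratorError("region labels must be positive")
        mask = np.zeros(shape, dtype=bool)
        if "box" in geom:
            (z0, z1), (y0, y1), (x0, x1) = geom["box"]
            mask[z0:z1, y0:y1, x0:x1] = True
        elif "sphere" in geom:
            center, radius = geom["sphere"]
            zz, yy, xx = np.ogrid[0 : shape[0], 0 : shape[1], 0 : shape[2]]
            mask = (
                (zz - center[0]) ** 2 + (yy - center[1]) ** 2 + (xx - center[2]) ** 2
            ) <= radius**2
        else:
            raise GeneratorError(f"unknown geometry for label {label}: {geom}")
        if np.any(labels[mask] != 0):
            raise GeneratorError(f"region {label} overlaps an existing region")
        labels[mask] = label
        names[label] = acronym
    return LabelVolume(labels, names)


def _sphere_offsets(radius: float) -> np.ndarray:
    r = int(np.floor(radius))
    zz, yy, xx = np.mgrid[-r : r + 1, -r : r + 1, -r : r + 1]
    keep = zz**2 + yy**2 + xx**2 <= radius**2
    return np.stack([zz[keep], yy[keep], xx[keep]], axis=1)


def gen_plaque_volume(
    labels: LabelVolume,
    per_region_volume_fraction: dict[int, float],
    plaque_radius_vox_range: tuple[float, float] = (2.0, 5.0),
    snr: float = 10.0,
    background: float = 100.0,
    noise_sd: float = 10.0,
    spacing_um: tuple[float, float, float] = (5.0, 5.0, 5.0),
    seed: int = 0,
    max_failures: int = 2000,
) -> tuple[BrainVolume, SyntheticTruth]:
    """Seed each region with non-overlapping bright spheres at a target burden.

    Spheres of uniform-random radius are placed at uniform-random centers
    fully inside their region until the realized plaque-voxel fraction
    reaches the target. A candidate sphere is only placed while doing so
    keeps the running total within half its own volume of the target, so the
    realized fraction lands within one sphere's volume of the target and the
    quantization error is symmetric (no systematic overshoot that would bias
    between-group ratios). Plaque amplitude is ``snr × noise_sd``
    above the background, and Gaussian noise of SD ``noise_sd`` is added
    everywhere. Truth records the *realized* fraction and sphere centers.
    """
    rng = np.random.default_rng(seed)
    grid = labels.labels
    occupied = np.zeros(grid.shape, dtype=bool)
    # inflated footprint keeps placed spheres >1 voxel apart so they stay
    # separate 26-connected components for the detector
    blocked = np.zeros(grid.shape, dtype=bool)
    realized: dict[int, dict] = {}
    r_lo, r_hi = plaque_radius_vox_range
    for label, target in sorted(per_region_volume_fraction.items()):
        if not (0.0 <= target <= 0.2):
            raise GeneratorError("target volume fraction must be in [0, 0.2]")
        region_idx = np.argwhere(grid == label)
        if region_idx.size == 0:
            raise GeneratorError(f"label {label} absent from label volume")
        n_region = len(region_idx)
        target_vox = target * n_region
        placed_vox = 0
        centers: list[list[float]] = []
        radii: list[float] = []
        failures = 0
        while placed_vox < target_vox:
            if failures >= max_failures:
                raise GeneratorError(
                    f"target fraction {target} unreachable without overlap in "
                    f"region {label}"
                )
            radius = rng.uniform(r_lo, r_hi)
            offsets = _sphere_offsets(radius)
            if placed_vox + len(offsets) / 2.0 > target_vox:
                break  # placing would overshoot more than stopping undershoots
            center = region_idx[rng.integers(n_region)]
            vox = center[np.newaxis, :] + offsets
            if (
                np.any(vox < 0)
                or np.any(vox >= np.asarray(grid.shape)[np.newaxis, :])
            ):
                failures += 1
                continue
            flat = tuple(vox.T)
            if np.any(grid[flat] != label) or np.any(blocked[flat]):
                failures += 1
                continue
            occupied[flat] = True
            inflated = center[np.newaxis, :] + _sphere_offsets(radius + 1.8)
            inflated = inflated[
                np.all(inflated >= 0, axis=1)
                & np.all(inflated < np.asarray(grid.shape)[np.newaxis, :], axis=1)
            ]
            blocked[tuple(inflated.T)] = True
            placed_vox += len(vox)
            centers.append([float(c) for c in center])
            radii.append(float(radius))
            failures = 0
        realized[label] = {
            "target_fraction": target,
            "realized_fraction": placed_vox / n_region,
            "n_plaques": len(centers),
            "centers_zyx": centers,
            "radii_vox": radii,
        }
    amplitude = snr * noise_sd
    volume = (
        background
        + amplitude * occupied.astype(np.float64)
        + rng.normal(0.0, noise_sd, grid.shape)
    )
    truth = SyntheticTruth(
        generator="gen_plaque_volume",
        seed=seed,
        params={
            "snr": snr,
            "background": background,
            "noise_sd": noise_sd,
            "amplitude": amplitude,
            "spacing_um": list(spacing_um),
            "regions": realized,
        },
    )
    return (
        BrainVolume(volume, spacing_um, channel="Abeta", name=f"synthetic_{seed}"),
        truth,
    )


def gen_group_study(
    labels: LabelVolume,
    base_fraction: float = 0.02,
    effect_fraction: float = 0.39,
    n_control: int = 5,
    n_treated: int = 5,
    between_animal_cv: float = 0.15,
    snr: float = 10.0,
    spacing_um: tuple[float, float, float] = (5.0, 5.0, 5.0),
    seed: int = 0,
) -> list[tuple[BrainVolume, str, SyntheticTruth]]:
    """Simulate a two-group treatment study with a known reduction effect.

    Control animals draw their per-animal plaque burden from a lognormal
    with mean ``base_fraction`` and coefficient of variation
    ``between_animal_cv``; treated animals from the same family with mean
    ``base_fraction × (1 − effect_fraction)``. One labeled plaque volume is
    generated per animal (every region gets the animal's burden).
    """
    if not (0.0 <= effect_fraction < 1.0):
        raise GeneratorError("effect_fraction must be in [0, 1)")
    if between_animal_cv < 0:
        raise GeneratorError("between_animal_cv must be >= 0")
    rng = np.random.default_rng(seed)
    sigma2 = np.log1p(between_animal_cv**2)
    region_labels = sorted(labels.region_voxel_counts())

    def draw_fraction(mean: float) -> float:
        if between_animal_cv == 0:
            return mean
        mu = np.log(mean) - sigma2 / 2.0
        return float(
            np.clip(rng.lognormal(mu, np.sqrt(sigma2)), 1e-6, 0.2)
        )

    study = []
    for group, n, mean in (
        ("control", n_control, base_fraction),
        ("treated", n_treated, base_fraction * (1.0 - effect_fraction)),
    ):
        for i in range(n):
            frac = draw_fraction(mean)
            child_seed = int(rng.integers(0, 2**31 - 1))
            volume, truth = gen_plaque_volume(
                labels,
                {lab: frac for lab in region_labels},
                snr=snr,
                spacing_um=spacing_um,
                seed=child_seed,
            )
            truth.params.update(
                {
                    "group": group,
                    "animal": i,
                    "animal_fraction": frac,
                    "base_fraction": base_fraction,
                    "effect_fraction": effect_fraction,
                    "between_animal_cv": between_animal_cv,
                }
            )
            volume.name = f"{group}_{i}"
            study.append((volume, group, truth))
    return study


# ---------------------------------------------------------------------------
# behavior
# ---------------------------------------------------------------------------


def gen_trajectory(
    arena_center: tuple[float, float] = (0.0, 0.0),
    arena_radius_cm: float = 60.0,
    platform_center: tuple[float, float] = (30.0, 30.0),
    platform_radius_cm: float = 5.0,
    start_xy: tuple[float, float] | None = None,
    mean_speed_cm_s: float = 18.0,
    heading_persistence: float = 0.8,
    goal_bias: float = 0.0,
    trial_cap_s: float = 60.0,
    dt_s: float = 0.1,
    seed: int = 0,
) -> tuple[Trajectory, SyntheticTruth]:
    """Correlated random walk with optional drift toward the platform.

    Heading is a persistence-weighted blend of the previous heading and
    fresh directional noise, mixed with a straight-to-platform component
    weighted by ``goal_bias`` (0 = blind search, 1 = beeline). Positions
    reflect at the arena wall. The walk stops at platform entry or at the
    trial cap; truth records the entry time (None when capped).
    """
    if dt_s <= 0 or mean_speed_cm_s <= 0:
        raise GeneratorError("dt and speed must be positive")
    pd_ = np.hypot(
        platform_center[0] - arena_center[0], platform_center[1] - arena_center[1]
    )
    if pd_ + platform_radius_cm > arena_radius_cm:
        raise GeneratorError("platform outside arena")
    rng = np.random.default_rng(seed)
    if start_xy is None:
        ang = np.arctan2(
            platform_center[1] - arena_center[1], platform_center[0] - arena_center[0]
        )
        start_xy = (
            arena_center[0] - 0.9 * arena_radius_cm * np.cos(ang),
            arena_center[1] - 0.9 * arena_radius_cm * np.sin(ang),
        )
    pos = np.asarray(start_xy, dtype=float)
    heading = rng.normal(size=2)
    heading /= np.linalg.norm(heading)
    ts, xs, ys = [0.0], [pos[0]], [pos[1]]
    entry_time = None
    center = np.asarray(arena_center, dtype=float)
    platform = np.asarray(platform_center, dtype=float)
    n_steps = int(np.ceil(trial_cap_s / dt_s))
    if np.linalg.norm(pos - platform) < platform_radius_cm:
        entry_time = 0.0
    for k in range(1, n_steps + 1):
        if entry_time is not None:
            break
        noise = rng.normal(size=2)
        noise /= np.linalg.norm(noise)
        wander = heading_persistence * heading + (1 - heading_persistence) * noise
        wander /= np.linalg.norm(wander)
        to_goal = platform - pos
        dist_goal = np.linalg.norm(to_goal)
        to_goal = to_goal / dist_goal if dist_goal > 0 else wander
        direction = (1 - goal_bias) * wander + goal_bias * to_goal
        direction /= np.linalg.norm(direction)
        new = pos + mean_speed_cm_s * dt_s * direction
        r = np.linalg.norm(new - center)
        if r > arena_radius_cm:
            # reflect across the wall normal
            normal = (new - center) / r
            new = center + normal * (2 * arena_radius_cm - r)
            direction = direction - 2 * np.dot(direction, normal) * normal
        heading = direction
        pos = new
        ts.append(k * dt_s)
        xs.append(pos[0])
        ys.append(pos[1])
        if np.linalg.norm(pos - platform) < platform_radius_cm:
            entry_time = k * dt_s
    traj = Trajectory(
        np.asarray(ts),
        np.asarray(xs),
        np.asarray(ys),
        arena_center=arena_center,
        arena_radius_cm=arena_radius_cm,
        platform_center=platform_center,
        platform_radius_cm=platform_radius_cm,
    )
    truth = SyntheticTruth(
        generator="gen_trajectory",
        seed=seed,
        params={
            "mean_speed_cm_s": mean_speed_cm_s,
            "heading_persistence": heading_persistence,
            "goal_bias": goal_bias,
            "trial_cap_s": trial_cap_s,
            "entry_time_s": entry_time,
            "start_xy": list(start_xy),
            "start_distance_cm": float(np.linalg.norm(np.asarray(start_xy) - platform)),
        },
    )
    return traj, truth


def gen_exploration(
    preference: float = 0.5,
    total_time_s: float = 50.0,
    concentration: float = 20.0,
    seed: int = 0,
) -> tuple[ExplorationRecord, SyntheticTruth]:
    """Split a total exploration time by a Beta draw centered at ``preference``.

    The realized novel-object share p' ~ Beta(preference·κ, (1−preference)·κ)
    so E[p'] = preference; κ (``concentration``) sets the between-animal
    spread. Degenerate preferences 0 and 1 are returned exactly.
    """
    if not (0.0 <= preference <= 1.0):
        raise GeneratorError("preference must be in [0, 1]")
    if total_time_s <= 0:
        raise GeneratorError("total time must be > 0")
    rng = np.random.default_rng(seed)
    if preference in (0.0, 1.0):
        share = preference
    else:
        share = float(
            rng.beta(preference * concentration, (1.0 - preference) * concentration)
        )
    rec = ExplorationRecord(
        t_novel_s=total_time_s * share, t_familiar_s=total_time_s * (1.0 - share)
    )
    truth = SyntheticTruth(
        generator="gen_exploration",
        seed=seed,
        params={
            "preference": preference,
            "total_time_s": total_time_s,
            "concentration": concentration,
            "realized_share": share,
        },
    )
    return rec, truth


# ---------------------------------------------------------------------------
# temperature traces
# ---------------------------------------------------------------------------


def gen_temperature_trace(
    schedule: ProtocolSchedule,
    baseline_c: float = 37.0,
    rise_c: float = 1.0,
    time_constant_s: float = 60.0,
    noise_sd: float = 0.0,
    dt_s: float = 1.0,
    baseline_duration_s: float = 120.0,
    seed: int = 0,
) -> tuple[TemperatureTrace, SyntheticTruth]:
    """First-order thermal response to the irradiation schedule.

    During irradiation the temperature relaxes exponentially toward
    ``baseline + rise`` with the given time constant; during pauses (and the
    leading baseline window) it relaxes back toward baseline. Gaussian
    measurement noise is added on top.
    """
    if time_constant_s <= 0:
        raise GeneratorError("time constant must be > 0")
    rng = np.random.default_rng(seed)
    segments: list[tuple[str, float, float]] = [("baseline", 0.0, baseline_duration_s)]
    t_cursor = baseline_duration_s
    for seg in schedule.segments:
        segments.append((seg.kind, t_cursor, t_cursor + seg.minutes * 60.0))
        t_cursor += seg.minutes * 60.0
    t = np.arange(0.0, t_cursor + dt_s, dt_s)
    temp = np.empty_like(t)
    current = baseline_c
    seg_iter = iter(segments)
    kind, s0, s1 = next(seg_iter)
    t_ref, t_start = current, 0.0
    for i, ti in enumerate(t):
        while ti >= s1 and s1 < t_cursor:
            try:
                kind, s0, s1 = next(seg_iter)
            except StopIteration:
                break
            t_ref, t_start = current, s0
        target = baseline_c + (rise_c if kind == "irradiation" else 0.0)
        current = target + (t_ref - target) * np.exp(-(ti - t_start) / time_constant_s)
        temp[i] = current
    if noise_sd > 0:
        temp = temp + rng.normal(0.0, noise_sd, temp.shape)
    trace = TemperatureTrace(t, temp, segments)
    truth = SyntheticTruth(
        generator="gen_temperature_trace",
        seed=seed,
        params={
            "baseline_c": baseline_c,
            "rise_c": rise_c,
            "time_constant_s": time_constant_s,
            "noise_sd": noise_sd,
            "baseline_duration_s": baseline_duration_s,
        },
    )
    return trace, truth
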