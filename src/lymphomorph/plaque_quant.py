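"""3D amyloid-plaque detection, atlas-region mapping and density scoring.

Plaques are bright blobs in a cleared-brain light-sheet volume. Detection is
global thresholding (Otsu over the whole volume, or a fixed value) followed
by 26-connected component labeling and a minimum-size filter. Each plaque is
assigned to the atlas region whose label sits at its (rounded) centroid, and
per-region burden is reported two ways:

* ``count_density`` — plaques per mm³ of region volume, and
* ``volume_fraction`` — summed plaque volume over region volume, the
  conventional "plaque burden" and the default headline metric.

Between-group treatment effects are scored as a reduction rate
``100 × (1 − mean(treated) / mean(control))`` on per-animal densities, with
a two-sided Welch t-test attached; a mean-of-per-animal-ratios alternative
is reported alongside.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import ndimage

from . import group_stats
from .imaging_io import BrainVolume, LabelVolume
from .vessel_morphometry import compute_otsu_threshold, VesselError


class PlaqueError(ValueError):
    pass


@dataclasses.dataclass
class Plaque:
    id: int
    centroid_zyx: tuple[float, float, float]  # subvoxel, intensity-weighted
    voxel_count: int
    volume_um3: float
    mean_intensity: float
    region: int = 0  # 0 = background / unassigned


@dataclasses.dataclass
class PlaqueSet:
    plaques: list[Plaque]
    volume_shape: tuple[int, int, int]
    spacing_um: tuple[float, float, float]
    threshold: float
    min_voxels: int

    def __len__(self) -> int:
        return len(self.plaques)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": [p.id for p in self.plaques],
                "z": [p.centroid_zyx[0] for p in self.plaques],
                "y": [p.centroid_zyx[1] for p in self.plaques],
                "x": [p.centroid_zyx[2] for p in self.plaques],
                "voxel_count": [p.voxel_count for p in self.plaques],
                "volume_um3": [p.volume_um3 for p in self.plaques],
                "mean_intensity": [p.mean_intensity for p in self.plaques],
                "region": [p.region for p in self.plaques],
            }
        )


# 26-connectivity: matches the usual blob/surface notion in 3D
_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


def detect_plaques(
    volume: BrainVolume,
    threshold_method: str = "otsu",
    fixed_threshold: float | None = None,
    min_voxels: int = 5,
) -> PlaqueSet:
    """Threshold a volume and extract 26-connected bright components.

    Components smaller than ``min_voxels`` are discarded. Centroids are
    intensity-weighted means of member voxel coordinates (subvoxel).
    """
    if min_voxels < 1:
        raise PlaqueError("min_voxels must be >= 1")
    if threshold_method == "otsu":
        try:
            threshold = compute_otsu_threshold(volume.voxels)
        except VesselError as exc:
            raise PlaqueError(f"cannot threshold: {exc}") from exc
    elif threshold_method == "fixed":
        if fixed_threshold is None:
            raise PlaqueError("fixed_threshold required for method 'fixed'")
        threshold = float(fixed_threshold)
    else:
        raise PlaqueError(f"unknown threshold method {threshold_method!r}")

    fg = volume.voxels > threshold
    labeled, n = ndimage.label(fg, structure=_STRUCT_26)
    plaques: list[Plaque] = []
    if n:
        idx = np.arange(1, n + 1)
        sizes = ndimage.sum_labels(fg, labeled, idx)
        keep = idx[sizes >= min_voxels]
        vox_vol = volume.voxel_volume_um3
        intensities = volume.voxels.astype(np.float64)
        for new_id, lab in enumerate(keep, start=1):
            members = np.argwhere(labeled == lab)
            w = intensities[tuple(members.T)]
            centroid = (members * w[:, None]).sum(axis=0) / w.sum()
            plaques.append(
                Plaque(
                    id=new_id,
                    centroid_zyx=tuple(float(c) for c in centroid),
                    voxel_count=int(len(members)),
                    volume_um3=float(len(members) * vox_vol),
                    mean_intensity=float(w.mean()),
                )
            )
    return PlaqueSet(
        plaques=plaques,
        volume_shape=volume.shape,
        spacing_um=volume.spacing_um,
        threshold=float(threshold),
        min_voxels=int(min_voxels),
    )


def assign_regions(plaques: PlaqueSet, labels: LabelVolume) -> PlaqueSet:
    """Assign each plaque the atlas label at its rounded centroid voxel.

    Plaques whose centroid falls on background keep region 0; they stay in
    the set but are excluded from region tables.
    """
    if tuple(labels.shape) != tuple(plaques.volume_shape):
        raise PlaqueError(
            f"label volume shape {labels.shape} != plaque source shape "
            f"{plaques.volume_shape}"
        )
    grid = labels.labels
    for p in plaques.plaques:
        vox = tuple(
            int(np.clip(round(c), 0, s - 1))
            for c, s in zip(p.centroid_zyx, plaques.volume_shape)
        )
        p.region = int(grid[vox])
    return plaques


def region_density(
    plaques: PlaqueSet,
    labels: LabelVolume,
    spacing_um: tuple[float, float, float] | None = None,
) -> pd.DataFrame:
    """Per-region plaque count, volume, count density (/mm³), volume fraction.

    Regions present in the label volume appear even with zero plaques;
    background (label 0) is never listed.
    """
    spacing = spacing_um or plaques.spacing_um
    vox_vol_um3 = float(np.prod(spacing))
    region_counts = labels.region_voxel_counts()
    rows = []
    for label, n_vox in sorted(region_counts.items()):
        members = [p for p in plaques.plaques if p.region == label]
        region_volume_um3 = n_vox * vox_vol_um3
        plaque_volume_um3 = float(sum(p.volume_um3 for p in members))
        rows.append(
            {
                "label": label,
                "acronym": labels.region_names.get(label, str(label)),
                "plaque_count": len(members),
                "total_plaque_volume_um3": plaque_volume_um3,
                "region_volume_um3": region_volume_um3,
                "count_density_per_mm3": len(members) / (region_volume_um3 * 1e-9),
                "volume_fraction": plaque_volume_um3 / region_volume_um3,
            }
        )
    return pd.DataFrame(rows)


def merge_region_groups(
    table: pd.DataFrame, grouping: dict[str, list[int]]
) -> pd.DataFrame:
    """Pool subregions into coarse regions (e.g. CA1+CA2+CA3+DG → hippocampus).

    Counts and volumes are summed over members and densities recomputed from
    the sums — never averaged across rows.
    """
    rows = []
    known = set(table["label"].tolist())
    for name, members in grouping.items():
        missing = sorted(set(members) - known)
        if missing:
            raise PlaqueError(f"unknown member labels for {name!r}: {missing}")
        sub = table[table["label"].isin(members)]
        count = int(sub["plaque_count"].sum())
        plaque_vol = float(sub["total_plaque_volume_um3"].sum())
        region_vol = float(sub["region_volume_um3"].sum())
        rows.append(
            {
                "label": -1,
                "acronym": name,
                "plaque_count": count,
                "total_plaque_volume_um3": plaque_vol,
                "region_volume_um3": region_vol,
                "count_density_per_mm3": count / (region_vol * 1e-9),
                "volume_fraction": plaque_vol / region_vol,
            }
        )
    return pd.DataFrame(rows)


@dataclasses.dataclass
class ReductionResult:
    """Between-group density reduction for one region.

    ``reduction_rate_pct`` compares group means; ``reduction_of_ratios_pct``
    is the alternative mean of per-animal ratios (pairing control/treated by
    index order), reported for transparency.
    """

    region: str
    mean_control: float
    mean_treated: float
    reduction_rate_pct: float
    reduction_of_ratios_pct: float | None
    t: float
    df: float
    p: float
    stars: str
    n_control: int
    n_treated: int


def reduction_rate(
    control, treated, region: str = "", t_variant: str = "welch"
) -> ReductionResult:
    """Reduction rate 100 × (1 − mean(treated)/mean(control)) with Welch t."""
    control = np.asarray(control, dtype=float)
    treated = np.asarray(treated, dtype=float)
    if control.size < 1 or treated.size < 1:
        raise PlaqueError("each group needs n >= 1")
    mc, mt = float(control.mean()), float(treated.mean())
    if mc == 0:
        raise PlaqueError("undefined reduction: control mean is zero")
    rate = 100.0 * (1.0 - mt / mc)
    ratios = None
    if control.size == treated.size and np.all(control > 0):
        ratios = float(100.0 * (1.0 - np.mean(treated / control)))
    if control.size >= 2 and treated.size >= 2:
        tres = group_stats.t_test(control, treated, variant=t_variant)
        t, df, p = tres.t, tres.df, tres.p
        stars = group_stats.star_flags(p)
    else:
        t = df = p = float("nan")
        stars = "ns"
    return ReductionResult(
        region=region,
        mean_control=mc,
        mean_treated=mt,
        reduction_rate_pct=rate,
        reduction_of_ratios_pct=ratios,
        t=t,
        df=df,
        p=p,
        stars=stars,
        n_control=int(control.size),
        n_treated=int(treated.size),
    )


def compare_group_tables(
    control_tables: list[pd.DataFrame],
    treated_tables: list[pd.DataFrame],
    metric: str = "volume_fraction",
) -> pd.DataFrame:
    """Region-wise reduction rates from per-animal region-density tables."""
    if metric not in ("volume_fraction", "count_density_per_mm3"):
        raise PlaqueError(f"unknown metric {metric!r}")
    ref = control_tables[0][["label", "acronym"]]
    rows = []
    for _, (label, acronym) in ref.iterrows():
        ctrl = [
            float(t.loc[t["label"] == label, metric].iloc[0]) for t in control_tables
        ]
        trt = [
            float(t.loc[t["label"] == label, metric].iloc[0]) for t in treated_tables
        ]
        r = reduction_rate(ctrl, trt, region=str(acronym))
        rows.append(
            {
                "label": label,
                "acronym": acronym,
                "metric": metric,
                "mean_control": r.mean_control,
                "mean_treated": r.mean_treated,
                "reduction_rate_pct": r.reduction_rate_pct,
                "t": r.t,
                "df": r.df,
                "p": r.p,
                "stars": r.stars,
                "n_control": r.n_control,
                "n_treated": r.n_treated,
            }
        )
    return pd.DataFrame(rows)
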