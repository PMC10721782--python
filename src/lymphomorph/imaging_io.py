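"""File I/O, grids, spacing and configuration shared by every analysis stage.

All on-disk formats pass through here: TIFF images and label volumes, CSV
tables, and JSON/YAML parameter files. Downstream modules operate only on the
in-memory types defined in this module and never touch files themselves.

Conventions
-----------
* Axis order is ``(z, y, x)`` for volumes and ``(y, x)`` for images; indices
  are 0-based and voxel centers sit at integer coordinates.
* All physical lengths are micrometres. Pixel/voxel spacing is always supplied
  explicitly (config or CLI flag); TIFF resolution tags are ignored because
  they are unreliable across microscope exporters.
* Images are single-channel by contract; multi-channel data must be pre-split.
* Label volumes use 0 for background; every nonzero label must be named.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

logger = logging.getLogger(__name__)

_SUPPORTED_DTYPES = ("uint8", "uint16", "float32", "float64")


class ImagingIOError(ValueError):
    """Raised for malformed inputs (wrong channel count, orphan labels, ...)."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class VesselImage:
    """2D single-channel fluorescence image with isotropic pixel spacing."""

    pixels: np.ndarray
    spacing_um: float
    name: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ImagingIOError("VesselImage requires a non-empty 2D array")
        if not (np.isfinite(self.spacing_um) and self.spacing_um > 0):
            raise ImagingIOError("pixel spacing must be finite and positive")
        if not np.all(np.isfinite(self.pixels)):
            raise ImagingIOError("image intensities must be finite")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.pixels.shape


@dataclasses.dataclass
class BrainVolume:
    """3D single-channel intensity volume with anisotropic voxel spacing.

    ``spacing_um`` is ``(z, y, x)`` in micrometres per voxel. ``channel``
    records which stain the volume carries (e.g. ``"Abeta"`` for the amyloid
    channel of a cleared-brain light-sheet stack).
    """

    voxels: np.ndarray
    spacing_um: tuple[float, float, float]
    channel: str = "Abeta"
    name: str = ""

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3 or self.voxels.size == 0:
            raise ImagingIOError("BrainVolume requires a non-empty 3D array")
        self.spacing_um = tuple(float(s) for s in self.spacing_um)
        if len(self.spacing_um) != 3 or any(
            not (np.isfinite(s) and s > 0) for s in self.spacing_um
        ):
            raise ImagingIOError("voxel spacing must be three positive values (z, y, x)")
        if not np.all(np.isfinite(self.voxels)):
            raise ImagingIOError("voxel intensities must be finite")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.voxels.shape

    @property
    def voxel_volume_um3(self) -> float:
        return float(np.prod(self.spacing_um))


@dataclasses.dataclass
class LabelVolume:
    """Integer region-label volume aligned to a :class:`BrainVolume` grid.

    Stands in for an atlas label volume deformed into the acquisition frame
    by registration; the registration itself is upstream of this package.
    Background is label 0 and is excluded from all region statistics.
    """

    labels: np.ndarray
    region_names: dict[int, str]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3 or self.labels.size == 0:
            raise ImagingIOError("LabelVolume requires a non-empty 3D array")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ImagingIOError("labels must be integer-valued")
        if self.labels.min() < 0:
            raise ImagingIOError("labels must be non-negative")
        self.region_names = {int(k): str(v) for k, v in self.region_names.items()}
        present = set(np.unique(self.labels).tolist()) - {0}
        orphans = sorted(present - set(self.region_names))
        if orphans:
            raise ImagingIOError(f"labels without a region name: {orphans}")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.labels.shape

    def region_voxel_counts(self) -> dict[int, int]:
        """Voxel count per nonzero label present in the volume."""
        counts = np.bincount(self.labels.ravel())
        return {int(k): int(counts[k]) for k in range(1, len(counts)) if counts[k] > 0}


@dataclasses.dataclass
class BinaryMask:
    """A {0,1} mask sharing the grid and spacing of its source image."""

    grid: np.ndarray
    spacing_um: float = 1.0

    def __post_init__(self) -> None:
        arr = np.asarray(self.grid)
        if arr.size == 0:
            raise ImagingIOError("BinaryMask requires a non-empty array")
        if arr.dtype != bool:
            vals = np.unique(arr)
            if not np.all(np.isin(vals, (0, 1))):
                raise ImagingIOError("mask values must be 0/1")
            arr = arr.astype(bool)
        self.grid = arr

    @property
    def shape(self) -> tuple[int, ...]:
        return self.grid.shape


# ---------------------------------------------------------------------------
# image reading / writing
# ---------------------------------------------------------------------------


def _load_tiff(path: str | Path, integer_ok: bool = False) -> np.ndarray:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(path) as tf:
        page = tf.pages[0]
        if (page.samplesperpixel or 1) > 1:
            raise ImagingIOError("single-channel required (input has multiple samples)")
        arr = tf.asarray()
    if arr.dtype.name not in _SUPPORTED_DTYPES and not (
        integer_ok and np.issubdtype(arr.dtype, np.integer)
    ):
        raise ImagingIOError(
            f"unsupported bit depth {arr.dtype}; expected one of {_SUPPORTED_DTYPES}"
        )
    return arr


def read_image(
    path: str | Path,
    spacing_um: float | tuple[float, float, float],
    name: str = "",
    channel: str = "Abeta",
) -> VesselImage | BrainVolume:
    """Read a single- or multi-page TIFF.

    A single page yields a :class:`VesselImage` (scalar ``spacing_um``); a
    multi-page stack yields a :class:`BrainVolume` with page order mapping to
    ascending z (``spacing_um`` must then be a ``(z, y, x)`` triple). Spacing
    always comes from the caller, never from TIFF tags.
    """
    arr = _load_tiff(path)
    name = name or Path(path).stem
    if arr.ndim == 2:
        return VesselImage(arr, float(np.atleast_1d(spacing_um)[0]), name=name)
    if arr.ndim == 3:
        spacing = np.atleast_1d(np.asarray(spacing_um, dtype=float))
        if spacing.size == 1:
            spacing = np.repeat(spacing, 3)
        return BrainVolume(arr, tuple(spacing), channel=channel, name=name)
    raise ImagingIOError(f"expected 2D or 3D TIFF, got ndim={arr.ndim}")


def read_volume(
    path: str | Path,
    spacing_um: tuple[float, float, float],
    channel: str = "Abeta",
) -> BrainVolume:
    """Read a TIFF as a 3D volume, promoting a single page to shape (1, H, W)."""
    arr = _load_tiff(path)
    if arr.ndim == 2:
        arr = arr[np.newaxis]
    return BrainVolume(arr, tuple(spacing_um), channel=channel, name=Path(path).stem)


def write_image(obj: VesselImage | BrainVolume | LabelVolume, path: str | Path) -> None:
    data = (
        obj.labels
        if isinstance(obj, LabelVolume)
        else obj.pixels if isinstance(obj, VesselImage) else obj.voxels
    )
    tifffile.imwrite(Path(path), np.asarray(data), photometric="minisblack")


def read_label_volume(path: str | Path, names_path: str | Path) -> LabelVolume:
    """Read an integer label TIFF plus its two-column (label, acronym) CSV."""
    arr = _load_tiff(path, integer_ok=True)
    if arr.ndim == 2:
        arr = arr[np.newaxis]
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.allclose(arr, np.round(arr)):
            raise ImagingIOError("label volume must be integer-valued")
        arr = arr.astype(np.int64)
    names_path = Path(names_path)
    if not names_path.exists():
        raise FileNotFoundError(names_path)
    names: dict[int, str] = {}
    if names_path.stat().st_size > 0:
        df = pd.read_csv(names_path, header=None, names=["label", "acronym"])
        # tolerate an optional header row
        if len(df) and str(df.iloc[0, 0]).strip().lower() == "label":
            df = df.iloc[1:]
        names = {int(row.label): str(row.acronym) for row in df.itertuples()}
    return LabelVolume(arr, names)


def write_label_names(names: dict[int, str], path: str | Path) -> None:
    pd.DataFrame(
        {"label": list(names.keys()), "acronym": list(names.values())}
    ).to_csv(path, index=False, header=False)


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------


def write_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a table as UTF-8 CSV ('.' decimal, NaN as empty field)."""
    if table.columns.duplicated().any():
        dupes = table.columns[table.columns.duplicated()].tolist()
        raise ImagingIOError(f"duplicate column names: {dupes}")
    table.to_csv(Path(path), index=False, encoding="utf-8")


def read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split(",")
    if len(header) != len(set(header)):
        raise ImagingIOError(f"duplicate column names in {path.name}")
    return pd.read_csv(path, encoding="utf-8")


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class AnalysisConfig:
    """Validated parameter set governing every pipeline stage.

    Lengths are in pixels unless suffixed ``_um``; times in seconds.
    """

    # spacing (must be user-supplied for real data; generators fill them in)
    spacing_um: float | None = None
    spacing_um_zyx: tuple[float, float, float] | None = None
    # vessel morphometry
    closing_radius_px: int = 2
    min_object_px: int = 64
    prune_px: float = 5.0
    tangent_window_px: float = 5.0
    step_px: float = 1.0
    junction_exclusion_px: float = 3.0
    max_chord_px: float = 100.0
    # plaque quantification
    threshold_method: str = "otsu"
    fixed_threshold: float | None = None
    min_plaque_voxels: int = 5
    # physiology
    baseline_window_s: float = 60.0
    safety_rise_c: float = 0.5
    # behavior
    trial_cap_s: float = 60.0

    def __post_init__(self) -> None:
        if self.spacing_um is not None and not self.spacing_um > 0:
            raise ImagingIOError("spacing_um must be > 0")
        if self.spacing_um_zyx is not None:
            self.spacing_um_zyx = tuple(float(s) for s in self.spacing_um_zyx)
            if len(self.spacing_um_zyx) != 3 or any(s <= 0 for s in self.spacing_um_zyx):
                raise ImagingIOError("spacing_um_zyx must be three positive values")
        if self.threshold_method not in ("otsu", "fixed"):
            raise ImagingIOError("threshold_method must be 'otsu' or 'fixed'")
        for field in (
            "closing_radius_px",
            "min_object_px",
            "min_plaque_voxels",
        ):
            if getattr(self, field) < 0:
                raise ImagingIOError(f"{field} must be >= 0")


def load_config(path: str | Path | None = None, **overrides) -> AnalysisConfig:
    """Load a JSON/YAML config, apply defaults, reject unknown keys.

    The full effective configuration is echoed to the module logger so runs
    are self-documenting.
    """
    params: dict = {}
    if path is not None:
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(path)
        text = path.read_text(encoding="utf-8")
        if path.suffix.lower() == ".json":
            params = json.loads(text) or {}
        else:
            params = yaml.safe_load(text) or {}
        if not isinstance(params, dict):
            raise ImagingIOError("config root must be a mapping")
    params.update(overrides)
    known = {f.name for f in dataclasses.fields(AnalysisConfig)}
    unknown = sorted(set(params) - known)
    if unknown:
        raise ImagingIOError(f"unknown config keys: {unknown}")
    cfg = AnalysisConfig(**params)
    logger.info("effective config: %s", dataclasses.asdict(cfg))
    return cfg
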