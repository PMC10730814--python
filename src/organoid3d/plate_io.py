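"""Plate-level image I/O: tile assembly, chunked storage and metadata.

A plate well is imaged as a rectangular grid of *fields*; each field is a
z-stack of 2D planes acquired per channel.  This module assembles the
per-field tiles into one 4D array per well, ordered ``(channel, z, y, x)``,
persists it to a chunked Zarr store (v2 layout) and parses the neutral
plate-layout configuration that replaces vendor metadata.

Conventions (used everywhere in the package):

* axis order ``(channel, z, y, x)``;
* all coordinates 0-based;
* bounding boxes are half-open ``[start, stop)``;
* fields tile the well edge-to-edge with zero overlap, in row-major order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml
import zarr

logger = logging.getLogger(__name__)

_REQUIRED_KEYS = (
    "rows",
    "cols",
    "field_grid",
    "planes_per_field",
    "channels",
    "field_shape_px",
    "voxel_size_um",
)


class PlateConfigError(ValueError):
    """A plate-layout configuration is missing keys or fails validation."""


class AssemblyError(ValueError):
    """Tile collection cannot be assembled into a well volume."""


@dataclass(frozen=True)
class PlateLayout:
    """Geometry of one plate: well grid, field layout and voxel size.

    Parameters
    ----------
    rows, cols:
        Number of well rows / columns on the plate.
    field_grid:
        ``(rows_of_fields, cols_of_fields)`` — how fields tile one well.
    planes_per_field:
        Number of z-planes per field.
    channels:
        Ordered channel names; channel indices everywhere refer to this order.
    field_shape_px:
        ``(height, width)`` of a single field in pixels.
    voxel_size_um:
        Physical voxel size ``(dz, dy, dx)`` in micrometres.
    """

    rows: int
    cols: int
    field_grid: tuple[int, int]
    planes_per_field: int
    channels: tuple[str, ...]
    field_shape_px: tuple[int, int]
    voxel_size_um: tuple[float, float, float]

    def __post_init__(self) -> None:
        object.__setattr__(self, "field_grid", tuple(int(v) for v in self.field_grid))
        object.__setattr__(self, "channels", tuple(self.channels))
        object.__setattr__(self, "field_shape_px", tuple(int(v) for v in self.field_shape_px))
        object.__setattr__(self, "voxel_size_um", tuple(float(v) for v in self.voxel_size_um))
        for name in ("rows", "cols", "planes_per_field"):
            if getattr(self, name) < 1:
                raise PlateConfigError(f"{name} must be >= 1, got {getattr(self, name)}")
        if any(v < 1 for v in self.field_grid):
            raise PlateConfigError(f"field_grid entries must be >= 1, got {self.field_grid}")
        if any(v < 1 for v in self.field_shape_px):
            raise PlateConfigError(f"field_shape_px must be positive, got {self.field_shape_px}")
        if any(v <= 0 for v in self.voxel_size_um):
            raise PlateConfigError(f"voxel_size_um must be positive, got {self.voxel_size_um}")
        if not self.channels:
            raise PlateConfigError("channels must be non-empty")

    @property
    def fields_per_well(self) -> int:
        return self.field_grid[0] * self.field_grid[1]

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    @property
    def well_shape(self) -> tuple[int, int, int, int]:
        """Shape of an assembled well volume: (channel, z, y, x)."""
        fr, fc = self.field_grid
        h, w = self.field_shape_px
        return (self.n_channels, self.planes_per_field, fr * h, fc * w)

    def field_slices(self, field_index: int) -> tuple[slice, slice]:
        """(y, x) slices of a field within the stitched well, row-major order."""
        fr, fc = self.field_grid
        if not 0 <= field_index < self.fields_per_well:
            raise IndexError(f"field index {field_index} out of range for {fr}x{fc} grid")
        h, w = self.field_shape_px
        r, c = divmod(field_index, fc)
        return slice(r * h, (r + 1) * h), slice(c * w, (c + 1) * w)

    def channel_index(self, channel: int | str) -> int:
        if isinstance(channel, str):
            try:
                return self.channels.index(channel)
            except ValueError:
                raise KeyError(f"unknown channel {channel!r}; have {list(self.channels)}") from None
        if not 0 <= channel < self.n_channels:
            raise KeyError(f"channel index {channel} out of range")
        return int(channel)

    def to_dict(self) -> dict:
        return {
            "rows": self.rows,
            "cols": self.cols,
            "field_grid": list(self.field_grid),
            "planes_per_field": self.planes_per_field,
            "channels": list(self.channels),
            "field_shape_px": list(self.field_shape_px),
            "voxel_size_um": list(self.voxel_size_um),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PlateLayout":
        missing = [k for k in _REQUIRED_KEYS if k not in d]
        if missing:
            raise PlateConfigError(f"plate layout missing required key(s): {missing}")
        known = set(_REQUIRED_KEYS) | {"fields_per_well"}
        unknown = sorted(set(d) - known)
        if unknown:
            logger.warning("ignoring unknown plate-layout keys: %s", unknown)
        layout = cls(
            rows=int(d["rows"]),
            cols=int(d["cols"]),
            field_grid=tuple(d["field_grid"]),
            planes_per_field=int(d["planes_per_field"]),
            channels=tuple(d["channels"]),
            field_shape_px=tuple(d["field_shape_px"]),
            voxel_size_um=tuple(d["voxel_size_um"]),
        )
        if "fields_per_well" in d and int(d["fields_per_well"]) != layout.fields_per_well:
            raise PlateConfigError(
                f"fields_per_well={d['fields_per_well']} inconsistent with "
                f"field_grid {layout.field_grid}"
            )
        return layout


@dataclass
class WellVolume:
    """One assembled well: 4D intensity array + layout + well position."""

    data: np.ndarray  # (channel, z, y, x)
    layout: PlateLayout
    well_id: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        if self.data.ndim != 4:
            raise AssemblyError(f"well data must be 4D (c,z,y,x), got ndim={self.data.ndim}")
        if self.data.shape != self.layout.well_shape:
            raise AssemblyError(
                f"well data shape {self.data.shape} != layout well shape {self.layout.well_shape}"
            )

    @property
    def voxel_size_um(self) -> tuple[float, float, float]:
        return self.layout.voxel_size_um

    def channel(self, channel: int | str) -> np.ndarray:
        """3D (z, y, x) view of one channel."""
        return self.data[self.layout.channel_index(channel)]


def parse_plate_metadata(path: str | Path) -> PlateLayout:
    """Read a plate-layout YAML file and return a validated :class:`PlateLayout`.

    The file is a flat mapping with the keys of :class:`PlateLayout`
    (``field_grid``, ``field_shape_px`` and ``voxel_size_um`` as 2-/3-lists).
    Unknown keys are ignored with a warning; missing keys raise
    :class:`PlateConfigError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"plate layout file not found: {path}")
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise PlateConfigError(f"plate layout file {path} does not contain a mapping")
    return PlateLayout.from_dict(raw)


def write_plate_metadata(layout: PlateLayout, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        yaml.safe_dump(layout.to_dict(), fh, sort_keys=False)
    return path


def assemble_well(
    tiles: Iterable[tuple[int, int, int, np.ndarray]],
    layout: PlateLayout,
    well_id: tuple[int, int] = (0, 0),
    dtype=None,
) -> WellVolume:
    """Assemble ``(field, plane, channel, image)`` tiles into one 4D well volume.

    Every (field, plane, channel) combination must be present exactly once and
    all tiles must share ``layout.field_shape_px``.  Tiles are placed
    edge-to-edge (no overlap) in row-major field order; pixel values are
    copied unmodified.
    """
    tiles = list(tiles)
    if dtype is None:
        dtype = tiles[0][3].dtype if tiles else np.uint16
    data = np.zeros(layout.well_shape, dtype=dtype)
    expected = {
        (f, p, c)
        for f in range(layout.fields_per_well)
        for p in range(layout.planes_per_field)
        for c in range(layout.n_channels)
    }
    seen: set[tuple[int, int, int]] = set()
    for f, p, c, img in tiles:
        key = (f, p, c)
        if key not in expected:
            raise AssemblyError(f"tile index {key} outside layout")
        if key in seen:
            raise AssemblyError(f"duplicate tile for (field, plane, channel) = {key}")
        seen.add(key)
        img = np.asarray(img)
        if img.shape != layout.field_shape_px:
            raise AssemblyError(
                f"tile {key} has shape {img.shape}, expected {layout.field_shape_px}"
            )
        ys, xs = layout.field_slices(f)
        data[c, p, ys, xs] = img
    missing = sorted(expected - seen)
    if missing:
        raise AssemblyError(
            f"{len(missing)} missing tile(s); first missing (field, plane, channel): "
            f"{missing[:5]}"
        )
    return WellVolume(data=data, layout=layout, well_id=well_id)


def disassemble_well(vol: WellVolume) -> list[tuple[int, int, int, np.ndarray]]:
    """Inverse of :func:`assemble_well`: cut the volume back into field tiles."""
    out = []
    lay = vol.layout
    for f in range(lay.fields_per_well):
        ys, xs = lay.field_slices(f)
        for p in range(lay.planes_per_field):
            for c in range(lay.n_channels):
                out.append((f, p, c, vol.data[c, p, ys, xs].copy()))
    return out


def extract_field(vol: WellVolume, field_index: int) -> np.ndarray:
    """4D (c, z, y, x) view of one field of the assembled well."""
    ys, xs = vol.layout.field_slices(field_index)
    return vol.data[:, :, ys, xs]


def well_store_name(well_id: tuple[int, int]) -> str:
    return f"r{well_id[0]}c{well_id[1]}"


def write_store(vol: WellVolume, path: str | Path) -> Path:
    """Persist a well volume to a Zarr (v2 layout) directory store.

    Chunking is one (channel, plane) slab per chunk, so reading a single
    z-plane never loads the full volume.
    """
    path = Path(path)
    _, _, h, w = vol.data.shape
    arr = zarr.open_array(
        str(path),
        mode="w",
        shape=vol.data.shape,
        chunks=(1, 1, h, w),
        dtype=vol.data.dtype,
        zarr_format=2,
    )
    arr[:] = vol.data
    arr.attrs["layout"] = vol.layout.to_dict()
    arr.attrs["well_id"] = list(vol.well_id)
    arr.attrs["axes"] = "czyx"
    return path


def read_store(path: str | Path) -> WellVolume:
    """Load a well volume previously written by :func:`write_store`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"well store not found: {path}")
    try:
        arr = zarr.open_array(str(path), mode="r")
        layout = PlateLayout.from_dict(dict(arr.attrs["layout"]))
        well_id = tuple(arr.attrs.get("well_id", (0, 0)))
        data = np.asarray(arr[:])
    except FileNotFoundError:
        raise
    except Exception as exc:  # corrupt store
        raise IOError(f"failed to read well store at {path}: {exc}") from exc
    return WellVolume(data=data, layout=layout, well_id=(int(well_id[0]), int(well_id[1])))


def read_plane(path: str | Path, channel: int, z: int) -> np.ndarray:
    """Read a single (channel, z) plane from a stored well without loading it all."""
    arr = zarr.open_array(str(Path(path)), mode="r")
    return np.asarray(arr[channel, z])


def max_projection(vol: WellVolume | np.ndarray, channel: int | str | None = None) -> np.ndarray:
    """2D per-pixel maximum across z of one channel.

    Accepts either a :class:`WellVolume` plus a channel, or a bare 3D
    (z, y, x) array.
    """
    if isinstance(vol, WellVolume):
        if channel is None:
            raise KeyError("channel required for a WellVolume")
        stack = vol.channel(channel)
    else:
        stack = np.asarray(vol)
        if stack.ndim != 3:
            raise ValueError(f"expected a 3D (z,y,x) stack, got ndim={stack.ndim}")
    return stack.max(axis=0)


def write_tiles_tiff(
    tiles: Sequence[tuple[int, int, int, np.ndarray]],
    directory: str | Path,
    pattern: str = "f{field:02d}p{plane:03d}c{channel:02d}.tif",
) -> list[Path]:
    """Write tiles as single-plane TIFF files named by a configurable pattern."""
    import tifffile

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for f, p, c, img in tiles:
        out = directory / pattern.format(field=f, plane=p, channel=c)
        tifffile.imwrite(out, np.asarray(img))
        paths.append(out)
    return paths


def read_tiles_tiff(
    directory: str | Path,
    layout: PlateLayout,
    pattern: str = "f{field:02d}p{plane:03d}c{channel:02d}.tif",
) -> list[tuple[int, int, int, np.ndarray]]:
    """Read tiles written by :func:`write_tiles_tiff` back into assembly form."""
    import tifffile

    directory = Path(directory)
    tiles = []
    for f in range(layout.fields_per_well):
        for p in range(layout.planes_per_field):
            for c in range(layout.n_channels):
                path = directory / pattern.format(field=f, plane=p, channel=c)
                if not path.exists():
                    raise AssemblyError(f"missing tile file: {path}")
                tiles.append((f, p, c, tifffile.imread(path)))
    return tiles
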