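"""Stage 1: 3D organoid segmentation and per-organoid feature tables.

Each field is cleaned (debris removal on the 2D max projection), smoothed
with an anisotropy-aware Gaussian and binarized with the triangle histogram
threshold — per field, because fields vary in noise and intensity.  Field
masks are stitched to the full well extent *before* 3D connected-component
labeling so organoids spanning field borders receive a single label; small
components are removed and the survivors are measured into a feature table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure, morphology

from .plate_io import PlateLayout, WellVolume

logger = logging.getLogger(__name__)


class DegenerateHistogramError(ValueError):
    """Raised when an image is constant and has no histogram geometry."""


@dataclass(frozen=True)
class LabeledVolume:
    """3D integer label image (z, y, x); 0 is background."""

    labels: np.ndarray
    voxel_size_um: tuple[float, float, float]

    def __post_init__(self) -> None:
        if self.labels.ndim != 3:
            raise ValueError(f"labels must be 3D (z,y,x), got ndim={self.labels.ndim}")

    @property
    def n_objects(self) -> int:
        return int(self.labels.max())


@dataclass(frozen=True)
class SegmentationParams:
    """Tunable parameters of the organoid stage.

    debris_threshold_frac:
        Cleaning binarization threshold as a fraction of the dtype range
        (of the data maximum for float input).
    opening_radius / dilation_radius:
        Disk radii (px) of the binary opening and dilation applied to the
        2D cleaning mask.
    gaussian_sigma:
        Smoothing sigma in voxels, (z, y, x); the default reflects z >> xy
        anisotropy.
    min_volume_voxels:
        Connected components smaller than this are discarded (roughly one
        nucleus volume by default).
    connectivity:
        3D connectivity for labeling (3 = 26-connectivity).
    fluorescence_channels:
        Indices of the channels carrying nuclear fluorescence (None = all);
        the grayscale image is their per-pixel maximum so organoids visible
        in either channel of a mixed-clone well are preserved.
    """

    debris_threshold_frac: float = 0.02
    opening_radius: int = 2
    dilation_radius: int = 1
    gaussian_sigma: tuple[float, float, float] = (0.5, 2.0, 2.0)
    min_volume_voxels: int = 64
    connectivity: int = 3
    fluorescence_channels: tuple[int, ...] | None = None


def _grayscale(field_czyx: np.ndarray, fluor: tuple[int, ...] | None) -> np.ndarray:
    """Per-voxel max across the fluorescence channels -> 3D grayscale."""
    if field_czyx.ndim != 4:
        raise ValueError(f"expected (c,z,y,x) field, got ndim={field_czyx.ndim}")
    sel = field_czyx if fluor is None else field_czyx[list(fluor)]
    return sel.max(axis=0)


def _debris_threshold_value(data: np.ndarray, frac: float) -> float:
    if np.issubdtype(data.dtype, np.integer):
        span = float(np.iinfo(data.dtype).max)
    else:
        span = float(data.max()) if data.size else 1.0
    return frac * span


def clean_field(field_czyx: np.ndarray, params: SegmentationParams = SegmentationParams()) -> np.ndarray:
    """Remove debris from one field by masking with a cleaned 2D max projection.

    The per-pixel maximum across fluorescence channels and z is binarized at
    a low fixed threshold, opened (removes small bright dots) then dilated
    (closes small holes at object borders); the resulting 2D mask is
    broadcast over z and multiplied into every channel.  An all-zero field
    comes back all-zero.
    """
    gray2d = _grayscale(field_czyx, params.fluorescence_channels).max(axis=0)
    thr = _debris_threshold_value(gray2d, params.debris_threshold_frac)
    mask = gray2d > thr
    if params.opening_radius > 0:
        mask = morphology.opening(mask, morphology.disk(params.opening_radius))
    if params.dilation_radius > 0:
        mask = morphology.dilation(mask, morphology.disk(params.dilation_radius))
    return field_czyx * mask[None, None, :, :].astype(field_czyx.dtype)


def triangle_threshold(image: np.ndarray, nbins: int = 256) -> float:
    """Histogram-geometric (triangle) threshold of a grayscale image.

    Builds an ``nbins``-bin histogram, draws the line from the histogram
    peak to the farthest nonzero tail bin, and returns the intensity of the
    bin whose histogram point lies at maximum perpendicular distance below
    that line.

    Raises
    ------
    DegenerateHistogramError
        If the image is constant.
    """
    image = np.asarray(image)
    lo, hi = float(image.min()), float(image.max())
    if hi == lo:
        raise DegenerateHistogramError("degenerate histogram: image is constant")
    counts, edges = np.histogram(image.ravel(), bins=nbins, range=(lo, hi))
    centers = 0.5 * (edges[:-1] + edges[1:])
    peak = int(np.argmax(counts))
    nz = np.flatnonzero(counts)
    first, last = nz[0], nz[-1]
    # tail on the side of the longer arm from the peak
    if (last - peak) >= (peak - first):
        tail = last
        idx = np.arange(peak, tail + 1)
    else:
        tail = first
        idx = np.arange(tail, peak + 1)
    if tail == peak:
        raise DegenerateHistogramError("degenerate histogram: single occupied bin")
    # perpendicular distance from (i, counts[i]) to the peak->tail line
    x1, y1 = float(peak), float(counts[peak])
    x2, y2 = float(tail), float(counts[tail])
    num = np.abs((y2 - y1) * idx - (x2 - x1) * counts[idx] + x2 * y1 - y2 * x1)
    best = idx[int(np.argmax(num))]
    return float(centers[best])


def segment_field(
    cleaned_czyx: np.ndarray, params: SegmentationParams = SegmentationParams()
) -> np.ndarray:
    """Binary organoid mask of one cleaned field.

    Gaussian-smooths the channel-max grayscale volume with the configured
    anisotropic sigma and binarizes with :func:`triangle_threshold`.  The
    threshold is computed over the voxels the cleaning step kept (the
    cleaned support): the zeros written outside the cleaning mask carry no
    information and would otherwise dominate the histogram peak.  A
    degenerate (constant or empty) field yields an empty mask, not an
    error.
    """
    gray = _grayscale(cleaned_czyx, params.fluorescence_channels).astype(np.float32)
    support2d = gray.max(axis=0) > 0
    smooth = ndimage.gaussian_filter(gray, sigma=params.gaussian_sigma)
    if not support2d.any():
        return np.zeros(gray.shape, dtype=bool)
    try:
        thr = triangle_threshold(smooth[:, support2d])
    except DegenerateHistogramError:
        logger.info("degenerate field (constant intensity); returning empty mask")
        return np.zeros(gray.shape, dtype=bool)
    return smooth > thr


def stitch_label_filter(
    field_masks: Mapping[int, np.ndarray] | Sequence[np.ndarray],
    layout: PlateLayout,
    min_volume_voxels: int = 64,
    connectivity: int = 3,
) -> LabeledVolume:
    """Stitch per-field masks, 3D-label, drop small objects, relabel.

    Masks are stitched to the full well extent *before* labeling so an
    organoid straddling a field border gets exactly one label.  Components
    with fewer than ``min_volume_voxels`` voxels are removed and the rest
    are relabeled 1..N in raster (z, y, x) order of their first voxel.
    """
    if not isinstance(field_masks, Mapping):
        field_masks = dict(enumerate(field_masks))
    if len(field_masks) != layout.fields_per_well:
        raise ValueError(
            f"expected {layout.fields_per_well} field masks, got {len(field_masks)}"
        )
    nz = layout.planes_per_field
    fr, fc = layout.field_grid
    h, w = layout.field_shape_px
    well_mask = np.zeros((nz, fr * h, fc * w), dtype=bool)
    expected_shape = (nz, h, w)
    for f, mask in field_masks.items():
        mask = np.asarray(mask)
        if mask.shape != expected_shape:
            raise ValueError(f"field {f} mask shape {mask.shape} != {expected_shape}")
        ys, xs = layout.field_slices(f)
        well_mask[:, ys, xs] = mask
    labels = measure.label(well_mask, connectivity=connectivity)
    labels = drop_small_labels(labels, min_volume_voxels)
    labels = relabel_raster_order(labels)
    return LabeledVolume(labels=labels, voxel_size_um=layout.voxel_size_um)


def drop_small_labels(labels: np.ndarray, min_voxels: int) -> np.ndarray:
    """Zero out labels with fewer than ``min_voxels`` voxels."""
    if min_voxels <= 1 or labels.max() == 0:
        return labels
    counts = np.bincount(labels.ravel())
    lut = np.where(counts >= min_voxels, np.arange(len(counts)), 0).astype(labels.dtype)
    lut[0] = 0
    return lut[labels]


def relabel_raster_order(labels: np.ndarray) -> np.ndarray:
    """Relabel consecutively from 1, ordered by each object's first voxel."""
    flat = labels.ravel()
    order = pd.unique(flat[flat > 0])
    if order.size == 0:
        return np.zeros_like(labels)
    lut = np.zeros(int(flat.max()) + 1, dtype=labels.dtype)
    lut[order] = np.arange(1, order.size + 1, dtype=labels.dtype)
    return lut[labels]


# regionprops properties measured in physical units (spacing-aware)
_PHYSICAL_PROPS = (
    "label",
    "area",
    "area_bbox",
    "area_filled",
    "area_convex",
    "axis_major_length",
    "axis_minor_length",
    "euler_number",
    "extent",
    "solidity",
    "inertia_tensor_eigvals",
)


def organoid_features(labeled: LabeledVolume, vol: WellVolume) -> pd.DataFrame:
    """Per-organoid feature table (one row per label).

    Voxel-count features are converted to µm³ with dz·dy·dx; axis lengths
    are in µm under anisotropic spacing; intensity statistics are computed
    per input channel over the labeled voxels.  Solidity (filled/convex
    volume ratio) serves as a packing measure and the Euler number as a
    measure of holes.
    """
    labels = labeled.labels
    if labels.shape != vol.data.shape[1:]:
        raise ValueError(
            f"label shape {labels.shape} != image shape {vol.data.shape[1:]}"
        )
    return region_feature_table(
        labels,
        intensity_czyx=vol.data,
        channel_names=vol.layout.channels,
        voxel_size_um=labeled.voxel_size_um,
    )


def region_feature_table(
    labels: np.ndarray,
    intensity_czyx: np.ndarray,
    channel_names: Sequence[str],
    voxel_size_um: tuple[float, float, float],
    extra_properties: Sequence[str] = (),
) -> pd.DataFrame:
    """Measure 3D regionprops of ``labels`` into a tidy table.

    Shared by the organoid and nucleus stages.  Geometry columns use
    physical units (µm, µm³) via anisotropic spacing; centroid and bbox are
    kept in voxel coordinates (bbox half-open, 6 columns
    zmin,ymin,xmin,zmax,ymax,xmax).
    """
    spacing = tuple(float(v) for v in voxel_size_um)
    if labels.max() == 0:
        cols = (
            ["label", "centroid_z", "centroid_y", "centroid_x",
             "bbox_zmin", "bbox_ymin", "bbox_xmin", "bbox_zmax", "bbox_ymax", "bbox_xmax",
             "volume", "volume_bbox", "volume_filled", "volume_convex",
             "major_axis_length", "minor_axis_length", "euler_number", "extent",
             "solidity", "n_voxels",
             "inertia_tensor_eigvals_0", "inertia_tensor_eigvals_1", "inertia_tensor_eigvals_2"]
            + [f"intensity_{s}_{ch}" for s in ("min", "mean", "max") for ch in channel_names]
            + list(extra_properties)
        )
        return pd.DataFrame(columns=cols)

    # intensity image with trailing channel axis for multichannel regionprops
    intensity = np.moveaxis(np.asarray(intensity_czyx), 0, -1)
    phys = measure.regionprops_table(
        labels,
        spacing=spacing,
        properties=_PHYSICAL_PROPS,
    )
    vox = measure.regionprops_table(
        labels,
        intensity_image=intensity,
        properties=("label", "centroid", "bbox", "num_pixels",
                    "intensity_min", "intensity_mean", "intensity_max"),
    )
    df = pd.DataFrame(phys).merge(pd.DataFrame(vox), on="label")
    rename = {
        "area": "volume",
        "area_bbox": "volume_bbox",
        "area_filled": "volume_filled",
        "area_convex": "volume_convex",
        "axis_major_length": "major_axis_length",
        "axis_minor_length": "minor_axis_length",
        "centroid-0": "centroid_z",
        "centroid-1": "centroid_y",
        "centroid-2": "centroid_x",
        "bbox-0": "bbox_zmin",
        "bbox-1": "bbox_ymin",
        "bbox-2": "bbox_xmin",
        "bbox-3": "bbox_zmax",
        "bbox-4": "bbox_ymax",
        "bbox-5": "bbox_xmax",
        "num_pixels": "n_voxels",
        "inertia_tensor_eigvals-0": "inertia_tensor_eigvals_0",
        "inertia_tensor_eigvals-1": "inertia_tensor_eigvals_1",
        "inertia_tensor_eigvals-2": "inertia_tensor_eigvals_2",
    }
    for stat in ("min", "mean", "max"):
        for ci, ch in enumerate(channel_names):
            rename[f"intensity_{stat}-{ci}"] = f"intensity_{stat}_{ch}"
        # single-channel intensity images yield unsuffixed columns
        rename.setdefault(f"intensity_{stat}", f"intensity_{stat}_{channel_names[0]}")
    df = df.rename(columns=rename)
    return df
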