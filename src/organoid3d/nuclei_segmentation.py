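"""Stage 2: per-organoid nucleus segmentation and feature tables.

Each organoid is cropped from the well volume by its 3D bounding box,
percentile-normalized per channel, and its nuclei segmented per
fluorescence channel by a pluggable backend.  The backend is a contract:
any callable mapping a normalized 3D crop to a label volume can be
registered.  The default backend is a classical anisotropy-aware seeded
watershed; an adapter slot exists for star-convex CNN models (for which
the reference configuration is recorded in :class:`BackendConfig`) when
externally trained weights are available.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import feature, filters, measure, segmentation

from .organoid_segmentation import (
    LabeledVolume,
    drop_small_labels,
    region_feature_table,
    relabel_raster_order,
)
from .plate_io import WellVolume

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BackendConfig:
    """Configuration of a nucleus-segmentation backend.

    Parameters
    ----------
    backend_name:
        Registered backend to use; ``"watershed"`` is the built-in default.
    anisotropy:
        Relative (z, y, x) scale factors of the voxel grid.  The reference
        star-convex CNN configuration for data with 5 µm z-steps is
        ``(9.0, 1.0, 1.0)`` with 64 rays and a receptive field of
        (17, 30, 30) voxels; those values are carried in ``extra`` when that
        backend is selected.
    p_low, p_high:
        Percentiles of the per-crop, per-channel intensity normalization.
    smoothing_sigma_um:
        Gaussian pre-smoothing, physical µm (watershed backend).
    min_seed_separation_um:
        Minimum physical distance between watershed seeds.
    min_nucleus_volume_um3:
        Labels smaller than this are discarded.
    extra:
        Backend-specific parameters (e.g. rays / patch size for the
        star-convex adapter).
    """

    backend_name: str = "watershed"
    anisotropy: tuple[float, float, float] = (1.0, 1.0, 1.0)
    p_low: float = 1.0
    p_high: float = 99.8
    smoothing_sigma_um: float = 1.0
    min_seed_separation_um: float = 6.0
    min_nucleus_volume_um3: float = 20.0
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.p_low < self.p_high:
            raise ValueError(f"require p_low < p_high, got ({self.p_low}, {self.p_high})")
        if any(a <= 0 for a in self.anisotropy):
            raise ValueError(f"anisotropy must be positive, got {self.anisotropy}")


def crop_organoid(
    vol: WellVolume,
    bbox: tuple[int, int, int, int, int, int],
    pad_voxels: int | tuple[int, int, int] = 2,
) -> tuple[np.ndarray, tuple[int, int, int]]:
    """Extract all channels over an organoid's padded 3D bbox.

    ``bbox`` is half-open (zmin, ymin, xmin, zmax, ymax, xmax) in well
    voxel coordinates.  Padding is clipped to the volume; the returned
    offset (z, y, x) maps crop coordinates back to the well frame.
    """
    zmin, ymin, xmin, zmax, ymax, xmax = (int(v) for v in bbox)
    if zmax <= zmin or ymax <= ymin or xmax <= xmin:
        raise ValueError(f"empty bbox {bbox}")
    if isinstance(pad_voxels, int):
        pad_voxels = (pad_voxels, pad_voxels, pad_voxels)
    _, nz, ny, nx = vol.data.shape
    z0, y0, x0 = (max(0, zmin - pad_voxels[0]), max(0, ymin - pad_voxels[1]),
                  max(0, xmin - pad_voxels[2]))
    z1 = min(nz, zmax + pad_voxels[0])
    y1 = min(ny, ymax + pad_voxels[1])
    x1 = min(nx, xmax + pad_voxels[2])
    crop = vol.data[:, z0:z1, y0:y1, x0:x1]
    return crop, (z0, y0, x0)


def normalize_percentile(
    crop_channel: np.ndarray, p_low: float = 1.0, p_high: float = 99.8
) -> np.ndarray:
    """Percentile-based normalization: (x − P_lo) / (P_hi − P_lo), clipped to [0, 1].

    A constant crop (P_hi == P_lo) returns all zeros with a log message.
    """
    lo, hi = np.percentile(np.asarray(crop_channel), [p_low, p_high])
    x = np.asarray(crop_channel, dtype=np.float32)
    if hi == lo:
        logger.info("constant crop during percentile normalization; returning zeros")
        return np.zeros_like(x)
    return np.clip((x - lo) / (hi - lo), 0.0, 1.0)


BackendFn = Callable[[np.ndarray, BackendConfig, tuple[float, float, float]], np.ndarray]
_BACKENDS: dict[str, BackendFn] = {}


def register_backend(name: str, fn: BackendFn) -> None:
    """Register a nucleus-segmentation backend under ``name``."""
    _BACKENDS[name] = fn


def _watershed_backend(
    crop: np.ndarray, cfg: BackendConfig, voxel_size_um: tuple[float, float, float]
) -> np.ndarray:
    """Classical backend: smooth -> Otsu -> EDT -> seeded watershed.

    All length parameters are physical (µm) and converted to voxels with
    the anisotropic voxel size, so behaviour is invariant to resampling.
    """
    dz, dy, dx = voxel_size_um
    sigma = (cfg.smoothing_sigma_um / dz, cfg.smoothing_sigma_um / dy, cfg.smoothing_sigma_um / dx)
    smooth = ndimage.gaussian_filter(crop.astype(np.float32), sigma=sigma)
    if smooth.max() == smooth.min():
        return np.zeros(crop.shape, dtype=np.int32)
    thr = filters.threshold_otsu(smooth)
    mask = smooth > thr
    if not mask.any():
        return np.zeros(crop.shape, dtype=np.int32)
    dist = ndimage.distance_transform_edt(mask, sampling=voxel_size_um)
    foot = tuple(
        max(1, int(round(cfg.min_seed_separation_um / d)) | 1) for d in voxel_size_um
    )
    coords = feature.peak_local_max(
        dist, footprint=np.ones(foot, dtype=bool), labels=mask, exclude_border=False
    )
    markers = np.zeros(crop.shape, dtype=np.int32)
    markers[tuple(coords.T)] = np.arange(1, len(coords) + 1)
    markers, _ = ndimage.label(markers > 0)
    labels = segmentation.watershed(-dist, markers=markers, mask=mask)
    return labels.astype(np.int32)


register_backend("watershed", _watershed_backend)


def _stardist_backend(
    crop: np.ndarray, cfg: BackendConfig, voxel_size_um: tuple[float, float, float]
) -> np.ndarray:  # pragma: no cover - optional plug-in
    """Star-convex CNN adapter; requires an external model in ``cfg.extra['model']``.

    Note that non-star-convex nuclei are a documented failure mode of this
    backend family.
    """
    model = cfg.extra.get("model")
    if model is None:
        raise RuntimeError(
            "star-convex backend needs an externally supplied trained model in "
            "BackendConfig.extra['model'] (training and weights are not shipped)"
        )
    pred_labels, _ = model.predict_instances(crop)
    return np.asarray(pred_labels, dtype=np.int32)


register_backend("stardist", _stardist_backend)


def segment_nuclei(
    crop_channel: np.ndarray,
    cfg: BackendConfig = BackendConfig(),
    voxel_size_um: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> LabeledVolume:
    """Segment nuclei in one normalized single-channel 3D crop.

    The contract is backend-independent: the input is a [0, 1]-normalized
    crop and the output labels are connected components with small objects
    removed and labels consecutive in raster order.
    """
    crop = np.asarray(crop_channel)
    if crop.ndim != 3:
        raise ValueError(f"crop must be 3D (z,y,x), got ndim={crop.ndim}")
    if crop.size and (crop.min() < -0.01 or crop.max() > 1.5):
        warnings.warn(
            "segment_nuclei expects a [0,1]-normalized crop; values look unnormalized",
            stacklevel=2,
        )
    backend = _BACKENDS.get(cfg.backend_name)
    if backend is None:
        raise KeyError(f"unknown backend {cfg.backend_name!r}; registered: {sorted(_BACKENDS)}")
    labels = backend(crop, cfg, voxel_size_um)
    min_voxels = cfg.min_nucleus_volume_um3 / float(np.prod(voxel_size_um))
    labels = drop_small_labels(labels, int(round(min_voxels)))
    labels = relabel_raster_order(labels)
    return LabeledVolume(labels=labels, voxel_size_um=tuple(voxel_size_um))


def nucleus_features(
    labeled: LabeledVolume,
    crop_channel: np.ndarray,
    organoid_label: int,
    offset: tuple[int, int, int] = (0, 0, 0),
    channel: str = "ch0",
) -> pd.DataFrame:
    """Per-nucleus feature table in well-frame coordinates.

    One row per nucleus with the morphology/intensity features of the
    organoid table plus eccentricity (minor/major axis ratio) and border
    flags; centroids and bboxes are shifted to the well frame by
    ``offset``.  Each fluorescence channel is measured separately, so
    ``crop_channel`` is the (raw) intensity crop of the channel that was
    segmented.
    """
    labels = labeled.labels
    crop = np.asarray(crop_channel)
    if crop.shape != labels.shape:
        raise ValueError(f"crop shape {crop.shape} != labels shape {labels.shape}")
    df = region_feature_table(
        labels,
        intensity_czyx=crop[None],
        channel_names=(channel,),
        voxel_size_um=labeled.voxel_size_um,
    )
    df = df.rename(columns={"label": "nucleus_label"})
    if df.empty:
        df["organoid_label"] = pd.Series(dtype=int)
        df["channel"] = pd.Series(dtype=str)
        df["eccentricity"] = pd.Series(dtype=float)
        df["on_border"] = pd.Series(dtype=bool)
        df["is_dead"] = pd.Series(dtype=bool)
        return df
    with np.errstate(divide="ignore", invalid="ignore"):
        df["eccentricity"] = df["minor_axis_length"] / df["major_axis_length"]
    # border flag before shifting to well frame
    nz, ny, nx = labels.shape
    df["on_border"] = (
        (df["bbox_zmin"] == 0) | (df["bbox_ymin"] == 0) | (df["bbox_xmin"] == 0)
        | (df["bbox_zmax"] == nz) | (df["bbox_ymax"] == ny) | (df["bbox_xmax"] == nx)
    )
    oz, oy, ox = offset
    for col, d in (("centroid_z", oz), ("centroid_y", oy), ("centroid_x", ox),
                   ("bbox_zmin", oz), ("bbox_zmax", oz),
                   ("bbox_ymin", oy), ("bbox_ymax", oy),
                   ("bbox_xmin", ox), ("bbox_xmax", ox)):
        df[col] = df[col] + d
    df["organoid_label"] = int(organoid_label)
    df["channel"] = channel
    df["is_dead"] = False
    # generic intensity column names (single channel per table)
    df = df.rename(
        columns={f"intensity_{s}_{channel}": f"intensity_{s}" for s in ("min", "mean", "max")}
    )
    front = ["nucleus_label", "organoid_label", "channel"]
    return df[front + [c for c in df.columns if c not in front]]


def segment_organoid_nuclei(
    vol: WellVolume,
    organoid_row: pd.Series,
    cfg: BackendConfig = BackendConfig(),
    fluorescence_channels: tuple[int, ...] | None = None,
    pad_voxels: int = 2,
) -> tuple[pd.DataFrame, dict[str, LabeledVolume], tuple[int, int, int]]:
    """Run stage 2 for one organoid: crop, normalize, segment per channel.

    Returns the concatenated nucleus table, the per-channel label volumes
    (crop frame) and the crop offset.
    """
    bbox = tuple(int(organoid_row[f"bbox_{k}"]) for k in
                 ("zmin", "ymin", "xmin", "zmax", "ymax", "xmax"))
    crop, offset = crop_organoid(vol, bbox, pad_voxels)
    channels = (
        range(vol.layout.n_channels) if fluorescence_channels is None else fluorescence_channels
    )
    tables, label_maps = [], {}
    for ci in channels:
        name = vol.layout.channels[ci]
        norm = normalize_percentile(crop[ci], cfg.p_low, cfg.p_high)
        labeled = segment_nuclei(norm, cfg, vol.voxel_size_um)
        label_maps[name] = labeled
        tables.append(
            nucleus_features(labeled, crop[ci], int(organoid_row["label"]), offset, name)
        )
    table = pd.concat(tables, ignore_index=True) if tables else pd.DataFrame()
    return table, label_maps, offset
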