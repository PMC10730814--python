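"""Well-level derived quantities.

Imaged area occupied by organoids (for area-normalized cell densities),
dead-nucleus filtering from a dead-cell dye channel, per-well summaries
(live counts, densities, clone ratios) and normalization of clone
proportions to untreated control wells.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from skimage import morphology

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AreaParams:
    """Parameters of the imaged-area estimate.

    huge_object_frac:
        2D objects covering more than this fraction of the projection are
        treated as non-organoid artifacts and removed.
    dilation_radius / closing_radius:
        Disk radii (px) used to close the space between adjacent organoids.
    """

    huge_object_frac: float = 0.25
    dilation_radius: int = 2
    closing_radius: int = 5


@dataclass
class WellSummary:
    """Per-well quantification: area, live counts, densities, clone ratio."""

    well_id: tuple[int, int]
    imaged_area_mm2: float
    n_organoids: int
    n_cells: dict[str, int]
    cell_density: dict[str, float]
    clone_ratio: float | None  # channel A : channel B among live cells; None if undefined
    dose: float | None = None
    treatment: str | None = None

    def to_row(self) -> dict:
        row = {
            "well_row": self.well_id[0],
            "well_col": self.well_id[1],
            "imaged_area_mm2": self.imaged_area_mm2,
            "n_organoids": self.n_organoids,
            "clone_ratio": np.nan if self.clone_ratio is None else self.clone_ratio,
            "clone_ratio_defined": self.clone_ratio is not None,
            "dose": np.nan if self.dose is None else self.dose,
            "treatment": self.treatment,
        }
        for ch, n in self.n_cells.items():
            row[f"n_cells_{ch}"] = n
            row[f"density_{ch}"] = self.cell_density[ch]
        return row


def imaged_area(
    labels_or_mask: np.ndarray,
    pixel_size_um: tuple[float, float],
    params: AreaParams = AreaParams(),
) -> float:
    """Area (mm²) of the imaged well that contains organoids.

    Works on the 2D max projection of the organoid label volume: very big
    non-organoid objects are removed, the space between adjacent organoids
    is closed by dilation followed by binary closing, nonzero pixels are
    counted and converted with the pixel area.
    """
    arr = np.asarray(labels_or_mask)
    mask2d = (arr.max(axis=0) if arr.ndim == 3 else arr) > 0
    if not mask2d.any():
        logger.warning("imaged_area: empty organoid mask, area = 0")
        return 0.0
    if params.huge_object_frac < 1.0:
        cutoff = params.huge_object_frac * mask2d.size
        lab, n = morphology.label(mask2d, return_num=True, connectivity=2)
        if n:
            counts = np.bincount(lab.ravel())
            huge = np.flatnonzero(counts > cutoff)
            huge = huge[huge > 0]
            if huge.size:
                logger.info("imaged_area: removing %d huge object(s)", huge.size)
                mask2d &= ~np.isin(lab, huge)
    if params.dilation_radius > 0:
        mask2d = morphology.dilation(mask2d, morphology.disk(params.dilation_radius))
    if params.closing_radius > 0:
        mask2d = morphology.closing(mask2d, morphology.disk(params.closing_radius))
    dy, dx = pixel_size_um
    return float(mask2d.sum()) * dy * dx / 1e6


def classify_dead(
    nuclei: pd.DataFrame,
    organoid_crop_dead_channel: np.ndarray,
    offset: tuple[int, int, int] = (0, 0, 0),
    threshold: float = 0.1,
    normalization: str = "minmax",
    percentiles: tuple[float, float] = (1.0, 99.8),
    range_floor: float | str = "auto",
) -> pd.DataFrame:
    """Flag dead nuclei from the dead-cell dye channel of one organoid crop.

    The dye crop is normalized to [0, 1] per organoid (min–max by default;
    ``normalization="percentile"`` is a hot-pixel-robust alternative).  For
    each nucleus the mean normalized intensity over its *bounding box* is
    computed and the nucleus is dead iff that mean is strictly greater than
    ``threshold``.

    A crop whose dynamic range is below ``range_floor`` carries no dye
    signal (normalizing it would only amplify read noise), so all nuclei
    are called live; ``"auto"`` sets the floor to 12×1.4826×MAD of the
    crop, ~12 noise SD.  Rows of ``nuclei`` are expected in well-frame
    coordinates; ``offset`` is the crop's well-frame origin.
    """
    nuclei = nuclei.copy()
    crop = np.asarray(organoid_crop_dead_channel, dtype=np.float64)
    span = float(crop.max() - crop.min()) if crop.size else 0.0
    if range_floor == "auto":
        mad = float(np.median(np.abs(crop - np.median(crop)))) if crop.size else 0.0
        floor = 12.0 * 1.4826 * mad
    else:
        floor = float(range_floor)
    if span == 0.0 or span <= floor:
        logger.info("dead channel near-constant (range %.3g <= floor %.3g): all live", span, floor)
        nuclei["is_dead"] = False
        return nuclei
    if normalization == "minmax":
        lo, hi = float(crop.min()), float(crop.max())
    elif normalization == "percentile":
        lo, hi = np.percentile(crop, percentiles)
        if hi == lo:
            nuclei["is_dead"] = False
            return nuclei
    else:
        raise ValueError(f"unknown normalization {normalization!r}")
    norm = np.clip((crop - lo) / (hi - lo), 0.0, 1.0)
    oz, oy, ox = offset
    nz, ny, nx = norm.shape
    dead = np.zeros(len(nuclei), dtype=bool)
    for i, row in enumerate(nuclei.itertuples(index=False)):
        z0 = int(np.clip(row.bbox_zmin - oz, 0, nz))
        z1 = int(np.clip(row.bbox_zmax - oz, 0, nz))
        y0 = int(np.clip(row.bbox_ymin - oy, 0, ny))
        y1 = int(np.clip(row.bbox_ymax - oy, 0, ny))
        x0 = int(np.clip(row.bbox_xmin - ox, 0, nx))
        x1 = int(np.clip(row.bbox_xmax - ox, 0, nx))
        box = norm[z0:z1, y0:y1, x0:x1]
        dead[i] = box.size > 0 and float(box.mean()) > threshold
    nuclei["is_dead"] = dead
    return nuclei


def well_summary(
    organoids: pd.DataFrame,
    nuclei: pd.DataFrame,
    area_mm2: float,
    well_id: tuple[int, int] = (0, 0),
    clone_channels: tuple[str, str] | None = None,
    dose: float | None = None,
    treatment: str | None = None,
) -> WellSummary:
    """Aggregate one well: live counts and densities per channel, clone ratio.

    The clone ratio is n_live(A) / n_live(B) for ``clone_channels=(A, B)``
    (defaults to the first two channels present); a zero denominator leaves
    the ratio undefined (flagged), not NaN-propagated.
    """
    if "is_dead" in nuclei.columns and len(nuclei):
        live = nuclei[~nuclei["is_dead"].astype(bool)]
    else:
        live = nuclei
    channels = (
        list(dict.fromkeys(nuclei["channel"])) if "channel" in nuclei.columns and len(nuclei) else []
    )
    if clone_channels is not None:
        channels = sorted(set(channels) | set(clone_channels), key=str)
    counts = {ch: int((live["channel"] == ch).sum()) if len(live) else 0 for ch in channels}
    density = {
        ch: (counts[ch] / area_mm2 if area_mm2 > 0 else float("nan")) for ch in channels
    }
    ratio: float | None = None
    if clone_channels is None and len(channels) >= 2:
        clone_channels = (channels[0], channels[1])
    if clone_channels is not None:
        a, b = clone_channels
        nb = counts.get(b, 0)
        if nb > 0:
            ratio = counts.get(a, 0) / nb
        else:
            logger.warning("well %s: clone ratio undefined (no live %s cells)", well_id, b)
    return WellSummary(
        well_id=well_id,
        imaged_area_mm2=area_mm2,
        n_organoids=int(organoids["label"].nunique()) if len(organoids) else 0,
        n_cells=counts,
        cell_density=density,
        clone_ratio=ratio,
        dose=dose,
        treatment=treatment,
    )


def organoid_clone_fractions(
    nuclei: pd.DataFrame, clone_channels: tuple[str, str]
) -> pd.DataFrame:
    """Per-organoid live-cell counts and clone fractions (input to spatial stats)."""
    if len(nuclei) == 0:
        return pd.DataFrame(columns=["organoid_label", "n_total",
                                     f"n_{clone_channels[0]}", f"n_{clone_channels[1]}",
                                     f"frac_{clone_channels[0]}", f"frac_{clone_channels[1]}"])
    live = nuclei[~nuclei.get("is_dead", pd.Series(False, index=nuclei.index)).astype(bool)]
    a, b = clone_channels
    rows = []
    for org, grp in live.groupby("organoid_label"):
        na = int((grp["channel"] == a).sum())
        nb = int((grp["channel"] == b).sum())
        n = na + nb
        rows.append({
            "organoid_label": org, "n_total": n, f"n_{a}": na, f"n_{b}": nb,
            f"frac_{a}": na / n if n else np.nan, f"frac_{b}": nb / n if n else np.nan,
        })
    return pd.DataFrame(rows)


def normalize_to_control(
    summaries: pd.DataFrame,
    value_col: str,
    dose_col: str = "dose",
    control_doses: Sequence[float] = (0.0,),
) -> pd.DataFrame:
    """Normalize a per-well quantity to the mean of untreated control wells.

    Returns one row per dose with the replicate mean and SD of
    ``value / mean(control values)``.
    """
    control = summaries[summaries[dose_col].isin(control_doses)][value_col]
    if len(control) == 0:
        raise ValueError(f"no control wells at dose(s) {list(control_doses)}")
    c = float(control.mean())
    if c == 0:
        raise ValueError("control mean is zero; cannot normalize")
    out = summaries.copy()
    out["normalized"] = out[value_col] / c
    agg = (
        out.groupby(dose_col)["normalized"]
        .agg(mean="mean", sd="std", n="count")
        .reset_index()
    )
    return agg
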