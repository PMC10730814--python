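"""Per-well pipeline orchestration.

``run_well`` executes assemble/load -> organoid stage -> nuclei stage ->
quantification for one well and writes its CSV artifacts atomically;
``run_plate`` fans out over wells, optionally in parallel processes.
Wells share no mutable state, so per-well outputs are identical regardless
of worker count or execution order.
"""

from __future__ import annotations

import logging
import os
import re
import tempfile
import traceback
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import zarr

from . import plate_io
from .nuclei_segmentation import BackendConfig, crop_organoid, segment_organoid_nuclei
from .organoid_segmentation import (
    SegmentationParams,
    clean_field,
    organoid_features,
    segment_field,
    stitch_label_filter,
)
from .well_quantification import (
    AreaParams,
    classify_dead,
    imaged_area,
    organoid_clone_fractions,
    well_summary,
)

logger = logging.getLogger(__name__)

_WELL_RE = re.compile(r"^r(\d+)c(\d+)\.zarr$")


@dataclass
class RunConfig:
    """Configuration of a plate run."""

    input_dir: Path
    output_dir: Path
    seg_params: SegmentationParams = field(default_factory=SegmentationParams)
    backend: BackendConfig = field(default_factory=BackendConfig)
    area_params: AreaParams = field(default_factory=AreaParams)
    clone_channels: tuple[str, str] | None = None
    dead_channel: str | None = None
    dead_threshold: float = 0.1
    wells: list[tuple[int, int]] | None = None  # None = all discovered
    workers: int = 1
    resume: bool = False
    pad_voxels: int = 2

    def __post_init__(self) -> None:
        self.input_dir = Path(self.input_dir)
        self.output_dir = Path(self.output_dir)


def _atomic_write_csv(df: pd.DataFrame, path: Path) -> Path:
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=".tmp")
    os.close(fd)
    try:
        df.to_csv(tmp, index=False)
        os.replace(tmp, path)
    finally:
        if os.path.exists(tmp):
            os.unlink(tmp)
    return path


def discover_wells(input_dir: Path) -> list[tuple[int, int]]:
    """Wells present in the input directory as r{row}c{col}.zarr stores."""
    wells = []
    for p in sorted(Path(input_dir).iterdir()):
        m = _WELL_RE.match(p.name)
        if m:
            wells.append((int(m.group(1)), int(m.group(2))))
    return wells


def well_artifact_paths(cfg: RunConfig, well_id: tuple[int, int]) -> dict[str, Path]:
    stem = plate_io.well_store_name(well_id)
    out = cfg.output_dir
    return {
        "organoids": out / f"{stem}_organoids.csv",
        "nuclei": out / f"{stem}_nuclei.csv",
        "clone_fractions": out / f"{stem}_clone_fractions.csv",
        "summary": out / f"{stem}_summary.csv",
        "labels": out / f"{stem}_labels.zarr",
    }


def segment_well_organoids(vol: plate_io.WellVolume, params: SegmentationParams):
    """Stage 1 on an assembled well: per-field clean+segment, stitch, measure."""
    masks = {}
    for f in range(vol.layout.fields_per_well):
        fld = plate_io.extract_field(vol, f)
        cleaned = clean_field(fld, params)
        masks[f] = segment_field(cleaned, params)
    labeled = stitch_label_filter(
        masks, vol.layout, params.min_volume_voxels, params.connectivity
    )
    return labeled, organoid_features(labeled, vol)


def segment_well_nuclei(
    vol: plate_io.WellVolume,
    organoids: pd.DataFrame,
    backend: BackendConfig,
    fluorescence_channels: tuple[int, ...] | None = None,
    dead_channel: str | None = None,
    dead_threshold: float = 0.1,
    pad_voxels: int = 2,
) -> pd.DataFrame:
    """Stage 2 + dead-cell filtering for every organoid of a well."""
    if fluorescence_channels is None:
        names = vol.layout.channels
        fluorescence_channels = tuple(
            i for i, ch in enumerate(names) if ch != dead_channel
        )
    tables = []
    for _, row in organoids.iterrows():
        table, _, offset = segment_organoid_nuclei(
            vol, row, backend, fluorescence_channels, pad_voxels
        )
        if dead_channel is not None and len(table):
            bbox = tuple(int(row[f"bbox_{k}"]) for k in
                         ("zmin", "ymin", "xmin", "zmax", "ymax", "xmax"))
            crop, off = crop_organoid(vol, bbox, pad_voxels)
            dead_crop = crop[vol.layout.channel_index(dead_channel)]
            table = classify_dead(table, dead_crop, off, threshold=dead_threshold)
        tables.append(table)
    if not tables:
        return pd.DataFrame()
    return pd.concat(tables, ignore_index=True)


def run_well(well_id: tuple[int, int], cfg: RunConfig) -> dict:
    """Run the full pipeline for one well; returns artifact paths + summary row."""
    paths = well_artifact_paths(cfg, well_id)
    store = cfg.input_dir / f"{plate_io.well_store_name(well_id)}.zarr"
    vol = plate_io.read_store(store)
    labeled, organoids = segment_well_organoids(vol, cfg.seg_params)
    arr = zarr.open_array(
        str(paths["labels"]), mode="w", shape=labeled.labels.shape,
        chunks=(1,) + labeled.labels.shape[1:], dtype=labeled.labels.dtype, zarr_format=2,
    )
    arr[:] = labeled.labels
    _atomic_write_csv(organoids, paths["organoids"])
    nuclei = segment_well_nuclei(
        vol, organoids, cfg.backend,
        dead_channel=cfg.dead_channel, dead_threshold=cfg.dead_threshold,
        pad_voxels=cfg.pad_voxels,
    )
    _atomic_write_csv(nuclei, paths["nuclei"])
    area = imaged_area(labeled.labels, vol.voxel_size_um[1:], cfg.area_params)
    clone_channels = cfg.clone_channels
    if clone_channels is None:
        fluor = [ch for ch in vol.layout.channels if ch != cfg.dead_channel]
        clone_channels = tuple(fluor[:2]) if len(fluor) >= 2 else None
    summary = well_summary(organoids, nuclei, area, well_id, clone_channels)
    summary_df = pd.DataFrame([summary.to_row()])
    _atomic_write_csv(summary_df, paths["summary"])
    if clone_channels is not None:
        _atomic_write_csv(
            organoid_clone_fractions(nuclei, clone_channels), paths["clone_fractions"]
        )
    return {"well_id": well_id, "paths": {k: str(v) for k, v in paths.items()},
            "summary": summary.to_row()}


def _run_well_safe(args) -> dict:
    well_id, cfg = args
    try:
        return run_well(well_id, cfg)
    except Exception as exc:  # per-well isolation: other wells proceed
        return {"well_id": well_id, "error": f"{exc}\n{traceback.format_exc()}"}


def _well_complete(cfg: RunConfig, well_id: tuple[int, int]) -> bool:
    paths = well_artifact_paths(cfg, well_id)
    return all(paths[k].exists() for k in ("organoids", "nuclei", "summary"))


def run_plate(cfg: RunConfig) -> pd.DataFrame:
    """Run every selected well and aggregate the per-well summaries.

    With ``cfg.resume`` wells whose artifacts already exist are skipped
    (their stored summaries are re-read).  Failures are recorded per well;
    the aggregate table carries an ``error`` column for failed wells.
    """
    wells = cfg.wells if cfg.wells is not None else discover_wells(cfg.input_dir)
    if not wells:
        raise FileNotFoundError(f"no well stores (r*c*.zarr) found in {cfg.input_dir}")
    cfg.output_dir.mkdir(parents=True, exist_ok=True)
    todo = [w for w in wells if not (cfg.resume and _well_complete(cfg, w))]
    skipped = [w for w in wells if w not in todo]
    if skipped:
        logger.info("resume: skipping %d completed well(s)", len(skipped))
    if cfg.workers > 1 and len(todo) > 1:
        with ProcessPoolExecutor(max_workers=cfg.workers) as pool:
            results = list(pool.map(_run_well_safe, [(w, cfg) for w in todo]))
    else:
        results = [_run_well_safe((w, cfg)) for w in todo]
    rows = []
    for res in results:
        if "error" in res:
            logger.error("well %s failed: %s", res["well_id"], res["error"])
            rows.append({"well_row": res["well_id"][0], "well_col": res["well_id"][1],
                         "error": res["error"].splitlines()[0]})
        else:
            rows.append(res["summary"])
    for w in skipped:
        rows.append(pd.read_csv(well_artifact_paths(cfg, w)["summary"]).iloc[0].to_dict())
    report = pd.DataFrame(rows).sort_values(["well_row", "well_col"]).reset_index(drop=True)
    _atomic_write_csv(report, cfg.output_dir / "wells_summary.csv")
    return report
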