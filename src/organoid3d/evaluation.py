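"""Benchmark routines: run the pipeline on synthetic truth and score it.

These are the heavier evaluation experiments shared by the test suite and
the reproduction script: end-to-end recovery of organoids/nuclei/clone
ratios from rendered wells, IC50 bootstrap-coverage simulation, and the
dead-cell-filter exactness check.  Everything is deterministic given the
seeds passed in.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .dose_response import fit_nplr, logistic5
from .metrics import match_instances
from .nuclei_segmentation import BackendConfig, segment_organoid_nuclei
from .organoid_segmentation import SegmentationParams
from .pipeline import segment_well_organoids
from .synthetic_data import (
    SimulationConfig,
    generate_well_volume,
    rasterize_nuclei,
    rasterize_organoids,
)
from .well_quantification import classify_dead


def evaluate_well_recovery(
    cfg: SimulationConfig,
    iou_organoid: float = 0.5,
    iou_nucleus: float = 0.4,
    nucleus_f1: bool = False,
) -> dict:
    """Render one well, run both stages, score against ground truth.

    Returns organoid precision/recall at ``iou_organoid``, the relative
    nucleus-count error, the recovered clone fraction (channel A of A+B)
    and, optionally, per-channel nucleus F1 at ``iou_nucleus``.
    """
    vol, truth = generate_well_volume(cfg)
    labeled, organoids = segment_well_organoids(vol, SegmentationParams())
    truth_orgs = rasterize_organoids(truth, cfg.layout)
    m_org = match_instances(truth_orgs, labeled.labels, iou_organoid)
    a, b = cfg.clone_channels
    fluor = (vol.layout.channel_index(a), vol.layout.channel_index(b))
    counts = {a: 0, b: 0}
    pred_labels = {ch: np.zeros(vol.data.shape[1:], np.int32) for ch in (a, b)}
    nxt = {a: 0, b: 0}
    for _, row in organoids.iterrows():
        table, lmaps, off = segment_organoid_nuclei(vol, row, BackendConfig(), fluor)
        for ch in (a, b):
            counts[ch] += int((table["channel"] == ch).sum()) if len(table) else 0
            lab = lmaps[ch].labels
            sl = tuple(slice(o, o + s) for o, s in zip(off, lab.shape))
            m = lab > 0
            pred_labels[ch][sl][m] = lab[m] + nxt[ch]
            nxt[ch] += int(lab.max())
    n_a, n_b = counts[a], counts[b]
    n_true = len(truth.nuclei)
    out = {
        "organoid_precision": m_org.precision,
        "organoid_recall": m_org.recall,
        "n_organoids_truth": m_org.n_truth,
        "n_organoids_pred": m_org.n_pred,
        "nucleus_count_error": abs((n_a + n_b) - n_true) / n_true,
        "n_nuclei_truth": n_true,
        "n_nuclei_pred": n_a + n_b,
        "clone_fraction_true": float((truth.nuclei["clone"] == a).mean()),
        "clone_fraction_pred": n_a / (n_a + n_b) if (n_a + n_b) else np.nan,
    }
    if nucleus_f1:
        for ch in (a, b):
            truth_nuc = rasterize_nuclei(truth, cfg.layout, clone=ch)
            res = match_instances(truth_nuc, pred_labels[ch], iou_nucleus)
            out[f"nucleus_f1_{ch}"] = res.f1
    return out


def clone_ratio_errors(
    base_cfg: SimulationConfig, fractions=(0.2, 0.4, 0.6, 0.8)
) -> dict[float, float]:
    """Seeded clone-fraction recovery error (fraction points) per mix fraction."""
    errors = {}
    for frac in fractions:
        cfg = replace(base_cfg, clone_fraction=frac)
        res = evaluate_well_recovery(cfg)
        errors[frac] = abs(res["clone_fraction_pred"] - frac)
    return errors


def ic50_coverage_experiment(
    seed: int,
    n_sims: int = 200,
    n_boot: int = 200,
    true_ic50: float = 2.0,
    noise_sd: float = 0.05,
    n_replicates: int = 3,
) -> dict:
    """Fraction of seeded noisy simulations whose 95% bootstrap CI covers truth."""
    doses = np.repeat([0.125, 0.25, 0.5, 1.0, 2.0, 4.0, 8.0, 16.0], n_replicates)
    x = np.log10(doses)
    covered = failures = 0
    for s in range(n_sims):
        rng = np.random.default_rng((seed + 1) * 100_000 + s)
        y = logistic5(x, 0.0, 1.0, np.log10(true_ic50), -1.0, 1.0)
        y = y + rng.normal(0, noise_sd, y.size)
        try:
            fit = fit_nplr(doses, y, seed=int(rng.integers(2**31)), n_boot=n_boot)
        except Exception:
            failures += 1
            continue
        if fit.ic50_ci_95 is None:
            failures += 1
            continue
        lo, hi = fit.ic50_ci_95
        covered += lo <= true_ic50 <= hi
    return {"coverage": covered / max(n_sims - failures, 1), "n_sims": n_sims,
            "failures": failures}


def sparse_dead_config(seed: int, layout=None) -> SimulationConfig:
    """Organoids sparse enough that bbox dye averaging cannot cross-contaminate.

    Bounding-box averaging (how the dead filter reads the dye channel) picks
    up a neighbour's dye blob whenever a live nucleus sits closer than about
    the bbox half-diagonal plus the blob reach, so the exactness check uses
    a 14 µm centre separation.
    """
    from .synthetic_data import default_layout

    return SimulationConfig(
        layout=layout if layout is not None else default_layout(),
        n_organoids=4,
        organoid_radius_um=(30.0, 1.0),
        organoid_z_radius_um=(12.0, 0.5),
        organoid_gap_um=15.0,
        nuclei_per_organoid=(6.0, 1.0),
        nucleus_min_separation_um=14.0,
        dead_fraction=0.4,
        seed=seed,
    )


def dead_filter_exactness(cfg: SimulationConfig, threshold: float = 0.1) -> dict:
    """Compare flagged-dead counts to the programmed dye-positive truth.

    Uses the truth nucleus bounding boxes (radius boxes in voxel space)
    against the rendered dye channel, isolating the dead filter from
    segmentation noise.
    """
    vol, truth = generate_well_volume(cfg)
    dz, dy, dx = cfg.layout.voxel_size_um
    dead_ch = vol.channel(cfg.dead_channel)
    exact = 0
    total_true = total_flagged = 0
    orgs = truth.organoids.set_index("organoid_id")
    for oid, grp in truth.nuclei.groupby("organoid_id"):
        org = orgs.loc[oid]
        z0 = int((org.center_z_um - org.radius_z_um) / dz)
        z1 = int(np.ceil((org.center_z_um + org.radius_z_um) / dz)) + 1
        y0 = int((org.center_y_um - org.radius_xy_um) / dy)
        y1 = int(np.ceil((org.center_y_um + org.radius_xy_um) / dy)) + 1
        x0 = int((org.center_x_um - org.radius_xy_um) / dx)
        x1 = int(np.ceil((org.center_x_um + org.radius_xy_um) / dx)) + 1
        crop = dead_ch[max(z0, 0):z1, max(y0, 0):y1, max(x0, 0):x1]
        rows = []
        for nuc in grp.itertuples(index=False):
            r = nuc.radius_um
            rows.append(dict(
                bbox_zmin=int((nuc.z_um - r) / dz), bbox_ymin=int((nuc.y_um - r) / dy),
                bbox_xmin=int((nuc.x_um - r) / dx),
                bbox_zmax=int(np.ceil((nuc.z_um + r) / dz)),
                bbox_ymax=int(np.ceil((nuc.y_um + r) / dy)),
                bbox_xmax=int(np.ceil((nuc.x_um + r) / dx))))
        out = classify_dead(pd.DataFrame(rows), crop,
                            offset=(max(z0, 0), max(y0, 0), max(x0, 0)),
                            threshold=threshold)
        k_true = int(grp["dead"].sum())
        k_flag = int(out["is_dead"].sum())
        exact += (out["is_dead"].to_numpy() == grp["dead"].to_numpy()).all()
        total_true += k_true
        total_flagged += k_flag
    return {"n_organoids": len(orgs), "n_exact": int(exact),
            "k_true": total_true, "k_flagged": total_flagged}
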