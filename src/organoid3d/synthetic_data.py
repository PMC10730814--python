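"""Ground-truthed synthetic plate generator.

Emulates the imaging regime the pipeline targets: each well holds several
organoids — dense clusters of ellipsoidal nuclei — imaged in two nuclear
fluorescence channels (one per clone) plus a dead-cell dye channel, as a
multi-field anisotropic z-stack.  Nuclei are rendered as flat-top blobs
with soft Gaussian edges (so watershed valleys exist between neighbours)
on top of a diffuse organoid body; Gaussian read noise and point debris
are optional.  Clone
labels are assigned by a spatial-affinity process: ``affinity`` = 0 gives
uniformly random labels, 1 gives two contiguous blocks, intermediate
values interpolate.  Dose ladders thin each clone binomially by its
survival curve and scale nucleus volume/intensity.

Everything is deterministic given the seed; truth tables store µm
coordinates in the well frame, converted with the same voxel-size
convention as the pipeline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .plate_io import PlateLayout, WellVolume, disassemble_well

logger = logging.getLogger(__name__)

HALF_MAX_FACTOR = float(np.sqrt(2.0 * np.log(2.0)))  # blob sigma -> FWHM/2


class PackingError(RuntimeError):
    """Requested objects cannot be packed into the available space."""


def default_layout() -> PlateLayout:
    """Desk-scale layout: 3×3 fields of 256×256 px, 30 planes, voxel (2,1,1) µm."""
    return PlateLayout(
        rows=2,
        cols=3,
        field_grid=(3, 3),
        planes_per_field=30,
        channels=("egfp", "mcherry", "draq7"),
        field_shape_px=(256, 256),
        voxel_size_um=(2.0, 1.0, 1.0),
    )


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the generator; fully deterministic given ``seed``."""

    layout: PlateLayout = field(default_factory=default_layout)
    n_organoids: int = 20
    organoid_radius_um: tuple[float, float] = (35.0, 3.0)  # xy (mean, sd)
    organoid_z_radius_um: tuple[float, float] = (20.0, 2.0)
    organoid_gap_um: float = 15.0
    nuclei_per_organoid: tuple[float, float] = (75.0, 8.0)  # (mean, sd)
    nucleus_radius_um: tuple[float, float] = (3.5, 0.25)
    nucleus_min_separation_um: float = 8.0
    nucleus_peak_intensity: tuple[float, float] = (10000.0, 1500.0)
    nucleus_edge_sigma_um: float = 0.8  # Gaussian rolloff outside the core radius
    body_intensity: float = 400.0
    background: float = 200.0
    noise_sigma: float = 20.0
    clone_fraction: float = 0.5  # fraction of channel-A (first clone channel) nuclei
    affinity: float = 0.0  # 0 = random labels, 1 = contiguous clone blocks
    dead_fraction: float = 0.0
    dead_peak_intensity: float = 9000.0
    debris_rate: float = 0.0  # expected debris points per well
    debris_intensity: float = 3000.0
    debris_sigma_um: float = 1.0
    volume_multiplier: float = 1.0  # dose effect on nucleus volume
    intensity_multiplier: float = 1.0  # dose effect on nucleus intensity
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("clone_fraction", "affinity", "dead_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.nucleus_radius_um[0] <= 0 or self.organoid_radius_um[0] <= 0:
            raise ValueError("radii must be positive")

    @property
    def clone_channels(self) -> tuple[str, str]:
        return (self.layout.channels[0], self.layout.channels[1])

    @property
    def dead_channel(self) -> str | None:
        return self.layout.channels[2] if len(self.layout.channels) > 2 else None


@dataclass
class GroundTruth:
    """Truth tables for one generated well (µm, well frame)."""

    organoids: pd.DataFrame  # organoid_id, center_*_um, radius_xy_um, radius_z_um, n_nuclei, ...
    nuclei: pd.DataFrame  # nucleus_id, organoid_id, z/y/x_um, radius_um, sigma_um, clone, dead


def _well_extent_um(layout: PlateLayout) -> tuple[float, float, float]:
    _, nz, ny, nx = layout.well_shape
    dz, dy, dx = layout.voxel_size_um
    return nz * dz, ny * dy, nx * dx


def _sample_organoid_centers(cfg: SimulationConfig, rng: np.random.Generator):
    """Dart-throwing placement of non-overlapping organoid ellipsoids."""
    ez, ey, ex = _well_extent_um(cfg.layout)
    placed = []  # (center z,y,x, r_xy, r_z)
    attempts = 0
    max_attempts = 2000 * max(cfg.n_organoids, 1)
    while len(placed) < cfg.n_organoids:
        if attempts > max_attempts:
            raise PackingError(
                f"could not place {cfg.n_organoids} organoids in a "
                f"{ey:.0f}x{ex:.0f} µm well after {attempts} attempts"
            )
        attempts += 1
        r_xy = max(5.0, rng.normal(*cfg.organoid_radius_um))
        r_z = max(4.0, rng.normal(*cfg.organoid_z_radius_um))
        margin = r_xy + cfg.organoid_gap_um / 2.0
        if 2 * margin >= min(ey, ex):
            raise PackingError("organoid radius too large for the well")
        y = rng.uniform(margin, ey - margin)
        x = rng.uniform(margin, ex - margin)
        z_lo, z_hi = min(r_z + 2.0, ez / 2), max(ez - r_z - 2.0, ez / 2)
        z = rng.uniform(z_lo, z_hi) if z_hi > z_lo else ez / 2
        ok = True
        for (pz, py, px, pr, _prz) in placed:
            if np.hypot(y - py, x - px) < r_xy + pr + cfg.organoid_gap_um:
                ok = False
                break
        if ok:
            placed.append((z, y, x, r_xy, r_z))
    return placed


def _pack_nuclei(center, r_xy, r_z, n, min_sep, rng) -> np.ndarray:
    """Uniform points in the ellipsoid with pairwise min separation (µm)."""
    cz, cy, cx = center
    pts: list[np.ndarray] = []
    attempts, max_attempts = 0, 400 * max(n, 1)
    inner = 0.92  # keep nuclei off the organoid rim
    while len(pts) < n and attempts < max_attempts:
        attempts += 1
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        rad = rng.uniform() ** (1.0 / 3.0) * inner
        cand = np.array([cz + u[0] * rad * r_z, cy + u[1] * rad * r_xy, cx + u[2] * rad * r_xy])
        if all(np.linalg.norm(cand - p) >= min_sep for p in pts):
            pts.append(cand)
    if len(pts) < n:
        logger.warning("packed only %d/%d nuclei in organoid at (%.0f, %.0f)", len(pts), n, cy, cx)
    return np.asarray(pts) if pts else np.empty((0, 3))


def _assign_clones(points: np.ndarray, frac_a: float, affinity: float,
                   rng: np.random.Generator) -> np.ndarray:
    """Spatial-affinity clone labels: rank a blend of a random spatial axis
    and uniform noise; the lowest ``frac_a`` quantile becomes clone A."""
    n = len(points)
    if n == 0:
        return np.zeros(0, dtype=bool)
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    proj = points @ direction
    order = np.argsort(proj, kind="stable")
    rank = np.empty(n)
    rank[order] = np.linspace(0.0, 1.0, n)
    score = affinity * rank + (1.0 - affinity) * rng.uniform(size=n)
    n_a = int(round(frac_a * n))
    is_a = np.zeros(n, dtype=bool)
    is_a[np.argsort(score, kind="stable")[:n_a]] = True
    return is_a


def sample_truth(cfg: SimulationConfig, rng: np.random.Generator | None = None) -> GroundTruth:
    """Sample organoid/nucleus geometry, clones and dead flags (no rendering)."""
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    clone_a, clone_b = cfg.clone_channels
    centers = _sample_organoid_centers(cfg, rng)
    org_rows, nuc_rows = [], []
    nid = 0
    for oid, (cz, cy, cx, r_xy, r_z) in enumerate(centers, start=1):
        n = max(1, int(round(rng.normal(*cfg.nuclei_per_organoid))))
        pts = _pack_nuclei((cz, cy, cx), r_xy, r_z, n, cfg.nucleus_min_separation_um, rng)
        is_a = _assign_clones(pts, cfg.clone_fraction, cfg.affinity, rng)
        dead = rng.uniform(size=len(pts)) < cfg.dead_fraction
        radii = np.clip(rng.normal(*cfg.nucleus_radius_um, size=len(pts)), 1.5, None)
        peaks = np.clip(rng.normal(*cfg.nucleus_peak_intensity, size=len(pts)), 500.0, None)
        for j in range(len(pts)):
            nid += 1
            nuc_rows.append({
                "nucleus_id": nid, "organoid_id": oid,
                "z_um": pts[j, 0], "y_um": pts[j, 1], "x_um": pts[j, 2],
                "radius_um": radii[j], "edge_sigma_um": cfg.nucleus_edge_sigma_um,
                "peak": peaks[j], "clone": clone_a if is_a[j] else clone_b,
                "dead": bool(dead[j]),
            })
        org_rows.append({
            "organoid_id": oid, "center_z_um": cz, "center_y_um": cy, "center_x_um": cx,
            "radius_xy_um": r_xy, "radius_z_um": r_z, "n_nuclei": len(pts),
            "n_clone_a": int(is_a.sum()), "n_clone_b": int(len(pts) - is_a.sum()),
            "frac_clone_a": float(is_a.mean()) if len(pts) else np.nan,
        })
    return GroundTruth(organoids=pd.DataFrame(org_rows), nuclei=pd.DataFrame(nuc_rows))


def _add_nucleus_blob(vol3d: np.ndarray, center_um, radius_um, edge_sigma_um,
                      amplitude, voxel_size: tuple[float, float, float]) -> None:
    """Add a flat-top nucleus blob: constant core of ``radius_um`` with a
    Gaussian rolloff of ``edge_sigma_um`` outside it (anisotropy-aware,
    local patch only).  The soft edge leaves watershed valleys between
    close neighbours while keeping the object's physical size well defined."""
    dz, dy, dx = voxel_size
    cz, cy, cx = center_um
    reach = radius_um + 3.5 * edge_sigma_um
    nz, ny, nx = vol3d.shape
    z0, z1 = max(0, int((cz - reach) / dz)), min(nz, int((cz + reach) / dz) + 2)
    y0, y1 = max(0, int((cy - reach) / dy)), min(ny, int((cy + reach) / dy) + 2)
    x0, x1 = max(0, int((cx - reach) / dx)), min(nx, int((cx + reach) / dx) + 2)
    if z0 >= z1 or y0 >= y1 or x0 >= x1:
        return
    zz = np.arange(z0, z1) * dz - cz
    yy = np.arange(y0, y1) * dy - cy
    xx = np.arange(x0, x1) * dx - cx
    d = np.sqrt(zz[:, None, None] ** 2 + yy[None, :, None] ** 2 + xx[None, None, :] ** 2)
    excess = np.maximum(d - radius_um, 0.0)
    vol3d[z0:z1, y0:y1, x0:x1] += amplitude * np.exp(-0.5 * (excess / edge_sigma_um) ** 2)


def _add_blob(vol3d: np.ndarray, center_um, sigma_um, amplitude,
              voxel_size: tuple[float, float, float]) -> None:
    """Add an anisotropy-aware Gaussian blob in place (local patch only)."""
    dz, dy, dx = voxel_size
    cz, cy, cx = (center_um[0] / dz, center_um[1] / dy, center_um[2] / dx)
    sz, sy, sx = (sigma_um / dz, sigma_um / dy, sigma_um / dx)
    nz, ny, nx = vol3d.shape
    z0, z1 = max(0, int(cz - 3.5 * sz)), min(nz, int(cz + 3.5 * sz) + 2)
    y0, y1 = max(0, int(cy - 3.5 * sy)), min(ny, int(cy + 3.5 * sy) + 2)
    x0, x1 = max(0, int(cx - 3.5 * sx)), min(nx, int(cx + 3.5 * sx) + 2)
    if z0 >= z1 or y0 >= y1 or x0 >= x1:
        return
    zz = (np.arange(z0, z1) - cz) / sz
    yy = (np.arange(y0, y1) - cy) / sy
    xx = (np.arange(x0, x1) - cx) / sx
    g = np.exp(-0.5 * (zz[:, None, None] ** 2 + yy[None, :, None] ** 2 + xx[None, None, :] ** 2))
    vol3d[z0:z1, y0:y1, x0:x1] += amplitude * g


def _ellipsoid_mask_patch(shape, center_um, r_z, r_xy, voxel_size):
    """(slices, boolean patch) of an axis-aligned ellipsoid in voxel space."""
    dz, dy, dx = voxel_size
    cz, cy, cx = center_um[0] / dz, center_um[1] / dy, center_um[2] / dx
    rz_v, ry_v, rx_v = r_z / dz, r_xy / dy, r_xy / dx
    nz, ny, nx = shape
    z0, z1 = max(0, int(cz - rz_v) - 1), min(nz, int(cz + rz_v) + 2)
    y0, y1 = max(0, int(cy - ry_v) - 1), min(ny, int(cy + ry_v) + 2)
    x0, x1 = max(0, int(cx - rx_v) - 1), min(nx, int(cx + rx_v) + 2)
    zz = (np.arange(z0, z1) - cz) / rz_v
    yy = (np.arange(y0, y1) - cy) / ry_v
    xx = (np.arange(x0, x1) - cx) / rx_v
    patch = (zz[:, None, None] ** 2 + yy[None, :, None] ** 2 + xx[None, None, :] ** 2) <= 1.0
    return (slice(z0, z1), slice(y0, y1), slice(x0, x1)), patch


def render_truth(truth: GroundTruth, cfg: SimulationConfig,
                 rng: np.random.Generator | None = None,
                 well_id: tuple[int, int] = (0, 0)) -> WellVolume:
    """Render truth tables into a noisy multi-channel well volume (uint16)."""
    rng = np.random.default_rng(cfg.seed + 1) if rng is None else rng
    lay = cfg.layout
    vol = np.zeros(lay.well_shape, dtype=np.float32)
    vox = lay.voxel_size_um
    a_idx = lay.channel_index(cfg.clone_channels[0])
    b_idx = lay.channel_index(cfg.clone_channels[1])
    dead_idx = lay.channel_index(cfg.dead_channel) if cfg.dead_channel else None
    # diffuse organoid body in both clone channels keeps each organoid one
    # connected bright region for stage 1
    for org in truth.organoids.itertuples(index=False):
        sl, patch = _ellipsoid_mask_patch(
            vol.shape[1:], (org.center_z_um, org.center_y_um, org.center_x_um),
            org.radius_z_um, org.radius_xy_um, vox,
        )
        for ci in (a_idx, b_idx):
            vol[ci][sl][patch] += cfg.body_intensity
    scale = cfg.volume_multiplier ** (1.0 / 3.0)
    for nuc in truth.nuclei.itertuples(index=False):
        ci = a_idx if nuc.clone == cfg.clone_channels[0] else b_idx
        center = (nuc.z_um, nuc.y_um, nuc.x_um)
        _add_nucleus_blob(vol[ci], center, nuc.radius_um * scale, nuc.edge_sigma_um,
                          nuc.peak * cfg.intensity_multiplier, vox)
        if nuc.dead and dead_idx is not None:
            _add_nucleus_blob(vol[dead_idx], center, nuc.radius_um * scale,
                              nuc.edge_sigma_um, cfg.dead_peak_intensity, vox)
    n_debris = rng.poisson(cfg.debris_rate)
    ez, ey, ex = _well_extent_um(lay)
    for _ in range(n_debris):
        center = (rng.uniform(0, ez), rng.uniform(0, ey), rng.uniform(0, ex))
        for ci in (a_idx, b_idx):
            _add_blob(vol[ci], center, cfg.debris_sigma_um, cfg.debris_intensity, vox)
    vol += cfg.background
    if cfg.noise_sigma > 0:
        vol += rng.normal(0.0, cfg.noise_sigma, size=vol.shape).astype(np.float32)
    data = np.clip(vol, 0, 65535).astype(np.uint16)
    return WellVolume(data=data, layout=lay, well_id=well_id)


def generate_well_volume(
    cfg: SimulationConfig, well_id: tuple[int, int] = (0, 0)
) -> tuple[WellVolume, GroundTruth]:
    """Generate one well as an assembled volume plus its ground truth."""
    rng = np.random.default_rng(cfg.seed)
    truth = sample_truth(cfg, rng)
    vol = render_truth(truth, cfg, rng, well_id=well_id)
    return vol, truth


def generate_well(
    cfg: SimulationConfig, well_id: tuple[int, int] = (0, 0)
) -> tuple[list[tuple[int, int, int, np.ndarray]], GroundTruth]:
    """Generate one well as per-field tiles (plate_io assembly format) + truth."""
    vol, truth = generate_well_volume(cfg, well_id)
    return disassemble_well(vol), truth


def apply_dose_effect(
    truth: GroundTruth,
    survival: Mapping[str, float],
    rng: np.random.Generator,
) -> GroundTruth:
    """Binomially thin each clone's nuclei by its survival probability."""
    nuc = truth.nuclei
    keep = np.ones(len(nuc), dtype=bool)
    for clone, s in survival.items():
        if not 0.0 <= s <= 1.0:
            raise ValueError(f"survival for {clone!r} must be in [0,1], got {s}")
        sel = (nuc["clone"] == clone).to_numpy()
        keep[sel] = rng.uniform(size=int(sel.sum())) < s
    nuclei = nuc[keep].reset_index(drop=True)
    orgs = truth.organoids.copy()
    counts = nuclei.groupby("organoid_id").size()
    orgs["n_nuclei"] = orgs["organoid_id"].map(counts).fillna(0).astype(int)
    if len(nuclei):
        clones = sorted(truth.nuclei["clone"].unique())
        by = nuclei.groupby(["organoid_id", "clone"]).size().unstack(fill_value=0)
        for i, cname in enumerate(clones[:2]):
            col = "n_clone_a" if i == 0 else "n_clone_b"
            orgs[col] = (
                orgs["organoid_id"].map(by[cname]).fillna(0).astype(int) if cname in by else 0
            )
        orgs["frac_clone_a"] = orgs["n_clone_a"] / orgs["n_nuclei"].replace(0, np.nan)
    return GroundTruth(organoids=orgs, nuclei=nuclei)


def generate_dose_ladder(
    cfg: SimulationConfig,
    doses: Sequence[float],
    survival_curves: Mapping[str, Callable[[float], float]],
    n_replicates: int = 3,
    volume_multiplier: Callable[[float], float] | None = None,
    intensity_multiplier: Callable[[float], float] | None = None,
) -> list[dict]:
    """Generate replicate wells across a dose ladder.

    Each clone's nucleus count is binomially thinned by its survival curve
    at each dose; optional per-dose multipliers scale nucleus volume and
    intensity (programmable analogues of drug-induced morphology shifts).
    Returns records ``{dose, replicate, well, truth}``.
    """
    records = []
    for di, dose in enumerate(doses):
        surv = {clone: float(f(dose)) for clone, f in survival_curves.items()}
        vm = float(volume_multiplier(dose)) if volume_multiplier else 1.0
        im = float(intensity_multiplier(dose)) if intensity_multiplier else 1.0
        for rep in range(n_replicates):
            seed = int(np.random.SeedSequence([cfg.seed, di, rep]).generate_state(1)[0] % (2**31))
            sub = replace(cfg, seed=seed, volume_multiplier=vm, intensity_multiplier=im)
            rng = np.random.default_rng(seed)
            base = sample_truth(sub, rng)
            truth = apply_dose_effect(base, surv, rng)
            well = render_truth(truth, sub, rng, well_id=(di, rep))
            records.append({"dose": float(dose), "replicate": rep, "well": well, "truth": truth})
    return records


def rasterize_organoids(truth: GroundTruth, layout: PlateLayout) -> np.ndarray:
    """Voxelize truth organoid ellipsoids into a 3D label volume."""
    _, nz, ny, nx = layout.well_shape
    labels = np.zeros((nz, ny, nx), dtype=np.int32)
    for org in truth.organoids.itertuples(index=False):
        sl, patch = _ellipsoid_mask_patch(
            (nz, ny, nx), (org.center_z_um, org.center_y_um, org.center_x_um),
            org.radius_z_um, org.radius_xy_um, layout.voxel_size_um,
        )
        labels[sl][patch] = org.organoid_id
    return labels


def rasterize_nuclei(
    truth: GroundTruth, layout: PlateLayout, clone: str | None = None
) -> np.ndarray:
    """Voxelize truth nuclei as their rendered half-maximum supports.

    A rendered nucleus is a flat core of ``radius_um`` with a Gaussian
    rolloff; its half-max support is the ball of radius
    ``radius_um + sqrt(2 ln 2) * edge_sigma_um`` — the standard object
    extent for a soft-edged emitter, and the reference against which
    predicted nuclei are IoU-matched.
    """
    _, nz, ny, nx = layout.well_shape
    labels = np.zeros((nz, ny, nx), dtype=np.int32)
    nuclei = truth.nuclei
    if clone is not None:
        nuclei = nuclei[nuclei["clone"] == clone]
    for nuc in nuclei.itertuples(index=False):
        r = nuc.radius_um + HALF_MAX_FACTOR * nuc.edge_sigma_um
        sl, patch = _ellipsoid_mask_patch(
            (nz, ny, nx), (nuc.z_um, nuc.y_um, nuc.x_um), r, r, layout.voxel_size_um,
        )
        region = labels[sl]
        region[patch] = nuc.nucleus_id
    return labels
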