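"""Clone co-localization statistics on per-organoid nucleus point sets.

For an organoid whose nuclei carry clone labels, the windowed localization
score of clone X is

    Lc = X_n / (K * R_x)          (per clone-X cell)
    Lo = (1/n) * sum_i Lc_i       (organoid score)

where X_n is the number of clone-X cells among the focal cell's K nearest
neighbours, R_x the clone-X fraction in the whole organoid and n the number
of clone-X cells.  Lo = 1 indicates random mixing; Lo > 1 co-localization.
The radial variant replaces the K-cell window with a ball of radius
r_i = i * r_max / 6 (r_max = largest pairwise distance in the organoid).
Significance comes from shuffling clone labels over the fixed geometry.

Distances are Euclidean in physical µm — centroids must be scaled by the
(anisotropic) voxel size before constructing the point set.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

logger = logging.getLogger(__name__)


class CloneAbsentError(ValueError):
    """The requested clone has no cells in the organoid."""


@dataclass
class CellPointSet:
    """Nucleus centroids (µm) with per-point clone labels for one organoid."""

    points: np.ndarray  # (n, 3) float, (z, y, x) µm
    clones: np.ndarray  # (n,) labels
    organoid_label: int = 0

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.clones = np.asarray(self.clones)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError(f"points must be (n, 3), got {self.points.shape}")
        if len(self.clones) != len(self.points):
            raise ValueError("clones and points must have equal length")

    @property
    def n_total(self) -> int:
        return len(self.points)

    def n_clone(self, clone) -> int:
        return int((self.clones == clone).sum())

    def fraction(self, clone, include_focal: bool = True) -> float:
        """R_x: proportion of the clone among all cells of the organoid."""
        return self.n_clone(clone) / self.n_total

    @classmethod
    def from_nuclei(
        cls,
        nuclei: pd.DataFrame,
        voxel_size_um: tuple[float, float, float],
        organoid_label: int,
        clone_col: str = "channel",
        live_only: bool = True,
    ) -> "CellPointSet":
        """Build a point set from a stage-2 nucleus table (voxel centroids -> µm)."""
        sel = nuclei[nuclei["organoid_label"] == organoid_label]
        if live_only and "is_dead" in sel.columns:
            sel = sel[~sel["is_dead"].astype(bool)]
        pts = sel[["centroid_z", "centroid_y", "centroid_x"]].to_numpy(dtype=float)
        pts = pts * np.asarray(voxel_size_um, dtype=float)
        return cls(points=pts, clones=sel[clone_col].to_numpy(), organoid_label=organoid_label)


@dataclass
class LocalizationResult:
    """Localization score of one clone in one organoid at one window/radius."""

    clone: object
    score: float  # Lo
    per_cell: np.ndarray  # Lc values
    n: int  # number of clone-X cells scored
    window: int | None = None  # K (cells), for the windowed score
    radius_um: float | None = None  # r_i, for the radial score
    organoid_label: int = 0


def _distance_matrix(points: np.ndarray) -> np.ndarray:
    return squareform(pdist(points))


def knn_window(points: np.ndarray, focal_index: int, K: int,
               dist: np.ndarray | None = None) -> np.ndarray:
    """Indices of the K nearest neighbours of ``focal_index`` (focal excluded).

    Distances are Euclidean in the units of ``points``; ties are broken by
    stable index order.  ``dist`` may carry a precomputed full distance
    matrix.
    """
    points = np.asarray(points)
    n = len(points)
    if not 1 <= K <= n - 1:
        raise ValueError(f"K must be in [1, n-1] = [1, {n - 1}], got {K}")
    if dist is None:
        d = np.linalg.norm(points - points[focal_index], axis=1)
    else:
        d = dist[focal_index]
    d = d.copy()
    d[focal_index] = np.inf
    order = np.argsort(d, kind="stable")
    return order[:K]


def localization_score(
    ps: CellPointSet,
    clone,
    K: int,
    include_focal_in_fraction: bool = True,
    dist: np.ndarray | None = None,
) -> LocalizationResult:
    """Windowed localization score Lo of ``clone`` at window size ``K``.

    For each clone-X cell, X_n counts clone-X cells among its K nearest
    neighbours (focal excluded from its own window); Lc = X_n/(K·R_x) with
    R_x the clone fraction over all cells (focal included by default,
    config-flagged); Lo is the mean Lc over the clone's cells.
    """
    n = ps.n_total
    if n < 2:
        raise ValueError("need at least 2 cells for a localization score")
    if K > n - 1:
        raise ValueError(f"K={K} exceeds n_total-1={n - 1}")
    n_x = ps.n_clone(clone)
    if n_x == 0:
        raise CloneAbsentError(f"clone {clone!r} absent from organoid {ps.organoid_label}")
    if dist is None:
        dist = _distance_matrix(ps.points)
    is_x = ps.clones == clone
    focals = np.flatnonzero(is_x)
    lc = np.empty(len(focals))
    for j, i in enumerate(focals):
        nbrs = knn_window(ps.points, i, K, dist=dist)
        x_n = int(is_x[nbrs].sum())
        r_x = n_x / n if include_focal_in_fraction else max(n_x - 1, 0) / (n - 1)
        if r_x == 0:
            raise CloneAbsentError("clone fraction is zero with focal excluded")
        lc[j] = x_n / (K * r_x)
    return LocalizationResult(
        clone=clone, score=float(lc.mean()), per_cell=lc, n=len(focals),
        window=K, organoid_label=ps.organoid_label,
    )


def radial_localization_score(
    ps: CellPointSet,
    clone,
    i: int = 2,
    dist: np.ndarray | None = None,
) -> LocalizationResult:
    """Radial localization score at radius r_i = i·r_max/6.

    r_max is the largest pairwise distance in the organoid and i runs over
    six equally spaced radii; i = 2 is the default reporting radius.  For
    each clone-X cell the proportion of clone-X cells within r_i (focal
    excluded) is normalized by R_x; the scores are averaged over the
    clone's cells.  Focal cells with no neighbour within r_i are skipped
    with a warning; if every cell is skipped an error is raised.
    """
    if not 1 <= i <= 6:
        raise ValueError(f"radius index i must be in 1..6, got {i}")
    n = ps.n_total
    if n < 2:
        raise ValueError("need at least 2 cells")
    n_x = ps.n_clone(clone)
    if n_x == 0:
        raise CloneAbsentError(f"clone {clone!r} absent from organoid {ps.organoid_label}")
    if dist is None:
        dist = _distance_matrix(ps.points)
    r_max = float(dist.max())
    r_i = i * r_max / 6.0
    is_x = ps.clones == clone
    r_x = n_x / n
    lc, skipped = [], 0
    for f in np.flatnonzero(is_x):
        within = (dist[f] <= r_i)
        within[f] = False
        m = int(within.sum())
        if m == 0:
            skipped += 1
            continue
        lc.append((is_x[within].sum() / m) / r_x)
    if skipped:
        warnings.warn(f"radial score: skipped {skipped} focal cell(s) with empty "
                      f"neighbourhood at r_{i}={r_i:.3g} µm", stacklevel=2)
    if not lc:
        raise ValueError(f"all focal cells had empty neighbourhoods at r_{i}={r_i:.3g} µm")
    lc = np.asarray(lc)
    return LocalizationResult(
        clone=clone, score=float(lc.mean()), per_cell=lc, n=len(lc),
        radius_um=r_i, organoid_label=ps.organoid_label,
    )


def permutation_null(
    ps: CellPointSet,
    clone,
    K: int,
    n_perm: int = 1000,
    seed: int | None = None,
) -> dict:
    """Permutation test of Lo against random clone labeling on the fixed geometry.

    Clone labels are shuffled ``n_perm`` times (seeded); the one-sided
    p-value is (1 + #{Lo_perm >= Lo_obs}) / (1 + n_perm).
    """
    if n_perm < 100:
        raise ValueError(f"n_perm must be >= 100, got {n_perm}")
    rng = np.random.default_rng(seed)
    dist = _distance_matrix(ps.points)
    obs = localization_score(ps, clone, K, dist=dist).score
    null = np.empty(n_perm)
    shuffled = CellPointSet(ps.points, ps.clones.copy(), ps.organoid_label)
    for t in range(n_perm):
        shuffled.clones = rng.permutation(ps.clones)
        null[t] = localization_score(shuffled, clone, K, dist=dist).score
    p = (1.0 + np.sum(null >= obs)) / (1.0 + n_perm)
    return {"observed": obs, "null": null, "p_value": float(p), "n_perm": n_perm}


def stratify_by_fraction(
    results: pd.DataFrame,
    fraction_col: str = "fraction",
    score_col: str = "score",
    bin_width: float = 0.2,
    balanced_range: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Bin per-organoid scores by clone fraction.

    Fractions are binned into [0, w), [w, 2w), ...; empty bins are omitted.
    ``balanced_range=(0.4, 0.6)`` restricts to organoids whose clone
    fraction lies in that closed range — the filter used when comparing
    homogeneously vs heterogeneously mixed organoids.
    """
    df = results.copy()
    if balanced_range is not None:
        lo, hi = balanced_range
        df = df[(df[fraction_col] >= lo) & (df[fraction_col] <= hi)]
    if df.empty:
        return pd.DataFrame(columns=["bin_left", "bin_right", "n", "mean", "median", "sd"])
    edges = np.arange(0.0, 1.0 + bin_width, bin_width)
    idx = np.clip(np.digitize(df[fraction_col], edges) - 1, 0, len(edges) - 2)
    df = df.assign(_bin=idx)
    rows = []
    for b, grp in df.groupby("_bin"):
        rows.append({
            "bin_left": edges[b], "bin_right": edges[b + 1], "n": len(grp),
            "mean": grp[score_col].mean(), "median": grp[score_col].median(),
            "sd": grp[score_col].std(),
        })
    return pd.DataFrame(rows).sort_values("bin_left").reset_index(drop=True)


def score_table(
    point_sets: list[CellPointSet],
    clone,
    windows: tuple[int, ...] = (5, 10, 20, 30, 40, 50),
) -> pd.DataFrame:
    """Windowed scores for many organoids at several K (organoids with
    n_total <= K are skipped for that K, logged)."""
    rows = []
    for ps in point_sets:
        if ps.n_clone(clone) == 0:
            continue
        dist = _distance_matrix(ps.points)
        for K in windows:
            if ps.n_total <= K:
                logger.info("organoid %s skipped at K=%d (n=%d)",
                            ps.organoid_label, K, ps.n_total)
                continue
            res = localization_score(ps, clone, K, dist=dist)
            rows.append({
                "organoid_label": ps.organoid_label, "clone": clone, "K": K,
                "score": res.score, "n_clone": res.n, "n_total": ps.n_total,
                "fraction": ps.fraction(clone),
            })
    return pd.DataFrame(rows)
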