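"""Permutation cluster-mass inference on centrality maps.

The group contrast is assessed voxelwise in an OLS general linear model with
nuisance covariates; suprathreshold clusters (both contrast directions) are
scored by their mass, the sum of |t| over the cluster.  The null
distribution comes from permuting group labels; the cluster-forming
threshold is selected automatically as the value that maximizes the mean
number of null clusters, and the cluster-mass significance threshold is set
so that at most one false-positive cluster per image is expected under the
null.  The significant-voxel masks of the analyses with and without motion
regression are intersected to exclude motion-driven effects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "DesignMatrix",
    "StatMap",
    "Cluster",
    "ClusterReport",
    "build_design",
    "voxelwise_glm",
    "extract_clusters",
    "auto_cluster_threshold",
    "mass_significance_threshold",
    "run_cluster_test",
    "significant_voxel_mask",
    "intersect_analyses",
    "default_threshold_grid",
    "cluster_table",
]

_COVARIATES = ["gender", "age", "ngmv", "framingham"]


def default_threshold_grid() -> np.ndarray:
    """Candidate cluster-forming |t| thresholds: 1.5 to 5.0 in steps of 0.1."""
    return np.round(np.arange(1.5, 5.0 + 1e-9, 0.1), 10)


@dataclass
class DesignMatrix:
    """Group-contrast design: intercept, group, and nuisance covariates."""

    matrix: np.ndarray           # (n_subjects, p)
    columns: list[str]
    contrast_index: int          # position of the group column

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        g = self.matrix[:, self.contrast_index]
        if not np.all(np.isin(g, [0.0, 1.0])):
            raise ValueError("group column must be binary 0/1")
        if np.linalg.matrix_rank(self.matrix) < self.matrix.shape[1]:
            raise ValueError("design matrix is rank deficient after pruning")

    @property
    def n_subjects(self) -> int:
        return self.matrix.shape[0]

    def with_group(self, group: np.ndarray) -> "DesignMatrix":
        m = self.matrix.copy()
        m[:, self.contrast_index] = group
        return DesignMatrix(m, list(self.columns), self.contrast_index)


def build_design(table: pd.DataFrame, covariates: list[str] | None = None) -> DesignMatrix:
    """Design [intercept, group, gender, age, ngmv, framingham] from the table.

    Constant or collinear covariate columns are pruned with a warning; the
    intercept and the group column are always kept.
    """
    if covariates is None:
        covariates = list(_COVARIATES)
    n = len(table)
    cols = [np.ones(n), table["group"].to_numpy(dtype=np.float64)]
    names = ["intercept", "group"]
    for c in covariates:
        v = table[c].to_numpy(dtype=np.float64)
        candidate = np.column_stack(cols + [v])
        if v.std() == 0 or np.linalg.matrix_rank(candidate) < candidate.shape[1]:
            warnings.warn(f"covariate {c!r} is constant or collinear; dropped")
            continue
        cols.append(v)
        names.append(c)
    return DesignMatrix(np.column_stack(cols), names, contrast_index=1)


@dataclass
class StatMap:
    """Per-voxel t-statistic of the group contrast on the analysis mask."""

    t: np.ndarray                # (N,) over mask voxels, C order
    df: int
    mask: np.ndarray             # 3D bool

    def to_volume(self) -> np.ndarray:
        vol = np.zeros(self.mask.shape, dtype=np.float64)
        vol[self.mask] = self.t
        return vol


@dataclass
class Cluster:
    """A connected suprathreshold component of a statistic map."""

    voxels: np.ndarray           # (k, 3) coordinates
    mass: float                  # sum of |t| over the component
    size: int
    sign: int                    # +1 / -1 contrast direction
    significant: bool = False

    def volume_mm3(self, voxel_size_mm: float) -> float:
        return self.size * voxel_size_mm ** 3


@dataclass
class ClusterReport:
    """Observed clusters plus the thresholds and null distribution behind them."""

    clusters: list[Cluster]
    stat_map: StatMap
    forming_threshold: float
    mass_threshold: float
    null_masses: np.ndarray
    n_permutations: int

    @property
    def significant_clusters(self) -> list[Cluster]:
        return [c for c in self.clusters if c.significant]


def voxelwise_glm(ec_stack: np.ndarray, design: DesignMatrix,
                  mask: np.ndarray) -> StatMap:
    """OLS t-map of the group contrast over all mask voxels at once.

    ``ec_stack`` is (n_subjects, N) with one row per design row.  df is
    n - p; voxels with zero residual variance get t = 0.
    """
    y = np.asarray(ec_stack, dtype=np.float64)
    x = design.matrix
    n, p = x.shape
    if y.shape[0] != n:
        raise ValueError("one map per design row required")
    if n <= p:
        raise ValueError(f"need more subjects ({n}) than design columns ({p})")
    xtx_inv = np.linalg.inv(x.T @ x)
    beta = xtx_inv @ (x.T @ y)                  # (p, N)
    resid = y - x @ beta
    df = n - p
    sigma2 = np.einsum("ij,ij->j", resid, resid) / df
    c = design.contrast_index
    # voxels whose residual variance vanishes (response in the design span)
    # carry no evidence either way: t = 0 there
    scale = np.einsum("ij,ij->j", y, y) / n + np.finfo(np.float64).tiny
    degenerate = sigma2 <= 1e-18 * scale
    se = np.sqrt(np.maximum(sigma2 * xtx_inv[c, c], 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(degenerate | (se == 0), 0.0, beta[c] / np.where(se > 0, se, 1.0))
    return StatMap(t=t, df=df, mask=mask)


def _connectivity_structure(connectivity: int) -> np.ndarray:
    if connectivity == 6:
        return ndimage.generate_binary_structure(3, 1)
    if connectivity == 18:
        return ndimage.generate_binary_structure(3, 2)
    if connectivity == 26:
        return ndimage.generate_binary_structure(3, 3)
    raise ValueError("connectivity must be 6, 18 or 26")


def extract_clusters(stat: StatMap, threshold: float,
                     connectivity: int = 26) -> list[Cluster]:
    """Connected components of {t > thr} and {-t > thr}, scored by mass."""
    if threshold <= 0:
        raise ValueError("cluster-forming threshold must be positive")
    vol = stat.to_volume()
    structure = _connectivity_structure(connectivity)
    clusters: list[Cluster] = []
    for sign in (1, -1):
        supra = (sign * vol) > threshold
        labels, n_lab = ndimage.label(supra, structure=structure)
        for lab in range(1, n_lab + 1):
            coords = np.argwhere(labels == lab)
            mass = float(np.abs(vol[labels == lab]).sum())
            clusters.append(
                Cluster(voxels=coords, mass=mass, size=len(coords), sign=sign)
            )
    return clusters


def _count_clusters(vol: np.ndarray, threshold: float,
                    structure: np.ndarray) -> int:
    n_pos = ndimage.label(vol > threshold, structure=structure)[1]
    n_neg = ndimage.label(-vol > threshold, structure=structure)[1]
    return n_pos + n_neg


def auto_cluster_threshold(null_t_volumes: list[np.ndarray],
                           candidate_grid: np.ndarray,
                           connectivity: int = 26) -> float:
    """Grid value maximizing the mean null suprathreshold-cluster count.

    Both contrast directions are counted; ties are broken toward the larger
    threshold.  Raises if no candidate produces any cluster.
    """
    grid = np.asarray(candidate_grid, dtype=np.float64)
    if grid.size == 0:
        raise ValueError("candidate grid is empty")
    if len(null_t_volumes) == 0:
        raise ValueError("need at least one null statistic map")
    structure = _connectivity_structure(connectivity)
    best_thr, best_count = None, -np.inf
    for thr in grid:
        mean_count = float(
            np.mean([_count_clusters(v, thr, structure) for v in null_t_volumes])
        )
        if mean_count >= best_count:   # >= prefers the larger threshold on ties
            best_thr, best_count = float(thr), mean_count
    if best_count <= 0:
        raise ValueError(
            "no suprathreshold clusters in the null at any candidate threshold; "
            "use a denser / lower grid"
        )
    return best_thr


def mass_significance_threshold(null_cluster_masses: np.ndarray,
                                n_permutations: int) -> float:
    """Smallest mass yielding at most one expected false positive per image.

    Returns the smallest observed null mass m with
    count(null masses >= m) / n_permutations <= 1; +inf if even the largest
    null mass fails; 0 with a warning when the null produced no clusters.
    """
    if n_permutations < 1:
        raise ValueError("need at least one permutation")
    masses = np.sort(np.asarray(null_cluster_masses, dtype=np.float64))
    if masses.size == 0:
        warnings.warn(
            "empty null cluster-mass distribution; significance threshold "
            "degenerates to 0 (everything significant)"
        )
        return 0.0
    # count(masses >= masses[k]) = size - first index of masses[k]
    counts = masses.size - np.searchsorted(masses, masses, side="left")
    ok = counts <= n_permutations
    if not ok.any():
        return np.inf
    return float(masses[ok][0])


def run_cluster_test(
    ec_stack: np.ndarray,
    mask: np.ndarray,
    design: DesignMatrix,
    n_permutations: int = 1000,
    seed: int = 0,
    candidate_grid: np.ndarray | None = None,
    connectivity: int = 26,
) -> ClusterReport:
    """Full permutation cluster-mass test of the group contrast.

    Pipeline: observed t-map; null t-maps from ``n_permutations`` label
    shuffles of the group column (covariates fixed); automatic
    cluster-forming threshold from the null maps; pooled null cluster masses
    at that threshold; mass significance threshold by the one-expected-
    false-positive rule; observed clusters flagged where mass >= threshold.
    Deterministic given ``seed``.
    """
    if n_permutations < 1:
        raise ValueError("need at least one permutation")
    if candidate_grid is None:
        candidate_grid = default_threshold_grid()
    rng = np.random.default_rng(seed)
    observed = voxelwise_glm(ec_stack, design, mask)
    group = design.matrix[:, design.contrast_index]

    null_vols: list[np.ndarray] = []
    for _ in range(n_permutations):
        perm_design = design.with_group(rng.permutation(group))
        null_vols.append(voxelwise_glm(ec_stack, perm_design, mask).to_volume())

    forming_thr = auto_cluster_threshold(null_vols, candidate_grid, connectivity)
    structure = _connectivity_structure(connectivity)
    null_masses: list[float] = []
    for vol in null_vols:
        for sign in (1, -1):
            labels, n_lab = ndimage.label((sign * vol) > forming_thr,
                                          structure=structure)
            if n_lab:
                null_masses.extend(
                    ndimage.sum_labels(np.abs(vol), labels, np.arange(1, n_lab + 1))
                )
    null_masses_arr = np.asarray(null_masses, dtype=np.float64)
    mass_thr = mass_significance_threshold(null_masses_arr, n_permutations)

    clusters = extract_clusters(observed, forming_thr, connectivity)
    for c in clusters:
        c.significant = c.mass >= mass_thr
    return ClusterReport(
        clusters=clusters,
        stat_map=observed,
        forming_threshold=forming_thr,
        mass_threshold=mass_thr,
        null_masses=null_masses_arr,
        n_permutations=n_permutations,
    )


def significant_voxel_mask(clusters: list[Cluster], grid_shape: tuple[int, int, int],
                           sign: int | None = None) -> np.ndarray:
    """3D mask of voxels in significant clusters (optionally one direction)."""
    mask = np.zeros(grid_shape, dtype=bool)
    for c in clusters:
        if c.significant and (sign is None or c.sign == sign):
            mask[tuple(c.voxels.T)] = True
    return mask


def intersect_analyses(clusters_a: list[Cluster], clusters_b: list[Cluster],
                       grid_shape: tuple[int, int, int]) -> np.ndarray:
    """Direction-matched intersection of two analyses' significant voxels.

    A voxel survives if it belongs to a significant cluster of the same
    contrast direction in both analyses.  An empty result is a valid
    outcome that downstream stages must handle.
    """
    out = np.zeros(grid_shape, dtype=bool)
    for sign in (1, -1):
        out |= (significant_voxel_mask(clusters_a, grid_shape, sign)
                & significant_voxel_mask(clusters_b, grid_shape, sign))
    return out


def cluster_table(report: ClusterReport, voxel_size_mm: float) -> pd.DataFrame:
    """Tabular cluster summary (label, size, volume, mass, sign, significant)."""
    rows = []
    order = np.argsort([-c.mass for c in report.clusters])
    for label, idx in enumerate(order, start=1):
        c = report.clusters[idx]
        rows.append(
            {
                "label": label,
                "size": c.size,
                "volume_mm3": c.volume_mm3(voxel_size_mm),
                "mass": c.mass,
                "sign": c.sign,
                "significant": c.significant,
            }
        )
    return pd.DataFrame(
        rows, columns=["label", "size", "volume_mm3", "mass", "sign", "significant"]
    )
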