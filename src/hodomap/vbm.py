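"""Simplified voxel-wise GLM ("VBM-lite").

Mass-univariate ordinary least squares of smoothed per-voxel lesion-evidence
images on behavioural covariates: one model per voxel, a t statistic for a
single contrast, a cluster-forming threshold at an uncorrected voxel p, an
extent threshold in mm³ (800 mm³ = 100 voxels on the default 2 mm grid), and
cluster-level multiple-comparison correction by permutation (Freedman–Lane
residual shuffling) rather than random-field theory.

For synthetic runs the input images are the 12-mm-FWHM-smoothed lesion masks
themselves — a lesion-density stand-in for segmented grey matter that
preserves the inference structure.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .volumes import ScalarVolume, assert_same_grid

__all__ = [
    "DesignMatrix",
    "ClusterResult",
    "build_design_matrix",
    "fit_voxelwise_glm",
    "extract_clusters",
    "permutation_cluster_p",
    "clusters_to_frame",
    "DESIGN_COLUMNS",
]

#: Full design: intercept + behavioural scores + confound covariates.
DESIGN_COLUMNS = [
    "intercept",
    "global_pct",
    "local_pct",
    "age",
    "sex",
    "handedness",
    "lesion_volume_cc",
]

_CONNECTIVITY_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


@dataclasses.dataclass
class DesignMatrix:
    """n_subjects × p design with named columns; checked full column rank."""

    X: np.ndarray
    columns: list[str]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2 or self.X.shape[1] != len(self.columns):
            raise ValueError("design shape incongruent with column names")
        if np.linalg.matrix_rank(self.X) < self.X.shape[1]:
            raise ValueError("design matrix is rank deficient")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def df_resid(self) -> int:
        return self.X.shape[0] - self.X.shape[1]

    def contrast_for(self, column: str, sign: float = 1.0) -> np.ndarray:
        """Unit contrast on one named column."""
        c = np.zeros(len(self.columns))
        c[self.columns.index(column)] = sign
        return c


def build_design_matrix(behaviour: pd.DataFrame) -> DesignMatrix:
    """Design from a behaviour table: scores + age, sex, handedness, lesion volume.

    Sex is coded M=1/F=0 and handedness R=1/L=0.
    """
    required = ["global_pct", "local_pct", "age", "sex", "handedness", "lesion_volume_cc"]
    missing = [c for c in required if c not in behaviour.columns]
    if missing:
        raise ValueError(f"behaviour table missing design columns: {missing}")
    n = len(behaviour)
    sex = behaviour["sex"].map({"M": 1.0, "F": 0.0})
    hand = behaviour["handedness"].map({"R": 1.0, "L": 0.0})
    if sex.isna().any() or hand.isna().any():
        raise ValueError("sex must be coded M/F and handedness R/L")
    X = np.column_stack(
        [
            np.ones(n),
            behaviour["global_pct"].to_numpy(dtype=float),
            behaviour["local_pct"].to_numpy(dtype=float),
            behaviour["age"].to_numpy(dtype=float),
            sex.to_numpy(dtype=float),
            hand.to_numpy(dtype=float),
            behaviour["lesion_volume_cc"].to_numpy(dtype=float),
        ]
    )
    return DesignMatrix(X, list(DESIGN_COLUMNS))


def _tmap_array(Y: np.ndarray, X: np.ndarray, contrast: np.ndarray) -> np.ndarray:
    """Per-voxel OLS t for a contrast; zero where residual variance is zero.

    ``Y`` is n_subjects × n_voxels.  Closed form: β = (XᵀX)⁻¹XᵀY,
    t = cᵀβ / sqrt(s² · cᵀ(XᵀX)⁻¹c).
    """
    n, p = X.shape
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ Y
    resid = Y - X @ beta
    df = n - p
    s2 = (resid**2).sum(axis=0) / df
    denom2 = s2 * float(contrast @ xtx_inv @ contrast)
    effect = contrast @ beta
    t = np.zeros_like(effect)
    ok = denom2 > 0
    t[ok] = effect[ok] / np.sqrt(denom2[ok])
    return t


def fit_voxelwise_glm(
    images: Sequence[ScalarVolume],
    design: DesignMatrix,
    contrast: np.ndarray,
) -> tuple[ScalarVolume, int]:
    """Mass-univariate OLS t-statistic map for one contrast.

    Voxels with zero residual variance report t = 0; their count is returned
    alongside the map.  The contrast must be non-zero and match the design
    width.
    """
    images = list(images)
    if len(images) != design.n:
        raise ValueError(
            f"got {len(images)} images for a design with {design.n} rows"
        )
    contrast = np.asarray(contrast, dtype=float)
    if contrast.shape != (len(design.columns),):
        raise ValueError(
            f"contrast length {contrast.shape} incongruent with design "
            f"({len(design.columns)} columns)"
        )
    if not np.any(contrast):
        raise ValueError("contrast of all zeros is invalid")
    grid = assert_same_grid(images)
    Y = np.stack([im.values.ravel() for im in images], axis=0)
    t = _tmap_array(Y, design.X, contrast)
    n_degenerate = int(np.count_nonzero(t == 0.0))
    return ScalarVolume(grid, t.reshape(grid.shape)), n_degenerate


@dataclasses.dataclass
class ClusterResult:
    size_voxels: int
    size_mm3: float
    peak_world_mm: tuple[float, float, float]
    peak_stat: float
    cluster_p: float | None = None


def _label_clusters(
    tmap: ScalarVolume, t_crit: float, extent_mm3: float, connectivity: int
) -> list[ClusterResult]:
    structure = _CONNECTIVITY_STRUCTURES[connectivity]
    supra = tmap.values >= t_crit
    labels, n_labels = ndimage.label(supra, structure=structure)
    vox_mm3 = tmap.grid.voxel_volume_mm3
    clusters: list[ClusterResult] = []
    for lab in range(1, n_labels + 1):
        idx = labels == lab
        size = int(np.count_nonzero(idx))
        if size * vox_mm3 < extent_mm3:
            continue
        masked = np.where(idx, tmap.values, -np.inf)
        peak_idx = np.unravel_index(int(np.argmax(masked)), tmap.grid.shape)
        peak_world = tuple(
            float(tmap.grid.origin_mm[a] + peak_idx[a] * tmap.grid.spacing_mm[a])
            for a in range(3)
        )
        clusters.append(
            ClusterResult(
                size_voxels=size,
                size_mm3=size * vox_mm3,
                peak_world_mm=peak_world,
                peak_stat=float(tmap.values[peak_idx]),
            )
        )
    clusters.sort(key=lambda c: c.size_voxels, reverse=True)
    return clusters


def extract_clusters(
    tmap: ScalarVolume,
    df: int,
    voxel_p: float = 0.001,
    extent_mm3: float = 800.0,
    connectivity: int = 26,
) -> list[ClusterResult]:
    """Suprathreshold clusters of a t map.

    The cluster-forming threshold is the one-sided critical t at ``voxel_p``
    with ``df`` degrees of freedom; connected components (6/18/26
    connectivity) smaller than ``extent_mm3`` are discarded.  Clusters come
    back largest first.
    """
    if df < 1:
        raise ValueError(f"df must be >= 1, got {df}")
    if not (0.0 < voxel_p < 1.0):
        raise ValueError(f"voxel_p must lie in (0, 1), got {voxel_p}")
    if connectivity not in _CONNECTIVITY_STRUCTURES:
        raise ValueError(f"connectivity must be one of 6/18/26, got {connectivity}")
    t_crit = float(stats.t.ppf(1.0 - voxel_p, df))
    return _label_clusters(tmap, t_crit, extent_mm3, connectivity)


def permutation_cluster_p(
    images: Sequence[ScalarVolume],
    design: DesignMatrix,
    contrast: np.ndarray,
    n_perm: int = 1000,
    seed: int = 0,
    voxel_p: float = 0.001,
    extent_mm3: float = 800.0,
    connectivity: int = 26,
) -> list[ClusterResult]:
    """Cluster-level correction by Freedman–Lane permutation.

    The reduced (nuisance-only) model is fitted once; its residuals are
    row-shuffled and added back to the nuisance fit to build each surrogate
    dataset, which is then analysed with the full design.  Each observed
    cluster's corrected p is

        (1 + #{permutations with max cluster size >= observed}) / (1 + n_perm)

    so the smallest attainable p is 1/(1 + n_perm).  Deterministic given
    ``seed``.
    """
    if n_perm < 100:
        raise ValueError(f"n_perm must be >= 100 for a usable p resolution, got {n_perm}")
    images = list(images)
    grid = assert_same_grid(images)
    contrast = np.asarray(contrast, dtype=float)
    tmap, _ = fit_voxelwise_glm(images, design, contrast)
    df = design.df_resid
    if df < 1:
        raise ValueError("design leaves no residual degrees of freedom")
    t_crit = float(stats.t.ppf(1.0 - voxel_p, df))
    observed = _label_clusters(tmap, t_crit, extent_mm3, connectivity)
    if not observed:
        return []

    X = design.X
    interest = contrast != 0
    Z = X[:, ~interest]
    if Z.size == 0:
        Z = np.ones((X.shape[0], 1))
    Y = np.stack([im.values.ravel() for im in images], axis=0)
    # reduced-model fit and residuals (Freedman–Lane)
    Z_pinv = np.linalg.pinv(Z)
    fitted_nuis = Z @ (Z_pinv @ Y)
    resid_nuis = Y - fitted_nuis

    rng = np.random.default_rng(seed)
    n = X.shape[0]
    max_sizes = np.zeros(n_perm, dtype=int)
    structure = _CONNECTIVITY_STRUCTURES[connectivity]
    for b in range(n_perm):
        perm = rng.permutation(n)
        Y_star = fitted_nuis + resid_nuis[perm]
        t_star = _tmap_array(Y_star, X, contrast).reshape(grid.shape)
        supra = t_star >= t_crit
        if supra.any():
            labels, n_labels = ndimage.label(supra, structure=structure)
            if n_labels:
                sizes = np.bincount(labels.ravel())[1:]
                max_sizes[b] = int(sizes.max())

    vox_mm3 = grid.voxel_volume_mm3
    out = []
    for c in observed:
        exceed = int(np.count_nonzero(max_sizes >= c.size_voxels))
        out.append(dataclasses.replace(c, cluster_p=(1 + exceed) / (1 + n_perm)))
    return out


def clusters_to_frame(clusters: Sequence[ClusterResult]) -> pd.DataFrame:
    """Tabulate clusters in the reporting-table layout (p, size, peak, coords)."""
    return pd.DataFrame(
        [
            {
                "cluster_p": c.cluster_p,
                "size_voxels": c.size_voxels,
                "size_mm3": c.size_mm3,
                "peak_stat": c.peak_stat,
                "peak_x_mm": c.peak_world_mm[0],
                "peak_y_mm": c.peak_world_mm[1],
                "peak_z_mm": c.peak_world_mm[2],
            }
            for c in clusters
        ]
    )
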