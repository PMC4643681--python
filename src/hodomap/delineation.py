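"""Automated single-case lesion delineation.

A patient image is compared voxel-by-voxel against a small control sample
with the Crawford–Howell single-case t statistic,

    t = (x - mean) / (sd * sqrt((n + 1) / n)),    df = n - 1,

which accounts for the control sample being small (the naive z score is
anti-conservative for n below ~50).  The resulting outlier t-score map codes
the degree of abnormality of each voxel; thresholding its hypointense tail
yields a binary lesion map, from which the lesion volume in cm³ follows.

The binarization threshold is deliberately configurable: by default it is the
one-tailed critical t at p = 0.01 with df = n - 1.
"""

from __future__ import annotations

import dataclasses
from typing import Literal, Sequence

import numpy as np
from scipy import ndimage, stats

from .volumes import MaskVolume, ScalarVolume, VolumeGrid, assert_same_grid, volume_cc

__all__ = [
    "ControlReference",
    "DelineationSettings",
    "DelineationReport",
    "fit_control_reference",
    "crawford_howell_t",
    "t_map",
    "binarize_lesion",
    "delineate",
    "dice_coefficient",
]

Tail = Literal["hypointense", "hyperintense", "two_sided"]

# Voxels whose control sd falls below this fraction of the mean sd are treated
# as degenerate (t undefined) and report t = 0.
SD_FLOOR_FRACTION = 1e-6


@dataclasses.dataclass
class ControlReference:
    """Voxel-wise mean and sample sd (n-1 denominator) of a control sample."""

    grid: VolumeGrid
    mean: np.ndarray
    sd: np.ndarray
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError(f"control reference needs n >= 2, got n={self.n}")
        if self.mean.shape != self.grid.shape or self.sd.shape != self.grid.shape:
            raise ValueError("mean/sd arrays incongruent with grid")
        if np.any(self.sd < 0):
            raise ValueError("sd must be non-negative")


def fit_control_reference(controls: Sequence[ScalarVolume]) -> ControlReference:
    """Voxel-wise sample mean and sd over >= 2 controls sharing one grid."""
    controls = list(controls)
    if len(controls) < 2:
        raise ValueError(f"need at least 2 control volumes, got {len(controls)}")
    grid = assert_same_grid(controls)
    stack = np.stack([c.values for c in controls], axis=0)
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1)
    return ControlReference(grid=grid, mean=mean, sd=sd, n=len(controls))


def crawford_howell_t(x: float, mean: float, sd: float, n: int) -> tuple[float, int]:
    """Crawford–Howell single-case t and its degrees of freedom (n - 1)."""
    if n < 2:
        raise ValueError(f"Crawford–Howell requires n >= 2 controls, got {n}")
    if sd <= 0:
        raise ValueError("Crawford–Howell t is undefined for sd = 0 (degenerate voxel)")
    t = (x - mean) / (sd * np.sqrt((n + 1) / n))
    return float(t), n - 1


def t_map(patient: ScalarVolume, ref: ControlReference) -> tuple[ScalarVolume, int]:
    """Voxel-wise Crawford–Howell outlier t-score map.

    Degenerate voxels (control sd below ``SD_FLOOR_FRACTION`` of the mean sd)
    are set to t = 0; their count is returned alongside the map.
    """
    assert_same_grid([patient, ref])
    floor = SD_FLOOR_FRACTION * float(ref.sd.mean())
    degenerate = ref.sd <= floor
    n_degenerate = int(np.count_nonzero(degenerate))
    safe_sd = np.where(degenerate, 1.0, ref.sd)
    t = (patient.values - ref.mean) / (safe_sd * np.sqrt((ref.n + 1) / ref.n))
    t[degenerate] = 0.0
    return ScalarVolume(patient.grid, t), n_degenerate


def binarize_lesion(
    tmap: ScalarVolume,
    t_threshold: float,
    tail: Tail = "hypointense",
    min_cluster_voxels: int = 0,
) -> MaskVolume:
    """Threshold an outlier t map into a binary lesion map.

    ``hypointense`` keeps voxels with t <= -threshold (ischemic tissue is dark
    on CT), ``hyperintense`` t >= +threshold, ``two_sided`` either.  Connected
    components (26-connectivity) smaller than ``min_cluster_voxels`` are
    optionally removed.
    """
    if t_threshold <= 0:
        raise ValueError(f"t_threshold must be > 0, got {t_threshold}")
    t = tmap.values
    if tail == "hypointense":
        mask = t <= -t_threshold
    elif tail == "hyperintense":
        mask = t >= t_threshold
    elif tail == "two_sided":
        mask = np.abs(t) >= t_threshold
    else:
        raise ValueError(f"unknown tail {tail!r}")
    if min_cluster_voxels > 1 and mask.any():
        structure = np.ones((3, 3, 3), dtype=bool)  # 26-connectivity
        labels, n_labels = ndimage.label(mask, structure=structure)
        if n_labels:
            sizes = np.bincount(labels.ravel())
            keep = sizes >= min_cluster_voxels
            keep[0] = False
            mask = keep[labels]
    return MaskVolume(tmap.grid, mask)


@dataclasses.dataclass
class DelineationSettings:
    """Threshold policy for turning a t map into a lesion map.

    ``t_threshold`` may be a number or ``"auto"``, meaning the one-tailed
    critical t at ``auto_p`` with df = n_controls - 1.
    """

    t_threshold: float | str = "auto"
    auto_p: float = 0.01
    tail: Tail = "hypointense"
    min_cluster_voxels: int = 0

    def resolve_threshold(self, df: int) -> float:
        if self.t_threshold == "auto":
            return float(stats.t.ppf(1.0 - self.auto_p, df))
        return float(self.t_threshold)


@dataclasses.dataclass
class DelineationReport:
    t_threshold: float
    df: int
    tail: str
    n_degenerate_voxels: int
    lesion_volume_cc: float

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def delineate(
    patient: ScalarVolume,
    ref: ControlReference,
    settings: DelineationSettings | None = None,
) -> tuple[MaskVolume, DelineationReport]:
    """t map -> binary lesion map -> volume, with a small audit report."""
    settings = settings or DelineationSettings()
    tmap, n_degenerate = t_map(patient, ref)
    df = ref.n - 1
    threshold = settings.resolve_threshold(df)
    mask = binarize_lesion(tmap, threshold, settings.tail, settings.min_cluster_voxels)
    report = DelineationReport(
        t_threshold=threshold,
        df=df,
        tail=settings.tail,
        n_degenerate_voxels=n_degenerate,
        lesion_volume_cc=volume_cc(mask),
    )
    return mask, report


def dice_coefficient(a: MaskVolume, b: MaskVolume) -> float:
    """Dice overlap 2|A∩B| / (|A| + |B|); 1.0 for two empty masks."""
    assert_same_grid([a, b])
    na, nb = a.n_voxels, b.n_voxels
    if na + nb == 0:
        return 1.0
    inter = int(np.count_nonzero(a.values & b.values))
    return 2.0 * inter / (na + nb)
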