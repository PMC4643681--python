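"""Synthetic stroke-cohort generator.

Every downstream stage — lesion delineation, tract overlap, track-wise
regression, the voxel-wise GLM — is exercised on data produced here, with no
external download: smooth control head volumes, patients with inserted
hypointense ellipsoid lesions of known extent, tube-shaped lateralized
probabilistic tract maps, and behavioural scores generated from an explicit
linear disconnection→deficit model with Gaussian noise.

The generative behavioural model, per outcome (global %, local %):

    score = clip(baseline - Σ_t w_t · disc_t  - b_vol · lesion_cc
                 - b_age · (age - age_mean) + ε,  0, 100),   ε ~ N(0, noise_sd²)

where ``disc_t`` is the true lesion ∩ tract-core overlap in cm³.  The default
scenario mirrors a lateralized dissociation: one left association pathway
carries the local-score weight, two right pathways carry the global-score
weights.

Randomness: one pseudo-random stream per subject, derived from
``(seed, stream-kind, subject-index)``, so adding or removing subjects never
perturbs the others.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage

from .disconnection import (
    DEFAULT_TRACT_THRESHOLD,
    TractAtlas,
    TractEntry,
    overlap_cc,
    threshold_tract,
)
from .volumes import MaskVolume, ScalarVolume, VolumeGrid, volume_cc, write_volume

__all__ = [
    "TractSpec",
    "CovariateModel",
    "CohortSpec",
    "SyntheticDataset",
    "default_grid",
    "default_tracts",
    "default_cohort_spec",
    "make_baseline",
    "make_control_volume",
    "make_tract_map",
    "make_patient_volume",
    "make_behaviour",
    "generate_cohort",
    "make_null_table",
    "write_cohort",
]


@dataclasses.dataclass(frozen=True)
class TractSpec:
    """Geometry of one synthetic tract: a Gaussian tube around a polyline.

    The map value at a voxel is ``peak_probability * exp(-d² / (2 (r/2)²))``
    with ``d`` the distance to the centerline and ``r`` the nominal radius,
    so the tube's 50% "anatomical core" is a little over half the nominal
    radius wide (for peak 0.9).
    """

    name: str
    hemisphere: str          # "left" | "right" | "commissural"
    centerline: tuple[tuple[float, float, float], ...]
    radius_mm: float = 10.0
    peak_probability: float = 0.9
    category: str = "association"

    def __post_init__(self) -> None:
        if len(self.centerline) < 2:
            raise ValueError(f"tract {self.name!r}: centerline needs >= 2 points")
        if self.radius_mm <= 0:
            raise ValueError(f"tract {self.name!r}: radius must be > 0")
        if not (0.0 < self.peak_probability <= 1.0):
            raise ValueError(f"tract {self.name!r}: peak probability must be in (0, 1]")

    @property
    def column(self) -> str:
        return f"{self.name}_{self.hemisphere}"


@dataclasses.dataclass(frozen=True)
class CovariateModel:
    """Covariate distribution and nuisance effects of the behavioural model.

    Age distribution anchors on the sub-acute stroke population (mean 72,
    sd 13 years); lesion volume and age each subtract points from both scores.
    """

    age_mean: float = 72.0
    age_sd: float = 13.0
    lesion_volume_coef: float = 0.15   # %-points lost per cm³ of lesion
    age_coef: float = 0.08             # %-points lost per year above the mean


@dataclasses.dataclass(frozen=True)
class CohortSpec:
    grid: VolumeGrid
    n_controls: int
    n_patients: int
    tracts: tuple[TractSpec, ...]
    #: tract column -> %-points of deficit per cm³ of disconnection, per outcome
    global_weights: dict[str, float]
    local_weights: dict[str, float]
    baseline_scores: tuple[float, float] = (88.0, 86.0)  # (global %, local %)
    noise_sd: float = 5.0
    covariates: CovariateModel = CovariateModel()
    lesion_size_range_mm: tuple[float, float] = (8.0, 24.0)  # ellipsoid semi-axes
    lesion_intensity_drop: float = 20.0
    control_noise_sd: float = 2.0
    #: fraction of patients whose lesion is aimed at a weighted ("effect") tract
    effect_fraction: float = 0.5
    tract_threshold: float = DEFAULT_TRACT_THRESHOLD
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_controls < 2:
            raise ValueError("n_controls must be >= 2 (control sd needs n-1 > 0)")
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        columns = {t.column for t in self.tracts}
        for key in list(self.global_weights) + list(self.local_weights):
            if key not in columns:
                raise ValueError(f"effect weight names unknown tract {key!r}")
        for b in self.baseline_scores:
            if not (0.0 <= b <= 100.0):
                raise ValueError("baseline scores must lie in [0, 100]")

    @property
    def effect_columns(self) -> list[str]:
        return sorted(set(self.global_weights) | set(self.local_weights))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["grid"] = {
            "shape": list(self.grid.shape),
            "spacing_mm": list(self.grid.spacing_mm),
            "origin_mm": list(self.grid.origin_mm),
        }
        d["tracts"] = [dataclasses.asdict(t) for t in self.tracts]
        return d


@dataclasses.dataclass
class SyntheticDataset:
    spec: CohortSpec
    patient_ids: list[str]
    controls: list[ScalarVolume]
    patients: list[ScalarVolume]
    true_lesions: list[MaskVolume]
    atlas: TractAtlas
    behaviour: pd.DataFrame
    truth: pd.DataFrame            # per-patient true disconnection (cm³) per tract
    generating_weights: dict[str, dict[str, float]]


# ---------------------------------------------------------------------------
# defaults: grid and tract geometry

def default_grid() -> VolumeGrid:
    """2 mm isotropic 40x48x40 grid centred on the midline (x = 0)."""
    return VolumeGrid(
        shape=(40, 48, 40), spacing_mm=(2.0, 2.0, 2.0), origin_mm=(-40.0, -48.0, -40.0)
    )


def _lateral_pair(
    name: str,
    points: Sequence[tuple[float, float, float]],
    radius_mm: float = 10.0,
    category: str = "association",
) -> list[TractSpec]:
    """Build mirrored left/right tracts from right-hemisphere (x > 0) points."""
    right = TractSpec(
        name=name,
        hemisphere="right",
        centerline=tuple(points),
        radius_mm=radius_mm,
        category=category,
    )
    left = TractSpec(
        name=name,
        hemisphere="left",
        centerline=tuple((-x, y, z) for x, y, z in points),
        radius_mm=radius_mm,
        category=category,
    )
    return [left, right]


def default_tracts() -> tuple[TractSpec, ...]:
    """Six mirrored association-pathway pairs (12 maps).

    Anterior–posterior tubes at distinct lateral/axial stations, loosely
    mimicking long association pathways; the full 16-tract canonical
    inventory stays the Bonferroni reference regardless of how many maps a
    synthetic cohort carries.
    """
    tracts: list[TractSpec] = []
    tracts += _lateral_pair(
        "inferior_fronto_occipital_fasciculus",
        [(26.0, -36.0, -2.0), (28.0, 0.0, 0.0), (26.0, 34.0, 2.0)],
    )
    tracts += _lateral_pair(
        "slf_iii",
        [(30.0, -26.0, 14.0), (31.0, 0.0, 16.0), (30.0, 26.0, 14.0)],
    )
    tracts += _lateral_pair(
        "perisylvian_long_segment",
        [(32.0, -30.0, -6.0), (33.0, -12.0, 8.0), (32.0, 8.0, 18.0), (31.0, 22.0, 16.0)],
    )
    tracts += _lateral_pair(
        "inferior_longitudinal_fasciculus",
        [(33.0, -38.0, -16.0), (34.0, -8.0, -14.0), (33.0, 20.0, -12.0)],
    )
    tracts += _lateral_pair(
        "slf_ii",
        [(24.0, -28.0, 24.0), (25.0, 0.0, 26.0), (24.0, 26.0, 24.0)],
    )
    tracts += _lateral_pair(
        "uncinate",
        [(26.0, 10.0, -18.0), (28.0, 24.0, -16.0), (26.0, 34.0, -6.0)],
    )
    return tuple(tracts)


#: Default dissociation scenario: the left inferior fronto-occipital fasciculus
#: carries the local-score deficit; the right SLF III and right long perisylvian
#: segment carry the global-score deficit.  Weight magnitudes were chosen from
#: an a-priori power sketch (target |t| ≈ 5 for a designated tract at n = 60,
#: noise sd 5), not adjusted afterwards.
DEFAULT_LOCAL_WEIGHTS = {"inferior_fronto_occipital_fasciculus_left": 8.0}
DEFAULT_GLOBAL_WEIGHTS = {"slf_iii_right": 8.0, "perisylvian_long_segment_right": 6.0}


def default_cohort_spec(
    seed: int = 0,
    n_controls: int = 20,
    n_patients: int = 60,
    noise_sd: float = 5.0,
    **overrides,
) -> CohortSpec:
    """The default asymmetric-dissociation cohort."""
    return CohortSpec(
        grid=default_grid(),
        n_controls=n_controls,
        n_patients=n_patients,
        tracts=default_tracts(),
        global_weights=dict(DEFAULT_GLOBAL_WEIGHTS),
        local_weights=dict(DEFAULT_LOCAL_WEIGHTS),
        noise_sd=noise_sd,
        seed=seed,
        **overrides,
    )


# ---------------------------------------------------------------------------
# image-level generators

def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, *key])


def make_baseline(grid: VolumeGrid, seed: int) -> ScalarVolume:
    """Shared smooth 'anatomy' field: mean ≈ 100 arbitrary units, positive."""
    rng = _rng(seed, 3)
    coarse_shape = tuple(max(2, s // 8) for s in grid.shape)
    coarse = rng.standard_normal(coarse_shape)
    zoom = [s / c for s, c in zip(grid.shape, coarse_shape)]
    field = ndimage.zoom(coarse, zoom, order=3)[
        : grid.shape[0], : grid.shape[1], : grid.shape[2]
    ]
    field = ndimage.gaussian_filter(field, sigma=2.0, mode="reflect")
    sd = field.std()
    if sd > 0:
        field = (field - field.mean()) / sd
    values = 100.0 + 8.0 * field
    return ScalarVolume(grid, np.maximum(values, 1.0))


def make_control_volume(
    grid: VolumeGrid,
    seed: int,
    noise_sd: float = 2.0,
    baseline: ScalarVolume | None = None,
) -> ScalarVolume:
    """One control image: the smooth baseline plus i.i.d. Gaussian noise.

    Deterministic given ``seed``; all values strictly positive.
    """
    if baseline is None:
        baseline = make_baseline(grid, seed)
    rng = _rng(seed, 0)
    values = baseline.values + noise_sd * rng.standard_normal(grid.shape)
    return ScalarVolume(grid, np.maximum(values, 1e-3))


def make_tract_map(spec: TractSpec, grid: VolumeGrid) -> ScalarVolume:
    """Probabilistic tube map around the tract's centerline polyline."""
    lo = np.array(grid.origin_mm)
    hi = lo + (np.array(grid.shape) - 1) * np.array(grid.spacing_mm)
    pts = np.asarray(spec.centerline, dtype=float)
    if np.any(pts < lo - 1e-9) or np.any(pts > hi + 1e-9):
        raise ValueError(
            f"tract {spec.name!r}: centerline leaves the grid bounding box "
            f"[{lo} .. {hi}]"
        )
    x, y, z = grid.world_coordinates()
    vox = np.stack(np.broadcast_arrays(x, y, z), axis=-1).reshape(-1, 3)
    d2 = np.full(vox.shape[0], np.inf)
    for a, b in zip(pts[:-1], pts[1:]):
        ab = b - a
        denom = float(ab @ ab)
        if denom == 0.0:
            proj = np.zeros(vox.shape[0])
        else:
            proj = np.clip((vox - a) @ ab / denom, 0.0, 1.0)
        nearest = a + proj[:, None] * ab
        d2 = np.minimum(d2, ((vox - nearest) ** 2).sum(axis=1))
    sigma = spec.radius_mm / 2.0
    values = spec.peak_probability * np.exp(-d2 / (2.0 * sigma**2))
    return ScalarVolume(grid, values.reshape(grid.shape))


def _ellipsoid_mask(
    grid: VolumeGrid,
    center_mm: Sequence[float],
    radii_mm: Sequence[float],
) -> MaskVolume:
    x, y, z = grid.world_coordinates()
    cx, cy, cz = center_mm
    rx, ry, rz = radii_mm
    if min(rx, ry, rz) <= 0:
        raise ValueError("ellipsoid radii must be positive")
    q = ((x - cx) / rx) ** 2 + ((y - cy) / ry) ** 2 + ((z - cz) / rz) ** 2
    return MaskVolume(grid, q <= 1.0)


def make_patient_volume(
    baseline: ScalarVolume,
    lesion_center_mm: Sequence[float],
    lesion_radii_mm: Sequence[float],
    intensity_drop: float,
) -> tuple[ScalarVolume, MaskVolume]:
    """Insert a sharp hypointense ellipsoid lesion into a control-like image.

    Returns the lesioned image and the exact ellipsoid mask as ground truth.
    The ellipsoid must intersect the grid.
    """
    mask = _ellipsoid_mask(baseline.grid, lesion_center_mm, lesion_radii_mm)
    if mask.n_voxels == 0:
        raise ValueError(
            f"lesion ellipsoid at {tuple(lesion_center_mm)} does not intersect the grid"
        )
    values = baseline.values - intensity_drop * mask.values
    return ScalarVolume(baseline.grid, values), mask


# ---------------------------------------------------------------------------
# behaviour

def make_behaviour(
    truth: pd.DataFrame,
    lesion_volumes_cc: Sequence[float],
    spec: CohortSpec,
) -> pd.DataFrame:
    """Generate the behavioural table from true disconnections.

    ``truth`` has one row per patient and one column per tract (cm³).
    Deterministic given ``spec.seed``; scores clipped to [0, 100].
    """
    n = len(truth)
    if n != len(lesion_volumes_cc):
        raise ValueError("lesion volume list does not match truth rows")
    cov = spec.covariates
    base_g, base_l = spec.baseline_scores
    rows = []
    for i in range(n):
        rng = _rng(spec.seed, 2, i)
        age = float(rng.normal(cov.age_mean, cov.age_sd))
        sex = "M" if rng.random() < 0.5 else "F"
        handedness = "R" if rng.random() < 0.92 else "L"
        vf_left = int(rng.poisson(0.5))
        vf_right = int(rng.poisson(0.5))
        les = float(lesion_volumes_cc[i])
        nuisance = cov.lesion_volume_coef * les + cov.age_coef * (age - cov.age_mean)
        g = base_g - nuisance
        l = base_l - nuisance
        for col, w in spec.global_weights.items():
            g -= w * float(truth.iloc[i][col])
        for col, w in spec.local_weights.items():
            l -= w * float(truth.iloc[i][col])
        g += float(rng.normal(0.0, spec.noise_sd)) if spec.noise_sd > 0 else 0.0
        l += float(rng.normal(0.0, spec.noise_sd)) if spec.noise_sd > 0 else 0.0
        rows.append(
            {
                "patient_id": truth.index[i],
                "age": age,
                "sex": sex,
                "handedness": handedness,
                "vf_miss_left": vf_left,
                "vf_miss_right": vf_right,
                "global_pct": float(np.clip(g, 0.0, 100.0)),
                "local_pct": float(np.clip(l, 0.0, 100.0)),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# cohort assembly

def _place_lesion(
    spec: CohortSpec, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Pick a lesion centre (biased toward effect tracts) and semi-axes."""
    effect_cols = spec.effect_columns
    by_column = {t.column: t for t in spec.tracts}
    if effect_cols and rng.random() < spec.effect_fraction:
        tract = by_column[effect_cols[rng.integers(len(effect_cols))]]
    else:
        tract = spec.tracts[rng.integers(len(spec.tracts))]
    pts = np.asarray(tract.centerline)
    seg = rng.integers(len(pts) - 1)
    t = rng.random()
    center = pts[seg] + t * (pts[seg + 1] - pts[seg])
    center = center + rng.normal(0.0, 3.0, size=3)
    lo, hi = spec.lesion_size_range_mm
    radii = rng.uniform(lo, hi, size=3)
    # keep the centre inside the grid so the ellipsoid always intersects it
    gmin = np.array(spec.grid.origin_mm)
    gmax = gmin + (np.array(spec.grid.shape) - 1) * np.array(spec.grid.spacing_mm)
    center = np.clip(center, gmin, gmax)
    return center, radii


def generate_cohort(spec: CohortSpec, include_images: bool = True) -> SyntheticDataset:
    """Generate a full synthetic dataset from a cohort specification.

    With ``include_images=False`` the control and patient intensity volumes
    are skipped (lesion masks, atlas, truth and behaviour are still produced);
    useful for statistics-only simulation studies where the image channel
    would only add runtime.
    """
    grid = spec.grid
    baseline = make_baseline(grid, spec.seed)

    atlas = TractAtlas(
        [
            TractEntry(
                name=t.name,
                hemisphere=t.hemisphere,
                category=t.category,
                map=make_tract_map(t, grid),
            )
            for t in spec.tracts
        ]
    )
    cores = {e.column: threshold_tract(e.map, spec.tract_threshold) for e in atlas.entries}

    patient_ids = [f"p{i:03d}" for i in range(spec.n_patients)]
    controls: list[ScalarVolume] = []
    if include_images:
        for j in range(spec.n_controls):
            rng = _rng(spec.seed, 0, j)
            noisy = baseline.values + spec.control_noise_sd * rng.standard_normal(grid.shape)
            controls.append(ScalarVolume(grid, np.maximum(noisy, 1e-3)))

    patients: list[ScalarVolume] = []
    true_lesions: list[MaskVolume] = []
    truth_rows = []
    for i in range(spec.n_patients):
        rng = _rng(spec.seed, 1, i)
        center, radii = _place_lesion(spec, rng)
        if include_images:
            noisy = ScalarVolume(
                grid,
                np.maximum(
                    baseline.values + spec.control_noise_sd * rng.standard_normal(grid.shape),
                    1e-3,
                ),
            )
            image, lesion = make_patient_volume(
                noisy, center, radii, spec.lesion_intensity_drop
            )
            patients.append(image)
        else:
            lesion = _ellipsoid_mask(grid, center, radii)
        true_lesions.append(lesion)
        truth_rows.append({col: overlap_cc(lesion, core) for col, core in cores.items()})

    truth = pd.DataFrame(truth_rows, index=pd.Index(patient_ids, name="patient_id"))
    lesion_volumes = [volume_cc(m) for m in true_lesions]
    behaviour = make_behaviour(truth, lesion_volumes, spec)

    return SyntheticDataset(
        spec=spec,
        patient_ids=patient_ids,
        controls=controls,
        patients=patients,
        true_lesions=true_lesions,
        atlas=atlas,
        behaviour=behaviour,
        truth=truth,
        generating_weights={
            "global_pct": dict(spec.global_weights),
            "local_pct": dict(spec.local_weights),
        },
    )


# ---------------------------------------------------------------------------
# table-level null generator (for type-I calibration studies)

def make_null_table(
    n_patients: int,
    tract_columns: Sequence[str],
    hemispheres: dict[str, str],
    seed: int,
    noise_sd: float = 5.0,
    covariates: CovariateModel = CovariateModel(),
    baseline_scores: tuple[float, float] = (88.0, 86.0),
) -> pd.DataFrame:
    """Disconnection-style table with NO tract→deficit effect.

    Overlaps follow a sparse exponential pattern confined to one lesioned
    hemisphere per patient; lesion volume is correlated with the overlaps
    (as in real cohorts) and does feed the outcome, so the null exercises the
    covariate adjustment, not just independent noise.
    """
    rng = _rng(seed, 7)
    rows = []
    for i in range(n_patients):
        side = "left" if rng.random() < 0.5 else "right"
        overlaps = {}
        for col in tract_columns:
            hemi = hemispheres[col]
            if hemi in (side, "commissural") and rng.random() < 0.45:
                overlaps[col] = float(rng.exponential(0.8))
            else:
                overlaps[col] = 0.0
        lesion_cc = sum(overlaps.values()) + float(rng.exponential(8.0))
        age = float(rng.normal(covariates.age_mean, covariates.age_sd))
        nuisance = covariates.lesion_volume_coef * lesion_cc + covariates.age_coef * (
            age - covariates.age_mean
        )
        g = float(
            np.clip(baseline_scores[0] - nuisance + rng.normal(0, noise_sd), 0, 100)
        )
        l = float(
            np.clip(baseline_scores[1] - nuisance + rng.normal(0, noise_sd), 0, 100)
        )
        rows.append(
            {
                "patient_id": f"p{i:03d}",
                "lesion_volume_cc": lesion_cc,
                "lesion_volume_left_cc": lesion_cc if side == "left" else 0.0,
                "lesion_volume_right_cc": lesion_cc if side == "right" else 0.0,
                "age": age,
                "sex": "M" if rng.random() < 0.5 else "F",
                "handedness": "R" if rng.random() < 0.92 else "L",
                "vf_miss_left": int(rng.poisson(0.5)),
                "vf_miss_right": int(rng.poisson(0.5)),
                "global_pct": g,
                "local_pct": l,
                **overlaps,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# on-disk cohort layout

def write_cohort(dataset: SyntheticDataset, directory: str | Path) -> None:
    """Write a cohort to a directory: NIfTI volumes, behaviour.tsv, truth.json,
    cohort_spec.yaml and an atlas manifest."""
    directory = Path(directory)
    for sub in ("controls", "patients", "lesions", "atlas"):
        (directory / sub).mkdir(parents=True, exist_ok=True)
    for j, vol in enumerate(dataset.controls):
        write_volume(vol, directory / "controls" / f"c{j:03d}.nii.gz")
    for pid, vol in zip(dataset.patient_ids, dataset.patients):
        write_volume(vol, directory / "patients" / f"{pid}.nii.gz")
    for pid, mask in zip(dataset.patient_ids, dataset.true_lesions):
        write_volume(mask, directory / "lesions" / f"{pid}.nii.gz")
    manifest = {"tracts": []}
    for e in dataset.atlas.entries:
        fname = f"{e.column}.nii.gz"
        write_volume(e.map, directory / "atlas" / fname)
        manifest["tracts"].append(
            {
                "name": e.name,
                "hemisphere": e.hemisphere,
                "category": e.category,
                "path": f"atlas/{fname}",
            }
        )
    (directory / "atlas_manifest.yaml").write_text(yaml.safe_dump(manifest))
    dataset.behaviour.to_csv(directory / "behaviour.tsv", sep="\t", index=False)
    truth_payload = {
        "disconnection_cc": {
            pid: {col: float(dataset.truth.loc[pid, col]) for col in dataset.truth.columns}
            for pid in dataset.truth.index
        },
        "generating_weights": dataset.generating_weights,
    }
    (directory / "truth.json").write_text(json.dumps(truth_payload, indent=2))
    (directory / "cohort_spec.yaml").write_text(yaml.safe_dump(dataset.spec.to_dict()))
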