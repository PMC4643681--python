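"""Track-wise disconnection quantification.

Each atlas entry is a probabilistic tract map (voxel value = probability of
belonging to that tract).  Thresholding at 50% keeps the anatomical core of
the tract and drops its variable periphery; the disconnection measure for a
patient and a tract is then the volume of the lesion ∩ core overlap in cubic
centimetres — a continuous severity measure, not a binary hit.

Also provides the descriptive group maps: the lesion overlap count map and
the percentage of patients disconnected per tract.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .volumes import (
    MaskVolume,
    ScalarVolume,
    assert_same_grid,
    hemisphere_mask,
    read_mask,
    read_volume,
    volume_cc,
)

__all__ = [
    "CANONICAL_TRACTS",
    "canonical_tract_names",
    "TractEntry",
    "TractAtlas",
    "DisconnectionTable",
    "threshold_tract",
    "overlap_cc",
    "build_disconnection_table",
    "percent_disconnected",
    "group_lesion_overlap",
    "load_atlas",
    "DEFAULT_TRACT_THRESHOLD",
    "COVARIATE_COLUMNS",
]

DEFAULT_TRACT_THRESHOLD = 0.5

#: The canonical white-matter pathway inventory used for the track-wise
#: analyses: 10 association, 2 commissural and 4 projection pathways
#: (16 tracts in total, the count behind the Bonferroni default).
CANONICAL_TRACTS: tuple[tuple[str, str], ...] = (
    ("inferior_longitudinal_fasciculus", "association"),
    ("inferior_fronto_occipital_fasciculus", "association"),
    ("perisylvian_anterior_segment", "association"),
    ("perisylvian_posterior_segment", "association"),
    ("perisylvian_long_segment", "association"),
    ("cingulum", "association"),
    ("uncinate", "association"),
    ("slf_i", "association"),
    ("slf_ii", "association"),
    ("slf_iii", "association"),
    ("anterior_commissure", "commissural"),
    ("corpus_callosum", "commissural"),
    ("fornix", "projection"),
    ("internal_capsule", "projection"),
    ("optic_radiations", "projection"),
    ("cortico_spinal_tract", "projection"),
)


def canonical_tract_names() -> list[str]:
    return [name for name, _ in CANONICAL_TRACTS]


@dataclasses.dataclass
class TractEntry:
    name: str
    hemisphere: str          # "left" | "right" | "commissural"
    category: str            # "association" | "commissural" | "projection"
    map: ScalarVolume

    @property
    def column(self) -> str:
        """Column label used in disconnection tables."""
        return f"{self.name}_{self.hemisphere}"


@dataclasses.dataclass
class TractAtlas:
    entries: list[TractEntry]

    def __post_init__(self) -> None:
        cols = [e.column for e in self.entries]
        if len(set(cols)) != len(cols):
            raise ValueError("atlas entries must be unique by (name, hemisphere)")
        if self.entries:
            assert_same_grid([e.map for e in self.entries])
        for e in self.entries:
            e.map = _normalize_probability_scale(e.map, e.column)

    @property
    def grid(self):
        return self.entries[0].map.grid

    def columns(self) -> list[str]:
        return [e.column for e in self.entries]


def _normalize_probability_scale(vol: ScalarVolume, label: str) -> ScalarVolume:
    """Bring a tract map onto the [0, 1] probability scale.

    Published atlas files come in either [0, 1] or percent [0, 100]; a map
    whose maximum exceeds 1 is treated as percent-scaled and divided by 100.
    """
    vmax = float(vol.values.max(initial=0.0))
    vmin = float(vol.values.min(initial=0.0))
    if vmin < 0:
        raise ValueError(f"tract map {label!r} has negative values")
    if vmax > 1.0:
        if vmax > 100.0:
            raise ValueError(f"tract map {label!r} exceeds the percent scale (max={vmax})")
        return ScalarVolume(vol.grid, vol.values / 100.0)
    return vol


def threshold_tract(map: ScalarVolume, threshold: float = DEFAULT_TRACT_THRESHOLD) -> MaskVolume:
    """Tract core: voxels with probability >= threshold (inclusive)."""
    if not (0.0 < threshold < 1.0):
        raise ValueError(f"threshold must lie in (0, 1), got {threshold}")
    return MaskVolume(map.grid, map.values >= threshold)


def overlap_cc(lesion: MaskVolume, tract_mask: MaskVolume) -> float:
    """Volume in cm³ of the lesion ∩ tract-core intersection."""
    assert_same_grid([lesion, tract_mask])
    inter = MaskVolume(lesion.grid, lesion.values & tract_mask.values)
    return volume_cc(inter)


#: Fixed non-tract columns every disconnection table carries.
COVARIATE_COLUMNS = [
    "patient_id",
    "lesion_volume_cc",
    "age",
    "sex",
    "handedness",
    "vf_miss_left",
    "vf_miss_right",
    "global_pct",
    "local_pct",
]


@dataclasses.dataclass
class DisconnectionTable:
    """Patients × tracts overlap table plus covariates and outcomes.

    ``data`` holds one row per patient with the ``COVARIATE_COLUMNS`` plus one
    overlap column per atlas entry (named ``<tract>_<hemisphere>``); zero (not
    missing) encodes "no overlap".
    """

    data: pd.DataFrame
    tract_columns: list[str]
    tract_hemispheres: dict[str, str]

    def __post_init__(self) -> None:
        for col in COVARIATE_COLUMNS:
            if col not in self.data.columns:
                raise ValueError(f"disconnection table missing column {col!r}")
        for col in self.tract_columns:
            if col not in self.data.columns:
                raise ValueError(f"disconnection table missing tract column {col!r}")
            vals = self.data[col].to_numpy(dtype=float)
            if np.any(np.isnan(vals)):
                raise ValueError(f"tract column {col!r} has missing cells")
            if np.any(vals < 0):
                raise ValueError(f"tract column {col!r} has negative overlap")
            over = vals > self.data["lesion_volume_cc"].to_numpy(dtype=float) + 1e-9
            if np.any(over):
                raise ValueError(f"tract column {col!r}: overlap exceeds lesion volume")

    def to_tsv(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t", index=False)


def build_disconnection_table(
    lesions: Mapping[str, MaskVolume],
    atlas: TractAtlas,
    behaviour: pd.DataFrame,
    threshold: float = DEFAULT_TRACT_THRESHOLD,
) -> DisconnectionTable:
    """Measure every patient × tract overlap and join with behaviour rows.

    ``lesions`` maps patient id -> lesion mask; ``behaviour`` must carry one
    row per patient (``patient_id`` column) with covariates and outcomes.
    Lesion volumes are recomputed from the masks, never trusted from input.
    """
    if "patient_id" not in behaviour.columns:
        raise ValueError("behaviour table must have a patient_id column")
    behaviour = behaviour.copy()
    behaviour["patient_id"] = behaviour["patient_id"].astype(str)
    lesion_ids = set(str(k) for k in lesions)
    table_ids = set(behaviour["patient_id"])
    if lesion_ids != table_ids:
        raise ValueError(
            "patient id mismatch between lesions and behaviour: "
            f"only-in-lesions={sorted(lesion_ids - table_ids)}, "
            f"only-in-behaviour={sorted(table_ids - lesion_ids)}"
        )
    assert_same_grid(list(lesions.values()) + [e.map for e in atlas.entries])

    cores = {e.column: threshold_tract(e.map, threshold) for e in atlas.entries}
    grid = atlas.grid
    hemi_masks = {side: hemisphere_mask(grid, side) for side in ("left", "right")}
    rows = []
    for pid, lesion in sorted(lesions.items(), key=lambda kv: str(kv[0])):
        row: dict[str, object] = {
            "patient_id": str(pid),
            "lesion_volume_cc": volume_cc(lesion),
            # laterality of the damage, used to restrict per-hemisphere analyses
            "lesion_volume_left_cc": overlap_cc(lesion, hemi_masks["left"]),
            "lesion_volume_right_cc": overlap_cc(lesion, hemi_masks["right"]),
        }
        for col, core in cores.items():
            row[col] = overlap_cc(lesion, core)
        rows.append(row)
    overlaps = pd.DataFrame(rows)
    data = behaviour.merge(overlaps, on="patient_id", how="inner", suffixes=("_given", ""))
    if "lesion_volume_cc_given" in data.columns:
        data = data.drop(columns=["lesion_volume_cc_given"])
    tract_cols = [e.column for e in atlas.entries]
    data = data[
        [c for c in COVARIATE_COLUMNS if c in data.columns]
        + ["lesion_volume_left_cc", "lesion_volume_right_cc"]
        + tract_cols
    ]
    return DisconnectionTable(
        data=data.reset_index(drop=True),
        tract_columns=tract_cols,
        tract_hemispheres={e.column: e.hemisphere for e in atlas.entries},
    )


def percent_disconnected(
    table: DisconnectionTable, min_overlap_cc: float = 0.0
) -> pd.Series:
    """% of patients with any disconnection per tract (overlap > min, default 0)."""
    n = len(table.data)
    if n == 0:
        raise ValueError("empty disconnection table")
    out = {}
    for col in table.tract_columns:
        hit = (table.data[col].to_numpy(dtype=float) > min_overlap_cc).sum()
        out[col] = 100.0 * hit / n
    return pd.Series(out, name="percent_disconnected")


def group_lesion_overlap(lesions: Sequence[MaskVolume]) -> ScalarVolume:
    """Per-voxel count of patients lesioned at that voxel."""
    grid = assert_same_grid(lesions)
    counts = np.zeros(grid.shape, dtype=np.float64)
    for lesion in lesions:
        counts += lesion.values
    return ScalarVolume(grid, counts)


def load_atlas(manifest_path: str | Path) -> TractAtlas:
    """Load a tract atlas from a YAML manifest.

    Manifest schema: ``tracts: [{name, hemisphere, category, path}, ...]``;
    paths are resolved relative to the manifest file.
    """
    manifest_path = Path(manifest_path)
    raw = yaml.safe_load(manifest_path.read_text())
    if not isinstance(raw, dict) or "tracts" not in raw:
        raise ValueError(f"{manifest_path}: manifest must have a top-level 'tracts' list")
    entries = []
    for item in raw["tracts"]:
        missing = {"name", "hemisphere", "category", "path"} - set(item)
        if missing:
            raise ValueError(f"{manifest_path}: tract entry missing keys {sorted(missing)}")
        vol = read_volume(manifest_path.parent / item["path"])
        entries.append(
            TractEntry(
                name=item["name"],
                hemisphere=item["hemisphere"],
                category=item["category"],
                map=vol,
            )
        )
    return TractAtlas(entries)


def load_lesion_directory(directory: str | Path) -> dict[str, MaskVolume]:
    """Load all ``*.nii``/``*.nii.gz`` masks in a directory, keyed by stem."""
    directory = Path(directory)
    lesions: dict[str, MaskVolume] = {}
    for path in sorted(directory.glob("*.nii*")):
        stem = path.name.removesuffix(".gz").removesuffix(".nii")
        lesions[stem] = read_mask(path)
    if not lesions:
        raise FileNotFoundError(f"no NIfTI lesion masks found in {directory}")
    return lesions
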