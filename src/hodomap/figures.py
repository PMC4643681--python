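"""Complex-figure copy scoring: the 47-point whole-figure scheme and the
modified global/local decomposition.

The figure is a rectangular layout of three large boxes with smaller details
inside.  Two scoring views coexist:

* **Whole-figure score (max 47).**  16 scoreable units; 15 of them earn one
  point each for presence, correct shape and correct placement, and the
  middle square earns presence + shape only.

* **Global/local scores (max 6 / max 14).**  20 features graded for presence
  only: 6 "global" features carrying the larger layout, 14 "local" refining
  details.  Scores are expressed as percentages of their maxima before any
  statistical modelling, because the two maxima differ.

The unit/feature mapping lives in a data registry (``data/figure_registry.yaml``)
validated at load; two units own a global whole plus two local sub-features,
and those rows are flagged ambiguous in the data rather than silently merged.
"""

from __future__ import annotations

import dataclasses
from importlib import resources
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

__all__ = [
    "FigureFeature",
    "FigureUnit",
    "FigureRegistry",
    "DrawingRecord",
    "load_registry",
    "total_score",
    "global_score",
    "local_score",
    "percent_scores",
    "load_drawing_record",
    "perfect_record",
    "MAX_TOTAL",
    "MAX_GLOBAL",
    "MAX_LOCAL",
]

MAX_TOTAL = 47
MAX_GLOBAL = 6
MAX_LOCAL = 14


@dataclasses.dataclass(frozen=True)
class FigureFeature:
    id: str
    level: str              # "global" | "local"
    unit_id: str
    primary: bool = False   # carries the unit's presence/shape/placement credit
    ambiguous: bool = False


@dataclasses.dataclass(frozen=True)
class FigureUnit:
    id: str
    region: str             # "left" | "right" | "middle"
    scoring: str            # "presence_shape_placement" | "presence_shape_only"
    features: tuple[FigureFeature, ...]

    @property
    def primary_feature(self) -> FigureFeature:
        return next(f for f in self.features if f.primary)

    @property
    def max_points(self) -> int:
        return 2 if self.scoring == "presence_shape_only" else 3


@dataclasses.dataclass(frozen=True)
class FigureRegistry:
    units: tuple[FigureUnit, ...]

    @property
    def features(self) -> tuple[FigureFeature, ...]:
        return tuple(f for u in self.units for f in u.features)

    def feature(self, feature_id: str) -> FigureFeature:
        for f in self.features:
            if f.id == feature_id:
                return f
        raise KeyError(f"unknown figure feature: {feature_id!r}")

    def validate(self) -> None:
        units = self.units
        if len(units) != 16:
            raise ValueError(f"registry must hold 16 scoreable units, got {len(units)}")
        psp = [u for u in units if u.scoring == "presence_shape_placement"]
        pso = [u for u in units if u.scoring == "presence_shape_only"]
        if len(psp) != 15 or len(pso) != 1:
            raise ValueError(
                "registry must hold 15 presence/shape/placement units and 1 "
                f"presence/shape-only unit, got {len(psp)}/{len(pso)}"
            )
        feats = self.features
        ids = [f.id for f in feats]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate feature ids in registry")
        n_global = sum(1 for f in feats if f.level == "global")
        n_local = sum(1 for f in feats if f.level == "local")
        if n_global != MAX_GLOBAL or n_local != MAX_LOCAL:
            raise ValueError(
                f"registry features must split {MAX_GLOBAL} global / {MAX_LOCAL} "
                f"local, got {n_global}/{n_local}"
            )
        for u in units:
            if sum(1 for f in u.features if f.primary) != 1:
                raise ValueError(f"unit {u.id!r} must have exactly one primary feature")
        max_total = sum(u.max_points for u in units)
        if max_total != MAX_TOTAL:
            raise ValueError(f"registry maximum must be {MAX_TOTAL}, got {max_total}")


def load_registry(path: str | Path | None = None) -> FigureRegistry:
    """Load and validate the figure registry (packaged default if no path)."""
    if path is None:
        text = (resources.files("hodomap") / "data" / "figure_registry.yaml").read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    units = []
    for u in raw["units"]:
        features = tuple(
            FigureFeature(
                id=f["id"],
                level=f["level"],
                unit_id=u["id"],
                primary=bool(f.get("primary", False)),
                ambiguous=bool(f.get("ambiguous", False)),
            )
            for f in u["features"]
        )
        units.append(
            FigureUnit(id=u["id"], region=u["region"], scoring=u["scoring"], features=features)
        )
    registry = FigureRegistry(tuple(units))
    registry.validate()
    return registry


_DEFAULT_REGISTRY: FigureRegistry | None = None


def default_registry() -> FigureRegistry:
    global _DEFAULT_REGISTRY
    if _DEFAULT_REGISTRY is None:
        _DEFAULT_REGISTRY = load_registry()
    return _DEFAULT_REGISTRY


@dataclasses.dataclass(frozen=True)
class FeatureMark:
    present: bool
    shape_correct: bool = False
    placement_correct: bool = False

    def __post_init__(self) -> None:
        if (self.shape_correct or self.placement_correct) and not self.present:
            raise ValueError("shape/placement credit requires the feature to be present")


class DrawingRecord:
    """One patient's copy of the figure, as presence/shape/placement marks.

    Holds one :class:`FeatureMark` per registry feature (20 entries).  Every
    feature id must appear exactly once; shape or placement credit without
    presence is rejected at construction.
    """

    def __init__(
        self,
        marks: Mapping[str, FeatureMark],
        registry: FigureRegistry | None = None,
    ) -> None:
        registry = registry or default_registry()
        expected = {f.id for f in registry.features}
        got = set(marks)
        if got != expected:
            missing = sorted(expected - got)
            unknown = sorted(got - expected)
            parts = []
            if missing:
                parts.append(f"missing features: {missing}")
            if unknown:
                parts.append(f"unknown features: {unknown}")
            raise ValueError("invalid drawing record: " + "; ".join(parts))
        self.registry = registry
        self.marks = dict(marks)

    def mark(self, feature_id: str) -> FeatureMark:
        return self.marks[feature_id]


def total_score(rec: DrawingRecord) -> int:
    """Whole-figure score in [0, 47].

    Each unit's credit is read from its primary feature: presence, shape and
    (except for the middle square) placement, one point each.
    """
    score = 0
    for unit in rec.registry.units:
        m = rec.mark(unit.primary_feature.id)
        score += int(m.present) + int(m.shape_correct)
        if unit.scoring == "presence_shape_placement":
            score += int(m.placement_correct)
    return score


def global_score(rec: DrawingRecord) -> int:
    """Count of global features present (presence only; shape/placement ignored)."""
    return sum(
        1 for f in rec.registry.features if f.level == "global" and rec.mark(f.id).present
    )


def local_score(rec: DrawingRecord) -> int:
    """Count of local features present (presence only)."""
    return sum(
        1 for f in rec.registry.features if f.level == "local" and rec.mark(f.id).present
    )


def percent_scores(rec: DrawingRecord) -> tuple[float, float]:
    """(global %, local %) — scores rescaled to their unequal maxima."""
    return (
        100.0 * global_score(rec) / MAX_GLOBAL,
        100.0 * local_score(rec) / MAX_LOCAL,
    )


def perfect_record(registry: FigureRegistry | None = None) -> DrawingRecord:
    """Record with every feature present, shaped and placed correctly."""
    registry = registry or default_registry()
    marks = {
        f.id: FeatureMark(present=True, shape_correct=True, placement_correct=True)
        for f in registry.features
    }
    return DrawingRecord(marks, registry)


_BOOL = {"1": True, "0": False, "true": True, "false": False, "yes": True, "no": False}


def _parse_bool(value: object, column: str, feature: str) -> bool:
    if isinstance(value, (bool,)):
        return value
    if isinstance(value, (int, float)) and value in (0, 1):
        return bool(value)
    key = str(value).strip().lower()
    if key in _BOOL:
        return _BOOL[key]
    raise ValueError(f"cannot parse {column}={value!r} for feature {feature!r}")


def load_drawing_record(
    path: str | Path, registry: FigureRegistry | None = None
) -> DrawingRecord:
    """Load a drawing record from delimited text.

    One row per feature; columns ``feature_id``, ``present``, ``shape_correct``,
    ``placement_correct`` (tab- or comma-separated, header row required).
    """
    registry = registry or default_registry()
    df = pd.read_csv(path, sep=None, engine="python")
    required = {"feature_id", "present", "shape_correct", "placement_correct"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: record must have columns {sorted(required)}")
    marks: dict[str, FeatureMark] = {}
    for row in df.itertuples(index=False):
        fid = str(row.feature_id)
        if fid in marks:
            raise ValueError(f"{path}: duplicate feature row {fid!r}")
        marks[fid] = FeatureMark(
            present=_parse_bool(row.present, "present", fid),
            shape_correct=_parse_bool(row.shape_correct, "shape_correct", fid),
            placement_correct=_parse_bool(row.placement_correct, "placement_correct", fid),
        )
    return DrawingRecord(marks, registry)
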