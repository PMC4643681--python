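"""One-command orchestration of the full analysis.

``run_pipeline`` chains the stages in their natural order — simulate (or
ingest) a cohort, delineate lesions against the control sample, build the
disconnection table, run the track-wise regressions for both outcomes and
both covariate models, run the voxel-wise GLM for both contrasts — and
writes a unified, reproducible output bundle:

    lesions/*.nii.gz, disconnection_table.tsv, trackwise_results.tsv,
    clusters_global.tsv, clusters_local.tsv, report.json, pipeline.log

Everything stochastic draws from seeds derived from one top-level seed, so a
rerun with the same config is byte-identical (timestamps excluded).
"""

from __future__ import annotations

import difflib
import json
import logging
import time
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
import pydantic
import yaml

from . import disconnection, synthetic, trackwise, vbm
from .delineation import DelineationSettings, delineate, fit_control_reference
from .volumes import MaskVolume, ScalarVolume, gaussian_smooth, read_volume, write_volume

__all__ = [
    "PipelineConfig",
    "ConfigError",
    "validate_config",
    "run_pipeline",
]

logger = logging.getLogger("hodomap.pipeline")


class ConfigError(ValueError):
    """Configuration schema violation, with key paths and typo suggestions."""


class _Model(pydantic.BaseModel):
    model_config = pydantic.ConfigDict(extra="forbid")


class SimulateSettings(_Model):
    n_controls: int = pydantic.Field(default=20, ge=2)
    n_patients: int = pydantic.Field(default=60, ge=1)
    noise_sd: float = pydantic.Field(default=5.0, ge=0.0)
    effect_fraction: float = pydantic.Field(default=0.5, ge=0.0, le=1.0)
    lesion_intensity_drop: float = pydantic.Field(default=20.0, gt=0.0)


class IngestSettings(_Model):
    lesions_dir: Optional[str] = None
    patients_dir: Optional[str] = None
    controls_dir: Optional[str] = None
    atlas_manifest: Optional[str] = None
    behaviour_tsv: Optional[str] = None


class DelineationConfig(_Model):
    t_threshold: float | Literal["auto"] = "auto"
    auto_p: float = pydantic.Field(default=0.01, gt=0.0, lt=1.0)
    tail: Literal["hypointense", "hyperintense", "two_sided"] = "hypointense"
    min_cluster_voxels: int = pydantic.Field(default=0, ge=0)


class TrackwiseConfig(_Model):
    family_alpha: float = pydantic.Field(default=0.05, gt=0.0, lt=1.0)
    n_tests: int = pydantic.Field(default=16, ge=1)
    include_vf: bool = True
    tract_threshold: float = pydantic.Field(default=0.5, gt=0.0, lt=1.0)


class GlmConfig(_Model):
    fwhm_mm: float = pydantic.Field(default=12.0, gt=0.0)
    voxel_p: float = pydantic.Field(default=0.001, gt=0.0, lt=1.0)
    extent_mm3: float = pydantic.Field(default=800.0, ge=0.0)
    connectivity: Literal[6, 18, 26] = 26
    n_perm: int = pydantic.Field(default=200, ge=100)


class PipelineConfig(_Model):
    mode: Literal["simulate", "ingest"] = "simulate"
    seed: int = 0
    log_level: str = "INFO"
    simulate: SimulateSettings = SimulateSettings()
    ingest: IngestSettings = IngestSettings()
    delineation: DelineationConfig = DelineationConfig()
    trackwise: TrackwiseConfig = TrackwiseConfig()
    glm: GlmConfig = GlmConfig()


def _suggest(unknown_key: str, valid: list[str]) -> str:
    match = difflib.get_close_matches(unknown_key, valid, n=1)
    return f" (did you mean {match[0]!r}?)" if match else ""


_VALID_KEYS = {
    "": list(PipelineConfig.model_fields),
    "simulate": list(SimulateSettings.model_fields),
    "ingest": list(IngestSettings.model_fields),
    "delineation": list(DelineationConfig.model_fields),
    "trackwise": list(TrackwiseConfig.model_fields),
    "glm": list(GlmConfig.model_fields),
}


def validate_config(path_or_mapping) -> PipelineConfig:
    """Parse, default and validate a pipeline config (YAML path or mapping).

    Unknown keys are rejected with a nearest-valid-key suggestion; other
    schema violations are reported with their full key path.
    """
    if isinstance(path_or_mapping, (str, Path)):
        raw = yaml.safe_load(Path(path_or_mapping).read_text()) or {}
    else:
        raw = dict(path_or_mapping)
    try:
        config = PipelineConfig.model_validate(raw)
    except pydantic.ValidationError as err:
        messages = []
        for e in err.errors():
            loc = ".".join(str(p) for p in e["loc"])
            if e["type"] == "extra_forbidden":
                section = ".".join(str(p) for p in e["loc"][:-1])
                key = str(e["loc"][-1])
                hint = _suggest(key, _VALID_KEYS.get(section, []))
                messages.append(f"unknown key {loc!r}{hint}")
            else:
                messages.append(f"{loc}: {e['msg']}")
        raise ConfigError("; ".join(messages)) from None
    if config.mode == "ingest":
        ing = config.ingest
        required = {
            "lesions_dir": ing.lesions_dir,
            "atlas_manifest": ing.atlas_manifest,
            "behaviour_tsv": ing.behaviour_tsv,
        }
        for key, value in required.items():
            if value is None:
                raise ConfigError(f"ingest mode requires ingest.{key}")
            if not Path(value).exists():
                raise ConfigError(f"ingest.{key}: path does not exist: {value}")
    return config


def _derive_seed(seed: int, stage: int) -> int:
    return int(np.random.SeedSequence([seed & 0x7FFFFFFF, stage]).generate_state(1)[0] % (2**31))


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Run every stage and write the report bundle; returns report dict."""
    t0 = time.time()
    out = Path(out_dir)
    (out / "lesions").mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "pipeline.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(config.log_level.upper())
    report: dict = {"settings": config.model_dump(), "stages": {}}
    try:
        # ---- stage 1: cohort -------------------------------------------------
        if config.mode == "simulate":
            sim = config.simulate
            spec = synthetic.default_cohort_spec(
                seed=_derive_seed(config.seed, 1),
                n_controls=sim.n_controls,
                n_patients=sim.n_patients,
                noise_sd=sim.noise_sd,
                effect_fraction=sim.effect_fraction,
                lesion_intensity_drop=sim.lesion_intensity_drop,
                tract_threshold=config.trackwise.tract_threshold,
            )
            dataset = synthetic.generate_cohort(spec)
            controls = dataset.controls
            patients = dict(zip(dataset.patient_ids, dataset.patients))
            atlas = dataset.atlas
            behaviour = dataset.behaviour
            logger.info(
                "simulated cohort: %d controls, %d patients, %d tract maps",
                len(controls), len(patients), len(atlas.entries),
            )
        else:
            ing = config.ingest
            atlas = disconnection.load_atlas(ing.atlas_manifest)
            behaviour = pd.read_csv(ing.behaviour_tsv, sep="\t")
            patients = {}
            controls = []
            if ing.patients_dir and ing.controls_dir:
                for p in sorted(Path(ing.patients_dir).glob("*.nii*")):
                    stem = p.name.removesuffix(".gz").removesuffix(".nii")
                    patients[stem] = read_volume(p)
                controls = [
                    read_volume(p) for p in sorted(Path(ing.controls_dir).glob("*.nii*"))
                ]
            logger.info("ingested cohort: %d tract maps", len(atlas.entries))
        report["stages"]["cohort"] = {
            "mode": config.mode,
            "n_patients": len(patients) if patients else None,
        }

        # ---- stage 2: lesion delineation ------------------------------------
        lesions: dict[str, MaskVolume]
        if patients and controls:
            ref = fit_control_reference(controls)
            settings = DelineationSettings(
                t_threshold=config.delineation.t_threshold,
                auto_p=config.delineation.auto_p,
                tail=config.delineation.tail,
                min_cluster_voxels=config.delineation.min_cluster_voxels,
            )
            lesions = {}
            reports = {}
            for pid, img in patients.items():
                mask, rep = delineate(img, ref, settings)
                lesions[pid] = mask
                reports[pid] = rep.to_dict()
                write_volume(mask, out / "lesions" / f"{pid}.nii.gz")
            report["stages"]["delineation"] = {
                "n_delineated": len(lesions),
                "t_threshold": reports[next(iter(reports))]["t_threshold"],
                "df": ref.n - 1,
            }
            logger.info("delineated %d lesions", len(lesions))
        else:
            lesions = disconnection.load_lesion_directory(config.ingest.lesions_dir)
            report["stages"]["delineation"] = {
                "n_delineated": 0,
                "n_precomputed": len(lesions),
            }
            logger.info("loaded %d precomputed lesion masks", len(lesions))

        # ---- stage 3: disconnection table -----------------------------------
        table = disconnection.build_disconnection_table(
            lesions, atlas, behaviour, threshold=config.trackwise.tract_threshold
        )
        table.to_tsv(out / "disconnection_table.tsv")
        pct = disconnection.percent_disconnected(table)
        pct.rename_axis("tract").reset_index().to_csv(
            out / "percent_disconnected.tsv", sep="\t", index=False
        )
        overlap_map = disconnection.group_lesion_overlap(list(lesions.values()))
        write_volume(overlap_map, out / "lesion_overlap_map.nii.gz")
        report["stages"]["disconnection"] = {
            "n_rows": len(table.data),
            "n_tracts": len(table.tract_columns),
        }

        # ---- stage 4: track-wise regressions --------------------------------
        alpha = trackwise.bonferroni_alpha(
            config.trackwise.n_tests, config.trackwise.family_alpha
        )
        all_results = []
        for outcome in ("global_pct", "local_pct"):
            for include_vf in ([False, True] if config.trackwise.include_vf else [False]):
                res = trackwise.run_trackwise_analysis(
                    table, outcome, include_vf=include_vf
                )
                all_results.extend(trackwise.flag_significant(res, alpha))
        results_frame = trackwise.results_to_frame(all_results)
        results_frame.to_csv(out / "trackwise_results.tsv", sep="\t", index=False)
        n_skipped = int(results_frame["skipped"].sum())
        report["stages"]["trackwise"] = {
            "corrected_alpha": alpha,
            "n_models": len(results_frame),
            "n_skipped": n_skipped,
            "n_significant": int(results_frame["significant"].fillna(False).sum()),
        }
        logger.info(
            "trackwise: %d models (%d skipped), alpha=%.6f",
            len(results_frame), n_skipped, alpha,
        )

        # ---- stage 5: voxel-wise GLM ----------------------------------------
        # lesion-density images: smoothed binary lesion maps
        ids = sorted(lesions)
        images = [
            gaussian_smooth(
                ScalarVolume(lesions[i].grid, lesions[i].values.astype(float)),
                config.glm.fwhm_mm,
            )
            for i in ids
        ]
        merged = table.data.set_index("patient_id").loc[ids].reset_index()
        design = vbm.build_design_matrix(merged)
        for outcome in ("global_pct", "local_pct"):
            # deficit direction: more lesion density where the score is lower
            contrast = design.contrast_for(outcome, sign=-1.0)
            clusters = vbm.permutation_cluster_p(
                images,
                design,
                contrast,
                n_perm=config.glm.n_perm,
                seed=_derive_seed(config.seed, 5),
                voxel_p=config.glm.voxel_p,
                extent_mm3=config.glm.extent_mm3,
                connectivity=config.glm.connectivity,
            )
            frame = vbm.clusters_to_frame(clusters)
            name = "clusters_global.tsv" if outcome == "global_pct" else "clusters_local.tsv"
            frame.to_csv(out / name, sep="\t", index=False)
            report["stages"].setdefault("glm", {})[outcome] = {
                "n_clusters": len(clusters),
                "min_cluster_p": min((c.cluster_p for c in clusters), default=None),
            }
        report["runtime_s"] = round(time.time() - t0, 2)
        report["seed"] = config.seed
        (out / "report.json").write_text(json.dumps(report, indent=2))
        logger.info("pipeline complete in %.1fs", report["runtime_s"])
        return report
    except Exception as err:  # annotate the failing stage before propagating
        done = list(report["stages"])
        logger.error("pipeline failed after stages %s: %s", done, err)
        raise
    finally:
        logger.removeHandler(handler)
        handler.close()
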