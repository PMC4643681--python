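"""Canned simulation studies: calibration and recovery checks.

Each function runs one self-contained simulation study against the package's
own machinery and returns plain numbers.  They are the substance behind the
numbered analysis drivers and the reproducibility script, and double as the
integration-level checks of the test suite:

* lesion recovery — can the Crawford–Howell delineation find a known
  ellipsoid lesion, and does it stay quiet on lesion-free patients?
* track-wise recovery — does the per-tract regression find the designated
  lateralized effects and nothing in the crossed hemisphere/outcome cells?
* null calibration — is the per-tract type-I error at the Bonferroni level
  what it claims to be?
* permutation GLM — are cluster-level p-values valid under the null, and
  does a strongly planted effect survive correction?

Study sizes are chosen for desk-scale runtimes (a few tens of seconds each);
every study is deterministic given its seed.
"""

from __future__ import annotations

import numpy as np

from . import disconnection, trackwise
from .delineation import (
    DelineationSettings,
    binarize_lesion,
    delineate,
    dice_coefficient,
    fit_control_reference,
    t_map,
)
from .synthetic import (
    DEFAULT_GLOBAL_WEIGHTS,
    DEFAULT_LOCAL_WEIGHTS,
    default_cohort_spec,
    default_tracts,
    make_baseline,
    make_null_table,
    make_patient_volume,
)
from .vbm import DesignMatrix, permutation_cluster_p
from .volumes import ScalarVolume, VolumeGrid

__all__ = [
    "lesion_recovery_study",
    "trackwise_recovery_study",
    "trackwise_null_calibration",
    "permutation_null_study",
    "permutation_planted_study",
]

#: Designated effect tracts of the default cohort and the outcome each drives.
DESIGNATED = {
    "inferior_fronto_occipital_fasciculus_left": "local_pct",
    "slf_iii_right": "global_pct",
    "perisylvian_long_segment_right": "global_pct",
}


def lesion_recovery_study(seed: int = 0) -> dict:
    """Single-case delineation under strong contrast, plus null specificity.

    A 10-control-sd hypointense ellipsoid is inserted into one patient
    (control noise sd 1, 20 controls); recovery is scored as Dice against
    the ground-truth mask, delineating at the default one-tailed p=.01
    threshold with the small-component filter (10 voxels) enabled.  A second,
    lesion-free patient measures the raw two-sided false-positive rate at
    the |t| = t(.005, df) threshold with no cleanup.
    """
    grid = VolumeGrid((32, 32, 32), (2.0, 2.0, 2.0), (-32.0, -32.0, -32.0))
    base = make_baseline(grid, seed)
    rng = np.random.default_rng([seed & 0x7FFFFFFF, 101])
    noise_sd = 1.0
    controls = [
        ScalarVolume(grid, base.values + noise_sd * rng.standard_normal(grid.shape))
        for _ in range(20)
    ]
    ref = fit_control_reference(controls)

    noisy = ScalarVolume(grid, base.values + noise_sd * rng.standard_normal(grid.shape))
    patient, truth = make_patient_volume(
        noisy, (12.0, 2.0, -6.0), (9.0, 12.0, 8.0), 10.0 * noise_sd
    )
    mask, report = delineate(patient, ref, DelineationSettings(min_cluster_voxels=10))
    dice = dice_coefficient(mask, truth)

    null_patient = ScalarVolume(
        grid, base.values + noise_sd * rng.standard_normal(grid.shape)
    )
    tmap, _ = t_map(null_patient, ref)
    from scipy import stats

    t_crit = float(stats.t.ppf(1.0 - 0.005, ref.n - 1))
    null_mask = binarize_lesion(tmap, t_crit, tail="two_sided")
    n_voxels = int(np.prod(grid.shape))
    return {
        "dice": float(dice),
        "lesion_volume_cc": report.lesion_volume_cc,
        "null_suprathreshold_fraction": null_mask.n_voxels / n_voxels,
        "n_voxels": n_voxels,
        "df": report.df,
    }


def _fit_cohort(seed: int, n_patients: int = 60, noise_sd: float = 5.0):
    """One asymmetric cohort -> flagged track-wise results for both outcomes."""
    from .synthetic import generate_cohort

    spec = default_cohort_spec(seed=seed, n_patients=n_patients, noise_sd=noise_sd)
    ds = generate_cohort(spec, include_images=False)
    table = disconnection.build_disconnection_table(
        dict(zip(ds.patient_ids, ds.true_lesions)),
        ds.atlas,
        ds.behaviour,
        threshold=spec.tract_threshold,
    )
    alpha = trackwise.bonferroni_alpha(16, 0.05)
    out = {}
    for outcome in ("global_pct", "local_pct"):
        results = trackwise.run_trackwise_analysis(table, outcome)
        out[outcome] = trackwise.flag_significant(results, alpha)
    return out


def trackwise_recovery_study(n_reps: int = 50, seed: int = 0) -> dict:
    """Seeded replicates of the lateralized-dissociation cohort.

    Counts, per designated tract, the fraction of replicates in which it is
    Bonferroni-significant for its own outcome; also counts crossed flags
    (left tracts significant for the global score, right tracts for the
    local score), which should stay at chance level.
    """
    hits = {col: 0 for col in DESIGNATED}
    cross_flags = 0
    cross_tests = 0
    for rep in range(n_reps):
        flagged = _fit_cohort(seed=int(seed) + 1000 + rep)
        for outcome, results in flagged.items():
            for r in results:
                if r.tract in DESIGNATED and DESIGNATED[r.tract] == outcome:
                    hits[r.tract] += int(bool(r.significant))
                crossed = (r.hemisphere == "left") == (outcome == "global_pct")
                if crossed:
                    cross_tests += 1
                    cross_flags += int(bool(r.significant))
    return {
        "n_reps": n_reps,
        "recovery_rate": {col: hits[col] / n_reps for col in hits},
        "min_recovery_rate": min(hits.values()) / n_reps,
        "cross_hemisphere_flags": cross_flags,
        "cross_hemisphere_tests": cross_tests,
        "cross_flag_rate": cross_flags / cross_tests if cross_tests else 0.0,
    }


def trackwise_null_calibration(n_cohorts: int = 200, seed: int = 0) -> dict:
    """Type-I error of the per-tract test on cohorts with no tract effect.

    Null tables keep the realistic nuisance structure (overlaps feed lesion
    volume; lesion volume and age feed the outcome) so the calibration
    exercises the covariate adjustment.  Returns the pooled rejection rate
    at the Bonferroni-corrected level across cohorts, tracts and outcomes.
    """
    tracts = default_tracts()
    columns = [t.column for t in tracts]
    hemis = {t.column: t.hemisphere for t in tracts}
    alpha = trackwise.bonferroni_alpha(16, 0.05)
    n_tests = 0
    n_rejections = 0
    for rep in range(n_cohorts):
        data = make_null_table(60, columns, hemis, seed=int(seed) + 5000 + rep)
        table = disconnection.DisconnectionTable(data, columns, hemis)
        for outcome in ("global_pct", "local_pct"):
            results = trackwise.run_trackwise_analysis(table, outcome)
            for r in trackwise.flag_significant(results, alpha):
                if not r.skipped:
                    n_tests += 1
                    n_rejections += int(bool(r.significant))
    return {
        "n_cohorts": n_cohorts,
        "alpha": alpha,
        "n_tests": n_tests,
        "n_rejections": n_rejections,
        "rejection_rate": n_rejections / n_tests if n_tests else 0.0,
    }


def _noise_images(grid: VolumeGrid, n: int, rng: np.random.Generator):
    return [ScalarVolume(grid, rng.standard_normal(grid.shape)) for _ in range(n)]


def permutation_null_study(
    n_reps: int = 20, seed: int = 0, alpha: float = 0.2, n_perm: int = 100
) -> dict:
    """Validity of permutation cluster p-values under a global null.

    Pure-noise images, a lenient cluster-forming threshold and no extent
    gate, so null clusters actually form and receive p-values; counts the
    replicates whose smallest cluster p falls below ``alpha``.  Validity of
    the max-statistic correction demands that rate stay at or below alpha.
    """
    grid = VolumeGrid((12, 12, 12), (2.0, 2.0, 2.0), (-12.0, -12.0, -12.0))
    n = 30
    n_below = 0
    for rep in range(n_reps):
        rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, 300 + rep])
        x = rng.standard_normal(n)
        design = DesignMatrix(np.column_stack([np.ones(n), x]), ["intercept", "x"])
        images = _noise_images(grid, n, rng)
        clusters = permutation_cluster_p(
            images,
            design,
            design.contrast_for("x"),
            n_perm=n_perm,
            seed=int(seed) + rep,
            voxel_p=0.01,
            extent_mm3=0.0,
        )
        min_p = min((c.cluster_p for c in clusters), default=1.0)
        n_below += int(min_p <= alpha)
    return {
        "n_reps": n_reps,
        "alpha": alpha,
        "n_rejections": n_below,
        "rejection_rate": n_below / n_reps,
    }


def permutation_planted_study(seed: int = 0, n_perm: int = 200) -> dict:
    """Corrected p of a strongly planted effect (effect sd = 3x noise sd, n=40)."""
    grid = VolumeGrid((16, 16, 16), (2.0, 2.0, 2.0), (-16.0, -16.0, -16.0))
    n = 40
    rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, 400])
    x = rng.standard_normal(n)
    design = DesignMatrix(np.column_stack([np.ones(n), x]), ["intercept", "x"])
    blob = np.zeros(grid.shape, bool)
    blob[5:11, 5:11, 5:11] = True  # 216 voxels = 1728 mm3
    b = 3.0 / float(np.std(x))
    images = []
    for xi in x:
        vals = rng.standard_normal(grid.shape)
        vals[blob] += b * xi
        images.append(ScalarVolume(grid, vals))
    clusters = permutation_cluster_p(
        images, design, design.contrast_for("x"), n_perm=n_perm, seed=int(seed) + 1
    )
    if not clusters:
        return {"planted_cluster_p": 1.0, "planted_cluster_voxels": 0, "n_perm": n_perm}
    biggest = clusters[0]
    return {
        "planted_cluster_p": float(biggest.cluster_p),
        "planted_cluster_voxels": biggest.size_voxels,
        "n_perm": n_perm,
    }
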