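"""Synthetic cohort generator: determinism, geometry, the behavioural model."""

import numpy as np
import pandas as pd
import pytest

from hodomap import disconnection
from hodomap.synthetic import (
    CohortSpec,
    CovariateModel,
    TractSpec,
    default_cohort_spec,
    default_grid,
    default_tracts,
    generate_cohort,
    make_behaviour,
    make_control_volume,
    make_patient_volume,
    make_tract_map,
    write_cohort,
)
from hodomap.volumes import VolumeGrid, volume_cc


@pytest.fixture(scope="module")
def tiny_spec():
    return default_cohort_spec(seed=3, n_controls=4, n_patients=6)


@pytest.fixture(scope="module")
def tiny_cohort(tiny_spec):
    return generate_cohort(tiny_spec)


class TestControlVolume:
    def test_deterministic_and_seed_sensitive(self, grid2mm):
        a = make_control_volume(grid2mm, 11)
        b = make_control_volume(grid2mm, 11)
        c = make_control_volume(grid2mm, 12)
        np.testing.assert_array_equal(a.values, b.values)
        assert np.any(a.values != c.values)

    def test_positive_with_plausible_scale(self, grid2mm):
        vol = make_control_volume(grid2mm, 4)
        assert np.all(vol.values > 0)
        assert 80 < vol.values.mean() < 120


class TestTractMap:
    def test_centerline_voxel_attains_peak(self):
        grid = VolumeGrid((21, 21, 21), (2.0, 2.0, 2.0), (-20.0, -20.0, -20.0))
        spec = TractSpec(
            "t", "left", centerline=((-10.0, -16.0, 0.0), (-10.0, 16.0, 0.0)),
            radius_mm=8.0, peak_probability=0.9,
        )
        vol = make_tract_map(spec, grid)
        # voxel at (-10, 0, 0) lies exactly on the centerline
        idx = (5, 10, 10)
        assert vol.values[idx] == pytest.approx(0.9, abs=1e-9)
        assert vol.values.max() <= 0.9 + 1e-12

    def test_distant_voxels_decay_to_nothing(self):
        grid = VolumeGrid((31, 31, 31), (2.0, 2.0, 2.0), (-30.0, -30.0, -30.0))
        spec = TractSpec(
            "t", "left", centerline=((-20.0, -20.0, -20.0), (-20.0, 20.0, -20.0)),
            radius_mm=4.0,
        )
        vol = make_tract_map(spec, grid)
        assert vol.values[30, 15, 30] < 1e-6  # ~70 mm away

    def test_thresholded_core_is_a_tube(self):
        grid = VolumeGrid((21, 21, 21), (2.0, 2.0, 2.0), (-20.0, -20.0, -20.0))
        spec = TractSpec(
            "t", "left", centerline=((0.0, -16.0, 0.0), (0.0, 16.0, 0.0)),
            radius_mm=8.0, peak_probability=0.9,
        )
        core = disconnection.threshold_tract(make_tract_map(spec, grid), 0.5)
        assert core.n_voxels > 0
        # analytic core radius: d <= (r/2) sqrt(2 ln(0.9/0.5)) ~ 4.34 mm
        x, y, z = grid.world_coordinates()
        d = np.sqrt(x**2 + 0 * y + z**2)
        d_core = np.broadcast_to(d, grid.shape)[core.values]
        assert d_core.max() <= (spec.radius_mm / 2) * np.sqrt(2 * np.log(0.9 / 0.5)) + 1e-9

    def test_centerline_outside_grid_rejected(self, grid2mm):
        spec = TractSpec("t", "left", centerline=((0.0, 0.0, 0.0), (500.0, 0.0, 0.0)))
        with pytest.raises(ValueError, match="bounding box"):
            make_tract_map(spec, grid2mm)


@pytest.fixture(scope="module")
def baseline():
    grid = VolumeGrid((30, 30, 30), (2.0, 2.0, 2.0), (-30.0, -30.0, -30.0))
    return make_control_volume(grid, 2)


class TestPatientVolume:
    def test_zero_drop_leaves_image_untouched(self, baseline):
        img, mask = make_patient_volume(baseline, (0, 0, 0), (8, 8, 8), 0.0)
        np.testing.assert_array_equal(img.values, baseline.values)
        assert mask.n_voxels > 0

    def test_mask_volume_matches_analytic_ellipsoid(self, baseline):
        a, b, c = 9.0, 12.0, 7.0
        _, mask = make_patient_volume(baseline, (0, 0, 0), (a, b, c), 5.0)
        analytic_cc = 4.0 / 3.0 * np.pi * a * b * c / 1000.0
        # voxelization error bound: one voxel layer over the ellipsoid surface
        surface_cc = 4.0 * np.pi * ((a * b * c) ** (2 / 3)) * 2.0 / 1000.0
        assert abs(volume_cc(mask) - analytic_cc) < surface_cc

    def test_lesioned_voxels_drop_by_exactly_the_contrast(self, baseline):
        drop = 7.5
        img, mask = make_patient_volume(baseline, (4, -6, 2), (8, 9, 10), drop)
        np.testing.assert_allclose(
            img.values[mask.values], baseline.values[mask.values] - drop
        )
        np.testing.assert_array_equal(
            img.values[~mask.values], baseline.values[~mask.values]
        )

    def test_disjoint_ellipsoid_rejected(self, baseline):
        with pytest.raises(ValueError, match="intersect"):
            make_patient_volume(baseline, (500.0, 500.0, 500.0), (5, 5, 5), 1.0)


class TestBehaviouralModel:
    def _spec(self, **kw):
        defaults = dict(
            grid=default_grid(),
            n_controls=2,
            n_patients=3,
            tracts=default_tracts(),
            global_weights={},
            local_weights={},
            baseline_scores=(88.0, 86.0),
            noise_sd=0.0,
            covariates=CovariateModel(lesion_volume_coef=0.0, age_coef=0.0),
            seed=21,
        )
        defaults.update(kw)
        return CohortSpec(**defaults)

    def _truth(self, spec, values=0.0):
        cols = [t.column for t in spec.tracts]
        data = np.full((spec.n_patients, len(cols)), float(values))
        return pd.DataFrame(
            data, columns=cols, index=pd.Index([f"p{i}" for i in range(spec.n_patients)]),
        )

    def test_no_noise_no_effects_gives_baseline(self):
        spec = self._spec()
        behaviour = make_behaviour(self._truth(spec), [0.0] * 3, spec)
        assert (behaviour["global_pct"] == 88.0).all()
        assert (behaviour["local_pct"] == 86.0).all()

    def test_single_weighted_tract_subtracts_linearly(self):
        col = "slf_iii_right"
        spec = self._spec(global_weights={col: 5.0})
        truth = self._truth(spec)
        truth[col] = 2.0
        behaviour = make_behaviour(truth, [0.0] * 3, spec)
        assert (behaviour["global_pct"] == 78.0).all()   # 88 - 5*2
        assert (behaviour["local_pct"] == 86.0).all()    # local untouched

    def test_effect_monotone_until_clipped(self):
        col = "slf_iii_right"
        spec = self._spec(global_weights={col: 10.0})
        scores = []
        for disc in (0.0, 2.0, 5.0, 8.0, 20.0):
            truth = self._truth(spec)
            truth[col] = disc
            scores.append(make_behaviour(truth, [0.0] * 3, spec)["global_pct"].iloc[0])
        assert scores == sorted(scores, reverse=True)
        assert scores[-1] == 0.0  # clipped at the floor

    def test_scores_always_within_bounds(self):
        spec = self._spec(noise_sd=50.0)
        behaviour = make_behaviour(self._truth(spec), [0.0] * 3, spec)
        assert behaviour["global_pct"].between(0, 100).all()
        assert behaviour["local_pct"].between(0, 100).all()

    def test_unknown_weight_key_rejected(self):
        with pytest.raises(ValueError, match="unknown tract"):
            self._spec(global_weights={"no_such_tract": 1.0})


class TestGenerateCohort:
    def test_cardinalities(self, tiny_spec, tiny_cohort):
        ds = tiny_cohort
        assert len(ds.patients) == tiny_spec.n_patients
        assert len(ds.true_lesions) == tiny_spec.n_patients
        assert len(ds.behaviour) == tiny_spec.n_patients
        assert len(ds.controls) == tiny_spec.n_controls
        assert len(ds.atlas.entries) == len(tiny_spec.tracts)

    def test_reproducible_from_seed(self, tiny_spec, tiny_cohort):
        again = generate_cohort(tiny_spec)
        assert tiny_cohort.behaviour.to_csv() == again.behaviour.to_csv()
        np.testing.assert_array_equal(
            tiny_cohort.patients[0].values, again.patients[0].values
        )

    def test_truth_consistent_with_measured_overlap(self, tiny_spec, tiny_cohort):
        """Generator truth equals the disconnection module's own measurement."""
        ds = tiny_cohort
        table = disconnection.build_disconnection_table(
            dict(zip(ds.patient_ids, ds.true_lesions)),
            ds.atlas,
            ds.behaviour,
            threshold=tiny_spec.tract_threshold,
        )
        for col in ds.truth.columns:
            np.testing.assert_array_equal(
                table.data[col].to_numpy(), ds.truth[col].to_numpy()
            )

    def test_disjoint_tract_has_zero_truth(self, tiny_cohort):
        ds = tiny_cohort
        cores = {
            e.column: disconnection.threshold_tract(e.map, ds.spec.tract_threshold)
            for e in ds.atlas.entries
        }
        for i, lesion in enumerate(ds.true_lesions):
            for col, core in cores.items():
                if not np.any(lesion.values & core.values):
                    assert ds.truth.iloc[i][col] == 0.0

    def test_statistics_only_mode_skips_images(self, tiny_spec):
        ds = generate_cohort(tiny_spec, include_images=False)
        assert ds.patients == [] and ds.controls == []
        assert len(ds.true_lesions) == tiny_spec.n_patients


class TestCohortOnDisk:
    def test_write_cohort_layout_and_roundtrip(self, tmp_path, tiny_cohort):
        write_cohort(tiny_cohort, tmp_path / "cohort")
        root = tmp_path / "cohort"
        assert len(list((root / "patients").glob("*.nii.gz"))) == 6
        assert (root / "behaviour.tsv").exists()
        assert (root / "truth.json").exists()
        assert (root / "cohort_spec.yaml").exists()
        atlas = disconnection.load_atlas(root / "atlas_manifest.yaml")
        assert len(atlas.entries) == len(tiny_cohort.atlas.entries)
        behaviour = pd.read_csv(root / "behaviour.tsv", sep="\t")
        pd.testing.assert_frame_equal(
            behaviour, tiny_cohort.behaviour, check_exact=False, rtol=1e-12
        )
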