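"""Voxel-wise GLM: t-map oracle, cluster extraction, permutation correction."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from hodomap.vbm import (
    ClusterResult,
    DesignMatrix,
    build_design_matrix,
    clusters_to_frame,
    extract_clusters,
    fit_voxelwise_glm,
    permutation_cluster_p,
)
from hodomap.volumes import ScalarVolume, VolumeGrid


@pytest.fixture(scope="module")
def grid4():
    return VolumeGrid((4, 4, 4), (2.0, 2.0, 2.0), (-4.0, -4.0, -4.0))


def simple_design(n, seed=0, extra=1):
    rng = np.random.default_rng(seed)
    cols = [np.ones(n)] + [rng.standard_normal(n) for _ in range(extra)]
    names = ["intercept"] + [f"x{i}" for i in range(extra)]
    return DesignMatrix(np.column_stack(cols), names)


class TestDesignMatrix:
    def test_build_from_behaviour_table(self):
        rng = np.random.default_rng(0)
        n = 12
        behaviour = pd.DataFrame(
            {
                "global_pct": rng.uniform(40, 100, n),
                "local_pct": rng.uniform(40, 100, n),
                "age": rng.normal(72, 13, n),
                "sex": list(rng.choice(["M", "F"], n)),
                "handedness": list(rng.choice(["R", "L"], n)),
                "lesion_volume_cc": rng.uniform(1, 40, n),
            }
        )
        design = build_design_matrix(behaviour)
        assert design.n == n
        assert design.columns[0] == "intercept"
        np.testing.assert_array_equal(
            design.X[:, design.columns.index("sex")],
            (behaviour["sex"] == "M").astype(float),
        )

    def test_missing_column_and_bad_coding_rejected(self):
        base = {
            "global_pct": [1.0, 2, 3, 4],
            "local_pct": [1.0, 2, 3, 4],
            "age": [50.0, 60, 70, 80],
            "sex": ["M", "F", "M", "F"],
            "handedness": ["R", "R", "L", "R"],
            "lesion_volume_cc": [1.0, 2, 3, 4],
        }
        with pytest.raises(ValueError, match="missing design columns"):
            build_design_matrix(pd.DataFrame({k: v for k, v in base.items() if k != "age"}))
        bad = dict(base)
        bad["sex"] = ["male", "F", "M", "F"]
        with pytest.raises(ValueError, match="M/F"):
            build_design_matrix(pd.DataFrame(bad))

    def test_rank_deficiency_rejected(self):
        X = np.column_stack([np.ones(10), np.ones(10)])
        with pytest.raises(ValueError, match="rank"):
            DesignMatrix(X, ["a", "b"])


class TestTMap:
    def test_matches_per_voxel_statsmodels_loop(self, grid4):
        n = 15
        design = simple_design(n, seed=2, extra=2)
        rng = np.random.default_rng(5)
        images = [ScalarVolume(grid4, rng.standard_normal(grid4.shape)) for _ in range(n)]
        contrast = design.contrast_for("x0")
        tmap, n_deg = fit_voxelwise_glm(images, design, contrast)
        assert n_deg == 0
        Y = np.stack([im.values for im in images], axis=0)
        for idx in np.ndindex(grid4.shape):
            fit = sm.OLS(Y[(slice(None),) + idx], design.X).fit()
            expected = fit.tvalues[design.columns.index("x0")]
            assert tmap.values[idx] == pytest.approx(expected, abs=1e-8)

    def test_perfect_fit_gives_enormous_t(self, grid4):
        n = 12
        design = simple_design(n, seed=3)
        x = design.X[:, 1]
        images = [ScalarVolume(grid4, np.full(grid4.shape, 2.0 * xi)) for xi in x]
        tmap, _ = fit_voxelwise_glm(images, design, design.contrast_for("x0"))
        assert np.all(np.abs(tmap.values) > 1e6)

    def test_zero_and_malformed_contrasts_rejected(self, grid4):
        design = simple_design(8)
        images = [ScalarVolume(grid4, np.zeros(grid4.shape)) for _ in range(8)]
        with pytest.raises(ValueError, match="all zeros"):
            fit_voxelwise_glm(images, design, np.zeros(2))
        with pytest.raises(ValueError, match="incongruent"):
            fit_voxelwise_glm(images, design, np.array([1.0]))

    def test_image_count_must_match_design(self, grid4):
        design = simple_design(8)
        images = [ScalarVolume(grid4, np.zeros(grid4.shape)) for _ in range(7)]
        with pytest.raises(ValueError, match="images"):
            fit_voxelwise_glm(images, design, design.contrast_for("x0"))


class TestClusters:
    def _blob_tmap(self, n_blob_voxels):
        grid = VolumeGrid((12, 12, 12), (2.0, 2.0, 2.0), (-12.0, -12.0, -12.0))
        values = np.zeros(grid.shape)
        flat_idx = np.argwhere(np.ones(grid.shape, bool))
        # build a compact connected blob by taking the first voxels in a ball ordering
        center = np.array([5.5, 5.5, 5.5])
        order = np.argsort(((flat_idx - center) ** 2).sum(axis=1), kind="stable")
        for k in order[:n_blob_voxels]:
            values[tuple(flat_idx[k])] = 6.0
        return ScalarVolume(grid, values)

    def test_flat_map_has_no_clusters(self):
        grid = VolumeGrid((8, 8, 8), (2.0, 2.0, 2.0))
        assert extract_clusters(ScalarVolume(grid, np.zeros(grid.shape)), df=30) == []

    def test_blob_above_extent_threshold_is_reported(self):
        clusters = extract_clusters(self._blob_tmap(120), df=30, extent_mm3=800.0)
        assert len(clusters) == 1
        assert clusters[0].size_voxels == 120
        assert clusters[0].size_mm3 == pytest.approx(960.0)

    def test_blob_below_extent_threshold_is_dropped(self):
        assert extract_clusters(self._blob_tmap(90), df=30, extent_mm3=800.0) == []

    def test_hundred_voxels_on_2mm_grid_are_exactly_800_mm3(self):
        clusters = extract_clusters(self._blob_tmap(100), df=30, extent_mm3=800.0)
        assert len(clusters) == 1
        assert clusters[0].size_mm3 == 800.0

    def test_stricter_voxel_p_never_grows_clusters(self):
        rng = np.random.default_rng(8)
        grid = VolumeGrid((12, 12, 12), (2.0, 2.0, 2.0))
        tmap = ScalarVolume(grid, 3 * rng.standard_normal(grid.shape))
        sizes = []
        for p in (0.05, 0.01, 0.001):
            clusters = extract_clusters(tmap, df=30, voxel_p=p, extent_mm3=0.0)
            sizes.append(sum(c.size_voxels for c in clusters))
        assert sizes == sorted(sizes, reverse=True)

    def test_peak_is_reported_in_world_coordinates(self):
        grid = VolumeGrid((10, 10, 10), (2.0, 2.0, 2.0), (-10.0, -10.0, -10.0))
        values = np.zeros(grid.shape)
        values[4:7, 4:7, 4:7] = 5.0
        values[5, 5, 5] = 9.0
        clusters = extract_clusters(ScalarVolume(grid, values), df=30, extent_mm3=0.0)
        assert clusters[0].peak_stat == 9.0
        assert clusters[0].peak_world_mm == (0.0, 0.0, 0.0)

    @pytest.mark.parametrize("kwargs", [dict(df=0), dict(voxel_p=0.0), dict(connectivity=5)])
    def test_invalid_parameters(self, kwargs):
        grid = VolumeGrid((4, 4, 4), (2.0, 2.0, 2.0))
        tmap = ScalarVolume(grid, np.zeros(grid.shape))
        params = dict(df=30)
        params.update(kwargs)
        with pytest.raises(ValueError):
            extract_clusters(tmap, **params)


class TestPermutation:
    def _planted(self, n=24, seed=6):
        grid = VolumeGrid((10, 10, 10), (2.0, 2.0, 2.0), (-10.0, -10.0, -10.0))
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(n)
        design = DesignMatrix(np.column_stack([np.ones(n), x]), ["intercept", "x0"])
        blob = np.zeros(grid.shape, bool)
        blob[3:8, 3:8, 3:8] = True
        images = []
        b = 3.0 / np.std(x)
        for xi in x:
            vals = rng.standard_normal(grid.shape)
            vals[blob] += b * xi
            images.append(ScalarVolume(grid, vals))
        return images, design

    def test_deterministic_given_seed(self):
        images, design = self._planted()
        c1 = permutation_cluster_p(images, design, design.contrast_for("x0"), n_perm=100, seed=4)
        c2 = permutation_cluster_p(images, design, design.contrast_for("x0"), n_perm=100, seed=4)
        assert [c.cluster_p for c in c1] == [c.cluster_p for c in c2]

    def test_p_values_bounded_below_by_permutation_resolution(self):
        images, design = self._planted()
        clusters = permutation_cluster_p(
            images, design, design.contrast_for("x0"), n_perm=100, seed=1
        )
        assert clusters  # the planted blob survives
        for c in clusters:
            assert c.cluster_p >= 1.0 / 101.0

    def test_too_few_permutations_rejected(self):
        images, design = self._planted()
        with pytest.raises(ValueError, match="n_perm"):
            permutation_cluster_p(images, design, design.contrast_for("x0"), n_perm=50)

    def test_cluster_frame_schema(self):
        frame = clusters_to_frame(
            [ClusterResult(10, 80.0, (0.0, 2.0, -2.0), 4.5, cluster_p=0.02)]
        )
        assert list(frame.columns) == [
            "cluster_p", "size_voxels", "size_mm3", "peak_stat",
            "peak_x_mm", "peak_y_mm", "peak_z_mm",
        ]
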