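import numpy as np
import pytest

from scnmap import (
    CohortSpec,
    GMImage,
    build_interaction_design,
    compare_groups,
    extract_sphere_values,
    fit_voxelwise_glm,
    generate_cohort,
    group_correlations,
    split_mask_coronal,
)
from scnmap.errors import DegenerateDesignError, GeometryError

AFF = np.diag([2.0, 2.0, 2.0, 1.0])


def two_group_inputs(rng, n=6):
    seed = rng.normal(size=n)
    group = np.repeat([0.0, 1.0], n // 2)
    gender = rng.integers(0, 2, size=n).astype(float)
    return seed, group, gender


class TestInteractionDesign:
    def test_full_rank_five_columns(self, rng):
        seed, group, gender = two_group_inputs(rng)
        gender[:2] = [0, 1]  # ensure non-constant
        d = build_interaction_design(seed, group, gender)
        assert d.values.shape == (6, 5)
        assert np.linalg.matrix_rank(d.values) == 5
        assert d.contrast("interaction+")[4] == 1.0
        assert d.contrast("interaction-")[4] == -1.0

    def test_group_swap_negates_interaction_tmap(self, rng):
        n, shape = 16, (8, 8, 8)
        seed = rng.normal(size=n)
        group = np.repeat([0.0, 1.0], n // 2)
        gender = rng.integers(0, 2, size=n).astype(float)
        Y = rng.normal(size=(n, 512))
        imgs = [GMImage(y.reshape(shape), AFF, f"s{i}") for i, y in enumerate(Y)]
        t_ab = fit_voxelwise_glm(
            imgs, build_interaction_design(seed, group, gender), "interaction+"
        ).tmap
        t_ba = fit_voxelwise_glm(
            imgs, build_interaction_design(seed, 1.0 - group, gender), "interaction+"
        ).tmap
        assert np.allclose(t_ab, -t_ba, atol=1e-8)

    def test_interaction_t_invariant_to_seed_shift(self, rng):
        n, shape = 16, (8, 8, 8)
        seed = rng.normal(size=n)
        group = np.repeat([0.0, 1.0], n // 2)
        gender = rng.integers(0, 2, size=n).astype(float)
        Y = rng.normal(size=(n, 512))
        imgs = [GMImage(y.reshape(shape), AFF, f"s{i}") for i, y in enumerate(Y)]
        t0 = fit_voxelwise_glm(
            imgs, build_interaction_design(seed, group, gender), "interaction+"
        ).tmap
        t1 = fit_voxelwise_glm(
            imgs, build_interaction_design(seed + 7.3, group, gender), "interaction+"
        ).tmap
        assert np.allclose(t0, t1, atol=1e-7)

    def test_three_groups_rejected_with_pairwise_advice(self, rng):
        seed = rng.normal(size=9)
        group = np.repeat([0.0, 1.0, 2.0], 3)
        with pytest.raises(DegenerateDesignError, match="pairwise"):
            build_interaction_design(seed, group, np.zeros(9))

    def test_empty_group_rejected(self, rng):
        seed = rng.normal(size=6)
        with pytest.raises(DegenerateDesignError):
            build_interaction_design(seed, np.zeros(6), np.zeros(6))


class TestCompareGroups:
    def planted_cohort(self, rng_seed=7, lam=0.8, n=40):
        grid = (16, 20, 16)
        lam_old = np.zeros(grid)
        lam_old[2:7, 2:7, 2:7] = lam
        spec = CohortSpec(
            n_per_group=n,
            age_ranges=((18, 23), (61, 89)),
            group_labels=("young", "old"),
            female_fraction=(0.625, 0.6875),
            grid_shape=grid,
            coupling_map={"old": lam_old},
            rng_seed=rng_seed,
        )
        return generate_cohort(spec), lam_old > 0

    def test_planted_block_lands_in_young_lt_old_table(self):
        cohort, block = self.planted_cohort(n=80)
        anterior, _ = split_mask_coronal(cohort.hippo_label)
        gt, lt = compare_groups(
            cohort.images, cohort.subject_table(), anterior,
            group_pair=("young", "old"), n_perm=300, rng_seed=11,
        )
        assert gt.direction == "young>old" and lt.direction == "young<old"
        assert len(lt.clusters) >= 1
        top = lt.clusters[0]
        assert top.max_t > 0
        # peak voxel lies inside the planted block
        inv = np.linalg.inv(cohort.images[0].affine)
        idx = tuple(np.round(inv[:3, :3] @ np.array(top.peak_world_mm)
                             + inv[:3, 3]).astype(int))
        assert block[idx]

    def test_table_columns_match_report_convention(self):
        from scnmap import clusters_to_frame

        cohort, _ = self.planted_cohort(n=80)
        anterior, _ = split_mask_coronal(cohort.hippo_label)
        _, lt = compare_groups(cohort.images, cohort.subject_table(), anterior,
                               group_pair=("young", "old"), n_perm=300,
                               rng_seed=11)
        frame = clusters_to_frame(lt.clusters)
        assert list(frame.columns) == [
            "seed", "contrast", "x_mm", "y_mm", "z_mm", "k_voxels", "max_t"]

    def test_mismatched_lengths_rejected(self, small_cohort):
        table = small_cohort.subject_table().iloc[:-1]
        anterior, _ = split_mask_coronal(small_cohort.hippo_label)
        with pytest.raises(ValueError):
            compare_groups(small_cohort.images, table, anterior,
                           group_pair=("young", "old"), n_perm=100)


class TestSphereExtraction:
    def grid_images(self, rng, n=3, shape=(9, 9, 9)):
        return [GMImage(rng.normal(size=shape), AFF, f"s{i}") for i in range(n)]

    def test_zero_radius_returns_center_voxel(self, rng):
        imgs = self.grid_images(rng)
        center = AFF[:3, :3] @ np.array([4, 5, 6]) + AFF[:3, 3]
        vals = extract_sphere_values(imgs, center, radius_mm=0.0)
        for img, v in zip(imgs, vals):
            assert v == img.data[4, 5, 6]

    def test_membership_matches_exhaustive_distance_scan(self, rng):
        # 2-mm grid, 4-mm radius: count voxel centers within the closed ball
        imgs = self.grid_images(rng, n=1)
        center = np.array([0.0, 0.0, 0.0])  # voxel (0,0,0) world? shift to interior
        center = AFF[:3, :3] @ np.array([4, 4, 4]) + AFF[:3, 3]
        count = 0
        total = 0.0
        for i in range(9):
            for j in range(9):
                for k in range(9):
                    world = AFF[:3, :3] @ np.array([i, j, k]) + AFF[:3, 3]
                    if np.sum((world - center) ** 2) <= 16.0:
                        count += 1
                        total += imgs[0].data[i, j, k]
        assert count == 33  # exhaustive-scan oracle for r=4 on a 2-mm grid
        vals = extract_sphere_values(imgs, center, radius_mm=4.0)
        assert vals[0] == pytest.approx(total / count, abs=1e-12)

    def test_constant_image_mean_is_radius_independent(self):
        imgs = [GMImage(np.full((9, 9, 9), 0.4), AFF, "s0")]
        center = AFF[:3, :3] @ np.array([4, 4, 4]) + AFF[:3, 3]
        for r in (0.0, 2.0, 4.0, 8.0):
            assert extract_sphere_values(imgs, center, r)[0] == pytest.approx(0.4)

    def test_center_outside_grid_rejected(self, rng):
        imgs = self.grid_images(rng)
        with pytest.raises(GeometryError):
            extract_sphere_values(imgs, (500.0, 0.0, 0.0), 4.0)


class TestGroupCorrelations:
    def test_perfect_and_anti_correlation(self, rng):
        seed = rng.normal(size=8)
        labels = np.array(["a"] * 4 + ["b"] * 4)
        values = np.where(labels == "a", seed, -seed)
        out = group_correlations(values, seed, labels)
        assert out["a"] == pytest.approx(1.0)
        assert out["b"] == pytest.approx(-1.0)

    def test_zero_variance_flags_nan(self, rng):
        seed = rng.normal(size=6)
        out = group_correlations(np.zeros(6), seed, np.array(["a"] * 6))
        assert np.isnan(out["a"])

    def test_opposite_sign_coupling_recovered(self):
        """Planted negative coupling in the young group and positive in the
        old group shows up as opposite-sign within-group correlations near
        the analytic generating value lam*sd(s)/sd(voxel)."""
        grid = (16, 20, 16)
        # block kept clear of the hippocampus label (small y indices)
        lam_y = np.zeros(grid)
        lam_o = np.zeros(grid)
        lam_y[4:7, 0:3, 4:7] = -0.3
        lam_o[4:7, 0:3, 4:7] = 0.5
        spec = CohortSpec(
            n_per_group=80,
            age_ranges=((18, 23), (61, 89)),
            group_labels=("young", "old"),
            grid_shape=grid,
            coupling_map={"young": lam_y, "old": lam_o},
            rng_seed=21,
        )
        cohort = generate_cohort(spec)
        affine = cohort.images[0].affine
        center = affine[:3, :3] @ np.array([5, 1, 5]) + affine[:3, 3]
        vals = extract_sphere_values(cohort.images, center, radius_mm=2.0)
        seed = cohort.truth.s
        out = group_correlations(vals, seed, cohort.groups)
        for lab, lam in (("young", -0.3), ("old", 0.5)):
            sel = cohort.groups == lab
            gen_r = lam * np.std(seed[sel]) / np.std(vals[sel])
            assert abs(out[lab] - gen_r) < 0.15
            assert np.sign(out[lab]) == np.sign(lam)

    def test_small_group_rejected(self, rng):
        with pytest.raises(ValueError):
            group_correlations(rng.normal(size=4), rng.normal(size=4),
                               np.array(["a", "a", "b", "b"]))
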