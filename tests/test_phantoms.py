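"""Phantom generator: shape sampling, rasterization, labeling, distributions."""

import json

import numpy as np
import pytest
from scipy import ndimage, stats

import mcdn
from mcdn.phantoms import (
    OpticalProperties,
    ShapeSpec,
    compose_phantom,
    generate_dataset,
    quaternion_matrix,
    random_phantom,
    rasterize_convex_hull,
    rasterize_letter,
    rasterize_polyhedron,
    sample_optical_properties,
    sample_shape,
    sample_simulation_config,
)

IDENTITY_Q = (1.0, 0.0, 0.0, 0.0)


class TestSampleShape:
    def test_polyhedron_point_count_range(self, rng):
        for _ in range(200):
            spec = sample_shape(rng, (16, 16, 16), kind="polyhedron")
            assert 4 <= spec.n_points <= 10

    def test_deterministic_under_seed(self):
        s1 = sample_shape(np.random.default_rng(7), (16, 16, 16))
        s2 = sample_shape(np.random.default_rng(7), (16, 16, 16))
        assert s1 == s2

    def test_kind_split_is_even(self, rng):
        kinds = [sample_shape(rng, (16, 16, 16)).kind for _ in range(10_000)]
        frac = np.mean([k == "polyhedron" for k in kinds])
        assert 0.47 <= frac <= 0.53

    def test_degenerate_grid_rejected(self, rng):
        with pytest.raises(ValueError, match=">= 8"):
            sample_shape(rng, (16, 4, 16))


class TestRasterizePolyhedron:
    def test_tetrahedron_vertices_at_voxel_centers(self):
        verts = np.array([[2.5, 2.5, 2.5], [6.5, 2.5, 2.5],
                          [2.5, 6.5, 2.5], [2.5, 2.5, 6.5]])
        mask = rasterize_convex_hull(verts, (10, 10, 10), 1.0)
        for v in verts:
            assert mask[tuple((v - 0.5).astype(int))]

    def test_cube_hull_matches_halfspace_oracle(self):
        # independent oracle: point-in-hull via the hull's facet inequalities
        from scipy.spatial import ConvexHull

        rng = np.random.default_rng(5)
        verts = rng.uniform(1.5, 7.5, size=(8, 3))
        grid_shape, vs = (10, 10, 10), 1.0
        mask = rasterize_convex_hull(verts, grid_shape, vs)
        hull = ConvexHull(verts)
        centers = (np.indices(grid_shape).reshape(3, -1).T + 0.5) * vs
        inside = np.all(
            centers @ hull.equations[:, :3].T + hull.equations[:, 3] <= 1e-9,
            axis=1)
        np.testing.assert_array_equal(mask.ravel(), inside)

    def test_hull_outside_grid_is_empty(self):
        verts = np.array([[50.0, 50, 50], [55, 50, 50], [50, 55, 50],
                          [50, 50, 55]])
        assert not rasterize_convex_hull(verts, (10, 10, 10), 1.0).any()

    def test_degenerate_points_resampled_or_error(self, rng):
        spec = ShapeSpec(kind="polyhedron", rotation=IDENTITY_Q,
                         translation=(0, 0, 0), n_points=4,
                         sphere_center=(8.0, 8.0, 8.0), sphere_radius=3.0)
        mask = rasterize_polyhedron(spec, (16, 16, 16), 1.0, rng=rng)
        assert mask.any()


class TestRasterizeLetter:
    def _spec(self, char="I", angle=0.0, thickness=3):
        return ShapeSpec(kind="ascii-letter", rotation=IDENTITY_Q,
                         translation=(0.0, 0.0, 0.0), character=char,
                         font_size=12, angle_2d=angle, thickness=thickness)

    def test_extruded_slices_identical_without_3d_rotation(self):
        mask = rasterize_letter(self._spec(thickness=4), (32, 32, 32), 1.0)
        occupied = np.where(mask.any(axis=(0, 1)))[0]
        assert len(occupied) == 4
        ref = mask[:, :, occupied[0]]
        for k in occupied[1:]:
            np.testing.assert_array_equal(mask[:, :, k], ref)

    def test_letter_i_is_single_connected_slab(self):
        mask = rasterize_letter(self._spec("I"), (32, 32, 32), 1.0)
        assert mask.any()
        _, n_components = ndimage.label(mask)
        assert n_components == 1

    def test_zero_rotation_round_trip(self):
        a = rasterize_letter(self._spec(angle=0.0), (32, 32, 32), 1.0)
        b = rasterize_letter(self._spec(angle=360.0), (32, 32, 32), 1.0)
        # a full turn must reproduce the unrotated raster
        np.testing.assert_array_equal(a, b)

    def test_wrong_kind_rejected(self):
        spec = ShapeSpec(kind="polyhedron", rotation=IDENTITY_Q,
                         translation=(0, 0, 0), n_points=5,
                         sphere_center=(8, 8, 8), sphere_radius=3.0)
        with pytest.raises(ValueError):
            rasterize_letter(spec, (16, 16, 16), 1.0)


class TestComposePhantom:
    def test_zero_masks_gives_homogeneous_background(self, rng):
        ph = compose_phantom([], rng, (12, 12, 12), 1.0)
        assert set(np.unique(ph.label_grid)) == {0}
        assert 0 in ph.properties

    def test_overlap_creates_distinct_label(self, rng):
        shape = (12, 12, 12)
        m1 = np.zeros(shape, dtype=bool)
        m2 = np.zeros(shape, dtype=bool)
        m1[2:8, 2:8, 2:8] = True
        m2[5:11, 5:11, 5:11] = True
        ph = compose_phantom([m1, m2], rng, shape, 1.0)
        assert ph.label_grid[6, 6, 6] == 3  # overlap of coefficients 1 and 2
        assert ph.label_grid[3, 3, 3] == 1
        assert ph.label_grid[9, 9, 9] == 2
        assert set(np.unique(ph.label_grid)) == {0, 1, 2, 3}

    def test_three_overlapping_masks_enumerate_subset_sums(self, rng):
        shape = (12, 12, 12)
        masks = []
        for lo in (1, 3, 5):
            m = np.zeros(shape, dtype=bool)
            m[lo:lo + 6, 2:10, 2:10] = True
            masks.append(m)
        ph = compose_phantom(masks, rng, shape, 1.0)
        labels = set(np.unique(ph.label_grid))
        assert labels <= set(range(8))  # all subset sums of {1, 2, 4} plus 0
        assert {0, 7} <= labels  # background and the triple overlap

    def test_mismatched_mask_shapes_rejected(self, rng):
        with pytest.raises(ValueError, match="shape"):
            compose_phantom([np.zeros((4, 4, 4), bool)], rng, (12, 12, 12), 1.0)


class TestOpticalProperties:
    def test_distributional_bounds(self, rng):
        draws = [sample_optical_properties(rng) for _ in range(10_000)]
        assert all(0.9 <= p.g < 1.0 for p in draws)
        assert all(1.0 <= p.n <= 10.0 for p in draws)
        assert all(p.mua >= 0 for p in draws)
        assert all(p.mus >= 0 for p in draws)

    def test_musp_mean_matches_folded_normal(self, rng):
        # E|N(1,1)| in closed form via the folded-normal expectation
        n_draws = 100_000
        musp = np.array([sample_optical_properties(rng).musp
                         for _ in range(n_draws)])
        expected = np.sqrt(2 / np.pi) * np.exp(-0.5) + (1 - 2 * stats.norm.cdf(-1))
        se = musp.std() / np.sqrt(n_draws)
        assert abs(musp.mean() - expected) < 3 * se

    def test_mus_monotone_in_g_at_fixed_musp(self):
        musp = 1.0
        mus = [musp / (1.0 - g) for g in (0.9, 0.95, 0.99, 0.999)]
        assert all(a < b for a, b in zip(mus, mus[1:]))

    def test_invariant_violations_rejected(self):
        with pytest.raises(ValueError):
            OpticalProperties(mua=-0.1, mus=1.0, g=0.9, n=1.4)
        with pytest.raises(ValueError):
            OpticalProperties(mua=0.1, mus=1.0, g=1.0, n=1.4)
        with pytest.raises(ValueError):
            OpticalProperties(mua=0.1, mus=1.0, g=0.9, n=0.5)


class TestSimulationConfigSampling:
    def test_time_gate_and_source_bounds(self, rng):
        ph = random_phantom(np.random.default_rng(0), (12, 12, 12), n_shapes=0)
        for _ in range(1000):
            src, gate = sample_simulation_config(rng, ph)
            assert 0.1 <= gate <= 1.0
            assert all(0 < p < 12 for p in src.position)

    def test_reproducible_under_seed(self):
        ph = random_phantom(np.random.default_rng(0), (12, 12, 12), n_shapes=0)
        a = sample_simulation_config(np.random.default_rng(3), ph)
        b = sample_simulation_config(np.random.default_rng(3), ph)
        assert a == b


class TestPhantomInvariants:
    def test_label_closure_and_determinism_on_seeded_phantoms(self):
        for seed in range(100):
            ph1 = random_phantom(np.random.default_rng(seed), (16, 16, 16))
            assert set(np.unique(ph1.label_grid)) <= set(ph1.properties)
            ph2 = random_phantom(np.random.default_rng(seed), (16, 16, 16))
            assert ph1.content_hash() == ph2.content_hash()


class TestGenerateDataset:
    def test_manifest_byte_identical_under_seed(self, tmp_path):
        d1, d2 = tmp_path / "a", tmp_path / "b"
        generate_dataset(3, (12, 12, 12), d1, seed=5)
        generate_dataset(3, (12, 12, 12), d2, seed=5)
        assert (d1 / "manifest.json").read_bytes() == (d2 / "manifest.json").read_bytes()

    def test_records_round_trip(self, tmp_path):
        records = generate_dataset(2, (12, 12, 12), tmp_path, seed=9)
        assert len(records) == 2
        loaded = json.loads((tmp_path / "manifest.json").read_text())
        assert loaded == records
        ph = mcdn.phantoms.load_phantom(tmp_path, records[0])
        assert ph.grid_shape == (12, 12, 12)

    def test_requires_positive_domain_count(self, tmp_path):
        with pytest.raises(ValueError):
            generate_dataset(0, (12, 12, 12), tmp_path, seed=1)


def test_quaternion_matrix_is_rotation(rng):
    from mcdn.phantoms import _random_quaternion

    for _ in range(25):
        R = quaternion_matrix(_random_quaternion(rng))
        np.testing.assert_allclose(R @ R.T, np.eye(3), atol=1e-12)
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-12)
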