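import numpy as np
import pytest

import ligandblob as lb
from ligandblob.errors import DegenerateBlobError
from oracles import brute_force_divisor


def multiset(points):
    return sorted(map(tuple, np.round(points, 9)))


class TestGridToPointCloud:
    def test_voxel_center_convention(self):
        g = lb.VoxelGrid(values=np.zeros((2, 2, 2)), spacing=0.2, origin=(0, 0, 0))
        g.values[0, 0, 0] = 3.0
        pc = lb.grid_to_point_cloud(g)
        np.testing.assert_allclose(pc.points, [[0.1, 0.1, 0.1, 3.0]])

    def test_point_count_and_density_multiset(self, random_grid):
        pc = lb.grid_to_point_cloud(random_grid)
        assert len(pc) == random_grid.nonzero_count()
        assert sorted(pc.densities) == sorted(random_grid.values[random_grid.values > 0])

    def test_all_zero_grid_is_error(self):
        with pytest.raises(DegenerateBlobError):
            lb.grid_to_point_cloud(lb.VoxelGrid(values=np.zeros((3, 3, 3))))


class TestMetaVoxelPartition:
    def test_worked_example_20_16_10(self):
        n_blocks, shape = lb.meta_voxel_blocks((20, 16, 10), 2)
        assert n_blocks == 8
        assert shape == (10, 8, 5)

    def test_small_mask_refines_to_single_voxel_blocks(self):
        mask = np.zeros((8, 8, 8), bool)
        mask[:2, :2, :2] = True  # 8 nonzero voxels << max_p
        part = lb.partition_meta_voxels((8, 8, 8), mask, max_p=2000)
        assert part.block_shape == (1, 1, 1)
        assert part.occupied_count == 8

    @pytest.mark.parametrize("seed", range(6))
    @pytest.mark.parametrize("max_p", [5, 50, 500])
    def test_agrees_with_brute_force_scan(self, seed, max_p):
        rng = np.random.default_rng(seed)
        shape = tuple(rng.integers(4, 33, size=3))
        mask = rng.random(shape) < 0.3
        part = lb.partition_meta_voxels(shape, mask, max_p=max_p)
        assert part.divisor == brute_force_divisor(shape, mask, max_p)
        assert part.occupied_count <= max_p

    def test_fully_occupied_grid(self):
        part = lb.partition_meta_voxels((8, 8, 8), np.ones((8, 8, 8), bool), max_p=2000)
        assert part.divisor == brute_force_divisor((8, 8, 8), np.ones((8, 8, 8), bool), 2000)
        assert part.occupied_count <= 2000


class TestUniformMax:
    def test_under_budget_is_identity(self, random_grid):
        pc = lb.grid_to_point_cloud(random_grid)
        out = lb.sample_uniform_max(pc, random_grid, max_p=10**6)
        assert multiset(out.points) == multiset(pc.points)

    def test_octant_argmax_on_linear_ramp(self):
        values = np.zeros((4, 4, 4))
        for i in range(4):
            for j in range(4):
                for k in range(4):
                    values[i, j, k] = 1 + i + 10 * j + 100 * k
        grid = lb.VoxelGrid(values=values, spacing=0.2)
        pc = lb.grid_to_point_cloud(grid)
        out = lb.sample_uniform_max(pc, grid, max_p=8)
        assert len(out) == 8
        expected = sorted(
            values[i : i + 2, j : j + 2, k : k + 2].max()
            for i in (0, 2)
            for j in (0, 2)
            for k in (0, 2)
        )
        assert sorted(out.densities) == expected

    def test_output_is_submultiset_of_input(self, random_grid):
        pc = lb.grid_to_point_cloud(random_grid)
        out = lb.sample_uniform_max(pc, random_grid, max_p=5)
        inset = set(multiset(pc.points))
        assert all(tuple(p) in inset for p in np.round(out.points, 9))

    def test_deterministic(self, random_grid):
        pc = lb.grid_to_point_cloud(random_grid)
        a = lb.sample_uniform_max(pc, random_grid, max_p=7)
        b = lb.sample_uniform_max(pc, random_grid, max_p=7)
        np.testing.assert_array_equal(a.points, b.points)


class TestRandomSampling:
    def test_identity_when_under_budget(self, random_grid):
        pc = lb.grid_to_point_cloud(random_grid)
        out = lb.sample_random(pc, max_p=10**6, seed=3)
        assert multiset(out.points) == multiset(pc.points)

    def test_same_seed_same_output(self, random_grid):
        pc = lb.grid_to_point_cloud(random_grid)
        a = lb.sample_random(pc, max_p=5, seed=11)
        b = lb.sample_random(pc, max_p=5, seed=11)
        np.testing.assert_array_equal(a.points, b.points)

    def test_inclusion_frequencies_are_uniform(self):
        """10 choose 5 without replacement: every point included ~50% of the
        time over many seeded draws (binomial 3-SE band)."""
        pts = np.column_stack(
            [np.arange(10.0), np.zeros(10), np.zeros(10), np.ones(10)]
        )
        pc = lb.PointCloud(points=pts)
        n_draws = 10**4
        counts = np.zeros(10)
        for seed in range(n_draws):
            out = lb.sample_random(pc, max_p=5, seed=seed)
            counts[out.coords[:, 0].astype(int)] += 1
        freq = counts / n_draws
        se = np.sqrt(0.25 / n_draws)
        assert np.all(np.abs(freq - 0.5) < 3 * se + 0.01)


class TestSurfaceSampling:
    def test_solid_cube_shell_count(self):
        values = np.zeros((7, 7, 7))
        values[1:6, 1:6, 1:6] = 1.0
        grid = lb.VoxelGrid(values=values, spacing=0.2)
        pc = lb.grid_to_point_cloud(grid)
        out = lb.sample_surface(pc, grid, max_p=10**6, seed=0)
        assert len(out) == 5**3 - 3**3  # 98 shell voxels

    def test_single_voxel_is_its_own_shell(self):
        g = lb.VoxelGrid(values=np.zeros((3, 3, 3)), spacing=0.2)
        g.values[1, 1, 1] = 2.0
        pc = lb.grid_to_point_cloud(g)
        out = lb.sample_surface(pc, g, max_p=10, seed=0)
        assert len(out) == 1

    def test_every_sampled_point_has_zero_6_neighbor(self, random_grid):
        pc = lb.grid_to_point_cloud(random_grid)
        out = lb.sample_surface(pc, random_grid, max_p=10**6, seed=1)
        vals = random_grid.values
        for x, y, z in out.coords:
            i, j, k = [int(round((c - o) / 0.2 - 0.5)) for c, o in zip((x, y, z), random_grid.origin)]
            has_zero = False
            for d in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)):
                a, b, c2 = i + d[0], j + d[1], k + d[2]
                if not (0 <= a < vals.shape[0] and 0 <= b < vals.shape[1] and 0 <= c2 < vals.shape[2]):
                    has_zero = True
                elif vals[a, b, c2] == 0:
                    has_zero = True
            assert has_zero


class TestClusteringSampling:
    def test_identity_at_or_under_budget(self, random_grid):
        pc = lb.grid_to_point_cloud(random_grid)
        out = lb.sample_clustering(pc, max_p=len(pc), seed=0)
        assert multiset(out.points) == multiset(pc.points)

    def test_two_separated_clusters_recover_means(self, rng):
        a = rng.normal(0, 0.05, size=(100, 3))
        b = rng.normal(0, 0.05, size=(100, 3)) + [10, 0, 0]
        pts = np.vstack([a, b])
        pc = lb.PointCloud(points=np.column_stack([pts, np.ones(200)]))
        out = lb.sample_clustering(pc, max_p=2, seed=0)
        got = sorted(map(tuple, np.round(out.coords, 3)))
        means = sorted(map(tuple, np.round([a.mean(axis=0), b.mean(axis=0)], 3)))
        for g, m in zip(got, means):
            assert np.linalg.norm(np.asarray(g) - np.asarray(m)) < 0.1

    def test_output_size_exact(self, random_grid):
        pc = lb.grid_to_point_cloud(random_grid)
        out = lb.sample_clustering(pc, max_p=6, seed=0)
        assert len(out) == min(6, len(pc))


class TestStrategyContracts:
    @pytest.mark.parametrize("strategy", ["random", "uniform", "surface", "clustering"])
    def test_budget_respected(self, random_grid, strategy):
        out = lb.sample(strategy, random_grid, max_p=4, seed=2)
        assert len(out) <= 4

    @pytest.mark.parametrize("strategy", ["random", "uniform", "surface"])
    def test_provenance_submultiset(self, random_grid, strategy):
        full = set(multiset(lb.grid_to_point_cloud(random_grid).points))
        out = lb.sample(strategy, random_grid, max_p=6, seed=2)
        assert all(tuple(p) in full for p in np.round(out.points, 9))

    def test_uniform_max_permutation_invariant(self, random_grid):
        pc = lb.grid_to_point_cloud(random_grid)
        shuffled = lb.PointCloud(points=pc.points[::-1].copy())
        a = lb.sample_uniform_max(pc, random_grid, max_p=5)
        b = lb.sample_uniform_max(shuffled, random_grid, max_p=5)
        assert multiset(a.points) == multiset(b.points)
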