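"""Tests for free-energy grids, minimal paths, Kabsch superposition and PCA."""

import itertools

import numpy as np
import pytest

from conftest import random_rotation
from hairpinmc.landscapes import (
    FESurface,
    fe_profile_1d,
    fe_surface_2d,
    integer_bin_edges,
    joint_pca,
    kabsch_superpose,
    loop_distance_distributions,
    marginalize,
    minimal_energy_path,
    pca_fe_surface,
)


class TestProfile1D:
    def test_uniform_two_bins_flat(self):
        surf = fe_profile_1d(
            np.array([0.25, 0.75, 0.25, 0.75]), kt=1.0, bin_edges=np.array([0, 0.5, 1])
        )
        np.testing.assert_allclose(surf.free_energy, [0.0, 0.0], atol=1e-12)

    def test_eighty_twenty_split(self):
        values = np.array([0.2] * 8 + [0.8] * 2)
        surf = fe_profile_1d(values, kt=1.0, bin_edges=np.array([0, 0.5, 1]))
        assert surf.free_energy[0] == 0.0
        assert surf.free_energy[1] == pytest.approx(np.log(4.0))

    def test_masked_bins_never_enter_minimum(self):
        values = np.array([0.1, 0.1, 2.9])
        surf = fe_profile_1d(values, kt=1.0, bin_edges=np.arange(0.0, 4.0))
        assert surf.mask.tolist() == [False, True, False]
        assert np.nanmin(surf.free_energy[~surf.mask]) == 0.0

    def test_normalization_recoverable(self):
        rng = np.random.default_rng(0)
        surf = fe_profile_1d(rng.normal(size=500), kt=0.7)
        p = surf.probabilities()
        assert p.sum() == pytest.approx(1.0, rel=1e-9)

    def test_contour_levels_are_kt_multiples(self):
        rng = np.random.default_rng(1)
        surf = fe_profile_1d(rng.normal(size=300), kt=0.55)
        levels = surf.contour_levels
        np.testing.assert_allclose(levels / surf.kt, np.arange(len(levels)))

    def test_empty_input_is_an_error(self):
        with pytest.raises(ValueError):
            fe_profile_1d(np.array([]), kt=1.0)


class TestSurface2D:
    def test_single_occupied_bin(self):
        surf = fe_surface_2d(
            np.array([0.5]), np.array([0.5]), kt=1.0,
            x_edges=np.arange(0.0, 3.0), y_edges=np.arange(0.0, 3.0),
        )
        assert surf.free_energy[0, 0] == 0.0
        assert surf.mask.sum() == surf.mask.size - 1

    def test_independent_marginals_separate(self):
        rng = np.random.default_rng(5)
        x = rng.integers(0, 3, size=20_000).astype(float)
        y = rng.integers(0, 2, size=20_000).astype(float)
        surf = fe_surface_2d(
            x, y, kt=1.0,
            x_edges=integer_bin_edges(2), y_edges=integer_bin_edges(1),
        )
        fx = fe_profile_1d(x, kt=1.0, bin_edges=integer_bin_edges(2)).free_energy
        fy = fe_profile_1d(y, kt=1.0, bin_edges=integer_bin_edges(1)).free_energy
        # F(x, y) - Fx(x) - Fy(y) should be constant over unmasked bins
        resid = surf.free_energy - fx[:, None] - fy[None, :]
        resid = resid[~surf.mask]
        assert resid.max() - resid.min() < 0.15  # statistical tolerance

    def test_marginalizing_recovers_1d_profile(self):
        rng = np.random.default_rng(6)
        x = rng.integers(0, 4, size=5000).astype(float)
        y = rng.integers(0, 3, size=5000).astype(float)
        surf = fe_surface_2d(
            x, y, kt=1.0,
            x_edges=integer_bin_edges(3), y_edges=integer_bin_edges(2),
        )
        marg = marginalize(surf, axis=1)
        direct = fe_profile_1d(x, kt=1.0, bin_edges=integer_bin_edges(3))
        np.testing.assert_allclose(marg.free_energy, direct.free_energy, atol=1e-9)

    def test_duplicating_samples_leaves_surface_unchanged(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=400)
        y = rng.normal(size=400)
        kwargs = dict(
            kt=1.0, x_edges=np.linspace(-4, 4, 9), y_edges=np.linspace(-4, 4, 9)
        )
        once = fe_surface_2d(x, y, **kwargs)
        twice = fe_surface_2d(np.tile(x, 2), np.tile(y, 2), **kwargs)
        np.testing.assert_allclose(
            once.free_energy[~once.mask], twice.free_energy[~twice.mask], atol=1e-12
        )
        assert np.array_equal(once.mask, twice.mask)


def _brute_force_best_path(f, mask, start, end):
    """Exhaustive enumeration of simple 8-connected paths, ranked by
    (max F, total F, lexicographic order)."""
    shape = f.shape
    best = None

    def neighbors(node):
        i, j = node
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                if di == dj == 0:
                    continue
                ni, nj = i + di, j + dj
                if 0 <= ni < shape[0] and 0 <= nj < shape[1] and not mask[ni, nj]:
                    yield (ni, nj)

    def dfs(node, visited, path):
        nonlocal best
        if node == end:
            key = (
                max(f[p] for p in path),
                sum(f[p] for p in path),
                tuple(path),
            )
            if best is None or key < best:
                best = key
            return
        for nb in neighbors(node):
            if nb not in visited:
                dfs(nb, visited | {nb}, path + [nb])

    dfs(start, {start}, [start])
    return None if best is None else list(best[2])


class TestMinimalEnergyPath:
    def test_start_equals_end(self):
        surf = fe_profile_1d(np.array([0.0]), kt=1.0, bin_edges=np.array([-0.5, 0.5]))
        grid = FESurface(
            axis_names=("a", "b"),
            bin_edges=(np.arange(3.0), np.arange(3.0)),
            free_energy=np.zeros((2, 2)),
            mask=np.zeros((2, 2), dtype=bool),
            kt=1.0,
            norm=0.25,
        )
        assert minimal_energy_path(grid, (1, 1), (1, 1)) == [(1, 1)]

    def test_two_basin_surface_crosses_the_saddle(self):
        f = np.array(
            [
                [0.0, 5.0, 5.0],
                [5.0, 1.0, 5.0],
                [5.0, 5.0, 0.2],
            ]
        )
        grid = FESurface(
            axis_names=("a", "b"),
            bin_edges=(np.arange(4.0), np.arange(4.0)),
            free_energy=f,
            mask=np.zeros((3, 3), dtype=bool),
            kt=1.0,
            norm=1.0,
        )
        path = minimal_energy_path(grid, (0, 0), (2, 2))
        assert (1, 1) in path  # the saddle bin

    def test_masked_endpoint_is_an_error(self):
        mask = np.zeros((2, 2), dtype=bool)
        mask[0, 0] = True
        grid = FESurface(
            axis_names=("a", "b"),
            bin_edges=(np.arange(3.0), np.arange(3.0)),
            free_energy=np.where(mask, np.nan, 1.0),
            mask=mask,
            kt=1.0,
            norm=0.5,
        )
        with pytest.raises(ValueError, match="masked"):
            minimal_energy_path(grid, (0, 0), (1, 1))

    def test_disconnected_grid_is_an_error(self):
        mask = np.array([[False, True], [True, False]])
        grid = FESurface(
            axis_names=("a", "b"),
            bin_edges=(np.arange(3.0), np.arange(3.0)),
            free_energy=np.where(mask, np.nan, 1.0),
            mask=mask,
            kt=1.0,
            norm=0.5,
        )
        # 8-connectivity joins the diagonal, so build a 3x3 with a full wall
        mask3 = np.zeros((3, 3), dtype=bool)
        mask3[:, 1] = True
        grid3 = FESurface(
            axis_names=("a", "b"),
            bin_edges=(np.arange(4.0), np.arange(4.0)),
            free_energy=np.where(mask3, np.nan, 1.0),
            mask=mask3,
            kt=1.0,
            norm=0.5,
        )
        with pytest.raises(ValueError, match="connected"):
            minimal_energy_path(grid3, (0, 0), (0, 2))

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_exhaustive_enumeration_on_random_grids(self, seed):
        rng = np.random.default_rng(seed)
        shape = (int(rng.integers(2, 5)), int(rng.integers(2, 5)))
        f = np.round(rng.uniform(0, 4, size=shape), 2)
        mask = rng.random(shape) < 0.2
        unmasked = [
            (i, j) for i, j in itertools.product(range(shape[0]), range(shape[1]))
            if not mask[i, j]
        ]
        if len(unmasked) < 2:
            return
        start, end = unmasked[0], unmasked[-1]
        grid = FESurface(
            axis_names=("a", "b"),
            bin_edges=(np.arange(shape[0] + 1, dtype=float), np.arange(shape[1] + 1, dtype=float)),
            free_energy=np.where(mask, np.nan, f),
            mask=mask,
            kt=1.0,
            norm=0.1,
        )
        expected = _brute_force_best_path(f, mask, start, end)
        if expected is None:
            with pytest.raises(ValueError):
                minimal_energy_path(grid, start, end)
            return
        path = minimal_energy_path(grid, start, end)
        # bottleneck and total must match the exhaustive optimum
        assert max(f[p] for p in path) == pytest.approx(max(f[p] for p in expected))
        assert sum(f[p] for p in path) == pytest.approx(sum(f[p] for p in expected))


class TestKabsch:
    def test_identity_superposition(self, rng):
        cloud = rng.normal(size=(10, 3))
        rot, trans, rmsd = kabsch_superpose(cloud, cloud)
        np.testing.assert_allclose(rot, np.eye(3), atol=1e-9)
        np.testing.assert_allclose(trans, 0.0, atol=1e-9)
        assert rmsd == pytest.approx(0.0, abs=1e-9)

    def test_recovers_known_rotation(self, rng):
        cloud = rng.normal(size=(12, 3))
        true_rot = random_rotation(rng)
        moved = cloud @ true_rot.T + np.array([1.0, -2.0, 0.5])
        rot, trans, rmsd = kabsch_superpose(cloud, moved)
        assert rmsd == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(rot, true_rot, atol=1e-9)
        assert np.linalg.det(rot) == pytest.approx(1.0)

    def test_reflection_not_permitted(self, rng):
        cloud = rng.normal(size=(20, 3))
        reflected = cloud * np.array([-1.0, 1.0, 1.0])
        rot, _, rmsd = kabsch_superpose(cloud, reflected)
        assert np.linalg.det(rot) == pytest.approx(1.0)
        assert rmsd > 0.1

    def test_degenerate_inputs_rejected(self, rng):
        with pytest.raises(ValueError):
            kabsch_superpose(rng.normal(size=(2, 3)), rng.normal(size=(2, 3)))
        line = np.outer(np.arange(5.0), np.array([1.0, 0.0, 0.0]))
        with pytest.raises(ValueError, match="collinear"):
            kabsch_superpose(line, line)


class TestJointPCA:
    def test_repeated_frame_gives_zero_eigenvalues(self):
        frame = np.random.default_rng(2).normal(size=(16, 3))
        pca = joint_pca({"x": np.repeat(frame[None], 5, axis=0)})
        np.testing.assert_allclose(pca.eigenvalues, 0.0, atol=1e-18)

    def test_recovers_planted_direction(self, rng):
        """Frames displaced along a single known 3N-direction: PC1 aligns
        with it (|cosine| > 0.99)."""
        base = rng.normal(size=(16, 3)) * 3.0
        direction = rng.normal(size=(16, 3))
        direction -= direction.mean(axis=0)  # no net translation component
        direction = direction.reshape(-1)
        direction /= np.linalg.norm(direction)
        amplitudes = rng.normal(0, 2.0, size=120)
        frames = base[None] + (amplitudes[:, None] * direction[None]).reshape(-1, 16, 3)
        pca = joint_pca({"x": frames}, n_iterations=0)
        cosine = abs(pca.components[0] @ direction)
        assert cosine > 0.99

    def test_projection_covariance_is_diagonal_top_eigenvalues(self, rng):
        frames = rng.normal(size=(80, 16, 3))
        pca = joint_pca({"a": frames[:50], "b": frames[50:]})
        cov = np.cov(pca.projections.T)
        assert cov[0, 0] == pytest.approx(pca.eigenvalues[0], rel=1e-6)
        assert cov[1, 1] == pytest.approx(pca.eigenvalues[1], rel=1e-6)
        assert abs(cov[0, 1]) < 1e-8 * max(1.0, pca.eigenvalues[0])

    def test_eigenvalues_invariant_under_rigid_transform(self, rng):
        frames = rng.normal(size=(40, 16, 3))
        rot = random_rotation(rng)
        moved = frames @ rot.T + np.array([3.0, 1.0, -2.0])
        a = joint_pca({"x": frames})
        b = joint_pca({"x": moved})
        np.testing.assert_allclose(a.eigenvalues, b.eigenvalues, atol=1e-8)

    def test_mismatched_atom_counts_rejected(self, rng):
        with pytest.raises(ValueError, match="atoms"):
            joint_pca({"a": rng.normal(size=(5, 16, 3)), "b": rng.normal(size=(5, 12, 3))})

    def test_labels_preserved(self, rng):
        pca = joint_pca(
            {"a": rng.normal(size=(7, 16, 3)), "b": rng.normal(size=(4, 16, 3))}
        )
        assert pca.projections_for("a").shape == (7, 2)
        assert pca.projections_for("b").shape == (4, 2)


class TestPcaSurfaceAndDistributions:
    def test_pca_fe_surface_shares_grid_across_labels(self, rng):
        pca = joint_pca(
            {"a": rng.normal(size=(60, 16, 3)), "b": rng.normal(size=(60, 16, 3))}
        )
        sa = pca_fe_surface(pca, kt=1.0, label="a", n_bins=10)
        sb = pca_fe_surface(pca, kt=1.0, label="b", n_bins=10)
        np.testing.assert_allclose(sa.bin_edges[0], sb.bin_edges[0])
        np.testing.assert_allclose(sa.bin_edges[1], sb.bin_edges[1])

    def test_loop_distance_densities_normalized(self, rng):
        distances = {"pep": rng.uniform(4, 12, size=200)}
        labels = {"pep": np.array(["folded"] * 120 + ["unfolded"] * 80)}
        out = loop_distance_distributions(distances, labels)
        for state, (edges, density) in out["pep"].items():
            widths = np.diff(edges)
            assert (density * widths).sum() == pytest.approx(1.0, rel=1e-9)

    def test_all_folded_omits_unfolded_density(self, rng):
        distances = {"pep": rng.uniform(4, 8, size=50)}
        labels = {"pep": np.array(["folded"] * 50)}
        with pytest.warns(UserWarning, match="no unfolded"):
            out = loop_distance_distributions(distances, labels)
        assert "unfolded" not in out["pep"]
        assert "folded" in out["pep"]

    def test_bimodal_input_yields_two_modes(self, rng):
        lo = rng.normal(5.0, 0.3, size=400)
        hi = rng.normal(10.0, 0.3, size=400)
        distances = {"pep": np.concatenate([lo, hi])}
        labels = {"pep": np.array(["unfolded"] * 800)}
        out = loop_distance_distributions(
            distances, labels, bin_edges=np.arange(3.0, 13.0, 0.5)
        )
        _, density = out["pep"]["unfolded"]
        interior = density[1:-1]
        peaks = np.sum(
            (interior > np.maximum(density[:-2], 1e-12))
            & (interior > np.maximum(density[2:], 1e-12))
        )
        assert peaks >= 2
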