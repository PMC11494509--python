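"""WHAM reconstruction, spline corrections, grid stationary points."""

import itertools

import numpy as np
import pytest

from preorg import (
    CorrectionSpline,
    GridSpec,
    PmfSurface,
    ToyPotentialSpec,
    UmbrellaDataset,
    UmbrellaWindow,
    bootstrap_pmf_error,
    locate_stationary_points,
    sample_umbrella_windows,
    spline_correct,
    wham,
)
from preorg.constants import KJ_TO_KCAL, R_KJ_MOL_K


class TestWham:
    def test_single_unbiased_window_equals_histogram_estimator(self):
        rng = np.random.default_rng(5)
        samples = rng.normal(0.0, 0.5, size=4000)
        ds = UmbrellaDataset(
            [UmbrellaWindow(center=[0.0], force_constant=0.0, samples=samples)],
            temperature=310.0,
        )
        grid = GridSpec(-2.0, 2.0, 40)
        surf = wham(ds, grid)
        counts, _ = np.histogram(samples, bins=grid.edges()[0])
        p = counts / counts.sum()
        ref = np.full(p.shape, np.nan)
        ref[p > 0] = -R_KJ_MOL_K * 310.0 * np.log(p[p > 0]) * KJ_TO_KCAL
        ref -= np.nanmin(ref)
        np.testing.assert_allclose(surf.G[surf.sampled], ref[p > 0], atol=1e-9)

    def test_window_order_invariance(self):
        pot = ToyPotentialSpec(form="harmonic", a=20.0, x0=0.2)
        ds = sample_umbrella_windows(pot, np.linspace(-0.4, 0.8, 25),
                                     n_samples=400, seed=9)
        grid = GridSpec(-0.5, 0.9, 56)
        surf = wham(ds, grid)
        reordered = UmbrellaDataset(list(reversed(ds.windows)), ds.temperature)
        surf2 = wham(reordered, grid)
        np.testing.assert_allclose(surf.G, surf2.G, atol=1e-6, equal_nan=True)

    def test_flat_potential_recovers_flat_pmf(self):
        pot = ToyPotentialSpec(form="flat")
        ds = sample_umbrella_windows(pot, np.linspace(-0.5, 0.5, 21),
                                     n_samples=800, seed=2)
        grid = GridSpec(-0.55, 0.55, 44)
        surf = wham(ds, grid)
        se = bootstrap_pmf_error(ds, grid, n_boot=20, seed=3)
        dev = np.abs(surf.G[surf.sampled] - np.nanmean(surf.G[surf.sampled]))
        assert np.nanmax(dev - 3 * se[surf.sampled]) < 0.15  # kcal/mol

    def test_empty_window_histogram_is_error(self):
        w = UmbrellaWindow(center=[5.0], force_constant=100.0,
                           samples=np.full(50, 5.0))
        ds = UmbrellaDataset([w], temperature=310.0)
        with pytest.raises(ValueError, match="empty"):
            wham(ds, GridSpec(-1.0, 1.0, 10))

    def test_nonconvergence_raises_with_residual(self):
        pot = ToyPotentialSpec(form="double_well", b=8.0, c=1.0)
        ds = sample_umbrella_windows(pot, np.linspace(-1.2, 1.2, 25),
                                     n_samples=300, seed=4)
        with pytest.raises(RuntimeError, match="converge"):
            wham(ds, GridSpec(-1.3, 1.3, 52), tol=1e-14, max_iter=3)

    def test_dimensionality_mismatch_is_error(self):
        w = UmbrellaWindow(center=[0.0], force_constant=1.0,
                           samples=np.linspace(-1, 1, 100))
        with pytest.raises(ValueError, match="dimensionality"):
            wham(UmbrellaDataset([w]), GridSpec([-1, -1], [1, 1], [8, 8]))


class TestSplineCorrection:
    def _surface(self, n=21):
        x = np.linspace(0.0, 2.0, n)
        g = (x - 1.0) ** 2
        return PmfSurface.from_values([x], g)

    def test_zero_correction_is_identity(self):
        surf = self._surface()
        corr = CorrectionSpline(nodes=[np.linspace(0, 2, 5)], delta=np.zeros(5))
        out = spline_correct(surf, corr)
        np.testing.assert_allclose(out.G, surf.G, atol=1e-12)

    def test_corrected_equals_high_level_at_nodes(self):
        x = np.linspace(0.0, 2.0, 21)
        nodes = x[::5]  # coarse nodes are grid points
        rng = np.random.default_rng(0)
        delta = rng.normal(size=nodes.size)
        surf = self._surface(21)
        out = spline_correct(surf, CorrectionSpline(nodes=[nodes], delta=delta))
        raw = surf.G + CorrectionSpline(nodes=[nodes], delta=delta)([x])
        # min-shift aside, corrected == LL + ΔE exactly at the nodes
        shift = np.nanmin(raw)
        for i, xn in enumerate(nodes):
            j = np.argmin(np.abs(x - xn))
            assert out.G[j] == pytest.approx(surf.G[j] + delta[i] - shift, abs=1e-9)

    def test_linear_delta_field_reproduced_exactly_1d(self):
        x = np.linspace(0.0, 2.0, 41)
        nodes = np.linspace(0.0, 2.0, 5)
        a, b = 0.7, -0.3
        corr = CorrectionSpline(nodes=[nodes], delta=a * nodes + b, order=1)
        surf = self._surface(41)
        out = spline_correct(surf, corr)
        expected = PmfSurface.from_values([x], surf.G + a * x + b)
        np.testing.assert_allclose(out.G, expected.G, atol=1e-10)

    def test_linear_delta_field_reproduced_exactly_2d(self):
        x = np.linspace(0, 1, 11)
        y = np.linspace(0, 2, 13)
        nodes = [np.linspace(0, 1, 4), np.linspace(0, 2, 5)]
        dx, dy = np.meshgrid(nodes[0], nodes[1], indexing="ij")
        delta = 2.0 * dx - 1.5 * dy + 0.25
        xx, yy = np.meshgrid(x, y, indexing="ij")
        ll = (xx - 0.5) ** 2 + (yy - 1.0) ** 2
        surf = PmfSurface.from_values([x, y], ll)
        out = spline_correct(surf, CorrectionSpline(nodes=nodes, delta=delta, order=1))
        expected = PmfSurface.from_values([x, y], ll + 2.0 * xx - 1.5 * yy + 0.25)
        np.testing.assert_allclose(out.G, expected.G, atol=1e-10)

    def test_extrapolation_beyond_node_hull_is_error(self):
        surf = self._surface()
        corr = CorrectionSpline(nodes=[np.linspace(0.5, 1.5, 4)], delta=np.zeros(4))
        with pytest.raises(ValueError, match="extrapolation"):
            spline_correct(surf, corr)


class TestStationaryPoints:
    def test_1d_double_well_saddle_is_max_between_minima(self):
        x = np.linspace(-1.5, 1.5, 31)
        g = (x**2 - 1.0) ** 2
        surf = PmfSurface.from_values([x], g)
        minima, saddles = locate_stationary_points(surf)
        assert len(minima) == 2
        (pair, energy), = saddles.items()
        i, j = sorted(idx[0] for idx, _ in minima)
        assert energy == pytest.approx(g[i:j + 1].max() - g.min())

    def test_single_basin_paraboloid_has_one_minimum_no_saddles(self):
        x = np.linspace(-1, 1, 15)
        y = np.linspace(-1, 1, 15)
        xx, yy = np.meshgrid(x, y, indexing="ij")
        surf = PmfSurface.from_values([x, y], xx**2 + yy**2)
        minima, saddles = locate_stationary_points(surf)
        assert len(minima) == 1
        assert saddles == {}

    def test_2d_minimax_saddle_matches_brute_force_path_enumeration(self):
        rng = np.random.default_rng(3)
        g = rng.uniform(1.0, 5.0, size=(6, 6))
        g[1, 1] = 0.0
        g[4, 4] = 0.2
        g -= g.min()
        surf = PmfSurface.from_values(
            [np.arange(6.0), np.arange(6.0)], g
        )
        minima, saddles = locate_stationary_points(surf)
        min_nodes = [idx for idx, _ in minima]
        assert (1, 1) in min_nodes and (4, 4) in min_nodes

        # oracle: exhaustive DFS over all simple 8-connected paths
        def neighbors(c):
            i, j = c
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    if (di, dj) != (0, 0) and 0 <= i + di < 6 and 0 <= j + dj < 6:
                        yield (i + di, j + dj)

        best = [np.inf]

        def dfs(node, target, visited, peak):
            if peak >= best[0]:
                return
            if node == target:
                best[0] = peak
                return
            for nb in neighbors(node):
                if nb not in visited:
                    dfs(nb, target, visited | {nb}, max(peak, g[nb]))

        a, b = min_nodes.index((1, 1)), min_nodes.index((4, 4))
        dfs((1, 1), (4, 4), {(1, 1)}, g[1, 1])
        assert saddles[frozenset({a, b})] == pytest.approx(best[0])

    def test_saddle_at_least_both_minima_energies(self):
        x = np.linspace(-1.5, 1.5, 41)
        g = (x**2 - 1.0) ** 2 + 0.3 * x
        surf = PmfSurface.from_values([x], g)
        minima, saddles = locate_stationary_points(surf)
        for pair, e in saddles.items():
            for idx in pair:
                assert e >= minima[idx][1]

    def test_masked_gap_disconnecting_minima_is_error(self):
        x = np.linspace(-1.5, 1.5, 31)
        g = (x**2 - 1.0) ** 2
        sampled = np.ones_like(x, dtype=bool)
        sampled[14:17] = False  # cut the barrier region out
        vals = np.where(sampled, g, np.nan)
        surf = PmfSurface.from_values([x], vals, sampled=sampled)
        with pytest.raises(ValueError, match="disconnect"):
            locate_stationary_points(surf)
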