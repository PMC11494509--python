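"""Umbrella-sampling free-energy reconstruction.

The weighted histogram analysis method (WHAM) unbiases a set of
overlapping harmonically restrained sampling windows into a single
potential of mean force. With window l holding N_l samples, histogram
counts n_l(b) on the PMF grid, and bias Boltzmann factors
c_l(b) = exp(−β w_l(b)) for w_l(x) = k/2 |x − x_l|², the
self-consistent equations are

    P(b) = Σ_l n_l(b) / Σ_l N_l f_l c_l(b),    f_l⁻¹ = Σ_b c_l(b) P(b)

iterated until the unbiased density P changes by less than a relative
tolerance (default 1e-3, the convergence criterion used for the
QM/MM surfaces this module mirrors at desk scale). The PMF is
−RT ln P, min-shifted to zero; bins never visited stay masked rather
than being silently interpolated.

Also here: interpolated high-level corrections (a spline through
HL − LL single-point energy differences on a coarse node grid, added
to the low-level surface) and grid-level stationary-point analysis
with exact minimax saddle energies via a sorted union–find flood.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.interpolate import InterpolatedUnivariateSpline, RectBivariateSpline

from .constants import DEFAULT_TEMPERATURE_K, KJ_TO_KCAL, R_KJ_MOL_K

__all__ = [
    "UmbrellaWindow",
    "UmbrellaDataset",
    "PmfSurface",
    "CorrectionSpline",
    "GridSpec",
    "wham",
    "bootstrap_pmf_error",
    "spline_correct",
    "locate_stationary_points",
    "DEFAULT_FORCE_CONSTANT",
]

#: Harmonic restraint force constant, kJ·mol⁻¹·Å⁻².
DEFAULT_FORCE_CONSTANT = 2500.0
#: WHAM density convergence tolerance (max relative change of P).
DEFAULT_TOL = 1e-3


@dataclass
class UmbrellaWindow:
    """One biased window: restraint center, force constant, samples."""

    center: np.ndarray  # shape (d,)
    force_constant: float = DEFAULT_FORCE_CONSTANT
    samples: np.ndarray = field(default_factory=lambda: np.empty((0, 1)))
    n_equil_discard: int = 0

    def __post_init__(self) -> None:
        self.center = np.atleast_1d(np.asarray(self.center, dtype=float))
        s = np.asarray(self.samples, dtype=float)
        if s.ndim == 1:
            s = s[:, None]
        self.samples = s
        if self.force_constant < 0:
            raise ValueError("force_constant must be nonnegative")
        if self.production().shape[0] == 0:
            raise ValueError("window has no samples after equilibration discard")
        if self.samples.shape[1] != self.center.shape[0]:
            raise ValueError("sample dimensionality does not match the center")

    def production(self) -> np.ndarray:
        return self.samples[self.n_equil_discard:]

    def bias_energy(self, points: np.ndarray) -> np.ndarray:
        """w(x) = k/2 · |x − center|², kJ/mol, at grid points (m, d)."""
        d2 = np.sum((np.atleast_2d(points) - self.center) ** 2, axis=1)
        return 0.5 * self.force_constant * d2


@dataclass
class UmbrellaDataset:
    windows: list[UmbrellaWindow]
    temperature: float = DEFAULT_TEMPERATURE_K

    def __post_init__(self) -> None:
        if not self.windows:
            raise ValueError("dataset has no windows")
        dims = {w.center.shape[0] for w in self.windows}
        if len(dims) != 1:
            raise ValueError(f"inconsistent window dimensionality: {sorted(dims)}")
        self.dimensionality = dims.pop()
        if self.dimensionality not in (1, 2):
            raise ValueError("only 1D and 2D coordinates are supported")


@dataclass
class GridSpec:
    """Regular PMF grid; bin centers double as histogram bins."""

    mins: Sequence[float]
    maxs: Sequence[float]
    nbins: Sequence[int]

    def __post_init__(self) -> None:
        self.mins = tuple(float(v) for v in np.atleast_1d(self.mins))
        self.maxs = tuple(float(v) for v in np.atleast_1d(self.maxs))
        self.nbins = tuple(int(v) for v in np.atleast_1d(self.nbins))
        for lo, hi, n in zip(self.mins, self.maxs, self.nbins):
            if hi <= lo or n < 2:
                raise ValueError("grid needs max > min and ≥ 2 bins per axis")

    @property
    def ndim(self) -> int:
        return len(self.mins)

    def edges(self) -> list[np.ndarray]:
        return [
            np.linspace(lo, hi, n + 1)
            for lo, hi, n in zip(self.mins, self.maxs, self.nbins)
        ]

    def centers(self) -> list[np.ndarray]:
        return [0.5 * (e[:-1] + e[1:]) for e in self.edges()]

    def mesh_points(self) -> np.ndarray:
        """All bin centers flattened to (n_bins_total, ndim), C order."""
        grids = np.meshgrid(*self.centers(), indexing="ij")
        return np.stack([g.ravel() for g in grids], axis=1)


@dataclass
class PmfSurface:
    """Free-energy grid (kcal/mol), min-shifted to 0 over sampled nodes."""

    axes: list[np.ndarray]  # bin-center coordinates per dimension
    G: np.ndarray  # shape = tuple(len(ax) for ax in axes); NaN where masked
    sampled: np.ndarray  # boolean mask, same shape

    def __post_init__(self) -> None:
        self.G = np.asarray(self.G, dtype=float)
        self.sampled = np.asarray(self.sampled, dtype=bool)
        if self.G.shape != self.sampled.shape:
            raise ValueError("G and sampled mask shapes differ")
        if self.sampled.any():
            gmin = np.nanmin(self.G[self.sampled])
            if abs(gmin) > 1e-9:
                raise ValueError("surface must be min-shifted to 0 over sampled nodes")

    @property
    def ndim(self) -> int:
        return self.G.ndim

    @classmethod
    def from_values(
        cls, axes: list[np.ndarray], values: np.ndarray, sampled: np.ndarray | None = None
    ) -> "PmfSurface":
        values = np.asarray(values, dtype=float)
        if sampled is None:
            sampled = np.isfinite(values)
        shifted = values - np.nanmin(values[sampled])
        out = np.full(values.shape, np.nan)
        out[sampled] = shifted[sampled]
        return cls(axes=[np.asarray(a, float) for a in axes], G=out, sampled=sampled)


# ---------------------------------------------------------------------------
# WHAM
# ---------------------------------------------------------------------------

def _histogram_counts(window: UmbrellaWindow, grid: GridSpec) -> np.ndarray:
    samples = window.production()
    counts, _ = np.histogramdd(samples, bins=grid.edges())
    return counts.ravel()


def wham(
    dataset: UmbrellaDataset,
    grid: GridSpec,
    tol: float = DEFAULT_TOL,
    max_iter: int = 100_000,
) -> PmfSurface:
    """Self-consistent WHAM reconstruction of the PMF on ``grid``.

    Convergence: max relative change of the unbiased density over
    occupied bins < ``tol``. Non-overlapping window sets trigger a
    warning and any never-visited bins stay masked in the result.
    Raises if the iteration does not converge within ``max_iter``.
    """
    if grid.ndim != dataset.dimensionality:
        raise ValueError("grid and dataset dimensionality differ")
    beta = 1.0 / (R_KJ_MOL_K * dataset.temperature)
    points = grid.mesh_points()

    counts = np.array([_histogram_counts(w, grid) for w in dataset.windows])
    if np.all(counts.sum(axis=1) == 0):
        raise ValueError("all window histograms are empty on this grid")
    empties = [i for i, c in enumerate(counts.sum(axis=1)) if c == 0]
    if empties:
        raise ValueError(f"window(s) {empties} have empty histograms on this grid")

    occupied_per_window = counts > 0
    if len(dataset.windows) > 1:
        overlap = occupied_per_window @ occupied_per_window.T
        if np.any((overlap > 0).sum(axis=1) < 2):
            warnings.warn(
                "some windows share no occupied bins with any other window; "
                "the reconstructed PMF may have masked gaps",
                stacklevel=2,
            )

    n_samples = counts.sum(axis=1)  # N_l
    total_counts = counts.sum(axis=0)  # M_b
    occupied = total_counts > 0

    # bias Boltzmann factors per window per bin
    log_c = np.array([-beta * w.bias_energy(points) for w in dataset.windows])
    c = np.exp(log_c - log_c.max(axis=1, keepdims=True))  # scale per window
    scale = np.exp(log_c.max(axis=1))  # restore later in f_l, cancels in P

    # c_actual[l,b] = c[l,b]*scale[l]; fold the scale into f_l iterates
    f = np.ones(len(dataset.windows))
    P = np.where(occupied, total_counts / total_counts.sum(), 0.0)
    for _it in range(max_iter):
        f = 1.0 / np.maximum((c * scale[:, None]) @ P, 1e-300)
        denom = (n_samples * f * scale) @ c  # Σ_l N_l f_l c_l(b)
        P_new = np.where(occupied, total_counts / np.maximum(denom, 1e-300), 0.0)
        P_new /= P_new.sum()
        rel = np.max(np.abs(P_new[occupied] - P[occupied]) / np.maximum(P[occupied], 1e-300))
        P = P_new
        if rel < tol:
            break
    else:
        raise RuntimeError(
            f"WHAM did not converge within {max_iter} iterations (residual {rel:.3e})"
        )

    G_kj = np.full(points.shape[0], np.nan)
    G_kj[occupied] = -R_KJ_MOL_K * dataset.temperature * np.log(P[occupied])
    shape = tuple(grid.nbins)
    return PmfSurface.from_values(
        axes=grid.centers(),
        values=(G_kj * KJ_TO_KCAL).reshape(shape),
        sampled=occupied.reshape(shape),
    )


def bootstrap_pmf_error(
    dataset: UmbrellaDataset,
    grid: GridSpec,
    n_boot: int = 50,
    tol: float = DEFAULT_TOL,
    seed: int | None = None,
) -> np.ndarray:
    """Per-node standard error of the PMF from window-sample bootstrap.

    Each replicate resamples every window's production samples with
    replacement and reruns WHAM; the SE is the across-replicate std of
    the min-shifted surfaces (NaN where any replicate left a node
    unsampled).
    """
    rng = np.random.default_rng(seed)
    reps = []
    for _ in range(n_boot):
        windows = []
        for w in dataset.windows:
            prod = w.production()
            idx = rng.integers(0, prod.shape[0], prod.shape[0])
            windows.append(
                UmbrellaWindow(
                    center=w.center.copy(),
                    force_constant=w.force_constant,
                    samples=prod[idx],
                )
            )
        surf = wham(UmbrellaDataset(windows, dataset.temperature), grid, tol=tol)
        reps.append(surf.G)
    return np.nanstd(np.stack(reps), axis=0, ddof=1)


# ---------------------------------------------------------------------------
# Spline high-level correction
# ---------------------------------------------------------------------------

@dataclass
class CorrectionSpline:
    """Interpolated HL − LL correction on a coarse node grid.

    ``nodes`` are per-axis coordinates of a regular coarse grid; the
    interpolant passes through ΔE exactly at each node, so the
    corrected surface equals the high-level energy there.
    """

    nodes: list[np.ndarray]
    delta: np.ndarray  # ΔE(HL−LL) at nodes; shape matches node grid
    order: int = 3

    def __post_init__(self) -> None:
        if isinstance(self.nodes, (list, tuple)):
            self.nodes = [np.asarray(n, dtype=float) for n in self.nodes]
        else:
            self.nodes = [np.asarray(self.nodes, dtype=float)]
        self.delta = np.asarray(self.delta, dtype=float)
        expected = tuple(len(n) for n in self.nodes)
        if self.delta.shape != expected:
            raise ValueError(f"delta shape {self.delta.shape} != node grid {expected}")
        if self.order < 1:
            raise ValueError("interpolation order must be ≥ 1")

    def _interpolant(self) -> Callable[..., np.ndarray]:
        if len(self.nodes) == 1:
            k = min(self.order, len(self.nodes[0]) - 1)
            spl = InterpolatedUnivariateSpline(self.nodes[0], self.delta, k=k)
            return lambda x: spl(x)
        kx = min(self.order, len(self.nodes[0]) - 1)
        ky = min(self.order, len(self.nodes[1]) - 1)
        spl = RectBivariateSpline(self.nodes[0], self.nodes[1], self.delta, kx=kx, ky=ky)
        return lambda x, y: spl(x, y, grid=True)

    def __call__(self, axes: list[np.ndarray]) -> np.ndarray:
        """Evaluate S(ΔE) on a target grid given by per-axis coordinates."""
        for ax, nd in zip(axes, self.nodes):
            if ax.min() < nd.min() - 1e-9 or ax.max() > nd.max() + 1e-9:
                raise ValueError(
                    "target grid extends beyond the correction node hull "
                    f"([{ax.min():.4g}, {ax.max():.4g}] vs [{nd.min():.4g}, {nd.max():.4g}]); "
                    "extrapolation is not performed"
                )
        return self._interpolant()(*axes)


def spline_correct(surface: PmfSurface, correction: CorrectionSpline) -> PmfSurface:
    """Add the interpolated HL − LL correction to a low-level surface.

    At correction nodes the result equals E_LL + ΔE exactly; elsewhere
    the spline interpolates. The corrected surface is re-min-shifted.
    """
    if len(correction.nodes) != surface.ndim:
        raise ValueError("correction and surface dimensionality differ")
    corr = correction(surface.axes)
    return PmfSurface.from_values(surface.axes, surface.G + corr, surface.sampled)


# ---------------------------------------------------------------------------
# Stationary points on grids
# ---------------------------------------------------------------------------

def _neighbors(idx: tuple[int, ...], shape: tuple[int, ...]):
    if len(shape) == 1:
        (i,) = idx
        for j in (i - 1, i + 1):
            if 0 <= j < shape[0]:
                yield (j,)
    else:
        i, j = idx
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                if di == dj == 0:
                    continue
                ni, nj = i + di, j + dj
                if 0 <= ni < shape[0] and 0 <= nj < shape[1]:
                    yield (ni, nj)


def locate_stationary_points(
    surface: PmfSurface,
) -> tuple[list[tuple[tuple[int, ...], float]], dict[frozenset[int], float]]:
    """Grid minima and exact minimax saddle energies between them.

    A node is a minimum when it is below every sampled neighbor
    (8-connectivity in 2D); exact ties resolve to the
    lower flat index. The saddle energy between two minima is the
    minimax path cost — the lowest possible value of the highest node
    on any connecting path — computed exactly by activating nodes in
    ascending energy order and merging components with union–find: the
    activation energy at which two minima's components join is their
    saddle. Masked gaps that leave minima disconnected raise an error.

    Returns (minima as [(index, G)], {frozenset({i, j}): saddle_G})
    where i, j index the returned minima list.
    """
    G = surface.G
    shape = G.shape
    sampled_idx = [tuple(t) for t in np.argwhere(surface.sampled)]
    if not sampled_idx:
        raise ValueError("surface has no sampled nodes")

    def flat(idx: tuple[int, ...]) -> int:
        return int(np.ravel_multi_index(idx, shape))

    minima: list[tuple[tuple[int, ...], float]] = []
    for idx in sampled_idx:
        g = G[idx]
        is_min = True
        for nb in _neighbors(idx, shape):
            if not surface.sampled[nb]:
                continue
            gn = G[nb]
            if gn < g or (gn == g and flat(nb) < flat(idx)):
                is_min = False
                break
        if is_min:
            minima.append((idx, float(g)))
    minima.sort(key=lambda m: flat(m[0]))

    # union-find flood in ascending energy
    parent: dict[int, int] = {}

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    min_flat = {flat(idx): i for i, (idx, _) in enumerate(minima)}
    comp_minima: dict[int, set[int]] = {}
    saddles: dict[frozenset[int], float] = {}
    active: set[tuple[int, ...]] = set()

    for idx in sorted(sampled_idx, key=lambda t: (G[t], flat(t))):
        f = flat(idx)
        parent[f] = f
        comp_minima[f] = {min_flat[f]} if f in min_flat else set()
        active.add(idx)
        for nb in _neighbors(idx, shape):
            if nb not in active:
                continue
            ra, rb = find(f), find(flat(nb))
            if ra == rb:
                continue
            ma, mb = comp_minima[ra], comp_minima[rb]
            for i in ma:
                for j in mb:
                    saddles.setdefault(frozenset({i, j}), float(G[idx]))
            parent[rb] = ra
            comp_minima[ra] = ma | mb
            del comp_minima[rb]

    roots = {find(flat(idx)) for idx, _ in minima}
    if len(roots) > 1:
        raise ValueError(
            "masked gaps disconnect the surface: "
            f"{len(roots)} separate components contain minima"
        )
    return minima, saddles
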