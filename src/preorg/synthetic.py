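"""Synthetic fixtures with known ground truth.

Everything downstream is certified on inputs whose answers are known
in closed form: toy "proteins" of point-charge residues at prescribed
Cα distances, Metropolis samples from analytic 1D/2D potentials under
harmonic umbrella restraints, exact toy free-energy grids with
declared minima and saddles, and water shells with constructed
H-bond geometry. Every generator is a pure function of (spec, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .constants import DEFAULT_TEMPERATURE_K, KJ_TO_KCAL, R_KJ_MOL_K
from .structures import AtomRecord, ChargedStructure, classify_group
from .wham import (
    DEFAULT_FORCE_CONSTANT,
    GridSpec,
    PmfSurface,
    UmbrellaDataset,
    UmbrellaWindow,
)

__all__ = [
    "ToyResidue",
    "ToyProteinSpec",
    "ToyPotentialSpec",
    "make_toy_protein",
    "sample_umbrella_windows",
    "make_toy_fes",
    "make_water_shell",
]

_MIN_ATOM_SEPARATION = 0.5  # Å


@dataclass
class ToyResidue:
    name: str
    net_charge: float
    ca_distance: float            # Å from the origin probe
    direction: np.ndarray | None = None  # unit vector; random if None
    n_atoms: int = 1
    spread: str = "point"         # "point": all charge on Cα; "uniform": split evenly

    def __post_init__(self) -> None:
        if self.ca_distance <= 0:
            raise ValueError("Cα distance must be positive")
        if self.n_atoms < 1:
            raise ValueError("need at least one atom")
        if self.direction is not None:
            d = np.asarray(self.direction, dtype=float)
            self.direction = d / np.linalg.norm(d)
        if self.spread not in ("point", "uniform"):
            raise ValueError(f"unknown spread rule {self.spread!r}")


@dataclass
class ToyProteinSpec:
    """Globular arrangement of point-charge residues around an origin probe."""

    residues: list[ToyResidue]
    waters: int = 0
    water_shell_radius: float = 30.0
    ions: list[tuple[str, float, float]] = field(default_factory=list)  # (name, charge, distance)


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def make_toy_protein(spec: ToyProteinSpec, seed: int = 0) -> ChargedStructure:
    """Build a charged toy structure; Cα atoms sit exactly at the
    prescribed distances from the origin, so shell profiles step at
    exactly those radii. Deterministic given the seed."""
    rng = np.random.default_rng(seed)
    atoms: list[AtomRecord] = []
    atom_id = 1
    for seq, res in enumerate(spec.residues, start=1):
        direction = res.direction if res.direction is not None else _random_unit(rng)
        ca_pos = direction * res.ca_distance
        if res.spread == "point":
            charges = [res.net_charge] + [0.0] * (res.n_atoms - 1)
        else:
            charges = [res.net_charge / res.n_atoms] * res.n_atoms
        # satellites on well-separated fixed directions 1.5 Å from the Cα
        phi = (1 + math.sqrt(5)) / 2
        ico = np.array(
            [[0, 1, phi], [0, -1, phi], [0, 1, -phi], [0, -1, -phi],
             [1, phi, 0], [-1, phi, 0], [1, -phi, 0], [-1, -phi, 0],
             [phi, 0, 1], [-phi, 0, 1], [phi, 0, -1], [-phi, 0, -1]]
        )
        ico = ico / np.linalg.norm(ico, axis=1, keepdims=True)
        for j in range(res.n_atoms):
            if j == 0:
                offset = np.zeros(3)
            else:
                offset = 1.5 * ico[(j - 1) % 12] * (1 + (j - 1) // 12)
            name = "CA" if j == 0 else f"CS{j}"
            atoms.append(
                AtomRecord(
                    atom_id=atom_id,
                    atom_name=name,
                    residue_name=res.name,
                    residue_seq=seq,
                    chain_id="A",
                    position=ca_pos + offset,
                    charge=charges[j],
                    group_kind="protein",
                )
            )
            atom_id += 1
    seq = len(spec.residues)
    for w in range(spec.waters):
        seq += 1
        pos = _random_unit(rng) * spec.water_shell_radius
        atoms.append(
            AtomRecord(atom_id=atom_id, atom_name="O", residue_name="HOH",
                       residue_seq=seq, chain_id="W", position=pos,
                       charge=-0.834, group_kind="water")
        )
        atom_id += 1
        # rigid water geometry: 0.9572 Å O–H, 104.5° H–O–H
        u = _random_unit(rng)
        v = np.cross(u, _random_unit(rng))
        v /= np.linalg.norm(v)
        h_dirs = (u, math.cos(math.radians(104.5)) * u + math.sin(math.radians(104.5)) * v)
        for hname, hd in zip(("H1", "H2"), h_dirs):
            hpos = pos + 0.9572 * hd
            atoms.append(
                AtomRecord(atom_id=atom_id, atom_name=hname, residue_name="HOH",
                           residue_seq=seq, chain_id="W", position=hpos,
                           charge=0.417, group_kind="water")
            )
            atom_id += 1
    for name, q, dist in spec.ions:
        seq += 1
        atoms.append(
            AtomRecord(atom_id=atom_id, atom_name=name, residue_name=name,
                       residue_seq=seq, chain_id="I",
                       position=_random_unit(rng) * dist, charge=q,
                       group_kind="ion")
        )
        atom_id += 1

    pos = np.array([a.position for a in atoms])
    if len(pos) > 1:
        from scipy.spatial.distance import pdist

        if pdist(pos).min() < _MIN_ATOM_SEPARATION:
            raise ValueError(
                f"generated atoms overlap (< {_MIN_ATOM_SEPARATION} Å); "
                "respecify distances or retry with another seed"
            )
    return ChargedStructure(atoms, title=f"toy-protein(seed={seed})")


# ---------------------------------------------------------------------------
# Analytic potentials and biased sampling
# ---------------------------------------------------------------------------

@dataclass
class ToyPotentialSpec:
    """Analytic 1D/2D potential with closed-form stationary points.

    Forms (energies in kJ/mol, coordinates in Å):

    * ``flat``: U = 0
    * ``harmonic``: U = a (x − x0)², minimum at x0
    * ``double_well``: U = b (x² − c²)² / c⁴ — minima at ±c (U = 0),
      saddle at 0 with barrier b
    * ``gaussians2d``: U = Σ_k −A_k exp(−|r − μ_k|²/(2 σ_k²))
    """

    form: str = "flat"
    a: float = 10.0
    x0: float = 0.0
    b: float = 12.0
    c: float = 1.0
    gaussians: list[tuple[float, tuple[float, float], float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.form not in ("flat", "harmonic", "double_well", "gaussians2d"):
            raise ValueError(f"unknown potential form {self.form!r}")
        if self.form == "double_well" and (self.b <= 0 or self.c <= 0):
            raise ValueError("double well needs b > 0 and c > 0")
        if self.form == "harmonic" and self.a <= 0:
            raise ValueError("harmonic needs a > 0")

    @property
    def ndim(self) -> int:
        return 2 if self.form == "gaussians2d" else 1

    def energy(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.form == "flat":
            return np.zeros(x.shape[:-1] if x.ndim > 1 else x.shape)
        if self.form == "harmonic":
            return self.a * (np.squeeze(x) - self.x0) ** 2
        if self.form == "double_well":
            xs = np.squeeze(x)
            return self.b * (xs**2 - self.c**2) ** 2 / self.c**4
        pts = np.atleast_2d(x)
        u = np.zeros(pts.shape[0])
        for amp, mu, sigma in self.gaussians:
            u -= amp * np.exp(-np.sum((pts - np.asarray(mu)) ** 2, axis=1) / (2 * sigma**2))
        return u if np.asarray(x).ndim > 1 else u[0]

    def stationary_points(self) -> dict:
        """Closed-form minima and saddle (kJ/mol) where available."""
        if self.form == "flat":
            return {"minima": [], "saddles": []}
        if self.form == "harmonic":
            return {"minima": [(self.x0, 0.0)], "saddles": []}
        if self.form == "double_well":
            return {
                "minima": [(-self.c, 0.0), (self.c, 0.0)],
                "saddles": [(0.0, self.b)],
            }
        return {
            "minima": [(mu, -amp) for amp, mu, sigma in self.gaussians],
            "saddles": [],  # no general closed form for Gaussian mixtures
        }


def sample_umbrella_windows(
    potential: ToyPotentialSpec,
    centers: Sequence[float] | Sequence[tuple[float, float]],
    force_constant: float = DEFAULT_FORCE_CONSTANT,
    n_samples: int = 2000,
    temperature: float = DEFAULT_TEMPERATURE_K,
    seed: int = 0,
    thin: int = 5,
) -> UmbrellaDataset:
    """Metropolis sampling of U(x) + (k/2)|x − x₀|² per window.

    A burn-in of 10% of ``n_samples`` sweeps is discarded while the
    proposal step is auto-tuned toward 30–60% acceptance; production
    then records one sample every ``thin`` sweeps to suppress chain
    autocorrelation (so downstream resampling error estimates treat
    samples as approximately independent). Acceptance rates are
    recorded on each window (``acceptance_rate`` attribute).
    Deterministic given the seed. Raises if a window accepts nothing.
    """
    rng = np.random.default_rng(seed)
    beta = 1.0 / (R_KJ_MOL_K * temperature)
    ndim = potential.ndim
    windows: list[UmbrellaWindow] = []
    n_burn = max(1, n_samples // 10)
    for center in centers:
        c = np.atleast_1d(np.asarray(center, dtype=float))
        if c.shape[0] != ndim:
            raise ValueError("center dimensionality does not match the potential")

        def total_u(x: np.ndarray) -> float:
            return float(potential.energy(x if ndim > 1 else x[0])) + \
                0.5 * force_constant * float(np.sum((x - c) ** 2))

        # start at the restraint center; tune step during burn-in
        step = math.sqrt(1.0 / (beta * max(force_constant, 1.0)))
        x = c.copy()
        u = total_u(x)
        accepted = 0
        for i in range(n_burn):
            prop = x + rng.normal(scale=step, size=ndim)
            du = total_u(prop) - u
            if du <= 0 or rng.random() < math.exp(-beta * du):
                x, u = prop, u + du
                accepted += 1
            if (i + 1) % 50 == 0:
                rate = accepted / (i + 1)
                if rate < 0.3:
                    step *= 0.8
                elif rate > 0.6:
                    step *= 1.25
        samples = np.empty((n_samples, ndim))
        accepted = 0
        n_sweeps = n_samples * max(1, thin)
        for i in range(n_sweeps):
            prop = x + rng.normal(scale=step, size=ndim)
            du = total_u(prop) - u
            if du <= 0 or rng.random() < math.exp(-beta * du):
                x, u = prop, u + du
                accepted += 1
            if (i + 1) % max(1, thin) == 0:
                samples[(i + 1) // max(1, thin) - 1] = x
        accepted_rate_denom = n_sweeps
        if accepted == 0:
            raise RuntimeError(
                f"window at {center}: zero Metropolis acceptance; reduce the step size"
            )
        w = UmbrellaWindow(center=c, force_constant=force_constant, samples=samples)
        w.acceptance_rate = accepted / accepted_rate_denom
        windows.append(w)
    return UmbrellaDataset(windows=windows, temperature=temperature)


def make_toy_fes(
    spec: ToyPotentialSpec, grid: GridSpec
) -> tuple[PmfSurface, dict]:
    """Exact evaluation of an analytic potential on a grid (kcal/mol),
    plus its declared closed-form stationary points (also kcal/mol)."""
    pts = grid.mesh_points()
    u_kj = np.asarray(potential_on_points(spec, pts))
    shape = tuple(grid.nbins)
    surface = PmfSurface.from_values(
        axes=grid.centers(),
        values=(u_kj * KJ_TO_KCAL).reshape(shape),
        sampled=np.ones(shape, dtype=bool),
    )
    declared = spec.stationary_points()
    declared_kcal = {
        "minima": [(x, e * KJ_TO_KCAL) for x, e in declared["minima"]],
        "saddles": [(x, e * KJ_TO_KCAL) for x, e in declared["saddles"]],
    }
    return surface, declared_kcal


def potential_on_points(spec: ToyPotentialSpec, points: np.ndarray) -> np.ndarray:
    points = np.atleast_2d(points)
    if spec.ndim == 1:
        return np.asarray(spec.energy(points[:, 0]))
    return np.asarray(spec.energy(points))


def make_water_shell(
    center: np.ndarray = (0.0, 0.0, 0.0),
    n_inner: int = 5,
    r_inner: float = 3.0,
    n_outer: int = 0,
    r_outer: float = 6.0,
    orientation: str = "H-toward-center",
    seed: int = 0,
    center_name: str = "CL",
    center_charge: float = -1.0,
) -> ChargedStructure:
    """Water shells around an anion with constructed H-bond geometry.

    ``orientation`` = ``"H-toward-center"`` points one O–H of each
    water exactly at the center (a linear, donating H-bond by
    construction); ``"H-away"`` points both hydrogens outward so no
    water donates. TIP3P charges throughout; oxygens sit exactly at
    the shell radii. Raises if radii are inconsistent or waters overlap.
    """
    if r_inner <= 0 or (n_outer > 0 and r_outer <= r_inner):
        raise ValueError("need 0 < r_inner < r_outer")
    if orientation not in ("H-toward-center", "H-away"):
        raise ValueError(f"unknown orientation rule {orientation!r}")
    rng = np.random.default_rng(seed)
    center = np.asarray(center, dtype=float)
    atoms = [
        AtomRecord(atom_id=1, atom_name=center_name, residue_name=center_name,
                   residue_seq=1, chain_id="I", position=center,
                   charge=center_charge, group_kind="ion")
    ]
    atom_id, seq = 2, 1

    def place_shell(n: int, r: float) -> None:
        nonlocal atom_id, seq
        dirs: list[np.ndarray] = []
        for _ in range(n):
            for _try in range(200):
                d = _random_unit(rng)
                if all(np.linalg.norm(r * d - r * e) >= 2.5 for e in dirs):
                    dirs.append(d)
                    break
            else:
                raise ValueError(f"cannot place {n} non-overlapping waters at r={r}")
        for d in dirs:
            seq += 1
            o_pos = center + r * d
            toward = (center - o_pos) / np.linalg.norm(center - o_pos)
            if orientation == "H-toward-center":
                h1 = o_pos + 0.9572 * toward
            else:
                h1 = o_pos - 0.9572 * toward
            # second H off-axis, on the far side from the center
            perp = np.cross(toward, _random_unit(rng))
            perp /= np.linalg.norm(perp)
            h2 = o_pos - 0.9572 * (0.5 * toward - 0.866 * perp) / np.linalg.norm(
                0.5 * toward - 0.866 * perp
            )
            for name, pos, q in (("O", o_pos, -0.834), ("H1", h1, 0.417), ("H2", h2, 0.417)):
                atoms.append(
                    AtomRecord(atom_id=atom_id, atom_name=name, residue_name="HOH",
                               residue_seq=seq, chain_id="W", position=pos,
                               charge=q, group_kind="water")
                )
                atom_id += 1

    if n_inner:
        place_shell(n_inner, r_inner)
    if n_outer:
        place_shell(n_outer, r_outer)
    return ChargedStructure(atoms, title=f"water-shell(seed={seed})")
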