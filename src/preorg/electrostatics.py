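"""Classical electrostatic potential at active-site probes.

The potential of a fixed partial-charge distribution at a point r is

    V(r) = f_C · Σ_i q_i / |r − r_i|,      f_C = N_A e²/(4π ε₀)

with q in elementary charges, r in Å and V in kJ·mol⁻¹·e⁻¹. No
distance cutoff or switching function is applied — the sum runs over
every included atom — and an optional uniform relative dielectric
(default 1, vacuum permittivity) simply divides f_C.

Three views are provided: the bare potential, its exact decomposition
into per-residue contributions, and cumulative distance-shell profiles
under the Cα-to-probe distance convention used to scan how V_elec
builds up between 7 and 24 Å from the electrophilic carbon.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import COULOMB_KJ_MOL_ANG
from .structures import ChargedStructure, ResidueKey

__all__ = [
    "PotentialDecomposition",
    "ShellProfile",
    "ContributorRanking",
    "potential_at_point",
    "decompose_by_residue",
    "shell_profile",
    "rank_contributors",
]

DEFAULT_THRESHOLD = 60.0  # kJ·mol⁻¹·e⁻¹ labelling threshold for key contributors
_SINGULARITY_TOL = 1e-6  # Å


def _select_atoms(
    structure: ChargedStructure,
    include: set[str] | None,
    exclude_residues: set[ResidueKey] | None,
):
    include = set(include) if include is not None else {"protein", "water", "ion", "substrate"}
    exclude_residues = exclude_residues or set()
    return [
        a for a in structure.atoms
        if a.group_kind in include and a.residue_key not in exclude_residues
    ]


def potential_at_point(
    structure: ChargedStructure,
    probe: np.ndarray,
    include: set[str] | None = None,
    exclude_residues: set[ResidueKey] | None = None,
    dielectric: float = 1.0,
) -> float:
    """V(probe) in kJ·mol⁻¹·e⁻¹ over the included atom scope.

    Raises if any included atom lies within 1e-6 Å of the probe
    (Coulomb singularity), naming the atom.
    """
    probe = np.asarray(probe, dtype=float)
    atoms = _select_atoms(structure, include, exclude_residues)
    if not atoms:
        return 0.0
    if any(a.charge is None for a in atoms):
        raise ValueError("structure has unassigned charges")
    pos = np.array([a.position for a in atoms])
    q = np.array([a.charge for a in atoms])
    dist = np.linalg.norm(pos - probe, axis=1)
    if np.any(dist < _SINGULARITY_TOL):
        bad = atoms[int(np.argmin(dist))]
        raise ValueError(
            f"atom {bad.residue_key}:{bad.atom_name} coincides with the probe "
            f"(distance {dist.min():.2e} Å)"
        )
    return float(COULOMB_KJ_MOL_ANG / dielectric * np.sum(q / dist))


@dataclass
class PotentialDecomposition:
    """Total V_elec at a probe plus exact per-residue contributions."""

    probe_label: str
    probe_position: np.ndarray
    total: float
    per_group: dict[ResidueKey, float]
    included_kinds: frozenset[str]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "chain_id": k.chain_id,
                "residue_seq": k.residue_seq,
                "residue_name": k.residue_name,
                "contribution_kJ_mol_e": v,
            }
            for k, v in self.per_group.items()
        ]
        return pd.DataFrame(rows)


def decompose_by_residue(
    structure: ChargedStructure,
    probe: np.ndarray,
    include: set[str] | None = None,
    dielectric: float = 1.0,
    probe_label: str = "probe",
) -> PotentialDecomposition:
    """Per-residue decomposition of V(probe); entries sum to the total.

    Waters, ions and the substrate appear as their own residue entries
    when their group kind is included.
    """
    probe = np.asarray(probe, dtype=float)
    atoms = _select_atoms(structure, include, None)
    per: dict[ResidueKey, float] = {}
    for a in atoms:
        if a.charge is None:
            raise ValueError("structure has unassigned charges")
        d = float(np.linalg.norm(a.position - probe))
        if d < _SINGULARITY_TOL:
            raise ValueError(
                f"atom {a.residue_key}:{a.atom_name} coincides with the probe"
            )
        per[a.residue_key] = per.get(a.residue_key, 0.0) + COULOMB_KJ_MOL_ANG / dielectric * a.charge / d
    kinds = frozenset(include) if include is not None else frozenset({"protein", "water", "ion", "substrate"})
    return PotentialDecomposition(
        probe_label=probe_label,
        probe_position=probe,
        total=float(sum(per.values())),
        per_group=per,
        included_kinds=kinds,
    )


@dataclass
class ShellProfile:
    """Cumulative V_elec and residue counts within growing Cα radii."""

    radii: np.ndarray
    cumulative_V: np.ndarray
    cumulative_count: np.ndarray
    excluded: list[ResidueKey] = field(default_factory=list)
    distance_convention: str = "Cα-to-probe"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "radius_A": self.radii,
                "cumulative_V_kJ_mol_e": self.cumulative_V,
                "cumulative_count": self.cumulative_count,
            }
        )


def shell_profile(
    structure: ChargedStructure,
    probe: np.ndarray,
    r_min: float = 7.0,
    r_max: float = 24.0,
    step: float = 1.0,
    dielectric: float = 1.0,
) -> ShellProfile:
    """Cumulative per-residue potential within Cα distance ≤ r.

    A residue contributes (its whole-residue potential) at every radius
    at or beyond its Cα–probe distance. Residues without a Cα — waters,
    ions, the substrate — are excluded and reported in ``excluded``.
    """
    if r_min >= r_max:
        raise ValueError(f"r_min ({r_min}) must be < r_max ({r_max})")
    if step <= 0:
        raise ValueError(f"step must be positive, got {step}")
    probe = np.asarray(probe, dtype=float)
    n = int(round((r_max - r_min) / step))
    radii = r_min + step * np.arange(n + 1)

    decomp = decompose_by_residue(structure, probe, dielectric=dielectric)
    residues = structure.residues()
    dist: dict[ResidueKey, float] = {}
    excluded: list[ResidueKey] = []
    for key, atoms in residues.items():
        ca = [a for a in atoms if a.atom_name.upper() == "CA"]
        if not ca:
            excluded.append(key)
            continue
        dist[key] = float(np.linalg.norm(ca[0].position - probe))

    cum_v = np.zeros_like(radii)
    cum_n = np.zeros(radii.shape, dtype=int)
    for i, r in enumerate(radii):
        inside = [k for k, d in dist.items() if d <= r + 1e-12]
        cum_n[i] = len(inside)
        cum_v[i] = sum(decomp.per_group.get(k, 0.0) for k in inside)
    return ShellProfile(radii=radii, cumulative_V=cum_v, cumulative_count=cum_n, excluded=excluded)


@dataclass
class ContributorRanking:
    """Residues ranked by |contribution|, classed by sign vs a threshold."""

    entries: list[tuple[ResidueKey, float, str]]
    threshold: float

    def labelled(self) -> list[tuple[ResidueKey, float, str]]:
        """Entries exceeding the threshold in absolute value."""
        return [e for e in self.entries if e[2] != "negligible"]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "chain_id": k.chain_id,
                    "residue_seq": k.residue_seq,
                    "residue_name": k.residue_name,
                    "contribution_kJ_mol_e": v,
                    "sign_class": c,
                }
                for k, v, c in self.entries
            ]
        )


def rank_contributors(
    decomposition: PotentialDecomposition,
    threshold: float = DEFAULT_THRESHOLD,
) -> ContributorRanking:
    """Sort residues by |V contribution|; class by sign above threshold.

    ``negative`` contributions stabilize accumulated positive charge
    (e.g. on the nucleophile-activating lysine), ``positive`` ones
    destabilize it; anything within ±threshold is ``negligible``.
    """
    if threshold < 0:
        raise ValueError("threshold must be nonnegative")
    if not decomposition.per_group:
        raise ValueError("empty decomposition")
    entries = []
    for key, v in sorted(
        decomposition.per_group.items(), key=lambda kv: (-abs(kv[1]), str(kv[0]))
    ):
        if abs(v) > threshold:
            cls = "negative" if v < 0 else "positive"
        else:
            cls = "negligible"
        entries.append((key, v, cls))
    return ContributorRanking(entries=entries, threshold=threshold)
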