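"""First-hydration-shell analysis around an anion.

Counts waters coordinating a chosen atom (the leaving chloride, in the
motivating system) and the hydrogen bonds donated to it, using purely
geometric criteria: an O(water)–center distance cutoff for the shell,
and an H–center distance plus O–H···center angle test for H-bonds.
Defaults follow standard chloride-hydration conventions; every cutoff
is configurable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structures import AtomRecord, ChargedStructure

__all__ = ["ShellCriteria", "coordination_number", "count_hbonds"]

_WATER_O_NAMES = {"O", "OW", "OH2"}


@dataclass
class ShellCriteria:
    shell_cutoff: float = 3.9       # Å, center···O(water)
    hbond_H_cutoff: float = 2.9     # Å, center···H(water)
    hbond_angle_min: float = 150.0  # degrees, O–H···center angle at H

    def __post_init__(self) -> None:
        if self.shell_cutoff <= 0 or self.hbond_H_cutoff <= 0:
            raise ValueError("cutoffs must be positive")
        if not 0 < self.hbond_angle_min <= 180:
            raise ValueError("hbond_angle_min must lie in (0, 180]")


def _water_molecules(structure: ChargedStructure) -> dict:
    return {
        key: atoms
        for key, atoms in structure.residues().items()
        if atoms[0].group_kind == "water"
    }


def _find_center(structure: ChargedStructure, center: AtomRecord | str) -> AtomRecord:
    if isinstance(center, AtomRecord):
        return center
    matches = [a for a in structure.atoms if a.atom_name.upper() == center.upper()]
    if not matches:
        raise ValueError(f"no atom named {center!r} in structure")
    if len(matches) > 1:
        raise ValueError(f"atom name {center!r} is ambiguous ({len(matches)} matches)")
    return matches[0]


def coordination_number(
    structure: ChargedStructure,
    center: AtomRecord | str,
    criteria: ShellCriteria | None = None,
) -> int:
    """Number of waters whose O lies within the shell cutoff of the center."""
    criteria = criteria or ShellCriteria()
    c = _find_center(structure, center)
    n = 0
    for atoms in _water_molecules(structure).values():
        o = [a for a in atoms if a.atom_name.upper() in _WATER_O_NAMES]
        if not o:
            continue
        if np.linalg.norm(o[0].position - c.position) <= criteria.shell_cutoff:
            n += 1
    return n


def count_hbonds(
    structure: ChargedStructure,
    center: AtomRecord | str,
    criteria: ShellCriteria | None = None,
) -> int:
    """Water O–H groups donating an H-bond to the center.

    An O–H donates when its H sits within ``hbond_H_cutoff`` of the
    center and the O–H···center angle (at the hydrogen; 180° = linear)
    is at least ``hbond_angle_min``. Waters without explicit hydrogens
    are an error — H-bond geometry cannot be inferred.
    """
    criteria = criteria or ShellCriteria()
    c = _find_center(structure, center)
    n = 0
    for key, atoms in _water_molecules(structure).items():
        o_atoms = [a for a in atoms if a.atom_name.upper() in _WATER_O_NAMES]
        h_atoms = [a for a in atoms if a.atom_name.upper().startswith("H")]
        if not o_atoms:
            continue
        if not h_atoms:
            raise ValueError(f"water {key} lacks explicit hydrogens")
        o = o_atoms[0]
        for h in h_atoms:
            d = np.linalg.norm(h.position - c.position)
            if d > criteria.hbond_H_cutoff:
                continue
            v_o = o.position - h.position
            v_c = c.position - h.position
            cosang = np.dot(v_o, v_c) / (np.linalg.norm(v_o) * np.linalg.norm(v_c))
            angle = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
            if angle >= criteria.hbond_angle_min:
                n += 1
    return n
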