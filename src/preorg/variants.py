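"""Force-field charge-variant engineering.

These operations build the alchemical electrostatic experiments used
to dissect preorganization: *atrophy* (zero every environment charge
except a catalytic keep-set and the substrate), *restoration* (switch
selected residues' or the solvent's charges back on), charge-only
*mutation* at a position, and *λ-scaling* of one residue's charges.

Every operation is charge-only: coordinates, atom identities, residue
partition and Lennard-Jones parameters (were they present) are never
touched — mutations deliberately neglect any conformational response.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

import yaml

from .structures import ChargedStructure, ChargeLibrary, ResidueKey

__all__ = [
    "ChargeVariantSpec",
    "apply_atrophy",
    "restore_residues",
    "mutate_charges",
    "scale_residue",
    "build_variant",
    "DEFAULT_LAMBDA_GRID",
]

#: Default λ grid for charge-scaling scans: 0 → 1.4 in steps of 0.2.
DEFAULT_LAMBDA_GRID = tuple(round(0.2 * i, 10) for i in range(8))

WATERS = "waters"  # sentinel accepted in restore lists


def _resolve_keys(structure: ChargedStructure, keys: Iterable[ResidueKey]) -> set[ResidueKey]:
    known = set(structure.residues())
    keys = set(keys)
    missing = keys - known
    if missing:
        raise KeyError(f"unknown residue(s): {sorted(str(k) for k in missing)}")
    return keys


def apply_atrophy(structure: ChargedStructure, keep_list: Iterable[ResidueKey]) -> ChargedStructure:
    """Zero all charges except keep-list residues and the substrate.

    Protein, water and counterion charges are annihilated; the
    substrate group always keeps its charges (it is the reacting
    system, not environment). Idempotent.
    """
    keep = _resolve_keys(structure, keep_list)
    atoms = []
    for a in structure.atoms:
        if a.group_kind == "substrate" or a.residue_key in keep:
            atoms.append(replace(a, position=a.position.copy()))
        else:
            atoms.append(replace(a, position=a.position.copy(), charge=0.0))
    return ChargedStructure(atoms, structure.title)


def restore_residues(
    atrophied: ChargedStructure,
    original: ChargedStructure,
    restore_list: Iterable[ResidueKey | str],
) -> ChargedStructure:
    """Switch original charges back on for selected residues.

    ``restore_list`` holds residue keys and/or the sentinel string
    ``"waters"`` (all water molecules). Structures must be atom-aligned
    — same atom keys in the same order.
    """
    if len(atrophied) != len(original) or any(
        a.key != b.key for a, b in zip(atrophied.atoms, original.atoms)
    ):
        raise ValueError("structures are not atom-aligned")
    restore_keys: set[ResidueKey] = set()
    restore_waters = False
    for item in restore_list:
        if isinstance(item, str):
            if item.lower() != WATERS:
                raise ValueError(f"unknown restore sentinel {item!r}")
            restore_waters = True
        else:
            restore_keys.add(item)
    _resolve_keys(original, restore_keys)
    atoms = []
    for a, o in zip(atrophied.atoms, original.atoms):
        if a.residue_key in restore_keys or (restore_waters and a.group_kind == "water"):
            atoms.append(replace(a, position=a.position.copy(), charge=o.charge))
        else:
            atoms.append(replace(a, position=a.position.copy()))
    return ChargedStructure(atoms, atrophied.title)


def mutate_charges(
    structure: ChargedStructure,
    key: ResidueKey,
    target: str,
    library: ChargeLibrary,
) -> ChargedStructure:
    """Charge-only point mutation: reassign one residue's charges from
    the target residue's template.

    Atoms shared by name between source and target take the target
    charges; source atoms absent from the target template are zeroed
    (e.g. the extra carboxylate oxygen of Asp→Ala). Target-template
    atoms with no coordinates in the source (e.g. Glu's CD/OE1/OE2 on
    an Asp backbone) contribute their summed charge to the last matched
    template atom, so the residue always lands on the target's declared
    net formal charge. Geometry is never rebuilt.
    """
    target = target.upper()
    if target not in library:
        raise KeyError(f"target residue {target!r} not in charge library")
    _resolve_keys(structure, [key])
    template = library.charges[target]
    present = {
        a.atom_name.upper() for a in structure.atoms if a.residue_key == key
    }
    matched = [name for name in template if name in present]
    if not matched:
        raise ValueError(
            f"no atom of {key} matches the {target} template; cannot mutate"
        )
    residual = sum(q for name, q in template.items() if name not in present)
    charges = {name: template[name] for name in matched}
    charges[matched[-1]] += residual
    atoms = []
    for a in structure.atoms:
        if a.residue_key != key:
            atoms.append(replace(a, position=a.position.copy()))
            continue
        q = charges.get(a.atom_name.upper(), 0.0)
        atoms.append(replace(a, position=a.position.copy(), charge=q))
    return ChargedStructure(atoms, structure.title)


def scale_residue(structure: ChargedStructure, key: ResidueKey, lam: float) -> ChargedStructure:
    """Multiply one residue's charges by λ (λ ≥ 0; λ > 1 allowed —
    unnatural charge amplification is part of the scan)."""
    if lam < 0:
        raise ValueError(f"λ must be nonnegative, got {lam}")
    _resolve_keys(structure, [key])
    atoms = [
        replace(a, position=a.position.copy(), charge=a.charge * lam)
        if a.residue_key == key
        else replace(a, position=a.position.copy())
        for a in structure.atoms
    ]
    return ChargedStructure(atoms, structure.title)


@dataclass
class ChargeVariantSpec:
    """Declarative recipe for a charge variant.

    Applied in the fixed order atrophy → restore → mutate → λ-scale.
    Keep/restore lists must be disjoint from mutated keys.
    """

    atrophy: bool = False
    keep_list: list[ResidueKey] = field(default_factory=list)
    restore_list: list[ResidueKey | str] = field(default_factory=list)
    mutations: dict[ResidueKey, str] = field(default_factory=dict)
    lambda_map: dict[ResidueKey, float] = field(default_factory=dict)
    label: str | None = None

    def __post_init__(self) -> None:
        mutated = set(self.mutations)
        for k in self.keep_list:
            if k in mutated:
                raise ValueError(f"residue {k} appears in both keep_list and mutations")
        for k in self.restore_list:
            if isinstance(k, ResidueKey) and k in mutated:
                raise ValueError(f"residue {k} appears in both restore_list and mutations")
        for k, lam in self.lambda_map.items():
            if lam < 0:
                raise ValueError(f"λ for {k} must be nonnegative, got {lam}")

    # -- serialization -------------------------------------------------

    @staticmethod
    def _key_to_str(k: ResidueKey) -> str:
        return f"{k.chain_id}:{k.residue_name}:{k.residue_seq}"

    @staticmethod
    def _key_from_str(s: str) -> ResidueKey:
        chain, name, seq = s.split(":")
        return ResidueKey(chain, int(seq), name)

    def to_yaml(self) -> str:
        doc = {
            "atrophy": self.atrophy,
            "keep_list": [self._key_to_str(k) for k in self.keep_list],
            "restore_list": [
                k if isinstance(k, str) else self._key_to_str(k) for k in self.restore_list
            ],
            "mutations": {self._key_to_str(k): v for k, v in self.mutations.items()},
            "lambda_map": {self._key_to_str(k): v for k, v in self.lambda_map.items()},
            "label": self.label,
        }
        return yaml.safe_dump(doc, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "ChargeVariantSpec":
        doc = yaml.safe_load(text) or {}
        return cls(
            atrophy=bool(doc.get("atrophy", False)),
            keep_list=[cls._key_from_str(s) for s in doc.get("keep_list", [])],
            restore_list=[
                s if s == WATERS else cls._key_from_str(s)
                for s in doc.get("restore_list", [])
            ],
            mutations={cls._key_from_str(s): v for s, v in (doc.get("mutations") or {}).items()},
            lambda_map={cls._key_from_str(s): v for s, v in (doc.get("lambda_map") or {}).items()},
            label=doc.get("label"),
        )

    def canonical_label(self) -> str:
        """Canonical study label, e.g. Velec(OFF), Velec(D17&WAT), D17A, λ=0.8."""
        if self.label:
            return self.label
        parts: list[str] = []
        if self.atrophy:
            restored = []
            for k in self.restore_list:
                restored.append("WAT" if isinstance(k, str) else f"{_one_letter(k.residue_name)}{k.residue_seq}")
            parts.append(f"Velec({'&'.join(restored)})" if restored else "Velec(OFF)")
        for k, tgt in self.mutations.items():
            parts.append(f"{_one_letter(k.residue_name)}{k.residue_seq}{_one_letter(tgt)}")
        for k, lam in self.lambda_map.items():
            parts.append(f"λ={lam:g}")
        return "+".join(parts) if parts else "Velec(ON)"


_ONE_LETTER = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "CYM": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L",
    "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T",
    "TRP": "W", "TYR": "Y", "VAL": "V",
}


def _one_letter(resname: str) -> str:
    return _ONE_LETTER.get(resname.upper(), resname.upper())


def build_variant(
    structure: ChargedStructure,
    spec: ChargeVariantSpec,
    library: ChargeLibrary | None = None,
) -> tuple[ChargedStructure, str]:
    """Apply a variant recipe; returns (variant structure, label).

    Deterministic composition in the fixed order
    atrophy → restore → mutate → λ-scale. An empty spec is the
    identity (label ``Velec(ON)``).
    """
    out = structure.copy()
    if spec.atrophy:
        out = apply_atrophy(out, spec.keep_list)
        if spec.restore_list:
            out = restore_residues(out, structure, spec.restore_list)
    elif spec.restore_list:
        raise ValueError("restore_list without atrophy has no effect; set atrophy=True")
    if spec.mutations:
        if library is None:
            raise ValueError("mutations require a charge library")
        for key, target in spec.mutations.items():
            out = mutate_charges(out, key, target, library)
    for key, lam in spec.lambda_map.items():
        out = scale_residue(out, key, lam)
    return out, spec.canonical_label()
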