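"""Charged molecular structures and their file formats.

A :class:`ChargedStructure` is an ordered list of point charges grouped
into residues — the minimal representation needed to evaluate the
classical electrostatic potential V(r) = f_C Σ q_i/|r − r_i| at probe
points in an enzyme active site. Structures are read from PDB
(coordinates only; charges assigned afterwards from a
:class:`ChargeLibrary`) or PQR (charges inline), and written as PQR.

Parsing is deliberately strict: malformed records raise with the line
number, duplicate atom keys raise, and PDB-sourced atoms carry
``charge=None`` until :func:`assign_charges` runs — silent zero charges
are never produced.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "AtomRecord",
    "ResidueKey",
    "ChargedStructure",
    "ChargeLibrary",
    "ProbeSite",
    "GROUP_KINDS",
    "read_structure",
    "write_structure",
    "assign_charges",
    "resolve_probe",
    "load_default_library",
]

GROUP_KINDS = ("protein", "water", "ion", "substrate")

#: Residue names recognised as crystallographic / solvent water.
WATER_RESNAMES = {"HOH", "WAT", "TIP3", "TIP", "SOL", "SPC", "H2O"}
#: Monatomic ion residue names (counterions etc.).
ION_RESNAMES = {"NA", "NA+", "CL", "CL-", "K", "K+", "MG", "CA", "ZN", "SOD", "CLA"}

STANDARD_AMINO_ACIDS = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "CYM", "GLN", "GLU", "GLY", "HIS",
    "ILE", "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR",
    "VAL",
}


def classify_group(residue_name: str, het: bool = False) -> str:
    """Map a residue name onto one of the four charge groups.

    Standard amino acids are ``protein``; recognised solvent names are
    ``water``; monatomic counterions are ``ion``; anything else —
    notably bound ligands/inhibitors — is ``substrate``.
    """
    name = residue_name.upper()
    if name in WATER_RESNAMES:
        return "water"
    if name in ION_RESNAMES:
        return "ion"
    if name in STANDARD_AMINO_ACIDS and not het:
        return "protein"
    if name in STANDARD_AMINO_ACIDS:
        return "protein"
    return "substrate"


@dataclass(frozen=True)
class ResidueKey:
    """Addressing unit for per-residue decomposition."""

    chain_id: str
    residue_seq: int
    residue_name: str

    def __str__(self) -> str:  # e.g. "A/ASP17"
        return f"{self.chain_id}/{self.residue_name}{self.residue_seq}"


@dataclass
class AtomRecord:
    """One point charge: identity, position (Å) and partial charge (e).

    ``charge is None`` marks a PDB-sourced atom whose charge has not
    been assigned yet; electrostatics refuses to evaluate such atoms.
    """

    atom_id: int
    atom_name: str
    residue_name: str
    residue_seq: int
    chain_id: str
    position: np.ndarray
    charge: float | None
    group_kind: str

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise ValueError(f"position must be a 3-vector, got {self.position.shape}")
        if not np.all(np.isfinite(self.position)):
            raise ValueError(f"non-finite position for atom {self.atom_name}")
        if self.charge is not None and not math.isfinite(self.charge):
            raise ValueError(f"non-finite charge for atom {self.atom_name}")
        if self.group_kind not in GROUP_KINDS:
            raise ValueError(f"unknown group_kind {self.group_kind!r}")

    @property
    def residue_key(self) -> ResidueKey:
        return ResidueKey(self.chain_id, self.residue_seq, self.residue_name)

    @property
    def key(self) -> tuple[str, int, str]:
        """Uniqueness key (chain, residue_seq, atom_name)."""
        return (self.chain_id, self.residue_seq, self.atom_name)


@dataclass
class ChargedStructure:
    """Ordered atoms partitioned into residues."""

    atoms: list[AtomRecord]
    title: str = ""

    def __post_init__(self) -> None:
        seen: set[tuple[str, int, str]] = set()
        for a in self.atoms:
            if a.key in seen:
                raise ValueError(f"duplicate atom key {a.key}")
            seen.add(a.key)

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def charges_assigned(self) -> bool:
        return all(a.charge is not None for a in self.atoms)

    @property
    def total_charge(self) -> float:
        """Σ q_i over all atoms (requires assigned charges)."""
        if not self.charges_assigned:
            raise ValueError("structure has unassigned charges")
        return float(sum(a.charge for a in self.atoms))

    def residues(self) -> dict[ResidueKey, list[AtomRecord]]:
        """Residue partition, in first-appearance order."""
        out: dict[ResidueKey, list[AtomRecord]] = {}
        for a in self.atoms:
            out.setdefault(a.residue_key, []).append(a)
        return out

    def residue_net_charge(self, key: ResidueKey) -> float:
        atoms = self.residues().get(key)
        if atoms is None:
            raise KeyError(f"residue {key} not in structure")
        return float(sum(a.charge for a in atoms))

    def find_residues(self, name: str | None = None, seq: int | None = None) -> list[ResidueKey]:
        return [
            k for k in self.residues()
            if (name is None or k.residue_name.upper() == name.upper())
            and (seq is None or k.residue_seq == seq)
        ]

    def copy(self) -> "ChargedStructure":
        return ChargedStructure([replace(a, position=a.position.copy()) for a in self.atoms], self.title)

    def positions(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float)

    def charge_array(self) -> np.ndarray:
        if not self.charges_assigned:
            raise ValueError("structure has unassigned charges")
        return np.array([a.charge for a in self.atoms], dtype=float)


@dataclass
class ChargeLibrary:
    """residue_name → atom_name → partial charge (e), plus declared nets.

    The invariant that each residue's atom charges sum to its declared
    formal net charge (|Σq − net| ≤ 1e-6 e) is enforced at load time.
    """

    charges: dict[str, dict[str, float]]
    net_charges: dict[str, float]
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for res, table in self.charges.items():
            net = self.net_charges.get(res)
            if net is None:
                raise ValueError(f"no declared net charge for residue {res}")
            total = sum(table.values())
            if abs(total - net) > 1e-6:
                raise ValueError(
                    f"library residue {res}: Σq = {total:.6f} differs from "
                    f"declared net {net:+.1f} by more than 1e-6 e"
                )

    def __contains__(self, residue_name: str) -> bool:
        return residue_name.upper() in self.charges

    def lookup(self, residue_name: str, atom_name: str) -> float | None:
        return self.charges.get(residue_name.upper(), {}).get(atom_name.upper())

    @classmethod
    def from_csv(cls, path: str | Path) -> "ChargeLibrary":
        """Load from CSV with columns residue_name, atom_name, charge[, net_charge, note]."""
        charges: dict[str, dict[str, float]] = {}
        nets: dict[str, float] = {}
        prov: dict[str, str] = {}
        with open(path, newline="") as fh:
            rows = [r for r in csv.DictReader(filter(lambda ln: not ln.startswith("#"), fh))]
        if not rows:
            raise ValueError(f"empty charge library: {path}")
        for row in rows:
            res = row["residue_name"].strip().upper()
            charges.setdefault(res, {})[row["atom_name"].strip().upper()] = float(row["charge"])
            if row.get("net_charge") not in (None, ""):
                nets[res] = float(row["net_charge"])
            if row.get("note"):
                prov[res] = row["note"]
        for res, table in charges.items():
            nets.setdefault(res, round(sum(table.values())))
        return cls(charges, nets, prov)


@dataclass
class ProbeSite:
    """A point at which the potential is evaluated.

    Either a literal position, or a reference to a unique atom, e.g.
    the electrophilic C1 carbon of the bound substrate or Nζ of Lys33.
    """

    label: str
    position: np.ndarray | None = None
    atom_name: str | None = None
    residue_name: str | None = None
    residue_seq: int | None = None
    chain_id: str | None = None

    def __post_init__(self) -> None:
        if self.position is not None:
            self.position = np.asarray(self.position, dtype=float)
            if self.position.shape != (3,):
                raise ValueError("probe position must be a 3-vector")
        elif self.atom_name is None:
            raise ValueError(f"probe {self.label!r}: need a position or an atom reference")


def resolve_probe(structure: ChargedStructure, spec: ProbeSite) -> np.ndarray:
    """Resolve a probe site to Å coordinates.

    Atom references must match exactly one atom; ambiguity is an error
    rather than a silent first-match.
    """
    if spec.position is not None:
        return np.asarray(spec.position, dtype=float)
    matches = [
        a for a in structure.atoms
        if a.atom_name.upper() == spec.atom_name.upper()
        and (spec.residue_name is None or a.residue_name.upper() == spec.residue_name.upper())
        and (spec.residue_seq is None or a.residue_seq == spec.residue_seq)
        and (spec.chain_id is None or a.chain_id == spec.chain_id)
    ]
    if not matches:
        raise ValueError(f"probe {spec.label!r}: no atom matches {spec.atom_name}")
    if len(matches) > 1:
        raise ValueError(
            f"probe {spec.label!r}: atom reference {spec.atom_name} is ambiguous "
            f"({len(matches)} matches: {[str(a.residue_key) for a in matches[:5]]})"
        )
    return matches[0].position.copy()


# ---------------------------------------------------------------------------
# File formats
# ---------------------------------------------------------------------------

def _parse_pqr_line(line: str, lineno: int, atom_id_fallback: int) -> AtomRecord:
    """Whitespace-delimited PQR ATOM/HETATM line, charge then radius.

    Accepts both the 10-field (no chain) and 11-field (with chain)
    layouts emitted by common tools.
    """
    tokens = line.split()
    if len(tokens) == 11:
        (_rec, aid, aname, rname, chain, rseq, x, y, z, q, _rad) = tokens
    elif len(tokens) == 10:
        (_rec, aid, aname, rname, rseq, x, y, z, q, _rad) = tokens
        chain = ""
    else:
        raise ValueError(
            f"line {lineno}: malformed PQR record ({len(tokens)} fields, expected 10 or 11)"
        )
    het = line.startswith("HETATM")
    try:
        return AtomRecord(
            atom_id=int(aid) if aid.isdigit() else atom_id_fallback,
            atom_name=aname,
            residue_name=rname,
            residue_seq=int(rseq),
            chain_id=chain,
            position=np.array([float(x), float(y), float(z)]),
            charge=float(q),
            group_kind=classify_group(rname, het=het),
        )
    except ValueError as exc:
        raise ValueError(f"line {lineno}: malformed PQR record: {exc}") from exc


_ICODE_FOLD = 100


def _parse_pdb_atoms(lines: Sequence[str]) -> list[AtomRecord]:
    """Fixed-column PDB ATOM/HETATM parsing.

    Altloc policy: keep the highest-occupancy conformer of each atom,
    ties broken to the first listed. If any insertion codes occur in
    the file, every residue_seq is folded to seq*100 + icode_index
    (blank → 0, 'A' → 1, …) so keys remain plain integers.
    """
    raw: list[tuple[tuple[str, int, str, str], float, int, AtomRecord]] = []
    has_icode = any(
        ln[26].strip() for ln in lines
        if ln.startswith(("ATOM", "HETATM")) and len(ln) > 26
    )
    for lineno, ln in enumerate(lines, start=1):
        if not ln.startswith(("ATOM", "HETATM")):
            continue
        if len(ln) < 54:
            raise ValueError(f"line {lineno}: PDB record too short")
        try:
            aid = int(ln[6:11])
            aname = ln[12:16].strip()
            altloc = ln[16].strip()
            rname = ln[17:20].strip()
            chain = ln[21].strip()
            rseq = int(ln[22:26])
            icode = ln[26].strip() if len(ln) > 26 else ""
            x, y, z = float(ln[30:38]), float(ln[38:46]), float(ln[46:54])
            occ = float(ln[54:60]) if len(ln) >= 60 and ln[54:60].strip() else 1.0
        except ValueError as exc:
            raise ValueError(f"line {lineno}: malformed PDB record: {exc}") from exc
        if has_icode:
            rseq = rseq * _ICODE_FOLD + ((ord(icode) - ord("A") + 1) if icode else 0)
        rec = AtomRecord(
            atom_id=aid,
            atom_name=aname,
            residue_name=rname,
            residue_seq=rseq,
            chain_id=chain,
            position=np.array([x, y, z]),
            charge=None,
            group_kind=classify_group(rname, het=ln.startswith("HETATM")),
        )
        raw.append(((chain, rseq, aname, altloc), occ, lineno, rec))

    # altloc selection: highest occupancy per (chain, seq, atom name), tie → first
    best: dict[tuple[str, int, str], tuple[float, int, AtomRecord]] = {}
    order: list[tuple[str, int, str]] = []
    for (chain, rseq, aname, _alt), occ, lineno, rec in raw:
        k = (chain, rseq, aname)
        if k not in best:
            best[k] = (occ, lineno, rec)
            order.append(k)
        elif occ > best[k][0]:
            best[k] = (occ, lineno, rec)
    return [best[k][2] for k in order]


def read_structure(path: str | Path, format: str | None = None) -> ChargedStructure:
    """Read a charged structure from PDB or PQR.

    PQR supplies charges inline; PDB atoms carry ``charge=None`` until
    :func:`assign_charges`. Format inferred from the suffix when not
    given. Raises on empty files, malformed records (with line number)
    and duplicate atom keys.
    """
    path = Path(path)
    if format is None:
        format = path.suffix.lstrip(".").upper() or "PDB"
    format = format.upper()
    if format not in ("PDB", "PQR"):
        raise ValueError(f"unsupported format {format!r} (expected PDB or PQR)")
    lines = path.read_text().splitlines()
    if format == "PQR":
        atoms = [
            _parse_pqr_line(ln, i, atom_id_fallback=i)
            for i, ln in enumerate(lines, start=1)
            if ln.startswith(("ATOM", "HETATM"))
        ]
    else:
        atoms = _parse_pdb_atoms(lines)
    if not atoms:
        raise ValueError(f"no atoms in {path}")
    return ChargedStructure(atoms, title=path.stem)


def write_structure(structure: ChargedStructure, path: str | Path, format: str = "PQR") -> Path:
    """Write as PQR (whitespace-delimited, charge then radius column).

    Requires assigned charges; the radius column is written as 0.000
    (radii play no role in this package). Round-trips coordinates to
    1e-3 Å and charges to 1e-4 e by construction of the field widths.
    """
    if format.upper() != "PQR":
        raise ValueError("only PQR output is supported")
    if not structure.charges_assigned:
        raise ValueError("cannot write structure with unassigned charges")
    path = Path(path)
    lines = [f"REMARK  {structure.title}"] if structure.title else []
    for a in structure.atoms:
        rec = "HETATM" if a.group_kind == "substrate" else "ATOM"
        chain = a.chain_id if a.chain_id else "A"
        lines.append(
            f"{rec:<6} {a.atom_id:>5} {a.atom_name:<4} {a.residue_name:<4} "
            f"{chain:<1} {a.residue_seq:>5} "
            f"{a.position[0]:>10.4f} {a.position[1]:>10.4f} {a.position[2]:>10.4f} "
            f"{a.charge:>9.5f} {0.0:>7.3f}"
        )
    path.write_text("\n".join(lines) + "\n")
    return path


def assign_charges(structure: ChargedStructure, library: ChargeLibrary) -> ChargedStructure:
    """Return a new structure with library charges on every atom.

    Every (residue_name, atom_name) present in the structure must be in
    the library; all misses are collected and raised together — there
    are no silent zeros. Idempotent.
    """
    missing: list[str] = []
    new_atoms: list[AtomRecord] = []
    for a in structure.atoms:
        q = library.lookup(a.residue_name, a.atom_name)
        if q is None:
            missing.append(f"{a.residue_key}:{a.atom_name}")
            continue
        new_atoms.append(replace(a, position=a.position.copy(), charge=q))
    if missing:
        raise KeyError(
            f"{len(missing)} atom(s) missing from charge library: {', '.join(missing)}"
        )
    return ChargedStructure(new_atoms, structure.title)


def load_default_library() -> ChargeLibrary:
    """Load the bundled stand-in charge library.

    The shipped values are a synthetic, heavy-atom AMBER-style set whose
    per-residue sums equal formal net charges exactly; it is a
    user-replaceable placeholder, not a published force field.
    """
    here = Path(__file__).parent / "data" / "synthetic_charge_library.csv"
    return ChargeLibrary.from_csv(here)
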