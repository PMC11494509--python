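import numpy as np
import pytest

from preorg import ChargedStructure, AtomRecord
from preorg.synthetic import ToyProteinSpec, ToyResidue, make_toy_protein

THREE_ATOM_PQR = """\
ATOM      1 N    ALA A     1     0.000     0.000     0.000   0.41700   1.500
ATOM      2 CA   ALA A     1     1.500     0.000     0.000  -0.30000   1.700
HETATM    3 C1   SAL A     2     5.000     1.000     2.000  -0.11700   1.700
"""


@pytest.fixture
def three_atom_pqr(tmp_path):
    p = tmp_path / "three.pqr"
    p.write_text(THREE_ATOM_PQR)
    return p


@pytest.fixture
def toy_structure():
    """Five-residue toy protein with mixed charges, one water, one ion,
    plus a substrate atom near the origin probe."""
    spec = ToyProteinSpec(
        residues=[
            ToyResidue("ASP", -1.0, 8.0, direction=(1, 0, 0)),
            ToyResidue("LYS", +1.0, 10.0, direction=(0, 1, 0), n_atoms=3, spread="uniform"),
            ToyResidue("GLU", -1.0, 12.0, direction=(0, 0, 1)),
            ToyResidue("ARG", +1.0, 19.0, direction=(-1, 0, 0), n_atoms=2, spread="uniform"),
            ToyResidue("SER", 0.0, 15.0, direction=(0, -1, 0)),
        ],
        waters=2,
        water_shell_radius=25.0,
        ions=[("NA", 1.0, 30.0)],
    )
    s = make_toy_protein(spec, seed=42)
    s.atoms.append(
        AtomRecord(
            atom_id=len(s.atoms) + 1,
            atom_name="C1",
            residue_name="SAL",
            residue_seq=99,
            chain_id="S",
            position=np.array([0.5, 0.5, 0.5]),
            charge=0.2,
            group_kind="substrate",
        )
    )
    return ChargedStructure(s.atoms, s.title)


def library_asp_structure():
    """A single Asp with standard atom names, charged from the bundled
    library (so template-based operations have exact fixed points)."""
    from preorg import load_default_library

    lib = load_default_library()
    atoms = []
    for i, (name, q) in enumerate(sorted(lib.charges["ASP"].items()), start=1):
        atoms.append(
            AtomRecord(
                atom_id=i, atom_name=name, residue_name="ASP", residue_seq=17,
                chain_id="A", position=np.array([10.0 + 1.2 * i, 0.0, 0.0]),
                charge=q, group_kind="protein",
            )
        )
    return ChargedStructure(atoms, title="asp17")


def brute_force_decomposition(structure, probe, include=None):
    """Independent atom-loop oracle: per-residue Σ f_C q_i / r_i using
    plain Python floats and scipy's constants, no shared code path."""
    from scipy import constants as c

    f_c = c.N_A * c.e**2 / (4 * np.pi * c.epsilon_0) * 1e10 / 1e3
    include = include or {"protein", "water", "ion", "substrate"}
    per = {}
    for a in structure.atoms:
        if a.group_kind not in include:
            continue
        dx = a.position[0] - probe[0]
        dy = a.position[1] - probe[1]
        dz = a.position[2] - probe[2]
        r = (dx * dx + dy * dy + dz * dz) ** 0.5
        per[a.residue_key] = per.get(a.residue_key, 0.0) + f_c * a.charge / r
    return per
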