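"""Per-residue electrostatic field scan on a synthetic active site.

Builds a toy globular arrangement of charged residues emulating the
alternating positive/negative distance shells seen around a protease
electrophile, then runs the field pipeline at the origin probe:
per-residue decomposition, the cumulative 7–24 Å Cα shell profile,
and the contributor ranking with the 60 kJ·mol⁻¹·e⁻¹ labelling rule.
Finally, a λ-scan (0 → 1.4, step 0.2) on the dominant negative
contributor demonstrates the exact linearity of its potential
contribution — the property behind charge-decay correlation scans.

Writes results/field_scan/{decomposition,shell_profile,ranking,lambda_scan}.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from preorg import decompose_by_residue, scale_residue
from preorg.study import StudyConfig, run_field_scan
from preorg.synthetic import ToyProteinSpec, ToyResidue, make_toy_protein
from preorg.variants import DEFAULT_LAMBDA_GRID

SEED = 2024


def build_site():
    # inner shell negative (Asp-like), mid shell positive, far shell mixed
    residues = [
        ToyResidue("ASP", -1.0, 8.0, direction=(1, 0, 0), n_atoms=4, spread="uniform"),
        ToyResidue("LYS", 1.0, 9.5, direction=(0, 1, 0), n_atoms=4, spread="uniform"),
        ToyResidue("ASP", -1.0, 10.5, direction=(0, 0, 1), n_atoms=4, spread="uniform"),
        ToyResidue("ARG", 1.0, 13.0, direction=(-1, 1, 0), n_atoms=5, spread="uniform"),
        ToyResidue("GLU", -1.0, 16.0, direction=(0, -1, 1), n_atoms=5, spread="uniform"),
        ToyResidue("LYS", 1.0, 19.0, direction=(1, 1, 1), n_atoms=5, spread="uniform"),
        ToyResidue("ASP", -1.0, 22.0, direction=(-1, 0, -1), n_atoms=4, spread="uniform"),
        ToyResidue("SER", 0.0, 12.0, direction=(1, -1, 0), n_atoms=3, spread="uniform"),
    ]
    return make_toy_protein(ToyProteinSpec(residues=residues), seed=SEED)


if __name__ == "__main__":
    outdir = Path(__file__).resolve().parent.parent / "results" / "field_scan"
    site = build_site()
    cfg = StudyConfig(probe={"label": "origin", "position": [0.0, 0.0, 0.0]},
                      output_dir=str(outdir), seed=SEED)
    result = run_field_scan(cfg, structure=site)
    ranking = result["ranking"]
    print(f"total V_elec at probe: {result['decomposition'].total:+.1f} kJ/mol/e")
    print("residues above the 60 kJ/mol/e labelling threshold:")
    for key, v, cls in ranking.labelled():
        print(f"  {key}: {v:+.1f} kJ/mol/e ({cls})")

    # λ-scan on the dominant negative contributor
    dominant = next(k for k, v, c in ranking.entries if c == "negative")
    base = result["decomposition"].per_group[dominant]
    rows = []
    for lam in DEFAULT_LAMBDA_GRID:
        v = decompose_by_residue(scale_residue(site, dominant, lam),
                                 np.zeros(3)).per_group[dominant]
        rows.append({"lambda": lam, "contribution_kJ_mol_e": v})
    scan = pd.DataFrame(rows)
    scan.to_csv(outdir / "lambda_scan.csv", index=False)
    slope = np.polyfit(scan["lambda"], scan.contribution_kJ_mol_e, 1)[0]
    print(f"λ-scan on {dominant}: slope {slope:+.3f} kJ/mol/e per λ "
          f"(= V(λ=1) {base:+.3f}; linear by construction of the Coulomb sum)")
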