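"""First-hydration-shell analysis of a leaving chloride, on synthetic
water shells with constructed geometry.

Builds shells of TIP3P waters around a Cl⁻ ion — five inner-shell
waters at 3.0 Å oriented to donate one linear H-bond each plus outer
bulk-like waters — and reports the coordination number (O within
3.9 Å) and donated H-bond count (H within 2.9 Å, O–H···Cl ≥ 150°),
the diagnostics used to rationalize product-complex stabilization by
solvent.

Writes results/solvation/shell_counts.csv.
"""

from pathlib import Path

import pandas as pd

from preorg import ShellCriteria, coordination_number, count_hbonds, make_water_shell

SEED = 7

if __name__ == "__main__":
    outdir = Path(__file__).resolve().parent.parent / "results" / "solvation"
    outdir.mkdir(parents=True, exist_ok=True)
    crit = ShellCriteria()
    rows = []
    for n_inner, orientation in [(5, "H-toward-center"), (6, "H-toward-center"),
                                 (5, "H-away")]:
        s = make_water_shell(n_inner=n_inner, r_inner=3.0, n_outer=6, r_outer=6.5,
                             orientation=orientation, seed=SEED)
        cn = coordination_number(s, "CL", crit)
        hb = count_hbonds(s, "CL", crit)
        rows.append({"n_inner": n_inner, "orientation": orientation,
                     "coordination": cn, "hbonds": hb})
        print(f"{n_inner} inner waters, {orientation}: "
              f"coordination {cn}, donated H-bonds {hb}")
    pd.DataFrame(rows).to_csv(outdir / "shell_counts.csv", index=False)
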