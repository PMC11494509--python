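# preorg — electrostatic preorganization analysis for enzyme active sites

`preorg` is a Python toolkit for dissecting how a folded protein's
charge arrangement contributes to catalysis. It was built around the
inactivation of the 20S proteasome's three catalytic β-subunits by
Salinosporamide A — a system where zeroing the environment's partial
charges slows the reaction by ~10³⁵-fold — but every operation works on
any charged structure or free-energy profile.

It is aimed at computational enzymology practitioners who want the
*analysis* layer of a QM/MM preorganization study — the electrostatic
bookkeeping around the expensive simulations, not the simulations
themselves.

## What it computes

**Per-residue electrostatic potential.** The classical potential of a
fixed partial-charge distribution at a probe point r (e.g. the
electrophilic C1 of a bound inhibitor, or Nζ of a catalytic lysine),

&nbsp;&nbsp;&nbsp;&nbsp;V(r) = f_C Σᵢ qᵢ / |r − rᵢ|,&nbsp;&nbsp;&nbsp;&nbsp;f_C = N_A e²/(4π ε₀) ≈ 1389.35 kJ·mol⁻¹·Å·e⁻²,

decomposed exactly by residue, accumulated in Cα distance shells
(7–24 Å by default), and ranked with a labelling threshold
(60 kJ·mol⁻¹·e⁻¹ by default).

**Charge-variant engineering.** The alchemical experiments of a
preorganization study as declarative recipes: *atrophy* (zero every
protein/water/ion charge except a catalytic keep-set and the
substrate), selective *restoration*, charge-only point *mutation*, and
*λ-scaling* of one residue's charges (λ ∈ [0, 1.4] by default). All
operations touch charges only — geometry is never rebuilt.

**Profile kinetics.** Stationary-point free-energy profiles
(E:SalA → TS1 → E-I1 → TS2 → E-I2 → TS3 → E-PC) with step barriers,
the energetic-span rate-determining barrier (each TS measured from the
lowest preceding minimum), Eyring rates k = (k_BT/h)·e^(−ΔG‡/RT), and
rate retardation factors between variants.

**Umbrella sampling → PMF.** A self-consistent WHAM implementation
(density tolerance 10⁻³, harmonic restraints, default force constant
2500 kJ·mol⁻¹·Å⁻²) with bootstrap errors, spline-interpolated
high-level/low-level energy corrections, and exact minimax saddle
analysis on free-energy grids.

**Hydration shells.** Coordination numbers and geometric hydrogen-bond
counts around an ion (the leaving chloride analysis).

**Synthetic ground truth.** Generators for toy charged proteins at
prescribed Cα distances, Metropolis umbrella windows over analytic
potentials, exact toy free-energy grids, and oriented water shells —
every numerical claim in the test suite is certified against closed
forms or brute-force oracles.

## Worked example

```python
from preorg import (load_bundled_profiles, rate_determining_barrier,
                    retardation_factor, KineticsContext)

profiles = {(p.subunit, p.variant): p for p in load_bundled_profiles()}

for subunit in ("beta5", "beta2", "beta1"):
    b_on, ts_on = rate_determining_barrier(profiles[(subunit, "Velec(ON)")])
    b_off, ts_off = rate_determining_barrier(profiles[(subunit, "Velec(OFF)")])
    _, power = retardation_factor(b_on, b_off, KineticsContext(310.0))
    print(f"{subunit}: {b_on:.1f} ({ts_on}) -> {b_off:.1f} ({ts_off}), 10^{power}")
```

prints

```
beta5: 20.4 (TS1) -> 66.5 (TS3), 10^32
beta2: 20.5 (TS1) -> 70.0 (TS3), 10^35
beta1: 22.8 (TS3) -> 62.0 (TS3), 10^28
```

i.e. with the intact field the three subunits share near-identical
~20–23 kcal/mol rate-determining barriers; full charge atrophy raises
them to 62–70 kcal/mol, moves the bottleneck to the cyclization step
(TS3) everywhere, and corresponds to a slowdown of up to 10³⁵-fold.
Note β1: its largest *single-step* rise is TS1 (19.4 kcal/mol), but
the energetic span correctly selects TS3 (22.8 kcal/mol measured from
the reactant minimum).

The same dataset drives the command line:

```bash
preorg reproduce-tables --out-dir results/tables
preorg kinetics factor 20.5 70.0      # -> 7.8845e+34 (10^35)
```

Numbered drivers under `analysis/` run the full pipelines
(table regeneration, a synthetic field scan with a λ-scan, WHAM
recovery on analytic potentials, chloride hydration shells) and write
their tables under `results/`.

## Layout

- `src/preorg/` — the library (structures & charge libraries,
  electrostatics, variants, profiles/kinetics, WHAM, solvation,
  synthetic data, CLI, study orchestration)
- `analysis/` — numbered narrative drivers over the library
- `tests/` — unit, property and end-to-end suites
- `docs/methods.md` — models, conventions, numerical choices,
  limitations
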