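# Methods

## Scope and model

The package implements the analysis layer of an electrostatic
preorganization study: given a charged structure (atoms with Å
coordinates and partial charges in units of e, partitioned into
protein residues, waters, ions and a substrate group), it evaluates
the classical electrostatic potential at probe points, manipulates the
charge assignment alchemically, and post-processes free-energy data
(stationary-point profiles and umbrella-sampling windows) into
kinetic statements. It deliberately contains no electronic-structure
or molecular-dynamics machinery: the expensive QM/MM objects
(trajectories, optimized stationary structures, free-energy surfaces
of a real enzyme) enter only as transcribed numbers or as synthetic
stand-ins with known answers.

## Electrostatic potential

V(r) = f_C Σᵢ qᵢ/|r − rᵢ| with f_C = N_A e²/(4π ε₀) evaluated from
scipy's CODATA constants (≈ 1389.3546 kJ·mol⁻¹·Å·e⁻²), giving V in
kJ·mol⁻¹·e⁻¹ for q in e and r in Å. Design points:

- **No cutoff, no switching function.** The potential is an exact sum
  over the included scope; distance-based truncation is exactly the
  artifact the shell profiles are designed to expose. (Switching
  functions belong to the MD force evaluation, not to this analysis.)
- **Optional uniform relative dielectric** (default 1.0, vacuum) that
  simply divides f_C. No Poisson–Boltzmann screening.
- **Decomposition is exact bookkeeping:** per-residue entries are
  partial sums of the same Coulomb series, so Σ per-residue = total to
  rounding (asserted at 1e-8 relative in tests). Linearity in charges
  and 1/r decay are exact and used as property tests.
- **Shell profiles are cumulative** ("everything within radius R"),
  under the Cα-to-probe distance convention: a residue enters the
  profile at the radius of its Cα, with its *entire* contribution.
  Waters, ions and substrate have no Cα and are excluded from
  profiles (reported separately in decompositions). Default scan 7 to
  24 Å, 1.0 Å steps.
- **Ranking threshold** default 60 kJ·mol⁻¹·e⁻¹ in absolute value;
  sign classes are `negative` / `positive` / `negligible`. A negative
  potential stabilizes accumulated positive charge (e.g. on a
  nucleophile-activating lysine); interpretation as
  stabilizing/destabilizing therefore depends on the probed charge and
  is left to the caller.

## Structures, formats, charge library

PQR (whitespace-delimited, charge then radius; 10- or 11-field rows)
carries charges inline; PDB (fixed-column ATOM/HETATM) yields
structures whose atoms are explicitly *uncharged* until a library
assignment runs — there are no silent zero charges, and electrostatics
refuses unassigned structures. Parsing is strict: malformed records
raise with line numbers, duplicate (chain, residue, atom) keys raise.
Altloc policy: highest occupancy wins, ties to the first conformer.
Insertion codes are folded into the integer residue key
(seq×100 + icode index) only when a file contains any. PQR output
writes 4 decimals on coordinates and 5 on charges, so read∘write
round-trips to 1e-3 Å / 1e-4 e. The package's PQR reader is
cross-checked against MDAnalysis in the test suite.

The bundled charge library (`data/synthetic_charge_library.csv`) is a
**synthetic stand-in**: heavy-atom charges in an AMBER-like layout
whose per-residue sums hit the formal net charges exactly (enforced at
load to 1e-6 e), plus TIP3P water. It exists so that
assignment/mutation plumbing is fully exercisable; no scientific
conclusion in this package depends on its specific values, and users
with a real force field should replace it (same CSV schema).

## Charge variants

All variant operations are charge-only and return new structures;
coordinates, atom identities and the residue partition are invariant
(mirroring the convention that Lennard-Jones parameters stay in place
so the environment is still excluded-volume, just electrostatically
silent).

- **Atrophy** zeroes protein, water and ion charges except a keep-list;
  the substrate group always keeps its charges (it is the reacting
  system). Idempotent.
- **Restoration** copies original charges back for listed residues or
  the `waters` sentinel; restoring everything reproduces the original
  bit-exactly.
- **Mutation** is template-based and electrostatic-only: atoms shared
  by name take target charges, source-only atoms are zeroed, and the
  summed charge of target-template atoms with no coordinates in the
  source folds onto the last matched template atom so the residue
  lands exactly on the target's formal net charge. This is a
  deliberate, documented idealization — side-chain geometry is never
  rebuilt, so the spatial distribution of a "grown" side chain
  (e.g. Asp→Glu) is approximated by its stump.
- **λ-scaling** multiplies one residue's charges by λ ≥ 0 (λ > 1
  models unnatural charge amplification). Scaling composes
  multiplicatively and the residue's potential contribution is exactly
  linear in λ — the property that underwrites charge-decay
  correlation scans.
- **Recipes** compose in the fixed order atrophy → restore → mutate →
  λ-scale, serialize to YAML, and carry canonical labels
  (`Velec(ON)`, `Velec(OFF)`, `Velec(D17&WAT)`, `D17A`, `λ=0.8`).

## Profiles and kinetics

Profiles are ordered stationary points with cumulative Gibbs energies
in kcal/mol, starting at a zero minimum and alternating
minimum/TS (validated on construction). The bundled dataset
(`data/sala_profiles.csv`) transcribes published QM/MM profiles for
the proteasome–Salinosporamide A reaction — β5/β2/β1 under
unperturbed (`Velec(ON)`), atrophied (`Velec(OFF)`) and
Asp17-restored (`Velec(D17)`) electrostatics — and is marked as a
transcription, not a computation of this package.

- **Rate-determining barrier = energetic span:** for each TS, its span
  is G(TS) minus the lowest *preceding* minimum; the profile's maximum
  span (ties to the earliest TS) is rate-determining. This matters: a
  per-step maximum would misidentify profiles where an intermediate
  dips below the reactant (β1: TS1 rise 19.4 but span 22.8 at TS3).
- **TST:** k = (k_B T/h)·exp(−ΔG‡/RT), default T = 310 K (the 37 °C
  of the underlying inactivation-rate measurements); R, k_B, h from
  CODATA. Retardation factors are reported both as a ratio and a
  rounded power of ten; the log10 is computed directly so extreme
  ΔΔG cannot overflow.
- **Step tables** tabulate TS3 and E-PC relative to a reference
  minimum (default E-I2). Regeneration of the published table from the
  transcribed profiles reproduces 17 of 18 regenerable cells within
  0.05 kcal/mol (transcription rounding). Two caveats are flagged
  rather than hidden: the published β5-unperturbed TS3 cell (8.9) is
  inconsistent with its own source profile (18.8 − 9.1 = 9.7) and is
  reported as a mismatch; the D17&WAT column has no cumulative source
  profile and is reference-only (`no-source-profile` status).

## Umbrella sampling and WHAM

Standard self-consistent WHAM on a regular 1D/2D grid whose bin
centers double as PMF nodes (no separate binning). Iteration:
P(b) = Σ_l n_l(b) / Σ_l N_l f_l c_l(b), f_l⁻¹ = Σ_b c_l(b) P(b),
with per-window log-scaled bias factors for numerical safety.
Convergence metric: maximum relative change of the unbiased density
over occupied bins, threshold 10⁻³ by default (the tolerance named
for the production surfaces this mirrors; the metric itself is this
package's choice). Non-convergence raises with the residual; bins
never visited stay masked (NaN) and are never interpolated. For a
single unbiased window WHAM reduces exactly to the histogram
estimator, which is asserted in tests. PMFs are reported in kcal/mol
(internal kJ/mol, ×1/4.184), min-shifted to zero over sampled nodes.

**Error model.** The underlying study publishes no error bars, so the
package supplies a bootstrap: windows' production samples are
resampled with replacement, WHAM is rerun (default 50 replicates,
seeded), and the per-node standard deviation across replicates is the
SE. The synthetic Metropolis generator *thins* its chains (one sample
kept per 5 sweeps by default, after a 10%-of-samples burn-in during
which the proposal step is tuned to 30–60% acceptance), so that the
iid resampling assumption is approximately valid; without thinning the
bootstrap understates the error of an autocorrelated chain.

**Synthetic certification.** WHAM correctness is certified on analytic
ground truth: a flat potential (recovered PMF flat within 3× SE) and
a quartic double-well U = b(x² − c²)²/c⁴ (barrier b at x = 0,
minima at ±c). The certification uses the production force constant
2500 kJ·mol⁻¹·Å⁻², which makes window widths σ = √(RT/k) ≈ 0.032 Å —
windows must therefore be spaced ≈ 0.05 Å for histogram overlap, and
the desk-scale runs use 65 windows × 1200 samples on [−1.6, 1.6]
(about 10⁵ grid evaluations, seconds of runtime). Barriers are read
at the generator's *declared* stationary-point nodes; locating the
minimum on the noisy grid itself would bias the barrier upward by the
extreme-value statistics of the noise.

**Spline corrections.** High-level-minus-low-level energy differences
on a coarse regular node grid are interpolated (scipy interpolating
splines, default cubic, order capped by node count) and added to the
low-level surface; the interpolant passes through the nodes, so the
corrected surface equals the high-level energy there exactly, and an
order-1 correction reproduces any affine ΔE field exactly.
Extrapolation beyond the node hull raises — corrections are only
valid inside the region where both levels were evaluated.

**Stationary points on grids.** Minima are nodes below all sampled
neighbors (8-connectivity in 2D; exact ties resolve to the lower flat
index). The saddle energy between two minima is the exact minimax
path cost, computed by activating nodes in ascending energy and
merging components with union–find — the activation energy at which
two minima's components join is their saddle. This is exact (no path
heuristics) and is cross-checked against brute-force enumeration over
all simple paths on small grids. Masked gaps that disconnect minima
raise rather than silently bridging.

## Hydration shells

Coordination number: waters whose O lies within 3.9 Å of the center
(the conventional Cl⁻···O first-shell cutoff). Donated H-bonds: water
O–H groups with H within 2.9 Å of the center and an O–H···center
angle (at H, 180° = linear) of at least 150°. All three criteria are
parameters; the defaults are standard chloride-hydration conventions,
and no quantitative conclusion of the package depends on them. Waters
lacking explicit hydrogens are an error for H-bond counting — the
geometry cannot be inferred.

## Synthetic data: what it does and does not emulate

The generators provide *controlled* analogues, not realism:

- Toy proteins place point-charge "residues" (Cα plus optional
  satellite atoms on fixed icosahedral offsets) exactly at prescribed
  Cα distances, so shell profiles step at exactly known radii and the
  alternating-sign shell structure of a real active site can be
  scripted. There is no backbone, no excluded volume beyond a 0.5 Å
  overlap check, no dielectric heterogeneity.
- Umbrella windows are Metropolis samples of U(x) + harmonic bias at
  310 K — they share the statistics WHAM assumes, not the dynamics of
  MD. Passing tests certify the estimator, not any claim about real
  sampling convergence.
- Water shells have idealized rigid-water geometry with orientation
  rules chosen to make H-bond counts exact by construction.

Consequently, green tests demonstrate correctness of the arithmetic,
estimators and bookkeeping under known conditions; they say nothing
about force-field quality, sampling adequacy or conformational
response in a real enzyme — all explicitly out of scope.

## Numerical choices and degenerate inputs

- Coulomb singularity: any included atom within 1e-6 Å of the probe
  raises, naming the atom.
- WHAM guards: empty window histograms raise; windows sharing no
  occupied bins with any other window warn (masked gaps likely);
  denominators are floored at 1e-300 to avoid spurious division
  warnings during early iterations.
- Profile validation rejects non-alternating or non-zero-anchored
  profiles rather than reinterpreting them.
- Retardation powers of ten use round-half-even on log10.
- All randomness flows through `numpy.random.default_rng(seed)`; every
  generator is a pure function of (spec, seed), and manifests written
  by the pipelines record seeds and input hashes.

## Known limitations

- Charge-only mutation ignores conformational relaxation and places
  grown side-chain charge on the stump's last matched atom; this is
  the intended idealization for field-variation scans, not a
  structure-prediction method.
- The bundled charge library is a labelled synthetic stand-in.
- WHAM is 1D/2D only (the analyses it serves are 1D/2D); no MBAR.
- Shell profiles require Cα atoms; fully coarse-grained inputs must
  name their reference atoms CA to participate.
- The probe/inclusion conventions behind some published absolute
  potential values are under-specified upstream; absolute V values on
  real structures therefore depend on user configuration, while all
  *relative* statements (decompositions, scans, variant differences)
  are exact.
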