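# Methods

## Scope and model

`shiftkit` automates the post-processing side of DFT NMR chemical-shift
prediction for small organic molecules. The electronic-structure step
itself (GIAO isotropic shieldings from an NWChem-style engine) is treated
as an external black box: the package renders input decks, parses output
text, and does everything downstream — referencing, empirical scaling,
error statistics, environment-resolved error breakdowns, and Boltzmann
conformer weighting. A deterministic mock engine stands behind the same
runner contract as a real executable, so the full workflow is exercisable
and reproducible without a quantum-chemistry installation.

### Shift referencing

A computed isotropic shielding σ_i becomes a chemical shift via a
reference compound computed at the same level of theory:

    δ_i = σ_ref − σ_i + δ_ref

σ_ref per nucleus is the arithmetic mean over all atoms of that element
in the reference molecule — equivalent-nuclei averaging, chosen because
the reference's own per-nucleus mean shift is then identically zero when
δ_ref = 0 (the TMS convention for ¹H/¹³C). Any molecule with the
requested nuclei and known shifts can serve as reference.

### Error statistics

For paired experimental/computed shifts:

- MAE  = mean|δ_exp − δ_calc|
- RMSE = √(mean(δ_exp − δ_calc)²)
- MAXAE = max|δ_exp − δ_calc|
- CMAE = mean|δ_exp − (δ_calc − intercept)/slope|

MAE ≤ RMSE ≤ MAXAE holds on every non-empty pairing (power-mean
inequality); the test suite checks it as a property and checks all four
formulas against an independent elementwise evaluation to 1e−12.

### Empirical scaling

Systematic method error is removed by OLS of the computed quantity on
the experimental shift, `calc ≈ slope·δ_exp + intercept`, inverted as
`scaled = (calc − intercept)/slope`. Two modes share this single
(slope, intercept) meaning: *shift-based* regresses computed shifts
(slope near +1 for a reliable method) and *shielding-based* regresses
raw shieldings (slope near −1, since shielding falls as shift rises).
¹H and ¹³C are always fit separately; no outlier rejection is applied
before fitting. Atoms without experimental values are excluded from
pairings.

Model stability is assessed by Monte Carlo cross-validation: repeated
random train/test splits (default 80/20, 1000 repetitions, seeded),
refitting on each training fold and scoring the scaled test fold's MAE.
On well-conditioned data the fold parameters match the full-data fit.

### Boltzmann conformer weighting

Populations follow w_i ∝ exp(−(G_i − G_min)/RT) with
R = 1.987204×10⁻³ kcal·mol⁻¹·K⁻¹, default T = 298.15 K (room
temperature; the value is configurable since studies rarely state it).
Min-shifting the energies before exponentiating makes weights invariant
to the energy zero and overflow-safe for spreads of hundreds of
kcal/mol. Ensemble-averaged shifts are the weight-convex combination of
per-conformer shift tables aligned by atom index (one shared topology is
assumed and validated by element-sequence equality). The two-state
worked example — a 1.99 kcal/mol chair–chair gap at 298.15 K — gives a
3.4% minor population, 3% at integer rounding, the familiar
axial/equatorial split of methylcyclohexane.

### Environment-resolved errors

Hybridization is assigned from bond orders (any double or aromatic bond
→ sp², triple or cumulated doubles → sp, else sp³) rather than from
geometry angles, so it is deterministic from a Molfile. Ring membership
comes from cycle detection; hydrogen atoms are grouped by their single
heavy-atom neighbor (H–C, H–N, H–O). Attachment groups deliberately
overlap — a carbon bonded to both H and Cl contributes its error to
C–H and C–Cl — so attachment counts sum to more than the atom count;
hybridization groups partition the carbons exactly once.

## File conventions and numerical choices

- Atom indices are 1-based everywhere; atom order is frozen at record
  creation and preserved through decks, outputs, and Molfiles.
- Per-atom results ride in SDF data fields ISOTROPIC_SHIELDINGS,
  CHEMICAL_SHIFTS, SCALED_SHIFTS, EXPERIMENTAL_SHIFTS: one
  whitespace-separated value per atom, `NA` for absent. ppm values print
  to 4 decimals, coordinates to 6; round trips are exact at this printed
  precision.
- Deck templates use named placeholders ({geometry}, {basis}, {xc},
  {cosmo}, {tasks}); the COSMO dielectric table (chloroform 4.81, water
  78.4, DMSO 46.7, methanol 32.6) is overridable per method.
- 3D embedding uses distance geometry refined with MMFF94 under a fixed
  default seed, so "rough 3D structures" are reproducible.
- The mock engine derives shieldings from a SHA-256 hash of element and
  printed coordinates around per-element baselines (H ≈ 31.5 ppm,
  C ≈ 185 ppm): deterministic across processes and runs, distinct for
  distinct geometries, with no physical content beyond the baseline.
- Energy unit bridge: 1 Hartree = 627.509474 kcal/mol.

## Synthetic study conditions

The synthetic generator emulates the statistical structure of a
benchmark shift dataset, not its physics: experimental shifts are
uniform on the nucleus range (¹H [0, 17] ppm, ¹³C [0, 220] ppm), the
computed column is a near-unity line (default slope 1.02) plus Gaussian
noise (0.3 ppm ¹H, 4 ppm ¹³C — matching realistic MAE magnitudes), and
conformer ensembles are two labeled groups with an exact group-mean
free-energy gap. Passing tests therefore demonstrate correct
referencing, fitting, inversion, weighting, and plumbing under known
truth; they say nothing about the accuracy of any DFT method on real
molecules, which depends entirely on the engine behind the runner
contract.

Problem sizes used by the test suite and the acceptance script — 500
paired values per nucleus, 200 cross-validation repetitions, 80-conformer
ensembles, and the 3-molecule × 8-method mock pipeline — were chosen as
the smallest sets on which the estimators' sampling noise is negligible
relative to the checked tolerances.

## Known limitations

- The mock engine's shieldings carry no conformational or electronic
  physics; only a real engine behind `ExternalRunner` produces
  scientifically meaningful shifts.
- Bond perception from bare XYZ geometries can fail for exotic species;
  such records still flow through the pipeline but without environment
  classification.
- Single-reference scheme only (no per-hybridization multi-reference
  standards); linear scaling only.
- Free energies are taken as printed by the engine (or supplied
  directly); no internal thermochemistry is computed.
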