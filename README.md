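# shiftkit

Automated NMR chemical-shift calculation pipeline for small organic
molecules, aimed at standards-free metabolite identification: when no
authentic chemical standard exists, computed ¹H/¹³C chemical shifts are
the comparison library. `shiftkit` takes a list of molecules (InChI
strings or XYZ files) and a matrix of DFT methods
(functional × basis set × solvent × tasks), renders NWChem-dialect input
decks, runs them through an engine — a real executable or the built-in
deterministic mock — and turns the parsed isotropic shieldings into
referenced, scaled, error-annotated chemical shifts written back into
MDL Molfiles.

The core relations:

- **Referencing** δ_i = σ_ref − σ_i + δ_ref, with TMS (δ_ref = 0) as
  the default ¹H/¹³C reference; σ_ref averages equivalent nuclei.
- **Error metrics** MAE, RMSE, MAXAE, and CMAE — the mean absolute
  error after inverting a fitted linear correction.
- **Empirical scaling** OLS of computed shifts (or raw shieldings) on
  experimental shifts, calc ≈ slope·δ_exp + intercept, applied as
  scaled = (calc − intercept)/slope; Monte Carlo cross-validation
  quantifies its stability.
- **Conformer weighting** Boltzmann populations
  w_i ∝ exp(−ΔG_i/RT) and population-weighted ensemble shifts.
- **Environment statistics** per-group error reports by carbon
  hybridization (sp/sp²/sp³), bonded-neighbor element (C–H, C–Cl, H–O,
  …) and ring membership.

## Worked example

Weight the two chair conformers of methylcyclohexane, whose computed
free-energy gap is 1.99 kcal/mol, at room temperature:

```python
>>> from shiftkit import boltzmann_weights
>>> minor, major = boltzmann_weights([1.99, 0.0], temperature=298.15)
>>> print(f"axial {100*minor:.1f}% / equatorial {100*major:.1f}%")
axial 3.4% / equatorial 96.6%
```

— the familiar ~3% axial / 97% equatorial split.

Run the full mock pipeline on three tutorial molecules (methanol,
methyl isothiocyanate, nitromethane) against the stock 4-functional ×
2-basis method matrix:

```sh
$ printf '%s\n' \
    'InChI=1S/CH4O/c1-2/h2H,1H3' \
    'InChI=1S/C2H3NS/c1-3-2-4/h1H3' \
    'InChI=1S/CH3NO2/c1-2(3)4/h1H3' > molecules.csv
$ shiftkit prep --molecules molecules.csv --methods methods.csv --outdir out
prepared 24 decks under out
$ shiftkit run --molecules molecules.csv --methods methods.csv --outdir out
collected 24/24 pairs under out
```

Each of the 24 (molecule, method) directories now holds the input deck,
the engine output, and an augmented Molfile whose
`ISOTROPIC_SHIELDINGS` and `CHEMICAL_SHIFTS` data fields carry one ppm
value per atom in the original atom order. Given experimental shifts
(`--exp-dir`), `shiftkit score` adds per-nucleus error reports, fitted
scaling models, optional cross-validation, and environment-grouped
error tables.

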