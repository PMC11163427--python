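# stericfit

Fitting and transferability analysis of short-range repulsion between
topological atoms.

When two molecules approach, the quantum theory of atoms in molecules
(QTAIM) partitions their electron density into non-overlapping topological
atoms, and the interacting-quantum-atoms (IQA) decomposition assigns each
atom an intra-atomic (self) energy.  The change of that energy on
dimerization — the **deformation energy** E_def — behaves as short-range
repulsion and can be fitted to the repulsive part of the Buckingham
(Born–Mayer) potential,

    E(r) = A·exp(−B·r),

with A (kJ mol⁻¹) the magnitude and B (Å⁻¹) the decay rate of the
repulsion.  Part of E_def, however, is charge transfer rather than steric
hindrance; the grand-canonical correction E_CT = IP·ΔQ (ΔQ = N − N⁰, the
fractional electron-population shift) removes it, defining the **steric
energy** E_ST = E_def − E_CT.  `stericfit` implements this analysis end to
end for dimer distance scans:

* ingest per-atom intra-atomic energies and electron populations (CSV scan
  tables; hartree or kJ/mol),
* decompose into per-pair E_def / E_CT / E_ST curves (floor or ceiling
  convention for the integer electron count indexing the ionization energy),
* fit A·exp(−B·r) by Levenberg–Marquardt, with pathology detection
  (negative or non-exponential curves), initial-guess-grid stability checks
  and fit-range sensitivity tables,
* quantify cross-molecule parameter **transferability**,
  RMSE(X→Y) = √(1/N_Y · Σᵢ (E^Y(rᵢ) − A_X e^{−B_X rᵢ})²), as molecules ×
  molecules matrices with summaries against the 4 kJ mol⁻¹ chemical-accuracy
  threshold,
* characterize A–B parameter relationships (exponential and piecewise
  exponential-linear), substitution trends, and correlations with external
  molecular properties,
* build face-to-face dimer scan geometries (multi-frame XYZ) from a monomer,
* and generate synthetic scan suites with known ground truth — repulsion,
  charge transfer, polarization-dip pathology, noise — so the whole pipeline
  is testable without quantum-chemistry runs.

It is aimed at force-field developers and quantum-chemical-topology
practitioners who have (or plan) IQA dimer scans and want reproducible
repulsive parameters plus a quantitative answer to "do these parameters
carry over to other molecules?".

## A worked example

`examples/02_charge_transfer_correction.py` generates one synthetic carbonyl
scan in which 0.05 electrons flow from O to C with decay 1.5 Å⁻¹, then fits
both energy kinds:

```
C pair (truth A = 50000, B = 2.5):
  deformation fit: A =   48439.9  (-3.12% off)
  steric fit:      A =   50000.0  (+5.34e-11% off)
O pair (truth A = 60000, B = 2.6):
  deformation fit: A =   60309.8  (+0.52% off)
  steric fit:      A =   60000.0  (-7.06e-11% off)
```

The raw deformation fit is biased — strongly for carbon, whose ionization
energy (~1086 kJ mol⁻¹) amplifies the population shift — while the
charge-transfer-corrected steric fit returns the exact ground truth.  The
other scripts in `examples/` walk through plain parameter recovery,
transferability matrices, A–B relationship fits and scan-geometry
construction, each printing the numbers it computes and what they mean.

The same stages are scriptable from the shell:

```bash
stericfit simulate --n-molecules 26 --seed 0 --out scans/
stericfit run-all --n-molecules 26 --seed 0 --out run/
stericfit build-scan monomer.xyz --rmin 2.0 --rmax 4.6 --step 0.1 --out scan.xyz
```

`run-all` writes scan tables, decomposed curves, `fits.csv`, transferability
matrices with summaries in both diagonal conventions, A–B relation
coefficients and a run report (seed and conventions included) — all
byte-reproducible for a given seed.

## Data formats

* **Scan table** (CSV): `molecule_id, atom_label, separation_angstrom,
  e_intra_dimer, e_intra_monomer, n_dimer, n_monomer`, with a
  `# energy_unit: hartree|kJ/mol` header line.
* **Ionization table** (CSV): `element, electron_count_upper, ip_kj_per_mol`;
  a built-in table from literature atomic ionization energies and electron
  affinities covers H, C, N, O, F.
* **Geometries**: standard (multi-frame) XYZ.

See `docs/methods.md` for the model, conventions and numerical choices.
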