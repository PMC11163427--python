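# Methods

## The model

`stericfit` analyses short-range repulsion between topological (QTAIM)
atoms.  Its inputs are per-atom *intra-atomic* energies and electron
populations from an IQA decomposition of homodimer distance scans: for each
molecule, a face-to-face dimer at separations r (Å) plus the isolated
monomer.  Three energies are derived per atom pair:

* **Deformation energy** — per atom, E_def = E_intra(dimer) −
  E_intra(monomer); per pair, the sum over the two approaching atoms.
  Repulsion appears here as a mutual, additive deformation of the two atoms
  rather than a direct interatomic term.
* **Charge-transfer energy** — the grand-canonical linear estimate of the
  energy change caused by a fractional population shift ΔQ = N − N⁰:
  E_CT = IP·ΔQ, with the ionization energy evaluated at the integer electron
  count of the monomer reference plus one.  Because |ΔQ| < 1 in the systems
  handled here, a single IP per atom applies across a scan.
* **Steric energy** — E_ST = E_def − E_CT, the repulsion that remains after
  removing charge-transfer effects.  The identity E_ST + E_CT = E_def is
  enforced pointwise (< 1e−9 kJ/mol) by construction.

Each pair curve is fitted to the repulsive Buckingham (Born–Mayer) term

    E(r) = A·exp(−B·r),        A in kJ/mol, B in 1/Å,

by unweighted Levenberg–Marquardt least squares on the linear energy scale
(scipy's MINPACK `lm` with an analytic Jacobian).  A sets the magnitude of
the repulsion, B its decay rate.  The attractive −C/r⁶ part of the full
Buckingham potential is out of scope: only repulsion is analysed.

Transferability of fitted parameters is quantified as

    RMSE(X→Y) = sqrt( (1/N_Y) Σᵢ (E^Y(rᵢ) − A_X·exp(−B_X·rᵢ))² ),

molecule X's parameters against molecule Y's exact energy data for the same
atom type.  The n×n grid (rows = parameter source, columns = data target) is
generally asymmetric; its diagonal equals each molecule's own fit RMSE.  A
transfer below 4 kJ/mol (≈ 1 kcal/mol, chemical accuracy) counts as
transferable.

## Fitting protocol and numerical choices

* **Initial guess**: log-linear regression of ln E on r when all energies
  are positive, else (A₀, B₀) = (10⁴ kJ/mol, 3 Å⁻¹).  As a stability
  diagnostic (`initial_guess_grid_stability`), the fit can be restarted from
  every point of the grid A₀ ∈ [10³, 10⁵] step 1000, B₀ ∈ [1, 10] step 0.1
  (9,100 starts); converged optima agreeing to 1e−6 relative are clustered,
  and exactly one cluster means the solution is initialization-independent.
* **RMSE** uses 1/n (no degrees-of-freedom correction): fit RMSEs are
  compared across curves with different n, and transfer RMSEs use 1/N_Y, so
  the plain mean is the only internally consistent choice.
* **Pathology screening** before fitting: `negative_energy` if any point is
  ≤ 0 (a repulsive energy cannot be attractive), else `non_exponential` if
  the regression of ln E on r has R² < 0.99 or a non-negative slope.  The
  0.99 threshold is this package's convention for what a practitioner would
  call visibly non-exponential; it is configurable.  Flagged curves are
  still fitted when possible (the flag is recorded on the fit) but are
  excluded from transferability matrices.  When a per-atom-type fit range is
  configured, screening is restricted to that window — narrowing the scan
  range is exactly how problematic regions are kept out of the analysis.
* **Non-convergence** or a fitted A ≤ 0 is recorded as pathology `failed`,
  never raised mid-pipeline.
* **Rounding mode** for the IP lookup: `floor` (the primary convention,
  [N] = floor(N⁰)) or `ceiling`, exposed because rounding the other way
  sometimes fits better in practice.  Neither is hard-coded per molecule.
* **Chemically equivalent atoms**: the lowest atom index is selected,
  deterministically.
* **Degenerate inputs**: fits need ≥ 3 points; two exact points admit the
  closed form B = ln(E₁/E₂)/(r₂−r₁), A = E₁·e^{B·r₁}, used as a test oracle,
  not as a fitting path.

## A–B relationships

"Exponential relationship" between fitted parameters is operationalized as
linearity of ln A in B (OLS; R² reported on the log scale, since an
exponential is exactly a straight line there).  The piecewise alternative is
log-linear below a breakpoint B\* and linear in (B, A) above it, continuous
at B\*, with B\* chosen by exhaustive search over observed B values
minimizing total squared error in A.  The candidate set includes the largest
observed B, where the model collapses to the single exponential, so the
piecewise SSE never exceeds the exponential SSE (nested models).
Substitution-trend tables report strict monotonicity verdicts per parameter
column; molecular properties for correlation (dipole moments, atomic
volumes) are external inputs — computing them needs wavefunctions, which are
out of scope.

## The synthetic generator

The generator replaces the quantum-chemistry stage (geometry optimization,
dimer single points, basin integration) with a forward model whose ground
truth is known exactly, so every downstream stage is testable:

* Each synthetic molecule is a minimal carbonyl — one C (charge acceptor)
  and one O (donor) — in an exactly symmetric homodimer, so one set of atom
  rows represents both monomers and pair quantities are doubled per-atom
  values.
* Repulsion: the pair X···X′ contributes A·exp(−B·r), split half/half
  between the atoms.  Defaults A_C = 5×10⁴, B_C = 2.5, A_O = 6×10⁴,
  B_O = 2.6; suites sample A ∈ [2×10⁴, 10⁵] kJ/mol and B ∈ [2.0, 2.8] Å⁻¹,
  the range spanned by fitted carbonyl-atom values.
* Charge transfer: ΔN(r) = q0·e^{−b_q·r} electrons move O → C within each
  monomer (population conserved in the donor/acceptor pair), shifting each
  atom's energy by IP·ΔN with the same IP the correction uses — so the
  correction is exact on synthetic data and the steric fit recovers truth to
  numerical precision, while the deformation pair curve carries 2·IP·ΔN of
  contamination.  |q0| < 0.5 keeps |ΔN| < 1.  The linear-in-ΔN energy
  response mirrors the grand-canonical assumption of the correction itself;
  that is deliberate, giving a sharp acceptance surface.
* Polarization dip: an optional second, stronger CT-like channel on the
  acceptor — energy −(P/2)·e^{−B_p·r} with matching population shift
  −(P/2·IP)·e^{−B_p·r} — reproduces the real-data pathology in which the raw
  deformation energy turns negative/non-exponential while the corrected
  steric energy stays cleanly repulsive.  The dip channel's counter-charge
  is imagined on spectator atoms the scan table does not resolve (forcing it
  onto the O would require |ΔN| > 1 given oxygen's small grand-canonical
  slope).  B_p < B is required so the contamination has a different decay
  than the repulsion.
* Noise: i.i.d. Gaussian on each intra-atomic energy, default σ = 0.5
  kJ/mol.  Real scans have spatially structured basin-integration error, not
  i.i.d. noise; σ is a free parameter precisely because that error magnitude
  is not well characterized.
* Ionization energies default to literature atomic IPs/EAs (kJ/mol): any
  positive values would do for the synthetic algebra, but physical ones keep
  magnitudes realistic (e.g. carbon's ~1086 kJ/mol makes a 0.05 e shift bias
  the deformation A by a few percent).  Default monomer populations sit just
  below the integer count (C 5.7, O 8.7) so floor-mode lookups land on
  physical entries; an oxygen ceiling-mode lookup correctly fails, because
  the required (O, 10) entry would be the detachment energy of O²⁻, which is
  unbound.

What passing synthetic tests does **not** show: that real AIMAll-derived
curves are exactly exponential, that real charge transfer is exactly linear
in ΔN, or that real noise is Gaussian.  The generator validates the
*machinery* (decomposition identities, fit correctness, exclusion logic,
matrix algebra), not the physics of any particular molecule.

## Scan geometry construction

Dimer scans are built by translating a rigid copy of the monomer along the
unit normal of the carbonyl sp² plane (least-squares SVD plane through the
carbonyl C, O and the two substituents on C), centred on the carbonyl
carbon, over r = r_min + k·step computed by index (no floating-point drift;
default 2.0–4.6 Å step 0.1, 27 frames).  The second monomer is a pure
translated copy, keeping the carbonyls parallel; an optional flag rotates it
180° about the axis.  Methyl groups can be rotated rigidly about their local
C–C axis through an exhaustive 1° torsion grid to maximize the summed
distances between corresponding hydrogens — the deterministic, cheap way to
delay H···H overlap at short separations.  Frames with any intermonomer
distance < 0.5 Å raise an overlap error naming the offending atoms.

## Pipeline conventions

All energies are kJ/mol internally (1 hartree = 2625.4996394799 kJ/mol,
converted once at file boundaries) and all distances Å.  Scan tables and
matrices are written with shortest-round-trip decimal formatting in a
canonical sort order, so outputs are byte-reproducible given the seed and
re-ingestion is bit-exact.  All stochasticity lives in the generator; every
downstream stage is deterministic.  Transfer summary statistics are computed
in both conventions — off-diagonal only (default: only off-diagonal cells
are cross-molecule transfers) and all entries — and both are written to
`transfer_summaries.csv`.

## Problem sizes

The default validation suites are sized for a laptop: 200-curve recovery
suites, a 9,100-start initial-guess grid on one curve, a 50-molecule
pathology suite, and a 26-molecule end-to-end pipeline run; together they
complete in well under a minute.

## Known limitations

* Native AIMAll `.int`/`.sum` or Gaussian `.wfn` outputs are not parsed;
  converting them to the documented scan-table CSV is left to the user.
* The grand-canonical correction is linear by assumption; curvature in the
  true E(N) relation (hardness) is not modeled, in the generator or the
  correction.
* Transferability on fully random synthetic suites is poor by construction
  (each molecule's true parameters are drawn independently); meaningful
  transfer percentages require structured parameter families or real data.
* Nitrogen and other heteroatoms are supported by the machinery but the
  default ionization table only covers H, C, N, O, F.
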