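# Methods

## Thermodynamic cycle and reference electrode

Every redox couple is stored as a reduction, oxidized form + e⁻ →
reduced form, so the reaction Gibbs energy is always
Δ_rG = G(reduced) − G(oxidized) with the free energy of the electron
set to zero. Per-species free energies are consumed, not computed:
G(s) = E_s + G_corr, where E_s is the solution-phase electronic energy
and G_corr the thermal correction to the Gibbs free energy (ideal-gas /
rigid-rotor / harmonic-oscillator conditions, T = 298.15 K metadata).

Potentials vs the saturated calomel electrode follow

    E = −Δ_rG / n_e − E_SCE_abs − E_L

with E_SCE_abs = 4.522 V (absolute potential of the aqueous SCE) and
the intersolvent potential E_L bridging the aqueous reference to the
working solvent: 0.093 V for MeCN, 0.172 V for DMF, 0.0 V for DCM (no
literature value exists for DCM; its dipole moment is close to water's,
and E_L correlates with the dipole difference). Unknown solvents fall
back to E_L = 0 with a logged warning rather than an error, matching
the DCM convention. n_e defaults to 1; for one-electron couples an
energy in eV and a potential in V are numerically identical, and the
conversion is centralized so a future n_e ≠ 1 extension fails loudly
rather than silently.

Unit conventions are pinned in one table: hartree at ingestion
(1 hartree = 27.211386245988 eV), eV for reaction energies, V for
potentials, hc = 1239.84193 eV·nm for wavelength conversion.

Charge states are declared by the input table and never inferred from
structure — species such as eosin start at charge −2, so structural
inference is unsafe. The couple label (M⁺/M vs M/M⁻) is assigned
relative to the neutral species from the declared charge pair.

## Calibration

Computed potentials carry a largely systematic error associated with
the unit change of charge in the half reaction, so simple data-driven
corrections remove most of it. The accuracy metric is the mean absolute
error (MAE) throughout, which fixes the form of the optimal corrections:

* **Shift.** The additive shift minimizing MAE is the median of the
  residuals (reference − prediction); it is computed in closed form.
  For an even count the mean of the two central order statistics is
  used — one of the minimizers of the (piecewise-linear) objective. An
  exhaustive grid-search oracle over the shift remains in the test
  suite. Shifts are fitted per (method, couple) by default; a universal
  scope pools all residuals.
* **Linear.** Slope/intercept are fitted by least absolute deviations
  for internal consistency with the MAE criterion (the regression loss
  of the supplementary linear correction is an open choice; LAD keeps
  the shift correction exactly nested inside the linear one). The
  intercept is profiled out (residual median), leaving a 1-D convex
  problem solved by bounded minimization; on small inputs (≤ 200
  points) the solution is polished over the pairwise-slope breakpoints,
  which makes exact-line inputs recover their parameters exactly.
* **Scale.** The multiplicative factor k minimizing mean |ref − k·pred|
  is found by bounded 1-D minimization on [0.5, 1.2] plus a breakpoint
  polish over the ratio set, so noiseless data recovers k exactly. Its
  main use is the 0.91 factor mapping vertical absorption energies onto
  0–0 transition energies; an additive alternative on energies is
  supported but non-default (it yields inferior MAE).

Confidence intervals on MAEs are nonparametric percentile bootstraps
over molecules, 10,000 resamples by default with a fixed default seed.
Simulation places the empirical coverage of the 95% interval near 94%
at n = 100 — the usual mild undercoverage of the percentile method at
moderate n.

## 0–0 transition energies and excited-state composition

Four routes provide E₀,₀, each stamped as provenance on every
downstream excited-state record so mixed-route tables stay auditable:

1. `raw_abs` — the first vertical absorption energy as-is (a known
   overestimate);
2. `scaled_abs` — 0.91 × E_abs (default route);
3. `avg` — the mean of vertical absorption and emission energies.
   Missing emission is an error by default, not a silent fallback:
   averaging is a distinct, costlier route. An explicit flag enables
   fallback to `scaled_abs` with a warning;
4. `ml` — the fingerprint regressor below.

Excited-state potentials are composed, never inverted:
E(M⁺/M*) = E(M⁺/M) − E₀,₀ and E(M*/M⁻) = E(M/M⁻) + E₀,₀. Exact
identities (differences equal to E₀,₀; excited-minus-ground gap equal
to 2·E₀,₀) hold to 1e−12 and are enforced in tests. Vibrationally
resolved 0–0 computation is out of scope by design: its cost is not
repaid at this accuracy level and it degrades at high Stokes shifts.

## The ML E₀,₀ regressor

Targets are built from tabulated absorption and emission maxima by
converting each wavelength to eV and averaging the two energies
(convert-then-average). The alternative reading — average the
wavelengths, then convert — gives a slightly different number; the
energy-domain average was chosen because the quantity being
approximated is an energy midpoint. Targets are min-max scaled to
[0, 1] on the training split only; the inverse transform is exact and
values outside the training range are not clamped.

Features are 2048-bit Morgan (circular) fingerprints at radius 2
without chirality bits, computed on RDKit-canonicalized structures; the
radius is surfaced as configuration and stamped into every model
bundle. The regressor is a sequential network 2048 → 100 (ReLU) →
dropout 0.5 → 1 trained with Adam (lr 0.001) for 20 epochs on an MAE
loss over mini-batches of 32, after an 80:20 random split; the split
doubles as model selection and reporting (no third fold), with an
optional grid search over hidden units, learning rate and epochs at a
fixed split. One model is trained per solvent, and predicting for
another solvent is an error unless explicitly overridden.

The network is implemented directly on NumPy: weight initialization is
He-uniform, dropout is inverted (train-time scaling, disabled at
prediction), and the loss gradient is the sign of the residual. A
single integer seed fixes the split, the initialization, the batch
order and every dropout mask, so predictions are bit-for-bit
reproducible on one platform. Batch size, initialization and dropout
placement (after the hidden activation) are package choices; no
pretrained weights ship with the package.

## Solvation diagnostics

Implicit solvent models are least reliable where the solvation energy
changes strongly across the half reaction while the reaction free
energy stays small — in practice the reductions of highly charged
chromophores. Per couple the package computes
ΔE_solv = E_solv[red] − E_solv[ox] with E_solv[X] = E_s[X] − E_gas[X],
and flags couples with |ΔE_solv| ≥ 3.0 eV and |Δ_rG| ≤ 5.0 eV. Both
thresholds are package conventions for screening, prominently
configurable, and not literature values. Gas-phase energies are
optional input columns; their absence yields an explicit
"unavailable" status and an undetermined flag, never a silent zero.

## Synthetic data

The generators produce every table the pipeline reads, with planted
parameters emitted alongside (`truth.json`), and defaults that match
the study conditions the calibration analyses assume:

* **Redox benchmark** (default n = 200 molecules, MeCN): true
  potentials uniform in [−2.5, +2.5] V per couple; free energies are
  constructed so the pipeline reproduces true − b + N(0, σ) with
  b = 0.2 V and σ = 0.15 V. Gas-phase energies are added with solvation
  energies dominated by the square of the species charge plus small
  scatter, so charge drives the reaction-solvation variance.
* **Spectra** (default n = 100): true E₀,₀ uniform in [1.8, 3.2] eV,
  E_abs = E₀,₀/k + N(0, 0.1 eV) with k = 0.91, and
  E_em = 2·E₀,₀ − E_abs, so both the scaled and the averaging route
  recover the truth exactly in the noiseless case.
* **Chromophores** (defaults 1700 MeCN / 2300 DCM / 600 DMF entries):
  molecules are drawn from a ~3000-structure vocabulary enumerated from
  substituted aromatic cores (validated and canonicalized by RDKit,
  labelled by scaffold family). E₀,₀ is a fixed linear rule over five
  informative fingerprint bits (intercept 2.0 eV, weights in
  [0.05, 0.25] eV), optionally plus Gaussian noise; wavelengths are
  back-computed from E₀,₀ and a sampled Stokes shift (mean 0.35 eV,
  s.d. 0.1 eV) so target building inverts the construction to 1e−9.

What the fixtures do **not** emulate: real electronic structure,
solvatochromic shifts, vibrational structure, tautomers/charged resting
states, or any correlation between a scaffold's chemistry and its
potentials. Passing tests therefore demonstrate that the pipeline's
mathematics (conversions, fits, composition, reporting) is correct and
that the ML route can learn a structure-determined target — not that
any specific chemistry is predicted well.

## Reporting

Scaffold windows are five-number summaries per (scaffold, couple):
quartiles by linear interpolation of order statistics (the common
"type 7" rule — the plotting convention of reference box plots is not
standardized), whiskers at the most extreme data points within
1.5·IQR of the box, clamped to the box edge when no data point lies
outside it. Empty groups are omitted with a log entry, and molecules
without a scaffold assignment are reported — missing cells are explicit
absences, mirroring reference databases with unmeasurable couples.

All CSV output uses one dialect (comma, UTF-8, header row, '.' decimal,
six-decimal floats) and a deterministic provenance comment line, so
identical seeds give byte-identical files. Test problem sizes (400-
molecule corpora in unit tests, 1000 in the end-to-end learnability
check; 500 bootstrap-coverage replicates at 2000 resamples) were chosen
as the smallest sizes at which the checked statistics are stable.

## Known limitations

* The electronic-structure inputs are taken on faith; no consistency
  check exists between E_s, G_corr and E_gas beyond finiteness.
* The MAE-optimal shift is non-unique for even counts (any value
  between the central residuals); the median convention is one
  minimizer, which matters when comparing shifts across software.
* The ML route interpolates within its fingerprint neighborhood;
  molecules whose environments hash outside the training bits revert
  toward the training mean, with no out-of-distribution warning.
* Quenching feasibility is purely thermodynamic (sign of the potential
  difference); kinetics, diffusion and back-electron transfer are out
  of scope.
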