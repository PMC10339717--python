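# photoredox

Ground- and excited-state redox potentials of organic photocatalysts,
computed from quantum-chemistry free energies, empirically calibrated,
and combined with 0–0 transition energies into per-molecule and
per-scaffold redox windows.

## The problem

Photoredox catalysis runs on single-electron transfer from or to a
photoexcited organic chromophore. Whether a given catalyst can drive a
reaction is a question of four potentials vs SCE: the ground-state
couples E(M⁺/M) and E(M/M⁻), and the excited-state couples

    E(M⁺/M*) = E(M⁺/M) − E₀,₀        E(M*/M⁻) = E(M/M⁻) + E₀,₀

where E₀,₀ is the 0–0 transition energy of the S₀→S₁ excitation.
Experimental values are often missing or irreproducible (irreversible
voltammograms, coupled chemistry), so computation fills the holes.

This package implements the desk side of that workflow:

* **Thermodynamic cycle** — solution-phase Gibbs energies
  G(s) = E_s + G_corr per species (molecule × charge × solvent) are
  turned into reduction half-reaction energies (electron free energy set
  to zero) and potentials via the Nernst-type relation
  `E = −Δ_rG/n_e − E_SCE_abs − E_L`, with the absolute aqueous SCE
  potential 4.522 V and intersolvent potentials E_L of 0.093 V (MeCN),
  0.172 V (DMF) and 0.0 V (DCM).
* **Calibration** — MAE-optimal additive shifts (per method/couple or a
  single universal shift; the MAE-minimizing shift is the residual
  median, computed in closed form), least-absolute-deviation linear
  corrections, and the multiplicative 0.91 factor mapping vertical
  absorption energies onto E₀,₀. MAEs carry percentile-bootstrap 95%
  confidence intervals.
* **E₀,₀ routes** — raw vertical absorption, scaled absorption
  (k = 0.91), absorption–emission averaging, and a machine-learned
  route: 2048-bit Morgan fingerprints (radius 2) into a single-hidden-
  layer network (100 ReLU units, 50% dropout, Adam at lr 0.001,
  20 epochs, MAE loss on min-max-scaled targets, 80:20 random split),
  one model per solvent.
* **Diagnostics and summaries** — reaction solvation energies
  ΔE_solv = E_solv[red] − E_solv[ox] flagging couples where implicit
  solvation is least trustworthy, and per-scaffold box-plot windows of
  the excited-state potentials.
* **Synthetic data** — seeded generators that produce every table the
  pipeline reads with known planted parameters (shift bias, scale
  factor, a linear fingerprint-bit rule for E₀,₀), so every fit has a
  recoverable ground truth.

## Worked example

```python
from photoredox import (
    FreeEnergyRecord, half_reaction_delta_g, potential_vs_sce,
    CorrectionModel, apply_correction, SpectralRecord, e00_scaled,
    excited_potentials, quenching_feasibility, wavelength_to_energy,
)

ox  = FreeEnergyRecord("PC1", charge=+1, solvent="MeCN", E_s=-875.1042, G_corr=0.2098)
neu = FreeEnergyRecord("PC1", charge=0,  solvent="MeCN", E_s=-875.3421, G_corr=0.2104)
red = FreeEnergyRecord("PC1", charge=-1, solvent="MeCN", E_s=-875.4398, G_corr=0.2110)

e_ox  = potential_vs_sce(half_reaction_delta_g(ox, neu))    # M+ + e- -> M
e_red = potential_vs_sce(half_reaction_delta_g(neu, red))   # M  + e- -> M-

shift = CorrectionModel(kind="shift", shift_b=0.2, fitted_on_n=74)
e_ox_c, e_red_c = apply_correction(e_ox, shift), apply_correction(e_red, shift)

spec = SpectralRecord("PC1", "MeCN", E_abs=wavelength_to_energy(455.0))
e00 = e00_scaled(spec)                                      # E00 = 0.91 * E_abs
ox_star, red_star = excited_potentials(e_ox_c, e_red_c, e00)
verdict = quenching_feasibility(ox_star, -0.87, "oxidative")
```

prints, step by step:

```
E(M+/M)  = +1.842 V vs SCE
E(M/M-)  = -1.973 V vs SCE
shifted  : +2.042 / -1.773 V
E_abs    = 2.725 eV -> E00 = 2.480 eV (scaled_abs)
E(M+/M*) = -0.437 V vs SCE
E(M*/M-) = +0.707 V vs SCE
oxidative quenching by O2: feasible=False, driving force -0.433 V
```

Reading the numbers: the free-energy differences give a strongly
oxidizing ground-state catalyst (+1.84 V) that is hard to reduce
(−1.97 V). The universal +0.2 V shift compensates the systematic bias
of the underlying electronic-structure method. A 455 nm absorption
maximum (2.725 eV), scaled by 0.91, gives E₀,₀ = 2.48 eV; excitation
converts the catalyst into a moderate excited-state reductant
(E(M⁺/M*) = −0.44 V) and oxidant (E(M*/M⁻) = +0.71 V). Against the
O₂/O₂·⁻ couple at −0.87 V vs SCE, oxidative quenching is thermodynamically
uphill by 0.43 V for this molecule.

## Command line

The same pipeline is scriptable end to end:

```
photoredox simulate spec.json fixtures/         # synthetic tables + truth.json
photoredox gs-potentials fixtures/species.csv --out pots.csv
photoredox calibrate pots.csv fixtures/refs.csv --scope universal --out corr.json
photoredox e00 fixtures/spectra.csv --route scaled --out e00.csv
photoredox excited pots.csv e00.csv --correction corr.json --out excited.csv
photoredox windows excited.csv fixtures/scaffolds.csv --out windows.csv
photoredox solvation fixtures/species.csv --out diagnostics.csv
photoredox ml-train fixtures/corpus.csv --solvent MeCN --out model
photoredox ml-predict model smiles.csv --out e00_ml.csv
```

All outputs are deterministic for fixed seeds (fixed float precision,
no timestamps), so reruns are byte-identical.

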