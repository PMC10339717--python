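"""Physical constants and reference-electrode data used across the package.

All unit conversions are pinned here: energies arrive in hartree from
quantum-chemistry tables, reaction energies are handled in eV, and
electrode potentials in volts.  For a one-electron process an energy in
eV and a potential in V are numerically interchangeable, which is why a
single constants table suffices.
"""

from __future__ import annotations

#: 1 hartree in electronvolts (CODATA 2018).
HARTREE_TO_EV: float = 27.211386245988

#: hc in eV·nm, for wavelength <-> photon-energy conversion.
HC_EV_NM: float = 1239.84193

#: Absolute potential of the aqueous saturated calomel electrode (V).
E_SCE_ABS: float = 4.522

#: Intersolvent potentials E_L (V) linking the aqueous SCE to the working
#: solvent.  No literature value exists for DCM; 0.0 V is used because the
#: dipole moment of DCM is close to that of water.
E_L: dict[str, float] = {
    "MeCN": 0.093,
    "DMF": 0.172,
    "DCM": 0.0,
}

#: Default temperature (K) for thermal corrections (metadata only).
T_DEFAULT: float = 298.15

#: Default absorption-energy scaling factor for the 0-0 transition
#: estimate E00 = k * E_abs.
E00_SCALE_DEFAULT: float = 0.91

#: Benchmark partner couples for quenching-feasibility checks (V vs SCE,
#: in MeCN): superoxide formation and triethylamine oxidation.
E_O2_SUPEROXIDE: float = -0.87
E_TEA_RADICAL_CATION: float = 0.78
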