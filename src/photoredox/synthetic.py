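"""Synthetic fixtures with known ground truth for every pipeline stage.

Three generators emulate the data the real workflow consumes, each with
planted parameters that downstream fits must recover:

* :func:`gen_redox_benchmark` — a species free-energy table constructed
  so the thermodynamic-cycle pipeline reproduces ``true - b + noise`` as
  the "calculated" potential, mimicking the systematic underestimation
  that the shift calibration corrects.
* :func:`gen_spectra` — vertical absorption/emission tables built from
  true 0-0 energies through the inverse of the 0.91-type scaling, so the
  scaled-absorption and averaging routes both recover the truth.
* :func:`gen_chromophores` — a chromophore corpus whose 0-0 energy is a
  fixed linear rule over Morgan fingerprint bits, making the ML module's
  learnability test well-posed by construction.

Every generator is exactly reproducible from (spec, seed) and emits its
ground truth alongside the tables; the fixtures test the mathematics of
the pipeline, not the chemistry of real photocatalysts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger

from .constants import E_L, E_SCE_ABS, HARTREE_TO_EV, HC_EV_NM
from .ml_e00 import FINGERPRINT_BITS, FINGERPRINT_RADIUS, featurize

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for the generators.

    Defaults mirror the benchmark conditions the calibration analyses
    assume: a 0.2 V systematic shift with 0.15 V Gaussian scatter on 200
    redox couples, a 0.91 absorption scaling with 0.1 eV scatter on 100
    spectra, and per-solvent chromophore corpora of roughly 1700 (MeCN),
    2300 (DCM) and 600 (DMF) entries.
    """

    n_molecules: int = 200
    solvent: str = "MeCN"
    true_shift_b: float = 0.2          # V, planted systematic bias
    noise_sigma: float = 0.15          # V, scatter on calculated potentials
    n_spectra: int = 100
    true_scale_k: float = 0.91         # E_abs = E00 / k
    spectra_noise_sigma: float = 0.1   # eV, scatter on E_abs
    stokes_mean: float = 0.35          # eV, mean Stokes shift of the corpus
    stokes_sd: float = 0.10
    chromophore_counts: Mapping[str, int] = field(
        default_factory=lambda: {"MeCN": 1700, "DCM": 2300, "DMF": 600}
    )
    chromophore_noise_sigma: float = 0.0  # eV, optional noise on planted E00
    n_rule_bits: int = 5
    method_tag: str = "synthetic-dft"
    seed: int = 0


# --------------------------------------------------------------------------
# Redox benchmark
# --------------------------------------------------------------------------

def gen_redox_benchmark(
    spec: SyntheticSpec,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Species free energies + reference potentials with a planted shift.

    True potentials are drawn uniformly in [-2.5, +2.5] V per couple.
    The free energies are constructed so that running the species table
    through the thermodynamic cycle yields ``true - b + N(0, sigma)``;
    the reference table carries the true potentials.  Gas-phase energies
    are included with solvation energies driven primarily by the square
    of the species charge, so charged couples dominate the reaction
    solvation energy.
    """
    rng = np.random.default_rng(spec.seed)
    e_l = E_L.get(spec.solvent, 0.0)
    rows, ref_rows = [], []
    truth_pots = {}
    for i in range(spec.n_molecules):
        mid = f"PC{i:04d}"
        true_ox, true_red = sorted(rng.uniform(-2.5, 2.5, size=2))[::-1]
        calc_ox = true_ox - spec.true_shift_b + rng.normal(0, spec.noise_sigma)
        calc_red = true_red - spec.true_shift_b + rng.normal(0, spec.noise_sigma)
        # Half-reaction free energies (eV) the pipeline must reproduce.
        dg_ox = -(calc_ox + E_SCE_ABS + e_l)   # M+ + e- -> M
        dg_red = -(calc_red + E_SCE_ABS + e_l)  # M  + e- -> M-
        g_neutral = -(300.0 + 5.0 * rng.random())  # hartree, arbitrary scale
        g = {
            0: g_neutral,
            +1: g_neutral - dg_ox / HARTREE_TO_EV,
            -1: g_neutral + dg_red / HARTREE_TO_EV,
        }
        for q, g_tot in g.items():
            g_corr = 0.05 + 0.1 * rng.random()
            e_s = g_tot - g_corr
            # Solvation energy dominated by charge; small molecular scatter.
            e_solv_ev = -(0.3 + 2.0 * q * q + 0.05 * rng.standard_normal())
            rows.append({
                "molecule_id": mid, "charge": q, "solvent": spec.solvent,
                "method": spec.method_tag, "E_s_hartree": e_s,
                "G_corr_hartree": g_corr,
                "E_gas_hartree": e_s - e_solv_ev / HARTREE_TO_EV,
            })
        for couple, true_v in (("M+/M", true_ox), ("M/M-", true_red)):
            ref_rows.append({
                "molecule_id": mid, "couple": couple,
                "solvent": spec.solvent, "E_ref_V_vs_SCE": true_v,
            })
        truth_pots[mid] = {"M+/M": true_ox, "M/M-": true_red}
    truth = {
        "generator": "gen_redox_benchmark",
        "seed": spec.seed,
        "true_shift_b_V": spec.true_shift_b,
        "noise_sigma_V": spec.noise_sigma,
        "n_molecules": spec.n_molecules,
        "solvent": spec.solvent,
        "true_potentials_V": truth_pots,
    }
    return pd.DataFrame(rows), pd.DataFrame(ref_rows), truth


# --------------------------------------------------------------------------
# Spectra
# --------------------------------------------------------------------------

def gen_spectra(spec: SyntheticSpec) -> tuple[pd.DataFrame, dict]:
    """Spectral table with planted scaling: E_abs = E00/k + noise.

    Emission is set to ``2*E00 - E_abs`` so the absorption/emission
    average returns the true E00 exactly in the noiseless case.
    """
    rng = np.random.default_rng(spec.seed + 1)
    e00 = rng.uniform(1.8, 3.2, size=spec.n_spectra)
    e_abs = e00 / spec.true_scale_k + rng.normal(
        0, spec.spectra_noise_sigma, size=spec.n_spectra
    )
    e_em = 2.0 * e00 - e_abs
    df = pd.DataFrame({
        "molecule_id": [f"PC{i:04d}" for i in range(spec.n_spectra)],
        "solvent": spec.solvent,
        "method": spec.method_tag,
        "E_abs_eV": e_abs,
        "E_em_eV": e_em,
    })
    truth = {
        "generator": "gen_spectra",
        "seed": spec.seed,
        "true_scale_k": spec.true_scale_k,
        "noise_sigma_eV": spec.spectra_noise_sigma,
        "true_E00_eV": {m: float(v) for m, v in zip(df["molecule_id"], e00)},
    }
    return df, truth


# --------------------------------------------------------------------------
# Chromophore corpus
# --------------------------------------------------------------------------

# Cores with one substitution slot, labelled by scaffold family.  The
# families loosely follow common photocatalyst frames (acridines,
# xanthenes, phenazines, cyanoarenes, ...) without claiming fidelity.
_MONO_CORES: list[tuple[str, str]] = [
    ("BEN", "c1ccc({r})cc1"),
    ("NAP", "c1ccc2cc({r})ccc2c1"),
    ("ANT", "c1ccc2cc3cc({r})ccc3cc2c1"),
    ("PYR", "c1ccc({r})nc1"),
    ("THI", "c1cc({r})cs1"),
    ("FUR", "c1cc({r})co1"),
    ("CBZ", "c1ccc2c(c1)[nH]c1ccc({r})cc12"),
    ("XAN", "C1c2ccccc2Oc2ccc({r})cc21"),
    ("ACR", "c1ccc2nc3ccc({r})cc3cc2c1"),
    ("PHZ", "c1ccc2nc3ccc({r})cc3nc2c1"),
    ("PTZ", "c1ccc2c(c1)Nc1ccc({r})cc1S2"),
    ("POZ", "c1ccc2c(c1)Nc1ccc({r})cc1O2"),
    ("CA", "N#Cc1ccc({r})cc1"),
    ("BIP", "c1ccc(-c2ccc({r})cc2)cc1"),
    ("FLU", "C1c2ccccc2-c2ccc({r})cc21"),
    ("QUI", "c1ccc2ncc({r})cc2c1"),
    ("BTZ", "c1ccc2sc({r})nc2c1"),
    ("BOX", "c1ccc2oc({r})nc2c1"),
    ("STY", "C(=C{r})c1ccccc1"),
    ("PYM", "c1cnc({r})nc1"),
]

# Cores with two slots, used to enlarge the vocabulary combinatorially.
_DI_CORES: list[tuple[str, str]] = [
    ("BEN", "c1cc({r1})cc({r2})c1"),
    ("NAP", "c1cc({r1})c2cc({r2})ccc2c1"),
    ("BIP", "c1cc({r1})ccc1-c1ccc({r2})cc1"),
    ("PYR", "c1nc({r1})cc({r2})c1"),
    ("THI", "c1c({r1})cc({r2})s1"),
    ("CA", "N#Cc1cc({r1})cc({r2})c1"),
    ("FUR", "c1c({r1})cc({r2})o1"),
    ("QUI", "c1cc2ncc({r1})cc2cc1{r2}"),
]

_SUBSTITUENTS = [
    "C", "CC", "O", "OC", "N", "N(C)C", "F", "Cl", "Br", "C#N",
    "C(F)(F)F", "C(C)C", "OCC", "NC", "SC", "C=C", "CO", "C(=O)C",
    "C(=O)OC", "OC(F)F",
]

_VOCAB_CACHE: list[tuple[str, str]] | None = None


def build_vocabulary() -> list[tuple[str, str]]:
    """Deterministic list of (canonical SMILES, scaffold label).

    Enumerates substituted cores, keeps only SMILES RDKit parses, and
    deduplicates by canonical form.  Cached after the first call.
    """
    global _VOCAB_CACHE
    if _VOCAB_CACHE is not None:
        return _VOCAB_CACHE
    RDLogger.DisableLog("rdApp.*")
    seen: set[str] = set()
    vocab: list[tuple[str, str]] = []

    def try_add(smi: str, label: str) -> None:
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            return
        can = Chem.MolToSmiles(mol)
        if can not in seen:
            seen.add(can)
            vocab.append((can, label))

    for label, tpl in _MONO_CORES:
        for r in _SUBSTITUENTS:
            try_add(tpl.format(r=r), label)
    for label, tpl in _DI_CORES:
        for r1 in _SUBSTITUENTS:
            for r2 in _SUBSTITUENTS:
                try_add(tpl.format(r1=r1, r2=r2), label)
    RDLogger.EnableLog("rdApp.*")
    logger.info("chromophore vocabulary: %d molecules", len(vocab))
    _VOCAB_CACHE = vocab
    return vocab


def _select_rule_bits(
    fps: np.ndarray, n_bits: int, rng: np.random.Generator
) -> np.ndarray:
    # Informative bits: present in 20-80% of the vocabulary so the rule
    # actually varies across molecules.
    freq = fps.mean(axis=0)
    candidates = np.flatnonzero((freq > 0.2) & (freq < 0.8))
    if candidates.size < n_bits:
        candidates = np.argsort(np.abs(freq - 0.5))[: max(n_bits * 4, 20)]
    return rng.choice(candidates, size=n_bits, replace=False)


def gen_chromophores(
    spec: SyntheticSpec,
) -> tuple[pd.DataFrame, dict]:
    """Chromophore corpus whose E00 follows a linear fingerprint-bit rule.

    For each solvent in ``spec.chromophore_counts`` the requested number
    of molecules is sampled (without replacement within a solvent) from
    the template vocabulary.  The planted energy is

        E00 = intercept + sum_j w_j * bit_j (+ optional Gaussian noise)

    over ``n_rule_bits`` informative Morgan bits; absorption and emission
    maxima are back-computed from E00 and a sampled Stokes shift so that
    convert-then-average target building returns the planted value.
    """
    vocab = build_vocabulary()
    needed = max(spec.chromophore_counts.values(), default=0)
    if needed > len(vocab):
        raise ValueError(
            f"vocabulary has {len(vocab)} molecules; cannot draw {needed} "
            "distinct entries for one solvent"
        )
    rng = np.random.default_rng(spec.seed + 2)
    fps = np.array([
        featurize(smi, radius=FINGERPRINT_RADIUS, n_bits=FINGERPRINT_BITS)
        for smi, _ in vocab
    ], dtype=float)
    bits = _select_rule_bits(fps, spec.n_rule_bits, rng)
    weights = rng.uniform(0.05, 0.25, size=spec.n_rule_bits)
    intercept = 2.0
    rows = []
    truth_e00: dict[str, dict[str, float]] = {}
    for solvent, count in spec.chromophore_counts.items():
        idx = rng.choice(len(vocab), size=count, replace=False)
        truth_e00[solvent] = {}
        for i in idx:
            smi, scaffold = vocab[i]
            e00 = intercept + float(weights @ fps[i, bits])
            if spec.chromophore_noise_sigma > 0:
                e00 += rng.normal(0, spec.chromophore_noise_sigma)
            stokes = abs(rng.normal(spec.stokes_mean, spec.stokes_sd))
            stokes = min(stokes, 1.6 * (e00 - 0.1))  # keep both energies > 0
            e_abs, e_em = e00 + stokes / 2.0, e00 - stokes / 2.0
            rows.append({
                "smiles": smi, "solvent": solvent, "scaffold": scaffold,
                "lambda_abs_nm": HC_EV_NM / e_abs,
                "lambda_em_nm": HC_EV_NM / e_em,
            })
            truth_e00[solvent][smi] = e00
    truth = {
        "generator": "gen_chromophores",
        "seed": spec.seed,
        "rule": {
            "intercept_eV": intercept,
            "bits": [int(b) for b in bits],
            "weights_eV": [float(w) for w in weights],
            "noise_sigma_eV": spec.chromophore_noise_sigma,
        },
        "counts": dict(spec.chromophore_counts),
        "true_E00_eV": truth_e00,
    }
    return pd.DataFrame(rows), truth
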