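"""CSV/JSON table schemas, the scaffold window summary, and run configs.

One CSV dialect everywhere: comma-separated, UTF-8, header row, ``.``
decimal, floats written with six decimals so that determinism claims
hold at the byte level.  Each writer stamps a comment line with the
package version and, when relevant, the seed; readers skip ``#`` lines.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .redox_core import (
    Couple,
    FreeEnergyRecord,
    PotentialRecord,
    State,
    half_reaction_delta_g,
    potential_vs_sce,
)

logger = logging.getLogger(__name__)

FLOAT_FORMAT = "%.6f"

SPECIES_COLUMNS = ["molecule_id", "charge", "solvent", "method",
                   "E_s_hartree", "G_corr_hartree"]
REFERENCE_COLUMNS = ["molecule_id", "couple", "solvent", "E_ref_V_vs_SCE"]
SPECTRA_COLUMNS = ["molecule_id", "solvent", "method", "E_abs_eV", "E_em_eV"]
POTENTIAL_COLUMNS = ["molecule_id", "couple", "state", "solvent",
                     "value_V_vs_SCE", "method", "calibrated", "e00_route"]
E00_COLUMNS = ["molecule_id", "solvent", "E00_eV", "route", "scale_k"]
CORPUS_COLUMNS = ["smiles", "solvent", "lambda_abs_nm", "lambda_em_nm"]
SCAFFOLD_COLUMNS = ["molecule_id", "scaffold"]
WINDOW_COLUMNS = ["scaffold", "couple", "n", "min", "whisker_low", "q1",
                  "median", "q3", "whisker_high", "max"]
DIAGNOSTIC_COLUMNS = ["molecule_id", "couple", "solvent", "delta_E_solv_eV",
                      "delta_G_r_eV", "initial_charge", "risk_flag", "status"]


class SchemaError(ValueError):
    """A table is missing required columns."""


def _require_columns(df: pd.DataFrame, required: Sequence[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{what} table is missing column(s): {', '.join(missing)}"
        )


def read_table(path: str | Path, required: Sequence[str], what: str) -> pd.DataFrame:
    # Skip leading provenance comment lines only; '#' is a legal character
    # inside field values (e.g. triple bonds in SMILES), so a global
    # comment marker would corrupt them.
    skip = 0
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            skip += 1
    df = pd.read_csv(path, skiprows=skip)
    _require_columns(df, required, what)
    return df


def write_table(
    df: pd.DataFrame, path: str | Path, *, seed: int | None = None
) -> Path:
    """Write a CSV with a deterministic provenance header comment."""
    path = Path(path)
    stamp = f"# photoredox v{__version__}"
    if seed is not None:
        stamp += f" seed={seed}"
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(stamp + "\n")
        df.to_csv(fh, index=False, float_format=FLOAT_FORMAT)
    return path


# --------------------------------------------------------------------------
# Schema-specific readers
# --------------------------------------------------------------------------

def read_species(path: str | Path) -> list[FreeEnergyRecord]:
    df = read_table(path, SPECIES_COLUMNS, "species")
    records = records_from_frame(df)
    keys = [r.key for r in records]
    if len(set(keys)) != len(keys):
        dupes = {k for k in keys if keys.count(k) > 1}
        raise SchemaError(f"duplicate species keys: {sorted(dupes)[:5]}")
    return records


def records_from_frame(df: pd.DataFrame) -> list[FreeEnergyRecord]:
    """Build free-energy records from an in-memory species table."""
    _require_columns(df, SPECIES_COLUMNS, "species")
    has_gas = "E_gas_hartree" in df.columns
    out = []
    for row in df.itertuples(index=False):
        e_gas = getattr(row, "E_gas_hartree", None) if has_gas else None
        if isinstance(e_gas, float) and math.isnan(e_gas):
            e_gas = None
        out.append(FreeEnergyRecord(
            molecule_id=str(row.molecule_id), charge=int(row.charge),
            solvent=str(row.solvent), method_tag=str(row.method),
            E_s=float(row.E_s_hartree), G_corr=float(row.G_corr_hartree),
            E_gas=e_gas,
        ))
    return out


def aligned_pairs(
    potentials: Sequence[PotentialRecord], refs: pd.DataFrame
) -> tuple[np.ndarray, np.ndarray]:
    """Align computed potentials with a reference table by molecule/couple.

    Returns (predicted, reference) arrays over the overlap; records
    without a reference entry are dropped.
    """
    _require_columns(refs, REFERENCE_COLUMNS, "reference")
    ref_map = {(str(r.molecule_id), str(r.couple), str(r.solvent)):
               float(r.E_ref_V_vs_SCE) for r in refs.itertuples(index=False)}
    pred, ref = [], []
    for p in potentials:
        key = (p.molecule_id, p.couple.value, p.solvent)
        if key in ref_map:
            pred.append(p.value)
            ref.append(ref_map[key])
    return np.asarray(pred), np.asarray(ref)


def read_spectra(path: str | Path):
    from .excited_state import SpectralRecord

    df = read_table(path, SPECTRA_COLUMNS, "spectra")
    out = []
    for row in df.itertuples(index=False):
        e_em = row.E_em_eV
        if isinstance(e_em, float) and math.isnan(e_em):
            e_em = None
        out.append(SpectralRecord(
            molecule_id=str(row.molecule_id), solvent=str(row.solvent),
            method_tag=str(row.method), E_abs=float(row.E_abs_eV),
            E_em=None if e_em is None else float(e_em),
        ))
    return out


def read_potentials(path: str | Path) -> list[PotentialRecord]:
    df = read_table(path, POTENTIAL_COLUMNS, "potentials")
    out = []
    for row in df.itertuples(index=False):
        route = row.e00_route
        if isinstance(route, float) and math.isnan(route):
            route = None
        out.append(PotentialRecord(
            molecule_id=str(row.molecule_id), couple=Couple(row.couple),
            state=State(row.state), solvent=str(row.solvent),
            value=float(row.value_V_vs_SCE), method_tag=str(row.method),
            calibrated=bool(row.calibrated), e00_route=route,
        ))
    return out


def potentials_to_frame(records: Iterable[PotentialRecord]) -> pd.DataFrame:
    return pd.DataFrame([{
        "molecule_id": r.molecule_id, "couple": r.couple.value,
        "state": r.state.value, "solvent": r.solvent,
        "value_V_vs_SCE": r.value, "method": r.method_tag,
        "calibrated": r.calibrated, "e00_route": r.e00_route or "",
    } for r in records], columns=POTENTIAL_COLUMNS)


def e00_to_frame(estimates) -> pd.DataFrame:
    return pd.DataFrame([{
        "molecule_id": e.molecule_id, "solvent": e.solvent,
        "E00_eV": e.value, "route": e.route.value,
        "scale_k": e.scale_k if e.scale_k is not None else "",
    } for e in estimates], columns=E00_COLUMNS)


# --------------------------------------------------------------------------
# Species table -> ground-state potentials
# --------------------------------------------------------------------------

def ground_potentials(records: Sequence[FreeEnergyRecord]) -> list[PotentialRecord]:
    """Pair adjacent charge states per molecule and compute potentials.

    Within each (molecule, solvent, method) group every (q, q-1) charge
    pair present in the table becomes one reduction couple.
    """
    groups: dict[tuple, dict[int, FreeEnergyRecord]] = {}
    for r in records:
        groups.setdefault(
            (r.molecule_id, r.solvent, r.method_tag), {}
        )[r.charge] = r
    out = []
    for _, by_charge in sorted(groups.items()):
        for q in sorted(by_charge, reverse=True):
            if q - 1 in by_charge:
                hr = half_reaction_delta_g(by_charge[q], by_charge[q - 1])
                out.append(potential_vs_sce(hr))
    return out


# --------------------------------------------------------------------------
# Scaffold windows
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ScaffoldWindow:
    """Five-number summary with Tukey whiskers for one scaffold/couple."""

    scaffold: str
    couple: Couple
    n: int
    min: float
    whisker_low: float
    q1: float
    median: float
    q3: float
    whisker_high: float
    max: float

    def __post_init__(self) -> None:
        chain = (self.min, self.whisker_low, self.q1, self.median, self.q3,
                 self.whisker_high, self.max)
        if any(a > b + 1e-12 for a, b in zip(chain, chain[1:])):
            raise ValueError(f"summary ordering violated: {chain}")
        if self.n < 1:
            raise ValueError("empty group")


def _window(values: np.ndarray, scaffold: str, couple: Couple) -> ScaffoldWindow:
    # Quartiles via linear interpolation of order statistics ("type 7"),
    # whiskers at the most extreme points within 1.5*IQR of the box.
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    iqr = q3 - q1
    # Whiskers reach the most extreme data points within 1.5*IQR of the
    # box, clamped to the box edge when no data point lies outside it
    # (interpolated quartiles need not coincide with data).
    w_lo = min(float(values[values >= q1 - 1.5 * iqr].min()), float(q1))
    w_hi = max(float(values[values <= q3 + 1.5 * iqr].max()), float(q3))
    return ScaffoldWindow(
        scaffold=scaffold, couple=couple, n=values.size,
        min=float(values.min()), whisker_low=w_lo,
        q1=float(q1), median=float(med), q3=float(q3),
        whisker_high=w_hi, max=float(values.max()),
    )


def scaffold_windows(
    potentials: Sequence[PotentialRecord],
    scaffold_map: dict[str, str],
) -> list[ScaffoldWindow]:
    """Per-(scaffold, couple) box-plot summaries of a potential table.

    Molecules without a scaffold assignment are reported and skipped;
    empty groups are omitted with a log entry rather than emitted as
    zeros, mirroring reference databases with missing couples.
    """
    unmapped = sorted({p.molecule_id for p in potentials
                       if p.molecule_id not in scaffold_map})
    if unmapped:
        logger.warning("%d molecules have no scaffold assignment: %s",
                       len(unmapped), unmapped[:10])
    grouped: dict[tuple[str, Couple], list[float]] = {}
    for p in potentials:
        scaffold = scaffold_map.get(p.molecule_id)
        if scaffold is None:
            continue
        grouped.setdefault((scaffold, p.couple), []).append(p.value)
    out = []
    for (scaffold, couple), vals in sorted(
        grouped.items(), key=lambda kv: (kv[0][0], kv[0][1].value)
    ):
        out.append(_window(np.asarray(vals, dtype=float), scaffold, couple))
    return out


def windows_to_frame(windows: Sequence[ScaffoldWindow]) -> pd.DataFrame:
    return pd.DataFrame([{
        "scaffold": w.scaffold, "couple": w.couple.value, "n": w.n,
        "min": w.min, "whisker_low": w.whisker_low, "q1": w.q1,
        "median": w.median, "q3": w.q3, "whisker_high": w.whisker_high,
        "max": w.max,
    } for w in windows], columns=WINDOW_COLUMNS)


# --------------------------------------------------------------------------
# Run configuration snapshot
# --------------------------------------------------------------------------

def write_config_snapshot(path: str | Path, config: dict) -> Path:
    """Persist the resolved configuration of a run next to its outputs."""
    path = Path(path)
    payload = {"photoredox_version": __version__, **config}
    path.write_text(json.dumps(payload, indent=2, sort_keys=True))
    return path
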