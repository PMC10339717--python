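"""Implicit-solvation diagnostics for redox half reactions.

Implicit solvent models are least reliable where the solvation energy
changes strongly across a half reaction while the reaction free energy
itself is small — the regime populated by highly charged species such
as eosin dianions.  The diagnostic here computes, per couple, the
reaction solvation energy

    dE_solv = E_solv[reduced] - E_solv[oxidized],
    E_solv[X] = E_s[X] - E_gas[X]

and flags couples where |dE_solv| is large while |dG_r| is small.  The
numeric thresholds are configuration conveniences with documented
defaults; no canonical cut exists.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

from .constants import HARTREE_TO_EV
from .redox_core import Couple, FreeEnergyRecord, half_reaction_delta_g

logger = logging.getLogger(__name__)

#: Default flagging thresholds (eV).  These are package conventions for
#: screening, not literature values: |dE_solv| at least this large ...
DEFAULT_E_SOLV_THRESHOLD = 3.0
#: ... while |dG_r| stays at most this small.
DEFAULT_G_THRESHOLD = 5.0


class GasPhaseUnavailable(ValueError):
    """A record lacks the gas-phase energy the diagnostic needs."""


@dataclass(frozen=True)
class SolvationDiagnostic:
    """Per-couple solvation diagnostic; ``risk_flag=None`` means undetermined."""

    molecule_id: str
    couple: Couple
    solvent: str
    delta_E_solv: float | None
    delta_G_r: float
    initial_charge: int
    method_tag: str = ""
    risk_flag: bool | None = None
    status: str = "ok"  # "ok" | "unavailable"


def delta_e_solv(ox_form: FreeEnergyRecord, red_form: FreeEnergyRecord) -> float:
    """Reaction solvation energy E_solv[red] - E_solv[ox], in eV.

    Requires gas-phase electronic energies on both records; their
    absence is an explicit error, never a silent zero.
    """
    for rec in (ox_form, red_form):
        if rec.E_gas is None:
            raise GasPhaseUnavailable(
                f"{rec.molecule_id} (q={rec.charge}): gas-phase energy missing"
            )
    e_solv_ox = ox_form.E_s - ox_form.E_gas
    e_solv_red = red_form.E_s - red_form.E_gas
    return (e_solv_red - e_solv_ox) * HARTREE_TO_EV


def diagnose(
    ox_form: FreeEnergyRecord, red_form: FreeEnergyRecord
) -> SolvationDiagnostic:
    """Build the diagnostic record for one half reaction.

    Degrades gracefully: missing gas-phase energies give an
    ``unavailable`` status with an undetermined flag.
    """
    hr = half_reaction_delta_g(ox_form, red_form)
    try:
        de = delta_e_solv(ox_form, red_form)
        status = "ok"
    except GasPhaseUnavailable:
        de, status = None, "unavailable"
    return SolvationDiagnostic(
        molecule_id=hr.molecule_id, couple=hr.couple, solvent=hr.solvent,
        delta_E_solv=de, delta_G_r=hr.delta_G_r,
        initial_charge=ox_form.charge, method_tag=hr.method_tag,
        status=status,
    )


def flag_solvent_risk(
    d: SolvationDiagnostic,
    e_solv_threshold: float = DEFAULT_E_SOLV_THRESHOLD,
    g_threshold: float = DEFAULT_G_THRESHOLD,
) -> SolvationDiagnostic:
    """Flag couples with large |dE_solv| and small |dG_r|.

    ``risk_flag`` stays ``None`` (undetermined) when the solvation term
    is unavailable.
    """
    if d.delta_E_solv is None:
        logger.info("%s %s: risk undetermined (no gas-phase energies)",
                    d.molecule_id, d.couple.value)
        return replace(d, risk_flag=None)
    flag = (abs(d.delta_E_solv) >= e_solv_threshold
            and abs(d.delta_G_r) <= g_threshold)
    return replace(d, risk_flag=flag)
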