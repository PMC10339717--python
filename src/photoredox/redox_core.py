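"""Thermodynamic-cycle electrochemistry: free energies to potentials vs SCE.

The pipeline starts from solution-phase electronic energies ``E_s`` and
thermal Gibbs corrections ``G_corr`` computed by any electronic-structure
method, forms reduction half-reaction free energies with the electron's
free energy set to zero, and converts them to potentials against the
saturated calomel electrode (SCE) via

    E = -dG_r / n_e - E_SCE_abs - E_L

where ``E_SCE_abs`` = 4.522 V is the absolute potential of the aqueous
SCE and ``E_L`` is the intersolvent potential of the working solvent.

Every couple is stored as a *reduction* (oxidized form + e- -> reduced
form); ``dG_r = G(reduced) - G(oxidized)``.  A single sign convention
removes the most common source of sign errors in redox workflows.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import Enum

from .constants import E_L, E_SCE_ABS, HARTREE_TO_EV, HC_EV_NM, T_DEFAULT

logger = logging.getLogger(__name__)


class Couple(str, Enum):
    """Redox couple, named relative to the neutral photocatalyst M."""

    M_PLUS_OVER_M = "M+/M"       # oxidation couple: M+ + e- -> M
    M_OVER_M_MINUS = "M/M-"      # reduction couple: M + e- -> M-


class State(str, Enum):
    GROUND = "ground"
    EXCITED = "excited"


class PairingError(ValueError):
    """Two records that must describe the same system do not."""


class ConventionError(ValueError):
    """Input violates the one-electron reduction convention."""


@dataclass(frozen=True)
class FreeEnergyRecord:
    """One species (molecule x charge state x solvent) from a QC table.

    ``E_s`` is the solution-phase electronic energy and ``G_corr`` the
    thermal correction to the Gibbs free energy, both in hartree.
    ``E_gas`` is optional and only needed for solvation diagnostics.
    """

    molecule_id: str
    charge: int
    solvent: str
    E_s: float
    G_corr: float
    method_tag: str = ""
    T: float = T_DEFAULT
    E_gas: float | None = None

    def __post_init__(self) -> None:
        for name in ("E_s", "G_corr"):
            v = getattr(self, name)
            if v is None or not math.isfinite(v):
                raise ValueError(
                    f"record ({self.molecule_id}, q={self.charge}, "
                    f"{self.solvent}, {self.method_tag}): {name} must be finite"
                )
        if self.E_s >= 0:
            logger.warning(
                "E_s = %.6f hartree >= 0 for %s (q=%d); real molecules have "
                "negative electronic energies", self.E_s, self.molecule_id,
                self.charge,
            )

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.molecule_id, self.charge, self.solvent, self.method_tag)


@dataclass(frozen=True)
class SolventConstants:
    """Reference-electrode constants for one working solvent."""

    solvent: str
    E_SCE_abs: float = E_SCE_ABS
    E_L: float = field(default=float("nan"))

    def __post_init__(self) -> None:
        if math.isnan(self.E_L):
            object.__setattr__(self, "E_L", E_L.get(self.solvent, 0.0))
            if self.solvent not in E_L:
                logger.warning(
                    "no intersolvent potential tabulated for solvent %r; "
                    "using E_L = 0.0 V", self.solvent,
                )

    @classmethod
    def for_solvent(cls, solvent: str) -> "SolventConstants":
        return cls(solvent=solvent)


@dataclass(frozen=True)
class HalfReactionResult:
    """Reduction half-reaction Gibbs energy in eV, with n_e electrons."""

    molecule_id: str
    couple: Couple
    solvent: str
    delta_G_r: float
    n_e: int = 1
    method_tag: str = ""

    def __post_init__(self) -> None:
        if self.n_e < 1:
            raise ConventionError(f"n_e must be >= 1, got {self.n_e}")


@dataclass(frozen=True)
class PotentialRecord:
    """A redox potential in V vs SCE.

    ``e00_route`` carries the provenance of the 0-0 energy for
    excited-state records and must be set for them.
    """

    molecule_id: str
    couple: Couple
    state: State
    solvent: str
    value: float
    method_tag: str = ""
    calibrated: bool = False
    e00_route: str | None = None

    def __post_init__(self) -> None:
        if self.state is State.EXCITED and not self.e00_route:
            raise ValueError(
                f"excited-state record for {self.molecule_id} must carry the "
                "E00 route used to build it"
            )


def gibbs_free_energy(rec: FreeEnergyRecord) -> float:
    """Solution-phase Gibbs free energy G(s) = E_s + G_corr, in hartree."""
    return rec.E_s + rec.G_corr


def _infer_couple(ox_charge: int, red_charge: int) -> Couple:
    # The couple name is relative to the neutral species: a pair at or
    # above neutral charge is the oxidation couple M+/M, below it the
    # reduction couple M/M-.  For species that are charged at rest (e.g.
    # eosin dianions) the same rule applies to their declared charges.
    if red_charge >= 0:
        return Couple.M_PLUS_OVER_M
    return Couple.M_OVER_M_MINUS


def half_reaction_delta_g(
    ox_form: FreeEnergyRecord, red_form: FreeEnergyRecord
) -> HalfReactionResult:
    """Gibbs energy of the reduction half-reaction ox + e- -> red, in eV.

    The electron's free energy is set to zero, so
    ``dG_r = G(red) - G(ox)`` directly.  Both records must describe the
    same molecule, solvent and method, and the reduced form must carry
    exactly one more electron (charge lower by one).
    """
    if (ox_form.molecule_id, ox_form.solvent, ox_form.method_tag) != (
        red_form.molecule_id, red_form.solvent, red_form.method_tag
    ):
        raise PairingError(
            f"cannot pair {ox_form.key} with {red_form.key}: molecule, "
            "solvent and method must match"
        )
    if red_form.charge != ox_form.charge - 1:
        raise ConventionError(
            f"reduction must add one electron: ox charge {ox_form.charge}, "
            f"red charge {red_form.charge}"
        )
    dg_hartree = gibbs_free_energy(red_form) - gibbs_free_energy(ox_form)
    return HalfReactionResult(
        molecule_id=ox_form.molecule_id,
        couple=_infer_couple(ox_form.charge, red_form.charge),
        solvent=ox_form.solvent,
        delta_G_r=dg_hartree * HARTREE_TO_EV,
        n_e=1,
        method_tag=ox_form.method_tag,
    )


def potential_vs_sce(
    hr: HalfReactionResult, consts: SolventConstants | None = None
) -> PotentialRecord:
    """Convert a half-reaction Gibbs energy to a potential vs SCE.

    ``E = -dG_r/n_e - E_SCE_abs - E_L``; the per-electron energy in eV is
    read directly as a potential in V.
    """
    if consts is None:
        consts = SolventConstants.for_solvent(hr.solvent)
    if consts.solvent != hr.solvent:
        raise PairingError(
            f"solvent mismatch: half reaction in {hr.solvent!r}, constants "
            f"for {consts.solvent!r}"
        )
    value = -hr.delta_G_r / hr.n_e - consts.E_SCE_abs - consts.E_L
    return PotentialRecord(
        molecule_id=hr.molecule_id,
        couple=hr.couple,
        state=State.GROUND,
        solvent=hr.solvent,
        value=value,
        method_tag=hr.method_tag,
        calibrated=False,
    )


def delta_g_from_potential(
    p: PotentialRecord, consts: SolventConstants | None = None, n_e: int = 1
) -> HalfReactionResult:
    """Exact inverse of :func:`potential_vs_sce` (ground state only).

    Excited-state potentials are *composed* from ground-state potentials
    and an E00 estimate; inverting them back to a half-reaction free
    energy would be a category error, so they are rejected.
    """
    if p.state is not State.GROUND:
        raise ValueError(
            "excited-state potentials are composed, not inverted; "
            f"got record for {p.molecule_id}"
        )
    if consts is None:
        consts = SolventConstants.for_solvent(p.solvent)
    if consts.solvent != p.solvent:
        raise PairingError(
            f"solvent mismatch: potential in {p.solvent!r}, constants for "
            f"{consts.solvent!r}"
        )
    delta_g = -(p.value + consts.E_SCE_abs + consts.E_L) * n_e
    return HalfReactionResult(
        molecule_id=p.molecule_id,
        couple=p.couple,
        solvent=p.solvent,
        delta_G_r=delta_g,
        n_e=n_e,
        method_tag=p.method_tag,
    )


def wavelength_to_energy(lambda_nm: float) -> float:
    """Photon energy in eV of a wavelength in nm (E = hc / lambda)."""
    if lambda_nm <= 0:
        raise ValueError(f"wavelength must be positive, got {lambda_nm}")
    return HC_EV_NM / lambda_nm


def energy_to_wavelength(energy_ev: float) -> float:
    """Wavelength in nm of a photon energy in eV; inverse of the above."""
    if energy_ev <= 0:
        raise ValueError(f"energy must be positive, got {energy_ev}")
    return HC_EV_NM / energy_ev
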