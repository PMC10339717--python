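"""0-0 transition energies and excited-state redox potentials.

The excited-state potentials of a photocatalyst M follow from its
ground-state potentials and the 0-0 transition energy E00 of the S0->S1
excitation:

    E(M+/M*) = E(M+/M) - E00
    E(M*/M-) = E(M/M-) + E00

(one-electron couples, so an energy in eV maps onto a potential in V).
Photoexcitation makes the catalyst simultaneously a stronger reductant
and a stronger oxidant, by E00 on each side.

Three routes provide E00 on the quantum-chemistry side:

* ``raw_abs`` — the first vertical absorption energy E_abs as-is; it
  systematically overestimates E00.
* ``scaled_abs`` — k * E_abs with the empirical factor k = 0.91.
* ``avg`` — the mean of vertical absorption and emission energies,
  which brackets E00 from both sides.

A fourth route, ``ml``, comes from the fingerprint regressor in
:mod:`photoredox.ml_e00`.  Every excited-state potential carries the
route of the E00 it was built from.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum

from .constants import E00_SCALE_DEFAULT
from .redox_core import Couple, PairingError, PotentialRecord, State

logger = logging.getLogger(__name__)


class E00Route(str, Enum):
    RAW_ABS = "raw_abs"
    SCALED_ABS = "scaled_abs"
    AVG = "avg"
    ML = "ml"


@dataclass(frozen=True)
class SpectralRecord:
    """Vertical absorption (and optionally emission) energies in eV."""

    molecule_id: str
    solvent: str
    E_abs: float
    E_em: float | None = None
    method_tag: str = ""

    def __post_init__(self) -> None:
        if self.E_abs is None or self.E_abs <= 0:
            raise ValueError(
                f"{self.molecule_id}: absorption energy must be positive"
            )
        if self.E_em is not None and self.E_em > self.E_abs:
            logger.warning(
                "%s: emission energy %.3f eV above absorption %.3f eV "
                "(anti-Stokes) — physically suspect input",
                self.molecule_id, self.E_em, self.E_abs,
            )


@dataclass(frozen=True)
class E00Estimate:
    """A 0-0 transition energy in eV with its provenance."""

    molecule_id: str
    solvent: str
    value: float
    route: E00Route
    scale_k: float | None = None

    def __post_init__(self) -> None:
        if self.value <= 0:
            raise ValueError(
                f"{self.molecule_id}: E00 must be positive, got {self.value}"
            )


class MissingEmissionError(ValueError):
    """The averaging route needs an emission energy that is absent."""


def e00_raw(s: SpectralRecord) -> E00Estimate:
    """E00 approximated by the vertical absorption energy itself."""
    return E00Estimate(molecule_id=s.molecule_id, solvent=s.solvent,
                       value=s.E_abs, route=E00Route.RAW_ABS)


def e00_scaled(s: SpectralRecord, k: float = E00_SCALE_DEFAULT) -> E00Estimate:
    """E00 = k * E_abs with the empirical scaling factor (default 0.91)."""
    if k <= 0:
        raise ValueError(f"scale factor must be positive, got {k}")
    return E00Estimate(molecule_id=s.molecule_id, solvent=s.solvent,
                       value=k * s.E_abs, route=E00Route.SCALED_ABS,
                       scale_k=k)


def e00_avg(s: SpectralRecord, *, fallback_scaled: bool = False) -> E00Estimate:
    """E00 as the mean of vertical absorption and emission energies.

    Missing emission is an error by default: averaging is a distinct,
    costlier route, not a fallback chain.  ``fallback_scaled=True``
    substitutes the scaled-absorption estimate with a logged warning.
    """
    if s.E_em is None:
        if fallback_scaled:
            logger.warning(
                "%s: no emission energy; falling back to scaled absorption",
                s.molecule_id,
            )
            return e00_scaled(s)
        raise MissingEmissionError(
            f"{s.molecule_id}: averaging route requires an emission energy"
        )
    return E00Estimate(molecule_id=s.molecule_id, solvent=s.solvent,
                       value=0.5 * (s.E_abs + s.E_em), route=E00Route.AVG)


def excited_potentials(
    ground_ox: PotentialRecord,
    ground_red: PotentialRecord,
    e00: E00Estimate,
) -> tuple[PotentialRecord, PotentialRecord]:
    """Compose E(M+/M*) and E(M*/M-) from ground potentials and E00.

    ``ground_ox`` is the oxidation couple E(M+/M), ``ground_red`` the
    reduction couple E(M/M-); both must be ground-state records of the
    same molecule and solvent as the E00 estimate.
    """
    for rec, want in ((ground_ox, Couple.M_PLUS_OVER_M),
                      (ground_red, Couple.M_OVER_M_MINUS)):
        if rec.state is not State.GROUND:
            raise ValueError(
                f"{rec.molecule_id}: composition needs ground-state inputs"
            )
        if rec.couple is not want:
            raise PairingError(
                f"{rec.molecule_id}: expected couple {want.value}, "
                f"got {rec.couple.value}"
            )
    keys = {(ground_ox.molecule_id, ground_ox.solvent),
            (ground_red.molecule_id, ground_red.solvent),
            (e00.molecule_id, e00.solvent)}
    if len(keys) != 1:
        raise PairingError(
            f"mixed molecule/solvent keys in composition: {sorted(keys)}"
        )
    route = e00.route.value
    ox_star = PotentialRecord(
        molecule_id=ground_ox.molecule_id, couple=Couple.M_PLUS_OVER_M,
        state=State.EXCITED, solvent=ground_ox.solvent,
        value=ground_ox.value - e00.value, method_tag=ground_ox.method_tag,
        calibrated=ground_ox.calibrated, e00_route=route,
    )
    red_star = PotentialRecord(
        molecule_id=ground_red.molecule_id, couple=Couple.M_OVER_M_MINUS,
        state=State.EXCITED, solvent=ground_red.solvent,
        value=ground_red.value + e00.value, method_tag=ground_red.method_tag,
        calibrated=ground_red.calibrated, e00_route=route,
    )
    return ox_star, red_star


@dataclass(frozen=True)
class QuenchingVerdict:
    """Feasibility of a quenching step against a partner couple."""

    feasible: bool
    driving_force: float  # V; positive favors the quenching step
    borderline: bool
    direction: str


def quenching_feasibility(
    excited: PotentialRecord,
    partner_potential: float,
    direction: str,
    *,
    borderline_tol: float = 1e-9,
) -> QuenchingVerdict:
    """Thermodynamic feasibility of oxidative or reductive quenching.

    Oxidative quenching (excited catalyst donates an electron, e.g. to
    O2) is feasible when E(M+/M*) lies below the partner potential;
    reductive quenching (excited catalyst accepts an electron, e.g. from
    an amine donor) when E(M*/M-) lies above it.  The driving force is
    the signed potential difference in V.
    """
    if excited.state is not State.EXCITED:
        raise ValueError("quenching feasibility is defined for excited records")
    if direction == "oxidative":
        force = partner_potential - excited.value
    elif direction == "reductive":
        force = excited.value - partner_potential
    else:
        raise ValueError(f"direction must be oxidative|reductive, got {direction!r}")
    borderline = abs(force) <= borderline_tol
    return QuenchingVerdict(feasible=force > 0 and not borderline,
                            driving_force=force, borderline=borderline,
                            direction=direction)
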