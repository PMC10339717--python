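"""Empirical error calibration for computed potentials and energies.

Quantum-chemistry redox potentials carry a largely systematic bias (the
error accompanying the change of one unit of charge in the half
reaction), so simple data-driven corrections remove most of it.  Three
correction kinds are supported:

* ``shift`` — an additive offset b chosen to minimize the mean absolute
  error (MAE); the MAE-optimal b is the median of the residuals
  ``ref - pred``, implemented in closed form.
* ``linear`` — slope/intercept fitted by least absolute deviations, so
  the shift correction is nested inside it.
* ``scale`` — a multiplicative factor k (e.g. the 0.91 factor mapping
  vertical absorption energies onto 0-0 transition energies), fitted by
  1-D minimization of the MAE.

The accuracy metric throughout is the MAE with a nonparametric
percentile-bootstrap 95% confidence interval over molecules.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
from scipy.optimize import minimize_scalar

logger = logging.getLogger(__name__)

#: Default resample count for bootstrap confidence intervals.
BOOTSTRAP_RESAMPLES = 10_000
BOOTSTRAP_SEED = 20210915

Scope = tuple[str, str] | Literal["universal"]


class AlignmentError(ValueError):
    """Prediction and reference vectors cannot be aligned."""


class DegenerateFitError(ValueError):
    """The requested fit is underdetermined on this input."""


@dataclass(frozen=True)
class ErrorStats:
    """MAE with a 95% bootstrap confidence interval."""

    mae: float
    ci_low: float
    ci_high: float
    n: int
    by_group: Mapping[str, "ErrorStats"] | None = None

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.mae <= self.ci_high):
            raise ValueError("CI must bracket the MAE")
        if self.mae < 0:
            raise ValueError("MAE is nonnegative")


@dataclass(frozen=True)
class CorrectionModel:
    """A fitted shift, linear, or scale correction.

    ``scope`` is either ``(method_tag, couple)`` or ``"universal"`` when
    the correction pools every method and couple.
    """

    kind: Literal["shift", "linear", "scale"]
    scope: Scope = "universal"
    shift_b: float | None = None
    slope: float | None = None
    intercept: float | None = None
    scale_k: float | None = None
    fitted_on_n: int = 0
    ci_seed: int | None = None

    def __post_init__(self) -> None:
        populated = {
            "shift": self.shift_b is not None and self.slope is None
            and self.intercept is None and self.scale_k is None,
            "linear": self.slope is not None and self.intercept is not None
            and self.shift_b is None and self.scale_k is None,
            "scale": self.scale_k is not None and self.shift_b is None
            and self.slope is None and self.intercept is None,
        }
        if not populated.get(self.kind, False):
            raise ValueError(
                f"{self.kind!r} correction must populate exactly its own "
                "parameters"
            )
        min_n = 2 if self.kind == "linear" else 1
        if self.fitted_on_n and self.fitted_on_n < min_n:
            raise ValueError(
                f"{self.kind} fit needs at least {min_n} points, "
                f"got {self.fitted_on_n}"
            )

    def apply(self, value: float) -> float:
        if self.kind == "shift":
            return value + self.shift_b
        if self.kind == "linear":
            return self.slope * value + self.intercept
        return self.scale_k * value

    # -- JSON round trip ---------------------------------------------------
    def to_json(self) -> str:
        d = {
            "kind": self.kind,
            "scope": list(self.scope) if isinstance(self.scope, tuple)
            else self.scope,
            "fitted_on_n": self.fitted_on_n,
            "ci_seed": self.ci_seed,
        }
        for f_ in ("shift_b", "slope", "intercept", "scale_k"):
            v = getattr(self, f_)
            if v is not None:
                d[f_] = v
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "CorrectionModel":
        d = json.loads(text)
        scope = d.pop("scope")
        if isinstance(scope, list):
            scope = tuple(scope)
        return cls(scope=scope, **d)


def _as_aligned(pred: Sequence[float], ref: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(pred, dtype=float)
    r = np.asarray(ref, dtype=float)
    if p.shape != r.shape or p.ndim != 1 or p.size == 0:
        raise AlignmentError(
            f"prediction and reference must be equal-length nonempty 1-D "
            f"arrays, got shapes {p.shape} and {r.shape}"
        )
    return p, r


def mae(
    pred: Sequence[float],
    ref: Sequence[float],
    *,
    n_boot: int = BOOTSTRAP_RESAMPLES,
    seed: int = BOOTSTRAP_SEED,
    groups: Sequence[str] | None = None,
) -> ErrorStats:
    """Mean absolute error with a percentile-bootstrap 95% CI.

    The bootstrap resamples molecules (index positions) with replacement;
    ``groups`` optionally adds per-group sub-statistics keyed by label.
    """
    p, r = _as_aligned(pred, ref)
    abs_err = np.abs(p - r)
    point = float(abs_err.mean())
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, abs_err.size, size=(n_boot, abs_err.size))
    boot = abs_err[idx].mean(axis=1)
    lo, hi = np.percentile(boot, [2.5, 97.5])
    lo, hi = min(float(lo), point), max(float(hi), point)
    by_group = None
    if groups is not None:
        g = np.asarray(groups)
        if g.shape != p.shape:
            raise AlignmentError("groups must align with predictions")
        by_group = {
            str(k): mae(p[g == k], r[g == k], n_boot=n_boot, seed=seed)
            for k in np.unique(g)
        }
    return ErrorStats(mae=point, ci_low=lo, ci_high=hi, n=abs_err.size,
                      by_group=by_group)


def fit_shift(
    pred: Sequence[float], ref: Sequence[float], scope: Scope = "universal"
) -> CorrectionModel:
    """MAE-optimal additive shift: the median of the residuals ref - pred.

    The mean absolute deviation is minimized by the median; for an even
    number of points NumPy's median (mean of the two central order
    statistics) is one of the minimizers.
    """
    p, r = _as_aligned(pred, ref)
    b = float(np.median(r - p))
    return CorrectionModel(kind="shift", scope=scope, shift_b=b,
                           fitted_on_n=p.size)


def fit_universal_shift(
    pred_by_method: Mapping[str, Sequence[float]],
    ref_by_method: Mapping[str, Sequence[float]],
) -> CorrectionModel:
    """Single shift minimizing the MAE pooled over all methods/couples.

    Equivalent to the median of all residuals concatenated across the
    per-method tables.
    """
    if not pred_by_method:
        raise AlignmentError("need at least one method")
    if set(pred_by_method) != set(ref_by_method):
        raise AlignmentError("method keys of predictions and references differ")
    residuals = []
    for m in pred_by_method:
        p, r = _as_aligned(pred_by_method[m], ref_by_method[m])
        residuals.append(r - p)
    pooled = np.concatenate(residuals)
    return CorrectionModel(kind="shift", scope="universal",
                           shift_b=float(np.median(pooled)),
                           fitted_on_n=pooled.size)


def fit_linear(
    pred: Sequence[float], ref: Sequence[float], scope: Scope = "universal"
) -> CorrectionModel:
    """Least-absolute-deviations line ref ~ slope*pred + intercept.

    Solved as iteratively reweighted optimization via scipy on the
    profile: for a fixed slope the optimal intercept is the residual
    median, leaving a 1-D convex problem in the slope.
    """
    p, r = _as_aligned(pred, ref)
    if p.size < 2:
        raise DegenerateFitError("linear fit needs at least 2 points")
    if np.ptp(p) == 0:
        raise DegenerateFitError("linear fit undefined for constant predictions")

    def lad(slope: float) -> float:
        resid = r - slope * p
        return float(np.abs(resid - np.median(resid)).mean())

    # The LAD objective is convex piecewise-linear in the slope; bracket
    # around the least-squares slope, which is always within a few
    # residual-scales of the LAD optimum.
    ls_slope = float(np.polyfit(p, r, 1)[0])
    span = 10.0 * (abs(ls_slope) + 1.0)
    res = minimize_scalar(lad, bounds=(ls_slope - span, ls_slope + span),
                          method="bounded",
                          options={"xatol": 1e-10, "maxiter": 500})
    slope = float(res.x)
    if p.size <= 200:
        # LAD optima sit at pairwise slopes; polishing over them makes
        # exact-line inputs recover slope/intercept exactly.
        dp = p[None, :] - p[:, None]
        dr = r[None, :] - r[:, None]
        cand = np.unique(dr[dp != 0] / dp[dp != 0])
        vals = [lad(c) for c in cand]
        j = int(np.argmin(vals))
        if vals[j] <= lad(slope):
            slope = float(cand[j])
    intercept = float(np.median(r - slope * p))
    return CorrectionModel(kind="linear", scope=scope, slope=slope,
                           intercept=intercept, fitted_on_n=p.size)


def fit_scale(
    e_abs: Sequence[float],
    e00_ref: Sequence[float],
    *,
    bracket: tuple[float, float] = (0.5, 1.2),
) -> CorrectionModel:
    """Multiplicative factor k minimizing mean |e00_ref - k*e_abs|.

    Intended for mapping vertical absorption energies onto 0-0 transition
    energies; k is found by bounded 1-D minimization on ``bracket``.
    """
    a, r = _as_aligned(e_abs, e00_ref)
    if (a <= 0).any() or (r <= 0).any():
        raise ValueError("energies must be positive")

    def objective(k: float) -> float:
        return float(np.abs(r - k * a).mean())

    res = minimize_scalar(objective, bounds=bracket, method="bounded",
                          options={"xatol": 1e-10, "maxiter": 500})
    k = float(res.x)
    # Exact-recovery polish: the objective is piecewise linear with kinks
    # at the ratios e00_ref/e_abs; if the best kink beats the continuous
    # optimum take it (this makes noiseless data recover k exactly).
    ratios = np.unique(r / a)
    ratios = ratios[(ratios >= bracket[0]) & (ratios <= bracket[1])]
    if ratios.size:
        vals = np.abs(r[None, :] - ratios[:, None] * a[None, :]).mean(axis=1)
        j = int(np.argmin(vals))
        if vals[j] <= objective(k):
            k = float(ratios[j])
    return CorrectionModel(kind="scale", scope="universal", scale_k=k,
                           fitted_on_n=a.size)


def apply_correction(value, model: CorrectionModel, *,
                     method_tag: str | None = None,
                     couple: str | None = None):
    """Apply a fitted correction to a number or a PotentialRecord.

    A scoped model only applies when the record's method and couple match
    its scope; universal models apply to anything.
    """
    from .redox_core import PotentialRecord  # local import: avoid cycle
    from dataclasses import replace

    if isinstance(value, PotentialRecord):
        _check_scope(model, value.method_tag, value.couple.value)
        return replace(value, value=model.apply(value.value), calibrated=True)
    _check_scope(model, method_tag, couple)
    return model.apply(float(value))


def _check_scope(model: CorrectionModel, method_tag, couple) -> None:
    if model.scope == "universal":
        return
    want_method, want_couple = model.scope
    if method_tag is not None and method_tag != want_method:
        raise ValueError(
            f"correction fitted for method {want_method!r} applied to "
            f"{method_tag!r}"
        )
    if couple is not None and str(couple) != str(want_couple):
        raise ValueError(
            f"correction fitted for couple {want_couple!r} applied to "
            f"{couple!r}"
        )
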