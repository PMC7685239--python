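"""Closed-form concentration-time solutions for oral compartmental PK models.

Implements one- and two-compartment disposition with first-order oral
absorption and an absorption lag time, parameterised by apparent (oral)
parameters CL/F, V2/F, Q/F, V3/F, ka, ALAG and a relative bioavailability
F1.  Doses are in mg, times in hours, volumes in litres; concentrations are
returned in ng/mL (the mg/L -> ng/mL factor of 1000 is applied exactly once,
in :func:`conc_single_dose`).

The solutions are sums of exponentials in the shifted time ``t - alag``.
When the absorption rate constant collides with a disposition rate the
profile degenerates to a ``t * exp(-rate * t)`` form; the limiting
expression is used instead of dividing by a near-zero difference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.optimize import minimize_scalar

__all__ = [
    "StructuralParams",
    "MicroConstants",
    "HybridRates",
    "DoseRegimen",
    "SecondaryParams",
    "micro_constants",
    "hybrid_rates",
    "conc_single_dose",
    "conc_regimen",
    "secondary_params",
]

#: relative tolerance below which ka is treated as equal to a disposition rate
DEGENERACY_RTOL = 1e-8

#: absolute tolerance (hours) of the tmax search
TMAX_XATOL = 1e-4

MG_PER_L_TO_NG_PER_ML = 1000.0


class ValidationError(ValueError):
    """Raised when a parameter set or dosing input violates its invariants."""


@dataclass(frozen=True)
class StructuralParams:
    """Apparent PK parameters of one individual or the typical subject.

    ``q_f`` and ``v3_f`` are jointly present (two-compartment) or jointly
    ``None`` (one-compartment).
    """

    cl_f: float
    v2_f: float
    ka: float
    alag: float = 0.0
    q_f: float | None = None
    v3_f: float | None = None
    f_rel: float = 1.0

    def __post_init__(self) -> None:
        for name in ("cl_f", "v2_f", "ka", "f_rel"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be strictly positive")
        if self.alag < 0:
            raise ValidationError("alag must be non-negative")
        if (self.q_f is None) != (self.v3_f is None):
            raise ValidationError("q_f and v3_f must be jointly present or absent")
        if self.q_f is not None and (self.q_f <= 0 or self.v3_f <= 0):
            raise ValidationError("q_f and v3_f must be strictly positive")

    @property
    def n_compartments(self) -> int:
        return 2 if self.q_f is not None else 1

    def scaled(self, **multipliers: float) -> "StructuralParams":
        """Return a copy with named parameters multiplied (e.g. by exp(eta))."""
        updates = {k: getattr(self, k) * v for k, v in multipliers.items()}
        return replace(self, **updates)


@dataclass(frozen=True)
class MicroConstants:
    """First-order micro rate constants (k10 = CL/V2, k12 = Q/V2, k21 = Q/V3)."""

    k10: float
    ka: float
    k12: float | None = None
    k21: float | None = None

    def __post_init__(self) -> None:
        if self.k10 <= 0 or self.ka <= 0:
            raise ValidationError("k10 and ka must be strictly positive")
        if (self.k12 is None) != (self.k21 is None):
            raise ValidationError("k12 and k21 must be jointly present or absent")
        if self.k12 is not None and (self.k12 <= 0 or self.k21 <= 0):
            raise ValidationError("k12 and k21 must be strictly positive")


@dataclass(frozen=True)
class HybridRates:
    """Hybrid disposition rates; ``lambda_z`` sets the terminal slope."""

    lambda1: float
    lambda_z: float

    def __post_init__(self) -> None:
        if not self.lambda_z > 0:
            raise ValidationError("lambda_z must be strictly positive")
        if self.lambda1 < self.lambda_z:
            raise ValidationError("lambda1 must be >= lambda_z")


@dataclass(frozen=True)
class DoseRegimen:
    """Ordered oral dose events ``(time h, amount mg)``; optional interval tau.

    When ``tau`` is set the regimen describes steady-state once-per-tau
    dosing at the amount of its (single) event, and the steady-state
    shortcut is available.
    """

    events: tuple[tuple[float, float], ...]
    tau: float | None = None

    def __init__(self, events: Sequence[tuple[float, float]], tau: float | None = None):
        events = tuple((float(t), float(a)) for t, a in events)
        if not events:
            raise ValidationError("regimen must contain at least one dose event")
        times = [t for t, _ in events]
        if any(t1 > t2 for t1, t2 in zip(times, times[1:])):
            raise ValidationError("dose times must be non-decreasing")
        if any(a <= 0 for _, a in events):
            raise ValidationError("dose amounts must be strictly positive")
        if tau is not None:
            if tau <= 0:
                raise ValidationError("tau must be positive")
            if len({a for _, a in events}) > 1:
                raise ValidationError(
                    "steady-state shortcut requires a single repeated amount"
                )
        object.__setattr__(self, "events", events)
        object.__setattr__(self, "tau", tau)

    @classmethod
    def steady_state(cls, amount: float, tau: float = 24.0) -> "DoseRegimen":
        return cls([(0.0, amount)], tau=tau)


@dataclass(frozen=True)
class SecondaryParams:
    """Derived (secondary) PK metrics at steady state under once-per-tau dosing."""

    t_half: float
    vz_f: float
    auc_inf_per_dose: float  # ng*h/mL per mg
    cmax: float
    tmax: float
    ctrough: float


def micro_constants(p: StructuralParams) -> MicroConstants:
    """Re-parameterize apparent clearances/volumes into micro rate constants."""
    if p.n_compartments == 2:
        return MicroConstants(
            k10=p.cl_f / p.v2_f, ka=p.ka, k12=p.q_f / p.v2_f, k21=p.q_f / p.v3_f
        )
    return MicroConstants(k10=p.cl_f / p.v2_f, ka=p.ka)


def hybrid_rates(m: MicroConstants) -> HybridRates:
    """Eigenvalues of the disposition system.

    For two compartments these are the roots of
    ``lam^2 - (k10 + k12 + k21) lam + k10 k21 = 0``; for one compartment both
    collapse to ``k10``.
    """
    if m.k12 is None:
        return HybridRates(lambda1=m.k10, lambda_z=m.k10)
    s = m.k10 + m.k12 + m.k21
    prod = m.k10 * m.k21
    disc = math.sqrt(max(s * s - 4.0 * prod, 0.0))
    lam1 = 0.5 * (s + disc)
    # compute the small root from the product to avoid cancellation
    lam_z = prod / lam1
    return HybridRates(lambda1=lam1, lambda_z=lam_z)


def _exp_terms(dose: float, p: StructuralParams) -> tuple[list[tuple[float, float]], list[tuple[float, float]]]:
    """Exponential decomposition of the single-dose profile in shifted time.

    Returns ``(exp_terms, texp_terms)`` where the profile is
    ``sum(A * exp(-mu t')) + sum(B * t' * exp(-mu t'))`` in ng/mL.
    """
    exp_terms, texp_terms = unit_exp_terms(
        p.cl_f, p.v2_f, p.ka, p.f_rel, p.q_f, p.v3_f
    )
    return (
        [(dose * c, mu) for c, mu in exp_terms],
        [(dose * c, mu) for c, mu in texp_terms],
    )


def _eval_terms(
    tshift: np.ndarray,
    exp_terms: Sequence[tuple[float, float]],
    texp_terms: Sequence[tuple[float, float]],
    tau: float | None = None,
) -> np.ndarray:
    """Evaluate the exponential decomposition; with ``tau`` apply steady-state
    per-exponential geometric accumulation (valid for any t >= 0 interpreted
    as time since the most recent administered dose).

    At steady state the profile inside the lag window (shifted time <= 0) is
    fed by the previous doses only; those times are mapped forward by one
    interval so the accumulated sum starts at the first contributing dose.
    """
    tshift = np.asarray(tshift, dtype=float)
    out = np.zeros_like(tshift, dtype=float)
    if tau is not None:
        tshift = np.where(tshift <= 0, tshift + tau, tshift)
    pos = tshift > 0
    ts = tshift[pos]
    acc = np.zeros_like(ts)
    for coef, mu in exp_terms:
        e = np.exp(-mu * ts)
        if tau is not None:
            e = e / (1.0 - math.exp(-mu * tau))
        acc += coef * e
    for coef, mu in texp_terms:
        e = np.exp(-mu * ts)
        if tau is None:
            acc += coef * ts * e
        else:
            r = math.exp(-mu * tau)
            acc += coef * e * (ts / (1.0 - r) + tau * r / (1.0 - r) ** 2)
    out[pos] = acc
    return out


def conc_single_dose(t, dose: float, p: StructuralParams):
    """Concentration (ng/mL) after a single oral dose at time 0.

    Zero for ``t <= alag``; Bateman (one-compartment) or tri-exponential
    (two-compartment) closed form in the shifted time ``t - alag``, linear
    in ``dose``.
    """
    if dose <= 0:
        raise ValidationError("dose must be strictly positive")
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValidationError("times must be non-negative")
    exp_terms, texp_terms = _exp_terms(dose, p)
    out = _eval_terms(t_arr - p.alag, exp_terms, texp_terms)
    if np.isscalar(t) or t_arr.ndim == 0:
        return float(out)
    return out


def conc_steady_state(t, dose: float, tau: float, p: StructuralParams):
    """Steady-state concentration at time ``t`` since the last dose of an
    infinite once-per-tau history (superposition limit)."""
    t_arr = np.asarray(t, dtype=float)
    exp_terms, texp_terms = _exp_terms(dose, p)
    out = _eval_terms(t_arr - p.alag, exp_terms, texp_terms, tau=tau)
    if np.isscalar(t) or t_arr.ndim == 0:
        return float(out)
    return out


def conc_regimen(times, regimen: DoseRegimen, p: StructuralParams):
    """Concentrations (ng/mL) under a dosing history by superposition.

    With ``regimen.tau`` set the steady-state shortcut is used: each
    exponential term is accumulated geometrically, which equals the infinite
    superposition limit.  Times are measured from the first dose (or, for
    the steady-state shortcut, from the reference dose of the cycle).
    """
    t_arr = np.atleast_1d(np.asarray(times, dtype=float))
    if np.any(t_arr < 0):
        raise ValidationError("times must be non-negative")
    if regimen.tau is not None:
        out = conc_steady_state(t_arr, regimen.events[0][1], regimen.tau, p)
    else:
        dose_times = np.array([t for t, _ in regimen.events])
        amounts = np.array([a for _, a in regimen.events])
        out = conc_events(t_arr, dose_times, amounts, p)
    if np.isscalar(times) or np.asarray(times).ndim == 0:
        return float(out[0])
    return out


def unit_exp_terms(
    cl_f: float,
    v2_f: float,
    ka: float,
    f_rel: float = 1.0,
    q_f: float | None = None,
    v3_f: float | None = None,
) -> tuple[list[tuple[float, float]], list[tuple[float, float]]]:
    """Exponential decomposition for a unit (1 mg) dose from raw scalars.

    Fast path used inside the estimation loop; equivalent to
    ``_exp_terms(1.0, StructuralParams(...))`` without object construction.
    """
    scale = f_rel / v2_f * MG_PER_L_TO_NG_PER_ML
    exp_terms: list[tuple[float, float]] = []
    texp_terms: list[tuple[float, float]] = []
    k10 = cl_f / v2_f
    if q_f is None:
        if abs(ka - k10) < DEGENERACY_RTOL * k10:
            texp_terms.append((scale * ka, k10))
        else:
            c = scale * ka / (ka - k10)
            exp_terms.append((c, k10))
            exp_terms.append((-c, ka))
        return exp_terms, texp_terms
    k12 = q_f / v2_f
    k21 = q_f / v3_f
    s = k10 + k12 + k21
    prod = k10 * k21
    lam1 = 0.5 * (s + math.sqrt(max(s * s - 4.0 * prod, 0.0)))
    lam = (lam1, prod / lam1)
    degen = [abs(ka - li) < DEGENERACY_RTOL * li for li in lam]
    if not any(degen):
        for i, li in enumerate(lam):
            lj = lam[1 - i]
            exp_terms.append((scale * ka * (k21 - li) / ((ka - li) * (lj - li)), li))
        exp_terms.append((scale * ka * (k21 - ka) / ((lam[0] - ka) * (lam[1] - ka)), ka))
    else:
        i = degen.index(True)
        a, b = lam[i], lam[1 - i]
        exp_terms.append((scale * ka * (k21 - b) / ((a - b) * (a - b)), b))
        texp_terms.append((scale * ka * (k21 - a) / (b - a), a))
        exp_terms.append((-scale * ka * (k21 - b) / ((b - a) * (b - a)), a))
    return exp_terms, texp_terms


def conc_events(
    times: np.ndarray,
    dose_times: np.ndarray,
    amounts: np.ndarray,
    p: StructuralParams,
) -> np.ndarray:
    """Vectorized superposition over an arbitrary dose-event history.

    Exploits linearity in dose: the unit-dose exponential coefficients are
    computed once and summed over the (dose, time) lattice in one pass.
    """
    exp_terms, texp_terms = _exp_terms(1.0, p)
    # shifted elapsed time of each (dose, observation) pair
    dt = times[None, :] - dose_times[:, None] - p.alag  # (D, T)
    mask = dt > 0
    dts = np.where(mask, dt, 0.0)
    amt = amounts[:, None]
    out = np.zeros_like(times, dtype=float)
    for coef, mu in exp_terms:
        out += coef * np.sum(np.where(mask, amt * np.exp(-mu * dts), 0.0), axis=0)
    for coef, mu in texp_terms:
        out += coef * np.sum(
            np.where(mask, amt * dts * np.exp(-mu * dts), 0.0), axis=0
        )
    return out


def tmax_one_compartment(p: StructuralParams) -> float:
    """Closed-form single-dose tmax for the one-compartment model."""
    k10 = p.cl_f / p.v2_f
    if abs(p.ka - k10) < DEGENERACY_RTOL * k10:
        return 1.0 / k10 + p.alag
    return math.log(p.ka / k10) / (p.ka - k10) + p.alag


def secondary_params(p: StructuralParams, regimen: DoseRegimen) -> SecondaryParams:
    """Derived PK metrics: terminal half-life, Vz/F, dose-normalized AUC,
    and the steady-state Cmax/tmax/Ctrough under once-per-tau dosing.

    ``auc_inf_per_dose`` is reported as ``f_rel / cl_f`` in ng*h/mL per mg,
    which for linear kinetics equals both AUC(0-inf) of a unit single dose
    and the steady-state AUC over one dosing interval per unit dose.
    """
    if regimen.tau is None:
        raise ValidationError("secondary_params requires a regimen with tau set")
    tau = regimen.tau
    dose = regimen.events[0][1]
    h = hybrid_rates(micro_constants(p))
    t_half = math.log(2.0) / h.lambda_z
    vz_f = p.cl_f / h.lambda_z
    auc_per_dose = p.f_rel / p.cl_f * MG_PER_L_TO_NG_PER_ML

    if not tau > p.alag:
        raise ValidationError("tau must exceed the absorption lag time")

    def neg_conc(t: float) -> float:
        return -conc_steady_state(t, dose, tau, p)

    lo = p.alag + 1e-9
    res = minimize_scalar(
        neg_conc, bounds=(lo, tau), method="bounded", options={"xatol": TMAX_XATOL}
    )
    if not res.success:  # pragma: no cover - bounded search is robust
        raise RuntimeError(f"tmax search did not converge: {res.message}")
    tmax = float(res.x)
    cmax = -float(res.fun)
    ctrough = conc_steady_state(tau, dose, tau, p)
    return SecondaryParams(
        t_half=t_half,
        vz_f=vz_f,
        auc_inf_per_dose=auc_per_dose,
        cmax=cmax,
        tmax=tmax,
        ctrough=ctrough,
    )
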