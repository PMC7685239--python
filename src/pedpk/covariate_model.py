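"""Covariate model: subject covariates to individual PK parameters.

Maps fat-free mass (allometric power model), alpha-1-acid glycoprotein
(AGP, power model) and, for infants, CYP3A4 maturation onto the typical
structural parameters; realizes log-normal inter-individual variability;
applies combined additive + proportional residual error; and computes
weight-adjusted pediatric equivalent doses (PED).

AGP enters strictly as a ratio to the model's reference level, so its
units cancel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .structural_pk import StructuralParams, ValidationError

__all__ = [
    "Subject",
    "CovariateCoeffs",
    "OntogenyConfig",
    "OmegaSpec",
    "SigmaSpec",
    "DoseTable",
    "cyp3a4_maturation",
    "typical_params",
    "realize_individual",
    "apply_residual",
    "ped_dose",
    "age_group_label",
    "default_ffm",
]

PED_LEVELS = (2.5, 5.0, 7.5, 10.0)


def age_group_label(age: float) -> str:
    """Age-group label used throughout the trials' summaries."""
    if age < 0.5:
        raise ValidationError(f"age {age} below the trials' 6-month minimum")
    if age < 2:
        return "infant (0.5-<2 y)"
    if age < 5:
        return "young child (2-<5 y)"
    if age < 12:
        return "child (5-<12 y)"
    if age < 18:
        return "adolescent (12-<18 y)"
    return "adult (>=18 y)"


def default_ffm(age: float, weight: float) -> float:
    """Default fat-free-mass imputation for synthetic subjects.

    A simple declining fat-free fraction with age past 5 years; real
    datasets must carry FFM explicitly.
    """
    return weight * (0.85 - 0.003 * max(age - 5.0, 0.0))


@dataclass(frozen=True)
class Subject:
    """Covariate record for one trial participant."""

    id: str
    age: float  # years
    weight: float  # kg
    ffm: float  # kg
    agp: float  # ratio units relative to the model reference
    population: str = "OAB"  # OAB or NDO
    formulation: str = "A"  # reference suspension "A" or alternate "B"

    def __post_init__(self) -> None:
        if self.age <= 0:
            raise ValidationError(f"subject {self.id}: age must be positive")
        if not 0 < self.ffm <= self.weight:
            raise ValidationError(
                f"subject {self.id}: ffm must satisfy 0 < ffm <= weight"
            )
        if self.agp <= 0:
            raise ValidationError(f"subject {self.id}: agp must be positive")
        if self.population not in ("OAB", "NDO"):
            raise ValidationError(f"subject {self.id}: unknown population")

    @property
    def age_group(self) -> str:
        return age_group_label(self.age)


@dataclass(frozen=True)
class OntogenyConfig:
    """CYP3A4 maturation: Hill function of postnatal age.

    ``tm50`` is the age (years) of half-maximal activity and ``hill`` the
    sigmoidicity.  The defaults place near-complete maturation by age 2.
    """

    tm50: float = 0.3
    hill: float = 2.0

    def __post_init__(self) -> None:
        if self.tm50 <= 0 or self.hill <= 0:
            raise ValidationError("tm50 and hill must be positive")


@dataclass(frozen=True)
class CovariateCoeffs:
    """Population typical values and covariate coefficients.

    ``theta`` holds the typical structural parameters at the reference
    covariates (ffm_ref, agp_ref); ``ffm_exp``/``agp_exp`` are power-model
    exponents keyed by structural-parameter name.  ``theta_f1`` is the
    relative bioavailability of the alternate formulation.
    """

    theta: dict[str, float]
    ffm_exp: dict[str, float] = field(default_factory=dict)
    agp_exp: dict[str, float] = field(default_factory=dict)
    ffm_ref: float = 24.0
    agp_ref: float = 67.0
    ontogeny_enabled: bool = False
    cyp3a4_fraction: float = 0.8
    ontogeny: OntogenyConfig = field(default_factory=OntogenyConfig)
    theta_f1: float = 1.0

    def __post_init__(self) -> None:
        if self.ffm_ref <= 0 or self.agp_ref <= 0:
            raise ValidationError("ffm_ref and agp_ref must be positive")
        if not 0.0 <= self.cyp3a4_fraction <= 1.0:
            raise ValidationError("cyp3a4_fraction must lie in [0, 1]")
        for key in ("cl_f", "v2_f", "ka"):
            if key not in self.theta:
                raise ValidationError(f"theta must define {key}")

    @property
    def is_two_compartment(self) -> bool:
        return "q_f" in self.theta and "v3_f" in self.theta


@dataclass(frozen=True)
class OmegaSpec:
    """Log-scale inter-individual variability (SDs of eta) per parameter."""

    sd: dict[str, float]
    corr: np.ndarray | None = None  # optional correlation among listed etas

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.sd.values()):
            raise ValidationError("omega SDs must be non-negative")
        if self.corr is not None:
            c = np.asarray(self.corr, dtype=float)
            if c.shape != (len(self.sd), len(self.sd)):
                raise ValidationError("correlation matrix shape mismatch")
            eig = np.linalg.eigvalsh((c + c.T) / 2)
            if eig.min() < -1e-10:
                raise ValidationError("correlation matrix must be PSD")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.sd)

    def covariance(self) -> np.ndarray:
        s = np.array([self.sd[k] for k in self.names])
        if self.corr is None:
            return np.diag(s**2)
        return np.asarray(self.corr) * np.outer(s, s)


@dataclass(frozen=True)
class SigmaSpec:
    """Residual error: combined proportional (fraction) + additive (ng/mL)."""

    prop: float = 0.0
    add: float = 0.0
    study: str = ""

    def __post_init__(self) -> None:
        if self.prop < 0 or self.add < 0:
            raise ValidationError("sigma components must be non-negative")

    def variance(self, pred: np.ndarray) -> np.ndarray:
        return (self.prop * np.asarray(pred)) ** 2 + self.add**2


def cyp3a4_maturation(age: float, cfg: OntogenyConfig | None = None) -> float:
    """Fraction of adult CYP3A4 activity at a given postnatal age (years).

    Hill function ``age^h / (age^h + tm50^h)``: monotone increasing,
    half-maximal at ``tm50`` and approaching 1 with age.
    """
    cfg = cfg or OntogenyConfig()
    if age <= 0:
        raise ValidationError("age must be positive")
    ah = age**cfg.hill
    return ah / (ah + cfg.tm50**cfg.hill)


def typical_params(s: Subject, c: CovariateCoeffs) -> StructuralParams:
    """Individual typical parameters from covariates.

    Clearance and volumes scale with fat-free mass by estimated allometric
    exponents and with AGP by power models; for infants the CYP3A4-mediated
    fraction of clearance is scaled by the maturation function.
    """
    for fld in ("ffm", "agp", "age"):
        val = getattr(s, fld, None)
        if val is None or (isinstance(val, float) and math.isnan(val)):
            raise ValidationError(f"subject {s.id}: missing covariate {fld}")

    ffm_r = s.ffm / c.ffm_ref
    agp_r = s.agp / c.agp_ref

    def scale(name: str) -> float:
        out = c.theta[name]
        if name in c.ffm_exp:
            out *= ffm_r ** c.ffm_exp[name]
        if name in c.agp_exp:
            out *= agp_r ** c.agp_exp[name]
        return out

    cl = scale("cl_f")
    if c.ontogeny_enabled:
        mat = cyp3a4_maturation(s.age, c.ontogeny)
        cl *= 1.0 - c.cyp3a4_fraction * (1.0 - mat)
    kwargs: dict[str, float | None] = dict(
        cl_f=cl,
        v2_f=scale("v2_f"),
        ka=c.theta["ka"],
        alag=c.theta.get("alag", 0.0),
        f_rel=1.0 if s.formulation == "A" else c.theta_f1,
    )
    if c.is_two_compartment:
        kwargs["q_f"] = c.theta["q_f"]
        kwargs["v3_f"] = scale("v3_f")
    return StructuralParams(**kwargs)


def realize_individual(
    typ: StructuralParams, omega: OmegaSpec, rng: np.random.Generator
) -> tuple[StructuralParams, dict[str, float]]:
    """Draw one individual: multiply each affected parameter by exp(eta).

    Returns the realized parameters and the eta draws.  Deterministic for a
    fixed generator state.
    """
    names = omega.names
    if not names:
        return typ, {}
    if omega.corr is None:
        eta = np.array([rng.normal(0.0, omega.sd[k]) for k in names])
    else:
        # eigh factorisation tolerates semi-definite (zero-variance) blocks
        eta = rng.multivariate_normal(
            np.zeros(len(names)), omega.covariance(), method="eigh"
        )
    draws = dict(zip(names, eta))
    return typ.scaled(**{k: math.exp(e) for k, e in draws.items()}), draws


def apply_residual(
    conc, sigma: SigmaSpec, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Observed concentration ``y = conc * (1 + eps_p) + eps_a``.

    Negative results are floored at zero; the returned boolean mask flags
    floored values.
    """
    c = np.atleast_1d(np.asarray(conc, dtype=float))
    if np.any(c < 0):
        raise ValidationError("concentrations must be non-negative")
    y = c * (1.0 + rng.normal(0.0, sigma.prop, size=c.shape)) + rng.normal(
        0.0, sigma.add, size=c.shape
    )
    floored = y < 0
    return np.where(floored, 0.0, y), floored


@dataclass(frozen=True)
class DoseTable:
    """Pediatric-equivalent dose rule.

    The default rule scales the adult dose by ``(ffm / ffm_adult_ref)``
    raised to the clearance allometric exponent, so the typical
    steady-state AUC is independent of body size, then rounds to the
    suspension granularity (0.5 mg for the 1 mg/mL suspension).  An
    explicit band table (list of ``(level, min_ffm, max_ffm, dose_mg)``)
    may be supplied instead.
    """

    ffm_adult_ref: float = 52.0
    exponent: float = 0.652
    granularity: float = 0.5
    min_ffm: float = 5.0
    bands: tuple[tuple[float, float, float, float], ...] | None = None

    def __post_init__(self) -> None:
        if self.bands is not None:
            by_level: dict[float, list[tuple[float, float]]] = {}
            for level, lo, hi, dose in self.bands:
                if dose <= 0 or hi <= lo:
                    raise ValidationError("malformed dose band")
                by_level.setdefault(level, []).append((lo, dose))
            for level, rows in by_level.items():
                doses = [d for _, d in sorted(rows)]
                if any(a > b for a, b in zip(doses, doses[1:])):
                    raise ValidationError(
                        f"doses must be non-decreasing in size (level {level})"
                    )


def ped_dose(level: float, s: Subject, table: DoseTable | None = None) -> float:
    """Weight-adjusted pediatric equivalent dose (mg) for one subject.

    ``level`` is the adult-equivalent dose: one of 2.5, 5, 7.5 or 10 mg.
    """
    if level not in PED_LEVELS:
        raise ValidationError(f"PED level must be one of {PED_LEVELS}")
    table = table or DoseTable()
    if table.bands is not None:
        for lev, lo, hi, dose in table.bands:
            if lev == level and lo <= s.ffm < hi:
                return dose
        raise ValidationError(
            f"subject {s.id}: no dose band covers FFM {s.ffm} at PED{level:g}"
        )
    if s.ffm < table.min_ffm:
        raise ValidationError(
            f"subject {s.id}: FFM {s.ffm} below dosing table minimum {table.min_ffm}"
        )
    raw = level * (s.ffm / table.ffm_adult_ref) ** table.exponent
    dose = round(raw / table.granularity) * table.granularity
    return max(dose, table.granularity)
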