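"""Synthetic clinical-trial simulator.

Emulates the three phase-III pediatric solifenacin designs end to end —
population sampling, 3-weekly dose titration among the weight-adjusted
pediatric equivalent doses (PED2.5/5/7.5/10), sparse PK sampling windows,
combined residual error and censoring at the assay lower limit — plus the
richly sampled single-dose design used to stabilise the two-compartment
model.  Output is an analysis-ready event dataset in NONMEM-format layout.

Shipped presets: ``lion`` (OAB, 5-<18 y, 12 weeks, washout sample),
``monkey`` (NDO, 5-<18 y, 52 weeks), ``marmoset`` (NDO, 0.5-<5 y, 52
weeks, CYP3A4 ontogeny relevant) and ``giraffe`` (OAB, single dose at
three times the PED with a rich grid).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from . import covariate_model as cm
from .structural_pk import DoseRegimen, ValidationError, conc_regimen

__all__ = [
    "Stratum",
    "TrialConfig",
    "TitrationRules",
    "SimulationModel",
    "PKDataset",
    "DATASET_COLUMNS",
    "sample_population",
    "simulate_titration",
    "draw_sampling_times",
    "simulate_trial",
]

DATASET_COLUMNS = [
    "ID", "TIME", "TAD", "AMT", "DV", "EVID", "MDV", "BLQ",
    "PED", "WEEK", "AGE", "WT", "FFM", "AGP", "STUDY", "FORM",
]

#: rich sampling grid (h post dose) for the single-dose design
DEFAULT_RICH_GRID = (0.5, 1.0, 2.0, 3.0, 4.0, 6.0, 8.0, 12.0, 24.0, 48.0, 72.0)

ASSAY_LLOQ = 0.2  # ng/mL
ASSAY_ULOQ = 200.0  # ng/mL


@dataclass(frozen=True)
class Stratum:
    """One age stratum of a trial population."""

    label: str
    age_lo: float
    age_hi: float
    n: int
    weight_mean: float | None = None
    weight_sd: float | None = None
    weight_floor: float = 3.0
    #: optional piecewise-linear age -> median weight curve [(age, kg), ...]
    age_weight_curve: tuple[tuple[float, float], ...] | None = None
    weight_cv: float = 0.15  # used with the age-weight curve

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValidationError("stratum n must be non-negative")
        if self.age_hi <= self.age_lo:
            raise ValidationError("age range must be increasing")
        if self.age_weight_curve is None and (
            self.weight_mean is None or self.weight_sd is None
        ):
            raise ValidationError("stratum needs weight_mean/sd or an age-weight curve")


@dataclass(frozen=True)
class TitrationRules:
    """Per-visit titration policy.

    At each titration visit a bothersome event (probability ``p_down``)
    forces a one-level down-titration; otherwise a not-yet-dry patient
    (probability ``p_up``) is up-titrated one level.  ``propensity_sd``
    optionally spreads ``p_up`` across subjects on the logit scale.
    """

    p_up: float = 0.63
    p_down: float = 0.03
    propensity_sd: float = 0.0

    def __post_init__(self) -> None:
        if not (0 <= self.p_up <= 1 and 0 <= self.p_down <= 1):
            raise ValidationError("titration probabilities must lie in [0, 1]")

    def subject_p_up(self, rng: np.random.Generator) -> float:
        if self.propensity_sd == 0:
            return self.p_up
        p = min(max(self.p_up, 1e-6), 1 - 1e-6)
        logit = np.log(p / (1 - p)) + rng.normal(0.0, self.propensity_sd)
        return float(1.0 / (1.0 + np.exp(-logit)))


@dataclass(frozen=True)
class TrialConfig:
    """Design of one trial arm as simulated."""

    name: str
    study: str
    population: str
    strata: tuple[Stratum, ...]
    titration_weeks: tuple[int, ...]
    pk_visit_weeks: tuple[int, ...]
    duration_weeks: int
    #: (label, start h, end h) relative to the visit-day dose; pre-dose
    #: windows use negative offsets
    sampling_windows: tuple[tuple[str, float, float], ...]
    washout_window: tuple[float, float] | None = None
    start_level: float = 5.0
    start_level_under2: float = 2.5
    agp_median: float = 67.0
    agp_sdlog: float = 0.25
    titration: TitrationRules = field(default_factory=TitrationRules)
    lloq: float = ASSAY_LLOQ
    uloq: float = ASSAY_ULOQ
    single_dose: bool = False
    dose_multiplier: float = 1.0
    rich_grid: tuple[float, ...] | None = None
    #: single-dose designs assign each subject one ascending-dose level
    single_dose_levels: tuple[float, ...] = (2.5, 5.0, 10.0)
    formulation: str = "A"
    dose_jitter_h: float = 0.0

    def __post_init__(self) -> None:
        if not self.strata:
            raise ValidationError("trial must define at least one stratum")
        if not self.single_dose:
            if not self.sampling_windows:
                raise ValidationError("sampling windows must be non-empty")
            if list(self.titration_weeks) != sorted(self.titration_weeks):
                raise ValidationError("titration weeks must be ordered")
            if max(self.pk_visit_weeks, default=0) > self.duration_weeks:
                raise ValidationError("PK visit after trial end")
        if self.lloq < 0 or self.uloq <= self.lloq:
            raise ValidationError("assay limits must satisfy 0 <= lloq < uloq")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass(frozen=True)
class SimulationModel:
    """Model under which observations are generated."""

    coeffs: cm.CovariateCoeffs
    omega: cm.OmegaSpec
    sigma: cm.SigmaSpec
    dose_table: cm.DoseTable = field(default_factory=cm.DoseTable)


@dataclass
class PKDataset:
    """Longitudinal PK event records (NONMEM-format layout) plus provenance."""

    df: pd.DataFrame
    config_hash: str = ""
    seed: int | None = None

    def __post_init__(self) -> None:
        missing = [c for c in DATASET_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValidationError(f"dataset missing columns: {missing}")
        self.validate()

    def validate(self) -> None:
        df = self.df
        both = (df["EVID"] == 1) & df["DV"].notna()
        if both.any():
            raise ValidationError("rows cannot carry both a dose and an observation")
        if ((df["EVID"] == 0) & df["AMT"].notna()).any():
            raise ValidationError("observation rows cannot carry AMT")
        if ((df["BLQ"] == 1) & df["DV"].notna()).any():
            raise ValidationError("censored rows must not carry a numeric DV")
        for sid, g in df.groupby("ID", sort=False):
            t = g["TIME"].to_numpy()
            if np.any(np.diff(t) < 0):
                raise ValidationError(f"subject {sid}: times not non-decreasing")
            is_obs = (g["EVID"] == 0).to_numpy()
            is_dose = (g["EVID"] == 1).to_numpy()
            if is_obs.any():
                first_obs = int(np.argmax(is_obs))
                if not is_dose[:first_obs].any():
                    raise ValidationError(
                        f"subject {sid}: observation before any dose"
                    )

    @property
    def n_subjects(self) -> int:
        return self.df["ID"].nunique()

    def observations(self, include_blq: bool = False) -> pd.DataFrame:
        obs = self.df[self.df["EVID"] == 0]
        if not include_blq:
            obs = obs[obs["BLQ"] == 0]
        return obs

    def doses(self) -> pd.DataFrame:
        return self.df[self.df["EVID"] == 1]


def _interp_curve(age: float, curve: Sequence[tuple[float, float]]) -> float:
    xs = np.array([a for a, _ in curve])
    ys = np.array([w for _, w in curve])
    return float(np.interp(age, xs, ys))


def sample_population(cfg: TrialConfig, rng: np.random.Generator) -> list[cm.Subject]:
    """Draw a trial population: uniform ages within each stratum, truncated
    normal weights (+-2.5 SD and above a per-stratum floor), log-normal AGP
    around the reference median, and the default fat-free-mass imputation."""
    subjects: list[cm.Subject] = []
    idx = 1
    for st in cfg.strata:
        for _ in range(st.n):
            age = float(rng.uniform(st.age_lo, st.age_hi))
            if st.age_weight_curve is not None:
                mu = _interp_curve(age, st.age_weight_curve)
                sd = st.weight_cv * mu
            else:
                mu, sd = st.weight_mean, st.weight_sd
            lo = max(mu - 2.5 * sd, st.weight_floor)
            hi = mu + 2.5 * sd
            while True:
                w = float(rng.normal(mu, sd))
                if lo <= w <= hi:
                    break
            agp = float(cfg.agp_median * np.exp(rng.normal(0.0, cfg.agp_sdlog)))
            subjects.append(
                cm.Subject(
                    id=f"{cfg.study}-{idx:04d}",
                    age=age,
                    weight=w,
                    ffm=cm.default_ffm(age, w),
                    agp=agp,
                    population=cfg.population,
                    formulation=cfg.formulation,
                )
            )
            idx += 1
    return subjects


def simulate_titration(
    s: cm.Subject,
    rules: TitrationRules,
    cfg: TrialConfig,
    rng: np.random.Generator,
) -> dict[int, float]:
    """Dose level (PED) in force from each week boundary.

    Returns ``{week: level}`` for week 0 and each titration visit; the level
    moves at most one step per visit, clamped to the PED ladder, and is
    fixed after the last titration week.
    """
    levels = list(cm.PED_LEVELS)
    start = cfg.start_level_under2 if s.age < 2 else cfg.start_level
    level = start
    p_up = rules.subject_p_up(rng)
    schedule = {0: level}
    for week in cfg.titration_weeks:
        i = levels.index(level)
        if rng.uniform() < rules.p_down:
            i = max(i - 1, 0)
        elif rng.uniform() < p_up:
            i = min(i + 1, len(levels) - 1)
        level = levels[i]
        schedule[week] = level
    return schedule


def draw_sampling_times(
    cfg: TrialConfig, visit_week: int, rng: np.random.Generator
) -> list[float]:
    """Sampling offsets (h) relative to the visit-day dose.

    One uniform draw per window; pre-dose windows yield negative offsets.
    When the design includes a washout sample it is drawn relative to the
    final (trial-end) dose and appended for the last PK visit.
    """
    times = []
    for _, lo, hi in cfg.sampling_windows:
        u = float(rng.uniform(lo, hi))
        if hi <= 0 and u == hi:  # keep pre-dose draws strictly before dosing
            u = np.nextafter(hi, lo)
        times.append(u)
    if cfg.washout_window is not None and visit_week == max(cfg.pk_visit_weeks):
        lo, hi = cfg.washout_window
        times.append(float(rng.uniform(lo, hi)))
    return times


def _subject_rows(
    s: cm.Subject,
    cfg: TrialConfig,
    model: SimulationModel,
    rng: np.random.Generator,
    noise: bool,
    censor: bool,
) -> list[dict]:
    typical = cm.typical_params(s, model.coeffs)
    params, _ = cm.realize_individual(typical, model.omega, rng)

    rows: list[dict] = []
    base = dict(
        AGE=s.age, WT=s.weight, FFM=s.ffm, AGP=s.agp,
        STUDY=cfg.study, FORM=s.formulation,
    )

    if cfg.single_dose:
        level = float(rng.choice(cfg.single_dose_levels))
        amount = cfg.dose_multiplier * cm.ped_dose(level, s, model.dose_table)
        dose_times = np.array([0.0])
        amounts = np.array([amount])
        dose_levels = np.array([level])
        grid = cfg.rich_grid or DEFAULT_RICH_GRID
        obs_plan = [(t, t, level, 0) for t in grid]
    else:
        schedule = simulate_titration(s, cfg.titration, cfg, rng)
        weeks = sorted(schedule)
        last_dose_day = 7 * cfg.duration_weeks
        days = np.arange(0, last_dose_day + 1)
        week_edges = np.array(weeks)
        day_levels = np.array(
            [schedule[int(week_edges[np.searchsorted(week_edges, d // 7, "right") - 1])]
             for d in days]
        )
        dose_times = days * 24.0
        if cfg.dose_jitter_h > 0:
            jitter = rng.uniform(-cfg.dose_jitter_h, cfg.dose_jitter_h, size=days.size)
            jitter[0] = 0.0
            dose_times = dose_times + jitter
        amounts = np.array(
            [cm.ped_dose(lev, s, model.dose_table) for lev in day_levels]
        )
        visit_week = int(rng.choice(cfg.pk_visit_weeks))
        offsets = draw_sampling_times(cfg, visit_week, rng)
        t_visit = 7 * visit_week * 24.0
        obs_plan = []
        n_windows = len(cfg.sampling_windows)
        for k, off in enumerate(offsets):
            if k < n_windows:
                t_obs = t_visit + off
            else:  # washout sample, relative to the final dose of the trial
                t_obs = last_dose_day * 24.0 + off
            lev = day_levels[min(int(t_obs // 24), len(day_levels) - 1)]
            obs_plan.append((t_obs, off, float(lev), visit_week))
        # doses after the last observation are irrelevant
        keep = dose_times <= max(t for t, *_ in obs_plan)
        dose_times, amounts = dose_times[keep], amounts[keep]
        dose_levels = day_levels[keep]

    obs_plan.sort(key=lambda r: r[0])
    obs_times = np.array([t for t, *_ in obs_plan])
    regimen = DoseRegimen(list(zip(dose_times, amounts)))
    conc = conc_regimen(obs_times, regimen, params)
    if noise:
        y, _ = cm.apply_residual(conc, model.sigma, rng)
    else:
        y = conc

    for i, t in enumerate(dose_times):
        week = int(t // (7 * 24.0))
        rows.append(dict(
            ID=s.id, TIME=float(t), TAD=0.0, AMT=float(amounts[i]), DV=np.nan,
            EVID=1, MDV=1, BLQ=0, PED=float(dose_levels[i]), WEEK=week, **base,
        ))
    for (t_obs, _off, lev, week), c in zip(obs_plan, y):
        prior = dose_times[dose_times <= t_obs]
        tad = float(t_obs - prior[-1]) if prior.size else float(t_obs)
        blq = 1 if (censor and c < cfg.lloq) else 0
        rows.append(dict(
            ID=s.id, TIME=float(t_obs), TAD=tad,
            AMT=np.nan, DV=(np.nan if blq else float(c)),
            EVID=0, MDV=blq, BLQ=blq, PED=lev, WEEK=week, **base,
        ))
    rows.sort(key=lambda r: (r["TIME"], -r["EVID"]))
    return rows


def simulate_trial(
    cfg: TrialConfig,
    model: SimulationModel,
    rng: np.random.Generator | int,
    noise: bool = True,
    censor: bool = True,
) -> PKDataset:
    """Simulate one trial end to end and return the event dataset.

    Per subject: titrated once-daily dose history -> individual parameters
    -> concentrations at the drawn sampling times by full superposition ->
    residual error -> censoring below the assay lower limit (flagged, value
    withheld).  Deterministic for a fixed seed.
    """
    seed = None
    if isinstance(rng, (int, np.integer)):
        seed = int(rng)
        rng = np.random.default_rng(seed)
    subjects = sample_population(cfg, rng)
    rows: list[dict] = []
    for s in subjects:
        rows.extend(_subject_rows(s, cfg, model, rng, noise, censor))
    df = pd.DataFrame(rows, columns=DATASET_COLUMNS)
    return PKDataset(df=df, config_hash=cfg.config_hash(), seed=seed)
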