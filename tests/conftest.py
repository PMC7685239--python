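"""Shared fixtures: typical parameter sets, presets and an ODE oracle."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from pedpk import cli_io, trial_sim
from pedpk.covariate_model import SigmaSpec
from pedpk.structural_pk import StructuralParams, micro_constants


@pytest.fixture(scope="session")
def typical_2cpt() -> StructuralParams:
    """Typical two-compartment parameters of the OAB (children) population."""
    return StructuralParams(
        cl_f=8.81, v2_f=162.0, ka=0.742, alag=0.834, q_f=98.1, v3_f=174.0
    )


@pytest.fixture(scope="session")
def typical_1cpt() -> StructuralParams:
    return StructuralParams(cl_f=8.81, v2_f=162.0, ka=0.742, alag=0.834)


@pytest.fixture(scope="session")
def lion_final() -> cli_io.ModelConfig:
    return cli_io.load_model_config("lion_final")


@pytest.fixture(scope="session")
def lion_cfg() -> trial_sim.TrialConfig:
    return cli_io.load_trial_config("lion")


@pytest.fixture(scope="session")
def giraffe_cfg() -> trial_sim.TrialConfig:
    return cli_io.load_trial_config("giraffe")


def ode_conc(t: float, dose: float, p: StructuralParams, rtol=1e-11) -> float:
    """Independent oracle: numeric integration of the compartment ODEs."""
    if t <= p.alag:
        return 0.0
    m = micro_constants(p)

    if p.n_compartments == 2:
        def rhs(_t, y):
            a, c, per = y
            return [
                -m.ka * a,
                m.ka * a - (m.k10 + m.k12) * c + m.k21 * per,
                m.k12 * c - m.k21 * per,
            ]
        y0 = [p.f_rel * dose, 0.0, 0.0]
    else:
        def rhs(_t, y):
            a, c = y
            return [-m.ka * a, m.ka * a - m.k10 * c]
        y0 = [p.f_rel * dose, 0.0]

    sol = solve_ivp(rhs, (0.0, t - p.alag), y0, rtol=rtol, atol=1e-16)
    return float(sol.y[1, -1]) / p.v2_f * 1000.0


def random_params(rng: np.random.Generator, two_cpt: bool = True) -> StructuralParams:
    """Random but physiologically plausible parameter sets."""
    kwargs = dict(
        cl_f=float(rng.uniform(2, 30)),
        v2_f=float(rng.uniform(30, 400)),
        ka=float(rng.uniform(0.2, 3.0)),
        alag=float(rng.uniform(0, 1.5)),
        f_rel=float(rng.uniform(0.8, 1.3)),
    )
    if two_cpt:
        kwargs["q_f"] = float(rng.uniform(10, 200))
        kwargs["v3_f"] = float(rng.uniform(50, 500))
    return StructuralParams(**kwargs)


def giraffe_n(cfg: trial_sim.TrialConfig, n_children: int, n_adol: int):
    """Resize the single-dose design's strata."""
    strata = tuple(
        dataclasses.replace(s, n=n)
        for s, n in zip(cfg.strata, (n_children, n_adol))
    )
    return dataclasses.replace(cfg, strata=strata)


@pytest.fixture(scope="session")
def recovery_sigma() -> dict[str, SigmaSpec]:
    """Residual model used in the rich-sampling recovery experiments."""
    return {"GIRAFFE": SigmaSpec(prop=0.15, add=0.0, study="GIRAFFE")}
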