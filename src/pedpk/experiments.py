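"""Reusable simulation experiments for model validation.

The central one is the parameter-recovery experiment: simulate the richly
sampled single-dose design under the final-model typical values, refit the
population model from scratch, and report the relative estimation errors of
the identifiable fixed effects.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np

from . import cli_io
from .covariate_model import SigmaSpec
from .nlme_fit import PopPKModel
from .trial_sim import simulate_trial

__all__ = ["recovery_experiment", "RECOVERY_TRUTH"]

RECOVERY_TRUTH = {
    "theta.cl_f": 8.81,
    "theta.v2_f": 162.0,
    "theta.q_f": 98.1,
    "theta.v3_f": 174.0,
    "theta.ka": 0.742,
}

#: residual model of the rich-sampling study in the recovery experiment
RECOVERY_SIGMA = {"GIRAFFE": SigmaSpec(prop=0.15, add=0.0, study="GIRAFFE")}


def recovery_experiment(
    seed: int,
    n_children: int = 67,
    n_adolescents: int = 33,
    method: str = "lbfgsb",
    maxiter: int = 60,
) -> dict[str, float]:
    """Simulate-and-refit under the final-model values; return % errors.

    One run: ``n_children + n_adolescents`` subjects on the single-dose
    rich-sampling design, log-normal IIV on CL/F, V2/F and ka at the
    simulation defaults, proportional residual error; the five structural
    fixed effects plus the three IIV SDs and the residual SD are
    re-estimated from scratch starting at the generating values' published
    magnitudes.
    """
    mc = cli_io.load_model_config("lion_final")
    cfg = cli_io.load_trial_config("giraffe")
    cfg = dataclasses.replace(
        cfg,
        strata=tuple(
            dataclasses.replace(s, n=n)
            for s, n in zip(cfg.strata, (n_children, n_adolescents))
        ),
    )
    sim_model = dataclasses.replace(
        mc.simulation_model("GIRAFFE"), sigma=RECOVERY_SIGMA["GIRAFFE"]
    )
    ds = simulate_trial(cfg, sim_model, seed)
    spec = mc.fit_spec(
        estimated_theta=("cl_f", "v2_f", "q_f", "v3_f", "ka"),
        sigma=dict(RECOVERY_SIGMA),
    )
    model = PopPKModel(ds, spec)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(method=method, maxiter=maxiter, compute_se=False)
    out = {"objective": res.objective, "converged": float(res.converged)}
    for name, truth in RECOVERY_TRUTH.items():
        out[f"err_pct.{name}"] = 100.0 * (float(res.params[name]) / truth - 1.0)
    return out


def recovery_median_errors(seeds) -> dict[str, float]:
    """Median absolute % error of each fixed effect across seeds."""
    runs = [recovery_experiment(s) for s in seeds]
    out = {}
    for name in RECOVERY_TRUTH:
        errs = [abs(r[f"err_pct.{name}"]) for r in runs]
        out[name] = float(np.median(errs))
    return out
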