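"""Laplace likelihood against closed forms, limits, and identifiability."""

import dataclasses
import math
import warnings

import numpy as np
import pandas as pd
import pytest

from pedpk import cli_io
from pedpk.covariate_model import OmegaSpec, SigmaSpec
from pedpk.nlme_fit import (
    PopModelSpec,
    PopPKModel,
    _laplace_subject,
    conditional_neg2ll,
    empirical_bayes,
)
from pedpk.trial_sim import simulate_trial

from conftest import giraffe_n


def small_dataset(lion_final, giraffe_cfg, recovery_sigma, n=(6, 2), seed=3,
                  noise=True):
    cfg = giraffe_n(giraffe_cfg, *n)
    model = dataclasses.replace(
        lion_final.simulation_model("GIRAFFE"), sigma=recovery_sigma["GIRAFFE"]
    )
    # censoring stays on: the 0.5 h sample precedes the absorption lag and
    # is below the quantification limit by construction
    return simulate_trial(cfg, model, seed, noise=noise, censor=True)


def small_spec(lion_final, recovery_sigma, **kw):
    return lion_final.fit_spec(sigma=dict(recovery_sigma), **kw)


class TestLaplaceCore:
    def test_matches_conjugate_normal_closed_form(self):
        """On a linear-normal model the Laplace approximation is exact."""
        rng = np.random.default_rng(0)
        for trial in range(4):
            n, q = 8, 2
            X = rng.normal(size=(n, q))
            m = rng.normal(size=n) + 5
            omega = np.diag(rng.uniform(0.1, 1.0, q))
            sig = rng.uniform(0.1, 0.5)
            y = m + X @ rng.normal(size=q) + rng.normal(0, sig, n)

            nll, _ = _laplace_subject(
                lambda eta: m + X @ eta,
                lambda pred: np.full_like(pred, sig**2),
                y, omega, np.zeros(q),
            )
            Sigma = X @ omega @ X.T + sig**2 * np.eye(n)
            r = y - m
            closed = (
                np.linalg.slogdet(2 * np.pi * Sigma)[1]
                + r @ np.linalg.solve(Sigma, r)
            )
            assert nll == pytest.approx(closed, abs=1e-6)

    def test_omega_to_zero_collapses_to_els(self, lion_final, giraffe_cfg,
                                            recovery_sigma):
        """As IIV vanishes the marginal objective reduces to the
        fixed-effects extended-least-squares deviance."""
        ds = small_dataset(lion_final, giraffe_cfg, recovery_sigma)
        tiny = small_spec(
            lion_final, recovery_sigma,
            omega=OmegaSpec({"cl_f": 1e-7, "v2_f": 1e-7, "ka": 1e-7}),
            freeze_omega=True, freeze_sigma=True,
        )
        none = small_spec(
            lion_final, recovery_sigma,
            omega=OmegaSpec({"cl_f": 0.0, "v2_f": 0.0, "ka": 0.0}),
            freeze_omega=True, freeze_sigma=True,
        )
        obj_tiny = conditional_neg2ll(ds, tiny)
        obj_els = conditional_neg2ll(ds, none)
        assert obj_tiny == pytest.approx(obj_els, abs=1e-4)

    def test_subject_order_invariance(self, lion_final, giraffe_cfg,
                                      recovery_sigma):
        ds = small_dataset(lion_final, giraffe_cfg, recovery_sigma)
        spec = small_spec(lion_final, recovery_sigma)
        base = conditional_neg2ll(ds, spec)

        ids = ds.df["ID"].unique()[::-1]
        parts = [ds.df[ds.df["ID"] == i] for i in ids]
        shuffled = dataclasses.replace(
            ds, df=pd.concat(parts, ignore_index=True)
        )
        assert conditional_neg2ll(shuffled, spec) == pytest.approx(base, abs=1e-6)


class TestFitPopulation:
    def test_zero_noise_identifiability(self, lion_final, giraffe_cfg,
                                        recovery_sigma):
        """Noise-free data from known typicals pin the fixed effects."""
        from pedpk.trial_sim import SimulationModel

        sim = SimulationModel(
            coeffs=lion_final.coeffs,
            omega=OmegaSpec({"cl_f": 0.0, "v2_f": 0.0, "ka": 0.0}),
            sigma=SigmaSpec(),
        )
        ds = simulate_trial(
            giraffe_n(giraffe_cfg, 4, 2), sim, 3, noise=False, censor=True
        )
        spec = small_spec(
            lion_final, recovery_sigma,
            estimated_theta=("cl_f", "v2_f", "q_f", "v3_f", "ka"),
            omega=OmegaSpec({"cl_f": 0.0, "v2_f": 0.0, "ka": 0.0}),
            freeze_omega=True, freeze_sigma=True,
        )
        # near-zero frozen residual: the extended-least-squares log-variance
        # term carries an O(sigma^2) bias that vanishes with sigma
        spec = dataclasses.replace(
            spec, sigma={"GIRAFFE": SigmaSpec(prop=1e-4, add=0.0,
                                              study="GIRAFFE")},
        )
        model = PopPKModel(ds, spec)
        x0 = model.start_values() + np.array([0.2, -0.2, 0.1, -0.1, 0.15])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(start=x0, compute_se=False)
        for name, truth in [
            ("theta.cl_f", 8.81), ("theta.v2_f", 162.0), ("theta.q_f", 98.1),
            ("theta.v3_f", 174.0), ("theta.ka", 0.742),
        ]:
            assert res.params[name] == pytest.approx(truth, rel=1e-3)

    def test_descent_from_truth(self, lion_final, giraffe_cfg, recovery_sigma):
        """Starting at the generating values, optimisation cannot worsen
        the objective."""
        ds = small_dataset(lion_final, giraffe_cfg, recovery_sigma, n=(8, 3))
        spec = small_spec(lion_final, recovery_sigma)
        model = PopPKModel(ds, spec)
        x0 = model.start_values()
        obj0 = model.neg2ll(x0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(start=x0, compute_se=False, maxiter=20)
        assert res.objective <= obj0 + 1e-6

    def test_standard_errors_positive_and_finite(self, lion_final, giraffe_cfg,
                                                 recovery_sigma):
        ds = small_dataset(lion_final, giraffe_cfg, recovery_sigma, n=(10, 4))
        spec = small_spec(lion_final, recovery_sigma)
        model = PopPKModel(ds, spec)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(compute_se=True, maxiter=25)
        se = res.bse.dropna()
        assert len(se) > 0
        assert (se > 0).all()

    def test_sparse_two_compartment_warns(self, lion_cfg, lion_final,
                                          recovery_sigma):
        cfg = dataclasses.replace(
            lion_cfg,
            strata=tuple(dataclasses.replace(s, n=n)
                         for s, n in zip(lion_cfg.strata, (4, 2))),
        )
        ds = simulate_trial(cfg, lion_final.simulation_model("LION"), 9)
        spec = lion_final.fit_spec()
        with pytest.warns(UserWarning, match="sparse"):
            PopPKModel(ds, spec)


class TestEmpiricalBayes:
    def test_tiny_omega_shrinks_etas_to_zero(self, lion_final, giraffe_cfg,
                                             recovery_sigma):
        ds = small_dataset(lion_final, giraffe_cfg, recovery_sigma)
        spec = small_spec(
            lion_final, recovery_sigma,
            omega=OmegaSpec({"cl_f": 1e-4, "v2_f": 1e-4, "ka": 1e-4}),
        )
        model = PopPKModel(ds, spec)
        eta_df, _ = model._empirical_bayes_frame(
            spec.coeffs, dict(spec.omega.sd),
            {"GIRAFFE": recovery_sigma["GIRAFFE"]},
        )
        assert np.abs(eta_df.to_numpy()).max() < 1e-3

    def test_rich_data_limit_approaches_individual_fit(self, lion_final,
                                                       giraffe_cfg,
                                                       recovery_sigma):
        """With a diffuse prior the eta mode matches a per-subject fit."""
        from scipy.optimize import minimize

        ds = small_dataset(lion_final, giraffe_cfg, recovery_sigma, n=(1, 0),
                           seed=21)
        spec = small_spec(
            lion_final, recovery_sigma,
            omega=OmegaSpec({"cl_f": 5.0, "v2_f": 5.0, "ka": 5.0}),
        )
        model = PopPKModel(ds, spec)
        eta_df, _ = model._empirical_bayes_frame(
            spec.coeffs, dict(spec.omega.sd),
            {"GIRAFFE": recovery_sigma["GIRAFFE"]},
        )
        sd = model.subjects[0]
        from pedpk.nlme_fit import _FastPred

        pred = _FastPred(sd, spec.coeffs, ("cl_f", "v2_f", "ka"))

        def sse(eta):
            f = pred(eta)
            v = (0.15 * f) ** 2
            return float(np.sum(np.log(v) + (sd.y - f) ** 2 / v))

        ls = minimize(sse, np.zeros(3), method="Nelder-Mead",
                      options={"xatol": 1e-8, "fatol": 1e-10})
        np.testing.assert_allclose(
            eta_df.iloc[0].to_numpy(), ls.x, atol=0.02
        )

    def test_all_blq_subject_excluded(self, lion_final, giraffe_cfg,
                                      recovery_sigma):
        ds = small_dataset(lion_final, giraffe_cfg, recovery_sigma, n=(3, 0))
        df = ds.df.copy()
        victim = df["ID"].unique()[0]
        obs_rows = (df["ID"] == victim) & (df["EVID"] == 0)
        df.loc[obs_rows, "BLQ"] = 1
        df.loc[obs_rows, "DV"] = np.nan
        df.loc[obs_rows, "MDV"] = 1
        ds2 = dataclasses.replace(ds, df=df)
        model = PopPKModel(ds2, small_spec(lion_final, recovery_sigma))
        assert len(model.subjects) == 2
        assert victim not in [s.subject.id for s in model.subjects]

    def test_empirical_bayes_roundtrip(self, lion_final, giraffe_cfg,
                                       recovery_sigma):
        ds = small_dataset(lion_final, giraffe_cfg, recovery_sigma, n=(5, 2))
        spec = small_spec(lion_final, recovery_sigma)
        model = PopPKModel(ds, spec)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(compute_se=False, maxiter=10)
        params, eta_df = empirical_bayes(ds, res)
        assert set(params) == set(eta_df.index)
        for sid, p in params.items():
            assert p.cl_f > 0 and p.v2_f > 0
        # shrinkage is reported for every random effect
        assert set(res.shrinkage.index) == {"cl_f", "v2_f", "ka"}
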