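"""Nonlinear mixed-effects estimation for the population PK models.

The marginal likelihood over the subject-level random effects (eta) is
approximated by the Laplace method at the per-subject conditional mode:
the inner problem maximises the joint density of (data, eta), and the
curvature term uses a finite-difference Hessian of the data part plus the
analytic prior contribution.  Because the residual variance depends on the
individual prediction, this is the interaction variant of the conditional
estimation family.

The public surface follows the Model/Results convention: build a
:class:`PopPKModel` from a :class:`~pedpk.trial_sim.PKDataset` and a
:class:`PopModelSpec`, call :meth:`PopPKModel.fit`, and read estimates,
standard errors, empirical-Bayes etas and diagnostics off the returned
:class:`PopPKResults`.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from . import covariate_model as cm
from ._numdiff import approx_hessian
from .structural_pk import StructuralParams, ValidationError, unit_exp_terms
from .trial_sim import PKDataset

__all__ = [
    "PopModelSpec",
    "PopPKModel",
    "PopPKResults",
    "FitResult",
    "conditional_neg2ll",
    "fit_population",
    "empirical_bayes",
]

logger = logging.getLogger(__name__)

#: convergence tolerance of the inner eta optimisation
INNER_GTOL = 1e-8
#: relative finite-difference step for Hessians
HESS_REL_STEP = 1e-4

LOG2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class PopModelSpec:
    """What is estimated, and from which structural/covariate skeleton.

    ``coeffs`` supplies the full parameter skeleton (typical values,
    exponents, references, ontogeny); names listed in ``estimated_theta``
    (plus any exponent pairs in ``estimated_exponents``) are free, the rest
    stay fixed at their skeleton values.  ``iiv`` lists the parameters
    carrying log-normal random effects; ``omega`` gives their initial (or
    fixed) SDs.  ``sigma`` maps study label to the residual model; all of
    its strictly positive components are estimated unless ``freeze_sigma``.
    """

    coeffs: cm.CovariateCoeffs
    iiv: tuple[str, ...] = ("cl_f", "v2_f", "ka")
    omega: cm.OmegaSpec | None = None
    sigma: dict[str, cm.SigmaSpec] = field(default_factory=dict)
    estimated_theta: tuple[str, ...] = ("cl_f", "v2_f", "ka")
    estimated_exponents: tuple[tuple[str, str], ...] = ()
    estimate_f1: bool = False
    freeze_omega: bool = False
    freeze_sigma: bool = False
    blq: str = "M1"

    def __post_init__(self) -> None:
        if self.blq != "M1":
            raise ValidationError("only M1 (exclude) BLQ handling is implemented")
        for name in self.estimated_theta:
            if name not in self.coeffs.theta:
                raise ValidationError(f"estimated theta {name!r} has no initial value")
        if self.omega is None:
            object.__setattr__(
                self, "omega", cm.OmegaSpec({k: 0.3 for k in self.iiv})
            )
        for k in self.iiv:
            if k not in self.omega.sd:
                raise ValidationError(f"iiv parameter {k!r} missing from omega")


@dataclass
class _SubjectData:
    subject: cm.Subject
    dose_times: np.ndarray
    amounts: np.ndarray
    obs_times: np.ndarray
    y: np.ndarray
    study: str


def _prepare_subjects(data: PKDataset, required: tuple[str, ...]) -> list[_SubjectData]:
    out: list[_SubjectData] = []
    for sid, g in data.df.groupby("ID", sort=False):
        cov = g.iloc[0]
        for col in required:
            if col not in g.columns or pd.isna(cov[col]):
                raise ValidationError(f"subject {sid}: missing covariate column {col}")
        doses = g[g["EVID"] == 1]
        obs = g[(g["EVID"] == 0) & (g["BLQ"] == 0) & g["DV"].notna()]
        if len(obs) == 0:
            logger.info("subject %s excluded: no quantifiable observations", sid)
            continue
        out.append(
            _SubjectData(
                subject=cm.Subject(
                    id=str(sid),
                    age=float(cov["AGE"]),
                    weight=float(cov["WT"]),
                    ffm=float(cov["FFM"]),
                    agp=float(cov["AGP"]),
                    population="OAB",
                    formulation=str(cov.get("FORM", "A")),
                ),
                dose_times=doses["TIME"].to_numpy(float),
                amounts=doses["AMT"].to_numpy(float),
                obs_times=obs["TIME"].to_numpy(float),
                y=obs["DV"].to_numpy(float),
                study=str(cov.get("STUDY", "")),
            )
        )
    if not out:
        raise ValidationError("dataset contains no usable subjects")
    return out


def _laplace_subject(pred_fn, var_fn, y, omega_cov, eta0, inner_maxiter=200):
    """Laplace-approximate -2 log marginal likelihood for one subject.

    ``pred_fn(eta)`` returns the model predictions and ``var_fn(pred)`` the
    residual variances.  Returns ``(neg2ll, eta_star)``; the inner search
    failure is signalled with ``(inf, eta0)``.
    """
    q = len(eta0)
    omega_inv = np.linalg.inv(omega_cov)
    _, logdet_omega = np.linalg.slogdet(omega_cov)

    def datapart(eta):
        pred = pred_fn(eta)
        v = var_fn(pred)
        if np.any(v <= 0) or np.any(~np.isfinite(pred)):
            return np.inf
        return float(np.sum(np.log(2 * np.pi * v) + (y - pred) ** 2 / v))

    def h(eta):
        return datapart(eta) + float(eta @ omega_inv @ eta)

    res = minimize(
        h, eta0, method="BFGS",
        options={"gtol": INNER_GTOL, "maxiter": inner_maxiter},
    )
    eta_star = res.x
    if not np.all(np.isfinite(eta_star)) or not math.isfinite(res.fun):
        return np.inf, eta0
    # curvature: FD Hessian of the data part + analytic prior term
    hd = approx_hessian(datapart, eta_star, rel_step=HESS_REL_STEP)
    curv = 0.5 * hd + omega_inv
    sign, logdet_curv = np.linalg.slogdet(curv)
    if sign <= 0:
        # FD noise or a saddle: fall back to the prior-dominated curvature
        eigval, eigvec = np.linalg.eigh(0.5 * (curv + curv.T))
        eigval = np.maximum(eigval, 1e-10)
        logdet_curv = float(np.sum(np.log(eigval)))
    neg2ll = (
        res.fun
        + q * LOG2PI
        + logdet_omega
        - q * LOG2PI
        + logdet_curv
    )
    return float(neg2ll), eta_star


class _FastPred:
    """Per-subject prediction closure over the active etas.

    Precomputes the typical parameters and the (dose, observation) elapsed
    time lattice once per outer iteration so the inner eta search costs a
    handful of scalar operations plus small vectorised exponentials.
    """

    __slots__ = ("base", "idx", "single", "dt", "amt", "zero")

    _POS = {"cl_f": 0, "v2_f": 1, "ka": 2}

    def __init__(self, sd: _SubjectData, coeffs: cm.CovariateCoeffs,
                 iiv: tuple[str, ...]):
        typ = cm.typical_params(sd.subject, coeffs)
        self.base = (typ.cl_f, typ.v2_f, typ.ka, typ.q_f, typ.v3_f, typ.f_rel)
        self.idx = tuple(self._POS[k] for k in iiv)
        dt = sd.obs_times[None, :] - sd.dose_times[:, None] - typ.alag
        mask = dt > 0
        self.single = dt.shape[0] == 1
        if self.single:
            self.dt = np.where(mask[0], dt[0], 0.0)
            self.amt = float(sd.amounts[0])
            self.zero = ~mask[0]
        else:
            self.dt = np.where(mask, dt, 0.0)
            self.amt = np.where(mask, sd.amounts[:, None], 0.0)
            self.zero = None

    def __call__(self, eta: np.ndarray) -> np.ndarray:
        p = list(self.base)
        for j, e in zip(self.idx, eta):
            # clamp: |eta| > 40 is astronomically outside the prior and only
            # reachable by optimizer probes
            p[j] *= math.exp(min(max(e, -40.0), 40.0))
        ets, tts = unit_exp_terms(p[0], p[1], p[2], p[5], p[3], p[4])
        if self.single:
            out = (ets[0][0] * self.amt) * np.exp(-ets[0][1] * self.dt)
            for c, mu in ets[1:]:
                out += (c * self.amt) * np.exp(-mu * self.dt)
            for c, mu in tts:
                out += (c * self.amt) * self.dt * np.exp(-mu * self.dt)
            if self.zero.any():
                out[self.zero] = 0.0
            return out
        out = np.zeros(self.dt.shape[1])
        for c, mu in ets:
            out += c * np.einsum("dt,dt->t", self.amt, np.exp(-mu * self.dt))
        for c, mu in tts:
            out += c * np.einsum(
                "dt,dt->t", self.amt * self.dt, np.exp(-mu * self.dt)
            )
        return out


def _inner_mode(
    pred: "_FastPred",
    sigma: cm.SigmaSpec,
    y: np.ndarray,
    omega_inv: np.ndarray,
    eta0: np.ndarray,
    gtol: float = INNER_GTOL,
    maxiter: int = 60,
):
    """Conditional eta mode by damped Newton with a linearised Hessian.

    The gradient is exact (it includes the residual-variance interaction
    term); the search Hessian is the Gauss-Newton curvature plus the prior.
    Returns ``(eta*, h(eta*), converged)`` with
    ``h = sum(log 2 pi v + r^2 / v) + eta' Omega^-1 eta``.
    """
    q = eta0.size
    sp2 = sigma.prop**2
    sa2 = sigma.add**2
    fd = 1e-5

    def fv(eta):
        f = pred(eta)
        return f, sp2 * f * f + sa2

    def hval(f, v, eta):
        r = y - f
        return float(np.sum(np.log(2 * np.pi * v) + r * r / v)
                     + eta @ omega_inv @ eta)

    eta = eta0.astype(float).copy()
    f, v = fv(eta)
    if np.any(v <= 0) or not np.all(np.isfinite(f)):
        eta = np.zeros(q)
        f, v = fv(eta)
        if np.any(v <= 0):
            return eta, np.inf, False
    hcur = hval(f, v, eta)
    converged = False
    for _ in range(maxiter):
        J = np.empty((y.size, q))
        for i in range(q):
            ep = eta.copy()
            em = eta.copy()
            ep[i] += fd
            em[i] -= fd
            J[:, i] = (pred(ep) - pred(em)) / (2 * fd)
        r = y - f
        dv = 2.0 * sp2 * f  # d v / d f
        gdata = ((1.0 / v - (r * r) / (v * v)) * dv - 2.0 * r / v) @ J
        g = gdata + 2.0 * omega_inv @ eta
        if np.max(np.abs(g)) < gtol:
            converged = True
            break
        H = 2.0 * (J.T * (1.0 / v)) @ J + 2.0 * omega_inv
        try:
            delta = np.linalg.solve(H, -g)
        except np.linalg.LinAlgError:  # pragma: no cover
            delta = -g
        step = 1.0
        improved = False
        for _ls in range(30):
            cand = eta + step * delta
            fc, vc = fv(cand)
            hc = hval(fc, vc, cand)
            if math.isfinite(hc) and hc <= hcur:
                improved = True
                break
            step *= 0.5
        if not improved:
            converged = np.max(np.abs(g)) < 1e-3  # flat within line-search noise
            break
        tiny = np.max(np.abs(step * delta)) < 1e-12
        eta, f, v, hcur = cand, fc, vc, hc
        if tiny:
            converged = True
            break
    if not converged:
        # robust fallback: quasi-Newton from the best point found so far
        def hfun(e):
            fe, ve = fv(e)
            if np.any(ve <= 0) or not np.all(np.isfinite(fe)):
                return np.inf
            return hval(fe, ve, e)

        res = minimize(hfun, eta, method="BFGS",
                       options={"gtol": gtol, "maxiter": 200})
        if math.isfinite(res.fun) and res.fun <= hcur + 1e-9:
            eta, hcur = res.x, float(res.fun)
        converged = math.isfinite(hcur)
    return eta, hcur, converged


def _laplace_from_mode(pred, sigma, y, omega_cov, eta_star, h_star):
    """-2 log marginal likelihood given the conditional mode, with the
    curvature term from a finite-difference Hessian of the data part."""
    sp2 = sigma.prop**2
    sa2 = sigma.add**2
    omega_inv = np.linalg.inv(omega_cov)
    _, logdet_omega = np.linalg.slogdet(omega_cov)

    def datapart(eta):
        f = pred(eta)
        v = sp2 * f * f + sa2
        r = y - f
        return float(np.sum(np.log(2 * np.pi * v) + r * r / v))

    hd = approx_hessian(datapart, eta_star, rel_step=HESS_REL_STEP)
    curv = 0.5 * hd + omega_inv
    sign, logdet_curv = np.linalg.slogdet(curv)
    if sign <= 0:
        eigval = np.linalg.eigvalsh(0.5 * (curv + curv.T))
        logdet_curv = float(np.sum(np.log(np.maximum(eigval, 1e-10))))
    return h_star + logdet_omega + logdet_curv


class PopPKModel:
    """Population PK model bound to an event dataset.

    Parameters
    ----------
    data : PKDataset
        Longitudinal event records; below-limit rows are excluded (M1).
    spec : PopModelSpec
        Structural/covariate skeleton and the estimation plan.
    """

    def __init__(self, data: PKDataset, spec: PopModelSpec):
        self.data = data
        self.spec = spec
        self.subjects = _prepare_subjects(data, ("AGE", "WT", "FFM", "AGP"))
        self._eta_cache: dict[str, np.ndarray] = {}
        n_obs = [len(s.y) for s in self.subjects]
        if spec.coeffs.is_two_compartment and np.median(n_obs) < 6:
            warnings.warn(
                "two-compartment model requested for a sparse design "
                "(median observations per subject < 6); the profile shape "
                "may not be identifiable — consider the one-compartment model",
                UserWarning,
                stacklevel=2,
            )

    @classmethod
    def from_dataset(cls, data: PKDataset, spec: PopModelSpec) -> "PopPKModel":
        return cls(data, spec)

    # ---- parameter packing ------------------------------------------------

    @property
    def param_names(self) -> list[str]:
        names = [f"theta.{k}" for k in self.spec.estimated_theta]
        names += [f"exp.{cov}.{par}" for cov, par in self.spec.estimated_exponents]
        if self.spec.estimate_f1:
            names.append("theta.f1")
        if not self.spec.freeze_omega:
            names += [f"omega.{k}" for k in self.spec.iiv]
        if not self.spec.freeze_sigma:
            for study, sg in self.spec.sigma.items():
                if sg.prop > 0:
                    names.append(f"sigma.{study}.prop")
                if sg.add > 0:
                    names.append(f"sigma.{study}.add")
        return names

    def start_values(self) -> np.ndarray:
        spec = self.spec
        x = [math.log(spec.coeffs.theta[k]) for k in spec.estimated_theta]
        for cov, par in spec.estimated_exponents:
            table = spec.coeffs.ffm_exp if cov == "ffm" else spec.coeffs.agp_exp
            x.append(table.get(par, 0.0))
        if spec.estimate_f1:
            x.append(math.log(spec.coeffs.theta_f1))
        if not spec.freeze_omega:
            x += [math.log(max(spec.omega.sd[k], 1e-3)) for k in spec.iiv]
        if not spec.freeze_sigma:
            for sg in spec.sigma.values():
                if sg.prop > 0:
                    x.append(math.log(sg.prop))
                if sg.add > 0:
                    x.append(math.log(sg.add))
        return np.array(x)

    def _unpack(self, x: np.ndarray):
        spec = self.spec
        i = 0
        theta = dict(spec.coeffs.theta)
        for k in spec.estimated_theta:
            theta[k] = math.exp(x[i])
            i += 1
        ffm_exp = dict(spec.coeffs.ffm_exp)
        agp_exp = dict(spec.coeffs.agp_exp)
        for cov, par in spec.estimated_exponents:
            (ffm_exp if cov == "ffm" else agp_exp)[par] = x[i]
            i += 1
        theta_f1 = spec.coeffs.theta_f1
        if spec.estimate_f1:
            theta_f1 = math.exp(x[i])
            i += 1
        coeffs = replace(
            spec.coeffs, theta=theta, ffm_exp=ffm_exp, agp_exp=agp_exp,
            theta_f1=theta_f1,
        )
        omega_sd = dict(spec.omega.sd)
        if not spec.freeze_omega:
            for k in spec.iiv:
                omega_sd[k] = math.exp(x[i])
                i += 1
        sigma = {}
        for study, sg in spec.sigma.items():
            prop, add = sg.prop, sg.add
            if not spec.freeze_sigma:
                if sg.prop > 0:
                    prop = math.exp(x[i])
                    i += 1
                if sg.add > 0:
                    add = math.exp(x[i])
                    i += 1
            sigma[study] = cm.SigmaSpec(prop=prop, add=add, study=study)
        return coeffs, omega_sd, sigma

    # ---- likelihood -------------------------------------------------------

    def _sigma_for(self, sigma: dict[str, cm.SigmaSpec], study: str) -> cm.SigmaSpec:
        if study in sigma:
            return sigma[study]
        if "*" in sigma:
            return sigma["*"]
        raise ValidationError(f"no residual model for study {study!r}")

    def neg2ll(self, x: np.ndarray, update_cache: bool = True) -> float:
        """Laplace-approximate -2 log marginal likelihood at packed params."""
        try:
            coeffs, omega_sd, sigma = self._unpack(np.asarray(x, dtype=float))
        except (ValidationError, OverflowError):
            return np.inf
        iiv = tuple(k for k in self.spec.iiv if omega_sd[k] > 0)
        q = len(iiv)
        if q:
            omega_cov = np.diag([omega_sd[k] ** 2 for k in iiv])
            omega_inv = np.linalg.inv(omega_cov)
        total = 0.0
        for sd in self.subjects:
            sg = self._sigma_for(sigma, sd.study)
            try:
                pred = _FastPred(sd, coeffs, iiv)
            except ValidationError:
                return np.inf
            if not q:
                f = pred(np.zeros(0))
                v = sg.variance(f)
                if np.any(v <= 0):
                    return np.inf
                total += float(np.sum(np.log(2 * np.pi * v) + (sd.y - f) ** 2 / v))
                continue
            eta0 = self._eta_cache.get(sd.subject.id, np.zeros(q))
            if eta0.shape != (q,):
                eta0 = np.zeros(q)
            eta_star, h_star, ok = _inner_mode(pred, sg, sd.y, omega_inv, eta0)
            if not ok or not math.isfinite(h_star):
                logger.warning(
                    "inner optimisation failed for subject %s", sd.subject.id
                )
                return np.inf
            if update_cache:
                self._eta_cache[sd.subject.id] = eta_star
            total += _laplace_from_mode(pred, sg, sd.y, omega_cov, eta_star, h_star)
        return total

    # ---- fitting ----------------------------------------------------------

    def fit(
        self,
        start: np.ndarray | None = None,
        method: str = "lbfgsb",
        maxiter: int | None = None,
        compute_se: bool = True,
    ) -> "PopPKResults":
        """Minimise the approximate -2 log likelihood.

        All positive parameters are searched on the log scale; standard
        errors come from the inverse numerical Hessian at the optimum and
        are mapped back to the natural scale by the delta method.
        """
        x0 = self.start_values() if start is None else np.asarray(start, float)
        self._eta_cache.clear()
        trace: list[float] = []

        def obj(x):
            val = self.neg2ll(x)
            trace.append(val)
            return val

        n = len(x0)
        if method == "nelder-mead":
            res = minimize(
                obj, x0, method="Nelder-Mead",
                options={
                    "maxiter": maxiter or 400 * n,
                    "xatol": 1e-4, "fatol": 1e-3, "adaptive": True,
                },
            )
        elif method == "lbfgsb":
            res = minimize(
                obj, x0, method="L-BFGS-B",
                options={"maxiter": maxiter or 200, "eps": 1e-4, "ftol": 1e-9},
            )
        elif method == "powell":
            res = minimize(
                obj, x0, method="Powell",
                options={"maxiter": maxiter or 60 * n, "xtol": 1e-4, "ftol": 1e-4},
            )
        else:
            raise ValueError(f"unknown method {method!r}")

        converged = bool(res.success) and math.isfinite(res.fun)
        if not converged:
            warnings.warn(
                f"population fit did not fully converge: {res.message}",
                UserWarning,
                stacklevel=2,
            )
        xhat = res.x
        objective = float(self.neg2ll(xhat))

        names = self.param_names
        bse_t = np.full(n, np.nan)
        if compute_se:
            try:
                hess = approx_hessian(
                    lambda x: self.neg2ll(x), xhat, rel_step=HESS_REL_STEP
                )
                cov = 2.0 * np.linalg.inv(hess)
                diag = np.diag(cov)
                bse_t = np.sqrt(np.where(diag > 0, diag, np.nan))
            except np.linalg.LinAlgError:  # pragma: no cover
                warnings.warn("singular Hessian: standard errors unavailable")

        coeffs, omega_sd, sigma = self._unpack(xhat)
        natural = []
        bse_n = []
        for name, xv, se in zip(names, xhat, bse_t):
            if name.startswith("exp."):
                natural.append(xv)
                bse_n.append(se)
            else:  # log-transformed positive parameter
                natural.append(math.exp(xv))
                bse_n.append(se * math.exp(xv) if math.isfinite(se) else np.nan)

        params = pd.Series(natural, index=names, name="estimate")
        bse = pd.Series(bse_n, index=names, name="se")

        eta_df, shrinkage = self._empirical_bayes_frame(coeffs, omega_sd, sigma)

        return PopPKResults(
            model=self,
            params=params,
            bse=bse,
            coeffs=coeffs,
            omega_sd=pd.Series(omega_sd, name="omega_sd"),
            sigma=sigma,
            objective=objective,
            converged=converged,
            n_iter=int(res.get("nit", len(trace))),
            n_eval=len(trace),
            message=str(res.message),
            eta=eta_df,
            shrinkage=shrinkage,
            trace=np.array(trace),
        )

    # ---- empirical Bayes --------------------------------------------------

    def _empirical_bayes_frame(self, coeffs, omega_sd, sigma):
        iiv = tuple(k for k in self.spec.iiv if omega_sd[k] > 0)
        q = len(iiv)
        rows = {}
        if q:
            omega_inv = np.linalg.inv(np.diag([omega_sd[k] ** 2 for k in iiv]))
        for sd in self.subjects:
            if not q:
                rows[sd.subject.id] = np.zeros(0)
                continue
            sg = self._sigma_for(sigma, sd.study)
            pred = _FastPred(sd, coeffs, iiv)
            eta0 = self._eta_cache.get(sd.subject.id, np.zeros(q))
            if eta0.shape != (q,):
                eta0 = np.zeros(q)
            eta_star, _, _ = _inner_mode(pred, sg, sd.y, omega_inv, eta0)
            rows[sd.subject.id] = eta_star
        eta_df = pd.DataFrame.from_dict(rows, orient="index", columns=list(iiv))
        shrink = {}
        for k in iiv:
            w = omega_sd[k]
            sd_eta = float(eta_df[k].std(ddof=1)) if len(eta_df) > 1 else 0.0
            shrink[k] = 1.0 - sd_eta / w if w > 0 else np.nan
        return eta_df, pd.Series(shrink, name="shrinkage")


@dataclass
class PopPKResults:
    """Estimates, uncertainties and diagnostics of a population fit."""

    model: PopPKModel
    params: pd.Series
    bse: pd.Series
    coeffs: cm.CovariateCoeffs
    omega_sd: pd.Series
    sigma: dict[str, cm.SigmaSpec]
    objective: float
    converged: bool
    n_iter: int
    n_eval: int
    message: str
    eta: pd.DataFrame
    shrinkage: pd.Series
    trace: np.ndarray

    def individual_params(self) -> dict[str, StructuralParams]:
        """Per-subject empirical-Bayes structural parameters."""
        out = {}
        for sd in self.model.subjects:
            typical = cm.typical_params(sd.subject, self.coeffs)
            if sd.subject.id in self.eta.index and len(self.eta.columns):
                eta = self.eta.loc[sd.subject.id]
                typical = typical.scaled(
                    **{k: math.exp(eta[k]) for k in self.eta.columns}
                )
            out[sd.subject.id] = typical
        return out

    def summary(self) -> str:
        lines = [
            "Population PK fit (Laplace conditional estimation)",
            "=" * 58,
            f"subjects: {len(self.model.subjects)}   "
            f"observations: {sum(len(s.y) for s in self.model.subjects)}",
            f"-2 log-likelihood: {self.objective:.3f}",
            f"converged: {self.converged}  (iterations {self.n_iter}, "
            f"evaluations {self.n_eval})",
            "",
            f"{'parameter':<22}{'estimate':>12}{'SE':>12}",
            "-" * 46,
        ]
        for name in self.params.index:
            se = self.bse[name]
            se_s = f"{se:.4g}" if np.isfinite(se) else "-"
            lines.append(f"{name:<22}{self.params[name]:>12.4g}{se_s:>12}")
        if len(self.shrinkage):
            lines.append("")
            lines.append("eta shrinkage: " + ", ".join(
                f"{k}={v:.1%}" for k, v in self.shrinkage.items()
            ))
        return "\n".join(lines)


#: alias matching the domain vocabulary
FitResult = PopPKResults


def conditional_neg2ll(data: PKDataset, spec: PopModelSpec, params=None) -> float:
    """Objective value (-2 log approximate marginal likelihood) at given
    parameters (packed vector or None for the spec's start values)."""
    model = PopPKModel(data, spec)
    x = model.start_values() if params is None else np.asarray(params, float)
    return model.neg2ll(x)


def fit_population(
    data: PKDataset,
    spec: PopModelSpec,
    init: np.ndarray | None = None,
    options: dict | None = None,
) -> PopPKResults:
    """Fit the population model; see :meth:`PopPKModel.fit`."""
    options = options or {}
    return PopPKModel(data, spec).fit(start=init, **options)


def empirical_bayes(
    data: PKDataset, fit: PopPKResults
) -> tuple[dict[str, StructuralParams], pd.DataFrame]:
    """Per-subject empirical-Bayes parameters and eta modes at the final
    population estimates."""
    if not fit.converged:
        warnings.warn(
            "empirical-Bayes estimates requested from a non-converged fit",
            UserWarning,
            stacklevel=2,
        )
    model = PopPKModel(data, fit.model.spec)
    eta_df, _ = model._empirical_bayes_frame(
        fit.coeffs, dict(fit.omega_sd), fit.sigma
    )
    params = {}
    for sd in model.subjects:
        typical = cm.typical_params(sd.subject, fit.coeffs)
        if sd.subject.id in eta_df.index and len(eta_df.columns):
            eta = eta_df.loc[sd.subject.id]
            typical = typical.scaled(**{k: math.exp(eta[k]) for k in eta_df.columns})
        params[sd.subject.id] = typical
    return params, eta_df
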