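"""Bayesian mixed-model fitting for dyadic count data.

The model for a directed dyad-year count is

    y_sry ~ Family(exp(eta), pi, phi)
    eta   = X beta + b_year + b_sender + b_receiver + b_dyad
            + f(rank_s, rank_r) + log(effort hours)

with Family one of Poisson / zero-inflated Poisson / zero-inflated negative
binomial, weakly informative Normal(0, 1) priors on fixed effects, crossed
Gaussian random effects for year, sender identity, receiver identity and
(unordered) dyad identity with half-Normal(0, 1) priors on their SDs, a
Beta(1, 1) prior on the structural-zero probability, an Exponential(1) prior
on the reciprocal NB dispersion, and the tensor smooth fitted through a
hierarchical-shrinkage reparameterisation (roughness penalty as a Gaussian
prior with an estimated smoothing SD, half-Normal(0, 1) prior).

Two fitting modes are provided:

* ``method="map"`` (default; deterministic): the random-effect and smooth
  coefficients are profiled with a Newton inner solver, the variance/family
  hyperparameters maximise a Laplace-approximate marginal posterior
  (Nelder-Mead outer loop), and posterior draws come from the Gaussian
  Laplace approximation at the joint mode.
* ``method="hmc"``: Hamiltonian Monte Carlo over all parameters jointly,
  preconditioned by the Laplace covariance, with dual-averaging step-size
  adaptation during warm-up. Defaults follow common practice for these
  models: 3000 iterations on three chains, first half warm-up.

Both modes return a :class:`FitResult` with full posterior draws, the
pointwise log-likelihood matrix needed for PSIS-LOO, fixed-effect summaries
and Bayesian R-squared draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, cholesky
from scipy.optimize import minimize
from scipy.special import expit, logit

from .design import DesignMatrix
from .families import eta_derivatives, family_loglik, family_mean_var

__all__ = ["FamilySpec", "FitResult", "fit_model", "bayes_r2"]

_SQRT_HALF_NORM = float(np.log(2.0) - 0.5 * np.log(2.0 * np.pi))


@dataclass
class FamilySpec:
    """Observation family with optional fixed nuisance values.

    Leave ``pi``/``phi`` as None to estimate them from the data (the usual
    case); supply a value to hold it fixed.
    """

    family: str
    pi: Optional[float] = None
    phi: Optional[float] = None

    def __post_init__(self):
        if self.family not in ("poisson", "zip", "zinb"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.pi is not None and not (0.0 <= self.pi < 1.0):
            raise ValueError("pi must lie in [0, 1)")
        if self.phi is not None and self.phi <= 0:
            raise ValueError("phi must be positive")
        if self.family == "poisson" and self.pi not in (None, 0.0):
            raise ValueError("Poisson family has no zero inflation")


@dataclass
class FitResult:
    """Posterior draws and per-observation log-likelihoods for one model."""

    beta: np.ndarray            # draws x n_fixed
    colnames: list
    u: np.ndarray               # draws x n_coef (fixed + RE + smooth)
    theta: np.ndarray           # draws x n_hyper (unconstrained scale)
    theta_names: list
    pi: np.ndarray              # draws
    phi: np.ndarray             # draws
    sigmas: pd.DataFrame        # draws x RE-SD columns (natural scale)
    pointwise_loglik: np.ndarray  # draws x n_obs
    design: DesignMatrix
    y: np.ndarray
    family: str = "poisson"
    diagnostics: dict = field(default_factory=dict)

    @property
    def n_draws(self) -> int:
        return self.beta.shape[0]

    @property
    def fixed_effect_summaries(self) -> pd.DataFrame:
        q = np.percentile(self.beta, [2.5, 97.5], axis=0)
        return pd.DataFrame(
            {
                "mean": self.beta.mean(axis=0),
                "sd": self.beta.std(axis=0),
                "q2.5": q[0],
                "q97.5": q[1],
            },
            index=self.colnames,
        )

    def coef_draws(self, name: str) -> np.ndarray:
        return self.beta[:, self.colnames.index(name)]

    def summary_json(self) -> dict:
        return {
            "colnames": self.colnames,
            "fixed_effects": self.fixed_effect_summaries.to_dict(),
            "diagnostics": {k: v for k, v in self.diagnostics.items()
                            if np.isscalar(v) or isinstance(v, (str, bool))},
        }

    def to_files(self, stem: str) -> None:
        """Audit dump: columnar draws CSV plus a JSON summary."""
        import json

        draws = pd.DataFrame(self.beta, columns=self.colnames)
        for col in self.sigmas.columns:
            draws[col] = self.sigmas[col].to_numpy()
        if self.family in ("zip", "zinb"):
            draws["pi"] = self.pi
        if self.family == "zinb":
            draws["phi"] = self.phi
        draws.to_csv(f"{stem}_draws.csv", index=False)
        with open(f"{stem}_summary.json", "w") as fh:
            json.dump(self.summary_json(), fh, indent=1, default=str)


class _Model:
    """Internal: dense coefficient layout and log-posterior pieces."""

    def __init__(self, design: DesignMatrix, y, familyspec: FamilySpec):
        y = np.asarray(y, dtype=float)
        if len(y) != design.n_rows:
            raise ValueError("response length does not match design rows")
        self.y = y
        self.design = design
        self.fam = familyspec
        self.offset = design.offset

        blocks = [("beta", design.X.shape[1])]
        mats = [design.X]
        n = design.n_rows
        self.re_names = []
        for name in ("year", "sender", "receiver", "dyad"):
            codes, levels = design.groups[name]
            if len(levels) < 2:
                continue
            Z = np.zeros((n, len(levels)))
            Z[np.arange(n), codes] = 1.0
            blocks.append((name, len(levels)))
            mats.append(Z)
            self.re_names.append(name)
        self.has_smooth = design.smooth is not None
        if self.has_smooth:
            blocks.append(("smooth", design.smooth.basis.shape[1]))
            mats.append(design.smooth.basis)
            self.S = design.smooth.penalties[0] + design.smooth.penalties[1]
            # hierarchical-shrinkage smooth: the estimated smoothing SD acts
            # on the penalty range space; the (bilinear) null space is treated
            # like a fixed effect with a N(0,1) prior
            evals, evecs = np.linalg.eigh(self.S)
            null = evals < 1e-8 * max(evals.max(), 1.0)
            self.smooth_null_proj = evecs[:, null] @ evecs[:, null].T
            self.smooth_range_logdet = float(np.sum(np.log(evals[~null])))
            self.smooth_range_dim = int(np.sum(~null))
        self.blocks = blocks
        self.C = np.column_stack(mats)
        self.P = self.C.shape[1]
        self.slices = {}
        start = 0
        for name, size in blocks:
            self.slices[name] = slice(start, start + size)
            start += size

        # hyperparameters on the unconstrained scale
        self.theta_names = [f"log_sigma_{g}" for g in self.re_names]
        if self.has_smooth:
            self.theta_names.append("log_tau")
        self.est_pi = familyspec.family in ("zip", "zinb") and familyspec.pi is None
        self.est_phi = familyspec.family == "zinb" and familyspec.phi is None
        if self.est_pi:
            self.theta_names.append("logit_pi")
        if self.est_phi:
            self.theta_names.append("log_phi")
        self.M = len(self.theta_names)

    # -- hyperparameter bookkeeping -------------------------------------
    def unpack_theta(self, theta):
        i = 0
        sigmas = {}
        for g in self.re_names:
            sigmas[g] = np.exp(theta[i]); i += 1
        tau = None
        if self.has_smooth:
            tau = np.exp(theta[i]); i += 1
        pi = self.fam.pi if self.fam.pi is not None else 0.0
        if self.est_pi:
            pi = float(expit(theta[i])); i += 1
        phi = self.fam.phi if self.fam.phi is not None else 1.0
        if self.est_phi:
            phi = float(np.exp(theta[i])); i += 1
        return sigmas, tau, pi, phi

    def theta_init(self):
        theta = []
        for _ in self.re_names:
            theta.append(np.log(0.3))
        if self.has_smooth:
            theta.append(0.0)
        if self.est_pi:
            zero_frac = float(np.mean(self.y == 0))
            theta.append(float(logit(np.clip(zero_frac * 0.7 + 0.05, 0.05, 0.9))))
        if self.est_phi:
            theta.append(0.0)
        return np.array(theta)

    def prior_precision(self, theta):
        """Block-diagonal prior precision Q(theta) and its log-determinant."""
        sigmas, tau, _, _ = self.unpack_theta(theta)
        Qd = np.ones(self.P)  # beta block: N(0,1) -> precision 1
        logdet = 0.0
        for g in self.re_names:
            sl = self.slices[g]
            prec = 1.0 / sigmas[g] ** 2
            Qd[sl] = prec
            logdet += (sl.stop - sl.start) * np.log(prec)
        Q = np.diag(Qd)
        if self.has_smooth:
            sl = self.slices["smooth"]
            Qs = self.smooth_null_proj + self.S / tau**2
            Q[sl, sl] = Qs
            logdet += self.smooth_range_logdet \
                - 2.0 * self.smooth_range_dim * np.log(tau)
        return Q, logdet

    def log_prior_theta(self, theta):
        """Hyperpriors with change-of-variable Jacobians (unconstrained scale)."""
        lp = 0.0
        i = 0
        for _ in self.re_names:
            s = np.exp(theta[i])
            lp += _SQRT_HALF_NORM - 0.5 * s**2 + theta[i]  # half-N(0,1) + Jacobian
            i += 1
        if self.has_smooth:
            t = np.exp(theta[i])
            lp += _SQRT_HALF_NORM - 0.5 * t**2 + theta[i]
            i += 1
        if self.est_pi:
            # Beta(1,1) on pi; density of logit_pi is pi (1 - pi)
            p = expit(theta[i])
            lp += np.log(p) + np.log1p(-p)
            i += 1
        if self.est_phi:
            # Exponential(1) on 1/phi, transformed to log_phi
            lp += -np.exp(-theta[i]) - theta[i]
            i += 1
        return lp

    # -- inner problem ---------------------------------------------------
    def eta(self, u):
        return self.C @ u + self.offset

    def loglik(self, u, pi, phi):
        return float(np.sum(family_loglik(self.fam.family, self.y, self.eta(u),
                                          pi=pi, phi=phi)))

    def inner_newton(self, theta, u0=None, max_iter=60, tol=1e-8):
        """Posterior mode of the coefficients at fixed hyperparameters."""
        sigmas, tau, pi, phi = self.unpack_theta(theta)
        Q, _ = self.prior_precision(theta)
        u = np.zeros(self.P) if u0 is None else u0.copy()

        def objective(u):
            with np.errstate(over="ignore", invalid="ignore"):
                return self.loglik(u, pi, phi) - 0.5 * u @ Q @ u

        f = objective(u)
        H = None
        for _ in range(max_iter):
            g1, h2 = eta_derivatives(self.fam.family, self.y, self.eta(u),
                                     pi=pi, phi=phi)
            grad = self.C.T @ g1 - Q @ u
            W = np.maximum(-h2, 1e-10)
            H = (self.C.T * W) @ self.C + Q
            try:
                cf = cho_factor(H, lower=True)
            except np.linalg.LinAlgError:
                H = H + 1e-6 * np.eye(self.P)
                cf = cho_factor(H, lower=True)
            step = cho_solve(cf, grad)
            gmax = np.max(np.abs(grad))
            if gmax < tol * (1.0 + abs(f)):
                break
            t = 1.0
            for _ in range(30):
                u_new = u + t * step
                f_new = objective(u_new)
                if np.isfinite(f_new) and f_new >= f - 1e-12:
                    break
                t *= 0.5
            if f_new < f and gmax < 1e-5 * (1.0 + abs(f)):
                break
            u, f = u_new, f_new
        g1, h2 = eta_derivatives(self.fam.family, self.y, self.eta(u), pi=pi, phi=phi)
        W = np.maximum(-h2, 1e-10)
        H = (self.C.T * W) @ self.C + Q
        return u, f, H

    def laplace_objective(self, theta, u0=None):
        """Laplace-approximate log marginal posterior of the hyperparameters."""
        u, f, H = self.inner_newton(theta, u0=u0)
        _, logdetQ = self.prior_precision(theta)
        sign, logdetH = np.linalg.slogdet(H)
        if sign <= 0:
            return -np.inf, u
        value = f + 0.5 * logdetQ - 0.5 * logdetH + self.log_prior_theta(theta)
        return value, u

    # -- joint gradient (for HMC) ---------------------------------------
    def joint_logpost(self, u, theta):
        sigmas, tau, pi, phi = self.unpack_theta(theta)
        Q, logdetQ = self.prior_precision(theta)
        with np.errstate(over="ignore", invalid="ignore"):
            return (self.loglik(u, pi, phi) - 0.5 * u @ Q @ u + 0.5 * logdetQ
                    + self.log_prior_theta(theta))

    def joint_grad(self, u, theta, fd_eps=1e-5):
        sigmas, tau, pi, phi = self.unpack_theta(theta)
        Q, _ = self.prior_precision(theta)
        g1, _ = eta_derivatives(self.fam.family, self.y, self.eta(u), pi=pi, phi=phi)
        gu = self.C.T @ g1 - Q @ u

        gt = np.zeros(self.M)
        i = 0
        for g in self.re_names:
            sl = self.slices[g]
            b = u[sl]
            s = sigmas[g]
            q = sl.stop - sl.start
            gt[i] = (b @ b) / s**2 - q + (1.0 - s**2)  # lik + logdet + prior
            i += 1
        if self.has_smooth:
            sl = self.slices["smooth"]
            b = u[sl]
            gt[i] = (b @ self.S @ b) / tau**2 - self.smooth_range_dim \
                + (1.0 - tau**2)
            i += 1
        # pi / phi entries by central finite differences of the data loglik
        for j in range(i, self.M):
            tp = theta.copy(); tm = theta.copy()
            tp[j] += fd_eps; tm[j] -= fd_eps
            _, _, pip, phip = self.unpack_theta(tp)
            _, _, pim, phim = self.unpack_theta(tm)
            lp = self.loglik(u, pip, phip) + self.log_prior_theta(tp)
            lm = self.loglik(u, pim, phim) + self.log_prior_theta(tm)
            gt[j] = (lp - lm) / (2 * fd_eps)
        return gu, gt


def _laplace_draws(model, theta_hat, u_hat, H, theta_cov, n_draws, rng):
    """Gaussian draws around the joint mode (coefficients and hyperparameters)."""
    L = cholesky(np.linalg.inv(H + 1e-12 * np.eye(model.P)), lower=True)
    u_draws = u_hat + rng.standard_normal((n_draws, model.P)) @ L.T
    if model.M:
        Lt = cholesky(theta_cov + 1e-12 * np.eye(model.M), lower=True)
        t_draws = theta_hat + rng.standard_normal((n_draws, model.M)) @ Lt.T
    else:
        t_draws = np.zeros((n_draws, 0))
    return u_draws, t_draws


def _theta_covariance(model, theta_hat, u_hat, step=0.05):
    """Numeric Hessian of the Laplace objective -> hyperparameter covariance."""
    m = model.M
    if m == 0:
        return np.zeros((0, 0))
    f0, _ = model.laplace_objective(theta_hat, u0=u_hat)
    H = np.zeros((m, m))
    evals = {}

    def val(dt):
        key = tuple(np.round(dt / step).astype(int))
        if key not in evals:
            v, _ = model.laplace_objective(theta_hat + dt, u0=u_hat)
            evals[key] = v
        return evals[key]

    for i in range(m):
        ei = np.zeros(m); ei[i] = step
        H[i, i] = (val(ei) - 2 * f0 + val(-ei)) / step**2
        for j in range(i + 1, m):
            ej = np.zeros(m); ej[j] = step
            H[i, j] = H[j, i] = (
                val(ei + ej) - val(ei - ej) - val(-ei + ej) + val(-ei - ej)
            ) / (4 * step**2)
    prec = -H
    try:
        cov = np.linalg.inv(prec)
        if np.any(np.diag(cov) <= 0):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        cov = np.diag(1.0 / np.maximum(np.diag(prec), 1e-2))
    return (cov + cov.T) / 2.0


def _run_hmc(model, u0, theta0, H, theta_cov, chains, iterations, seed,
             target_accept=0.8):
    """Preconditioned HMC with dual-averaging step size (first half warm-up).

    Sampling happens in a standardised space ``x`` with ``params = centre +
    scales * x``, the scales taken from the Laplace approximation, so a single
    step size serves all coordinates.
    """
    dim_u, dim_t = model.P, model.M
    scale_u = 1.0 / np.sqrt(np.maximum(np.diag(H), 1e-8))
    scale_t = np.sqrt(np.maximum(np.diag(theta_cov), 1e-4)) if dim_t else np.zeros(0)
    scales = np.r_[scale_u, scale_t]
    centre = np.r_[u0, theta0]
    warmup = iterations // 2

    def logp_and_grad_x(x):
        z = centre + scales * x
        u, th = z[:dim_u], z[dim_u:]
        lp = model.joint_logpost(u, th)
        gu, gt = model.joint_grad(u, th)
        return lp, np.r_[gu, gt] * scales

    all_u, all_t, accept = [], [], []
    for chain in range(chains):
        rng = np.random.default_rng(seed + 1000 * chain)
        x = 0.01 * rng.standard_normal(dim_u + dim_t)
        lp, grad = logp_and_grad_x(x)
        eps = 0.1
        log_eps_bar, h_bar, mu = np.log(eps), 0.0, np.log(10 * eps)
        n_acc = 0
        for it in range(iterations):
            p0 = rng.standard_normal(dim_u + dim_t)
            x_new, p, grad_new, lp_new = x.copy(), p0.copy(), grad.copy(), lp
            n_leap = int(rng.integers(8, 16))
            ok = True
            p = p + 0.5 * eps * grad_new
            for leap in range(n_leap):
                x_new = x_new + eps * p
                lp_new, grad_new = logp_and_grad_x(x_new)
                if not np.isfinite(lp_new):
                    ok = False
                    break
                if leap < n_leap - 1:
                    p = p + eps * grad_new
            if ok:
                p = p + 0.5 * eps * grad_new
                log_alpha = (lp_new - 0.5 * p @ p) - (lp - 0.5 * p0 @ p0)
                alpha = float(np.exp(min(0.0, log_alpha)))
            else:
                alpha = 0.0
            if rng.random() < alpha:
                x, lp, grad = x_new, lp_new, grad_new
                n_acc += 1
            if it < warmup:  # Nesterov dual averaging toward target acceptance
                h_bar = (1 - 1 / (it + 11)) * h_bar + (target_accept - alpha) / (it + 11)
                log_eps = mu - np.sqrt(it + 1) / 0.05 * h_bar
                w = (it + 1) ** -0.75
                log_eps_bar = w * log_eps + (1 - w) * log_eps_bar
                eps = float(np.exp(log_eps))
            elif it == warmup:
                eps = float(np.exp(log_eps_bar))
            if it >= warmup:
                z = centre + scales * x
                all_u.append(z[:dim_u].copy())
                all_t.append(z[dim_u:].copy())
        accept.append(n_acc / iterations)
    return np.array(all_u), np.array(all_t), accept


def fit_model(
    design: DesignMatrix,
    y,
    familyspec: FamilySpec,
    mcmc: Optional[dict] = None,
    method: str = "map",
    n_draws: int = 1000,
    seed: int = 0,
) -> FitResult:
    """Fit one Bayesian mixed model and return posterior draws.

    ``method="map"`` is the fast deterministic mode (Laplace approximation at
    the penalised posterior mode, hyperparameters by marginal optimisation);
    ``method="hmc"`` samples all parameters with Hamiltonian Monte Carlo
    (``mcmc`` accepts ``chains``, ``iterations``, ``seed``; defaults 3 chains
    of 3000 iterations, first half warm-up).
    """
    model = _Model(design, y, familyspec)
    rng = np.random.default_rng(seed)

    theta0 = model.theta_init()
    u_warm = [None]

    if model.M:
        def neg(theta):
            value, u = model.laplace_objective(theta, u0=u_warm[0])
            u_warm[0] = u
            return -value

        res = minimize(neg, theta0, method="Nelder-Mead",
                       options={"maxfev": 80 * max(1, model.M), "xatol": 2e-2,
                                "fatol": 5e-3})
        theta_hat = res.x
    else:
        theta_hat = theta0
    u_hat, f_hat, H = model.inner_newton(theta_hat, u0=u_warm[0])
    diagnostics = {"method": method, "theta_hat": theta_hat,
                   "theta_names": model.theta_names, "map_objective": f_hat}

    if method == "map":
        theta_cov = _theta_covariance(model, theta_hat, u_hat)
        u_draws, t_draws = _laplace_draws(model, theta_hat, u_hat, H,
                                          theta_cov, n_draws, rng)
        diagnostics["converged"] = bool(np.all(np.isfinite(u_hat)))
    elif method == "hmc":
        mcmc = mcmc or {}
        chains = int(mcmc.get("chains", 3))
        iterations = int(mcmc.get("iterations", 3000))
        theta_cov = _theta_covariance(model, theta_hat, u_hat)
        u_draws, t_draws, accept = _run_hmc(
            model, u_hat, theta_hat, H, theta_cov, chains, iterations,
            int(mcmc.get("seed", seed)),
        )
        diagnostics["accept_rate"] = accept
        diagnostics["converged"] = bool(min(accept) > 0.4)
        if n_draws < len(u_draws):
            keep = rng.choice(len(u_draws), size=n_draws, replace=False)
            keep.sort()
            u_draws, t_draws = u_draws[keep], t_draws[keep]
    else:
        raise ValueError(f"unknown method {method!r}")

    S = len(u_draws)
    n = model.design.n_rows
    pis = np.empty(S)
    phis = np.empty(S)
    sig_rows = np.empty((S, len(model.re_names)))
    ll = np.empty((S, n))
    for s in range(S):
        sigmas, tau, pi, phi = model.unpack_theta(t_draws[s])
        pis[s], phis[s] = pi, phi
        sig_rows[s] = [sigmas[g] for g in model.re_names]
        eta = model.eta(u_draws[s])
        ll[s] = family_loglik(model.fam.family, model.y, eta, pi=pi, phi=phi)
    if not np.all(np.isfinite(ll)):
        ll = np.nan_to_num(ll, nan=-1e10, neginf=-1e10)
        diagnostics["nonfinite_loglik"] = True

    beta = u_draws[:, model.slices["beta"]]
    return FitResult(
        beta=beta,
        colnames=design.colnames,
        u=u_draws,
        theta=t_draws,
        theta_names=model.theta_names,
        pi=pis,
        phi=phis,
        sigmas=pd.DataFrame(sig_rows, columns=[f"sd_{g}" for g in model.re_names]),
        pointwise_loglik=ll,
        design=design,
        y=model.y,
        family=familyspec.family,
        diagnostics=diagnostics,
    )


def bayes_r2(fit: FitResult) -> dict:
    """Bayesian R-squared draws on the response scale.

    Per draw, R2 = var(fitted means) / (var(fitted means) + mean model-based
    residual variance), the posterior-predictive definition of explained
    variance for generalised models.
    """
    model_design = fit.design
    S = fit.n_draws
    r2 = np.empty(S)
    # rebuild the coefficient matrix used at fit time (layout only)
    m = _Model(model_design, fit.y, FamilySpec(family="poisson"))
    for s in range(S):
        eta = m.C @ fit.u[s] + model_design.offset
        mean, var = family_mean_var(fit.family, eta, pi=fit.pi[s], phi=fit.phi[s])
        vfit = float(np.var(mean))
        vres = float(np.mean(var))
        r2[s] = 0.0 if vfit + vres <= 0 else vfit / (vfit + vres)
    return {"draws": r2, "median": float(np.median(r2))}
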