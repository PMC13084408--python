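"""Gamma log-link mixed model of saccadic reaction time.

Fits RT_ij ~ Gamma(shape alpha, mean mu_ij) with
log mu_ij = x_ij' beta + u_i and neuron-level random intercepts
u_i ~ N(0, sigma^2), by maximising the Laplace-approximate marginal
likelihood.  The random intercepts enter one-dimensionally per neuron, so
the inner problem (the conditional mode of each u_i) is solved by a
globally convergent vectorised Newton iteration, and the outer problem
optimises the fixed effects, log random-effect SD and log Gamma shape
jointly by quasi-Newton.

The fixed-effect design is the fully crossed latency/strength-by-contrast
model: z-scored visual response latency, z-scored visual response
strength, z-scored (numeric) stimulus contrast, and the two feature-by-
contrast interactions, with an intercept.  Single-term deletion refits the
model without a predictor and all its interactions and compares marginal
likelihoods by a chi-square likelihood-ratio test (df = 2 for latency or
strength, 3 for contrast).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

__all__ = ["GammaMixedModel", "GammaMixedResults", "simulate_gamma_glmm"]

TERM_COLUMNS = {
    "latency": ["latency_z", "latency_z:contrast_z"],
    "strength": ["strength_z", "strength_z:contrast_z"],
    "contrast": ["contrast_z", "latency_z:contrast_z", "strength_z:contrast_z"],
}
DESIGN_COLUMNS = ["Intercept", "latency_z", "strength_z", "contrast_z",
                  "latency_z:contrast_z", "strength_z:contrast_z"]


def _zscore(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    sd = x.std(ddof=0)
    if sd == 0:
        raise ValueError("cannot z-score a constant predictor")
    return (x - x.mean()) / sd


class GammaMixedModel:
    """Gamma GLMM with log link and a single random intercept per group.

    Parameters
    ----------
    endog : array-like
        Strictly positive response (reaction times, ms).
    exog : ndarray
        Fixed-effect design matrix (including intercept column).
    groups : array-like
        Group labels (neuron identity) for the random intercepts.
    exog_names : list of str, optional
        Column names of ``exog``.
    """

    def __init__(self, endog, exog, groups, exog_names=None):
        self.endog = np.asarray(endog, dtype=float)
        self.exog = np.asarray(exog, dtype=float)
        if self.endog.ndim != 1 or self.exog.ndim != 2:
            raise ValueError("endog must be 1-d and exog 2-d")
        if len(self.endog) != len(self.exog):
            raise ValueError("endog and exog lengths differ")
        if np.any(self.endog <= 0) or not np.all(np.isfinite(self.endog)):
            raise ValueError("response must be strictly positive and finite")
        if len(self.endog) < 10:
            raise ValueError("need at least 10 observations")
        codes, self.group_labels = pd.factorize(np.asarray(groups))
        self.group_idx = codes
        self.n_groups = len(self.group_labels)
        self.exog_names = (list(exog_names) if exog_names is not None
                           else [f"x{j}" for j in range(self.exog.shape[1])])

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, response: str = "reaction_time_ms",
                       latency: str = "latency_ms", strength: str = "strength",
                       contrast: str = "contrast", group: str = "neuron_id",
                       ) -> "GammaMixedModel":
        """Build the crossed latency/strength-by-contrast design from a table.

        Rows with a missing latency or strength are dropped; the three
        predictors are z-scored over the fitted rows and contrast enters
        as a z-scored numeric percentage.
        """
        cols = [response, latency, strength, contrast, group]
        d = data[cols].dropna()
        if len(d) < 10:
            raise ValueError("need at least 10 complete observations")
        if d[group].nunique() < 2:
            raise ValueError("need at least 2 groups (neurons)")
        lz = _zscore(d[latency].to_numpy())
        sz = _zscore(d[strength].to_numpy())
        cz = _zscore(d[contrast].to_numpy(dtype=float))
        exog = np.column_stack([np.ones(len(d)), lz, sz, cz, lz * cz, sz * cz])
        return cls(d[response].to_numpy(), exog, d[group].to_numpy(),
                   exog_names=list(DESIGN_COLUMNS))

    # ---- Laplace-approximate marginal log-likelihood -------------------

    def _conditional_modes(self, eta_fixed, alpha, sigma2, u0):
        """Vectorised Newton solve for the per-group random-intercept modes.

        For group i the conditional log-density q_i(u) =
        -alpha sum_j (eta_ij + u + y_ij e^(-eta_ij - u)) - u^2/(2 sigma^2)
        is strictly concave; Newton from the previous mode converges in a
        handful of iterations.
        """
        y = self.endog
        gi = self.group_idx
        m = self.n_groups
        n_per = np.bincount(gi, minlength=m).astype(float)
        u = u0.copy()
        for _ in range(100):
            w = y * np.exp(-np.clip(eta_fixed + u[gi], -60.0, 60.0))
            s1 = np.bincount(gi, weights=w, minlength=m)
            grad = alpha * (s1 - n_per) - u / sigma2
            hess = -alpha * s1 - 1.0 / sigma2
            step = grad / hess
            # damped Newton for safety far from the mode
            step = np.clip(step, -5.0, 5.0)
            u = u - step
            if np.max(np.abs(grad)) < 1e-10 * max(1.0, alpha):
                break
        return u

    def _loglike(self, params, u_cache=None):
        """Laplace-approximate marginal log-likelihood at
        params = (beta, log_sigma, log_alpha)."""
        p = self.exog.shape[1]
        beta = params[:p]
        log_sigma, log_alpha = params[p], params[p + 1]
        sigma2 = np.exp(2.0 * log_sigma)
        alpha = np.exp(log_alpha)
        y = self.endog
        gi = self.group_idx
        eta_fixed = self.exog @ beta
        u0 = (u_cache if u_cache is not None
              else np.zeros(self.n_groups))
        u = self._conditional_modes(eta_fixed, alpha, sigma2, u0)
        if u_cache is not None:
            u_cache[:] = u
        eta = np.clip(eta_fixed + u[gi], -60.0, 60.0)
        # conditional Gamma log-likelihood at the modes
        const = (alpha * np.log(alpha) - special.gammaln(alpha)
                 + (alpha - 1.0) * np.log(y))
        ll_cond = const.sum() - alpha * np.sum(eta + y * np.exp(-eta))
        s1 = np.bincount(gi, weights=y * np.exp(-eta), minlength=self.n_groups)
        neg_q2 = alpha * s1 + 1.0 / sigma2  # -q''(u_hat) > 0
        ll = (ll_cond
              - 0.5 * np.sum(u**2) / sigma2
              - 0.5 * self.n_groups * np.log(sigma2)
              - 0.5 * np.sum(np.log(neg_q2)))
        return ll, u

    def _loglike_fixed(self, params):
        """Plain Gamma GLM log-likelihood (no random effects)."""
        p = self.exog.shape[1]
        beta = params[:p]
        alpha = np.exp(params[p])
        y = self.endog
        eta = np.clip(self.exog @ beta, -60.0, 60.0)
        const = (alpha * np.log(alpha) - special.gammaln(alpha)
                 + (alpha - 1.0) * np.log(y))
        return const.sum() - alpha * np.sum(eta + y * np.exp(-eta))

    def _start_params(self):
        y = self.endog
        ly = np.log(y)
        beta0, *_ = np.linalg.lstsq(self.exog, ly, rcond=None)
        resid = ly - self.exog @ beta0
        v = max(resid.var(), 1e-6)
        alpha0 = max(1.0 / v, 0.1)  # var(log Y) ~ 1/alpha for large alpha
        # decompose residual variance into between/within group parts
        gm = np.array([resid[self.group_idx == i].mean() if np.any(self.group_idx == i)
                       else 0.0 for i in range(self.n_groups)])
        sigma0 = max(np.sqrt(max(gm.var(), 1e-6)), 1e-3)
        return np.concatenate([beta0, [np.log(sigma0), np.log(alpha0)]])

    def fit(self, include_random: bool = True, maxiter: int = 200_000,
            gtol: float = 1e-7) -> "GammaMixedResults":
        """Maximise the (Laplace-approximate) marginal likelihood.

        ``include_random=False`` collapses the model to a plain Gamma GLM
        with jointly estimated shape (used for boundary checks and
        oracles).
        """
        p = self.exog.shape[1]
        n_obs = float(len(self.endog))
        if include_random:
            u_cache = np.zeros(self.n_groups)

            def nll(params):
                ll, _ = self._loglike(params, u_cache)
                return -ll / n_obs  # per-observation scale for the optimizer

            x0 = self._start_params()
        else:
            def nll(params):
                return -self._loglike_fixed(params) / n_obs

            x0 = np.delete(self._start_params(), p)

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            res = optimize.minimize(nll, x0, method="BFGS",
                                    options={"maxiter": maxiter, "gtol": gtol})
            if not res.success and np.linalg.norm(res.jac, ord=np.inf) > 1e-5:
                # one restart from the BFGS endpoint with Nelder-Mead polish
                res2 = optimize.minimize(nll, res.x, method="Nelder-Mead",
                                         options={"maxiter": 20000,
                                                  "xatol": 1e-9, "fatol": 1e-12})
                if res2.fun < res.fun:
                    res = res2
        params = res.x
        llf = -float(res.fun) * n_obs
        hess = _numerical_hessian(nll, params) * n_obs
        try:
            cov = np.linalg.inv(hess)
            bse_all = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
        except np.linalg.LinAlgError:
            cov = np.full((len(params),) * 2, np.nan)
            bse_all = np.full(len(params), np.nan)

        beta = params[:p]
        bse = bse_all[:p]
        if include_random:
            re_sd = float(np.exp(params[p]))
            shape = float(np.exp(params[p + 1]))
            k = p + 2
            _, u_hat = self._loglike(params)
        else:
            re_sd = 0.0
            shape = float(np.exp(params[p]))
            k = p + 1
            u_hat = np.zeros(self.n_groups)
        grad_norm = float(np.linalg.norm(res.jac, ord=np.inf)) \
            if getattr(res, "jac", None) is not None else np.nan
        converged = bool(res.success or grad_norm < 1e-5 or not np.isfinite(grad_norm))
        if not converged:
            warnings.warn(f"GLMM fit did not converge (grad inf-norm {grad_norm:.2e})",
                          stacklevel=2)
        return GammaMixedResults(
            model=self, params=beta, bse=bse, re_sd=re_sd, shape=shape,
            llf=llf, k_params=k, random_effects=u_hat,
            converged=converged, grad_norm=grad_norm,
            include_random=include_random)


def _numerical_hessian(f, x, eps=1e-4):
    n = len(x)
    h = np.empty((n, n))
    f0 = f(x)
    steps = eps * np.maximum(1.0, np.abs(x))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = steps[i]
            ej = np.zeros(n); ej[j] = steps[j]
            fpp = f(x + ei + ej)
            fpm = f(x + ei - ej)
            fmp = f(x - ei + ej)
            fmm = f(x - ei - ej)
            h[i, j] = h[j, i] = (fpp - fpm - fmp + fmm) / (4 * steps[i] * steps[j])
    return h


@dataclass
class GammaMixedResults:
    """Estimates, uncertainties and diagnostics of a fitted Gamma GLMM."""

    model: GammaMixedModel
    params: np.ndarray          # fixed-effect estimates
    bse: np.ndarray             # Wald standard errors
    re_sd: float                # random-intercept SD
    shape: float                # Gamma shape
    llf: float                  # marginal log-likelihood (Laplace)
    k_params: int               # counted parameters for AIC
    random_effects: np.ndarray  # conditional modes of the intercepts
    converged: bool
    grad_norm: float
    include_random: bool = True
    _deletion_cache: dict = field(default_factory=dict, repr=False)

    @property
    def zvalues(self) -> np.ndarray:
        return self.params / self.bse

    @property
    def pvalues(self) -> np.ndarray:
        return 2.0 * stats.norm.sf(np.abs(self.zvalues))

    @property
    def aic(self) -> float:
        return 2.0 * self.k_params - 2.0 * self.llf

    def single_term_deletion(self, term: str) -> dict:
        """Likelihood-ratio test removing ``term`` and all its interactions.

        Returns chisq, df, p and the reduced model's AIC.  df = 2 for
        latency or strength (main effect + its contrast interaction) and
        3 for contrast (main effect + both interactions).
        """
        if term not in TERM_COLUMNS:
            raise ValueError(f"term must be one of {sorted(TERM_COLUMNS)}")
        if term in self._deletion_cache:
            return self._deletion_cache[term]
        drop = TERM_COLUMNS[term]
        names = self.model.exog_names
        missing = [c for c in drop if c not in names]
        if missing:
            raise ValueError(f"design lacks columns {missing}")
        keep = [j for j, nm in enumerate(names) if nm not in drop]
        sub = GammaMixedModel(self.model.endog, self.model.exog[:, keep],
                              self.model.group_labels[self.model.group_idx],
                              exog_names=[names[j] for j in keep])
        red = sub.fit(include_random=self.include_random)
        if not red.converged:
            raise RuntimeError(f"reduced model without {term!r} did not converge")
        chisq = max(2.0 * (self.llf - red.llf), 0.0)
        df = len(drop)
        out = {"term": term, "chisq": float(chisq), "df": df,
               "p": float(stats.chi2.sf(chisq, df)), "aic_reduced": red.aic}
        self._deletion_cache[term] = out
        return out

    def summary(self) -> str:
        lines = ["Gamma log-link mixed model (Laplace approximation)",
                 f"  observations: {len(self.model.endog)}   "
                 f"groups: {self.model.n_groups}",
                 f"  logLik: {self.llf:.2f}   AIC: {self.aic:.2f}   "
                 f"converged: {self.converged}",
                 f"  random-intercept SD: {self.re_sd:.4f}   "
                 f"Gamma shape: {self.shape:.3f}",
                 "",
                 f"  {'term':<24}{'coef':>10}{'SE':>10}{'z':>9}{'p':>12}"]
        for nm, b, se, z, pv in zip(self.model.exog_names, self.params,
                                    self.bse, self.zvalues, self.pvalues):
            lines.append(f"  {nm:<24}{b:>10.4f}{se:>10.4f}{z:>9.2f}{pv:>12.3g}")
        return "\n".join(lines)


def simulate_gamma_glmm(beta: np.ndarray, n_neurons: int, n_trials: int,
                        re_sd: float, shape: float, seed: int,
                        contrasts=(10, 20, 50, 100)) -> pd.DataFrame:
    """Simulate reaction times from the model's own generative process.

    Latency and strength latents are standard normal per trial; contrast
    is drawn uniformly from ``contrasts`` and z-scored; the linear
    predictor uses the crossed design of :data:`DESIGN_COLUMNS` with
    coefficients ``beta`` (length 6, on the log-ms scale).  Used by
    parameter-recovery and null-calibration checks.
    """
    rng = np.random.default_rng(seed)
    n = n_neurons * n_trials
    g = np.repeat(np.arange(n_neurons), n_trials)
    lat = rng.normal(size=n)
    stren = rng.normal(size=n)
    con = rng.choice(np.asarray(contrasts, float), size=n)
    conz = (con - con.mean()) / con.std()
    X = np.column_stack([np.ones(n), lat, stren, conz, lat * conz, stren * conz])
    u = rng.normal(0.0, re_sd, n_neurons)
    mu = np.exp(X @ np.asarray(beta, float) + u[g])
    y = rng.gamma(shape, mu / shape)
    return pd.DataFrame({
        "reaction_time_ms": y, "latency_ms": lat, "strength": stren,
        "contrast": con, "neuron_id": g,
    })
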