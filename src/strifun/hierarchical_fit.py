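"""Hierarchical EM fitting and Monte-Carlo integrated-BIC model comparison.

Subject-level parameters are fitted in an unconstrained (transformed) space
under a diagonal population Gaussian prior.  The E-step computes each
subject's MAP estimate and a Laplace (inverse-Hessian) posterior
covariance; the M-step re-estimates the population mean and variance from
the subject posteriors.  Both sessions of a subject share one parameter
vector.

Models are compared with an integrated BIC: for every subject-session the
marginal likelihood is estimated by Monte-Carlo sampling parameter vectors
from the fitted population prior, and

    iBIC = -2 * sum log p(choices | prior)  +  M * log(N_choices)

where M counts population-level parameters (a mean and a variance per
active model parameter) and N_choices is the total number of recorded
choices entering the likelihoods.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import logsumexp

from . import _engine
from .rl_models import ModelSpec, RLParams, transformed_to_rows

SIGMA2_FLOOR = 1e-6

#: weakly-informative inverse-gamma(shape, scale) hyperprior on each
#: population variance (transformed space).  With few subjects the marginal
#: likelihood is nearly flat along ridges trading population spread against
#: population mean, and the plain M-step lets the variances collapse; a
#: hyperprior with prior mode scale/(shape+1) ~ 0.3 on the O(1) transformed
#: scale keeps the fixed point unique and the spread honest.
SIGMA2_HYPERPRIOR = (2.0, 1.0)


@dataclass
class PopulationPrior:
    """Diagonal Gaussian over the transformed parameter space."""

    mu: np.ndarray
    sigma2: np.ndarray

    def __post_init__(self):
        self.mu = np.asarray(self.mu, dtype=float)
        self.sigma2 = np.asarray(self.sigma2, dtype=float)
        if self.mu.shape != self.sigma2.shape:
            raise ValueError("mu and sigma2 must have the same shape")
        if np.any(self.sigma2 <= 0):
            raise ValueError("sigma2 must be positive elementwise")

    @property
    def n_params(self) -> int:
        return self.mu.shape[0]


def default_prior(spec: ModelSpec, mu0: float = 0.0,
                  sigma2_0: float = 6.25) -> PopulationPrior:
    """Weakly informative initialization in transformed space."""
    p = spec.n_params
    return PopulationPrior(mu=np.full(p, mu0), sigma2=np.full(p, sigma2_0))


@dataclass
class SubjectFit:
    """MAP estimate of one subject with local posterior information.

    ``x_mean``/``posterior_var`` hold importance-sampled posterior moments
    when the sampling E-step is used; otherwise ``x_mean`` is None and
    ``posterior_var`` is the Laplace (inverse-Hessian) diagonal.
    """

    x_map: np.ndarray
    hessian: np.ndarray
    nll_at_map: float
    objective_at_map: float
    posterior_var: np.ndarray
    success: bool = True
    x_mean: np.ndarray | None = None
    ess: float = np.nan

    @property
    def x_estimate(self) -> np.ndarray:
        return self.x_map if self.x_mean is None else self.x_mean

    def params(self, spec: ModelSpec) -> RLParams:
        return RLParams.from_transformed(self.x_estimate, spec)


@dataclass
class HierarchicalFit:
    spec: ModelSpec
    prior: PopulationPrior
    subject_fits: list
    n_iterations: int
    converged: bool
    mu_history: np.ndarray | None = None

    def natural_estimates(self) -> pd.DataFrame:
        """Per-subject MAP estimates mapped back to natural space."""
        rows = []
        for i, sf in enumerate(self.subject_fits):
            p = sf.params(self.spec)
            rows.append({"subject": i,
                         **{n: p.value(n, self.spec)
                            for n in self.spec.param_names}})
        return pd.DataFrame(rows)

    def quartile_table(self) -> pd.DataFrame:
        """25th/median/75th percentiles of subject estimates per parameter."""
        est = self.natural_estimates().drop(columns="subject")
        q = est.quantile([0.25, 0.5, 0.75]).T
        q.columns = ["q25", "median", "q75"]
        return q.reset_index(names="parameter")


def _pack_sessions(sessions) -> list:
    return [s.arrays() for s in sessions]


def _make_objective(packed, spec: ModelSpec, prior: PopulationPrior):
    mu, sigma2 = prior.mu, prior.sigma2

    def objective(x):
        row = transformed_to_rows(x, spec)[0]
        nll = 0.0
        for stim, act, rew in packed:
            nll += _engine.session_nll_core(stim, act, rew, *row)
        return nll + 0.5 * np.sum((x - mu) ** 2 / sigma2)

    return objective


def _fd_hessian(f, x, rel_step: float = 1e-4) -> np.ndarray:
    """Central finite-difference Hessian, symmetrized."""
    p = x.size
    h = rel_step * (1.0 + np.abs(x))
    H = np.empty((p, p))
    f0 = f(x)
    for i in range(p):
        ei = np.zeros(p)
        ei[i] = h[i]
        H[i, i] = (f(x + ei) - 2.0 * f0 + f(x - ei)) / h[i] ** 2
        for j in range(i + 1, p):
            ej = np.zeros(p)
            ej[j] = h[j]
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej)
                - f(x - ei + ej) + f(x - ei - ej)) / (4.0 * h[i] * h[j])
    return H


def _laplace_variances(H: np.ndarray) -> np.ndarray:
    """Diagonal of the inverse Hessian, with fallbacks for bad curvature."""
    try:
        var = np.diag(np.linalg.inv(H)).copy()
    except np.linalg.LinAlgError:
        var = np.diag(np.linalg.pinv(H)).copy()
    bad = ~np.isfinite(var) | (var <= 0)
    if np.any(bad):
        diag = np.diag(H)
        with np.errstate(divide="ignore"):
            fallback = np.where(diag > 0, 1.0 / diag, 1.0)
        var[bad] = fallback[bad]
    return np.maximum(var, 1e-8)


def map_fit(sessions, prior: PopulationPrior, spec: ModelSpec,
            optimizer_restarts: int = 3, seed=None,
            x0: np.ndarray | None = None) -> SubjectFit:
    """MAP estimate of one subject's parameters under the population prior.

    Maximizes log p(choices | params) + log N(params; mu, diag sigma2) over
    the transformed space, pooling all of the subject's sessions.  Multiple
    restarts are jittered from the prior; ``x0`` adds a warm start.
    """
    if len(sessions) < 1:
        raise ValueError("need at least one session")
    packed = _pack_sessions(sessions)
    objective = _make_objective(packed, spec, prior)
    rng = np.random.default_rng(seed)
    sd = np.sqrt(prior.sigma2)

    starts = []
    if x0 is not None:
        starts.append(np.asarray(x0, dtype=float))
    starts.append(prior.mu.copy())
    while len(starts) < max(optimizer_restarts, 1) + (x0 is not None):
        starts.append(prior.mu + sd * rng.standard_normal(prior.n_params))

    best = None
    for s in starts:
        res = minimize(objective, s, method="L-BFGS-B",
                       options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-7})
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.all(np.isfinite(best.x)):
        raise RuntimeError("MAP optimization failed for all restarts")

    H = _fd_hessian(objective, best.x)
    post_var = _laplace_variances(H)
    prior_term = 0.5 * np.sum((best.x - prior.mu) ** 2 / prior.sigma2)
    return SubjectFit(x_map=best.x, hessian=H, nll_at_map=best.fun - prior_term,
                      objective_at_map=float(best.fun),
                      posterior_var=post_var, success=bool(best.success))


def _importance_moments(packed, spec: ModelSpec, prior: PopulationPrior,
                        sf: SubjectFit, T: np.ndarray):
    """Posterior mean/variance via importance sampling around the MAP.

    The proposal is a multivariate Student-t (precomputed standard draws
    ``T``) centered on the MAP and scaled by the Cholesky factor of the
    inflated Laplace covariance; heavier tails than the skewed posterior
    keep the weights stable.  Returns (mean, variance, effective sample
    size); falls back to the Laplace moments when the weights degenerate.
    """
    p = sf.x_map.size
    df = _PROPOSAL_DF
    try:
        cov = np.linalg.inv(sf.hessian)
        cov = 0.5 * (cov + cov.T) * _PROPOSAL_SCALE ** 2
        L = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        L = np.diag(np.sqrt(sf.posterior_var) * _PROPOSAL_SCALE)
    X = sf.x_map + T @ L.T
    rows = transformed_to_rows(X, spec)
    nll = np.zeros(T.shape[0])
    for stim, act, rew in packed:
        nll += _engine.session_nll_batch(stim, act, rew, rows)
    log_post = -nll - 0.5 * np.sum((X - prior.mu) ** 2 / prior.sigma2,
                                   axis=1)
    log_q = -(df + p) / 2.0 * np.log1p(np.sum(T ** 2, axis=1) / df)
    lw = log_post - log_q
    lw -= logsumexp(lw)
    w = np.exp(lw)
    ess = 1.0 / np.sum(w ** 2)
    if not np.isfinite(ess) or ess < 50:
        return sf.x_map.copy(), sf.posterior_var.copy(), ess
    mean = w @ X
    var = np.maximum(w @ (X - mean) ** 2, 1e-10)
    return mean, var, ess


_PROPOSAL_SCALE = 2.0
_PROPOSAL_DF = 5.0


def em_fit(cohort_sessions, spec: ModelSpec, tol: float = 1e-3,
           max_iter: int = 50, seed=None, optimizer_restarts: int = 3,
           e_step: str = "sample", n_is: int = 2000,
           sigma2_hyperprior=SIGMA2_HYPERPRIOR) -> HierarchicalFit:
    """Fit the population prior and subject posteriors by EM.

    ``cohort_sessions`` is a list (one entry per subject) of lists of
    BehavioralSession; both sessions of a subject share one parameter
    vector.  The E-step locates each subject's MAP under the current prior
    and then estimates posterior mean and variance by importance sampling
    around the Laplace Gaussian (``e_step="sample"``, the default;
    ``e_step="laplace"`` uses the mode and inverse-Hessian directly).  The
    M-step re-estimates the population mean and variance from the subject
    moments; the variance update is the posterior mode under the
    ``sigma2_hyperprior`` inverse-gamma (pass None for the unregularized
    update, floored at a small positive constant).  The importance draws
    are fixed per subject across iterations (common random numbers), so
    the EM map is deterministic and convergence — max |delta mu| < tol —
    is well defined.
    """
    if len(cohort_sessions) < 2:
        raise ValueError("need at least two subjects")
    if e_step not in ("sample", "laplace"):
        raise ValueError("e_step must be 'sample' or 'laplace'")
    rng = np.random.default_rng(seed)
    prior = default_prior(spec)
    n_subj = len(cohort_sessions)
    packed_all = [_pack_sessions(s) for s in cohort_sessions]
    draws = None
    if e_step == "sample":
        z = rng.standard_normal((n_subj, n_is, spec.n_params))
        g = rng.chisquare(_PROPOSAL_DF, (n_subj, n_is))
        draws = z / np.sqrt(g / _PROPOSAL_DF)[:, :, None]
    warm = [None] * n_subj
    mu_hist = [prior.mu.copy()]
    converged = False
    fits = []
    for it in range(1, max_iter + 1):
        fits = []
        restarts = optimizer_restarts if it == 1 else 1
        for i, sessions in enumerate(cohort_sessions):
            sf = map_fit(sessions, prior, spec,
                         optimizer_restarts=restarts,
                         seed=rng.integers(2 ** 31), x0=warm[i])
            warm[i] = sf.x_map
            if e_step == "sample":
                mean, var, ess = _importance_moments(
                    packed_all[i], spec, prior, sf, draws[i])
                sf.x_mean, sf.posterior_var, sf.ess = mean, var, ess
            fits.append(sf)
        est = np.array([sf.x_estimate for sf in fits])
        pvar = np.array([sf.posterior_var for sf in fits])
        mu_new = est.mean(axis=0)
        s_hat = np.maximum((est ** 2 + pvar).mean(axis=0) - mu_new ** 2, 0.0)
        if sigma2_hyperprior is not None:
            a, b = sigma2_hyperprior
            sigma2_new = (b + 0.5 * n_subj * s_hat) / (a + 0.5 * n_subj + 1.0)
        else:
            sigma2_new = s_hat
        sigma2_new = np.maximum(sigma2_new, SIGMA2_FLOOR)
        delta = np.max(np.abs(mu_new - prior.mu))
        prior = PopulationPrior(mu=mu_new, sigma2=sigma2_new)
        mu_hist.append(mu_new.copy())
        if delta < tol:
            converged = True
            break
    return HierarchicalFit(spec=spec, prior=prior, subject_fits=fits,
                           n_iterations=it, converged=converged,
                           mu_history=np.array(mu_hist))


def total_choices(cohort_sessions) -> int:
    return int(sum(s.n_choices for subj in cohort_sessions for s in subj))


def integrated_bic(fit: HierarchicalFit, cohort_sessions,
                   n_samples: int = 200_000, seed=None) -> float:
    """Monte-Carlo integrated BIC of a fitted model on a cohort.

    For each subject-session, draws ``n_samples`` parameter vectors from the
    population prior and estimates log p(choices) as the log of the mean
    likelihood (log-sum-exp stabilized); sums -2x over subject-sessions and
    adds the M * log(N) complexity penalty.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    mu, sd = fit.prior.mu, np.sqrt(fit.prior.sigma2)
    log_marglik = 0.0
    for sessions in cohort_sessions:
        for sess in sessions:
            stim, act, rew = sess.arrays()
            X = mu + sd * rng.standard_normal((n_samples, fit.prior.n_params))
            rows = transformed_to_rows(X, fit.spec)
            nll = _engine.session_nll_batch(stim, act, rew, rows)
            log_marglik += logsumexp(-nll) - np.log(n_samples)
    n_choices = total_choices(cohort_sessions)
    m = 2 * fit.spec.n_params
    return float(-2.0 * log_marglik + m * np.log(n_choices))


@dataclass
class ModelComparisonRow:
    spec: ModelSpec
    ibic: float
    delta_ibic: float = np.nan
    converged: bool = True
    error: str | None = None


def compare_models(specs, cohort_sessions, em_config: dict | None = None,
                   ibic_config: dict | None = None,
                   seed=None) -> list:
    """Fit and score each candidate model; rows sorted by ascending iBIC."""
    if len(specs) < 2:
        raise ValueError("need at least two model specs to compare")
    em_config = dict(em_config or {})
    ibic_config = dict(ibic_config or {})
    ss = np.random.SeedSequence(seed)
    rows = []
    for spec, child in zip(specs, ss.spawn(len(specs))):
        em_seed, ibic_seed = (int(c.generate_state(1)[0] % (2 ** 31))
                              for c in child.spawn(2))
        try:
            fit = em_fit(cohort_sessions, spec, seed=em_seed, **em_config)
            ibic = integrated_bic(fit, cohort_sessions, seed=ibic_seed,
                                  **ibic_config)
            rows.append(ModelComparisonRow(spec=spec, ibic=ibic,
                                           converged=fit.converged))
        except RuntimeError as exc:  # flagged fit: annotate, keep the row
            rows.append(ModelComparisonRow(spec=spec, ibic=np.inf,
                                           converged=False, error=str(exc)))
    rows.sort(key=lambda r: r.ibic)
    best = rows[0].ibic
    for r in rows:
        r.delta_ibic = r.ibic - best
    return rows


def comparison_table(rows) -> pd.DataFrame:
    return pd.DataFrame([{"model": r.spec.to_string(), "ibic": r.ibic,
                          "delta_ibic": r.delta_ibic,
                          "converged": r.converged, "error": r.error}
                         for r in rows])
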