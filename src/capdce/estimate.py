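"""Maximum-likelihood MNL and panel mixed-logit estimation.

MNL uses Newton iterations with the analytic gradient and Hessian (the
log-likelihood is globally concave), classical covariance from the inverse
observed information, and a cluster-robust sandwich with scores summed
within respondent.  The mixed logit maximizes a panel simulated
log-likelihood over Halton (or pseudorandom) normal draws.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize as sp_optimize
from scipy.special import logsumexp
from scipy.stats import norm, qmc

from .simulate import ChoiceDataset, DataError

__all__ = [
    "MNLResult",
    "MMNLResult",
    "FitStats",
    "mnl_loglik",
    "fit_mnl",
    "fit_stats",
    "compute_fit_stats",
    "fit_mmnl",
    "mmnl_simulated_loglik",
]

logger = logging.getLogger(__name__)

_MAX_ITER = 500


@dataclass
class MNLResult:
    param_names: tuple[str, ...]
    beta_hat: np.ndarray
    cov_classical: np.ndarray
    cov_robust: np.ndarray
    ll_final: float
    ll_null: float
    n_obs: int
    n_respondents: int
    converged: bool
    grad_norm: float
    n_iter: int
    n_dropped_tasks: int = 0
    ll_baseline_user: float | None = None

    @property
    def k(self) -> int:
        return len(self.param_names)

    @property
    def se_classical(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self.cov_classical), 0, None))

    @property
    def se_robust(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self.cov_robust), 0, None))

    def coef(self, name: str) -> float:
        return float(self.beta_hat[self.param_names.index(name)])


@dataclass
class FitStats:
    aic: float
    bic: float
    adj_rho2: float
    baseline_used: str  # "equal_shares" or "user_supplied"


@dataclass
class MMNLResult:
    param_names: tuple[str, ...]
    random_names: tuple[str, ...]
    means: np.ndarray
    sds: np.ndarray  # aligned with random_names, >= 0
    n_draws: int
    draw_type: str
    sim_ll: float
    seed: int
    converged: bool
    n_obs: int
    n_respondents: int
    se_means: np.ndarray | None = None
    se_sds: np.ndarray | None = None


# ---------------------------------------------------------------------------
# data preparation

class _Prepared:
    """Arrays for vectorized group-wise likelihood work.

    Rows are sorted by (respondent, task, alt); ``starts`` indexes the first
    row of each choice observation, ``resp_of_obs`` maps observations to
    respondent group indices.
    """

    def __init__(self, data: ChoiceDataset):
        t = data.table.sort_values(["respondent_id", "task_id", "alt_id"], kind="stable")
        self.X = t[list(data.param_names)].to_numpy(dtype=float)
        self.chosen = t["chosen"].to_numpy(dtype=bool)
        obs_key = t["respondent_id"].to_numpy() * (t["task_id"].max() + 1) + t["task_id"].to_numpy()
        change = np.r_[True, obs_key[1:] != obs_key[:-1]]
        self.starts = np.flatnonzero(change)
        self.sizes = np.diff(np.r_[self.starts, len(t)])
        resp = t["respondent_id"].to_numpy()[self.starts]
        self.resp_codes, self.resp_of_obs = np.unique(resp, return_inverse=True)
        self.n_obs = len(self.starts)
        self.n_resp = len(self.resp_codes)
        self.k = self.X.shape[1]
        self.chosen_row = np.flatnonzero(self.chosen)
        if len(self.chosen_row) != self.n_obs:
            raise DataError("every choice observation needs exactly one chosen row")

    def logprobs(self, beta: np.ndarray) -> np.ndarray:
        """Per-row log choice probabilities (max-shifted softmax by observation)."""
        v = self.X @ beta
        vmax = np.maximum.reduceat(v, self.starts)
        v = v - np.repeat(vmax, self.sizes)
        e = np.exp(v)
        denom = np.add.reduceat(e, self.starts)
        return v - np.repeat(np.log(denom), self.sizes)

    def probs(self, beta: np.ndarray) -> np.ndarray:
        return np.exp(self.logprobs(beta))


def mnl_loglik(beta: np.ndarray, data: ChoiceDataset) -> float:
    """Sum over observations of the log probability of the chosen alternative.

    Accumulated per respondent, then over respondents, so that the panel
    simulated likelihood reduces to this value exactly when all random
    coefficient variances are zero.
    """
    prep = _Prepared(data)
    beta = np.asarray(beta, dtype=float)
    if beta.shape != (prep.k,):
        raise DataError(f"beta must have length {prep.k}, got {beta.shape}")
    lp_chosen = prep.logprobs(beta)[prep.chosen]
    by_resp = np.zeros(prep.n_resp)
    np.add.at(by_resp, prep.resp_of_obs, lp_chosen)
    return float(np.sum(by_resp))


def _ll_grad_scores(prep: _Prepared, beta: np.ndarray):
    """(ll, gradient, per-observation score matrix, per-row probabilities)."""
    lp = prep.logprobs(beta)
    p = np.exp(lp)
    ll = float(lp[prep.chosen].sum())
    xp = prep.X * p[:, None]
    xbar = np.add.reduceat(xp, prep.starts, axis=0)  # E[x] per observation
    scores = prep.X[prep.chosen_row] - xbar
    return ll, scores.sum(axis=0), scores, p


def _neg_hessian(prep: _Prepared, p: np.ndarray) -> np.ndarray:
    """Observed information: sum_s X_s'(diag(p_s) - p_s p_s')X_s."""
    xp = prep.X * p[:, None]
    a = prep.X.T @ xp
    xbar = np.add.reduceat(xp, prep.starts, axis=0)
    a -= xbar.T @ xbar
    return 0.5 * (a + a.T)


def fit_mnl(data: ChoiceDataset, include_optout: bool = True,
            start: np.ndarray | None = None, tol: float = 1e-8,
            cluster_by_respondent: bool = True, max_iter: int = _MAX_ITER) -> MNLResult:
    """Fit the main-effects MNL by Newton's method with step halving.

    ``include_optout=False`` gives the forced-choice model: opt-out rows are
    removed, tasks where the opt-out was chosen are dropped (count logged
    and stored on the result), and the ASC is excluded.

    Columns are standardized internally (divided by their max absolute
    value) so the gradient-norm stopping rule is scale-free; estimates and
    covariances are reported in the original units.  ``grad_norm`` is the
    gradient norm in the standardized parameterization.
    """
    n_dropped = 0
    if not include_optout:
        data, n_dropped = data.drop_optout()
        if n_dropped:
            logger.info("forced-choice: dropped %d tasks where the opt-out was chosen", n_dropped)

    prep = _Prepared(data)
    col_max = np.abs(prep.X).max(axis=0)
    scale = np.where(col_max > 0, col_max, 1.0)
    prep.X = prep.X / scale

    beta = np.zeros(prep.k) if start is None else np.asarray(start, dtype=float) * scale
    if beta.shape != (prep.k,):
        raise DataError(f"start must have length {prep.k}, got {beta.shape}")

    ll, grad, scores, p = _ll_grad_scores(prep, beta)
    converged = False
    singular = False
    it = 0
    for it in range(1, max_iter + 1):
        if np.linalg.norm(grad) <= tol:
            converged = True
            break
        info = _neg_hessian(prep, p)
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            singular = True
            step = np.linalg.lstsq(info, grad, rcond=None)[0]
        # step halving keeps the ascent monotone up to float noise in the LL
        alpha = 1.0
        noise = 1e-11 * max(1.0, abs(ll))
        for _ in range(60):
            cand = beta + alpha * step
            ll_new = float(prep.logprobs(cand)[prep.chosen].sum())
            if ll_new > ll - noise:
                break
            alpha *= 0.5
        else:
            break
        beta = beta + alpha * step
        ll, grad, scores, p = _ll_grad_scores(prep, beta)
    grad_norm = float(np.linalg.norm(grad))
    if grad_norm <= tol and not singular:
        converged = True

    info = _neg_hessian(prep, p)
    # scale-invariant identifiability check (raw codes can differ by 1e3+)
    d = np.sqrt(np.clip(np.diag(info), 0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        scaled = info / np.outer(d, d)
    cond = np.linalg.cond(scaled) if np.all(d > 0) else np.inf
    if not np.isfinite(cond) or cond > 1e10:
        logger.warning("observed information is (near-)singular (cond=%.2e); "
                       "model not identified, flagging non-convergence", cond)
        converged = False
        cov_classical = np.linalg.pinv(info)
    else:
        cov_classical = np.linalg.inv(info)

    if cluster_by_respondent:
        g = np.zeros((prep.n_resp, prep.k))
        np.add.at(g, prep.resp_of_obs, scores)
    else:
        g = scores
    bread = cov_classical
    meat = g.T @ g
    cov_robust = bread @ meat @ bread

    # back to original units
    beta = beta / scale
    cov_classical = cov_classical / np.outer(scale, scale)
    cov_robust = cov_robust / np.outer(scale, scale)

    ll_null = float(np.sum(np.log(1.0 / prep.sizes)))
    return MNLResult(
        param_names=tuple(data.param_names),
        beta_hat=beta,
        cov_classical=cov_classical,
        cov_robust=cov_robust,
        ll_final=ll,
        ll_null=ll_null,
        n_obs=prep.n_obs,
        n_respondents=prep.n_resp,
        converged=converged,
        grad_norm=grad_norm,
        n_iter=it,
        n_dropped_tasks=n_dropped,
    )


# ---------------------------------------------------------------------------
# fit statistics

def compute_fit_stats(ll_final: float, k: int, n_obs: int,
                      ll_baseline: float, baseline_used: str = "user_supplied") -> FitStats:
    """AIC = 2K - 2LL; BIC = K ln(N) - 2LL; adjusted rho^2 = 1 - (LL - K)/LL_base."""
    if n_obs <= 0:
        raise ValueError("n_obs must be positive")
    aic = 2 * k - 2 * ll_final
    bic = k * math.log(n_obs) - 2 * ll_final
    adj_rho2 = 1 - (ll_final - k) / ll_baseline if ll_baseline != 0 else 0.0
    if k == 0 and ll_final == ll_baseline:
        adj_rho2 = 0.0
    return FitStats(aic=aic, bic=bic, adj_rho2=adj_rho2, baseline_used=baseline_used)


def fit_stats(res: MNLResult, baseline: float | None = None) -> FitStats:
    """Fit statistics for an estimated model.

    The adjusted-rho^2 baseline defaults to the equal-shares null; supply
    ``baseline`` to use another convention (e.g. a constants-only model).
    """
    if baseline is None:
        return compute_fit_stats(res.ll_final, res.k, res.n_obs, res.ll_null,
                                 baseline_used="equal_shares")
    return compute_fit_stats(res.ll_final, res.k, res.n_obs, baseline,
                             baseline_used="user_supplied")


# ---------------------------------------------------------------------------
# panel mixed logit

def _normal_draws(n_resp: int, n_draws: int, dim: int, draw_type: str, seed: int) -> np.ndarray:
    """(n_resp, n_draws, dim) standard-normal draws; Halton draws are a fixed
    deterministic sequence (seed only matters for pseudorandom draws)."""
    if draw_type == "halton":
        sampler = qmc.Halton(d=dim, scramble=False)
        sampler.fast_forward(10)  # drop the degenerate leading points
        u = sampler.random(n_resp * n_draws)
        z = norm.ppf(u)
        return z.reshape(n_resp, n_draws, dim)
    if draw_type == "pseudorandom":
        rng = np.random.default_rng(seed)
        return rng.standard_normal((n_resp, n_draws, dim))
    raise ValueError(f"unknown draw_type {draw_type!r}")


def _mmnl_sim_ll(prep: _Prepared, means: np.ndarray, sds: np.ndarray,
                 rand_idx: np.ndarray, z: np.ndarray) -> float:
    """Panel simulated log-likelihood: per respondent, log of the draw-average
    of the product over tasks of chosen-alternative probabilities."""
    degenerate = not np.any(sds)
    if degenerate:
        z = z[:, :1, :]  # all draws identical; one suffices (and keeps exactness)
    n_draws = z.shape[1]
    base = prep.X @ means  # (rows,)
    dev = sds * z  # (n_resp, n_draws, R)
    resp_of_row = np.repeat(prep.resp_of_obs, prep.sizes)
    xr = prep.X[:, rand_idx]  # (rows, R)
    u = base[:, None] + np.einsum("ir,idr->id", xr, dev[resp_of_row])  # (rows, n_draws)
    umax = np.maximum.reduceat(u, prep.starts, axis=0)
    u = u - np.repeat(umax, prep.sizes, axis=0)
    e = np.exp(u)
    denom = np.add.reduceat(e, prep.starts, axis=0)
    lp_chosen = u[prep.chosen_row] - np.log(denom)  # (n_obs, n_draws)
    lsum = np.zeros((prep.n_resp, n_draws))
    np.add.at(lsum, prep.resp_of_obs, lp_chosen)  # log prod over tasks, per draw
    if degenerate:
        return float(np.sum(lsum[:, 0]))
    return float(np.sum(logsumexp(lsum, axis=1) - np.log(n_draws)))


def mmnl_simulated_loglik(data: ChoiceDataset, means: np.ndarray,
                          random_coefs, sds: np.ndarray,
                          n_draws: int = 500, draw_type: str = "halton",
                          seed: int = 0) -> float:
    """Evaluate the panel simulated log-likelihood at given means/sds.

    With all sds zero this equals :func:`mnl_loglik` at the means exactly.
    """
    prep = _Prepared(data)
    random_coefs = tuple(random_coefs)
    rand_idx = np.array([data.param_names.index(n) for n in random_coefs], dtype=int)
    means = np.asarray(means, dtype=float)
    sds = np.asarray(sds, dtype=float)
    z = _normal_draws(prep.n_resp, n_draws, max(len(rand_idx), 1), draw_type, seed)
    if len(rand_idx) == 0:
        rand_idx = np.array([0], dtype=int)
        sds = np.zeros(1)
    return _mmnl_sim_ll(prep, means, sds, rand_idx, z)


def fit_mmnl(data: ChoiceDataset, random_coefs, n_draws: int = 500,
             draw_type: str = "halton", seed: int = 0, tol: float = 1e-6,
             start: np.ndarray | None = None, max_iter: int = 200,
             compute_se: bool = False) -> MMNLResult:
    """Fit a panel mixed logit with independent normal random coefficients.

    Coefficients named in ``random_coefs`` get estimated means and standard
    deviations; the rest are fixed (sd 0).  Maximization is quasi-Newton on
    the simulated log-likelihood; sds are unconstrained internally and
    reported as absolute values.  ``compute_se=True`` adds standard errors
    from the inverse numerical Hessian of the simulated log-likelihood
    (an O(p^2) extra cost in likelihood evaluations).
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    prep = _Prepared(data)
    random_coefs = tuple(random_coefs)
    unknown = set(random_coefs) - set(data.param_names)
    if unknown:
        raise DataError(f"unknown random coefficient name(s): {sorted(unknown)}")
    rand_idx = np.array([data.param_names.index(n) for n in random_coefs], dtype=int)
    r = len(rand_idx)
    z = _normal_draws(prep.n_resp, n_draws, max(r, 1), draw_type, seed)

    # standardize columns so the quasi-Newton search is well conditioned
    col_max = np.abs(prep.X).max(axis=0)
    scale = np.where(col_max > 0, col_max, 1.0)
    prep.X = prep.X / scale

    # warm start at the MNL solution with small positive sds (scaled space)
    if start is None:
        mnl = fit_mnl(data)
        theta0 = np.r_[mnl.beta_hat * scale, np.full(r, 0.1)]
    else:
        start = np.asarray(start, dtype=float)
        if start.shape != (prep.k + r,):
            raise DataError(f"start must have length {prep.k + r}")
        theta0 = np.r_[start[: prep.k] * scale, start[prep.k:] * scale[rand_idx] if r else start[prep.k:]]

    def negll(theta: np.ndarray) -> float:
        means = theta[: prep.k]
        sds = np.abs(theta[prep.k:]) if r else np.zeros(1)
        idx = rand_idx if r else np.array([0])
        return -_mmnl_sim_ll(prep, means, sds, idx, z)

    res = sp_optimize.minimize(negll, theta0, method="L-BFGS-B",
                               options={"maxiter": max_iter, "ftol": 1e-12, "gtol": tol})
    theta = res.x

    se_means = se_sds = None
    if compute_se:
        from statsmodels.tools.numdiff import approx_hess1

        hess = approx_hess1(theta, negll)
        cov = np.linalg.pinv(0.5 * (hess + hess.T))
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
        se_means = se[: prep.k] / scale
        se_sds = se[prep.k:] / scale[rand_idx] if r else se[prep.k:]

    return MMNLResult(
        param_names=tuple(data.param_names),
        random_names=random_coefs,
        means=theta[: prep.k] / scale,
        sds=np.abs(theta[prep.k:]) / scale[rand_idx] if r else np.abs(theta[prep.k:]),
        n_draws=n_draws,
        draw_type=draw_type,
        sim_ll=float(-res.fun),
        seed=seed,
        converged=bool(res.success),
        n_obs=prep.n_obs,
        n_respondents=prep.n_resp,
        se_means=se_means,
        se_sds=se_sds,
    )
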