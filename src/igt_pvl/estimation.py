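"""PVL parameter estimation: per-subject MLE and hierarchical Bayes.

MLE maximizes the sequence log-likelihood over the open parameter box
(alpha in (0,1), lam in (0,5), A in (0,1), c in (0,5)) via multi-start
quasi-Newton optimization on an unconstrained logistic reparameterization,
so the likelihood is never evaluated outside the box.

The hierarchical model follows the standard probit-normal construction
for bounded cognitive-model parameters: on an unconstrained scale each
group has a location mu_p and scale sigma_p per parameter, individual
deviations are standard-normal (non-centered), and the individual value
is mapped through the normal CDF and scaled by the parameter's upper
bound:

    theta_ip = upper_p * Phi(mu_p + sigma_p * z_ip),   z_ip ~ N(0, 1)
    mu_p ~ N(0, 1),   sigma_p ~ HalfNormal(1)

Bounds for the hierarchical scheme are alpha in (0,2), lam in (0,10),
A in (0,1), c in (0,5).  Sampling uses an affine-invariant /
differential-evolution ensemble MCMC; convergence is judged by split-Rhat
(<= 1.1 on every quantity) computed with ArviZ.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import arviz as az
import emcee
import numpy as np
import pandas as pd
from numba import njit
from scipy.optimize import minimize
from scipy.special import expit, logit, ndtr

from .igt_task import SessionLog
from .pvl_model import (
    DEFAULT_OUTCOME_SCALE,
    HBA_BOUNDS,
    MLE_BOUNDS,
    PVLParameters,
    RULES,
    _loglik_core,
    encode_session,
)

PARAM_NAMES = ("alpha", "lam", "A", "c")


def _uppers(bounds: dict) -> np.ndarray:
    return np.array([bounds[k][1] for k in ("alpha", "lam", "A", "c")])


class NonConvergenceError(RuntimeError):
    """Every optimization start failed."""


@dataclass
class FitResult:
    params: PVLParameters
    loglik: float
    n_starts: int
    converged: bool
    start_seeds: list[int] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "alpha": self.params.alpha,
            "lam": self.params.lam,
            "A": self.params.recency_A,
            "c": self.params.consistency_c,
            "rule": self.params.rule,
            "loglik": self.loglik,
            "n_starts": self.n_starts,
            "converged": self.converged,
        }


def _from_unconstrained(z: np.ndarray, uppers: np.ndarray) -> np.ndarray:
    """Logistic map R^4 -> open box (0, upper)^4."""
    return uppers * expit(z)


def _to_unconstrained(theta: np.ndarray, uppers: np.ndarray) -> np.ndarray:
    return logit(theta / uppers)


def fit_mle(
    session: SessionLog,
    rule: str = "decay",
    n_starts: int = 20,
    seed: int = 0,
    outcome_scale: float = DEFAULT_OUTCOME_SCALE,
) -> FitResult:
    """Maximum-likelihood PVL fit of one session.

    Multi-start L-BFGS on the unconstrained scale; start points are drawn
    uniformly inside the box under ``seed``.  Deterministic given seed.
    """
    if rule not in RULES:
        raise ValueError(f"unknown rule {rule!r}")
    if session.n_trials < 1:
        raise ValueError("cannot fit an empty session")
    choices, x = encode_session(session, outcome_scale)
    uppers = _uppers(MLE_BOUNDS)
    decay = rule == "decay"

    def nll(z: np.ndarray) -> float:
        a, l, A, c = _from_unconstrained(z, uppers)
        return -_loglik_core(a, l, A, c, decay, choices, x, 40)

    rng = np.random.default_rng(seed)
    best = None
    n_ok = 0
    for _ in range(n_starts):
        theta0 = uppers * rng.uniform(0.05, 0.95, size=4)
        res = minimize(nll, _to_unconstrained(theta0, uppers), method="L-BFGS-B")
        if not np.isfinite(res.fun):
            continue
        n_ok += 1
        if best is None or res.fun < best.fun - 1e-12:
            best = res
    if best is None:
        raise NonConvergenceError(f"all {n_starts} starts failed for {session.subject_id}")
    a, l, A, c = _from_unconstrained(best.x, uppers)
    params = PVLParameters(
        alpha=float(a), lam=float(l), recency_A=float(A), consistency_c=float(c), rule=rule
    )
    return FitResult(
        params=params,
        loglik=-float(best.fun),
        n_starts=n_starts,
        converged=n_ok > 0,
        start_seeds=[seed],
    )


def compare_rules(
    session: SessionLog,
    n_starts: int = 20,
    seed: int = 0,
    outcome_scale: float = DEFAULT_OUTCOME_SCALE,
) -> dict[str, FitResult]:
    """Fit decay and delta rules to the same session; report both."""
    return {
        rule: fit_mle(session, rule, n_starts=n_starts, seed=seed, outcome_scale=outcome_scale)
        for rule in RULES
    }


def fits_table(results: Sequence[FitResult], subject_ids: Sequence[str] | None = None) -> pd.DataFrame:
    rows = [r.to_dict() for r in results]
    df = pd.DataFrame(rows)
    if subject_ids is not None:
        df.insert(0, "subject_id", list(subject_ids))
    return df


# ---------------------------------------------------------------------------
# Hierarchical Bayesian estimation


@dataclass
class PosteriorSummary:
    """Posterior summaries and diagnostics of one hierarchical fit."""

    rule: str
    subject_ids: list[str]
    subject_means: pd.DataFrame  # index subject, columns alpha/lam/A/c
    subject_ci_low: pd.DataFrame
    subject_ci_high: pd.DataFrame
    group_location_mean: dict[str, float]  # natural scale: upper * Phi(mu)
    group_location_ci: dict[str, tuple[float, float]]
    group_mu_mean: dict[str, float]  # unconstrained location
    group_sigma_mean: dict[str, float]
    rhat: dict[str, float]
    ess: dict[str, float]
    converged: bool
    chains: int
    iterations: int
    seed: int

    @property
    def max_rhat(self) -> float:
        return max(self.rhat.values())

    def to_json(self) -> str:
        return json.dumps(
            {
                "rule": self.rule,
                "subject_ids": self.subject_ids,
                "subject_means": self.subject_means.reset_index(drop=True).to_dict(
                    orient="records"
                ),
                "group_location_mean": self.group_location_mean,
                "group_location_ci": {k: list(v) for k, v in self.group_location_ci.items()},
                "group_mu_mean": self.group_mu_mean,
                "group_sigma_mean": self.group_sigma_mean,
                "rhat": self.rhat,
                "ess": self.ess,
                "converged": self.converged,
                "sampler": {
                    "chains": self.chains,
                    "iterations": self.iterations,
                    "seed": self.seed,
                },
            },
            indent=2,
        )

    def to_csv(self, path) -> None:
        df = self.subject_means.copy()
        df.insert(0, "subject_id", self.subject_ids)
        df.to_csv(path, index=False)


@njit(cache=True)
def _batch_loglik(
    theta: np.ndarray,  # (B, S, 4) natural-scale parameters
    choices: np.ndarray,  # (S, T) int64
    x: np.ndarray,  # (S, T) scaled nets
    decay: bool,
    total_cards: int,
) -> np.ndarray:
    """PVL log-likelihood for a batch of draws: (B, S) array.

    Routes every (draw, subject) pair through the same compiled
    single-session core the MLE uses, so ensemble samplers can evaluate
    all walkers in one vectorized call.
    """
    B, S, _ = theta.shape
    out = np.empty((B, S))
    for b in range(B):
        for s in range(S):
            out[b, s] = _loglik_core(
                theta[b, s, 0],
                theta[b, s, 1],
                theta[b, s, 2],
                theta[b, s, 3],
                decay,
                choices[s],
                x[s],
                total_cards,
            )
    return out


def hba_transform(mu: np.ndarray, sigma: np.ndarray, z: np.ndarray) -> np.ndarray:
    """Probit-normal map to the natural scale: upper * Phi(mu + sigma z)."""
    uppers = _uppers(HBA_BOUNDS)
    return uppers * ndtr(mu + sigma * z)


def simulate_hba_cohort_params(
    mu: Sequence[float], sigma: Sequence[float], n_subjects: int, seed: int
) -> np.ndarray:
    """Draw (n_subjects, 4) natural-scale parameters from the hierarchical model."""
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n_subjects, 4))
    return hba_transform(np.asarray(mu, float), np.asarray(sigma, float), z)


def fit_hba(
    sessions: Sequence[SessionLog],
    rule: str = "decay",
    chains: int = 4,
    iterations: int = 1000,
    warmup: int = 1000,
    seed: int = 0,
    outcome_scale: float = DEFAULT_OUTCOME_SCALE,
    nwalkers: int | None = None,
    subject_ids: Sequence[str] | None = None,
) -> PosteriorSummary:
    """Hierarchical Bayesian PVL fit of a cohort.

    ``chains`` and ``iterations`` parameterize the retained posterior
    sample: the ensemble is run for ``warmup + iterations`` steps and the
    post-warmup walkers are regrouped into ``chains`` pseudo-chains for
    split-Rhat.  The ensemble uses differential-evolution moves, which
    cope with the moderately high-dimensional non-centered posterior.
    A fit is flagged converged only if every monitored split-Rhat <= 1.1.
    """
    if rule not in RULES:
        raise ValueError(f"unknown rule {rule!r}")
    if len(sessions) < 2:
        raise ValueError("hierarchical fit needs at least 2 subjects")
    if chains < 1 or iterations < 1 or warmup < 0:
        raise ValueError("chains and iterations must be positive")
    S = len(sessions)
    T = sessions[0].n_trials
    if any(s.n_trials != T for s in sessions):
        raise ValueError("all sessions must have the same number of trials")
    if subject_ids is None:
        subject_ids = [s.subject_id for s in sessions]
    enc = [encode_session(s, outcome_scale) for s in sessions]
    choices = np.stack([c for c, _ in enc])  # (S, T)
    x = np.stack([xx for _, xx in enc])
    decay = rule == "decay"
    uppers = _uppers(HBA_BOUNDS)

    ndim = 8 + 4 * S  # mu(4), log_sigma(4), z(S*4)
    if nwalkers is None:
        nwalkers = max(2 * ndim + 2, 64)
        nwalkers += nwalkers % 2

    def log_prob(coords: np.ndarray) -> np.ndarray:
        coords = np.atleast_2d(coords)
        B = coords.shape[0]
        mu = coords[:, 0:4]
        log_sigma = coords[:, 4:8]
        z = coords[:, 8:].reshape(B, S, 4)
        sigma = np.exp(np.clip(log_sigma, -10, 4))
        # priors: mu ~ N(0,1); sigma ~ HalfNormal(1) with log-Jacobian; z ~ N(0,1)
        lp = -0.5 * (mu**2).sum(axis=1)
        lp += (-0.5 * sigma**2 + log_sigma).sum(axis=1)
        lp += -0.5 * (z**2).sum(axis=(1, 2))
        theta = uppers * ndtr(mu[:, None, :] + sigma[:, None, :] * z)
        # clip away exact bound hits from CDF underflow
        theta = np.clip(theta, 1e-12, uppers * (1 - 1e-12))
        lp += _batch_loglik(theta, choices, x, decay, 40).sum(axis=1)
        return lp

    rng = np.random.default_rng(seed)
    p0 = np.concatenate(
        [
            rng.normal(0, 0.5, (nwalkers, 4)),  # mu
            rng.normal(-1.0, 0.3, (nwalkers, 4)),  # log sigma
            rng.normal(0, 0.5, (nwalkers, 4 * S)),  # z
        ],
        axis=1,
    )
    moves = [(emcee.moves.DEMove(), 0.8), (emcee.moves.DESnookerMove(), 0.2)]
    sampler = emcee.EnsembleSampler(
        nwalkers, ndim, log_prob, moves=moves, vectorize=True
    )
    sampler.random_state = np.random.RandomState(seed).get_state()
    sampler.run_mcmc(p0, warmup + iterations, progress=False)
    chain = sampler.get_chain(discard=warmup)  # (iterations, nwalkers, ndim)

    # regroup walkers into `chains` pseudo-chains for diagnostics
    per = nwalkers // chains
    draws = chain[:, : per * chains, :].transpose(1, 0, 2)  # (walkers, iters, ndim)
    draws = draws.reshape(chains, per * iterations, ndim)

    mu_d = draws[:, :, 0:4]
    sigma_d = np.exp(draws[:, :, 4:8])
    z_d = draws[:, :, 8:].reshape(chains, -1, S, 4)
    theta_d = uppers * ndtr(mu_d[:, :, None, :] + sigma_d[:, :, None, :] * z_d)
    group_loc_d = uppers * ndtr(mu_d)  # natural-scale group location

    idata = az.from_dict(
        posterior={
            "group_location": group_loc_d,
            "mu": mu_d,
            "sigma": sigma_d,
            "theta": theta_d,
        },
        coords={"param": list(PARAM_NAMES), "subject": list(subject_ids)},
        dims={
            "group_location": ["param"],
            "mu": ["param"],
            "sigma": ["param"],
            "theta": ["subject", "param"],
        },
    )
    rhat_ds = az.rhat(idata, var_names=["mu", "sigma"])
    ess_ds = az.ess(idata, var_names=["mu", "sigma"])
    rhat = {}
    ess = {}
    for p_i, p in enumerate(PARAM_NAMES):
        rhat[f"mu_{p}"] = float(rhat_ds["mu"].values[p_i])
        rhat[f"sigma_{p}"] = float(rhat_ds["sigma"].values[p_i])
        ess[f"mu_{p}"] = float(ess_ds["mu"].values[p_i])
        ess[f"sigma_{p}"] = float(ess_ds["sigma"].values[p_i])
    converged = all(np.isfinite(v) and v <= 1.1 for v in rhat.values())

    flat_theta = theta_d.reshape(-1, S, 4)
    subj_mean = pd.DataFrame(flat_theta.mean(axis=0), index=list(subject_ids), columns=PARAM_NAMES)
    subj_lo = pd.DataFrame(
        np.quantile(flat_theta, 0.025, axis=0), index=list(subject_ids), columns=PARAM_NAMES
    )
    subj_hi = pd.DataFrame(
        np.quantile(flat_theta, 0.975, axis=0), index=list(subject_ids), columns=PARAM_NAMES
    )
    flat_loc = group_loc_d.reshape(-1, 4)
    loc_mean = {p: float(flat_loc[:, i].mean()) for i, p in enumerate(PARAM_NAMES)}
    loc_ci = {
        p: (float(np.quantile(flat_loc[:, i], 0.025)), float(np.quantile(flat_loc[:, i], 0.975)))
        for i, p in enumerate(PARAM_NAMES)
    }
    flat_mu = mu_d.reshape(-1, 4)
    flat_sigma = sigma_d.reshape(-1, 4)
    return PosteriorSummary(
        rule=rule,
        subject_ids=list(subject_ids),
        subject_means=subj_mean,
        subject_ci_low=subj_lo,
        subject_ci_high=subj_hi,
        group_location_mean=loc_mean,
        group_location_ci=loc_ci,
        group_mu_mean={p: float(flat_mu[:, i].mean()) for i, p in enumerate(PARAM_NAMES)},
        group_sigma_mean={p: float(flat_sigma[:, i].mean()) for i, p in enumerate(PARAM_NAMES)},
        rhat=rhat,
        ess=ess,
        converged=converged,
        chains=chains,
        iterations=iterations,
        seed=seed,
    )
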