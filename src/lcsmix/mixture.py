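"""Finite-mixture latent change score model (trajectory mixture).

The model: each subject belongs to one of K latent classes; within a class
the latent trajectory is fixed (within-class latent variance restricted to
zero), so all between-person variability in true change is carried by the
class structure.  The class-c trajectory is parameterized by an initial
level mean (eta1) and T-1 latent change-score means (delta eta), so the
wave-t class mean is the cumulative sum eta1 + sum_{s<=t} delta_s.
Observed scores are the class mean plus independent Gaussian measurement
error, so conditional on class the waves are independent and partially
missing records contribute the likelihood of exactly their observed waves
(full-information ML under MAR).

Estimation is multi-start EM with closed-form M-steps; the log-likelihood
is non-decreasing every iteration and the best solution must be replicated
across starts to be trusted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .data import PanelDataset

__all__ = [
    "MixtureParams",
    "EMConfig",
    "FittedMixture",
    "mixture_loglik",
    "posterior_probs",
    "em_fit",
    "relative_entropy",
    "information_criteria",
    "align_labels",
    "permute_classes",
    "n_free_params",
    "observed_information_se",
]

logger = logging.getLogger(__name__)

_LOG_2PI = float(np.log(2.0 * np.pi))

#: Residual-variance floor (PHQ-9 points squared); prevents degenerate
#: likelihood spikes when a class collapses onto few subjects.
VAR_FLOOR = 1e-3


@dataclass
class MixtureParams:
    """Parameters of a K-class trajectory mixture.

    ``theta`` is the (K, T) residual-variance matrix; its sharing pattern
    ("class" = class-specific time-constant, "shared" = one value,
    "classwave" = free per cell) is recorded so parameter counts and
    M-steps agree.
    """

    pi: np.ndarray  # (K,)
    eta1: np.ndarray  # (K,)
    deltas: np.ndarray  # (K, T-1)
    theta: np.ndarray  # (K, T)
    theta_structure: str = "class"

    def __post_init__(self):
        self.pi = np.asarray(self.pi, dtype=float)
        self.eta1 = np.asarray(self.eta1, dtype=float)
        self.deltas = np.asarray(self.deltas, dtype=float)
        self.theta = np.asarray(self.theta, dtype=float)
        if abs(self.pi.sum() - 1.0) > 1e-10:
            raise ValueError("mixing proportions must sum to 1")
        if np.any(self.theta < VAR_FLOOR - 1e-12):
            raise ValueError(f"residual variance below floor {VAR_FLOOR}")

    @property
    def K(self) -> int:
        return len(self.pi)

    @property
    def T(self) -> int:
        return self.deltas.shape[1] + 1

    @property
    def wave_means(self) -> np.ndarray:
        """(K, T) class wave means by cumulative summation."""
        return np.concatenate(
            [self.eta1[:, None], self.eta1[:, None] + np.cumsum(self.deltas, axis=1)],
            axis=1,
        )

    @classmethod
    def from_wave_means(cls, pi, means, theta, theta_structure="class"):
        means = np.asarray(means, dtype=float)
        return cls(
            pi=pi,
            eta1=means[:, 0],
            deltas=np.diff(means, axis=1),
            theta=theta,
            theta_structure=theta_structure,
        )


def n_free_params(params: MixtureParams) -> int:
    """Free-parameter count: K-1 proportions, K*T mean parameters, and the
    residual variances implied by the sharing structure."""
    K, T = params.K, params.T
    n_theta = {"shared": 1, "class": K, "classwave": K * T}[params.theta_structure]
    return (K - 1) + K * T + n_theta


def _cell_loglik(params: MixtureParams, y, observed) -> np.ndarray:
    """(n, K) matrix of per-subject, per-class Gaussian log-likelihoods
    over each subject's observed cells."""
    means = params.wave_means  # (K, T)
    out = np.empty((y.shape[0], params.K))
    yz = np.where(observed, y, 0.0)
    for c in range(params.K):
        resid2 = (yz - means[c]) ** 2
        ll = -0.5 * (_LOG_2PI + np.log(params.theta[c]) + resid2 / params.theta[c])
        out[:, c] = np.where(observed, ll, 0.0).sum(axis=1)
    return out


def mixture_loglik(params: MixtureParams, data: PanelDataset) -> float:
    """Observed-data log-likelihood, log-sum-exp stabilized."""
    lm = _cell_loglik(params, data.y, data.observed) + np.log(params.pi)[None, :]
    m = lm.max(axis=1)
    return float((m + np.log(np.exp(lm - m[:, None]).sum(axis=1))).sum())


def posterior_probs(params: MixtureParams, data: PanelDataset) -> np.ndarray:
    """(n, K) posterior class-membership probabilities (Bayes rule over
    each subject's observed cells); rows sum to 1."""
    lm = _cell_loglik(params, data.y, data.observed) + np.log(params.pi)[None, :]
    lm -= lm.max(axis=1, keepdims=True)
    p = np.exp(lm)
    p /= p.sum(axis=1, keepdims=True)
    return p


def relative_entropy(posterior: np.ndarray) -> float:
    """Relative entropy E = 1 - (-sum p log p) / (n log K), in [0, 1].

    1 means perfectly separated classes (one-hot posteriors), 0 means the
    classification carries no information (uniform posteriors).
    """
    posterior = np.asarray(posterior, dtype=float)
    n, K = posterior.shape
    if K < 2:
        raise ValueError("relative entropy requires K >= 2")
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(posterior > 0, posterior * np.log(posterior), 0.0)
    return float(1.0 - (-plogp.sum()) / (n * np.log(K)))


def information_criteria(loglik: float, n_params: int, n: int) -> dict:
    """AIC, BIC, and sample-size-adjusted BIC (penalty log((n+2)/24))."""
    if n_params < 1 or n < 2:
        raise ValueError("need n_params >= 1 and n >= 2")
    return {
        "aic": -2.0 * loglik + 2.0 * n_params,
        "bic": -2.0 * loglik + n_params * np.log(n),
        "abic": -2.0 * loglik + n_params * np.log((n + 2.0) / 24.0),
    }


@dataclass
class EMConfig:
    """Multi-start EM settings.

    All starts run a short EM pass; the ``refine_top`` best by likelihood
    are refined to full convergence.  The best refined log-likelihood
    should be replicated (within ``replication_tol``) by at least one
    other start, mirroring standard mixture practice; otherwise the fit is
    flagged.
    """

    n_starts: int = 50
    refine_top: int = 10
    tol: float = 1e-8
    max_iter: int = 1000
    short_tol: float = 1e-6
    short_max_iter: int = 80
    theta_structure: str = "class"
    replication_tol: float = 1e-3
    max_restarts: int = 3
    seed: int | None = None


@dataclass
class FittedMixture:
    params: MixtureParams
    posterior: np.ndarray
    loglik: float
    n_params: int
    converged: bool
    #: final log-likelihood of every refined start
    start_logliks: list = field(default_factory=list)
    #: how many refined starts matched the best LL within replication_tol
    replications: int = 0
    n_iter: int = 0
    flags: list = field(default_factory=list)

    @property
    def ll_replicated(self) -> bool:
        return self.replications >= 2


def _em_iterate(pi, means, theta, y, observed, structure, tol, max_iter, ll_trace=None):
    """Run EM to tolerance from the given parameter state.

    Returns (pi, means, theta, loglik, n_iter, ok).  ``ok`` is False when a
    class lost essentially all responsibility mass (empty class).  When
    ``ll_trace`` is a list, the log-likelihood of every iteration is
    appended to it (monotonicity diagnostics).
    """
    n, T = y.shape
    K = len(pi)
    yz = np.where(observed, y, 0.0)
    obs = observed.astype(float)
    prev_ll = -np.inf
    ll = -np.inf
    it = 0
    for it in range(1, max_iter + 1):
        # E-step
        lm = np.empty((n, K))
        for c in range(K):
            resid2 = (yz - means[c]) ** 2
            cell = -0.5 * (_LOG_2PI + np.log(theta[c]) + resid2 / theta[c])
            lm[:, c] = np.where(observed, cell, 0.0).sum(axis=1)
        lm += np.log(pi)[None, :]
        m = lm.max(axis=1)
        ll = float((m + np.log(np.exp(lm - m[:, None]).sum(axis=1))).sum())
        if ll_trace is not None:
            ll_trace.append(ll)
        gamma = np.exp(lm - m[:, None])
        gamma /= gamma.sum(axis=1, keepdims=True)

        mass = gamma.sum(axis=0)
        if np.any(mass < 1.0):
            return pi, means, theta, ll, it, False

        # M-step
        pi = mass / n
        new_means = np.empty_like(means)
        sse = np.empty((K, T))
        wsum = np.empty((K, T))
        for c in range(K):
            w = gamma[:, c][:, None] * obs  # (n, T)
            wt = w.sum(axis=0)
            wsum[c] = wt
            mu = np.where(wt > 0, (w * yz).sum(axis=0) / np.maximum(wt, 1e-300), means[c])
            new_means[c] = mu
            sse[c] = (w * (yz - mu) ** 2).sum(axis=0)
        means = new_means
        if structure == "shared":
            theta = np.full((K, T), max(sse.sum() / wsum.sum(), VAR_FLOOR))
        elif structure == "class":
            v = sse.sum(axis=1) / np.maximum(wsum.sum(axis=1), 1e-300)
            theta = np.tile(np.maximum(v, VAR_FLOOR)[:, None], (1, T))
        elif structure == "classwave":
            theta = np.maximum(
                np.where(wsum > 0, sse / np.maximum(wsum, 1e-300), theta), VAR_FLOOR
            )
        else:
            raise ValueError(f"unknown theta structure {structure!r}")

        if prev_ll > -np.inf and (ll - prev_ll) < tol * max(1.0, abs(ll)):
            break
        prev_ll = ll
    # evaluate the likelihood at the returned (post-M-step) parameters so
    # the reported loglik matches the reported params exactly
    lm = np.empty((n, K))
    for c in range(K):
        resid2 = (yz - means[c]) ** 2
        cell = -0.5 * (_LOG_2PI + np.log(theta[c]) + resid2 / theta[c])
        lm[:, c] = np.where(observed, cell, 0.0).sum(axis=1)
    lm += np.log(pi)[None, :]
    m = lm.max(axis=1)
    ll = float((m + np.log(np.exp(lm - m[:, None]).sum(axis=1))).sum())
    if ll_trace is not None:
        ll_trace.append(ll)
    return pi, means, theta, ll, it, True


def _kmeanspp_start(X, K, rng):
    """k-means++-style seeding on mean-imputed trajectories: class mean
    curves drawn from observed subjects, spread apart in squared distance."""
    n = X.shape[0]
    centers = [X[rng.integers(n)]]
    for _ in range(K - 1):
        d2 = np.min(
            np.stack([((X - c) ** 2).sum(axis=1) for c in centers]), axis=0
        )
        tot = d2.sum()
        if tot <= 0:
            centers.append(X[rng.integers(n)])
            continue
        centers.append(X[rng.choice(n, p=d2 / tot)])
    return np.stack(centers)


def em_fit(data: PanelDataset, K: int, config: EMConfig | None = None) -> FittedMixture:
    """Fit the K-class trajectory mixture by multi-start EM.

    E-step: posterior responsibilities by Bayes rule over observed cells.
    M-step (closed form): mixing proportions = mean responsibility; wave
    means = responsibility-weighted means of observed scores per class
    (eta1/delta recovered by differencing); residual variances =
    responsibility-weighted residual mean squares under the configured
    sharing structure.
    """
    if config is None:
        config = EMConfig()
    n, T = data.y.shape
    if K < 1 or n < K:
        raise ValueError("need 1 <= K <= n")
    rng = np.random.default_rng(config.seed)
    y, observed = data.y, data.observed
    yz = np.where(observed, y, 0.0)
    obs = observed.astype(float)

    wave_mean = (obs * yz).sum(axis=0) / obs.sum(axis=0)
    X = np.where(observed, y, wave_mean[None, :])  # mean-imputed, starts only
    total_var = float(((yz - wave_mean) ** 2 * obs).sum() / obs.sum())

    flags: list[str] = []
    if K == 1:
        pi0 = np.ones(1)
        means0 = wave_mean[None, :].copy()
        theta0 = np.full((1, T), max(total_var, VAR_FLOOR))
        pi, means, theta, ll, it, ok = _em_iterate(
            pi0, means0, theta0, y, observed, config.theta_structure,
            config.tol, config.max_iter,
        )
        params = MixtureParams.from_wave_means(pi, means, theta, config.theta_structure)
        return FittedMixture(
            params=params,
            posterior=posterior_probs(params, data),
            loglik=ll,
            n_params=n_free_params(params),
            converged=it < config.max_iter,
            start_logliks=[ll],
            replications=1,
            n_iter=it,
            flags=flags,
        )

    # -- short pass over all starts ---------------------------------------
    short_results = []
    for s in range(config.n_starts):
        ok = False
        state = None
        for attempt in range(config.max_restarts + 1):
            means0 = _kmeanspp_start(X, K, rng) + rng.normal(0, 0.1, size=(K, T))
            pi0 = np.full(K, 1.0 / K)
            theta0 = np.full((K, T), max(total_var, VAR_FLOOR))
            pi, means, theta, ll, it, ok = _em_iterate(
                pi0, means0, theta0, y, observed, config.theta_structure,
                config.short_tol, config.short_max_iter,
            )
            if ok:
                state = (pi, means, theta, ll)
                break
        if not ok:
            flags.append(f"start {s}: empty class after {config.max_restarts} restarts")
            continue
        logger.debug("start %d: short-pass LL %.4f", s, state[3])
        short_results.append(state)
    if not short_results:
        raise RuntimeError("all EM starts failed (empty classes)")

    # -- refine the top starts to full convergence -------------------------
    short_results.sort(key=lambda st: -st[3])
    refined = []
    for pi, means, theta, _ in short_results[: config.refine_top]:
        pi, means, theta, ll, it, ok = _em_iterate(
            pi, means, theta, y, observed, config.theta_structure,
            config.tol, config.max_iter,
        )
        if ok:
            refined.append((pi, means, theta, ll, it))
    if not refined:
        raise RuntimeError("all refined EM starts failed")
    refined.sort(key=lambda st: -st[3])
    pi, means, theta, best_ll, best_iter = refined[0]
    start_lls = [st[3] for st in refined]
    replications = sum(1 for v in start_lls if best_ll - v <= config.replication_tol)
    if replications < 2:
        flags.append("best log-likelihood not replicated across starts")
        logger.warning("best LL %.4f not replicated across starts", best_ll)

    params = MixtureParams.from_wave_means(pi, means, theta, config.theta_structure)
    return FittedMixture(
        params=params,
        posterior=posterior_probs(params, data),
        loglik=best_ll,
        n_params=n_free_params(params),
        converged=best_iter < config.max_iter,
        start_logliks=start_lls,
        replications=replications,
        n_iter=best_iter,
        flags=flags,
    )


def _pack_params(params: MixtureParams) -> np.ndarray:
    """Free-parameter vector: multinomial logits of pi (vs last class),
    eta1, deltas, and log residual variances per the sharing structure."""
    p = params
    logit_pi = np.log(p.pi[:-1] / p.pi[-1])
    if p.theta_structure == "shared":
        th = np.log(p.theta[:1, 0])
    elif p.theta_structure == "class":
        th = np.log(p.theta[:, 0])
    else:
        th = np.log(p.theta).ravel()
    return np.concatenate([logit_pi, p.eta1, p.deltas.ravel(), th])


def _unpack_params(x, K, T, structure) -> MixtureParams:
    i = K - 1
    logits = np.concatenate([x[:i], [0.0]])
    e = np.exp(logits - logits.max())
    pi = e / e.sum()
    eta1 = x[i : i + K]
    i += K
    deltas = x[i : i + K * (T - 1)].reshape(K, T - 1)
    i += K * (T - 1)
    if structure == "shared":
        theta = np.full((K, T), np.exp(x[i]))
    elif structure == "class":
        theta = np.tile(np.exp(x[i : i + K])[:, None], (1, T))
    else:
        theta = np.exp(x[i : i + K * T]).reshape(K, T)
    theta = np.maximum(theta, VAR_FLOOR)
    return MixtureParams(pi, eta1, deltas, theta, structure)


def observed_information_se(params: MixtureParams, data: PanelDataset, h: float = 1e-4) -> dict:
    """Standard errors from the numerically inverted observed information
    at the ML solution.

    The Hessian of the log-likelihood is taken on the unconstrained scale
    (multinomial logits for pi, log variances for theta); SEs for eta1 and
    the change means are direct, pi SEs come via the delta method.
    Returns a dict with "pi", "eta1", "deltas" SE arrays.
    """
    K, T = params.K, params.T
    x0 = _pack_params(params)

    def ll(x):
        return mixture_loglik(_unpack_params(x, K, T, params.theta_structure), data)

    m = len(x0)
    H = np.empty((m, m))
    f0 = ll(x0)
    steps = h * np.maximum(1.0, np.abs(x0))
    # central second differences
    fp = np.empty(m)
    fm = np.empty(m)
    for j in range(m):
        xp, xm = x0.copy(), x0.copy()
        xp[j] += steps[j]
        xm[j] -= steps[j]
        fp[j], fm[j] = ll(xp), ll(xm)
    for j in range(m):
        H[j, j] = (fp[j] - 2 * f0 + fm[j]) / steps[j] ** 2
        for k in range(j + 1, m):
            xpp = x0.copy()
            xpp[[j, k]] += steps[[j, k]]
            fjk = ll(xpp)
            H[j, k] = H[k, j] = (
                fjk - fp[j] - fp[k] + f0
            ) / (steps[j] * steps[k])
    cov = np.linalg.pinv(-H)
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    # delta method for pi from its logits
    J = np.diag(params.pi[:-1]) - np.outer(params.pi[:-1], params.pi[:-1])
    cov_pi = J @ cov[: K - 1, : K - 1] @ J.T
    se_pi_last = float(np.sqrt(max(np.sum(cov_pi), 0.0)))  # var of 1 - sum
    return {
        "pi": np.concatenate([np.sqrt(np.maximum(np.diag(cov_pi), 0.0)), [se_pi_last]]),
        "eta1": se[K - 1 : 2 * K - 1],
        "deltas": se[2 * K - 1 : 2 * K - 1 + K * (T - 1)].reshape(K, T - 1),
    }


def align_labels(estimated: MixtureParams, reference: MixtureParams) -> np.ndarray:
    """Permutation resolving label switching.

    Returns ``perm`` with ``perm[j]`` the estimated-class index matching
    reference class ``j``, chosen to minimize the total squared distance
    between class mean curves (optimal assignment).
    """
    if estimated.K != reference.K or estimated.T != reference.T:
        raise ValueError("class count / wave count mismatch")
    est, ref = estimated.wave_means, reference.wave_means
    cost = ((ref[:, None, :] - est[None, :, :]) ** 2).sum(axis=2)  # (ref, est)
    _, cols = linear_sum_assignment(cost)
    return cols


def permute_classes(fit: FittedMixture, perm: np.ndarray) -> FittedMixture:
    """Apply a class permutation consistently to params and posterior."""
    p = fit.params
    params = MixtureParams(
        pi=p.pi[perm],
        eta1=p.eta1[perm],
        deltas=p.deltas[perm],
        theta=p.theta[perm],
        theta_structure=p.theta_structure,
    )
    return FittedMixture(
        params=params,
        posterior=fit.posterior[:, perm],
        loglik=fit.loglik,
        n_params=fit.n_params,
        converged=fit.converged,
        start_logliks=fit.start_logliks,
        replications=fit.replications,
        n_iter=fit.n_iter,
        flags=fit.flags,
    )
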