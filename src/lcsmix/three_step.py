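"""Bias-adjusted 3-step analyses relating latent classes to external variables.

Step 1 fits the unconditional mixture (``lcsmix.mixture``).  Step 2 assigns
each subject to a class (modal assignment by default) and quantifies the
assignment's error rates in the K x K classification table
``Q[k, s] = P(assigned = s | true = k)``.  Step 3 treats the assignment as
a fallible indicator of the true class with known error rates Q and fits

* a multinomial-logit regression of true class membership on covariates
  (ML 3-step of the Vermunt kind), or
* class-specific probabilities of a binary distal outcome
  (Bolck-Croon-Hagenaars as extended by Vermunt),

maximizing a likelihood that marginalizes over the true class.  This avoids
re-defining the classes by the external variables while correcting the bias
that naive assignment-as-known analysis would incur.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import norm

__all__ = [
    "ClassificationTable",
    "ThreeStepResult",
    "modal_assignment",
    "proportional_assignment",
    "classification_errors",
    "step3_multinomial",
    "step3_distal",
]

logger = logging.getLogger(__name__)


def modal_assignment(posterior: np.ndarray) -> np.ndarray:
    """Assign each subject to the class with highest posterior probability.

    Ties are broken toward the lower class index and logged.
    """
    posterior = np.asarray(posterior, dtype=float)
    assign = posterior.argmax(axis=1)  # argmax takes the first maximum
    is_tie = (posterior == posterior.max(axis=1, keepdims=True)).sum(axis=1) > 1
    if is_tie.any():
        logger.info("modal assignment: %d tie(s) broken toward lower index", int(is_tie.sum()))
    return assign


def proportional_assignment(posterior: np.ndarray, rng) -> np.ndarray:
    """Random assignment proportional to posterior probabilities."""
    posterior = np.asarray(posterior, dtype=float)
    cum = posterior.cumsum(axis=1)
    return (rng.random((posterior.shape[0], 1)) > cum[:, :-1]).sum(axis=1)


@dataclass
class ClassificationTable:
    """Modal assignments with their estimated error rates.

    Q[k, s] = P(assigned = s | true = k), estimated from the posterior:
    Q[k, s] = sum_i p_ik 1[assign_i = s] / sum_i p_ik.
    """

    assignments: np.ndarray
    Q: np.ndarray
    counts: np.ndarray


def classification_errors(posterior: np.ndarray, assignments: np.ndarray) -> ClassificationTable:
    posterior = np.asarray(posterior, dtype=float)
    assignments = np.asarray(assignments)
    n, K = posterior.shape
    mass = posterior.sum(axis=0)  # expected class sizes
    if np.any(mass <= 0):
        raise ValueError("a class has zero total posterior mass")
    ind = np.zeros((n, K))
    ind[np.arange(n), assignments] = 1.0
    Q = (posterior.T @ ind) / mass[:, None]
    counts = ind.sum(axis=0).astype(int)
    return ClassificationTable(assignments=assignments, Q=Q, counts=counts)


@dataclass
class ThreeStepResult:
    """Step-3 estimates.

    For the covariate (multinomial) variant, ``table`` has one row per
    (predictor, non-reference class): log-odds coefficient, SE, OR, 95%
    Wald CI, p-value.  For the distal variant, one row per class with the
    outcome probability and CI.
    """

    mode: str
    reference: int | None
    table: pd.DataFrame
    loglik: float
    n_used: int
    n_dropped: int
    flags: list = field(default_factory=list)


def _softmax_rows(logits):
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _multinomial_negll_grad(theta, X, qa, K, ref):
    """Negative marginal log-likelihood and gradient.

    theta: flattened (p, K-1) coefficient matrix for non-reference classes.
    X: (n, p) design; qa: (n, K) with qa[i, k] = Q[k, assign_i].
    """
    n, p = X.shape
    B = theta.reshape(p, K - 1)
    logits = np.zeros((n, K))
    nonref = [k for k in range(K) if k != ref]
    logits[:, nonref] = X @ B
    P = _softmax_rows(logits)
    S = (P * qa).sum(axis=1)
    ll = float(np.log(np.maximum(S, 1e-300)).sum())
    R = P * qa / np.maximum(S, 1e-300)[:, None]  # posterior over true class
    G = X.T @ (R - P)  # (p, K) gradient wrt all logits
    return -ll, -G[:, nonref].ravel()


def _numeric_hessian(grad_fn, x, h=1e-5):
    m = len(x)
    H = np.empty((m, m))
    for j in range(m):
        step = h * max(1.0, abs(x[j]))
        xp = x.copy()
        xm = x.copy()
        xp[j] += step
        xm[j] -= step
        H[:, j] = (grad_fn(xp) - grad_fn(xm)) / (2.0 * step)
    return (H + H.T) / 2.0


def step3_multinomial(
    assignments,
    Q,
    covariates: pd.DataFrame,
    reference: int,
    predictors: list[str] | None = None,
    joint: bool = True,
    class_labels: tuple | None = None,
) -> ThreeStepResult:
    """Multinomial regression of latent class membership on covariates,
    correcting for classification error.

    Maximizes ``sum_i log sum_k P(X=k | z_i; gamma) Q[k, assign_i]`` over
    multinomial-logit coefficients gamma (reference class fixed at zero).
    With ``joint=True`` all predictors enter one model; otherwise one
    univariable model is fitted per predictor.  Subjects with a missing
    covariate are dropped listwise (count reported).
    """
    assignments = np.asarray(assignments)
    Q = np.asarray(Q, dtype=float)
    K = Q.shape[0]
    if not 0 <= reference < K:
        raise ValueError("invalid reference class")
    if predictors is None:
        predictors = list(covariates.columns)
    if class_labels is None:
        class_labels = tuple(str(k) for k in range(K))

    def fit_one(cols):
        Z = covariates[cols]
        ok = ~Z.isna().any(axis=1).to_numpy()
        Zv = Z.to_numpy(dtype=float)[ok]
        a = assignments[ok]
        n = len(a)
        X = np.column_stack([np.ones(n), Zv])
        qa = Q[:, a].T  # (n, K)
        x0 = np.zeros(X.shape[1] * (K - 1))
        res = minimize(
            _multinomial_negll_grad,
            x0,
            args=(X, qa, K, reference),
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": 5000, "ftol": 1e-14, "gtol": 1e-9},
        )
        grad_only = lambda x: _multinomial_negll_grad(x, X, qa, K, reference)[1]
        H = _numeric_hessian(grad_only, res.x)
        try:
            cov = np.linalg.inv(H)
            se = np.sqrt(np.maximum(np.diag(cov), 0.0))
        except np.linalg.LinAlgError:
            se = np.full(len(res.x), np.nan)
        return res, se, n, int((~ok).sum()), ["intercept", *cols], X.shape[1]

    rows = []
    flags: list[str] = []
    nonref = [k for k in range(K) if k != reference]
    total_ll = 0.0
    n_used = 0
    n_dropped = 0
    blocks = [predictors] if joint else [[p] for p in predictors]
    for cols in blocks:
        res, se, n, dropped, names, p_dim = fit_one(cols)
        total_ll += -res.fun
        n_used = n
        n_dropped = dropped
        B = res.x.reshape(p_dim, K - 1)
        SE = se.reshape(p_dim, K - 1)
        if np.any(np.abs(B) > 10):
            flags.append(f"possible separation in block {cols}")
        for r, name in enumerate(names):
            for j, k in enumerate(nonref):
                coef, s = B[r, j], SE[r, j]
                z = coef / s if s > 0 else np.nan
                with np.errstate(over="ignore"):  # separation -> infinite CI bound
                    rows.append(
                        {
                            "predictor": name,
                            "class": class_labels[k],
                            "coef": coef,
                            "se": s,
                            "or": np.exp(coef),
                            "ci_low": np.exp(coef - 1.959963984540054 * s),
                            "ci_high": np.exp(coef + 1.959963984540054 * s),
                            "p": 2.0 * norm.sf(abs(z)) if np.isfinite(z) else np.nan,
                        }
                    )
    table = pd.DataFrame(rows)
    return ThreeStepResult(
        mode="predictors" if joint else "predictors_univariable",
        reference=reference,
        table=table,
        loglik=total_ll,
        n_used=n_used,
        n_dropped=n_dropped,
        flags=flags,
    )


def step3_distal(
    assignments,
    Q,
    outcome,
    class_labels: tuple | None = None,
    tol: float = 1e-10,
    max_iter: int = 5000,
) -> ThreeStepResult:
    """Class-specific probabilities of a binary distal outcome, correcting
    for classification error.

    Maximizes ``sum_i log sum_k pi_k Bernoulli(y_i; rho_k) Q[k, assign_i]``
    by EM over class proportions pi and outcome probabilities rho.
    Subjects with a missing outcome are excluded (count reported).  Wald
    CIs for rho come from the numerically inverted observed information on
    the logit scale (delta method).
    """
    assignments = np.asarray(assignments)
    outcome = np.asarray(outcome, dtype=float)
    Q = np.asarray(Q, dtype=float)
    K = Q.shape[0]
    if class_labels is None:
        class_labels = tuple(str(k) for k in range(K))
    ok = ~np.isnan(outcome)
    y = outcome[ok]
    a = assignments[ok]
    n = len(y)
    if n == 0:
        raise ValueError("no observed outcomes")
    qa = Q[:, a].T  # (n, K)

    flags: list[str] = []
    pi = np.full(K, 1.0 / K)
    rho = np.full(K, y.mean()) + np.linspace(-0.05, 0.05, K)
    rho = np.clip(rho, 0.01, 0.99)
    ll = -np.inf
    for _ in range(max_iter):
        dens = np.where(y[:, None] > 0.5, rho[None, :], 1.0 - rho[None, :])
        joint = pi[None, :] * dens * qa
        S = joint.sum(axis=1)
        new_ll = float(np.log(np.maximum(S, 1e-300)).sum())
        w = joint / np.maximum(S, 1e-300)[:, None]
        mass = w.sum(axis=0)
        pi = mass / n
        rho = np.where(mass > 0, (w * y[:, None]).sum(axis=0) / np.maximum(mass, 1e-300), rho)
        if new_ll - ll < tol * max(1.0, abs(new_ll)):
            ll = new_ll
            break
        ll = new_ll

    degenerate = y.min() == y.max()
    if degenerate:
        flags.append("outcome constant: all class probabilities degenerate")

    # SEs on the logit scale via numerical observed information
    eps = 1e-6
    rho_c = np.clip(rho, eps, 1 - eps)
    pi_c = np.clip(pi, eps, None)
    pi_c = pi_c / pi_c.sum()
    x_hat = np.concatenate([np.log(pi_c[:-1] / pi_c[-1]), np.log(rho_c / (1 - rho_c))])

    def negll(x):
        api = np.concatenate([x[: K - 1], [0.0]])
        p = np.exp(api - api.max())
        p = p / p.sum()
        r = 1.0 / (1.0 + np.exp(-x[K - 1 :]))
        dens = np.where(y[:, None] > 0.5, r[None, :], 1.0 - r[None, :])
        S = (p[None, :] * dens * qa).sum(axis=1)
        return -float(np.log(np.maximum(S, 1e-300)).sum())

    se_rho = np.full(K, np.nan)
    if not degenerate:
        grad = lambda x: _finite_diff_grad(negll, x)
        H = _numeric_hessian(grad, x_hat, h=1e-4)
        try:
            cov = np.linalg.inv(H)
            se_logit = np.sqrt(np.maximum(np.diag(cov)[K - 1 :], 0.0))
            se_rho = se_logit * rho_c * (1 - rho_c)  # delta method
        except np.linalg.LinAlgError:
            flags.append("singular observed information for distal SEs")

    zcrit = 1.959963984540054
    rows = []
    for k in range(K):
        lo = rho[k] - zcrit * se_rho[k]
        hi = rho[k] + zcrit * se_rho[k]
        rows.append(
            {
                "class": class_labels[k],
                "pi": pi[k],
                "prob": rho[k],
                "se": se_rho[k],
                "ci_low": max(lo, 0.0) if np.isfinite(lo) else np.nan,
                "ci_high": min(hi, 1.0) if np.isfinite(hi) else np.nan,
            }
        )
    return ThreeStepResult(
        mode="distal",
        reference=None,
        table=pd.DataFrame(rows),
        loglik=ll,
        n_used=n,
        n_dropped=int((~ok).sum()),
        flags=flags,
    )


def _finite_diff_grad(f, x, h=1e-6):
    g = np.empty(len(x))
    for j in range(len(x)):
        step = h * max(1.0, abs(x[j]))
        xp = x.copy()
        xm = x.copy()
        xp[j] += step
        xm[j] -= step
        g[j] = (f(xp) - f(xm)) / (2.0 * step)
    return g
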