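"""Single-class latent change score model (LCSM).

Latent structure: the true score at wave 1 is eta1; each later wave's true
score is the previous true score plus a latent change score delta_t, so the
vector of true scores is a cumulative sum of (eta1, delta_2, ..., delta_T).
Observed scores add independent Gaussian measurement error.  With
x = (eta1, delta_2..delta_T) ~ N(alpha, Psi) and loading matrix L the
lower-triangular matrix of ones,

    mean  = L alpha
    cov   = L Psi L' + Theta          (Theta diagonal residual variances)

The model is estimated by full-information maximum likelihood: each subject
contributes the multivariate-normal log-density of exactly their observed
waves, so partially missing records are retained.  Fit indices (chi-square
against the saturated model, RMSEA with CI, CFI/TLI against the
independence baseline, SRMR, information criteria) follow standard SEM
definitions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve_triangular
from scipy.optimize import minimize
from scipy.stats import ncx2

from .data import PanelDataset

__all__ = [
    "LcsmSpec",
    "LcsmParams",
    "FitIndices",
    "implied_moments",
    "fiml_loglik",
    "fit_lcsm",
    "fit_saturated",
    "fit_baseline",
]

_LOG_2PI = float(np.log(2.0 * np.pi))

#: floor on residual variances, prevents degenerate likelihood spikes
THETA_FLOOR = 1e-4


@dataclass
class LcsmSpec:
    """Which LCSM parameters are free, fixed, or structurally zero.

    var_eta1: "free" or ("fixed", v)
    var_deltas: "free", "zero", or ("fixed", v) shared across deltas
    cov_eta1_deltas / cov_deltas: "free" or "zero"
    residual_variance: "constant", "per_wave", or ("per_wave_fixed", vector)

    Default (used for the population-level fit): free means, free latent
    variances, zero latent covariances, constant residual variance.
    """

    T: int = 9
    free_mean_eta1: bool = True
    free_mean_deltas: bool = True
    var_eta1: object = "free"
    var_deltas: object = "free"
    cov_eta1_deltas: str = "zero"
    cov_deltas: str = "zero"
    residual_variance: object = "constant"

    def n_free(self) -> int:
        T = self.T
        n = 0
        n += 1 if self.free_mean_eta1 else 0
        n += (T - 1) if self.free_mean_deltas else 0
        n += 1 if self.var_eta1 == "free" else 0
        n += (T - 1) if self.var_deltas == "free" else 0
        n += (T - 1) if self.cov_eta1_deltas == "free" else 0
        n += (T - 1) * (T - 2) // 2 if self.cov_deltas == "free" else 0
        if self.residual_variance == "constant":
            n += 1
        elif self.residual_variance == "per_wave":
            n += T
        return n


@dataclass
class LcsmParams:
    """Latent means, latent covariance block Psi, residual variances."""

    mean_eta1: float
    mean_deltas: np.ndarray  # (T-1,)
    psi: np.ndarray  # (T, T), ordered (eta1, delta_2..delta_T)
    theta: np.ndarray  # (T,) residual variances

    def __post_init__(self):
        self.mean_deltas = np.asarray(self.mean_deltas, dtype=float)
        self.psi = np.asarray(self.psi, dtype=float)
        self.theta = np.asarray(self.theta, dtype=float)
        if np.any(self.theta < THETA_FLOOR - 1e-12):
            raise ValueError(f"residual variance below floor {THETA_FLOOR}")

    @property
    def T(self) -> int:
        return len(self.theta)


@dataclass
class FitIndices:
    loglik: float
    n_params: int
    n: int
    chi2: float
    df: int
    rmsea: float
    rmsea_ci: tuple[float, float]
    cfi: float
    tli: float
    srmr: float
    aic: float
    bic: float
    abic: float


def implied_moments(params: LcsmParams):
    """Model-implied mean vector and covariance matrix.

    mean_t = mean_eta1 + sum_{s<=t} mean_delta_s;  cov = L Psi L' + Theta.
    Raises on a non-positive-semidefinite Psi.
    """
    T = params.T
    eigmin = float(np.linalg.eigvalsh(params.psi).min())
    if eigmin < -1e-8:
        raise ValueError("latent covariance block Psi is not PSD")
    L = np.tril(np.ones((T, T)))
    alpha = np.concatenate([[params.mean_eta1], params.mean_deltas])
    mean = L @ alpha
    cov = L @ params.psi @ L.T + np.diag(params.theta)
    return mean, cov


def _pattern_groups(observed: np.ndarray):
    """Group subject rows by identical missingness pattern."""
    keys = np.packbits(observed, axis=1)
    _, inverse = np.unique(keys, axis=0, return_inverse=True)
    groups = {}
    for i, g in enumerate(inverse):
        groups.setdefault(int(g), []).append(i)
    return [np.asarray(ix) for ix in groups.values()]


def fiml_loglik(mean, cov, data: PanelDataset) -> float:
    """Full-information Gaussian log-likelihood.

    Sum over subjects of the log multivariate-normal density restricted to
    each subject's observed waves.  Subjects are grouped by missingness
    pattern purely as an optimization.
    """
    mean = np.asarray(mean, dtype=float)
    cov = np.asarray(cov, dtype=float)
    total = 0.0
    for idx in _pattern_groups(data.observed):
        o = data.observed[idx[0]]
        k = int(o.sum())
        sub_mu = mean[o]
        sub_cov = cov[np.ix_(o, o)]
        try:
            chol = np.linalg.cholesky(sub_cov)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                "singular covariance on an observed sub-pattern"
            ) from exc
        dev = data.y[np.ix_(idx, np.where(o)[0])] - sub_mu
        sol = solve_triangular(chol, dev.T, lower=True)  # (k, m)
        quad = (sol**2).sum(axis=0)
        logdet = 2.0 * np.log(np.diag(chol)).sum()
        total += float(-0.5 * (k * _LOG_2PI + logdet + quad).sum())
    return total


# -- parameter packing ------------------------------------------------------


def _pack_template(spec: LcsmSpec):
    """Slices of the free-parameter vector, in a fixed order."""
    T = spec.T
    sl = {}
    i = 0

    def take(m):
        nonlocal i
        s = slice(i, i + m)
        i += m
        return s

    if spec.free_mean_eta1:
        sl["mean_eta1"] = take(1)
    if spec.free_mean_deltas:
        sl["mean_deltas"] = take(T - 1)
    if spec.var_eta1 == "free":
        sl["log_var_eta1"] = take(1)
    if spec.var_deltas == "free":
        sl["log_var_deltas"] = take(T - 1)
    if spec.cov_eta1_deltas == "free":
        sl["cov_eta1_deltas"] = take(T - 1)
    if spec.cov_deltas == "free":
        sl["cov_deltas"] = take((T - 1) * (T - 2) // 2)
    if spec.residual_variance == "constant":
        sl["log_theta"] = take(1)
    elif spec.residual_variance == "per_wave":
        sl["log_theta"] = take(T)
    return sl, i


def _unpack(x, spec: LcsmSpec) -> LcsmParams:
    T = spec.T
    sl, _ = _pack_template(spec)
    mean_eta1 = float(x[sl["mean_eta1"]][0]) if spec.free_mean_eta1 else 0.0
    mean_deltas = (
        np.asarray(x[sl["mean_deltas"]]) if spec.free_mean_deltas else np.zeros(T - 1)
    )
    psi = np.zeros((T, T))
    if spec.var_eta1 == "free":
        psi[0, 0] = np.exp(x[sl["log_var_eta1"]][0])
    elif isinstance(spec.var_eta1, tuple):
        psi[0, 0] = spec.var_eta1[1]
    if spec.var_deltas == "free":
        psi[np.arange(1, T), np.arange(1, T)] = np.exp(x[sl["log_var_deltas"]])
    elif isinstance(spec.var_deltas, tuple):
        psi[np.arange(1, T), np.arange(1, T)] = spec.var_deltas[1]
    if spec.cov_eta1_deltas == "free":
        c = np.asarray(x[sl["cov_eta1_deltas"]])
        psi[0, 1:] = c
        psi[1:, 0] = c
    if spec.cov_deltas == "free":
        c = np.asarray(x[sl["cov_deltas"]])
        iu = np.triu_indices(T - 1, k=1)
        block = psi[1:, 1:]
        block[iu] = c
        block[(iu[1], iu[0])] = c
        psi[1:, 1:] = block
    if spec.residual_variance == "constant":
        theta = np.full(T, max(np.exp(x[sl["log_theta"]][0]), THETA_FLOOR))
    elif spec.residual_variance == "per_wave":
        theta = np.maximum(np.exp(x[sl["log_theta"]]), THETA_FLOOR)
    else:
        theta = np.asarray(spec.residual_variance[1], dtype=float)
    return LcsmParams(mean_eta1, mean_deltas, psi, theta)


def _start_values(data: PanelDataset, spec: LcsmSpec) -> np.ndarray:
    obs = data.observed.astype(float)
    yz = np.where(data.observed, data.y, 0.0)
    wave_mean = (obs * yz).sum(axis=0) / np.maximum(obs.sum(axis=0), 1.0)
    wave_var = (obs * (yz - wave_mean) ** 2).sum(axis=0) / np.maximum(obs.sum(axis=0), 2.0)
    sl, m = _pack_template(spec)
    x = np.zeros(m)
    if spec.free_mean_eta1:
        x[sl["mean_eta1"]] = wave_mean[0]
    if spec.free_mean_deltas:
        x[sl["mean_deltas"]] = np.diff(wave_mean)
    if spec.var_eta1 == "free":
        x[sl["log_var_eta1"]] = np.log(max(wave_var[0] / 2.0, 0.1))
    if spec.var_deltas == "free":
        x[sl["log_var_deltas"]] = np.log(1.0)
    if "log_theta" in sl:
        x[sl["log_theta"]] = np.log(max(float(wave_var.mean()) / 2.0, 0.1))
    return x


def fit_saturated(data: PanelDataset, tol: float = 1e-8, max_iter: int = 500):
    """FIML estimate of an unstructured mean vector and covariance matrix
    via the standard EM algorithm for multivariate-normal missing data.
    Returns (mean, cov, loglik, n_params)."""
    n, T = data.y.shape
    obs = data.observed.astype(float)
    yz = np.where(data.observed, data.y, 0.0)
    mu = (obs * yz).sum(axis=0) / np.maximum(obs.sum(axis=0), 1.0)
    centered = np.where(data.observed, data.y - mu, 0.0)
    cov = (centered.T @ centered) / n + np.eye(T) * 1e-3
    prev = -np.inf
    ll = -np.inf
    for _ in range(max_iter):
        Ey = np.empty((n, T))
        Eyy = np.zeros((T, T))
        for idx in _pattern_groups(data.observed):
            o = data.observed[idx[0]]
            mset = np.where(~o)[0]
            oset = np.where(o)[0]
            yo = data.y[np.ix_(idx, oset)]
            if len(mset) == 0:
                Ey[idx] = yo
                Eyy += yo.T @ yo
                continue
            Soo = cov[np.ix_(oset, oset)]
            Smo = cov[np.ix_(mset, oset)]
            Smm = cov[np.ix_(mset, mset)]
            B = Smo @ np.linalg.inv(Soo)
            cond_cov = Smm - B @ Smo.T
            ym = mu[mset] + (yo - mu[oset]) @ B.T
            full = np.empty((len(idx), T))
            full[:, oset] = yo
            full[:, mset] = ym
            Ey[idx] = full
            Eyy += full.T @ full
            Eyy[np.ix_(mset, mset)] += cond_cov * len(idx)
        mu = Ey.mean(axis=0)
        cov = Eyy / n - np.outer(mu, mu)
        cov = (cov + cov.T) / 2.0
        ll = fiml_loglik(mu, cov, data)
        if prev > -np.inf and ll - prev < tol * max(1.0, abs(ll)):
            break
        prev = ll
    return mu, cov, ll, T + T * (T + 1) // 2


def fit_baseline(data: PanelDataset):
    """Independence baseline: free means and variances, zero covariances.
    Closed form on observed cells.  Returns (mean, cov, loglik, n_params)."""
    obs = data.observed.astype(float)
    yz = np.where(data.observed, data.y, 0.0)
    nt = np.maximum(obs.sum(axis=0), 1.0)
    mu = (obs * yz).sum(axis=0) / nt
    var = np.maximum((obs * (yz - mu) ** 2).sum(axis=0) / nt, THETA_FLOOR)
    T = data.y.shape[1]
    ll = fiml_loglik(mu, np.diag(var), data)
    return mu, np.diag(var), ll, 2 * T


def _rmsea_ci(chi2: float, df: int, n: int, level: float = 0.90):
    """RMSEA confidence interval by noncentral chi-square inversion
    (bisection to 1e-8 on the noncentrality)."""
    lo_p, hi_p = (1 + level) / 2.0, (1 - level) / 2.0

    def solve(target_p):
        # find lam with ncx2.cdf(chi2, df, lam) = target_p; cdf decreasing in lam
        if ncx2.cdf(chi2, df, 1e-12) < target_p:
            return 0.0
        lo, hi = 0.0, max(4.0 * chi2, 10.0)
        while ncx2.cdf(chi2, df, hi) > target_p:
            hi *= 2.0
            if hi > 1e8:
                break
        for _ in range(200):
            mid = (lo + hi) / 2.0
            if ncx2.cdf(chi2, df, mid) > target_p:
                lo = mid
            else:
                hi = mid
            if hi - lo < 1e-8:
                break
        return (lo + hi) / 2.0

    lam_lo, lam_hi = solve(lo_p), solve(hi_p)
    denom = df * (n - 1)
    return (float(np.sqrt(lam_lo / denom)), float(np.sqrt(lam_hi / denom)))


def _srmr(sample_mean, sample_cov, mean, cov) -> float:
    """Root mean square of standardized residual moments (covariances and
    means, standardized by sample SDs)."""
    sd = np.sqrt(np.diag(sample_cov))
    T = len(sd)
    resid = []
    for i in range(T):
        for j in range(i + 1):
            resid.append(
                (sample_cov[i, j] - cov[i, j]) / (sd[i] * sd[j])
            )
    resid.extend((sample_mean - mean) / sd)
    return float(np.sqrt(np.mean(np.square(resid))))


def fit_lcsm(
    data: PanelDataset,
    spec: LcsmSpec | None = None,
    maxiter: int = 2000,
):
    """Fit an LCSM by FIML; returns (LcsmParams, FitIndices, diagnostics).

    The saturated model (free means + free covariance) and the
    independence baseline are fitted alongside to form chi-square, RMSEA
    (n-1 convention), CFI/TLI, and SRMR.
    """
    if spec is None:
        spec = LcsmSpec(T=data.y.shape[1])
    n = data.n
    n_free = spec.n_free()
    if n <= n_free:
        raise ValueError("need more subjects than free parameters")

    def negll(x):
        try:
            params = _unpack(x, spec)
            mean, cov = implied_moments(params)
            return -fiml_loglik(mean, cov, data)
        except (np.linalg.LinAlgError, ValueError):
            return 1e12

    x0 = _start_values(data, spec)
    res = minimize(negll, x0, method="L-BFGS-B", options={"maxiter": maxiter})
    params = _unpack(res.x, spec)
    mean, cov = implied_moments(params)
    ll = fiml_loglik(mean, cov, data)

    mu_s, cov_s, ll_sat, p_sat = fit_saturated(data)
    _, _, ll_base, p_base = fit_baseline(data)

    chi2 = max(0.0, 2.0 * (ll_sat - ll))
    df = p_sat - n_free
    chi2_b = max(0.0, 2.0 * (ll_sat - ll_base))
    df_b = p_sat - p_base

    d = max(chi2 - df, 0.0)
    d_b = max(chi2_b - df_b, 0.0)
    cfi = 1.0 - d / max(d, d_b, np.finfo(float).tiny)
    if df > 0 and df_b > 0 and chi2_b / df_b > 1.0:
        tli = min(1.0, ((chi2_b / df_b) - (chi2 / df)) / ((chi2_b / df_b) - 1.0))
    else:
        tli = 1.0
    rmsea = float(np.sqrt(max(0.0, (chi2 - df) / (df * (n - 1))))) if df > 0 else 0.0
    ci = _rmsea_ci(chi2, df, n) if df > 0 else (0.0, 0.0)
    srmr = _srmr(mu_s, cov_s, mean, cov)
    indices = FitIndices(
        loglik=ll,
        n_params=n_free,
        n=n,
        chi2=chi2,
        df=df,
        rmsea=rmsea,
        rmsea_ci=ci,
        cfi=float(cfi),
        tli=float(tli),
        srmr=srmr,
        aic=-2 * ll + 2 * n_free,
        bic=-2 * ll + n_free * np.log(n),
        abic=-2 * ll + n_free * np.log((n + 2) / 24.0),
    )
    diagnostics = {
        "converged": bool(res.success),
        "grad_norm": float(np.max(np.abs(res.jac))) if res.jac is not None else np.nan,
        "n_iter": int(res.nit),
        "boundary_theta": bool(np.any(params.theta <= THETA_FLOOR * 1.01)),
    }
    return params, indices, diagnostics
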