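"""Small negative-binomial / binomial GLM engine for per-feature count models.

This is a deliberately compact fitting core for the differential-expression
and differential-usage tests: log-link NB2 regression (variance μ + αμ²)
fitted by Fisher-scoring IRLS, Cox–Reid adjusted profile likelihood for the
dispersion α, and likelihood-ratio tests between nested fits.  It makes no
attempt at numerical parity with edgeR/DESeq2-style estimators; the trend
and shrinkage defaults are documented in the methods note.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, special, stats

__all__ = [
    "nb_loglik",
    "nb_deviance",
    "nb_irls",
    "estimate_dispersion",
    "shrink_dispersions",
    "nb_lrt",
    "binom_irls",
]

_ETA_CLIP = 30.0


def nb_loglik(y: np.ndarray, mu: np.ndarray, alpha: float) -> float:
    """NB2 log-likelihood (Poisson when alpha == 0)."""
    y = np.asarray(y, dtype=float)
    mu = np.clip(np.asarray(mu, dtype=float), 1e-300, None)
    if alpha <= 0:
        return float(np.sum(y * np.log(mu) - mu - special.gammaln(y + 1)))
    r = 1.0 / alpha
    return float(
        np.sum(
            special.gammaln(y + r)
            - special.gammaln(r)
            - special.gammaln(y + 1)
            + r * np.log(r / (r + mu))
            + y * np.log(mu / (r + mu))
        )
    )


def nb_deviance(y: np.ndarray, mu: np.ndarray, alpha: float) -> float:
    """Unit-summed NB2 deviance (Poisson deviance when alpha == 0)."""
    y = np.asarray(y, dtype=float)
    mu = np.clip(np.asarray(mu, dtype=float), 1e-300, None)
    yl = np.where(y > 0, y * np.log(np.where(y > 0, y, 1.0) / mu), 0.0)
    if alpha <= 0:
        return float(2.0 * np.sum(yl - (y - mu)))
    r = 1.0 / alpha
    return float(2.0 * np.sum(yl - (y + r) * np.log((y + r) / (mu + r))))


@dataclass
class GlmFit:
    beta: np.ndarray
    mu: np.ndarray
    deviance: float
    loglik: float
    converged: bool
    n_iter: int
    info: np.ndarray  # X' W X at the solution


def nb_irls(
    y: np.ndarray,
    X: np.ndarray,
    offset: np.ndarray | None = None,
    alpha: float = 0.0,
    max_iter: int = 50,
    tol: float = 1e-8,
    ridge: float = 1e-6,
    beta0: np.ndarray | None = None,
) -> GlmFit:
    """Fisher-scoring IRLS for a log-link NB2 (or Poisson) regression.

    The ridge is applied to the normal equations only when the unpenalized
    solve fails (degenerate features), so well-posed fits are exact ML.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    offset = np.zeros(n) if offset is None else np.asarray(offset, dtype=float)
    if beta0 is not None:
        beta = np.asarray(beta0, dtype=float).copy()
    else:
        # moment start: intercept-like initialisation through the first column
        beta = np.zeros(p)
        ybar = max(np.mean(y / np.exp(np.clip(offset, -_ETA_CLIP, _ETA_CLIP))), 1e-8)
        if np.allclose(X[:, 0], 1.0):
            beta[0] = np.log(ybar)
    eta = np.clip(X @ beta + offset, -_ETA_CLIP, _ETA_CLIP)
    mu = np.exp(eta)
    dev = nb_deviance(y, mu, alpha)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        w = mu / (1.0 + alpha * mu)
        z = (eta - offset) + (y - mu) / mu
        Xw = X * w[:, None]
        A = X.T @ Xw
        b = Xw.T @ z
        try:
            beta_new = np.linalg.solve(A, b)
            if not np.all(np.isfinite(beta_new)):
                raise np.linalg.LinAlgError
        except np.linalg.LinAlgError:
            beta_new = np.linalg.solve(A + ridge * np.eye(p), b)
        # step-halving on deviance increase
        step = 1.0
        for _ in range(8):
            cand = beta + step * (beta_new - beta)
            eta_c = np.clip(X @ cand + offset, -_ETA_CLIP, _ETA_CLIP)
            mu_c = np.exp(eta_c)
            dev_c = nb_deviance(y, mu_c, alpha)
            if np.isfinite(dev_c) and dev_c <= dev + 1e-12:
                break
            step *= 0.5
        beta, eta, mu = cand, eta_c, mu_c
        if abs(dev - dev_c) < tol * (abs(dev_c) + 0.1):
            dev = dev_c
            converged = True
            break
        dev = dev_c
    w = mu / (1.0 + alpha * mu)
    info = X.T @ (X * w[:, None])
    return GlmFit(
        beta=beta,
        mu=mu,
        deviance=dev,
        loglik=nb_loglik(y, mu, alpha),
        converged=converged,
        n_iter=it,
        info=info,
    )


def _moment_dispersion(y: np.ndarray, mu: np.ndarray, p: int) -> float:
    """Method-of-moments dispersion with a residual-dof correction."""
    n = y.shape[0]
    denom = np.sum(mu**2)
    if denom <= 0:
        return 0.0
    scale = n / max(n - p, 1)
    return float(max((scale * np.sum((y - mu) ** 2) - np.sum(mu)) / denom, 0.0))


def estimate_dispersion(
    y: np.ndarray,
    X: np.ndarray,
    offset: np.ndarray | None = None,
    alpha_bounds: tuple[float, float] = (1e-6, 10.0),
) -> float:
    """Cox–Reid adjusted-profile-likelihood dispersion estimate for one feature.

    Maximizes loglik(α; β̂(α)) − ½ log det(X'WX) over log α.  Returns 0 when
    even the smallest admissible α is disfavoured (under-dispersed feature).
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    p = X.shape[1]
    start = nb_irls(y, X, offset=offset, alpha=0.0)
    a0 = _moment_dispersion(y, start.mu, p)

    def neg_apl(log_a: float) -> float:
        a = float(np.exp(log_a))
        fit = nb_irls(y, X, offset=offset, alpha=a, beta0=start.beta)
        sign, logdet = np.linalg.slogdet(fit.info)
        if sign <= 0:
            logdet = -50.0
        return -(fit.loglik - 0.5 * logdet)

    lo, hi = np.log(alpha_bounds[0]), np.log(alpha_bounds[1])
    res = optimize.minimize_scalar(
        neg_apl, bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-3},
    )
    a_hat = float(np.exp(res.x))
    # boundary check: APL may be monotone decreasing in alpha (Poisson-like gene)
    if a_hat <= alpha_bounds[0] * 1.5 and a0 < alpha_bounds[0]:
        return 0.0
    return a_hat


def shrink_dispersions(
    alphas: np.ndarray,
    log_means: np.ndarray,
    trend_weight: float = 0.75,
    lowess_frac: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Shrink per-feature dispersions toward a mean–dispersion lowess trend.

    Works on the log scale; returns (shrunken, trend).  ``trend_weight`` is the
    fixed weight on the trend (our moderation default, recorded in the run
    manifest).
    """
    from statsmodels.nonparametric.smoothers_lowess import lowess

    alphas = np.asarray(alphas, dtype=float)
    log_means = np.asarray(log_means, dtype=float)
    floor = 1e-6
    la = np.log(np.clip(alphas, floor, None))
    if alphas.size < 10 or np.allclose(log_means, log_means[0]):
        trend = np.full_like(la, la.mean())
    else:
        sm = lowess(la, log_means, frac=lowess_frac, return_sorted=False)
        trend = np.where(np.isfinite(sm), sm, la.mean())
    shrunk = np.exp(trend_weight * trend + (1.0 - trend_weight) * la)
    shrunk = np.where(alphas <= floor, np.minimum(shrunk, np.exp(trend)), shrunk)
    return shrunk, np.exp(trend)


def nb_lrt(
    y: np.ndarray,
    X_full: np.ndarray,
    X_null: np.ndarray,
    offset: np.ndarray | None = None,
    alpha: float = 0.0,
) -> tuple[float, float, GlmFit, GlmFit]:
    """Likelihood-ratio test of nested NB fits at a common dispersion."""
    full = nb_irls(y, X_full, offset=offset, alpha=alpha)
    null = nb_irls(y, X_null, offset=offset, alpha=alpha)
    lr = max(2.0 * (full.loglik - null.loglik), 0.0)
    df = X_full.shape[1] - X_null.shape[1]
    p = float(stats.chi2.sf(lr, df))
    return lr, p, full, null


def binom_irls(
    k: np.ndarray,
    n: np.ndarray,
    X: np.ndarray,
    max_iter: int = 50,
    tol: float = 1e-10,
    ridge: float = 1e-6,
) -> GlmFit:
    """Logit-link binomial IRLS (successes k of n trials)."""
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    X = np.asarray(X, dtype=float)
    use = n > 0
    nn, p = X.shape
    beta = np.zeros(p)
    phat = (k.sum() + 0.5) / (n.sum() + 1.0)
    if np.allclose(X[:, 0], 1.0):
        beta[0] = np.log(phat / (1 - phat))

    def loglik(beta):
        eta = np.clip(X @ beta, -_ETA_CLIP, _ETA_CLIP)
        pr = 1.0 / (1.0 + np.exp(-eta))
        pr = np.clip(pr, 1e-12, 1 - 1e-12)
        return float(np.sum((k * np.log(pr) + (n - k) * np.log(1 - pr))[use]))

    ll = loglik(beta)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = np.clip(X @ beta, -_ETA_CLIP, _ETA_CLIP)
        pr = np.clip(1.0 / (1.0 + np.exp(-eta)), 1e-10, 1 - 1e-10)
        w = n * pr * (1 - pr)
        z = eta + (k - n * pr) / np.where(w > 0, w, 1.0)
        Xw = X * w[:, None]
        A = X.T @ Xw
        b = Xw.T @ z
        try:
            beta_new = np.linalg.solve(A, b)
            if not np.all(np.isfinite(beta_new)):
                raise np.linalg.LinAlgError
        except np.linalg.LinAlgError:
            beta_new = np.linalg.solve(A + ridge * np.eye(p), b)
        step = 1.0
        for _ in range(8):
            cand = beta + step * (beta_new - beta)
            ll_c = loglik(cand)
            if np.isfinite(ll_c) and ll_c >= ll - 1e-12:
                break
            step *= 0.5
        beta = cand
        if abs(ll_c - ll) < tol * (abs(ll_c) + 0.1):
            ll = ll_c
            converged = True
            break
        ll = ll_c
    eta = np.clip(X @ beta, -_ETA_CLIP, _ETA_CLIP)
    pr = np.clip(1.0 / (1.0 + np.exp(-eta)), 1e-10, 1 - 1e-10)
    w = n * pr * (1 - pr)
    info = X.T @ (X * w[:, None])
    return GlmFit(
        beta=beta,
        mu=n * pr,
        deviance=np.nan,
        loglik=ll,
        converged=converged,
        n_iter=it,
        info=info,
    )
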