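"""Batched per-feature generalized linear models.

Two model families drive the whole pipeline:

* grouped-binomial logistic regression (per-CpG differential methylation,
  and the per-gene methylation stage test inside the permutation engine),
  tested by likelihood ratio;
* negative-binomial (NB2) regression with log link and per-feature
  dispersion (per-gene differential expression, and the pooled pathway
  model), tested by Wald.

Both are fitted for thousands of features simultaneously with a shared
design matrix, using IRLS vectorised over features.  The permutation
engine refits every feature under every relabelling, so this batching is
what keeps exhaustive enumeration affordable.

Dispersion is estimated per feature by maximising the Cox-Reid adjusted
profile likelihood (the adjustment subtracts half the log-determinant of
the weighted information; it removes the downward bias of plain ML when
the mean model consumes several degrees of freedom at small n, the same
correction edgeR and DESeq2 apply).  The dispersion is floored at 1e-8
and capped at 100.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special, stats

__all__ = [
    "LogisticLRTResult",
    "NBFitResult",
    "logistic_lrt",
    "nb_fit",
    "nb_wald",
    "ALPHA_FLOOR",
    "ALPHA_CAP",
]

ALPHA_FLOOR = 1e-8
ALPHA_CAP = 100.0

_ETA_CLIP = 30.0


# ---------------------------------------------------------------------------
# grouped-binomial logistic regression
# ---------------------------------------------------------------------------


@dataclass
class LogisticLRTResult:
    """Per-feature likelihood-ratio test of one column of the design."""

    coef: np.ndarray  # (S, p) log-odds coefficients of the full model
    stat: np.ndarray  # (S,) LR chi-square statistic, 1 df
    pvalue: np.ndarray  # (S,)
    degenerate: np.ndarray  # (S,) bool: fit failed, p forced to 1


def _binom_loglik(meth: np.ndarray, cov: np.ndarray, mu: np.ndarray) -> np.ndarray:
    mu = np.clip(mu, 1e-12, 1 - 1e-12)
    return np.sum(meth * np.log(mu) + (cov - meth) * np.log1p(-mu), axis=-1)


def _logistic_irls(
    meth: np.ndarray,
    cov: np.ndarray,
    X: np.ndarray,
    max_iter: int = 50,
    tol: float = 1e-10,
) -> tuple[np.ndarray, np.ndarray]:
    """Fit grouped-binomial logistic models for every row.

    meth, cov: (S, n) success / trial counts; X: (n, p) shared design.
    Returns (beta (S, p), loglik (S,)).  Linear predictors are clipped at
    +/-30, which bounds the fit under complete separation instead of
    diverging; the likelihood still converges in that case.
    """
    S, n = meth.shape
    p = X.shape[1]
    beta = np.zeros((S, p))
    # moment start for the intercept-like direction
    tot_m = meth.sum(axis=1)
    tot_c = cov.sum(axis=1)
    base = np.log((tot_m + 0.5) / (tot_c - tot_m + 0.5))
    beta[:, 0] = base
    ll_old = np.full(S, -np.inf)
    for _ in range(max_iter):
        eta = np.clip(beta @ X.T, -_ETA_CLIP, _ETA_CLIP)  # (S, n)
        mu = special.expit(eta)
        w = cov * mu * (1 - mu)
        w = np.maximum(w, 1e-12)
        z = eta + (meth - cov * mu) / w
        XtWX = np.einsum("ni,sn,nj->sij", X, w, X)
        XtWz = np.einsum("ni,sn->si", X, w * z)
        XtWX += 1e-10 * np.eye(p)  # ridge guard for separated rows
        beta = np.linalg.solve(XtWX, XtWz[..., None])[..., 0]
        eta = np.clip(beta @ X.T, -_ETA_CLIP, _ETA_CLIP)
        ll = _binom_loglik(meth, cov, special.expit(eta))
        if np.all(np.abs(ll - ll_old) < tol * (1 + np.abs(ll))):
            ll_old = ll
            break
        ll_old = ll
    return beta, ll_old


def logistic_lrt(
    meth: np.ndarray,
    cov: np.ndarray,
    X: np.ndarray,
    test_col: int,
) -> LogisticLRTResult:
    """Likelihood-ratio test of ``X[:, test_col]`` per feature.

    Fits the full design and the design with the tested column removed;
    the deviance difference is referred to chi-square with 1 df.  Rows
    where the fit degenerates (non-finite likelihood or negative LR
    statistic beyond round-off) are flagged and assigned p = 1 rather
    than raising.
    """
    meth = np.asarray(meth, dtype=float)
    cov = np.asarray(cov, dtype=float)
    X = np.asarray(X, dtype=float)
    if meth.shape != cov.shape:
        raise ValueError("meth and cov must have identical shapes")
    if np.any(cov <= 0):
        raise ValueError("zero-coverage cell reached the logistic fit; "
                         "the coverage filter contract was violated")
    X_red = np.delete(X, test_col, axis=1)
    beta_full, ll_full = _logistic_irls(meth, cov, X)
    _, ll_red = _logistic_irls(meth, cov, X_red)
    stat = 2.0 * (ll_full - ll_red)
    degenerate = ~np.isfinite(stat) | (stat < -1e-6)
    stat = np.where(degenerate, 0.0, np.maximum(stat, 0.0))
    pval = stats.chi2.sf(stat, df=1)
    pval = np.where(degenerate, 1.0, pval)
    return LogisticLRTResult(coef=beta_full, stat=stat, pvalue=pval,
                             degenerate=degenerate)


# ---------------------------------------------------------------------------
# negative-binomial regression
# ---------------------------------------------------------------------------


@dataclass
class NBFitResult:
    """Per-feature NB2 GLM fit with estimated dispersion."""

    coef: np.ndarray  # (G, p) natural-log-scale coefficients
    se: np.ndarray  # (G, p) observed-information standard errors
    alpha: np.ndarray  # (G,) dispersion (Var = mu + alpha mu^2)
    loglik: np.ndarray  # (G,)
    converged: np.ndarray  # (G,) bool
    tested: np.ndarray  # (G,) bool: False for all-zero features (skipped)


def _nb_loglik(y: np.ndarray, mu: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """NB2 log-likelihood summed over samples; alpha broadcast per feature."""
    a = alpha[..., None]
    r = 1.0 / a
    mu = np.maximum(mu, 1e-12)
    return np.sum(
        special.gammaln(y + r) - special.gammaln(r) - special.gammaln(y + 1.0)
        + y * np.log(a * mu) - (y + r) * np.log1p(a * mu),
        axis=-1,
    )


def _nb_profile_obj(y, mu, alpha, X, cr):
    """Profile (optionally Cox-Reid adjusted) log-likelihood in alpha."""
    ll = _nb_loglik(y, mu, alpha)
    if cr:
        w = mu / (1.0 + alpha[:, None] * mu)  # (G, n) Fisher weights
        XtWX = np.einsum("ni,gn,nj->gij", X, w, X)
        sign, logdet = np.linalg.slogdet(XtWX)
        ll = ll - 0.5 * np.where(sign > 0, logdet, np.inf)
    return ll


def _update_alpha(y, mu, X, cr, n_iter: int = 50) -> np.ndarray:
    """Golden-section maximisation of the profile likelihood over log-alpha."""
    lo = np.full(y.shape[0], np.log(ALPHA_FLOOR))
    hi = np.full(y.shape[0], np.log(ALPHA_CAP))
    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    c = hi - invphi * (hi - lo)
    d = lo + invphi * (hi - lo)
    fc = _nb_profile_obj(y, mu, np.exp(c), X, cr)
    fd = _nb_profile_obj(y, mu, np.exp(d), X, cr)
    for _ in range(n_iter):
        take_lo = fc > fd  # maximum lies in [lo, d]
        hi = np.where(take_lo, d, hi)
        lo = np.where(take_lo, lo, c)
        c = hi - invphi * (hi - lo)
        d = lo + invphi * (hi - lo)
        fc = _nb_profile_obj(y, mu, np.exp(c), X, cr)
        fd = _nb_profile_obj(y, mu, np.exp(d), X, cr)
    return np.exp((lo + hi) / 2.0)


def _nb_irls(y, X, offset, alpha, beta, n_iter: int = 25, tol: float = 1e-10):
    """IRLS for NB2 with log link at fixed per-feature dispersion."""
    p = X.shape[1]
    ll_old = np.full(y.shape[0], -np.inf)
    for _ in range(n_iter):
        eta = beta @ X.T + offset  # (G, n)
        eta = np.clip(eta, -_ETA_CLIP, _ETA_CLIP)
        mu = np.exp(eta)
        w = mu / (1.0 + alpha[:, None] * mu)
        z = (eta - offset) + (y - mu) / mu
        XtWX = np.einsum("ni,gn,nj->gij", X, w, X)
        XtWz = np.einsum("ni,gn->gi", X, w * z)
        XtWX += 1e-10 * np.eye(p)
        beta = np.linalg.solve(XtWX, XtWz[..., None])[..., 0]
        eta = np.clip(beta @ X.T + offset, -_ETA_CLIP, _ETA_CLIP)
        ll = _nb_loglik(y, np.exp(eta), alpha)
        done = np.abs(ll - ll_old) < tol * (1 + np.abs(ll))
        ll_old = ll
        if np.all(done):
            break
    return beta, ll_old


def nb_fit(
    counts: np.ndarray,
    X: np.ndarray,
    offset: np.ndarray | None = None,
    alpha: np.ndarray | float | None = None,
    cox_reid: bool = True,
    max_alternations: int = 50,
    rtol: float = 1e-8,
) -> NBFitResult:
    """Fit per-feature NB2 GLMs with log link.

    Parameters
    ----------
    counts:
        (G, n) non-negative counts.
    X:
        (n, p) design matrix shared by all features.
    offset:
        (n,) log-scale offset (e.g. log size factors); zeros if None.
    alpha:
        Fixed dispersion(s); estimated per feature when None.
    cox_reid:
        Apply the Cox-Reid adjustment when estimating dispersion.
    max_alternations, rtol:
        Budget and relative tolerance of the mean/dispersion alternation;
        exceeding the budget marks the feature unconverged.

    Features whose counts are all zero are skipped (``tested`` False,
    NaN coefficients): their group effect is unidentifiable.
    """
    y = np.asarray(counts, dtype=float)
    X = np.asarray(X, dtype=float)
    G, n = y.shape
    p = X.shape[1]
    if offset is None:
        offset = np.zeros(n)
    offset = np.asarray(offset, dtype=float)

    tested = y.sum(axis=1) > 0
    coef = np.full((G, p), np.nan)
    se = np.full((G, p), np.nan)
    alpha_out = np.full(G, np.nan)
    loglik = np.full(G, np.nan)
    converged = np.zeros(G, dtype=bool)
    if not tested.any():
        return NBFitResult(coef, se, alpha_out, loglik, converged, tested)

    yt = y[tested]
    Gt = yt.shape[0]
    # working-response least-squares start
    z0 = np.log(yt + 0.5) - offset
    beta = (np.linalg.pinv(X) @ z0.T).T

    estimate_alpha = alpha is None
    if estimate_alpha:
        # method-of-moments start on the initial means
        mu0 = np.exp(np.clip(beta @ X.T + offset, -_ETA_CLIP, _ETA_CLIP))
        resid = ((yt - mu0) ** 2 - mu0) / np.maximum(mu0, 1e-8) ** 2
        a = np.clip(resid.mean(axis=1), ALPHA_FLOOR, ALPHA_CAP)
    else:
        a = np.broadcast_to(np.asarray(alpha, dtype=float), (Gt,)).copy()
        a = np.clip(a, ALPHA_FLOOR, ALPHA_CAP)

    # convergence = no further likelihood improvement beyond tolerance
    # (the alternation is monotone up to inner-solver jitter)
    ll_best = np.full(Gt, -np.inf)
    ll_old = np.full(Gt, -np.inf)
    conv = np.zeros(Gt, dtype=bool)
    for _ in range(max_alternations):
        beta, ll = _nb_irls(yt, X, offset, a, beta)
        if estimate_alpha:
            mu = np.exp(np.clip(beta @ X.T + offset, -_ETA_CLIP, _ETA_CLIP))
            a = _update_alpha(yt, mu, X, cox_reid)
            ll = _nb_loglik(yt, mu, a)
        conv = (ll - ll_best) < rtol * (1 + np.abs(ll))
        ll_best = np.maximum(ll_best, ll)
        ll_old = ll
        if np.all(conv):
            break
        if not estimate_alpha:
            conv = np.ones(Gt, dtype=bool)
            break

    # observed-information standard errors at the final fit
    eta = np.clip(beta @ X.T + offset, -_ETA_CLIP, _ETA_CLIP)
    mu = np.exp(eta)
    w_obs = mu * (1.0 + a[:, None] * yt) / (1.0 + a[:, None] * mu) ** 2
    H = np.einsum("ni,gn,nj->gij", X, w_obs, X)
    H += 1e-10 * np.eye(p)
    cov = np.linalg.inv(H)
    se_t = np.sqrt(np.maximum(np.diagonal(cov, axis1=1, axis2=2), 0.0))

    coef[tested] = beta
    se[tested] = se_t
    alpha_out[tested] = a
    loglik[tested] = ll_old
    converged[tested] = conv
    return NBFitResult(coef, se, alpha_out, loglik, converged, tested)


def nb_wald(
    counts: np.ndarray,
    X: np.ndarray,
    offset: np.ndarray | None = None,
    test_col: int = 1,
    **fit_kwargs,
) -> tuple[NBFitResult, np.ndarray, np.ndarray]:
    """Two-sided Wald test of one design column across features.

    The statistic (coefficient over observed-information SE) is referred
    to a t distribution with n - p residual degrees of freedom rather
    than the normal: at a handful of samples per group the normal
    reference is visibly anti-conservative, and the t reference restores
    near-nominal type-I error while converging to the normal as n grows.

    Returns the fit plus per-feature Wald statistic and p (NaN for
    untested features).
    """
    fit = nb_fit(counts, X, offset=offset, **fit_kwargs)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = fit.coef[:, test_col] / fit.se[:, test_col]
    df_resid = max(X.shape[0] - X.shape[1], 1)
    pval = 2.0 * stats.t.sf(np.abs(z), df=df_resid)
    pval = np.where(np.isfinite(z), pval, np.nan)
    return fit, z, pval
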