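"""Differential SEEJ usage: Dirichlet-multinomial GLM and likelihood-ratio
test.

Per-sample SEEJ assignment counts ``y_i`` (row sums = the sample's token
count) are modeled as Dirichlet-multinomial with concentration
``alpha * p_i``, where the proportions come through a softmax link:

``p_ij = exp(x_i bhat_j + mu_j) / sum_k exp(x_i bhat_k + mu_k)``

for a binary group covariate ``x_i``, coefficients ``bhat`` and intercepts
``mu`` (reference category: the last SEEJ, ``mu_k = bhat_k = 0``). The
concentration carries a Gamma(1 + 1e-4, 1e-4) prior to stabilize the
maximum-likelihood fit. Differential usage between the two groups is a
likelihood-ratio test of the covariate model against the ``bhat = 0`` null,
with k - 1 degrees of freedom, and Benjamini-Hochberg correction across
loci.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.special import gammaln, digamma, softmax
from scipy.stats import chi2
from statsmodels.stats.multitest import multipletests

try:
    from sklearn.base import BaseEstimator
except ImportError:  # pragma: no cover
    BaseEstimator = object

# Gamma prior on the concentration (shape, rate)
_ALPHA_PRIOR_SHAPE = 1.0 + 1e-4
_ALPHA_PRIOR_RATE = 1e-4


def dirmult_log_likelihood(counts, alpha_vec) -> float:
    """Exact Dirichlet-multinomial log pmf of one count vector.

    ``counts`` sums to the draw total; ``alpha_vec`` are the positive
    concentration parameters. A zero total has probability 1 (log 0.0).
    """
    counts = np.asarray(counts, dtype=float)
    alpha_vec = np.asarray(alpha_vec, dtype=float)
    if (alpha_vec <= 0).any():
        raise ValueError("alpha_vec must be positive")
    n = counts.sum()
    if n == 0:
        return 0.0
    a0 = alpha_vec.sum()
    return float(gammaln(a0) - gammaln(n + a0)
                 + (gammaln(counts + alpha_vec) - gammaln(alpha_vec)).sum()
                 + gammaln(n + 1) - gammaln(counts + 1).sum())


def _unpack(params: np.ndarray, k: int, with_covariate: bool):
    log_alpha = params[0]
    mu = np.concatenate([params[1:k], [0.0]])
    if with_covariate:
        beta = np.concatenate([params[k:2 * k - 1], [0.0]])
    else:
        beta = np.zeros(k)
    return log_alpha, mu, beta


def _neg_log_posterior(params, Y, x, k, with_covariate, multinom_const):
    """Negative DirMult log-likelihood plus the negative Gamma log prior on
    alpha; returns (value, gradient). Gradient is analytic via digamma."""
    log_alpha, mu, beta = _unpack(params, k, with_covariate)
    alpha = np.exp(log_alpha)
    linpred = mu[None, :] + np.outer(x, beta)        # (n, k)
    P = softmax(linpred, axis=1)
    A = alpha * P                                    # (n, k)
    n_i = Y.sum(axis=1)

    ll = (gammaln(alpha) - gammaln(n_i + alpha)).sum() \
        + (gammaln(Y + A) - gammaln(A)).sum() + multinom_const
    ll += (_ALPHA_PRIOR_SHAPE - 1.0) * log_alpha - _ALPHA_PRIOR_RATE * alpha

    # d ll / d A_ij
    dA = digamma(Y + A) - digamma(A)                 # (n, k)
    # alpha direction (dA_ij/dlog_alpha = A_ij)
    g_log_alpha = (digamma(alpha) - digamma(n_i + alpha)).sum() * alpha \
        + (dA * A).sum() \
        + (_ALPHA_PRIOR_SHAPE - 1.0) - _ALPHA_PRIOR_RATE * alpha
    # softmax chain rule: dA_ij/dmu_m = A_ij (delta_jm - P_im)
    w = (dA * A)                                     # (n, k)
    row = w.sum(axis=1, keepdims=True)               # (n, 1)
    g_eta = w - row * P                              # (n, k) gradient wrt linpred
    g_mu = g_eta.sum(axis=0)[:k - 1]
    grads = [np.array([g_log_alpha]), g_mu]
    if with_covariate:
        grads.append((x[:, None] * g_eta).sum(axis=0)[:k - 1])
    return -ll, -np.concatenate(grads)


@dataclass
class DirMultGlmFit:
    """MLE in (mu, bhat), MAP in the concentration alpha."""

    coef_: np.ndarray            # bhat, k-vector (reference category 0)
    intercept_: np.ndarray       # mu, k-vector (reference category 0)
    concentration_: float        # alpha
    log_likelihood_: float       # maximized log posterior (prior included)
    converged_: bool
    with_covariate: bool

    def proportions(self, x: int) -> np.ndarray:
        return softmax(self.intercept_ + x * self.coef_)


@dataclass
class DiffResult:
    """Per-locus differential-usage test."""

    locus_id: str
    statistic: float
    df: int
    pvalue: float
    qvalue: float = np.nan
    reason: str | None = None

    @property
    def is_na(self) -> bool:
        return not np.isfinite(self.statistic)


def fit_glm(counts, groups=None, with_covariate: bool = True,
            n_restarts: int = 3, seed: int = 0,
            start: np.ndarray | None = None) -> DirMultGlmFit:
    """Fit the Dirichlet-multinomial GLM by quasi-Newton optimization.

    Parameters
    ----------
    counts : (n_samples, k) nonnegative integers
        Per-sample SEEJ assignment counts.
    groups : (n_samples,) binary labels, required when ``with_covariate``.
    with_covariate : bool
        True fits the group model; False fixes ``bhat = 0`` (null model).
    n_restarts : int
        Additional jittered starts; the best optimum is kept (the
        log-likelihood surface can be multimodal in the concentration).
    start : optional parameter vector
        Warm start in the packed parametrization (log alpha, mu, [bhat]);
        a shorter vector (e.g. a null fit's solution) is zero-padded.
    """
    Y = np.asarray(counts, dtype=float)
    n, k = Y.shape
    if k < 2:
        raise ValueError("need at least 2 SEEJs to fit the GLM")
    if with_covariate:
        x = np.asarray(groups, dtype=float)
        levels = np.unique(x)
        if not np.array_equal(levels, [0.0, 1.0]):
            raise ValueError("groups must contain both labels 0 and 1")
    else:
        x = np.zeros(n)

    multinom_const = float(gammaln(Y.sum(axis=1) + 1).sum()
                           - gammaln(Y + 1).sum())
    # moment start: overall proportions for mu, bhat = 0, alpha = 10
    pooled = Y.sum(axis=0) + 0.5
    mu0 = np.log(pooled / pooled[-1])[:k - 1]
    n_par = 1 + (k - 1) * (2 if with_covariate else 1)
    x0 = np.zeros(n_par)
    x0[0] = np.log(10.0)
    x0[1:k] = mu0
    if start is not None:
        x0 = np.zeros(n_par)
        x0[:len(start)] = start

    rng = np.random.default_rng(seed)
    best = None
    for trial in range(1 + max(0, n_restarts)):
        p_start = x0 if trial == 0 else x0 + rng.normal(scale=0.5, size=n_par)
        res = optimize.minimize(
            _neg_log_posterior, p_start, jac=True, method="L-BFGS-B",
            args=(Y, x, k, with_covariate, multinom_const),
            options={"maxiter": 1000, "ftol": 1e-12, "gtol": 1e-9})
        if best is None or res.fun < best.fun:
            best = res
    log_alpha, mu, beta = _unpack(best.x, k, with_covariate)
    # a stalled line search at a stationary point still counts as converged
    grad_ok = bool(np.max(np.abs(best.jac)) < 0.1)
    return DirMultGlmFit(coef_=beta, intercept_=mu,
                         concentration_=float(np.exp(log_alpha)),
                         log_likelihood_=float(-best.fun),
                         converged_=bool(best.success) or grad_ok,
                         with_covariate=with_covariate)


def lrt_test(counts, groups, locus_id: str = "locus", n_restarts: int = 3,
             seed: int = 0) -> DiffResult:
    """Likelihood-ratio test of differential SEEJ usage between two groups.

    statistic = 2 (l_alt - l_null), chi-square with k - 1 degrees of
    freedom; a slightly negative statistic (optimizer tolerance) is clamped
    to 0. Fewer than 2 SEEJs, or a non-converged fit, yields an NA result
    with a reason.
    """
    Y = np.asarray(counts)
    k = Y.shape[1] if Y.ndim == 2 else 0
    if k < 2:
        return DiffResult(locus_id, np.nan, max(k - 1, 0), np.nan,
                          reason="fewer than 2 SEEJs")
    null = fit_glm(Y, with_covariate=False, n_restarts=n_restarts, seed=seed)
    warm = np.concatenate([[np.log(null.concentration_)],
                           null.intercept_[:k - 1]])
    alt = fit_glm(Y, groups, with_covariate=True, n_restarts=n_restarts,
                  seed=seed, start=warm)
    if not (null.converged_ and alt.converged_):
        return DiffResult(locus_id, np.nan, k - 1, np.nan,
                          reason="fit did not converge")
    stat = 2.0 * (alt.log_likelihood_ - null.log_likelihood_)
    stat = max(stat, 0.0)
    p = float(chi2.sf(stat, df=k - 1))
    return DiffResult(locus_id, float(stat), k - 1, p)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (order-preserving; NaNs pass
    through)."""
    p = np.asarray(pvalues, dtype=float)
    q = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


def test_loci(count_matrices, groups, locus_ids=None, n_restarts: int = 3,
              seed: int = 0) -> list[DiffResult]:
    """Run the LRT per locus and BH-adjust across loci."""
    locus_ids = locus_ids or [f"locus{i}" for i in range(len(count_matrices))]
    results = [lrt_test(Y, groups, locus_id=lid, n_restarts=n_restarts,
                        seed=seed)
               for Y, lid in zip(count_matrices, locus_ids)]
    q = bh_adjust([r.pvalue for r in results])
    for r, qv in zip(results, q):
        r.qvalue = float(qv) if np.isfinite(qv) else np.nan
    return results


class DirichletMultinomialGLM(BaseEstimator):
    """scikit-learn style wrapper around :func:`fit_glm` / :func:`lrt_test`.

    ``fit(X, y)`` takes the (n_samples, k) count matrix as ``X`` and the
    binary group labels as ``y``; fits both the null and covariate models
    and exposes the LRT.
    """

    def __init__(self, n_restarts: int = 3, random_state: int = 0):
        self.n_restarts = n_restarts
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X)
        self.null_fit_ = fit_glm(X, with_covariate=False,
                                 n_restarts=self.n_restarts,
                                 seed=self.random_state)
        warm = np.concatenate([[np.log(self.null_fit_.concentration_)],
                               self.null_fit_.intercept_[:X.shape[1] - 1]])
        self.alt_fit_ = fit_glm(X, y, with_covariate=True,
                                n_restarts=self.n_restarts,
                                seed=self.random_state, start=warm)
        self.coef_ = self.alt_fit_.coef_
        self.intercept_ = self.alt_fit_.intercept_
        self.concentration_ = self.alt_fit_.concentration_
        stat = max(0.0, 2.0 * (self.alt_fit_.log_likelihood_
                               - self.null_fit_.log_likelihood_))
        self.lrt_statistic_ = stat
        self.df_ = X.shape[1] - 1
        self.pvalue_ = float(chi2.sf(stat, df=self.df_))
        return self

    def predict_proba(self, x_values) -> np.ndarray:
        """Fitted SEEJ proportions for covariate values (0 or 1)."""
        return np.stack([self.alt_fit_.proportions(int(v)) for v in
                         np.atleast_1d(x_values)])
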