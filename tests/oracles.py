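"""Independent oracles used by the tests.

Everything here is deliberately written against the model definitions, not
against the package's production code paths: direct REML maximization with
dense covariance algebra, closed-form BLUP, exhaustive enumeration for the
rank-based metrics and the Mantel permutation distribution.
"""

from __future__ import annotations

from itertools import permutations

import numpy as np
from scipy import optimize


def reml_kernel_h2(y, K) -> tuple[float, float, float]:
    """REML estimate of (h2, sigma2_u, sigma2_e) for y = 1 mu + u + e,
    u ~ N(0, K sigma2_u), by profiling the total variance and maximizing the
    restricted likelihood over h2 on the kernel eigenbasis."""
    y = np.asarray(y, dtype=float)
    n = len(y)
    w, Q = np.linalg.eigh(K)
    w = np.clip(w, 0.0, None)
    yt = Q.T @ y
    ones_t = Q.T @ np.ones(n)

    def neg_restricted_ll(h2):
        d = h2 * w + (1.0 - h2)  # V = s * Q diag(d) Q'
        xvx = np.sum(ones_t ** 2 / d)
        beta = np.sum(ones_t * yt / d) / xvx
        r = yt - beta * ones_t
        ypy = np.sum(r ** 2 / d)
        s = ypy / (n - 1)  # profiled total variance
        return 0.5 * (np.sum(np.log(d)) + (n - 1) * np.log(s)
                      + np.log(xvx) + (n - 1))

    res = optimize.minimize_scalar(neg_restricted_ll, bounds=(1e-4, 1 - 1e-4),
                                   method="bounded")
    h2 = float(res.x)
    d = h2 * w + (1 - h2)
    xvx = np.sum(ones_t ** 2 / d)
    beta = np.sum(ones_t * yt / d) / xvx
    s = np.sum((yt - beta * ones_t) ** 2 / d) / (n - 1)
    return h2, h2 * s, (1 - h2) * s


def reml_variance_components(y, X, Zs, x0=None) -> tuple[list, float]:
    """Generic REML for y = X b + sum Z_i u_i + e by direct optimization of
    the restricted log-likelihood over log variances (dense V, slogdet)."""
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, p = X.shape
    ZZt = [Z @ Z.T for Z in (np.asarray(Z, dtype=float) for Z in Zs)]
    vary = np.var(y)

    def neg_rll(log_s2):
        s2 = np.exp(log_s2)
        V = s2[-1] * np.eye(n)
        for s, G in zip(s2[:-1], ZZt):
            V = V + s * G
        sign, logdetV = np.linalg.slogdet(V)
        Vi = np.linalg.inv(V)
        XtViX = X.T @ Vi @ X
        sign2, logdetX = np.linalg.slogdet(XtViX)
        beta = np.linalg.solve(XtViX, X.T @ Vi @ y)
        r = y - X @ beta
        return 0.5 * (logdetV + logdetX + r @ Vi @ r)

    k = len(ZZt) + 1
    x0 = np.log(np.full(k, max(vary, 1e-3) / k)) if x0 is None else np.asarray(x0)
    res = optimize.minimize(neg_rll, x0, method="Nelder-Mead",
                            options={"xatol": 1e-8, "fatol": 1e-10,
                                     "maxiter": 4000})
    s2 = np.exp(res.x)
    return list(s2[:-1]), float(s2[-1])


def gls_blues(y, X, V) -> np.ndarray:
    """Generalized least squares fixed-effect estimates for known V."""
    Vi = np.linalg.inv(V)
    return np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)


def closed_form_blup(y, K, sigma2_u, sigma2_e) -> np.ndarray:
    """u_hat = K (K + lambda I)^-1 (y - ybar) at fixed variance components."""
    lam = sigma2_e / sigma2_u
    n = len(y)
    return K @ np.linalg.solve(K + lam * np.eye(n), y - y.mean())


def auc_pairwise(scores, labels, positive=1) -> float:
    """P(score+ > score-) + 0.5 P(tie) by explicit enumeration of all pairs."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == positive]
    neg = scores[labels != positive]
    total = 0.0
    for sp in pos:
        for sn in neg:
            total += 1.0 if sp > sn else (0.5 if sp == sn else 0.0)
    return total / (len(pos) * len(neg))


def mantel_exhaustive(A, B) -> tuple[float, float]:
    """Observed Mantel r and exact one-sided p over all n! permutations."""
    n = A.shape[0]
    iu = np.triu_indices(n, k=1)

    def corr(M):
        a, b = A[iu], M[iu]
        a = a - a.mean()
        b = b - b.mean()
        return float(a @ b / np.sqrt((a @ a) * (b @ b)))

    r_obs = corr(B)
    count, total = 0, 0
    for perm in permutations(range(n)):
        p = np.asarray(perm)
        r_p = corr(B[np.ix_(p, p)])
        count += r_p >= r_obs - 1e-12
        total += 1
    return r_obs, count / total
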