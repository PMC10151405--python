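"""EM-REML for small linear mixed models via Henderson's equations.

Used by the preprocessing stages (run/batch correction, per-line BLUEs,
conventional heritability). The model is

    y = X b + sum_i Z_i u_i + e,   u_i ~ N(0, I sigma^2_i),  e ~ N(0, I sigma^2_e)

with dense identity-covariance random factors, which covers replicated
phenotype designs and run/batch nuisance factors. Problems here are small
(a few hundred equations), so the mixed-model equations are solved densely.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class MixedFit:
    beta: np.ndarray
    u: list[np.ndarray]
    sigma2: list[float]          # one per random factor
    sigma2_e: float
    n_iter: int
    converged: bool

    def fitted_fixed(self, X: np.ndarray) -> np.ndarray:
        return X @ self.beta


def em_reml(y, X, Zs, max_iter: int = 500, tol: float = 1e-9,
            var_floor_frac: float = 1e-8) -> MixedFit:
    """Estimate variance components by EM-REML and solve the MME.

    Parameters
    ----------
    y : (n,) response
    X : (n, p) fixed-effect design
    Zs : list of (n, q_i) random-effect incidence matrices
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Zs = [np.asarray(Z, dtype=float) for Z in Zs]
    n, p = X.shape
    qs = [Z.shape[1] for Z in Zs]
    rank_x = np.linalg.matrix_rank(X)
    vary = float(np.var(y)) if np.var(y) > 0 else 1.0
    floor = var_floor_frac * vary

    W = np.hstack([X] + Zs)
    WtW = W.T @ W
    Wty = W.T @ y
    yty = float(y @ y)

    k = len(Zs)
    sigma2 = [max(vary / (k + 1), floor)] * k
    sigma2_e = max(vary / (k + 1), floor)

    # index ranges of each random factor inside the MME
    starts, pos = [], p
    for q in qs:
        starts.append((pos, pos + q))
        pos += q

    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        M = WtW.copy()
        for (a, b), s2 in zip(starts, sigma2):
            M[range(a, b), range(a, b)] += sigma2_e / s2
        # ridge for rank-deficient fixed part
        M[range(p), range(p)] += 1e-10 * (np.trace(WtW) / max(W.shape[1], 1))
        C = np.linalg.inv(M)
        theta = C @ Wty

        new_sigma2 = []
        for (a, b), q in zip(starts, qs):
            u = theta[a:b]
            tr = np.trace(C[a:b, a:b])
            new_sigma2.append(max((u @ u + sigma2_e * tr) / q, floor))
        resid_ss = yty - theta @ Wty
        new_sigma2_e = max(resid_ss / (n - rank_x), floor)

        delta = abs(new_sigma2_e - sigma2_e) + sum(
            abs(a - b) for a, b in zip(new_sigma2, sigma2))
        sigma2, sigma2_e = new_sigma2, new_sigma2_e
        if delta < tol * vary:
            converged = True
            break

    beta = theta[:p]
    us = [theta[a:b] for (a, b) in starts]
    return MixedFit(beta, us, sigma2, sigma2_e, it, converged)


def indicator(labels) -> tuple[np.ndarray, np.ndarray]:
    """Dense 0/1 incidence matrix for a label vector; returns (Z, levels)."""
    labels = np.asarray(labels)
    levels = np.unique(labels)
    Z = (labels[:, None] == levels[None, :]).astype(float)
    return Z, levels
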