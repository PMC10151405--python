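"""Genomic/metabolic relationship kernels, Mantel test, kernel PCA.

The relationship kernel of a centered, standardized feature matrix W
(lines × m) is K = W W' / m — the genomic relationship matrix G when W
holds SNP dosages, the metabolic relationship matrix M when it holds
metabolite abundances.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from ._util import rng_from
from .io import OmicsMatrix

logger = logging.getLogger(__name__)


@dataclass
class RelationshipKernel:
    values: np.ndarray
    line_ids: np.ndarray
    source: str = "genomic"  # "genomic" | "metabolic"
    n_features: int = 0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.line_ids = np.asarray(self.line_ids)
        n = len(self.line_ids)
        if self.values.shape != (n, n):
            raise ValueError("kernel must be square over line_ids")

    @property
    def n_lines(self) -> int:
        return self.values.shape[0]

    def to_csv(self, path) -> None:
        import pandas as pd
        pd.DataFrame(self.values, index=self.line_ids,
                     columns=self.line_ids).to_csv(path, index_label="line_id")

    @classmethod
    def from_csv(cls, path, source: str = "genomic") -> "RelationshipKernel":
        import pandas as pd
        df = pd.read_csv(path, index_col=0)
        return cls(df.to_numpy(dtype=float), df.index.to_numpy(), source=source)


def compute_kernel(W: OmicsMatrix, source: str | None = None) -> RelationshipKernel:
    """K = W W' / m from a standardized feature matrix; PSD by construction
    (eigenvalues are clipped at 0 if round-off produces tiny negatives)."""
    if not W.standardized:
        raise ValueError("compute_kernel expects a standardized matrix")
    if W.n_lines < 2:
        raise ValueError("kernel needs at least 2 lines")
    m = W.n_features
    K = (W.values @ W.values.T) / m
    K = 0.5 * (K + K.T)
    eig_min = np.linalg.eigvalsh(K)[0]
    if eig_min < -1e-8:
        logger.warning("clipping negative kernel eigenvalues (min %.3g)", eig_min)
        w, V = np.linalg.eigh(K)
        K = (V * np.clip(w, 0.0, None)) @ V.T
        K = 0.5 * (K + K.T)
    src = source or ("genomic" if W.kind == "marker" else "metabolic")
    return RelationshipKernel(K, W.line_ids, source=src, n_features=m)


def _offdiag_upper(K: np.ndarray) -> np.ndarray:
    iu = np.triu_indices_from(K, k=1)
    return K[iu]


def mantel_test(G: RelationshipKernel, M: RelationshipKernel,
                n_perm: int = 999, seed=None,
                alternative: str = "greater") -> tuple[float, float]:
    """Permutation Mantel test between two kernels over the same lines.

    r is the Pearson correlation of the strictly-upper-triangle entries;
    the permutation distribution applies the same random permutation to the
    rows and columns of M. One-sided (positive association) by default;
    p = (#{r_perm >= r_obs} + 1) / (n_perm + 1).
    """
    if G.n_lines != M.n_lines or not np.array_equal(G.line_ids, M.line_ids):
        raise ValueError("kernels must share line_ids in the same order")
    if n_perm < 99:
        warnings.warn("n_perm < 99 gives a very coarse p-value")
    rng = rng_from(seed)
    a = _offdiag_upper(G.values)
    r_obs = _mantel_r(a, M.values)
    n = G.n_lines
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        r_p = _mantel_r(a, M.values[np.ix_(perm, perm)])
        if alternative == "greater":
            count += r_p >= r_obs
        elif alternative == "two-sided":
            count += abs(r_p) >= abs(r_obs)
        else:
            raise ValueError(f"unknown alternative {alternative!r}")
    p = (count + 1) / (n_perm + 1)
    return float(r_obs), float(p)


def _mantel_r(a_upper: np.ndarray, M: np.ndarray) -> float:
    b = _offdiag_upper(M)
    a = a_upper - a_upper.mean()
    b = b - b.mean()
    denom = np.sqrt((a @ a) * (b @ b))
    return float(a @ b / denom) if denom > 0 else 0.0


def pca_scores(K: RelationshipKernel, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Principal-component scores from a relationship kernel.

    Double-centers the kernel, eigen-decomposes it, and returns scores
    (eigenvectors scaled by sqrt eigenvalue, descending) plus
    explained-variance fractions. Sign convention: the largest-magnitude
    loading of each component is positive.
    """
    n = K.n_lines
    if k > n:
        raise ValueError("k cannot exceed the number of lines")
    J = np.eye(n) - np.ones((n, n)) / n
    Kc = J @ K.values @ J
    w, V = np.linalg.eigh(Kc)
    order = np.argsort(w)[::-1]
    w, V = w[order], V[:, order]
    pos = np.clip(w, 0.0, None)
    rank = int((pos > 1e-10 * max(pos[0], 1.0)).sum())
    if k > rank:
        logger.warning("requested %d components but rank is %d; zero-filling", k, rank)
    scores = np.zeros((n, k))
    kk = min(k, rank)
    scores[:, :kk] = V[:, :kk] * np.sqrt(pos[:kk])
    for j in range(kk):
        i = np.argmax(np.abs(scores[:, j]))
        if scores[i, j] < 0:
            scores[:, j] *= -1
    total = pos.sum()
    frac = pos[:k] / total if total > 0 else np.zeros(k)
    return scores, frac
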