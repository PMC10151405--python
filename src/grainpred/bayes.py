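"""Gibbs samplers for the whole-genome / whole-metabolome regression models.

Models
------
- MOLS: ordinary least squares on metabolite abundances (only valid when
  lines outnumber features).
- Kernel BLUP: y = 1 mu + sum_k u_k + e with u_k ~ N(0, K_k sigma^2_k); one
  kernel gives GBLUP (genomic) or MBLUP (metabolic), two kernels give the
  multi-kernel GMBLUP. Sampled in the eigenbasis of each kernel, so the
  per-iteration cost is O(n) per kernel.
- BayesC: per-feature effects from a spike (prob pi) / normal slab mixture
  with a common effect variance.
- Bivariate GBLUP: two traits sharing the genomic kernel with inverse-Wishart
  priors on the 2x2 genetic and residual covariance matrices; missing trait
  records are data-augmented each iteration, which is what lets an auxiliary
  trait observed on test lines inform prediction of the masked target trait.

Priors follow the study conventions: flat prior on the mean; variance
components ~ scaled inverse chi-square with nu = 5 and scale chosen so the
prior mean is half the phenotypic variance; covariance matrices ~ inverse
Wishart with nu = 4 and scale chosen the same way. Heritabilities are
computed per retained sample as sigma^2_u / (total variance) and averaged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._util import VAR_FLOOR, rng_from, sample_scaled_inv_chi2, scale_from_prior_mean
from .io import OmicsMatrix
from .kernels import RelationshipKernel


@dataclass
class PriorSpec:
    """Variance priors: nu=5 scaled-inv-chi2 (univariate), nu=4 inv-Wishart
    (bivariate). scale=None derives the scale from half the phenotypic
    variance at fit time."""
    nu: float = 5.0
    scale: float | np.ndarray | None = None

    def univariate_scale(self, var_y: float) -> float:
        if self.scale is not None:
            return float(self.scale)
        return scale_from_prior_mean(0.5 * var_y, self.nu)


@dataclass
class McmcSpec:
    """Chain accounting: ``n_iter_post_burnin`` iterations after ``burnin``,
    keeping every ``thin``-th draw (defaults retain 3,000 samples)."""
    n_iter_post_burnin: int = 30_000
    burnin: int = 10_000
    thin: int = 10
    seed: int | None = None

    def __post_init__(self):
        if self.n_iter_post_burnin % self.thin:
            raise ValueError("thin must divide n_iter_post_burnin")

    @property
    def n_retained(self) -> int:
        return self.n_iter_post_burnin // self.thin


@dataclass
class PosteriorFit:
    model: str
    mu_mean: float | np.ndarray
    variance_components: dict = field(default_factory=dict)
    samples: dict = field(default_factory=dict, repr=False)
    random_effect_means: dict = field(default_factory=dict, repr=False)
    heritabilities: dict = field(default_factory=dict)
    inclusion_probs: np.ndarray | None = None
    line_ids: np.ndarray | None = None
    feature_ids: np.ndarray | None = None

    def to_summary(self) -> dict:
        mu = self.mu_mean
        return {
            "model": self.model,
            "mu": mu.tolist() if isinstance(mu, np.ndarray) else float(mu),
            "variance_components": {k: (np.asarray(v).tolist() if np.ndim(v) else float(v))
                                    for k, v in self.variance_components.items()},
            "heritabilities": {k: float(v) for k, v in self.heritabilities.items()},
        }


def _as_values(W) -> tuple[np.ndarray, np.ndarray | None, np.ndarray | None]:
    if isinstance(W, OmicsMatrix):
        if not W.standardized:
            raise ValueError("feature matrix must be standardized")
        return W.values, W.line_ids, W.feature_ids
    return np.asarray(W, dtype=float), None, None


def fit_mols(y, W) -> PosteriorFit:
    """Ordinary least squares of phenotype on (standardized) features."""
    Wv, line_ids, feature_ids = _as_values(W)
    y = np.asarray(y, dtype=float)
    n, m = Wv.shape
    if n <= m + 1:
        raise ValueError(
            f"MOLS needs n > m+1 (got n={n}, m={m}); use BayesC or kernel BLUP")
    X = np.column_stack([np.ones(n), Wv])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    fit = PosteriorFit(model="mols", mu_mean=float(coef[0]),
                       line_ids=line_ids, feature_ids=feature_ids)
    fit.random_effect_means["a"] = coef[1:]
    return fit


def _kernel_eigen(K: RelationshipKernel):
    w, V = np.linalg.eigh(K.values)
    if w[0] < -1e-6:
        raise ValueError(f"kernel {K.source} is not PSD (min eig {w[0]:.3g})")
    keep = w > 1e-10 * max(w[-1], 1.0)
    return V[:, keep], w[keep]


def fit_kernel_blup(y, kernels, prior: PriorSpec | None = None,
                    mcmc: McmcSpec | None = None,
                    fixed_variances: dict | None = None,
                    missing_mask=None) -> PosteriorFit:
    """Single- or two-kernel BLUP via Gibbs sampling in the kernel eigenbasis.

    ``kernels`` is one RelationshipKernel or a list of up to two (GMBLUP).
    ``missing_mask`` marks lines whose phenotype is unobserved; those records
    are data-augmented so the whole-population kernel can be used for
    prediction. ``fixed_variances`` (e.g. {"u_genomic": 1.0, "e": 1.0}) skips
    the variance updates — used to check the sampler against closed-form BLUP.
    """
    if isinstance(kernels, RelationshipKernel):
        kernels = [kernels]
    if not 1 <= len(kernels) <= 2:
        raise ValueError("one or two kernels supported")
    prior = prior or PriorSpec()
    mcmc = mcmc or McmcSpec()
    rng = rng_from(mcmc.seed)

    y = np.asarray(y, dtype=float).copy()
    n = len(y)
    miss = (np.zeros(n, dtype=bool) if missing_mask is None
            else np.asarray(missing_mask, dtype=bool))
    obs = ~miss
    if obs.sum() < 3:
        raise ValueError("too few observed phenotypes")
    var_y = float(np.var(y[obs]))
    s_prior = prior.univariate_scale(var_y)

    names = []
    eigs = []
    for K in kernels:
        if K.n_lines != n:
            raise ValueError("kernel size does not match y")
        names.append(f"u_{K.source}")
        eigs.append(_kernel_eigen(K))

    # state
    y[miss] = y[obs].mean()
    mu = float(y.mean())
    alphas = [np.zeros(len(d)) for _, d in eigs]
    us = [np.zeros(n) for _ in eigs]
    sig2 = {nm: 0.5 * var_y / len(kernels) for nm in names}
    sig2["e"] = 0.5 * var_y
    if fixed_variances:
        sig2.update(fixed_variances)

    n_keep = mcmc.n_retained
    keep_mu = np.empty(n_keep)
    keep_sig = {nm: np.empty(n_keep) for nm in list(names) + ["e"]}
    keep_h2 = {nm: np.empty(n_keep) for nm in names}
    sum_u = [np.zeros(n) for _ in eigs]
    kept = 0

    total = mcmc.burnin + mcmc.n_iter_post_burnin
    for it in range(total):
        if miss.any():
            pred_miss = mu + sum(u[miss] for u in us)
            y[miss] = pred_miss + rng.normal(size=miss.sum()) * np.sqrt(sig2["e"])
        # random effects, one kernel at a time in its eigenbasis
        for k, (nm, (Q, d)) in enumerate(zip(names, eigs)):
            r_k = y - mu - sum(us[j] for j in range(len(us)) if j != k)
            z = Q.T @ r_k
            v = 1.0 / (1.0 / sig2["e"] + 1.0 / (d * sig2[nm]))
            mean = v * z / sig2["e"]
            alphas[k] = mean + rng.normal(size=len(d)) * np.sqrt(v)
            us[k] = Q @ alphas[k]
        # mean (flat prior)
        resid_mu = y - sum(us)
        mu = float(resid_mu.mean() + rng.normal() * np.sqrt(sig2["e"] / n))
        # variances
        if not fixed_variances:
            for k, nm in enumerate(names):
                d = eigs[k][1]
                ss = float(np.sum(alphas[k] ** 2 / d))
                q = len(d)
                sig2[nm] = sample_scaled_inv_chi2(
                    rng, prior.nu + q, (prior.nu * s_prior + ss) / (prior.nu + q))
            e = y - mu - sum(us)
            sig2["e"] = sample_scaled_inv_chi2(
                rng, prior.nu + n, (prior.nu * s_prior + float(e @ e)) / (prior.nu + n))
        # record
        post = it - mcmc.burnin
        if post >= 0 and (post + 1) % mcmc.thin == 0:
            keep_mu[kept] = mu
            tot_var = sum(sig2[nm] for nm in names) + sig2["e"]
            for k, nm in enumerate(names):
                keep_sig[nm][kept] = sig2[nm]
                keep_h2[nm][kept] = sig2[nm] / tot_var
                sum_u[k] += us[k]
            keep_sig["e"][kept] = sig2["e"]
            kept += 1

    model = {1: "kernel_blup", 2: "multi_kernel"}[len(kernels)]
    fit = PosteriorFit(model=model, mu_mean=float(keep_mu.mean()),
                       line_ids=kernels[0].line_ids)
    for nm in names:
        fit.variance_components[nm] = float(keep_sig[nm].mean())
        fit.heritabilities[f"h2_{nm[2:]}"] = float(keep_h2[nm].mean())
    fit.variance_components["e"] = float(keep_sig["e"].mean())
    fit.samples = {**{nm: keep_sig[nm] for nm in list(names) + ["e"]},
                   **{f"h2_{nm[2:]}": keep_h2[nm] for nm in names},
                   "mu": keep_mu}
    for k, nm in enumerate(names):
        fit.random_effect_means[nm] = sum_u[k] / n_keep
    return fit


def fit_bayesc(y, W, pi: float = 0.99, prior: PriorSpec | None = None,
               mcmc: McmcSpec | None = None) -> PosteriorFit:
    """BayesC: spike-and-slab feature effects with a common slab variance.

    Each effect is zero with probability ``pi`` (fixed, not sampled) and
    N(0, sigma^2_a) otherwise. The slab-variance prior scale is chosen so the
    implied total signal variance (1-pi) * m * E[sigma^2_a] has prior mean
    equal to half the phenotypic variance.
    """
    if not 0 < pi < 1:
        raise ValueError("pi must lie in (0, 1)")
    Wv, line_ids, feature_ids = _as_values(W)
    y = np.asarray(y, dtype=float)
    n, m = Wv.shape
    prior = prior or PriorSpec()
    mcmc = mcmc or McmcSpec()
    rng = rng_from(mcmc.seed)

    var_y = float(np.var(y))
    s_e = prior.univariate_scale(var_y)
    msx = float(np.sum(Wv.var(axis=0)))  # = m for standardized W
    s_a = scale_from_prior_mean(0.5 * var_y / ((1.0 - pi) * msx), prior.nu)

    wtw = np.einsum("ij,ij->j", Wv, Wv)
    a = np.zeros(m)
    delta = np.zeros(m, dtype=bool)
    mu = float(y.mean())
    sig2_a = 0.5 * var_y / ((1.0 - pi) * msx)
    sig2_e = 0.5 * var_y
    resid = y - mu

    n_keep = mcmc.n_retained
    keep = {"mu": np.empty(n_keep), "a2": np.empty(n_keep), "e": np.empty(n_keep),
            "h2": np.empty(n_keep)}
    sum_a = np.zeros(m)
    sum_delta = np.zeros(m)
    kept = 0
    log_prior_odds = np.log1p(-pi) - np.log(pi)

    total = mcmc.burnin + mcmc.n_iter_post_burnin
    for it in range(total):
        for j in rng.permutation(m):
            w = Wv[:, j]
            if delta[j]:
                resid += w * a[j]
            rhs = float(w @ resid) / sig2_e
            C = wtw[j] / sig2_e + 1.0 / sig2_a
            log_odds = (log_prior_odds - 0.5 * np.log(sig2_a * C)
                        + 0.5 * rhs * rhs / C)
            p_incl = 1.0 / (1.0 + np.exp(-log_odds)) if log_odds < 35 else 1.0
            if rng.random() < p_incl:
                a[j] = rhs / C + rng.normal() * np.sqrt(1.0 / C)
                delta[j] = True
                resid -= w * a[j]
            else:
                a[j] = 0.0
                delta[j] = False
        # mean
        r_mu = resid + mu
        mu_new = float(r_mu.mean() + rng.normal() * np.sqrt(sig2_e / n))
        resid += mu - mu_new
        mu = mu_new
        # variances
        q = int(delta.sum())
        ss_a = float(a @ a)
        sig2_a = sample_scaled_inv_chi2(
            rng, prior.nu + q, (prior.nu * s_a + ss_a) / (prior.nu + q))
        sig2_e = sample_scaled_inv_chi2(
            rng, prior.nu + n, (prior.nu * s_e + float(resid @ resid)) / (prior.nu + n))
        post = it - mcmc.burnin
        if post >= 0 and (post + 1) % mcmc.thin == 0:
            keep["mu"][kept] = mu
            keep["a2"][kept] = sig2_a
            keep["e"][kept] = sig2_e
            sig_g = ss_a  # genic variance of included effects on standardized W
            keep["h2"][kept] = sig_g / (sig_g + sig2_e)
            sum_a += a
            sum_delta += delta
            kept += 1

    fit = PosteriorFit(model="bayesc", mu_mean=float(keep["mu"].mean()),
                       line_ids=line_ids, feature_ids=feature_ids)
    fit.variance_components = {"a": float(keep["a2"].mean()),
                               "e": float(keep["e"].mean())}
    fit.heritabilities = {"h2_features": float(keep["h2"].mean())}
    fit.samples = keep
    fit.random_effect_means["a"] = sum_a / n_keep
    fit.inclusion_probs = sum_delta / n_keep
    return fit


def _chol2(c11, c12, c22):
    """Cholesky factors of (possibly vectorized) 2x2 SPD matrices."""
    l11 = np.sqrt(c11)
    l21 = c12 / l11
    l22 = np.sqrt(np.maximum(c22 - l21 * l21, VAR_FLOOR))
    return l11, l21, l22


def _inv2(a, b, c):
    """Inverse of (vectorized) symmetric 2x2 [[a, b], [b, c]]."""
    det = np.maximum(a * c - b * b, VAR_FLOOR)
    return c / det, -b / det, a / det


def _sample_invwishart2(rng: np.random.Generator, df: float,
                        S: np.ndarray) -> np.ndarray:
    """IW(df, S) draw for p=2 via the Bartlett decomposition.

    If X ~ Wishart(df, S^-1) then X^-1 ~ IW(df, S). Specialized to 2x2 to
    keep the bivariate sampler's per-iteration cost flat.
    """
    i11, i12, i22 = _inv2(S[0, 0], S[0, 1], S[1, 1])
    # cholesky of S^-1
    l11 = np.sqrt(i11)
    l21 = i12 / l11
    l22 = np.sqrt(max(i22 - l21 * l21, VAR_FLOOR))
    # Bartlett factor A (lower triangular)
    a11 = np.sqrt(rng.chisquare(df))
    a22 = np.sqrt(rng.chisquare(df - 1))
    a21 = rng.standard_normal()
    # T = L @ A, X = T T'
    t11 = l11 * a11
    t21 = l21 * a11 + l22 * a21
    t22 = l22 * a22
    x11 = t11 * t11
    x12 = t11 * t21
    x22 = t21 * t21 + t22 * t22
    w11, w12, w22 = _inv2(x11, x12, x22)
    return np.array([[w11, w12], [w12, w22]])


def fit_bivariate_gblup(Y, G: RelationshipKernel, prior: PriorSpec | None = None,
                        mcmc: McmcSpec | None = None) -> PosteriorFit:
    """Bivariate GBLUP with inverse-Wishart covariance priors.

    ``Y`` is an n × 2 array (trait, auxiliary trait/metabolite) where np.nan
    marks missing records; missing entries are sampled each iteration from
    their conditional given the observed co-trait, the current genetic values
    and the residual covariance. Genetic values are sampled in the eigenbasis
    of G (rows decouple), so each sweep is O(n).
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim != 2 or Y.shape[1] != 2:
        raise ValueError("Y must be n x 2")
    n = Y.shape[0]
    if G.n_lines != n:
        raise ValueError("kernel size does not match Y")
    prior = prior or PriorSpec(nu=4.0)
    mcmc = mcmc or McmcSpec()
    rng = rng_from(mcmc.seed)

    miss = np.isnan(Y)
    if (~miss).sum(axis=0).min() == 0:
        raise ValueError("each trait needs at least one observed record")
    var_obs = np.array([np.nanvar(Y[:, t]) for t in range(2)])
    p = 2
    mult = prior.nu - p - 1  # = 1 at nu=4: prior mean S/(nu-p-1) = S
    if prior.scale is not None:
        S_prior = np.asarray(prior.scale, dtype=float)
    else:
        S_prior = 0.5 * np.diag(var_obs) * mult
    if mult <= 0:
        raise ValueError("inverse-Wishart nu must exceed p+1 for a prior mean")

    Q, d = _kernel_eigen(G)
    q = len(d)

    Yc = Y.copy()
    col_means = np.nanmean(Y, axis=0)
    for t in range(2):
        Yc[miss[:, t], t] = col_means[t]
    mu = col_means.copy()
    U = np.zeros((n, 2))
    Sg = 0.5 * np.diag(var_obs)
    Se = 0.5 * np.diag(var_obs)

    n_keep = mcmc.n_retained
    keep_Sg = np.empty((n_keep, 2, 2))
    keep_Se = np.empty((n_keep, 2, 2))
    keep_mu = np.empty((n_keep, 2))
    keep_rg = np.empty(n_keep)
    sum_u = np.zeros((n, 2))
    sum_pred = np.zeros((n, 2))
    kept = 0

    m0 = miss[:, 0] & ~miss[:, 1]
    m1 = miss[:, 1] & ~miss[:, 0]
    mb = miss[:, 0] & miss[:, 1]

    total = mcmc.burnin + mcmc.n_iter_post_burnin
    for it in range(total):
        # 1. augment missing records
        mean_full = mu + U
        if m0.any():
            b = Se[0, 1] / Se[1, 1]
            cv = max(Se[0, 0] - Se[0, 1] ** 2 / Se[1, 1], VAR_FLOOR)
            mu_c = mean_full[m0, 0] + b * (Yc[m0, 1] - mean_full[m0, 1])
            Yc[m0, 0] = mu_c + rng.normal(size=m0.sum()) * np.sqrt(cv)
        if m1.any():
            b = Se[0, 1] / Se[0, 0]
            cv = max(Se[1, 1] - Se[0, 1] ** 2 / Se[0, 0], VAR_FLOOR)
            mu_c = mean_full[m1, 1] + b * (Yc[m1, 0] - mean_full[m1, 0])
            Yc[m1, 1] = mu_c + rng.normal(size=m1.sum()) * np.sqrt(cv)
        if mb.any():
            l11, l21, l22 = _chol2(Se[0, 0], Se[0, 1], Se[1, 1])
            z = rng.normal(size=(mb.sum(), 2))
            Yc[mb, 0] = mean_full[mb, 0] + l11 * z[:, 0]
            Yc[mb, 1] = mean_full[mb, 1] + l21 * z[:, 0] + l22 * z[:, 1]

        # 2. genetic values in the eigenbasis
        Yt = Q.T @ (Yc - mu)
        ei11, ei12, ei22 = _inv2(Se[0, 0], Se[0, 1], Se[1, 1])
        gi11, gi12, gi22 = _inv2(Sg[0, 0], Sg[0, 1], Sg[1, 1])
        p11 = ei11 + gi11 / d
        p12 = ei12 + gi12 / d
        p22 = ei22 + gi22 / d
        c11, c12, c22 = _inv2(p11, p12, p22)
        rhs0 = ei11 * Yt[:, 0] + ei12 * Yt[:, 1]
        rhs1 = ei12 * Yt[:, 0] + ei22 * Yt[:, 1]
        mean0 = c11 * rhs0 + c12 * rhs1
        mean1 = c12 * rhs0 + c22 * rhs1
        l11, l21, l22 = _chol2(c11, c12, c22)
        z = rng.normal(size=(q, 2))
        Ut = np.column_stack([mean0 + l11 * z[:, 0],
                              mean1 + l21 * z[:, 0] + l22 * z[:, 1]])
        U = Q @ Ut

        # 3. mean (flat prior)
        r = Yc - U
        l11, l21, l22 = _chol2(Se[0, 0] / n, Se[0, 1] / n, Se[1, 1] / n)
        z = rng.normal(size=2)
        mu = r.mean(axis=0) + np.array([l11 * z[0], l21 * z[0] + l22 * z[1]])

        # 4. covariance matrices
        Su = np.einsum("ij,ik,i->jk", Ut, Ut, 1.0 / d)
        Sg = _sample_invwishart2(rng, prior.nu + q, S_prior + Su)
        E = Yc - mu - U
        Se = _sample_invwishart2(rng, prior.nu + n, S_prior + E.T @ E)

        post = it - mcmc.burnin
        if post >= 0 and (post + 1) % mcmc.thin == 0:
            keep_Sg[kept] = Sg
            keep_Se[kept] = Se
            keep_mu[kept] = mu
            keep_rg[kept] = Sg[0, 1] / np.sqrt(Sg[0, 0] * Sg[1, 1])
            sum_u += U
            sum_pred += mu + U
            kept += 1

    Sg_m, Se_m = keep_Sg.mean(axis=0), keep_Se.mean(axis=0)
    fit = PosteriorFit(model="bivariate", mu_mean=keep_mu.mean(axis=0),
                       line_ids=G.line_ids)
    fit.variance_components = {"Sigma_g": Sg_m, "Sigma_e": Se_m}
    fit.heritabilities = {
        f"h2_trait{t + 1}": float(np.mean(
            keep_Sg[:, t, t] / (keep_Sg[:, t, t] + keep_Se[:, t, t])))
        for t in range(2)}
    fit.samples = {"Sigma_g": keep_Sg, "Sigma_e": keep_Se, "mu": keep_mu,
                   "genetic_correlation": keep_rg}
    fit.variance_components["genetic_correlation"] = float(keep_rg.mean())
    fit.random_effect_means["u"] = sum_u / n_keep
    fit.random_effect_means["prediction"] = sum_pred / n_keep
    return fit


def predict(fit: PosteriorFit, target_lines=None, W_target=None) -> np.ndarray:
    """Predicted phenotypes for target lines.

    Kernel models: posterior-mean genetic value of each target line plus the
    posterior-mean intercept (the kernel must have been built over the whole
    population before masking). Feature models: mu + W_target @ a_hat.
    """
    if fit.model in ("kernel_blup", "multi_kernel", "bivariate"):
        if target_lines is None:
            idx = np.arange(len(fit.line_ids))
        else:
            lookup = {l: i for i, l in enumerate(fit.line_ids)}
            try:
                idx = np.array([lookup[l] for l in np.asarray(target_lines)])
            except KeyError as e:
                raise KeyError(f"unknown line {e.args[0]!r}") from None
        if fit.model == "bivariate":
            return fit.random_effect_means["prediction"][idx, 0]
        u = sum(v for k, v in fit.random_effect_means.items() if k.startswith("u_"))
        return fit.mu_mean + u[idx]
    if W_target is None:
        raise ValueError("feature models need W_target")
    Wv = W_target.values if isinstance(W_target, OmicsMatrix) else np.asarray(W_target)
    return fit.mu_mean + Wv @ fit.random_effect_means["a"]


def heritability(fit: PosteriorFit) -> dict:
    """Posterior-mean heritabilities (computed per retained sample)."""
    return dict(fit.heritabilities)
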