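"""Cross-validation engines and model-comparison statistics.

All designs use repeated random subsampling: 80/20 train/test splits,
repeated 25 times (classification, multi-trait) or 100 times (prediction),
with the repeat-r split a pure function of (master seed, r) so paired model
comparisons share identical splits. Kernels are built once from all lines
(an unsupervised step); only phenotypes are masked inside a split.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .bayes import McmcSpec, PriorSpec, fit_bayesc, fit_bivariate_gblup, \
    fit_kernel_blup, fit_mols, predict
from .io import OmicsMatrix
from .kernels import RelationshipKernel
from .metrics import accuracy, auc, confusion_counts, f1, pearson
from .ml import ModelSpec, decision_scores, tune_fit

logger = logging.getLogger(__name__)

DEFAULT_REPEATS = {"classification": 25, "prediction": 100, "multitrait": 25,
                   "subset": 20}


@dataclass
class CVDesign:
    kind: str = "prediction"
    train_frac: float = 0.8
    n_repeats: int = 25
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.train_frac < 1:
            raise ValueError("train_frac must lie in (0, 1)")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")

    def split(self, n: int, repeat: int) -> tuple[np.ndarray, np.ndarray]:
        """Deterministic 80/20 split for repeat r: depends only on (seed, r)."""
        rng = np.random.default_rng(np.random.SeedSequence([self.seed, repeat]))
        perm = rng.permutation(n)
        n_train = int(round(self.train_frac * n))
        return np.sort(perm[:n_train]), np.sort(perm[n_train:])


@dataclass
class CVResult:
    model: str
    metric_name: str
    per_repeat: np.ndarray
    trait: str = ""
    condition: str = ""
    design: str = ""

    @property
    def mean(self) -> float:
        return float(np.nanmean(self.per_repeat))

    @property
    def sd(self) -> float:
        return float(np.nanstd(self.per_repeat, ddof=1))

    @property
    def n_missing(self) -> int:
        return int(np.isnan(self.per_repeat).sum())


# ---------------------------------------------------------------- classification

def run_classification_cv(metab_control: OmicsMatrix, metab_hnt: OmicsMatrix,
                          models: dict[str, ModelSpec],
                          design: CVDesign) -> dict[str, dict[str, CVResult]]:
    """Classify growing condition (control=0 vs HNT=1) from metabolites.

    Per repeat: an 80/20 split drawn separately per condition, combined
    training set, inner-CV tuning per model, and accuracy/F1/AUC on the
    combined held-out set.
    """
    for mat, name in ((metab_control, "control"), (metab_hnt, "HNT")):
        if mat.n_lines < 5:
            raise ValueError(f"{name} condition has fewer than 5 lines")
    Xc, Xh = metab_control.values, metab_hnt.values
    out = {name: {m: [] for m in ("accuracy", "f1", "auc")} for name in models}
    for r in range(design.n_repeats):
        tr_c, te_c = design.split(len(Xc), r)
        sub = CVDesign(design.kind, design.train_frac, design.n_repeats,
                       seed=design.seed + 1)
        tr_h, te_h = sub.split(len(Xh), r)
        X_tr = np.vstack([Xc[tr_c], Xh[tr_h]])
        y_tr = np.r_[np.zeros(len(tr_c)), np.ones(len(tr_h))]
        X_te = np.vstack([Xc[te_c], Xh[te_h]])
        y_te = np.r_[np.zeros(len(te_c)), np.ones(len(te_h))]
        for name, spec in models.items():
            est, _ = tune_fit(spec, X_tr, y_tr, seed=design.seed * 1000 + r)
            pred = est.predict(X_te)
            scores = decision_scores(est, X_te)
            c = confusion_counts(y_te, pred, positive=1)
            out[name]["accuracy"].append(accuracy(c))
            out[name]["f1"].append(f1(c))
            out[name]["auc"].append(auc(scores, y_te, positive=1))
    return {name: {m: CVResult(model=name, metric_name=m,
                               per_repeat=np.asarray(v), design="classification")
                   for m, v in metrics.items()}
            for name, metrics in out.items()}


def run_subset_experiment(metab_control: OmicsMatrix, metab_hnt: OmicsMatrix,
                          models: dict[str, ModelSpec], design: CVDesign,
                          sizes=(10, 20, 30, 40, 50, 60),
                          n_resample: int = 20) -> pd.DataFrame:
    """Classification from random metabolite subsets of increasing size.

    Each size is redrawn ``n_resample`` times; each subset runs the full
    classification CV. Returns a tidy frame with per-(size, resample, model)
    mean accuracy, from which the size trend and its spread are read.
    """
    p = metab_control.n_features
    if max(sizes) > p:
        raise ValueError("subset size exceeds the number of metabolites")
    rows = []
    for size in sizes:
        for s in range(n_resample):
            rng = np.random.default_rng(
                np.random.SeedSequence([design.seed, int(size), s]))
            cols = (np.sort(rng.choice(p, size=size, replace=False))
                    if size < p else np.arange(p))
            sub_c = OmicsMatrix(metab_control.values[:, cols],
                                metab_control.line_ids,
                                metab_control.feature_ids[cols], "metabolite",
                                metab_control.standardized)
            sub_h = OmicsMatrix(metab_hnt.values[:, cols], metab_hnt.line_ids,
                                metab_hnt.feature_ids[cols], "metabolite",
                                metab_hnt.standardized)
            res = run_classification_cv(sub_c, sub_h, models, design)
            for name in models:
                rows.append({"size": size, "resample": s, "model": name,
                             "accuracy": res[name]["accuracy"].mean,
                             "f1": res[name]["f1"].mean,
                             "auc": res[name]["auc"].mean})
    return pd.DataFrame(rows)


# ------------------------------------------------------------------- prediction

BAYES_MODELS = ("mols", "bayesc", "mblup", "gblup", "gmblup")


@dataclass
class PredictorSet:
    """Inputs a prediction CV can draw on: standardized feature matrices and
    whole-population kernels, all aligned to one line order."""
    metabolites: OmicsMatrix | None = None
    markers: OmicsMatrix | None = None
    M: RelationshipKernel | None = None
    G: RelationshipKernel | None = None
    mcmc: McmcSpec = field(default_factory=McmcSpec)


def _fit_predict_one(model, pred: PredictorSet, y: np.ndarray,
                     train: np.ndarray, test: np.ndarray, seed: int) -> np.ndarray:
    """Fit one model with test phenotypes masked; return test predictions."""
    n = len(y)
    mask = np.zeros(n, dtype=bool)
    mask[test] = True
    mcmc = McmcSpec(pred.mcmc.n_iter_post_burnin, pred.mcmc.burnin,
                    pred.mcmc.thin, seed=seed)
    if isinstance(model, ModelSpec):
        W = pred.metabolites if pred.metabolites is not None else pred.markers
        est, _ = tune_fit(model, W.values[train], y[train], seed=seed)
        return np.asarray(est.predict(W.values[test]), dtype=float)
    if model == "mols":
        fit = fit_mols(y[train], pred.metabolites.values[train])
        return predict(fit, W_target=pred.metabolites.values[test])
    if model == "bayesc":
        fit = fit_bayesc(y[train], pred.metabolites.values[train], mcmc=mcmc)
        return predict(fit, W_target=pred.metabolites.values[test])
    if model in ("mblup", "gblup", "gmblup"):
        kernels = {"mblup": [pred.M], "gblup": [pred.G],
                   "gmblup": [pred.M, pred.G]}[model]
        fit = fit_kernel_blup(y, kernels, mcmc=mcmc, missing_mask=mask)
        line_ids = kernels[0].line_ids
        return predict(fit, target_lines=line_ids[test])
    raise ValueError(f"unknown model {model!r}")


def run_prediction_cv(y, models, pred: PredictorSet,
                      design: CVDesign) -> dict[str, CVResult]:
    """Repeated 80/20 prediction CV within one condition.

    ``models`` maps names to either a Bayes-model string ("mols", "bayesc",
    "mblup", "gblup", "gmblup") or an ml ModelSpec regressor. The metric is
    the Pearson correlation between predicted and observed test phenotypes.
    Kernel models use the whole-population kernel with test phenotypes
    masked (data augmentation); feature models fit on training rows only.
    """
    y = np.asarray(y, dtype=float)
    out = {name: [] for name in models}
    for r in range(design.n_repeats):
        train, test = design.split(len(y), r)
        if len(test) < 10:
            logger.warning("repeat %d has only %d test lines", r, len(test))
        for name, model in models.items():
            yhat = _fit_predict_one(model, pred, y, train, test,
                                    seed=design.seed * 1000 + r)
            out[name].append(pearson(y[test], yhat))
    return {name: CVResult(model=name, metric_name="pearson",
                           per_repeat=np.asarray(v), design="prediction")
            for name, v in out.items()}


def run_cross_condition(y_target, metab_source: OmicsMatrix,
                        metab_target: OmicsMatrix, model, pred_mcmc: McmcSpec,
                        design: CVDesign) -> dict[str, CVResult]:
    """Transferability of the metabolic signal across stress conditions.

    Per repeat the same split is used twice: effects are estimated on
    training lines from the source condition's metabolites and applied to
    the test lines' source metabolites ("transfer"), and compared with the
    within-condition run that uses the target condition's metabolites for
    both ("within"). Both predict the target condition's phenotypes.
    """
    if not np.array_equal(metab_source.line_ids, metab_target.line_ids):
        raise ValueError("conditions must cover the same lines")
    results = {}
    for label, mat in (("within", metab_target), ("transfer", metab_source)):
        M = None
        if model in ("mblup", "gmblup"):
            from .kernels import compute_kernel
            M = compute_kernel(mat, source="metabolic")
        pset = PredictorSet(metabolites=mat, M=M, mcmc=pred_mcmc)
        results[label] = run_prediction_cv(
            y_target, {model: model}, pset, design)[model]
        results[label].condition = label
    return results


# ------------------------------------------------------------------ multi-trait

@dataclass
class MultitraitResult:
    bivariate: CVResult
    univariate: CVResult
    gain: float
    win_fraction: float
    t_pvalue: float
    wilcoxon_pvalue: float


def run_multitrait(y_trait, aux, G: RelationshipKernel, scenario: int,
                   design: CVDesign, mcmc: McmcSpec | None = None,
                   prior: PriorSpec | None = None) -> MultitraitResult:
    """Bivariate (trait + auxiliary metabolite) vs univariate GBLUP.

    Scenario 1 masks both the trait and the auxiliary for test lines;
    Scenario 2 keeps the auxiliary observed on every line, so the bivariate
    sampler's data augmentation can borrow information for the masked trait.
    Paired one-sided t and Wilcoxon signed-rank tests ask whether the
    bivariate predictive correlation exceeds the univariate one.
    """
    y = np.asarray(y_trait, dtype=float)
    aux = np.asarray(aux, dtype=float)
    if np.std(aux) == 0:
        raise ValueError("auxiliary column is constant")
    if scenario not in (1, 2):
        raise ValueError("scenario must be 1 or 2")
    mcmc = mcmc or McmcSpec()
    prior = prior or PriorSpec(nu=4.0)
    biv, uni = [], []
    n = len(y)
    for r in range(design.n_repeats):
        train, test = design.split(n, r)
        mask = np.zeros(n, dtype=bool)
        mask[test] = True
        Y = np.column_stack([y, aux]).astype(float)
        Y[mask, 0] = np.nan
        if scenario == 1:
            Y[mask, 1] = np.nan
        m_biv = McmcSpec(mcmc.n_iter_post_burnin, mcmc.burnin, mcmc.thin,
                         seed=design.seed * 1000 + r)
        fit_b = fit_bivariate_gblup(Y, G, prior=prior, mcmc=m_biv)
        yhat_b = predict(fit_b, target_lines=G.line_ids[test])
        m_uni = McmcSpec(mcmc.n_iter_post_burnin, mcmc.burnin, mcmc.thin,
                         seed=design.seed * 1000 + r + 500_000)
        fit_u = fit_kernel_blup(y, [G], mcmc=m_uni, missing_mask=mask)
        yhat_u = predict(fit_u, target_lines=G.line_ids[test])
        biv.append(pearson(y[test], yhat_b))
        uni.append(pearson(y[test], yhat_u))
    biv, uni = np.asarray(biv), np.asarray(uni)
    res_b = CVResult("bivariate_gblup", "pearson", biv,
                     design=f"multitrait_s{scenario}")
    res_u = CVResult("gblup", "pearson", uni, design=f"multitrait_s{scenario}")
    t_p = stats.ttest_rel(biv, uni, alternative="greater").pvalue
    try:
        w_p = stats.wilcoxon(biv, uni, alternative="greater",
                             zero_method="wilcox").pvalue
    except ValueError:  # all differences zero
        w_p = 1.0
    return MultitraitResult(bivariate=res_b, univariate=res_u,
                            gain=res_b.mean - res_u.mean,
                            win_fraction=float(np.mean(biv > uni)),
                            t_pvalue=float(t_p), wilcoxon_pvalue=float(w_p))


# ------------------------------------------------------------------------ LOSO

def run_loso_cv(y, model, pred: PredictorSet, subpop_labels,
                seed: int = 0) -> pd.DataFrame:
    """Leave-one-subpopulation-out CV: predict each subpopulation from the
    rest. Subpopulations with fewer than 3 lines are skipped with a warning."""
    y = np.asarray(y, dtype=float)
    labels = np.asarray(subpop_labels)
    pops = np.unique(labels)
    if len(pops) < 2:
        raise ValueError("need at least 2 subpopulations")
    rows = []
    for pop in pops:
        test = np.where(labels == pop)[0]
        if len(test) < 3:
            logger.warning("skipping subpopulation %s (size %d)", pop, len(test))
            continue
        train = np.where(labels != pop)[0]
        yhat = _fit_predict_one(model, pred, y, train, test, seed=seed)
        rows.append({"subpop": pop, "n": len(test),
                     "pearson": pearson(y[test], yhat)})
    return pd.DataFrame(rows)


# ------------------------------------------------------------- comparison stats

def pairwise_win_fraction(a: CVResult, b: CVResult) -> dict:
    """Fraction of paired repeats where a strictly beats b; ties separate."""
    if len(a.per_repeat) != len(b.per_repeat):
        raise ValueError("results are not paired (different repeat counts)")
    av, bv = a.per_repeat, b.per_repeat
    ok = ~(np.isnan(av) | np.isnan(bv))
    wins = float(np.mean(av[ok] > bv[ok]))
    ties = float(np.mean(av[ok] == bv[ok]))
    return {"win_fraction": wins, "tie_fraction": ties,
            "n_pairs": int(ok.sum()),
            "table": pd.DataFrame({"repeat": np.where(ok)[0],
                                   "a": av[ok], "b": bv[ok]})}


def benjamini_hochberg(pvals) -> np.ndarray:
    """BH-adjusted p-values (step-up)."""
    p = np.asarray(pvals, dtype=float)
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.clip(ranked, 0, 1)
    return out


def correlation_report(metab: OmicsMatrix, traits: pd.DataFrame,
                       mm_threshold: float = 0.9,
                       mt_threshold: float = 0.3) -> dict[str, pd.DataFrame]:
    """Flag strongly correlated metabolite pairs (|r| > 0.9) and
    metabolite-trait associations (|r| > 0.3)."""
    V = metab.values
    R = np.corrcoef(V, rowvar=False)
    iu = np.triu_indices_from(R, k=1)
    mm = pd.DataFrame({
        "feature_a": metab.feature_ids[iu[0]],
        "feature_b": metab.feature_ids[iu[1]],
        "r": R[iu]})
    mm = mm[mm["r"].abs() > mm_threshold].reset_index(drop=True)
    mm["direction"] = np.where(mm["r"] > 0, "positive", "negative")

    rows = []
    for trait in traits.columns:
        tv = traits[trait].to_numpy(dtype=float)
        for j, fid in enumerate(metab.feature_ids):
            r = pearson(V[:, j], tv)
            if np.isfinite(r) and abs(r) > mt_threshold:
                rows.append({"feature": fid, "trait": trait, "r": r,
                             "direction": "positive" if r > 0 else "negative"})
    mt = pd.DataFrame(rows, columns=["feature", "trait", "r", "direction"])
    return {"metabolite_pairs": mm, "metabolite_trait": mt}
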