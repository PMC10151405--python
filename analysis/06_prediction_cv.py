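#!/usr/bin/env python
"""Metabolic, genomic and multi-omic prediction of grain-size BLUEs.

Repeated random-subsampling CV within each condition: MOLS, BayesC, MBLUP
(metabolic kernel), GBLUP (genomic kernel), GMBLUP (both kernels) and the ML
regressors, scored by the Pearson correlation between predicted and observed
test BLUEs. Also writes pairwise win fractions (share of paired repeats one
model strictly beats another) and the per-model heritability estimates.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from grainpred.bayes import McmcSpec, fit_kernel_blup
from grainpred.evaluation import (CVDesign, PredictorSet,
                                  pairwise_win_fraction, run_prediction_cv)
from grainpred.io import read_genotypes, read_omics, read_phenotypes
from grainpred.kernels import compute_kernel
from grainpred.ml import ModelSpec
from grainpred.preprocess import blues_vector, center_standardize

ROOT = Path(__file__).resolve().parents[1]


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--repeats", type=int, default=20,
                    help="desk-scale default; the study design uses 100")
    ap.add_argument("--trait", default="width")
    ap.add_argument("--with-ml", action="store_true",
                    help="also run SVR/RF/XGB regressors (slower)")
    ap.add_argument("--tables", type=Path, default=ROOT / "results" / "tables")
    args = ap.parse_args()

    geno = read_genotypes(args.tables / "genotypes_maf05.csv")
    G = compute_kernel(center_standardize(geno))
    blues = pd.read_csv(args.tables / "blues.csv")
    mcmc = McmcSpec(1500, 500, 3)

    all_rows, h2_rows = [], []
    for cond in ("control", "HNT"):
        metab, _ = read_omics(args.tables / f"metabolites_{cond}_corrected.csv")
        Wm = center_standardize(metab)
        M = compute_kernel(Wm)
        y = blues_vector(blues, cond, args.trait, geno.line_ids)

        models = {"mols": "mols", "bayesc": "bayesc", "mblup": "mblup",
                  "gblup": "gblup", "gmblup": "gmblup"}
        if args.with_ml:
            models.update({
                "svr": ModelSpec("svr_rbf", grid={"C": [1.0, 10.0],
                                                  "gamma_scale": [1.0]}),
                "rf": ModelSpec("rf_regress", grid={"n_estimators": [300],
                                                    "max_features": [0.333]}),
                "xgb": ModelSpec("xgb_regress", grid={"max_depth": [2, 4],
                                                      "learning_rate": [0.1],
                                                      "n_estimators": [150]})})
        pset = PredictorSet(metabolites=Wm, G=G, M=M, mcmc=mcmc)
        design = CVDesign("prediction", n_repeats=args.repeats, seed=args.seed)
        res = run_prediction_cv(y, models, pset, design)
        for name, cv in res.items():
            for rep, v in enumerate(cv.per_repeat):
                all_rows.append({"condition": cond, "trait": args.trait,
                                 "model": name, "repeat": rep, "pearson": v})
        names = list(res)
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                w = pairwise_win_fraction(res[a], res[b])
                all_rows.append({"condition": cond, "trait": args.trait,
                                 "model": f"win:{a}>{b}", "repeat": -1,
                                 "pearson": w["win_fraction"]})

        # whole-data heritability estimates (MBLUP / GBLUP / GMBLUP)
        for label, kernels in (("MBLUP", [M]), ("GBLUP", [G]), ("GMBLUP", [M, G])):
            fit = fit_kernel_blup(y, kernels,
                                  mcmc=McmcSpec(3000, 1000, 3, seed=args.seed))
            h2_rows.append({"condition": cond, "trait": args.trait,
                            "model": label, **fit.heritabilities})

    tidy = pd.DataFrame(all_rows)
    tidy.to_csv(args.tables / f"prediction_cv_{args.trait}.csv", index=False)
    h2 = pd.DataFrame(h2_rows)
    h2.to_csv(args.tables / f"heritability_{args.trait}.csv", index=False)
    per = tidy[tidy.repeat >= 0]
    print(per.groupby(["condition", "model"])["pearson"]
          .agg(["mean", "std"]).to_string())
    print("\nheritability estimates:")
    print(h2.to_string(index=False))


if __name__ == "__main__":
    main()
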