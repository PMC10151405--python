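#!/usr/bin/env python
"""Leave-one-subpopulation-out genomic prediction.

Predicts each subpopulation's grain-size BLUEs from a GBLUP model trained on
the remaining subpopulations, compared with repeated random-subsampling CV
on the same data. The study finds LOSO substantially below random-split CV:
prediction into an unrepresented subpopulation is hard.
"""

import argparse
from pathlib import Path

import pandas as pd

from grainpred.bayes import McmcSpec
from grainpred.evaluation import (CVDesign, PredictorSet, run_loso_cv,
                                  run_prediction_cv)
from grainpred.io import read_genotypes, read_subpops
from grainpred.kernels import compute_kernel
from grainpred.preprocess import blues_vector, center_standardize

ROOT = Path(__file__).resolve().parents[1]


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--trait", default="width")
    ap.add_argument("--condition", default="control")
    ap.add_argument("--data", type=Path, default=ROOT / "results" / "data")
    ap.add_argument("--tables", type=Path, default=ROOT / "results" / "tables")
    args = ap.parse_args()

    geno = read_genotypes(args.tables / "genotypes_maf05.csv")
    G = compute_kernel(center_standardize(geno))
    blues = pd.read_csv(args.tables / "blues.csv")
    y = blues_vector(blues, args.condition, args.trait, geno.line_ids)
    subpop = read_subpops(args.data / "subpops.csv").reindex(geno.line_ids)

    pset = PredictorSet(G=G, mcmc=McmcSpec(1500, 500, 3))
    loso = run_loso_cv(y, "gblup", pset, subpop.to_numpy(), seed=args.seed)
    rand = run_prediction_cv(y, {"gblup": "gblup"}, pset,
                             CVDesign(n_repeats=10, seed=args.seed))["gblup"]
    loso.to_csv(args.tables / f"loso_{args.condition}_{args.trait}.csv",
                index=False)
    print(loso.to_string(index=False))
    print(f"\nLOSO mean r = {loso['pearson'].mean():.3f}  vs  "
          f"random-split CV mean r = {rand.mean:.3f}")


if __name__ == "__main__":
    main()
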