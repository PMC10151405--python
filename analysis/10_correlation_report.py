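#!/usr/bin/env python
"""Correlation structure of the metabolome and its link to grain size.

Tabulates metabolite pairs with |r| > 0.9 (the study reports e.g. the
citraconic acid / arabinose / lyxose / ribose quadruple) and metabolite-
trait associations at |r| > 0.3 (grain width carries most of them).
"""

import argparse
from pathlib import Path

import pandas as pd

from grainpred.evaluation import correlation_report
from grainpred.io import read_genotypes, read_omics
from grainpred.preprocess import blues_vector

ROOT = Path(__file__).resolve().parents[1]


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--condition", default="control")
    ap.add_argument("--tables", type=Path, default=ROOT / "results" / "tables")
    args = ap.parse_args()

    geno = read_genotypes(args.tables / "genotypes_maf05.csv")
    metab, _ = read_omics(
        args.tables / f"metabolites_{args.condition}_corrected.csv")
    blues = pd.read_csv(args.tables / "blues.csv")
    traits = pd.DataFrame(
        {t: blues_vector(blues, args.condition, t, metab.line_ids)
         for t in ("length", "width", "perimeter")})

    out = correlation_report(metab, traits)
    out["metabolite_pairs"].to_csv(
        args.tables / f"correlated_pairs_{args.condition}.csv", index=False)
    out["metabolite_trait"].to_csv(
        args.tables / f"metabolite_trait_corr_{args.condition}.csv", index=False)
    print(f"{len(out['metabolite_pairs'])} metabolite pairs with |r| > 0.9")
    print(f"{len(out['metabolite_trait'])} metabolite-trait flags at |r| > 0.3")
    if len(out["metabolite_trait"]):
        print(out["metabolite_trait"].round(3).to_string(index=False))


if __name__ == "__main__":
    main()
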