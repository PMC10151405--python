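#!/usr/bin/env python
"""Transferability of the metabolic signal across stress conditions.

Trains metabolite effects with one condition's metabolite profiles and
predicts the other condition's phenotypes on held-out lines, compared with
the within-condition run on identical splits. The study reports a general
decrease when crossing conditions.
"""

import argparse
from pathlib import Path

import pandas as pd

from grainpred.bayes import McmcSpec
from grainpred.evaluation import CVDesign, run_cross_condition
from grainpred.io import read_genotypes, read_omics
from grainpred.preprocess import blues_vector, center_standardize

ROOT = Path(__file__).resolve().parents[1]


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--repeats", type=int, default=20)
    ap.add_argument("--trait", default="width")
    ap.add_argument("--tables", type=Path, default=ROOT / "results" / "tables")
    args = ap.parse_args()

    geno = read_genotypes(args.tables / "genotypes_maf05.csv")
    blues = pd.read_csv(args.tables / "blues.csv")
    mats = {c: center_standardize(
        read_omics(args.tables / f"metabolites_{c}_corrected.csv")[0])
        for c in ("control", "HNT")}

    rows = []
    for target, source in (("control", "HNT"), ("HNT", "control")):
        y = blues_vector(blues, target, args.trait, geno.line_ids)
        res = run_cross_condition(y, mats[source], mats[target], "mblup",
                                  McmcSpec(1200, 400, 2),
                                  CVDesign(n_repeats=args.repeats,
                                           seed=args.seed))
        within, transfer = res["within"].mean, res["transfer"].mean
        change = 100 * (transfer - within) / abs(within)
        rows.append({"target": target, "source": source, "within_r": within,
                     "transfer_r": transfer, "pct_change": change})
        print(f"{source} -> {target}: within r = {within:.3f}, "
              f"transfer r = {transfer:.3f} ({change:+.0f}%)")
    pd.DataFrame(rows).to_csv(args.tables / f"cross_condition_{args.trait}.csv",
                              index=False)


if __name__ == "__main__":
    main()
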