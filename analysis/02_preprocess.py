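#!/usr/bin/env python
"""Preprocess the simulated tables the way the study preprocesses real data.

Reads results/data/, applies the MAF < 0.05 marker filter, corrects
metabolite abundances for run and batch effects (random, per condition),
derives per-line BLUEs for each trait x condition, and estimates
conventional (replicate-based) heritability. Writes tidy tables under
results/tables/.
"""

import argparse
from pathlib import Path

import pandas as pd

from grainpred.io import read_genotypes, read_omics, read_phenotypes
from grainpred.preprocess import (compute_blues, conventional_heritability,
                                  correct_batch_effects, filter_maf)

ROOT = Path(__file__).resolve().parents[1]


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--data", type=Path, default=ROOT / "results" / "data")
    ap.add_argument("--out", type=Path, default=ROOT / "results" / "tables")
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    geno = read_genotypes(args.data / "genotypes.csv")
    n0 = geno.n_markers
    geno = filter_maf(geno, 0.05)
    print(f"MAF filter: kept {geno.n_markers}/{n0} markers")
    geno.to_dataframe().to_csv(args.out / "genotypes_maf05.csv",
                               index_label="line_id")

    for cond in ("control", "HNT"):
        mat, labels = read_omics(args.data / f"metabolites_{cond}.csv",
                                 label_cols=("run", "batch"))
        corrected = correct_batch_effects(mat, labels["run"], labels["batch"])
        corrected.to_dataframe().to_csv(
            args.out / f"metabolites_{cond}_corrected.csv",
            index_label="line_id")
        print(f"{cond}: corrected {mat.n_features} metabolites "
              f"({labels['run'].nunique()} runs, {labels['batch'].nunique()} batches)")

    pheno = read_phenotypes(args.data / "phenotypes.csv")
    blues = compute_blues(pheno)
    blues.to_csv(args.out / "blues.csv", index=False)
    h2 = conventional_heritability(pheno)
    h2.to_csv(args.out / "conventional_h2.csv", index=False)
    print("conventional heritability (replicate-based):")
    print(h2[["condition", "trait", "h2"]].to_string(index=False))


if __name__ == "__main__":
    main()
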