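#!/usr/bin/env python
"""Reproduce the real-panel heritability table from downloaded supplements.

Requires data that are not shipped here: the study's phenotype/metabolite
supplementary files (Figshare) and the HDRA 700k genotypes
(ricediversity.org), converted to the CSV dialects this package reads
(first column line_id). Given those, this driver applies the same pipeline
as the synthetic analysis — MAF < 0.05 filter, run/batch correction, BLUEs,
kernels — and estimates metabolic/genomic heritability per trait and
condition with MBLUP, GBLUP and GMBLUP.

Example:
    python analysis/11_real_data.py --genotypes hdra.csv \
        --metabolites-control mc.csv --metabolites-hnt mh.csv \
        --phenotypes pheno.csv
"""

import argparse
from pathlib import Path

import pandas as pd

from grainpred.bayes import McmcSpec, fit_kernel_blup
from grainpred.io import align_lines, read_genotypes, read_omics, read_phenotypes
from grainpred.kernels import compute_kernel
from grainpred.preprocess import (blues_vector, center_standardize,
                                  compute_blues, correct_batch_effects,
                                  filter_maf)

ROOT = Path(__file__).resolve().parents[1]


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--genotypes", type=Path, required=True)
    ap.add_argument("--metabolites-control", type=Path, required=True)
    ap.add_argument("--metabolites-hnt", type=Path, required=True)
    ap.add_argument("--phenotypes", type=Path, required=True)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=ROOT / "results" / "tables")
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    geno = filter_maf(read_genotypes(args.genotypes), 0.05)
    pheno = read_phenotypes(args.phenotypes)
    blues = compute_blues(pheno)
    mcmc = McmcSpec(seed=args.seed)  # full study chain: 30k/10k/10

    rows = []
    for cond, path in (("control", args.metabolites_control),
                       ("HNT", args.metabolites_hnt)):
        metab, labels = read_omics(path, label_cols=("run", "batch"))
        if len(labels.columns):
            metab = correct_batch_effects(metab, labels["run"], labels["batch"])
        lines = align_lines(geno.line_ids, metab.line_ids,
                            blues[blues.condition == cond]["line_id"])
        gsub = geno.subset_lines(
            [list(geno.line_ids).index(l) for l in lines])
        msub = metab.subset_lines(
            [list(metab.line_ids).index(l) for l in lines])
        G = compute_kernel(center_standardize(gsub))
        M = compute_kernel(center_standardize(msub))
        for trait in ("length", "width", "perimeter"):
            y = blues_vector(blues, cond, trait, lines)
            for label, ks in (("MBLUP", [M]), ("GBLUP", [G]),
                              ("GMBLUP", [M, G])):
                fit = fit_kernel_blup(y, ks, mcmc=mcmc)
                rows.append({"condition": cond, "trait": trait,
                             "model": label, **fit.heritabilities})
            print(f"{cond}/{trait}: done")
    out = pd.DataFrame(rows)
    out.to_csv(args.out / "real_data_heritability.csv", index=False)
    print(out.round(3).to_string(index=False))


if __name__ == "__main__":
    main()
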