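"""Preprocessing: MAF filter, standardization, batch correction, BLUEs.

These are the steps that turn raw tables into the inputs of the kernel and
regression models: markers are filtered at minor-allele frequency 0.05,
feature matrices are centered and standardized, metabolite abundances are
corrected for run and experimental batch effects (treated as random,
separately per condition), and replicated phenotypes are collapsed to
per-line best linear unbiased estimators (BLUEs).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .io import CONDITIONS, GenotypeMatrix, OmicsMatrix, PhenotypeTable
from .mixed import em_reml, indicator

logger = logging.getLogger(__name__)


def filter_maf(geno: GenotypeMatrix, threshold: float = 0.05) -> GenotypeMatrix:
    """Remove markers with minor-allele frequency strictly below ``threshold``."""
    keep = geno.maf >= threshold
    n_removed = int((~keep).sum())
    if keep.sum() == 0:
        raise ValueError("MAF filter removed every marker")
    if n_removed:
        logger.info("MAF filter removed %d of %d markers", n_removed, geno.n_markers)
    return GenotypeMatrix(geno.values[:, keep], geno.line_ids,
                          geno.marker_ids[keep], geno.subpop)


def center_standardize(mat, kind: str | None = None, ddof: int = 0) -> OmicsMatrix:
    """Center and standardize columns; drop zero-variance columns.

    Accepts an OmicsMatrix or GenotypeMatrix. Standardization divides by the
    population SD (ddof=0) so standardized columns satisfy sum(w^2) = n and
    the relationship kernel W W'/m has mean diagonal exactly 1.
    """
    if isinstance(mat, GenotypeMatrix):
        values, line_ids, feature_ids = mat.values, mat.line_ids, mat.marker_ids
        kind = kind or "marker"
    else:
        values, line_ids, feature_ids = mat.values, mat.line_ids, mat.feature_ids
        kind = kind or mat.kind
    if values.shape[0] < 2:
        raise ValueError("need at least 2 lines to standardize")
    sd = values.std(axis=0, ddof=ddof)
    keep = sd > 0
    if not keep.all():
        logger.warning("dropping %d constant column(s): %s", (~keep).sum(),
                       list(np.asarray(feature_ids)[~keep][:10]))
    vals = values[:, keep]
    std = (vals - vals.mean(axis=0)) / sd[keep]
    return OmicsMatrix(std, line_ids, np.asarray(feature_ids)[keep],
                       kind=kind, standardized=True)


def correct_batch_effects(metab: OmicsMatrix, run_labels, batch_labels) -> OmicsMatrix:
    """Remove random run and batch effects from metabolite abundances.

    Per metabolite, fits ``abundance = mu + run + batch + e`` with run and
    batch random (EM-REML) and returns ``mu + e`` (intercept plus residual)
    as the corrected abundance. Call separately per condition.
    """
    run_labels = np.asarray(run_labels)
    batch_labels = np.asarray(batch_labels)
    if len(run_labels) != metab.n_lines or len(batch_labels) != metab.n_lines:
        raise ValueError("run/batch labels must cover all lines")
    Zr, run_levels = indicator(run_labels)
    Zb, batch_levels = indicator(batch_labels)
    if len(run_levels) == 1 and len(batch_levels) == 1:
        logger.warning("single run and batch level: returning centered input")
        vals = metab.values - metab.values.mean(axis=0)
        return OmicsMatrix(vals, metab.line_ids, metab.feature_ids,
                           metab.kind, standardized=False)
    Zs = [Z for Z, lv in ((Zr, run_levels), (Zb, batch_levels)) if len(lv) > 1]
    X = np.ones((metab.n_lines, 1))
    corrected = np.empty_like(metab.values)
    n = metab.n_lines
    for j in range(metab.n_features):
        fit = em_reml(metab.values[:, j], X, Zs)
        # re-center each factor's effects (weighted by level counts) into the
        # intercept: the split is unidentified when the residual variance -> 0
        us = []
        for Z, u in zip(Zs, fit.u):
            wm = (Z.sum(axis=0) @ u) / n
            us.append(u - wm)
        nuisance = sum(Z @ u for Z, u in zip(Zs, us))
        corrected[:, j] = metab.values[:, j] - nuisance
    return OmicsMatrix(corrected, metab.line_ids, metab.feature_ids,
                       metab.kind, standardized=False)


def compute_blues(pheno: PhenotypeTable) -> pd.DataFrame:
    """Per-line BLUEs per condition and trait, accounting for replication.

    Fits ``value = line (fixed) + replicate (random) + e`` per (condition,
    trait) cell and returns a tidy frame (line_id, condition, trait, value).
    Lines with zero records in a cell are simply absent from that cell.
    """
    out = []
    for (cond, trait), d in pheno.data.groupby(["condition", "trait"], sort=True):
        X, lines = indicator(d["line_id"].to_numpy())
        Zr, rep_levels = indicator(d["replicate"].to_numpy())
        Zs = [Zr] if len(rep_levels) > 1 else []
        if Zs:
            fit = em_reml(d["value"].to_numpy(dtype=float), X, Zs)
            blues = fit.beta
        else:
            # single replicate: BLUE = observed value per line
            blues = np.linalg.lstsq(X, d["value"].to_numpy(dtype=float), rcond=None)[0]
        out.append(pd.DataFrame({"line_id": lines, "condition": cond,
                                 "trait": trait, "value": blues}))
    return pd.concat(out, ignore_index=True)


def blues_vector(blues: pd.DataFrame, condition: str, trait: str,
                 line_ids) -> np.ndarray:
    """Extract a BLUE vector aligned to ``line_ids`` for one condition/trait."""
    cell = blues[(blues["condition"] == condition) & (blues["trait"] == trait)]
    s = cell.set_index("line_id")["value"].reindex(line_ids)
    if s.isna().any():
        missing = list(s.index[s.isna()][:5])
        raise ValueError(f"lines without BLUEs in {condition}/{trait}: {missing}")
    return s.to_numpy(dtype=float)


def conventional_heritability(pheno: PhenotypeTable) -> pd.DataFrame:
    """Replicate-based heritability per condition and trait.

    Fits ``value = mu + genotype (random) + replicate (random) + e`` and
    reports sigma^2_geno / (sigma^2_geno + sigma^2_e). Non-positive variance
    estimates are floored at ~0 inside the EM.
    """
    rows = []
    for (cond, trait), d in pheno.data.groupby(["condition", "trait"], sort=True):
        Zg, _ = indicator(d["line_id"].to_numpy())
        Zr, rep_levels = indicator(d["replicate"].to_numpy())
        if len(rep_levels) < 2:
            logger.warning("%s/%s has <2 replicates; h2 undefined", cond, trait)
            continue
        X = np.ones((len(d), 1))
        fit = em_reml(d["value"].to_numpy(dtype=float), X, [Zg, Zr])
        s2_g, _s2_rep = fit.sigma2
        h2 = s2_g / (s2_g + fit.sigma2_e)
        rows.append({"condition": cond, "trait": trait, "h2": h2,
                     "sigma2_geno": s2_g, "sigma2_rep": _s2_rep,
                     "sigma2_e": fit.sigma2_e})
    return pd.DataFrame(rows)
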