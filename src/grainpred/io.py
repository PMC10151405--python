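"""Readers, writers and in-memory containers for the three data tables.

Genotypes are line × marker allele-dosage matrices (0/1/2 copies of the
minor allele), metabolites are line × feature abundance matrices with
run/batch labels, and phenotypes are long-format replicated grain-size
records (length, width, perimeter) per growing condition (control vs
high-night-temperature, HNT).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CONDITIONS = ("control", "HNT")
TRAITS = ("length", "width", "perimeter")


@dataclass
class GenotypeMatrix:
    """Line × marker dosage matrix with per-marker minor-allele frequency."""

    values: np.ndarray
    line_ids: np.ndarray
    marker_ids: np.ndarray
    subpop: np.ndarray | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.line_ids = np.asarray(self.line_ids)
        self.marker_ids = np.asarray(self.marker_ids)
        if len(set(self.line_ids)) != len(self.line_ids):
            raise ValueError("duplicate line_ids in genotype matrix")
        if self.values.shape != (len(self.line_ids), len(self.marker_ids)):
            raise ValueError("genotype shape does not match id lengths")

    @property
    def n_lines(self) -> int:
        return self.values.shape[0]

    @property
    def n_markers(self) -> int:
        return self.values.shape[1]

    @property
    def maf(self) -> np.ndarray:
        """Per-marker minor-allele frequency (ignoring missing entries)."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            freq = np.nanmean(self.values, axis=0) / 2.0
        return np.minimum(freq, 1.0 - freq)

    def subset_lines(self, idx) -> "GenotypeMatrix":
        sp = None if self.subpop is None else self.subpop[idx]
        return GenotypeMatrix(self.values[idx], self.line_ids[idx], self.marker_ids, sp)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.line_ids, columns=self.marker_ids)


@dataclass
class OmicsMatrix:
    """Line × feature real matrix (markers or metabolites).

    ``standardized`` marks matrices whose columns have mean 0 and SD 1
    (population-SD convention), the form the kernels and regressions expect.
    """

    values: np.ndarray
    line_ids: np.ndarray
    feature_ids: np.ndarray
    kind: str = "metabolite"  # "marker" | "metabolite"
    standardized: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.line_ids = np.asarray(self.line_ids)
        self.feature_ids = np.asarray(self.feature_ids)
        if self.values.shape != (len(self.line_ids), len(self.feature_ids)):
            raise ValueError("omics shape does not match id lengths")

    @property
    def n_lines(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def subset_lines(self, idx) -> "OmicsMatrix":
        return OmicsMatrix(self.values[idx], self.line_ids[idx], self.feature_ids,
                           self.kind, self.standardized)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.line_ids, columns=self.feature_ids)


@dataclass
class PhenotypeTable:
    """Long-format replicated phenotype records.

    Columns: line_id, condition in {control, HNT}, replicate, trait in
    {length, width, perimeter}, value.
    """

    data: pd.DataFrame = field(repr=False)

    REQUIRED = ("line_id", "condition", "replicate", "trait", "value")

    def __post_init__(self):
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise ValueError(f"phenotype table missing columns: {missing}")
        bad = set(self.data["condition"].unique()) - set(CONDITIONS)
        if bad:
            raise ValueError(f"unknown conditions {bad}; expected {CONDITIONS}")
        key = ["line_id", "condition", "replicate", "trait"]
        if self.data.duplicated(subset=key).any():
            raise ValueError("duplicate (line, condition, replicate, trait) records")

    @property
    def line_ids(self) -> np.ndarray:
        return np.sort(self.data["line_id"].unique())

    def subset(self, condition=None, trait=None) -> pd.DataFrame:
        d = self.data
        if condition is not None:
            d = d[d["condition"] == condition]
        if trait is not None:
            d = d[d["trait"] == trait]
        return d


def read_genotypes(path, format: str = "matrix-csv") -> GenotypeMatrix:
    """Read a genotype matrix from CSV/TSV or VCF and impute missing dosages.

    Missing dosages are imputed to the per-marker mean rounded to the nearest
    of {0,1,2}; dosage is then recoded to count the minor allele per marker.
    """
    if format == "matrix-csv":
        sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
        df = pd.read_csv(path, index_col=0, sep=sep)
        geno = GenotypeMatrix(df.to_numpy(dtype=float), df.index.to_numpy(),
                              df.columns.to_numpy())
    elif format == "vcf":
        geno = _read_vcf(path)
    else:
        raise ValueError(f"unknown genotype format {format!r}")
    _impute_missing(geno)
    _recode_minor(geno)
    return geno


def _read_vcf(path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = np.asarray(vcf.samples)
    rows, ids = [], []
    for var in vcf:
        if len(var.ALT) != 1:
            logger.warning("skipping multi-allelic record %s:%s", var.CHROM, var.POS)
            continue
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gt = var.gt_types.astype(float)
        dose = np.where(gt == 3, 2.0, gt)
        dose[gt == 2] = np.nan
        rows.append(dose)
        ids.append(var.ID if var.ID else f"{var.CHROM}_{var.POS}")
    vcf.close()
    if not rows:
        raise ValueError(f"no usable biallelic records in {path}")
    return GenotypeMatrix(np.column_stack(rows), samples, np.asarray(ids))


def _impute_missing(geno: GenotypeMatrix) -> None:
    vals = geno.values
    if not np.isnan(vals).any():
        return
    col_mean = np.nanmean(vals, axis=0)
    fill = np.clip(np.rint(col_mean), 0, 2)
    idx = np.where(np.isnan(vals))
    vals[idx] = fill[idx[1]]


def _recode_minor(geno: GenotypeMatrix) -> None:
    """Flip columns so the dosage counts the minor allele (freq ≤ 0.5)."""
    freq = geno.values.mean(axis=0) / 2.0
    flip = freq > 0.5
    if flip.any():
        geno.values[:, flip] = 2.0 - geno.values[:, flip]


def write_genotypes(geno: GenotypeMatrix, path) -> None:
    geno.to_dataframe().to_csv(path, index_label="line_id")


def read_omics(path, kind: str = "metabolite",
               label_cols: tuple = ()) -> tuple[OmicsMatrix, pd.DataFrame]:
    """Read an omics matrix; ``label_cols`` (e.g. ("run","batch")) are split off.

    Returns the matrix and a line-indexed DataFrame of the label columns
    (empty if none requested).
    """
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, index_col=0, sep=sep)
    labels = df[list(label_cols)] if label_cols else pd.DataFrame(index=df.index)
    feats = df.drop(columns=list(label_cols), errors="ignore")
    mat = OmicsMatrix(feats.to_numpy(dtype=float), feats.index.to_numpy(),
                      feats.columns.to_numpy(), kind=kind)
    return mat, labels


def write_omics(mat: OmicsMatrix, path, labels: pd.DataFrame | None = None) -> None:
    df = mat.to_dataframe()
    if labels is not None and len(labels.columns):
        df = pd.concat([labels.reindex(df.index), df], axis=1)
    df.to_csv(path, index_label="line_id")


def read_phenotypes(path) -> PhenotypeTable:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    return PhenotypeTable(pd.read_csv(path, sep=sep))


def write_phenotypes(pheno: PhenotypeTable, path) -> None:
    pheno.data.to_csv(path, index=False)


def read_subpops(path) -> pd.Series:
    """CSV with columns line_id, subpop → Series indexed by line_id."""
    df = pd.read_csv(path)
    return df.set_index("line_id")["subpop"]


def align_lines(*line_id_arrays) -> np.ndarray:
    """Intersection of line-id sets, canonical sorted order."""
    common = set(np.asarray(line_id_arrays[0]).tolist())
    for ids in line_id_arrays[1:]:
        common &= set(np.asarray(ids).tolist())
    if not common:
        raise ValueError("no shared line_ids across inputs")
    return np.array(sorted(common))
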