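"""Synthetic rice diversity-panel generator with known ground truth.

Emulates the study design: ~190 lines per growing condition genotyped at
biallelic SNPs (MAF >= 0.05) with mild subpopulation structure, 73 grain
metabolites with a partial genetic basis, block correlation, run/batch
nuisance effects and a condition (control vs HNT) mean shift on a subset of
metabolites, and replicated grain-size phenotypes whose line-level variance
decomposes into a genomic part (h2_g, from n_qtl markers), a metabolite-
mediated part (h2_m) and residual. An auxiliary trait with a chosen genetic
correlation to the target supports the multi-trait experiments.

Everything is driven by one integer seed and is bit-reproducible.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import GenotypeMatrix, OmicsMatrix, PhenotypeTable

logger = logging.getLogger(__name__)

# internal constants of the generator (documented in docs/methods.md)
METAB_GENETIC_FRACTION = 0.3   # share of each metabolite's variance that is genetic
MARKERS_PER_METABOLITE = 5
METAB_BLOCK_SIZE = 4           # mirrors the reported correlated quadruple
N_RUNS = 6
N_BATCHES = 2
REP_NOISE_VAR = 0.3            # within-replicate measurement variance
HNT_PHENO_SHIFT = -0.3         # HNT reduces grain size (in line-mean SD units)


@dataclass
class SimConfig:
    """Ground-truth parameters of one synthetic dataset."""

    n_lines: int = 190
    n_markers: int = 2000
    n_metabolites: int = 73
    maf_range: tuple = (0.05, 0.5)
    n_subpops: int = 4
    subpop_divergence: float = 0.15
    # markers come in clusters tagging one latent variant: dense arrays are
    # highly redundant, and without that redundancy an m >> n marker panel
    # yields a near-unidentifiable relationship kernel
    ld_cluster_size: int = 10
    ld_fidelity: float = 0.95
    h2_g: float = 0.5
    h2_m: float = 0.2
    n_qtl: int = 50
    condition_shift_sd: float = 1.0
    n_shifted_metabolites: int = 30
    metab_block_corr: float = 0.5
    n_reps: int = 3
    run_batch_sd: float = 0.5
    rho_aux: float = 0.0
    seed: int = 0

    def __post_init__(self):
        low, high = self.maf_range
        if not (0 < low <= high <= 0.5):
            raise ValueError("maf_range must satisfy 0 < low <= high <= 0.5")
        if not 0 <= self.h2_g < 1 or not 0 <= self.h2_m < 1:
            raise ValueError("heritabilities must lie in [0, 1)")
        if self.h2_g + self.h2_m >= 1:
            raise ValueError("h2_g + h2_m must be < 1")
        for name in ("n_lines", "n_markers", "n_metabolites", "n_subpops",
                     "n_qtl", "n_reps"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_shifted_metabolites > self.n_metabolites:
            raise ValueError("n_shifted_metabolites exceeds n_metabolites")
        if self.n_qtl > self.n_markers:
            raise ValueError("n_qtl exceeds n_markers")
        if not 0 <= self.metab_block_corr < 1:
            raise ValueError("metab_block_corr must lie in [0, 1)")
        if self.subpop_divergence < 0 or self.run_batch_sd < 0:
            raise ValueError("divergence and run_batch_sd must be nonnegative")
        if self.ld_cluster_size < 1 or not 0 <= self.ld_fidelity <= 1:
            raise ValueError("invalid marker-cluster settings")
        if not -1 <= self.rho_aux <= 1:
            raise ValueError("rho_aux must lie in [-1, 1]")


@dataclass
class SimTruth:
    """What the generator knows: recovery tests compare estimates to this."""

    marker_effects: np.ndarray = None
    qtl_indices: np.ndarray = None
    true_genetic_values: np.ndarray = None
    true_h2_g: float = 0.0
    true_h2_m: float = 0.0
    shifted_metabolite_indices: np.ndarray = None
    condition_shifts: np.ndarray = None
    true_rho_aux: float = 0.0
    aux_genetic_values: np.ndarray = None
    aux_trait_values: np.ndarray = None
    metabolite_channel: np.ndarray = None

    def to_json(self) -> str:
        def conv(v):
            return v.tolist() if isinstance(v, np.ndarray) else v
        return json.dumps({k: conv(v) for k, v in asdict(self).items()}, indent=1)


def _rng(cfg: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([cfg.seed, stream]))


def simulate_genotypes(cfg: SimConfig) -> GenotypeMatrix:
    """Binomial(2, p) dosages with subpopulation drift and marker redundancy.

    Markers come in clusters of ``ld_cluster_size`` tagging one latent
    variant: each cluster draws an ancestral frequency from ``maf_range`` and
    per-subpopulation frequencies drifted from it by a bounded perturbation
    scaled by ``subpop_divergence``. Within a cluster each marker allele
    copies the latent allele with probability ``ld_fidelity`` and is redrawn
    from the subpopulation frequency otherwise, so every marker keeps a
    binomial(2, p) marginal while markers in a cluster are correlated
    (pairwise dosage correlation ~ fidelity^2). Clusters containing a marker
    whose realized minor-allele frequency falls outside ``maf_range`` are
    resampled wholesale.
    """
    rng = _rng(cfg, 0)
    n, m = cfg.n_lines, cfg.n_markers
    low, high = cfg.maf_range
    subpop = np.array([f"pop{i % cfg.n_subpops + 1}" for i in range(n)])
    pop_idx = np.arange(n) % cfg.n_subpops
    line_ids = np.array([f"L{i:04d}" for i in range(n)])
    marker_ids = np.array([f"snp{j:05d}" for j in range(m)])

    csize = cfg.ld_cluster_size
    n_clusters = int(np.ceil(m / csize))
    cluster_of = np.repeat(np.arange(n_clusters), csize)[:m]

    values = np.empty((n, m))
    todo_clusters = np.arange(n_clusters)
    for _round in range(500):
        k = len(todo_clusters)
        cols = np.flatnonzero(np.isin(cluster_of, todo_clusters))
        local_cluster = np.searchsorted(todo_clusters, cluster_of[cols])
        p_anc = rng.uniform(low, high, size=k)
        drift = cfg.subpop_divergence * rng.standard_normal((cfg.n_subpops, k))
        p_sub = np.clip(p_anc + drift * np.sqrt(p_anc * (1 - p_anc)), 0.02, 0.98)
        p_line = p_sub[pop_idx, :]                       # (n, k)
        latent = rng.random((n, k, 2)) < p_line[:, :, None]
        keep = rng.random((n, len(cols), 2)) < cfg.ld_fidelity
        fresh = rng.random((n, len(cols), 2)) < p_line[:, local_cluster, None]
        alleles = np.where(keep, latent[:, local_cluster, :], fresh)
        values[:, cols] = alleles.sum(axis=2).astype(float)
        freq = values[:, cols].mean(axis=0) / 2.0
        maf = np.minimum(freq, 1 - freq)
        bad_cols = (maf < low - 1e-12) | (maf > high + 1e-12)
        todo_clusters = np.unique(cluster_of[cols[bad_cols]])
        if len(todo_clusters) == 0:
            break
    else:
        raise RuntimeError("could not satisfy maf_range by resampling")
    return GenotypeMatrix(values, line_ids, marker_ids, subpop=subpop)


def _standardize_cols(x: np.ndarray) -> np.ndarray:
    x = x - x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    return x / sd


@dataclass
class MetaboliteSim:
    control: OmicsMatrix
    hnt: OmicsMatrix
    run_labels: dict
    batch_labels: dict
    shifted_indices: np.ndarray
    condition_shifts: np.ndarray
    signal_control: np.ndarray = field(repr=False, default=None)
    signal_hnt: np.ndarray = field(repr=False, default=None)


def simulate_metabolites(geno: GenotypeMatrix, cfg: SimConfig) -> MetaboliteSim:
    """Condition-paired metabolite matrices with genetic basis and nuisance.

    Each metabolite j in block b is sqrt(rho)*z_b + sqrt(1-rho)*e_j where the
    block factor z_b and the idiosyncratic part e_j each carry a genetic
    component (random small marker subsets), so the metabolic kernel M is
    weakly but positively related to G. The HNT copy redraws the non-genetic
    parts, adds per-metabolite condition shifts (condition_shift_sd SD with
    random sign on n_shifted_metabolites columns) and both conditions get
    additive per-(run, metabolite) and per-(batch, metabolite) effects.
    """
    rng = _rng(cfg, 1)
    n, p = geno.n_lines, cfg.n_metabolites
    X = _standardize_cols(geno.values)
    gf = METAB_GENETIC_FRACTION
    rho = cfg.metab_block_corr

    def genetic_score(k):
        idx = rng.choice(geno.n_markers, size=MARKERS_PER_METABOLITE, replace=False)
        beta = rng.standard_normal(MARKERS_PER_METABOLITE)
        g = X[:, idx] @ beta
        sd = g.std()
        return g / sd if sd > 0 else g

    n_blocks = int(np.ceil(p / METAB_BLOCK_SIZE))
    block_of = np.repeat(np.arange(n_blocks), METAB_BLOCK_SIZE)[:p]
    zg_block = np.column_stack([genetic_score(b) for b in range(n_blocks)])
    eg_feat = np.column_stack([genetic_score(j) for j in range(p)])

    def draw_condition():
        z_env = rng.standard_normal((n, n_blocks))
        e_env = rng.standard_normal((n, p))
        z = np.sqrt(gf) * zg_block + np.sqrt(1 - gf) * z_env
        e = np.sqrt(gf) * eg_feat + np.sqrt(1 - gf) * e_env
        return np.sqrt(rho) * z[:, block_of] + np.sqrt(1 - rho) * e

    signal_c = draw_condition()
    signal_h = draw_condition()

    shifted = rng.choice(p, size=cfg.n_shifted_metabolites, replace=False)
    shifted.sort()
    shifts = np.zeros(p)
    shifts[shifted] = cfg.condition_shift_sd * rng.choice([-1.0, 1.0],
                                                          size=len(shifted))
    signal_h = signal_h + shifts

    run_labels, batch_labels, mats = {}, {}, {}
    for cond, signal in (("control", signal_c), ("HNT", signal_h)):
        runs = rng.permutation(np.arange(n) % N_RUNS)
        batches = rng.permutation(np.arange(n) % N_BATCHES)
        # centered across levels: nuisance effects reorder lines within a
        # condition but do not shift condition means (a mean shift would be
        # indistinguishable from a real condition effect)
        run_eff = rng.standard_normal((N_RUNS, p)) * cfg.run_batch_sd
        run_eff -= run_eff.mean(axis=0)
        batch_eff = rng.standard_normal((N_BATCHES, p)) * cfg.run_batch_sd
        batch_eff -= batch_eff.mean(axis=0)
        vals = signal + run_eff[runs] + batch_eff[batches]
        run_labels[cond] = np.array([f"run{r + 1}" for r in runs])
        batch_labels[cond] = np.array([f"batch{b + 1}" for b in batches])
        mats[cond] = OmicsMatrix(vals, geno.line_ids,
                                 np.array([f"met{j:03d}" for j in range(p)]),
                                 kind="metabolite")
    return MetaboliteSim(control=mats["control"], hnt=mats["HNT"],
                         run_labels=run_labels, batch_labels=batch_labels,
                         shifted_indices=shifted, condition_shifts=shifts,
                         signal_control=signal_c, signal_hnt=signal_h)


def simulate_phenotypes(geno: GenotypeMatrix, metab: MetaboliteSim,
                        cfg: SimConfig, stream: int = 2
                        ) -> tuple[PhenotypeTable, SimTruth]:
    """Replicated phenotypes: line mean = mu + genetic + metabolite channel.

    The genetic value comes from n_qtl random markers scaled to variance
    h2_g; the metabolite channel is a random linear combination of the
    (noise-free) control metabolite signals, residualized on the genetic
    value so the line-mean variance decomposition is (h2_g, h2_m, rest). The
    per-line residual variance is reduced by REP_NOISE_VAR/n_reps so line
    means have unit total variance. An auxiliary trait with genetic
    correlation rho_aux to the target is generated alongside.
    """
    if not np.array_equal(geno.line_ids, metab.control.line_ids):
        raise ValueError("genotypes and metabolites must share line ids")
    rng = _rng(cfg, stream)
    n = geno.n_lines
    X = _standardize_cols(geno.values)

    qtl = rng.choice(geno.n_markers, size=cfg.n_qtl, replace=False)
    qtl.sort()
    beta = rng.standard_normal(cfg.n_qtl)
    g_raw = X[:, qtl] @ beta
    g = (g_raw - g_raw.mean()) / g_raw.std()
    marker_effects = np.zeros(geno.n_markers)
    marker_effects[qtl] = beta

    # same metabolite weights per condition, applied to that condition's
    # metabolite signal: within-condition prediction works in both, while
    # cross-condition transfer degrades with the non-genetic signal overlap
    c = rng.standard_normal(cfg.n_metabolites)

    def channel(signal):
        ch = signal @ c
        ch = ch - (ch @ g) / (g @ g) * g  # clean (h2_g, h2_m) variance split
        sd = ch.std()
        return ch / sd if sd > 0 else ch

    chans = {"control": channel(metab.signal_control),
             "HNT": channel(metab.signal_hnt)}

    resid_var = 1.0 - cfg.h2_g - cfg.h2_m - REP_NOISE_VAR / cfg.n_reps
    if resid_var < 0.01:
        logger.warning("h2_g + h2_m near 1: flooring line residual variance")
        resid_var = 0.01

    def line_residual(chan):
        # orthogonal to the signal components and exactly scaled, so the
        # line-mean variance split is (h2_g, h2_m, rest) by construction
        e = rng.standard_normal(n)
        for v in (g, chan):
            vv = v @ v
            if vv > 0:
                e = e - (e @ v) / vv * v
        return e / e.std() * np.sqrt(resid_var)

    gv = np.sqrt(cfg.h2_g) * g
    mv = {cond: np.sqrt(cfg.h2_m) * ch for cond, ch in chans.items()}
    line_mean = {
        "control": 10.0 + gv + mv["control"] + line_residual(chans["control"]),
        "HNT": 10.0 + HNT_PHENO_SHIFT + gv + mv["HNT"]
               + line_residual(chans["HNT"])}

    rows = []
    for cond in ("control", "HNT"):
        for rep in range(1, cfg.n_reps + 1):
            rep_eff = rng.normal(scale=0.1)
            noise = rng.standard_normal(n) * np.sqrt(REP_NOISE_VAR)
            for i, lid in enumerate(geno.line_ids):
                rows.append((lid, cond, rep, line_mean[cond][i] + rep_eff + noise[i]))
    table = pd.DataFrame(rows, columns=["line_id", "condition", "replicate", "value"])

    # auxiliary trait for the multi-trait experiments
    qtl2 = rng.choice(geno.n_markers, size=cfg.n_qtl, replace=False)
    beta2 = rng.standard_normal(cfg.n_qtl)
    g2 = X[:, qtl2] @ beta2
    g2 = (g2 - g2.mean()) / g2.std()
    g2 = g2 - (g2 @ g) / (g @ g) * g  # orthogonalize, then mix to rho_aux
    sd2 = g2.std()
    g2 = g2 / sd2 if sd2 > 0 else g2
    g_aux = cfg.rho_aux * g + np.sqrt(max(1 - cfg.rho_aux ** 2, 0.0)) * g2
    aux_h2 = max(cfg.h2_g, 0.3)
    aux = (np.sqrt(aux_h2) * g_aux
           + rng.standard_normal(n) * np.sqrt(1 - aux_h2))

    truth = SimTruth(marker_effects=marker_effects, qtl_indices=qtl,
                     true_genetic_values=gv, true_h2_g=cfg.h2_g,
                     true_h2_m=cfg.h2_m,
                     shifted_metabolite_indices=metab.shifted_indices,
                     condition_shifts=metab.condition_shifts,
                     true_rho_aux=cfg.rho_aux,
                     aux_genetic_values=np.sqrt(aux_h2) * g_aux,
                     aux_trait_values=aux, metabolite_channel=mv["control"])
    return table, truth


@dataclass
class SimDataset:
    cfg: SimConfig
    genotypes: GenotypeMatrix
    metabolites: MetaboliteSim
    phenotypes: PhenotypeTable
    truths: dict  # trait -> SimTruth


def simulate_dataset(cfg: SimConfig) -> SimDataset:
    """Full bundle: genotypes, metabolites and the three grain-size traits."""
    geno = simulate_genotypes(cfg)
    metab = simulate_metabolites(geno, cfg)
    tables, truths = [], {}
    for k, trait in enumerate(("length", "width", "perimeter")):
        tab, truth = simulate_phenotypes(geno, metab, cfg, stream=2 + k)
        tab = tab.assign(trait=trait)
        tables.append(tab)
        truths[trait] = truth
    pheno = PhenotypeTable(pd.concat(tables, ignore_index=True)
                           [["line_id", "condition", "replicate", "trait", "value"]])
    return SimDataset(cfg, geno, metab, pheno, truths)


def write_dataset(data: SimDataset, outdir) -> None:
    """Write the dataset as the CSVs the readers consume + a truth sidecar."""
    from . import io as gio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    gio.write_genotypes(data.genotypes, outdir / "genotypes.csv")
    for cond, mat in (("control", data.metabolites.control),
                      ("HNT", data.metabolites.hnt)):
        labels = pd.DataFrame({"run": data.metabolites.run_labels[cond],
                               "batch": data.metabolites.batch_labels[cond]},
                              index=mat.line_ids)
        gio.write_omics(mat, outdir / f"metabolites_{cond}.csv", labels=labels)
    gio.write_phenotypes(data.phenotypes, outdir / "phenotypes.csv")
    pd.DataFrame({"line_id": data.genotypes.line_ids,
                  "subpop": data.genotypes.subpop}).to_csv(
        outdir / "subpops.csv", index=False)
    truth_doc = {t: json.loads(tr.to_json()) for t, tr in data.truths.items()}
    truth_doc["config"] = asdict(data.cfg)
    (outdir / "truth.json").write_text(json.dumps(truth_doc))
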