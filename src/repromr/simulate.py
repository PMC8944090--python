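"""Synthetic GWAS generator for correlated reproductive-trait analogues.

The generator produces three layers, each usable on its own:

1. **Genotypes** — dosage matrices with block-wise linkage disequilibrium.
   Each LD block is a latent Gaussian AR(rho) process, double-thresholded to
   Hardy–Weinberg 0/1/2 dosages at the configured minor-allele frequency.
2. **Traits** — eight reproductive-factor analogues generated along a causal
   DAG: each trait is the sum of direct SNP effects, causal contributions
   from upstream traits (in SD units), a loading on a shared heritable
   confounder (a childhood body-size analogue) and Gaussian noise, rescaled
   to unit variance.  Binary traits (ever parous) arise by thresholding the
   liability at the configured prevalence.
3. **Summary statistics** — either by running the per-SNP regressions of
   :mod:`repromr.assoc` on the individual-level cohort ("individual" mode) or
   by drawing effect estimates directly around the true marginal effects with
   the analytic standard error ``1/sqrt(2*maf*(1-maf)*n)`` ("analytic" mode,
   the fast path for estimator studies).

All operations are bit-reproducible given (config, seed).
"""

from __future__ import annotations

import graphlib
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .sumstats import CONTINUOUS, BINARY, SummaryStats, build_table

# The eight trait labels used throughout: age at menarche, age first had
# sexual intercourse, age at first/last live birth, number of live births,
# ever-parous status, lifetime number of sexual partners, age at menopause.
DEFAULT_TRAITS = ("menarche", "afs", "afb", "alb", "n_births", "parous",
                  "partners", "menopause")

CONFOUNDER_ID = "child_body_size"

# Never-parous fraction of 18.69% in the cohort the defaults emulate.
DEFAULT_PAROUS_PREVALENCE = 1.0 - 0.1869

# Direct causal effects (SD units) chosen so that the *total* effects along
# the DAG match the headline published estimates (totals in comments).
DEFAULT_THETA = {
    ("menarche", "afs"): 0.09,          # total 0.09
    ("menarche", "afb"): 0.0196,        # total 0.07
    ("menarche", "alb"): 0.0081,        # total 0.06
    ("menarche", "menopause"): 0.0460,  # total 0.06
    ("afs", "afb"): 0.56,               # total 0.56
    ("afs", "alb"): 0.0168,             # total 0.42
    ("afs", "n_births"): -0.0240,       # total -0.24
    ("afs", "partners"): -0.51,         # total -0.51
    ("afs", "menopause"): -0.0076,      # total 0.11
    ("afs", "parous"): -0.1259,         # total -0.105 (log OR 0.90)
    ("afb", "alb"): 0.72,               # total 0.72
    ("afb", "n_births"): -0.2432,       # total -0.38
    ("afb", "menopause"): 0.21,         # total 0.21
    ("alb", "n_births"): -0.19,         # total -0.19
    ("partners", "parous"): -0.041,     # total -0.041 (log OR 0.96)
}

# SNP heritabilities of the liability/trait; realistic mid-range values for
# questionnaire-derived reproductive traits.
DEFAULT_H2 = {
    "menarche": 0.25, "afs": 0.15, "afb": 0.15, "alb": 0.10,
    "n_births": 0.05, "parous": 0.05, "partners": 0.10, "menopause": 0.25,
}

DEFAULT_CONFOUNDER_GAMMA = {
    "menarche": -0.20, "afs": -0.10, "afb": -0.10,
}


@dataclass
class PleiotropySpec:
    """Direct SNP->target effects injected on a subset of a source trait's
    causal SNPs (horizontal pleiotropy)."""

    source_trait: str
    target_trait: str
    n_snps: int
    mean_effect: float = 0.0
    sd_effect: float = 0.02
    balanced: bool = False

    def effective_mean(self) -> float:
        return 0.0 if self.balanced else self.mean_effect


@dataclass
class CausalConfig:
    """Ground truth for the synthetic study: architecture, DAG, confounding.

    ``theta`` maps (source, target) trait pairs to *direct* causal effects in
    SD units; totals compose along DAG paths.  ``h2`` is the direct-SNP
    heritability per trait.  ``confounder_gamma`` loads traits on a shared
    heritable confounder.
    """

    trait_ids: Sequence[str] = DEFAULT_TRAITS
    n_snps_per_trait: int = 40
    h2: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_H2))
    theta: Mapping[tuple, float] = field(default_factory=lambda: dict(DEFAULT_THETA))
    confounder_gamma: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CONFOUNDER_GAMMA))
    confounder_h2: float = 0.20
    pleiotropy: Optional[PleiotropySpec] = None
    prevalence: Mapping[str, float] = field(
        default_factory=lambda: {"parous": DEFAULT_PAROUS_PREVALENCE})
    binary_traits: Sequence[str] = ("parous",)
    covariate_loadings: Mapping[str, float] = field(
        default_factory=lambda: {"age": 0.10, "batch": 0.05})
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for t, v in self.h2.items():
            if not 0.0 <= v < 1.0:
                raise ValueError(f"h2[{t!r}]={v} outside [0, 1)")
        for t, v in self.prevalence.items():
            if not 0.0 < v < 1.0:
                raise ValueError(f"prevalence[{t!r}]={v} outside (0, 1)")
        for (s, t) in self.theta:
            if s not in self.trait_ids or t not in self.trait_ids:
                raise ValueError(f"theta edge ({s!r}, {t!r}) not in trait registry")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate outside [0, 1)")
        self.topological_order()  # raises on cycles

    def topological_order(self) -> list:
        """Trait ids sorted so every causal source precedes its targets."""
        ts = graphlib.TopologicalSorter({t: set() for t in self.trait_ids})
        for (src, dst) in self.theta:
            ts.add(dst, src)
        try:
            order = [t for t in ts.static_order() if t in self.trait_ids]
        except graphlib.CycleError as err:
            raise ValueError("causal graph theta contains a cycle") from err
        return order

    def parents(self, trait: str) -> dict:
        return {s: v for (s, t), v in self.theta.items() if t == trait}

    def total_effect(self, source: str, target: str) -> float:
        """Total causal effect of ``source`` on ``target`` (sum over paths)."""
        if source == target:
            return 1.0
        total = 0.0
        for (s, t), d in self.theta.items():
            if t == target:
                total += d * self.total_effect(source, s)
        return total


@dataclass
class Block:
    """One LD block: ``n_snps`` variants with latent AR(rho) correlation."""

    n_snps: int
    rho: float = 0.0
    mafs: Optional[Sequence[float]] = None
    chrom: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_snps < 1:
            raise ValueError("block must contain at least one SNP")
        if not 0.0 <= self.rho < 1.0:
            raise ValueError(f"block rho={self.rho} outside [0, 1)")
        if self.mafs is not None:
            m = np.asarray(self.mafs, dtype=float)
            if len(m) != self.n_snps:
                raise ValueError("mafs length does not match n_snps")
            if ((m < 0.01) | (m > 0.5)).any():
                raise ValueError("MAFs outside [0.01, 0.5]")


@dataclass
class GenotypePanel:
    """Dosage matrix (individuals x SNPs) plus SNP metadata and LD blocks."""

    dosages: np.ndarray                      # int8, values 0/1/2
    snp_meta: pd.DataFrame                   # snp chr pos ea oa maf block
    block_structure: list                    # (start, length, rho)

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def subset_individuals(self, idx) -> "GenotypePanel":
        idx = np.asarray(idx)
        return GenotypePanel(self.dosages[idx], self.snp_meta,
                             self.block_structure)

    def snp_indices(self, snps: Iterable[str]) -> np.ndarray:
        lookup = pd.Index(self.snp_meta["snp"])
        return lookup.get_indexer(list(snps))

    def empirical_eaf(self) -> np.ndarray:
        return self.dosages.mean(axis=0, dtype=float) / 2.0

    def ld_r2(self, indices) -> np.ndarray:
        """Empirical squared dosage correlation among the given SNP columns."""
        sub = self.dosages[:, np.asarray(indices)].astype(float)
        sub -= sub.mean(axis=0)
        sd = sub.std(axis=0)
        sd[sd == 0] = np.nan
        corr = (sub.T @ sub) / self.n_individuals / np.outer(sd, sd)
        return corr ** 2

    def export(self, prefix: str) -> None:
        """Write dosages as .npy with a PLINK .bim-style sidecar TSV
        (chr, snp, cm, pos, a1, a2)."""
        np.save(f"{prefix}.dosages.npy", self.dosages)
        bim = pd.DataFrame({
            "chr": self.snp_meta["chr"], "snp": self.snp_meta["snp"],
            "cm": 0.0, "pos": self.snp_meta["pos"],
            "a1": self.snp_meta["ea"], "a2": self.snp_meta["oa"],
        })
        bim.to_csv(f"{prefix}.snps.tsv", sep="\t", index=False)


@dataclass
class TraitTable:
    """Per-individual trait values, covariates, and the realised genetic
    architecture (direct per-SNP effects on the dosage scale)."""

    values: pd.DataFrame                     # one column per trait, NaN = missing
    types: Mapping[str, str]                 # trait -> continuous|binary
    covariates: pd.DataFrame                 # age, batch
    direct_effects: Mapping[str, pd.Series]  # trait -> per-SNP dosage-scale beta

    @property
    def n_individuals(self) -> int:
        return len(self.values)

    def subset_individuals(self, idx) -> "TraitTable":
        idx = np.asarray(idx)
        return TraitTable(self.values.iloc[idx].reset_index(drop=True),
                          self.types,
                          self.covariates.iloc[idx].reset_index(drop=True),
                          self.direct_effects)

    def export(self, path) -> None:
        pd.concat([self.values, self.covariates], axis=1).to_csv(
            path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

_NONPALINDROMIC_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                         ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]
_PALINDROMIC_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]


def _ar_latent(rng: np.random.Generator, n: int, length: int, rho: float) -> np.ndarray:
    z = np.empty((n, length))
    z[:, 0] = rng.standard_normal(n)
    if length > 1:
        innov = rng.standard_normal((n, length - 1)) * np.sqrt(1.0 - rho ** 2)
        for k in range(1, length):
            z[:, k] = rho * z[:, k - 1] + innov[:, k - 1]
    return z


def simulate_genotypes(n: int, blocks: Sequence[Block], seed: int,
                       palindromic_fraction: float = 0.05) -> GenotypePanel:
    """Simulate HWE dosages with block-wise AR(rho) linkage disequilibrium.

    Each haplotype is an independent latent Gaussian AR(rho) draw per block,
    thresholded at the MAF quantile; the dosage is the sum of two haplotypes,
    so single-SNP genotypes follow Hardy–Weinberg proportions while
    within-block LD is governed by the latent correlation ``rho^|i-j|``.

    Blocks are laid out on chromosomes 1..22 (round robin unless a block
    pins ``chrom``), SNPs 1 kb apart within a block and blocks 5 Mb apart,
    so positions are strictly increasing within each chromosome.
    """
    if n < 2:
        raise ValueError("need at least 2 individuals")
    blocks = list(blocks)
    if not blocks:
        raise ValueError("need at least one block")
    rng = np.random.default_rng(seed)

    dosage_cols, meta_rows, structure = [], [], []
    next_pos: dict = {}
    start = 0
    for bi, block in enumerate(blocks):
        chrom = block.chrom if block.chrom is not None else (bi % 22) + 1
        if block.mafs is not None:
            mafs = np.asarray(block.mafs, dtype=float)
        else:
            mafs = rng.uniform(0.05, 0.5, size=block.n_snps)
        thresh = sps.norm.ppf(mafs)
        hap1 = _ar_latent(rng, n, block.n_snps, block.rho) < thresh
        hap2 = _ar_latent(rng, n, block.n_snps, block.rho) < thresh
        dosage_cols.append((hap1.astype(np.int8) + hap2.astype(np.int8)))

        pos0 = next_pos.get(chrom, 1_000_000)
        pos = pos0 + 1_000 * np.arange(block.n_snps)
        next_pos[chrom] = int(pos[-1]) + 5_000_000
        palindromic = rng.random(block.n_snps) < palindromic_fraction
        for j in range(block.n_snps):
            pair_pool = _PALINDROMIC_PAIRS if palindromic[j] else _NONPALINDROMIC_PAIRS
            ea, oa = pair_pool[rng.integers(len(pair_pool))]
            meta_rows.append((f"rs{start + j + 1}", chrom, int(pos[j]), ea, oa,
                              float(mafs[j]), bi))
        structure.append((start, block.n_snps, block.rho))
        start += block.n_snps

    meta = pd.DataFrame(meta_rows,
                        columns=["snp", "chr", "pos", "ea", "oa", "maf", "block"])
    return GenotypePanel(np.concatenate(dosage_cols, axis=1), meta, structure)


# ---------------------------------------------------------------------------
# traits
# ---------------------------------------------------------------------------

def _scaled_genetic_value(dosages: np.ndarray, idx: np.ndarray,
                          raw_effects: np.ndarray, target_var: float):
    """Linear genetic score over ``idx`` scaled to empirical variance
    ``target_var``; returns (score, dosage-scale effects)."""
    g = dosages[:, idx].astype(float)
    g -= g.mean(axis=0)
    score = g @ raw_effects
    sd = score.std()
    if sd == 0 or target_var == 0:
        return np.zeros(dosages.shape[0]), np.zeros(len(idx))
    scale = np.sqrt(target_var) / sd
    return score * scale, raw_effects * scale


def simulate_traits(panel: GenotypePanel, config: CausalConfig) -> TraitTable:
    """Generate the trait table along the causal DAG.

    Traits are built in topological order as direct-SNP genetics + causal
    contributions of upstream traits + confounder loading + covariate
    loadings + noise, then rescaled to unit variance (binary traits are
    liability-thresholded at the configured prevalence).  Raises if the
    systematic variance exceeds the unit budget.
    """
    rng = np.random.default_rng([config.seed, 1])
    n, m = panel.n_individuals, panel.n_snps
    order = config.topological_order()

    need = len(order) * config.n_snps_per_trait + (
        config.n_snps_per_trait if config.confounder_h2 > 0 else 0)
    if need > m:
        raise ValueError(f"panel has {m} SNPs, architecture needs {need}")
    pool = rng.permutation(m)
    assignments, cursor = {}, 0
    for trait in list(order) + [CONFOUNDER_ID]:
        if trait == CONFOUNDER_ID and config.confounder_h2 <= 0:
            continue
        assignments[trait] = np.sort(pool[cursor:cursor + config.n_snps_per_trait])
        cursor += config.n_snps_per_trait

    covariates = pd.DataFrame({
        "age": rng.standard_normal(n),
        "batch": rng.integers(0, 2, size=n).astype(float),
    })
    cov_part = sum(load * (covariates[name] - covariates[name].mean()).to_numpy()
                   for name, load in config.covariate_loadings.items())
    cov_var = float(np.var(cov_part)) if np.ndim(cov_part) else 0.0

    # shared heritable confounder (childhood body-size analogue)
    direct_effects: dict = {}
    if config.confounder_h2 > 0:
        idx = assignments[CONFOUNDER_ID]
        gscore, eff = _scaled_genetic_value(
            panel.dosages, idx, rng.standard_normal(len(idx)), config.confounder_h2)
        confounder = gscore + rng.standard_normal(n) * np.sqrt(1 - config.confounder_h2)
        confounder = (confounder - confounder.mean()) / confounder.std()
        direct_effects[CONFOUNDER_ID] = pd.Series(
            eff, index=panel.snp_meta["snp"].iloc[idx].to_numpy())
    else:
        confounder = np.zeros(n)

    values: dict = {}
    liabilities: dict = {}
    types = {t: (BINARY if t in config.binary_traits else CONTINUOUS)
             for t in config.trait_ids}

    for trait in order:
        h2 = float(config.h2.get(trait, 0.0))
        idx = assignments[trait]
        gscore, eff = _scaled_genetic_value(
            panel.dosages, idx, rng.standard_normal(len(idx)), h2)
        systematic = gscore.copy()
        for src, d in config.parents(trait).items():
            upstream = liabilities.get(src)
            if upstream is None:
                upstream = values[src].to_numpy(dtype=float)
            systematic = systematic + d * upstream
        gamma = float(config.confounder_gamma.get(trait, 0.0))
        systematic = systematic + gamma * confounder + cov_part

        plei = config.pleiotropy
        if plei is not None and plei.target_trait == trait:
            src_idx = assignments[plei.source_trait][:plei.n_snps]
            alpha = rng.normal(plei.effective_mean(), plei.sd_effect, len(src_idx))
            g = panel.dosages[:, src_idx].astype(float)
            systematic = systematic + (g - g.mean(axis=0)) @ alpha

        var_sys = float(systematic.var())
        if var_sys > 1.0 - 1e-9:
            raise ValueError(
                f"variance budget exceeded for {trait!r}: systematic variance "
                f"{var_sys:.3f} leaves no room for noise")
        y = systematic + rng.standard_normal(n) * np.sqrt(1.0 - var_sys)
        sd = y.std()
        y = (y - y.mean()) / sd
        eff = eff / sd

        if types[trait] == BINARY:
            prev = config.prevalence.get(trait)
            if prev is None:
                raise ValueError(f"binary trait {trait!r} needs a prevalence")
            liabilities[trait] = y
            tau = sps.norm.ppf(1.0 - prev)
            values[trait] = pd.Series((y > tau).astype(float))
        else:
            values[trait] = pd.Series(y)
        direct_effects[trait] = pd.Series(
            eff, index=panel.snp_meta["snp"].iloc[idx].to_numpy())

    frame = pd.DataFrame({t: values[t] for t in config.trait_ids})
    if config.missing_rate > 0:
        mask = rng.random(frame.shape) < config.missing_rate
        frame = frame.mask(mask)
    return TraitTable(frame, types, covariates, direct_effects)


# ---------------------------------------------------------------------------
# summary statistics
# ---------------------------------------------------------------------------

def true_marginal_betas(panel: GenotypePanel, traits: TraitTable,
                        trait_id: str) -> np.ndarray:
    """Empirical marginal per-SNP effects cov(g, y)/var(g) over the cohort
    (the large-sample truth the analytic emitter perturbs)."""
    y = traits.values[trait_id].to_numpy(dtype=float)
    ok = ~np.isnan(y)
    y = y[ok] - y[ok].mean()
    g = panel.dosages[ok].astype(float)
    g -= g.mean(axis=0)
    var = (g ** 2).mean(axis=0)
    var[var == 0] = np.nan
    return (g.T @ y) / len(y) / var


def emit_sumstats(panel: GenotypePanel, traits: Optional[TraitTable],
                  trait_id: str, mode: str = "analytic",
                  n_eff: Optional[int] = None, seed: int = 0,
                  beta_true: Optional[np.ndarray] = None) -> SummaryStats:
    """Emit summary statistics for one trait.

    ``analytic`` mode draws ``beta_hat ~ Normal(beta_true, se)`` with
    ``se = 1/sqrt(2*maf*(1-maf)*n_eff)`` (unit residual variance, the traits
    being unit-variance by construction); ``individual`` mode runs the
    per-SNP regressions of :func:`repromr.assoc.run_gwas`.
    """
    if traits is not None and trait_id not in traits.values.columns:
        raise ValueError(f"unknown trait id {trait_id!r}")
    if mode == "individual":
        from .assoc import run_gwas
        if traits is None:
            raise ValueError("individual mode needs a trait table")
        if n_eff is not None and n_eff < panel.n_individuals:
            rng = np.random.default_rng([seed, 2])
            idx = rng.choice(panel.n_individuals, size=n_eff, replace=False)
            panel, traits = panel.subset_individuals(idx), traits.subset_individuals(idx)
        return run_gwas(panel, traits, trait_id)
    if mode != "analytic":
        raise ValueError(f"unknown mode {mode!r}")
    if n_eff is None or n_eff < 10:
        raise ValueError("analytic mode needs n_eff >= 10")
    if beta_true is None:
        if traits is None:
            raise ValueError("analytic mode needs beta_true or a trait table")
        beta_true = true_marginal_betas(panel, traits, trait_id)
    beta_true = np.asarray(beta_true, dtype=float)
    if len(beta_true) != panel.n_snps:
        raise ValueError("beta_true length does not match the panel")

    rng = np.random.default_rng([seed, 3])
    meta = panel.snp_meta
    eaf = meta["maf"].to_numpy(dtype=float)
    se = 1.0 / np.sqrt(2.0 * eaf * (1.0 - eaf) * n_eff)
    beta_hat = beta_true + rng.standard_normal(panel.n_snps) * se
    table = build_table(meta["snp"], meta["chr"], meta["pos"], meta["ea"],
                        meta["oa"], eaf, beta_hat, se, n_eff)
    trait_type = CONTINUOUS
    if traits is not None:
        trait_type = traits.types.get(trait_id, CONTINUOUS)
    return SummaryStats(table, trait_id=trait_id, trait_type=trait_type)


def make_overlap_cohorts(panel: GenotypePanel, traits: TraitTable,
                         mode: str, seed: int = 0):
    """Exposure/outcome cohort index sets under the three overlap designs.

    ``full`` reuses the whole cohort for both sides; ``split`` partitions it
    into disjoint halves; ``none`` expects the caller to simulate a second
    independent cohort, so the exposure gets this cohort and the outcome an
    empty marker (index set disjoint by construction).
    """
    n = panel.n_individuals
    if mode == "full":
        idx = np.arange(n)
        return idx, idx
    if mode == "split":
        rng = np.random.default_rng([seed, 4])
        perm = rng.permutation(n)
        half = int(np.ceil(n / 2))
        return np.sort(perm[:half]), np.sort(perm[half:])
    if mode == "none":
        return np.arange(n), np.array([], dtype=int)
    raise ValueError(f"unknown overlap mode {mode!r}")
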