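"""Per-SNP association scans, standardisation and instrument selection.

The scan is a covariate-adjusted per-SNP regression: ordinary least squares
for continuous traits and logistic regression (log-odds per effect allele)
for binary traits, with two-sided Wald p-values.  Instrument selection
applies a genome-wide significance threshold followed by greedy LD clumping
against a reference genotype panel.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .simulate import GenotypePanel, TraitTable
from .sumstats import (BINARY, CONTINUOUS, UNITS_RAW, UNITS_SD, SummaryStats,
                       build_table)

logger = logging.getLogger(__name__)

GWS_THRESHOLD = 5e-8
CLUMP_R2 = 0.001
CLUMP_KB = 10_000.0


def rank_inverse_normal(values) -> np.ndarray:
    """Rank-based inverse normal (Blom) transform.

    Maps values to ``Phi^-1((rank - 3/8)/(n + 1/4))`` using average ranks for
    ties; missing values are preserved as NaN.  Used for heavily skewed
    traits such as lifetime number of sexual partners.
    """
    x = np.asarray(values, dtype=float)
    out = np.full(x.shape, np.nan)
    ok = ~np.isnan(x)
    n_ok = int(ok.sum())
    if n_ok == 0:
        raise ValueError("all values missing")
    if n_ok < 3:
        raise ValueError("need at least 3 non-missing values")
    ranks = sps.rankdata(x[ok], method="average")
    out[ok] = sps.norm.ppf((ranks - 0.375) / (n_ok + 0.25))
    return out


# ---------------------------------------------------------------------------
# per-SNP regressions
# ---------------------------------------------------------------------------

def _ols_scan(G: np.ndarray, y: np.ndarray, C: np.ndarray):
    """Vectorised per-SNP OLS with shared covariates.

    Residualises trait and dosages on the covariate design (Frisch–Waugh),
    then fits the per-SNP slope; equivalent to the joint per-SNP model.
    """
    n, m = G.shape
    Q, _ = np.linalg.qr(C)
    y_r = y - Q @ (Q.T @ y)
    G_r = G - Q @ (Q.T @ G)
    den = (G_r ** 2).sum(axis=0)
    mono = den <= 1e-12
    den[mono] = np.nan
    num = G_r.T @ y_r
    beta = num / den
    df = n - C.shape[1] - 1
    rss = (y_r ** 2).sum() - beta ** 2 * den
    sigma2 = np.clip(rss, 0.0, None) / df
    se = np.sqrt(sigma2 / den)
    return beta, se, mono


def _logistic_scan(G: np.ndarray, y: np.ndarray, C: np.ndarray,
                   max_iter: int = 30, tol: float = 1e-8,
                   chunk: int = 256):
    """Vectorised per-SNP logistic regression (Newton–Raphson).

    Each SNP gets its own model [intercept, dosage, covariates]; the solver
    runs all SNPs in a chunk simultaneously with per-SNP (p x p) solves.
    Returns (beta, se, failed) where beta is the log-odds per effect allele.
    """
    n, m = G.shape
    X_fixed = np.column_stack([np.ones(n), C[:, 1:]]) if C.shape[1] > 1 \
        else np.ones((n, 1))
    p = X_fixed.shape[1] + 1
    beta_out = np.full(m, np.nan)
    se_out = np.full(m, np.nan)
    failed = np.zeros(m, dtype=bool)

    base_rate = np.clip(y.mean(), 1e-6, 1 - 1e-6)
    for lo in range(0, m, chunk):
        hi = min(lo + chunk, m)
        g = G[:, lo:hi]
        c = g.shape[1]
        # parameter layout per SNP: [intercept, snp, covariates...]
        b = np.zeros((c, p))
        b[:, 0] = np.log(base_rate / (1 - base_rate))
        cols = [np.ones(n), None] + [X_fixed[:, j] for j in range(1, X_fixed.shape[1])]
        for _ in range(max_iter):
            eta = b[:, 0][None, :] + g * b[:, 1][None, :]
            for j in range(2, p):
                eta = eta + np.outer(cols[j], b[:, j])
            eta = np.clip(eta, -30, 30)
            mu = 1.0 / (1.0 + np.exp(-eta))
            w = mu * (1.0 - mu)
            resid = y[:, None] - mu
            grad = np.empty((c, p))
            hess = np.empty((c, p, p))
            feats = [np.ones((n, 1)), g] + [cols[j][:, None] for j in range(2, p)]
            for a in range(p):
                grad[:, a] = (np.broadcast_to(feats[a], (n, c)) * resid).sum(axis=0)
                for bb in range(a, p):
                    h = (np.broadcast_to(feats[a], (n, c)) *
                         np.broadcast_to(feats[bb], (n, c)) * w).sum(axis=0)
                    hess[:, a, bb] = h
                    hess[:, bb, a] = h
            try:
                step = np.linalg.solve(hess, grad[:, :, None])[:, :, 0]
            except np.linalg.LinAlgError:
                step = np.full((c, p), np.nan)
            b = b + np.clip(step, -5, 5)
            if np.nanmax(np.abs(step)) < tol:
                break
        with np.errstate(invalid="ignore"):
            try:
                cov = np.linalg.inv(hess)
                se_chunk = np.sqrt(cov[:, 1, 1])
            except np.linalg.LinAlgError:
                se_chunk = np.full(c, np.nan)
        beta_out[lo:hi] = b[:, 1]
        se_out[lo:hi] = se_chunk
    failed = ~np.isfinite(beta_out) | ~np.isfinite(se_out) | (se_out <= 0) \
        | (se_out > 100)
    return beta_out, se_out, failed


def run_gwas(panel: GenotypePanel, traits: TraitTable, trait_id: str,
             covariates=("age", "batch")) -> SummaryStats:
    """Per-SNP association scan with listwise deletion of missing data.

    Continuous traits: OLS of trait on dosage + covariates.  Binary traits:
    logistic regression, beta = log-odds.  Monomorphic or non-converged SNPs
    are excluded with a logged count.
    """
    if trait_id not in traits.values.columns:
        raise ValueError(f"unknown trait id {trait_id!r}")
    y = traits.values[trait_id].to_numpy(dtype=float)
    cov = traits.covariates.loc[:, list(covariates)].to_numpy(dtype=float) \
        if covariates else np.empty((len(y), 0))
    ok = ~np.isnan(y)
    if cov.size:
        ok &= ~np.isnan(cov).any(axis=1)
    y_use, cov_use = y[ok], cov[ok]
    G = panel.dosages[ok].astype(float)
    C = np.column_stack([np.ones(ok.sum()), cov_use])

    trait_type = traits.types.get(trait_id, CONTINUOUS)
    if trait_type == BINARY:
        beta, se, bad = _logistic_scan(G, y_use, C)
    else:
        beta, se, bad = _ols_scan(G, y_use, C)
    eaf = G.mean(axis=0) / 2.0
    bad |= (eaf <= 0) | (eaf >= 1)
    if bad.any():
        logger.info("run_gwas(%s): excluded %d SNP(s) (monomorphic or "
                    "non-converged)", trait_id, int(bad.sum()))
    keep = ~bad
    meta = panel.snp_meta.loc[keep]
    table = build_table(meta["snp"], meta["chr"], meta["pos"], meta["ea"],
                        meta["oa"], eaf[keep], beta[keep], se[keep],
                        int(ok.sum()))
    return SummaryStats(table, trait_id=trait_id, trait_type=trait_type)


# ---------------------------------------------------------------------------
# standardisation
# ---------------------------------------------------------------------------

def standardise_sumstats(stats: SummaryStats,
                         trait_sd: float | None = None) -> SummaryStats:
    """Rescale effect estimates to SD units of the trait.

    With ``trait_sd`` given, divides beta and se by it.  Without it, uses the
    summary-only approximation from the z statistic and allele frequency::

        beta_sd = z / sqrt(2*eaf*(1-eaf)*(n + z^2))
        se_sd   = 1 / sqrt(2*eaf*(1-eaf)*(n + z^2))

    Standardising already-standardised statistics is a no-op with a warning.
    """
    if stats.trait_type != CONTINUOUS:
        raise ValueError("standardisation applies to continuous traits only")
    if stats.units == UNITS_SD:
        warnings.warn("summary statistics already standardised; no-op",
                      stacklevel=2)
        return SummaryStats(stats.table.copy(), stats.trait_id,
                            stats.trait_type, UNITS_SD)
    t = stats.table.copy()
    if trait_sd is not None:
        if trait_sd <= 0:
            raise ValueError("trait_sd must be positive")
        t["beta"] = t["beta"] / trait_sd
        t["se"] = t["se"] / trait_sd
    else:
        z = t["beta"].to_numpy() / t["se"].to_numpy()
        denom = np.sqrt(2.0 * t["eaf"] * (1.0 - t["eaf"]) *
                        (t["n"] + z ** 2))
        t["beta"] = z / denom
        t["se"] = 1.0 / denom
    return SummaryStats(t, stats.trait_id, stats.trait_type, UNITS_SD)


# ---------------------------------------------------------------------------
# instrument selection
# ---------------------------------------------------------------------------

@dataclass
class InstrumentSet:
    """Genome-wide significant, LD-clumped instruments for one trait."""

    trait_id: str
    table: pd.DataFrame          # snp chr pos p r2_contrib
    p_threshold: float
    clump_r2: float
    clump_kb: float
    status: str = "ok"           # or "empty"

    @property
    def snps(self) -> list:
        return list(self.table["snp"])

    @property
    def k(self) -> int:
        return len(self.table)

    @property
    def r2_total(self) -> float:
        return float(self.table["r2_contrib"].sum())

    def write_tsv(self, path) -> None:
        self.table.loc[:, ["snp", "p", "r2_contrib"]].to_csv(
            path, sep="\t", index=False)


def select_instruments(stats: SummaryStats, ld_source: GenotypePanel,
                       p_threshold: float = GWS_THRESHOLD,
                       clump_r2: float = CLUMP_R2,
                       clump_kb: float = CLUMP_KB) -> InstrumentSet:
    """Threshold at genome-wide significance, then greedy LD clumping.

    Surviving SNPs are visited in ascending p order (ties broken by genomic
    coordinate); each accepted index SNP removes unaccepted SNPs on the same
    chromosome within ``clump_kb`` kb whose reference-panel r2 with it is at
    least ``clump_r2``.  Per-SNP variance contribution is ``z^2/(z^2 + n)``
    (the standardised-effect identity ``2*eaf*(1-eaf)*beta_sd^2``).
    """
    t = stats.table
    surviving = t.loc[t["p"] < p_threshold].copy()
    if surviving.empty:
        empty = pd.DataFrame(columns=["snp", "chr", "pos", "p", "r2_contrib"])
        return InstrumentSet(stats.trait_id, empty, p_threshold, clump_r2,
                             clump_kb, status="empty")
    surviving = surviving.sort_values(["p", "chr", "pos"],
                                      kind="mergesort").reset_index(drop=True)
    idx_in_panel = ld_source.snp_indices(surviving["snp"])
    if (idx_in_panel < 0).any():
        raise ValueError("instrument candidates missing from the LD reference")
    r2 = ld_source.ld_r2(idx_in_panel)

    chrom = surviving["chr"].to_numpy()
    pos = surviving["pos"].to_numpy(dtype=float)
    alive = np.ones(len(surviving), dtype=bool)
    accepted = []
    for i in range(len(surviving)):
        if not alive[i]:
            continue
        accepted.append(i)
        near = (chrom == chrom[i]) & (np.abs(pos - pos[i]) <= clump_kb * 1_000)
        hit = near & (r2[i] >= clump_r2)
        hit[i] = False
        alive &= ~hit
    kept = surviving.iloc[accepted].copy()
    z = kept["beta"].to_numpy() / kept["se"].to_numpy()
    kept["r2_contrib"] = z ** 2 / (z ** 2 + kept["n"].to_numpy(dtype=float))
    kept = kept.loc[:, ["snp", "chr", "pos", "p", "r2_contrib"]]
    return InstrumentSet(stats.trait_id, kept.reset_index(drop=True),
                         p_threshold, clump_r2, clump_kb)


def split_cohort(panel: GenotypePanel, traits: TraitTable, seed: int):
    """Random disjoint halves (sizes ceil(n/2), floor(n/2)); deterministic
    under seed."""
    n = panel.n_individuals
    if n < 4:
        raise ValueError("need at least 4 individuals to split")
    rng = np.random.default_rng([seed, 5])
    perm = rng.permutation(n)
    half = int(np.ceil(n / 2))
    a, b = np.sort(perm[:half]), np.sort(perm[half:])
    return ((panel.subset_individuals(a), traits.subset_individuals(a)),
            (panel.subset_individuals(b), traits.subset_individuals(b)))
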