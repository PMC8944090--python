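"""LD score regression: LD scores, munging, SNP heritability and genetic
correlation.

The regression model for one trait is ``E[chi2_j] = intercept + N*h2*l_j/M``
with the intercept absorbing confounding; for two traits it is
``E[z1_j z2_j] = intercept + sqrt(N1*N2)*rho_g*l_j/M`` with the free
intercept absorbing sample overlap (expected value
``n_overlap * pheno_corr / sqrt(N1*N2)``).  Fits use two-pass
heteroskedasticity weights and block-jackknife standard errors over
position-contiguous SNP blocks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .simulate import GenotypePanel
from .sumstats import SummaryStats, is_palindromic, COMPLEMENT

# chr6:26-34 Mb (1-based, inclusive): the extended MHC region, excluded
# because its long-range LD distorts the regression.
DEFAULT_EXCLUSION_REGIONS = ((6, 26_000_000, 34_000_000),)

DEFAULT_N_BLOCKS = 200
MIN_SNPS_PER_BLOCK = 10
MIN_REGRESSION_SNPS = 200


@dataclass
class LDScoreTable:
    """Per-SNP LD scores plus the reference SNP list used for munging."""

    table: pd.DataFrame      # snp chr pos l2
    ref: pd.DataFrame        # snp ea oa  (reference orientation)
    n_ref: int
    M: int

    def write_tsv(self, path) -> None:
        self.table.loc[:, ["snp", "chr", "pos", "l2"]].to_csv(
            path, sep="\t", index=False)

    def write_reference_snplist(self, path) -> None:
        """Plain SNP-id list so an external reference (e.g. HapMap3) can be
        swapped in."""
        self.ref.to_csv(path, sep="\t", index=False)


@dataclass
class H2Result:
    h2: float
    h2_se: float
    intercept: float
    intercept_se: float
    M: int
    n_blocks: int


@dataclass
class GeneticCorrelationResult:
    rg: float
    rg_se: float
    rho_g: float
    h2_1: float
    h2_1_se: float
    h2_2: float
    h2_2_se: float
    intercept_1: float
    intercept_2: float
    intercept_biv: float
    intercept_biv_se: float
    expected_intercept_biv: float
    M: int
    n_blocks: int
    defined: bool = True
    note: str = ""


def compute_ld_scores(panel: GenotypePanel, window_kb: float = 1000.0,
                      chunk: int = 512) -> LDScoreTable:
    """LD scores from a reference panel.

    ``l_j = sum_k r2_adj(j, k)`` over SNPs within ``window_kb`` on the same
    chromosome, with the small-sample adjustment
    ``r2_adj = r2 - (1 - r2)/(n_ref - 2)`` and the self term included
    (adjustment vanishes at r2 = 1).
    """
    if window_kb <= 0:
        raise ValueError("window_kb must be positive")
    n_ref = panel.n_individuals
    if n_ref < 50:
        raise ValueError("reference panel needs at least 50 individuals")
    meta = panel.snp_meta
    l2 = np.zeros(panel.n_snps)
    window = window_kb * 1_000
    for chrom in meta["chr"].unique():
        idx = np.flatnonzero((meta["chr"] == chrom).to_numpy())
        X = panel.dosages[:, idx].astype(float)
        X -= X.mean(axis=0)
        sd = X.std(axis=0)
        sd[sd == 0] = np.nan
        X /= sd
        pos = meta["pos"].to_numpy()[idx].astype(float)
        for lo in range(0, len(idx), chunk):
            hi = min(lo + chunk, len(idx))
            r = (X[:, lo:hi].T @ X) / n_ref
            r2 = r ** 2
            r2_adj = r2 - (1.0 - r2) / (n_ref - 2)
            in_window = np.abs(pos[lo:hi, None] - pos[None, :]) <= window
            l2[idx[lo:hi]] = np.where(in_window, r2_adj, 0.0).sum(axis=1)
    table = meta.loc[:, ["snp", "chr", "pos"]].copy()
    table["l2"] = l2
    ref = meta.loc[:, ["snp", "ea", "oa"]].copy()
    return LDScoreTable(table, ref, n_ref=n_ref, M=panel.n_snps)


def munge(stats: SummaryStats, reference: LDScoreTable,
          exclusion_regions=DEFAULT_EXCLUSION_REGIONS) -> pd.DataFrame:
    """Convert summary statistics to an aligned z-score table.

    Intersects with the reference SNP list, drops strand-ambiguous (A/T,
    G/C) SNPs and SNPs in the exclusion regions (default chr6:26-34 Mb),
    aligns the z sign to the reference effect allele, and returns a
    ``(snp, z, n)`` DataFrame.
    """
    t = stats.table.merge(reference.ref, on="snp", suffixes=("", "_ref"))
    if t.empty:
        raise ValueError("no overlap between summary statistics and reference")
    keep = ~t.apply(lambda r: is_palindromic(r["ea"], r["oa"]), axis=1)
    t = t.loc[keep]
    for (chrom, lo, hi) in exclusion_regions:
        t = t.loc[~((t["chr"] == chrom) & (t["pos"] >= lo) & (t["pos"] <= hi))]
    if t.empty:
        raise ValueError("no SNPs left after munging filters")

    sign = np.zeros(len(t))
    ea, oa = t["ea"].to_numpy(), t["oa"].to_numpy()
    ear, oar = t["ea_ref"].to_numpy(), t["oa_ref"].to_numpy()
    comp = np.vectorize(COMPLEMENT.get)
    same = (ea == ear) & (oa == oar)
    swap = (ea == oar) & (oa == ear)
    same_c = (comp(ea) == ear) & (comp(oa) == oar)
    swap_c = (comp(ea) == oar) & (comp(oa) == ear)
    sign[same | same_c] = 1.0
    sign[(swap | swap_c) & ~(same | same_c)] = -1.0
    t = t.loc[sign != 0].copy()
    sign = sign[sign != 0]
    if t.empty:
        raise ValueError("no SNPs with resolvable alleles after munging")
    z = sign * t["beta"].to_numpy() / t["se"].to_numpy()
    return pd.DataFrame({"snp": t["snp"].to_numpy(), "z": z,
                         "n": t["n"].to_numpy()})


# ---------------------------------------------------------------------------
# regression machinery
# ---------------------------------------------------------------------------

def _wls(y: np.ndarray, x: np.ndarray, w: np.ndarray):
    """Weighted least squares of y on [1, x]; returns (intercept, slope)."""
    X = np.column_stack([np.ones(len(x)), x])
    Xw = X * w[:, None]
    coef = np.linalg.solve(X.T @ Xw, Xw.T @ y)
    return float(coef[0]), float(coef[1])


def _contiguous_blocks(m: int, n_blocks: int) -> np.ndarray:
    """Block labels for position-ordered SNPs, near-equal sizes."""
    return np.repeat(np.arange(n_blocks),
                     np.diff(np.linspace(0, m, n_blocks + 1).astype(int)))


def _choose_n_blocks(m: int, requested: int = DEFAULT_N_BLOCKS) -> int:
    b = min(requested, m // MIN_SNPS_PER_BLOCK)
    if b < 2:
        raise ValueError("too few SNPs for a block jackknife (need >= 2 blocks)")
    return b


def _jackknife(y, x, w, blocks, n_blocks):
    """Delete-a-block WLS estimates; returns (B, 2) array of
    (intercept, slope)."""
    out = np.empty((n_blocks, 2))
    for b in range(n_blocks):
        keep = blocks != b
        out[b] = _wls(y[keep], x[keep], w[keep])
    return out


def _jackknife_se(estimates: np.ndarray) -> np.ndarray:
    B = estimates.shape[0]
    mean = estimates.mean(axis=0)
    return np.sqrt((B - 1) / B * ((estimates - mean) ** 2).sum(axis=0))


def _h2_weights(l2, N, M, h2_0, icpt_0):
    h2c = float(np.clip(h2_0, 0.0, 1.0))
    ic = max(float(icpt_0), 0.0)
    pred = np.maximum(ic + N * h2c * l2 / M, 0.1)
    return 1.0 / (np.maximum(l2, 1.0) * 2.0 * pred ** 2)


def _prepare(ztab: pd.DataFrame, ld: LDScoreTable):
    merged = ztab.merge(ld.table, on="snp")
    if len(merged) < MIN_REGRESSION_SNPS:
        raise ValueError(f"need >= {MIN_REGRESSION_SNPS} regression SNPs, "
                         f"have {len(merged)}")
    merged = merged.sort_values(["chr", "pos"]).reset_index(drop=True)
    l2 = merged["l2"].to_numpy(dtype=float)
    if np.ptp(l2) < 1e-12:
        raise ValueError("degenerate LD scores (no variation): slope "
                         "unidentifiable")
    return merged, l2


def ldsc_h2(ztab: pd.DataFrame, ld: LDScoreTable,
            N: Optional[float] = None,
            n_blocks: int = DEFAULT_N_BLOCKS,
            chi2_max: Optional[float] = None) -> H2Result:
    """SNP heritability by LD score regression with two-pass weights.

    The first pass initialises h2 from an unweighted fit; the second uses
    heteroskedasticity weights ``1/(2*(intercept + N*h2*l/M)^2) * 1/l``.
    SEs come from a delete-a-block jackknife over position-contiguous
    blocks.  ``chi2_max`` optionally winsorises chi-square values (common
    practice is ``max(80, 0.001*N)``; off by default).
    """
    merged, l2 = _prepare(ztab, ld)
    if N is None:
        N = float(np.median(merged["n"]))
    chi2 = merged["z"].to_numpy(dtype=float) ** 2
    if chi2_max is not None:
        chi2 = np.minimum(chi2, chi2_max)
    M = ld.M
    x = N * l2 / M

    icpt0, h2_0 = _wls(chi2, x, np.ones_like(x))
    w = _h2_weights(l2, N, M, h2_0, icpt0)
    icpt, h2 = _wls(chi2, x, w)

    B = _choose_n_blocks(len(l2), n_blocks)
    blocks = _contiguous_blocks(len(l2), B)
    jk = _jackknife(chi2, x, w, blocks, B)
    se = _jackknife_se(jk)
    return H2Result(h2=h2, h2_se=float(se[1]), intercept=icpt,
                    intercept_se=float(se[0]), M=M, n_blocks=B)


def ldsc_rg(z1: pd.DataFrame, z2: pd.DataFrame, ld: LDScoreTable,
            N1: Optional[float] = None, N2: Optional[float] = None,
            n_overlap: float = 0.0, pheno_corr: float = 0.0,
            n_blocks: int = DEFAULT_N_BLOCKS) -> GeneticCorrelationResult:
    """Cross-trait LD score regression for the genetic correlation.

    Regresses ``z1*z2`` on LD scores; the slope scales with the genetic
    covariance ``rho_g`` and the free intercept absorbs sample overlap.
    ``rg = rho_g / sqrt(h2_1 * h2_2)``; the SE jackknifes the entire
    pipeline (both heritabilities and the cross slope) over shared blocks.
    The computation is exactly symmetric in the two traits.
    """
    shared = z1.merge(z2, on="snp", suffixes=("_1", "_2"))
    if len(shared) < MIN_REGRESSION_SNPS:
        raise ValueError(f"traits share fewer than {MIN_REGRESSION_SNPS} SNPs")
    merged, l2 = _prepare(shared.rename(columns={"z_1": "z", "n_1": "n"})
                          .loc[:, ["snp", "z", "n"]], ld)
    merged = merged.merge(shared.loc[:, ["snp", "z_2", "n_2"]], on="snp")
    za = merged["z"].to_numpy(dtype=float)
    zb = merged["z_2"].to_numpy(dtype=float)
    if N1 is None:
        N1 = float(np.median(merged["n"]))
    if N2 is None:
        N2 = float(np.median(merged["n_2"]))
    M = ld.M
    x1, x2 = N1 * l2 / M, N2 * l2 / M
    xc = np.sqrt(N1 * N2) * l2 / M

    # univariate fits (two-pass weights)
    fits = []
    for z, x, N in ((za, x1, N1), (zb, x2, N2)):
        i0, s0 = _wls(z ** 2, x, np.ones_like(x))
        w = _h2_weights(l2, N, M, s0, i0)
        fits.append((_wls(z ** 2, x, w), w))
    (icpt1, h2_1), w1 = fits[0]
    (icpt2, h2_2), w2 = fits[1]

    # cross regression, two-pass
    y = za * zb
    ic0, rho0 = _wls(y, xc, np.ones_like(xc))
    pred1 = np.maximum(max(icpt1, 0.0) + N1 * np.clip(h2_1, 0, 1) * l2 / M, 0.1)
    pred2 = np.maximum(max(icpt2, 0.0) + N2 * np.clip(h2_2, 0, 1) * l2 / M, 0.1)
    predc = ic0 + np.sqrt(N1 * N2) * np.clip(rho0, -1, 1) * l2 / M
    wc = 1.0 / (np.maximum(l2, 1.0) * (pred1 * pred2 + predc ** 2))
    icpt_c, rho_g = _wls(y, xc, wc)

    defined = h2_1 > 0 and h2_2 > 0
    rg = rho_g / np.sqrt(h2_1 * h2_2) if defined else np.nan

    B = _choose_n_blocks(len(l2), n_blocks)
    blocks = _contiguous_blocks(len(l2), B)
    jk1 = _jackknife(za ** 2, x1, w1, blocks, B)
    jk2 = _jackknife(zb ** 2, x2, w2, blocks, B)
    jkc = _jackknife(y, xc, wc, blocks, B)
    se1, se2, sec = _jackknife_se(jk1), _jackknife_se(jk2), _jackknife_se(jkc)
    with np.errstate(invalid="ignore"):
        prod = jk1[:, 1] * jk2[:, 1]
        rg_blocks = np.where(prod > 0, jkc[:, 1] / np.sqrt(np.abs(prod)), np.nan)
    if defined and np.isfinite(rg_blocks).all():
        rg_se = float(_jackknife_se(rg_blocks[:, None])[0])
    else:
        rg_se = np.nan

    expected_icpt = (n_overlap * pheno_corr / np.sqrt(N1 * N2)
                     if N1 > 0 and N2 > 0 else 0.0)
    return GeneticCorrelationResult(
        rg=float(rg), rg_se=rg_se, rho_g=float(rho_g),
        h2_1=float(h2_1), h2_1_se=float(se1[1]),
        h2_2=float(h2_2), h2_2_se=float(se2[1]),
        intercept_1=float(icpt1), intercept_2=float(icpt2),
        intercept_biv=float(icpt_c), intercept_biv_se=float(sec[0]),
        expected_intercept_biv=float(expected_icpt), M=M, n_blocks=B,
        defined=bool(defined),
        note="" if defined else "h2 estimate non-positive; rg undefined")
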