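"""Harmonisation and the primary two-sample MR estimator suite.

The estimand is the effect (SD units, or log-odds for a binary outcome) of a
one-SD change in the exposure on the outcome, identified through genetic
instruments.  Per-SNP Wald ratios (SNP-outcome over SNP-exposure effect) are
combined by inverse-variance weighting under a multiplicative random-effects
model; MR-Egger, the weighted median and the weighted mode probe horizontal
pleiotropy, with SIMEX correcting Egger's regression-dilution bias when the
NOME assumption is weak (I2_GX < 90%).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .sumstats import SummaryStats, is_palindromic, COMPLEMENT

Z95 = 1.959963984540054

HARMONISED_COLUMNS = ["snp", "beta_exp", "se_exp", "beta_out", "se_out",
                      "eaf_exp", "eaf_out", "action"]

# minimum instrument counts per method
MIN_K = {"IVW": 2, "MR-Egger": 3, "Weighted median": 3, "Weighted mode": 3,
         "MR-Egger (SIMEX)": 3, "MR-PRESSO": 4}

SIMEX_I2_THRESHOLD = 0.90


@dataclass
class HarmonisedSet:
    """Exposure/outcome effect pairs on a common effect-allele orientation."""

    table: pd.DataFrame
    exposure: str
    outcome: str
    audit: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["snp", "action", "reason"]))
    note: str = ""

    def __post_init__(self) -> None:
        missing = [c for c in HARMONISED_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"harmonised table missing columns: {missing}")
        self.table = self.table.loc[:, HARMONISED_COLUMNS].reset_index(drop=True)
        if (self.table["se_exp"] <= 0).any() or (self.table["se_out"] <= 0).any():
            raise ValueError("non-positive standard errors in harmonised set")

    @property
    def k(self) -> int:
        return len(self.table)

    def arrays(self):
        t = self.table
        return (t["beta_exp"].to_numpy(dtype=float),
                t["se_exp"].to_numpy(dtype=float),
                t["beta_out"].to_numpy(dtype=float),
                t["se_out"].to_numpy(dtype=float))

    def subset(self, snps) -> "HarmonisedSet":
        keep = self.table["snp"].isin(set(snps))
        return replace(self, table=self.table.loc[keep].reset_index(drop=True))

    def write_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


@dataclass
class MRResult:
    """One exposure->outcome estimate with its diagnostics."""

    method: str
    exposure: str = ""
    outcome: str = ""
    estimate: float = np.nan
    se: float = np.nan
    ci_low: float = np.nan
    ci_high: float = np.nan
    p: float = np.nan
    nsnp: int = 0
    q: float = np.nan
    q_df: int = 0
    q_p: float = np.nan
    egger_intercept: float = np.nan
    egger_intercept_se: float = np.nan
    egger_intercept_p: float = np.nan
    i2_gx: float = np.nan
    notes: str = ""

    @property
    def skipped(self) -> bool:
        return "skipped" in self.notes

    def odds_ratio(self):
        """Exponentiated estimate/CI for binary-outcome (log-odds) results."""
        return (np.exp(self.estimate), np.exp(self.ci_low), np.exp(self.ci_high))

    def to_row(self) -> dict:
        return {"exposure": self.exposure, "outcome": self.outcome,
                "method": self.method, "nsnp": self.nsnp, "b": self.estimate,
                "se": self.se, "lo_ci": self.ci_low, "up_ci": self.ci_high,
                "p": self.p}


def _skipped(method: str, exposure: str, outcome: str, k: int) -> MRResult:
    return MRResult(method=method, exposure=exposure, outcome=outcome, nsnp=k,
                    notes=f"skipped: needs >= {MIN_K[method]} SNPs, have {k}")


def _finish(res: MRResult) -> MRResult:
    res.ci_low = res.estimate - Z95 * res.se
    res.ci_high = res.estimate + Z95 * res.se
    res.p = float(2.0 * sps.norm.sf(abs(res.estimate) / res.se)) \
        if res.se > 0 else np.nan
    return res


# ---------------------------------------------------------------------------
# harmonisation
# ---------------------------------------------------------------------------

def harmonise(exposure: SummaryStats, outcome: SummaryStats,
              palindrome_eaf_window: float = 0.08) -> HarmonisedSet:
    """Align outcome effects to the exposure's effect allele.

    Inner-joins on SNP id.  Swapped outcome alleles flip the outcome beta
    and complement its frequency; strand flips are resolved by base
    complementation.  Palindromic (A/T, G/C) SNPs are first letter-aligned,
    then kept only when both allele frequencies are outside
    ``0.5 +/- palindrome_eaf_window`` and on the same side; otherwise
    dropped.  Every action is recorded in the audit list.
    """
    merged = exposure.table.merge(outcome.table, on="snp",
                                  suffixes=("_exp", "_out"))
    if merged.empty:
        raise ValueError("exposure and outcome share no SNPs")
    w = palindrome_eaf_window
    rows, audit = [], []
    for r in merged.itertuples(index=False):
        ea_e, oa_e = r.ea_exp, r.oa_exp
        ea_o, oa_o = r.ea_out, r.oa_out
        beta_o, eaf_o = r.beta_out, r.eaf_out
        if is_palindromic(ea_e, oa_e):
            if {ea_o, oa_o} != {ea_e, oa_e}:
                action, reason = "dropped_mismatch", "allele sets differ"
            else:
                flip = ea_o == oa_e
                eaf_adj = 1.0 - eaf_o if flip else eaf_o
                inferable = (abs(r.eaf_exp - 0.5) > w and
                             abs(eaf_adj - 0.5) > w and
                             (r.eaf_exp - 0.5) * (eaf_adj - 0.5) > 0)
                if inferable:
                    action = "flipped" if flip else "kept"
                    if flip:
                        beta_o, eaf_o = -beta_o, 1.0 - eaf_o
                    reason = "palindrome aligned by eaf"
                else:
                    action, reason = "dropped_palindromic", \
                        "ambiguous palindrome (eaf near 0.5 or discordant)"
        else:
            candidates = {
                (ea_e, oa_e): False, (oa_e, ea_e): True,
                (COMPLEMENT[ea_e], COMPLEMENT[oa_e]): False,
                (COMPLEMENT[oa_e], COMPLEMENT[ea_e]): True,
            }
            if (ea_o, oa_o) in candidates:
                flip = candidates[(ea_o, oa_o)]
                action = "flipped" if flip else "kept"
                reason = ""
                if flip:
                    beta_o, eaf_o = -beta_o, 1.0 - eaf_o
            else:
                action, reason = "dropped_mismatch", \
                    "alleles not resolvable by swap/complement"
        audit.append((r.snp, action, reason))
        if action in ("kept", "flipped"):
            rows.append((r.snp, r.beta_exp, r.se_exp, beta_o, r.se_out,
                         r.eaf_exp, eaf_o, action))
    table = pd.DataFrame(rows, columns=HARMONISED_COLUMNS)
    audit_df = pd.DataFrame(audit, columns=["snp", "action", "reason"])
    return HarmonisedSet(table, exposure.trait_id, outcome.trait_id, audit_df)


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------

def wald_ratios(h: HarmonisedSet):
    """Per-SNP causal estimates: ratio = beta_out/beta_exp with the
    first-order delta-method SE ``se_out/|beta_exp|``.  SNPs with a zero
    exposure beta are excluded."""
    bx, sx, by, sy = h.arrays()
    ok = bx != 0
    ratio = by[ok] / bx[ok]
    se = sy[ok] / np.abs(bx[ok])
    return ratio, se, h.table["snp"].to_numpy()[ok]


def mr_ivw(h: HarmonisedSet) -> MRResult:
    """Inverse-variance-weighted estimate (multiplicative random effects).

    Weighted regression of outcome on exposure betas through the origin with
    weights ``1/se_out^2``; the SE is inflated by ``max(1, sqrt(Q/(k-1)))``
    so over-dispersion widens, but never narrows, the fixed-effect SE.
    """
    bx, sx, by, sy = h.arrays()
    k = h.k
    if k < MIN_K["IVW"]:
        return _skipped("IVW", h.exposure, h.outcome, k)
    w = 1.0 / sy ** 2
    sxx = float(np.sum(w * bx ** 2))
    est = float(np.sum(w * bx * by)) / sxx
    se_fixed = 1.0 / np.sqrt(sxx)
    q, q_df, q_p, _ = cochran_q(h, est)
    scale = max(1.0, np.sqrt(q / (k - 1))) if k > 1 else 1.0
    res = MRResult(method="IVW", exposure=h.exposure, outcome=h.outcome,
                   estimate=est, se=se_fixed * scale, nsnp=k,
                   q=q, q_df=q_df, q_p=q_p)
    return _finish(res)


def cochran_q(h: HarmonisedSet, ivw_estimate: float):
    """Heterogeneity of the per-SNP Wald ratios around the IVW estimate.

    ``Q = sum w_i (ratio_i - estimate)^2`` with ``w_i = se_ratio_i^-2``;
    Q above k-1 flags heterogeneity (invalid instruments / pleiotropy).
    """
    if h.k < 2:
        raise ValueError("Cochran's Q needs at least 2 SNPs")
    ratio, se_ratio, _ = wald_ratios(h)
    w = 1.0 / se_ratio ** 2
    q = float(np.sum(w * (ratio - ivw_estimate) ** 2))
    df = len(ratio) - 1
    p = float(sps.chi2.sf(q, df))
    return q, df, p, q > df


def _egger_orient(h: HarmonisedSet):
    bx, sx, by, sy = h.arrays()
    ok = bx != 0
    s = np.sign(bx[ok])
    return np.abs(bx[ok]), sx[ok], s * by[ok], sy[ok]


def _weighted_with_intercept(bx, by, w):
    X = np.column_stack([np.ones(len(bx)), bx])
    XtWX = X.T @ (X * w[:, None])
    coef = np.linalg.solve(XtWX, X.T @ (w * by))
    cov_unscaled = np.linalg.inv(XtWX)
    resid = by - X @ coef
    q = float(np.sum(w * resid ** 2))
    return coef, cov_unscaled, q


def i2_gx(h: HarmonisedSet) -> float:
    """NOME diagnostic for MR-Egger: heterogeneity of the (oriented)
    exposure betas weighted by exposure precision.  Values below 0.90 call
    for SIMEX correction."""
    bx, sx, _, _ = _egger_orient(h)
    w = 1.0 / sx ** 2
    mean = np.sum(w * bx) / np.sum(w)
    q_gx = float(np.sum(w * (bx - mean) ** 2))
    k = len(bx)
    if q_gx <= 0:
        return 0.0
    return max(0.0, (q_gx - (k - 1)) / q_gx)


def mr_egger(h: HarmonisedSet) -> MRResult:
    """MR-Egger regression: weighted fit of outcome on exposure betas WITH
    an intercept (rows oriented to positive exposure effects).

    The intercept estimates average directional pleiotropy; the slope is the
    bias-adjusted causal estimate under the InSIDE assumption.  SEs carry
    the same multiplicative over-dispersion floor as IVW.
    """
    k = h.k
    if k < MIN_K["MR-Egger"]:
        return _skipped("MR-Egger", h.exposure, h.outcome, k)
    bx, sx, by, sy = _egger_orient(h)
    w = 1.0 / sy ** 2
    coef, cov_u, q = _weighted_with_intercept(bx, by, w)
    scale = max(1.0, np.sqrt(q / (k - 2))) if k > 2 else 1.0
    se = np.sqrt(np.diag(cov_u)) * scale
    icpt_p = float(2.0 * sps.norm.sf(abs(coef[0]) / se[0]))
    res = MRResult(method="MR-Egger", exposure=h.exposure, outcome=h.outcome,
                   estimate=float(coef[1]), se=float(se[1]), nsnp=k,
                   q=q, q_df=k - 2, q_p=float(sps.chi2.sf(q, k - 2)),
                   egger_intercept=float(coef[0]),
                   egger_intercept_se=float(se[0]),
                   egger_intercept_p=icpt_p, i2_gx=i2_gx(h))
    return _finish(res)


def simex_egger(h: HarmonisedSet,
                lambdas: Sequence[float] = (0.0, 0.5, 1.0, 1.5, 2.0),
                n_boot: int = 1000, seed: int = 0) -> MRResult:
    """Simulation-extrapolation correction of MR-Egger regression dilution.

    For each lambda, exposure betas are perturbed with
    ``Normal(0, lambda * se_exp^2)`` noise ``n_boot`` times and the refitted
    Egger slopes averaged; a quadratic in lambda is extrapolated to
    lambda = -1 (the no-measurement-error limit).  Deterministic under seed.
    """
    k = h.k
    if k < MIN_K["MR-Egger (SIMEX)"]:
        return _skipped("MR-Egger (SIMEX)", h.exposure, h.outcome, k)
    lambdas = np.asarray(sorted(set(float(l) for l in lambdas)))
    if len(lambdas) < 3:
        raise ValueError("SIMEX needs >= 3 distinct lambdas for the quadratic")
    if (lambdas < 0).any():
        raise ValueError("lambdas must be non-negative")
    naive = mr_egger(h)
    bx0, sx, by0, sy = h.arrays()
    ok = bx0 != 0
    bx0, sx, by0, sy = bx0[ok], sx[ok], by0[ok], sy[ok]
    w = 1.0 / sy ** 2
    rng = np.random.default_rng([seed, 6])

    mean_slopes, mean_icpts, mean_ses = [], [], []
    for lam in lambdas:
        if lam == 0.0:
            mean_slopes.append(naive.estimate)
            mean_icpts.append(naive.egger_intercept)
            mean_ses.append(naive.se)
            continue
        noise = rng.standard_normal((n_boot, len(bx0))) * (np.sqrt(lam) * sx)
        bxp = bx0[None, :] + noise
        s = np.sign(bxp)
        s[s == 0] = 1.0
        bxa = np.abs(bxp)
        bya = s * by0[None, :]
        # closed-form weighted regression with intercept, per bootstrap row
        sw = np.sum(w)
        swx = bxa @ w
        swy = bya @ w
        swxx = (bxa ** 2) @ w
        swxy = (bxa * bya) @ w
        det = sw * swxx - swx ** 2
        slope = (sw * swxy - swx * swy) / det
        icpt = (swxx * swy - swx * swxy) / det
        resid_q = ((bya - icpt[:, None] - slope[:, None] * bxa) ** 2) @ w
        scale2 = np.maximum(1.0, resid_q / (len(bx0) - 2))
        se_b = np.sqrt(sw / det * scale2)
        mean_slopes.append(float(slope.mean()))
        mean_icpts.append(float(icpt.mean()))
        mean_ses.append(float(se_b.mean()))

    def extrapolate(values):
        coefs = np.polyfit(lambdas, np.asarray(values), 2)
        return float(np.polyval(coefs, -1.0))

    est = extrapolate(mean_slopes)
    icpt = extrapolate(mean_icpts)
    se = max(extrapolate(mean_ses), 1e-12)
    res = MRResult(method="MR-Egger (SIMEX)", exposure=h.exposure,
                   outcome=h.outcome, estimate=est, se=se, nsnp=k,
                   egger_intercept=icpt, i2_gx=naive.i2_gx,
                   notes=f"lambdas={list(lambdas)}, n_boot={n_boot}")
    return _finish(res)


def _weighted_median_est(ratio: np.ndarray, w: np.ndarray) -> float:
    order = np.argsort(ratio)
    r, wn = ratio[order], w[order] / w.sum()
    s = np.cumsum(wn) - wn / 2.0
    return float(np.interp(0.5, s, r))


def _parametric_boot(h: HarmonisedSet, estimator, n_boot: int, seed: int,
                     stream: int):
    bx, sx, by, sy = h.arrays()
    ok = bx != 0
    bx, sx, by, sy = bx[ok], sx[ok], by[ok], sy[ok]
    rng = np.random.default_rng([seed, stream])
    est = np.empty(n_boot)
    for b in range(n_boot):
        bxs = bx + rng.standard_normal(len(bx)) * sx
        bys = by + rng.standard_normal(len(by)) * sy
        bxs[bxs == 0] = 1e-300
        est[b] = estimator(bys / bxs, (np.abs(bxs) / sy) ** 2)
    return float(est.std(ddof=1))


def weighted_median(h: HarmonisedSet, n_boot: int = 1000,
                    seed: int = 0) -> MRResult:
    """Weighted median of the Wald ratios (valid if >=50% of weight comes
    from valid instruments).  Midpoint cumulative-weight interpolation;
    SE by parametric bootstrap."""
    k = h.k
    if k < MIN_K["Weighted median"]:
        return _skipped("Weighted median", h.exposure, h.outcome, k)
    ratio, se_ratio, _ = wald_ratios(h)
    w = 1.0 / se_ratio ** 2
    est = _weighted_median_est(ratio, w)
    se = _parametric_boot(h, _weighted_median_est, n_boot, seed, stream=7)
    res = MRResult(method="Weighted median", exposure=h.exposure,
                   outcome=h.outcome, estimate=est, se=se, nsnp=k,
                   notes=f"bootstrap SE, n_boot={n_boot}")
    return _finish(res)


def _weighted_mode_est(ratio: np.ndarray, w: np.ndarray,
                       bandwidth_factor: float = 1.0) -> float:
    if np.ptp(ratio) == 0:
        return float(ratio[0])
    sd = ratio.std(ddof=1)
    mad = 1.4826 * np.median(np.abs(ratio - np.median(ratio)))
    spread = min(sd, mad) if mad > 0 else sd
    bw = bandwidth_factor * 0.9 * spread * len(ratio) ** (-1 / 5)
    if bw <= 0:
        return float(np.average(ratio, weights=w))
    grid = np.linspace(ratio.min() - 3 * bw, ratio.max() + 3 * bw, 512)
    dens = (w[None, :] * np.exp(-0.5 * ((grid[:, None] - ratio[None, :]) / bw) ** 2)).sum(axis=1)
    return float(grid[np.argmax(dens)])


def weighted_mode(h: HarmonisedSet, bandwidth_factor: float = 1.0,
                  n_boot: int = 1000, seed: int = 0) -> MRResult:
    """Mode of the weighted Wald-ratio density (valid if the largest group
    of instruments sharing a ratio is valid).  Gaussian kernel with a
    modified Silverman bandwidth; SE by parametric bootstrap."""
    k = h.k
    if k < MIN_K["Weighted mode"]:
        return _skipped("Weighted mode", h.exposure, h.outcome, k)
    ratio, se_ratio, _ = wald_ratios(h)
    w = 1.0 / se_ratio ** 2
    est = _weighted_mode_est(ratio, w, bandwidth_factor)
    se = _parametric_boot(
        h, lambda r, ww: _weighted_mode_est(r, ww, bandwidth_factor),
        n_boot, seed, stream=8)
    res = MRResult(method="Weighted mode", exposure=h.exposure,
                   outcome=h.outcome, estimate=est, se=se, nsnp=k,
                   notes=f"bootstrap SE, n_boot={n_boot}")
    return _finish(res)


def mean_f_statistic(r2_total: float, n: float, k: int) -> float:
    """Mean instrument F statistic from the aggregate variance explained:
    ``F = (r2/(1-r2)) * ((n-k-1)/k)``.  Values above 10 are the standard
    evidence of strong instruments."""
    if not 0.0 <= r2_total < 1.0:
        raise ValueError("r2 must be in [0, 1)")
    if k < 1:
        raise ValueError("k must be >= 1")
    if n <= k + 1:
        raise ValueError("n must exceed k + 1")
    return (r2_total / (1.0 - r2_total)) * ((n - k - 1) / k)


def results_table(results) -> pd.DataFrame:
    """Stack MRResults into the standard results TSV shape
    (exposure outcome method nsnp b se lo_ci up_ci p)."""
    return pd.DataFrame([r.to_row() for r in results])
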