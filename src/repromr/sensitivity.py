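"""Outlier, directionality and confounding sensitivity analyses.

MR-PRESSO detects instruments whose outcome effects are inconsistent with
the bulk (horizontal pleiotropy) by comparing leave-one-out residual sums of
squares with a parametric null; the Steiger test orients the causal
direction by comparing the variance the instruments explain in exposure and
outcome; multivariable IVW adjusts the exposure effect for a second
heritable exposure (e.g. childhood body size as a shared confounder).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .mr import MRResult, HarmonisedSet, harmonise, mr_ivw, _finish, Z95
from .sumstats import SummaryStats


@dataclass
class PressoResult:
    rss_obs: float
    global_p: float
    outlier_table: pd.DataFrame      # snp resid p_raw p_bonferroni outlier
    outliers: list
    corrected: Optional[MRResult]
    distortion_p: Optional[float]
    n_sim: int
    seed: int
    note: str = ""


@dataclass
class SteigerResult:
    r2_exposure: float
    r2_outcome: float
    direction_correct: bool
    z: float
    p: float
    per_snp: pd.DataFrame            # snp r2_exp r2_out correct


def _loo_ivw(bx, by, w):
    """Leave-one-out IVW estimates, vectorised (one per SNP)."""
    sxy = np.sum(w * bx * by)
    sxx = np.sum(w * bx ** 2)
    return (sxy - w * bx * by) / (sxx - w * bx ** 2)


def mr_presso(h: HarmonisedSet, n_sim: int = 1000,
              outlier_alpha: float = 0.05, seed: int = 0,
              n_distortion: int = 1000) -> PressoResult:
    """MR-PRESSO: residual-sum-of-squares outlier test and correction.

    The observed RSS uses leave-one-out IVW predictions with outcome-
    precision weights; the null distribution re-simulates both effect
    estimates from their sampling distributions under the leave-one-out
    fits.  Per-SNP empirical p-values are Bonferroni-adjusted across
    instruments; the corrected estimate is IVW on the non-outliers, and the
    distortion test compares the estimate shift against removing random
    same-size SNP subsets.  SNPs are processed in id order, making the
    result invariant to input row order.
    """
    if h.k < 4:
        raise ValueError("MR-PRESSO needs at least 4 instruments")
    order = np.argsort(h.table["snp"].to_numpy())
    t = h.table.iloc[order].reset_index(drop=True)
    bx = t["beta_exp"].to_numpy(dtype=float)
    sx = t["se_exp"].to_numpy(dtype=float)
    by = t["beta_out"].to_numpy(dtype=float)
    sy = t["se_out"].to_numpy(dtype=float)
    snps = t["snp"].to_numpy()
    k = len(t)
    w = 1.0 / sy ** 2

    theta_loo = _loo_ivw(bx, by, w)
    resid_obs = w * (by - bx * theta_loo) ** 2
    rss_obs = float(resid_obs.sum())

    rng = np.random.default_rng([seed, 9])
    bx_s = bx[None, :] + rng.standard_normal((n_sim, k)) * sx
    by_s = bx_s * theta_loo[None, :] + rng.standard_normal((n_sim, k)) * sy
    sxy_s = (w * bx_s * by_s).sum(axis=1, keepdims=True)
    sxx_s = (w * bx_s ** 2).sum(axis=1, keepdims=True)
    theta_loo_s = (sxy_s - w * bx_s * by_s) / (sxx_s - w * bx_s ** 2)
    resid_s = w * (by_s - bx_s * theta_loo_s) ** 2
    rss_s = resid_s.sum(axis=1)

    global_p = float((1 + np.sum(rss_s >= rss_obs)) / (n_sim + 1))
    p_raw = (1 + (resid_s >= resid_obs[None, :]).sum(axis=0)) / (n_sim + 1)
    p_bonf = np.minimum(1.0, p_raw * k)
    outlier = p_bonf < outlier_alpha
    outlier_table = pd.DataFrame({
        "snp": snps, "resid": resid_obs, "p_raw": p_raw,
        "p_bonferroni": p_bonf, "outlier": outlier})
    outliers = list(snps[outlier])

    corrected, distortion_p, note = None, None, ""
    if outlier.any():
        keep = snps[~outlier]
        if len(keep) >= 2:
            corrected = mr_ivw(h.subset(keep))
            theta_all = mr_ivw(h).estimate
            if theta_all != 0:
                d_obs = (corrected.estimate - theta_all) / abs(theta_all)
                n_out = int(outlier.sum())
                d_rand = np.empty(n_distortion)
                for i in range(n_distortion):
                    drop = rng.choice(k, size=n_out, replace=False)
                    mask = np.ones(k, dtype=bool)
                    mask[drop] = False
                    est = (np.sum(w[mask] * bx[mask] * by[mask]) /
                           np.sum(w[mask] * bx[mask] ** 2))
                    d_rand[i] = (est - theta_all) / abs(theta_all)
                distortion_p = float(
                    (1 + np.sum(np.abs(d_rand) >= abs(d_obs))) /
                    (n_distortion + 1))
        else:
            note = "all but <2 SNPs flagged; corrected estimate undefined"
    return PressoResult(rss_obs=rss_obs, global_p=global_p,
                        outlier_table=outlier_table, outliers=outliers,
                        corrected=corrected, distortion_p=distortion_p,
                        n_sim=n_sim, seed=seed, note=note)


# ---------------------------------------------------------------------------
# Steiger directionality
# ---------------------------------------------------------------------------

def _per_snp_r2(beta, se, n):
    """Variance explained per SNP via the t-statistic transform
    ``r2 = t^2/(t^2 + n - 2)`` (valid for raw or standardised statistics)."""
    t = beta / se
    return t ** 2 / (t ** 2 + n - 2.0)


def _per_snp_r2_freq(beta_sd, eaf):
    """Alternative r2 form ``2*eaf*(1-eaf)*beta_sd^2`` for SD-unit betas."""
    return 2.0 * eaf * (1.0 - eaf) * beta_sd ** 2


def steiger(h: HarmonisedSet, n_exposure: float, n_outcome: float,
            r2_method: str = "tstat") -> SteigerResult:
    """MR Steiger test of causal direction.

    Aggregates per-SNP variance explained in exposure and outcome over the
    instruments and compares the implied correlations with a z test on the
    difference of Fisher-transformed values.  The direction is called
    correct when the instruments explain more variance in the exposure.
    """
    if h.k < 1:
        raise ValueError("Steiger test needs at least 1 SNP")
    if n_exposure <= 3 or n_outcome <= 3:
        raise ValueError("sample sizes must exceed 3")
    bx, sx, by, sy = h.arrays()
    if r2_method == "tstat":
        r2x = _per_snp_r2(bx, sx, n_exposure)
        r2y = _per_snp_r2(by, sy, n_outcome)
    elif r2_method == "freq":
        eaf = h.table["eaf_exp"].to_numpy(dtype=float)
        r2x = _per_snp_r2_freq(bx, eaf)
        r2y = _per_snp_r2_freq(by, eaf)
    else:
        raise ValueError(f"unknown r2_method {r2_method!r}")
    agg_x = float(np.clip(r2x.sum(), 0.0, 1.0 - 1e-12))
    agg_y = float(np.clip(r2y.sum(), 0.0, 1.0 - 1e-12))
    rx, ry = np.sqrt(agg_x), np.sqrt(agg_y)
    z = (np.arctanh(rx) - np.arctanh(ry)) / np.sqrt(
        1.0 / (n_exposure - 3) + 1.0 / (n_outcome - 3))
    per_snp = pd.DataFrame({"snp": h.table["snp"], "r2_exp": r2x,
                            "r2_out": r2y, "correct": r2x > r2y})
    return SteigerResult(r2_exposure=agg_x, r2_outcome=agg_y,
                         direction_correct=agg_x > agg_y, z=float(z),
                         p=float(2.0 * sps.norm.sf(abs(z))), per_snp=per_snp)


def steiger_filter(h: HarmonisedSet, n_exposure: float, n_outcome: float,
                   r2_method: str = "tstat") -> HarmonisedSet:
    """Drop instruments whose per-SNP variance explained favours the
    outcome; removed SNPs are appended to the audit list.  Re-running the
    IVW on the filtered set is the caller's responsibility."""
    res = steiger(h, n_exposure, n_outcome, r2_method)
    bad = res.per_snp.loc[~res.per_snp["correct"], "snp"]
    keep = h.table.loc[~h.table["snp"].isin(set(bad))].reset_index(drop=True)
    removed = pd.DataFrame({"snp": bad, "action": "dropped_steiger",
                            "reason": "r2_outcome >= r2_exposure"})
    audit = pd.concat([h.audit, removed], ignore_index=True)
    note = h.note
    if keep.empty:
        note = (note + "; " if note else "") + \
            "steiger filtering removed every instrument"
    return HarmonisedSet(keep, h.exposure, h.outcome, audit, note)


# ---------------------------------------------------------------------------
# multivariable MR
# ---------------------------------------------------------------------------

def mvmr_ivw(exposures: Sequence[SummaryStats], outcome: SummaryStats,
             instruments: Sequence[str]) -> list:
    """Multivariable IVW: joint weighted regression of outcome betas on the
    matrix of exposure betas (no intercept, outcome-precision weights).

    All statistics are harmonised to the first exposure's effect alleles.
    The per-exposure SE carries the same multiplicative random-effects floor
    as the univariable IVW, so a single-exposure call reproduces
    :func:`repromr.mr.mr_ivw` exactly.
    """
    if len(exposures) < 1:
        raise ValueError("at least one exposure required")
    instruments = list(instruments)
    base = exposures[0]
    h_out = harmonise(base.subset(instruments), outcome)
    frames = {"beta_out": h_out.table.set_index("snp")["beta_out"],
              "se_out": h_out.table.set_index("snp")["se_out"],
              base.trait_id: h_out.table.set_index("snp")["beta_exp"]}
    for exp in exposures[1:]:
        h_i = harmonise(base.subset(instruments), exp)
        frames[exp.trait_id] = h_i.table.set_index("snp")["beta_out"]
    joint = pd.DataFrame(frames).dropna()
    k = len(joint)
    ids = [e.trait_id for e in exposures]
    # an exposure whose betas are identically zero carries no instrument
    # signal: it is excluded from the fit (its estimate is undefined) so the
    # remaining exposures reduce exactly to the lower-dimensional model
    active = [t for t in ids if (joint[t] != 0).any()]
    p = len(active)
    if p == 0:
        raise ValueError("no exposure carries instrument signal")
    if k <= p:
        raise ValueError(f"only {k} joint instruments for {p} exposures")
    X = joint.loc[:, active].to_numpy(dtype=float)
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("exposure-beta matrix is rank deficient")
    y = joint["beta_out"].to_numpy(dtype=float)
    w = 1.0 / joint["se_out"].to_numpy(dtype=float) ** 2
    fit = sm.WLS(y, X, weights=w).fit()
    # statsmodels scales the covariance by RSS/(k-p); floor that factor at 1
    scale = max(1.0, np.sqrt(fit.scale))
    se = fit.bse / np.sqrt(fit.scale) * scale
    results = []
    for trait in ids:
        note = f"adjusted for {[t for t in ids if t != trait]}"
        if trait in active:
            j = active.index(trait)
            res = MRResult(method="MVMR-IVW", exposure=trait,
                           outcome=outcome.trait_id,
                           estimate=float(fit.params[j]), se=float(se[j]),
                           nsnp=k, notes=note)
            results.append(_finish(res))
        else:
            results.append(MRResult(
                method="MVMR-IVW", exposure=trait, outcome=outcome.trait_id,
                nsnp=k, notes=note + "; skipped: all instrument betas zero"))
    return results
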