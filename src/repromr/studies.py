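"""Instrument-level simulation studies for calibrating the estimator suite.

These helpers generate two-sample MR inputs directly at the level of
summary statistics: per-SNP exposure effects with a configurable aggregate
variance explained, outcome effects induced by a known causal effect, and
optional horizontal pleiotropy or outlier contamination.  They are the fast
path for recovery, calibration and power studies; cohort-level generation
lives in :mod:`repromr.simulate`.

All effects are handled on the per-allele (raw dosage) scale with the
analytic standard error ``1/sqrt(2*eaf*(1-eaf)*n)`` of a unit-variance
trait, so the implied Wald ratios are in SD units.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .mr import HarmonisedSet, HARMONISED_COLUMNS


def simulate_instruments(k: int, r2: float, rng: np.random.Generator,
                         effect_dist: str = "normal"):
    """Per-SNP exposure architecture: allele frequencies and raw-scale
    effects whose standardised contributions sum exactly to ``r2``.

    ``effect_dist='normal'`` draws effect magnitudes from a half-normal
    (realistic spread); ``'fixed'`` gives every SNP the same standardised
    magnitude with a random sign (useful when per-SNP power must be
    homogeneous).
    """
    eaf = rng.uniform(0.1, 0.5, size=k)
    signs = rng.choice([-1.0, 1.0], size=k)
    if effect_dist == "fixed":
        std_mag = np.full(k, 1.0)
    elif effect_dist == "normal":
        std_mag = np.abs(rng.standard_normal(k)) + 0.1
    else:
        raise ValueError(f"unknown effect_dist {effect_dist!r}")
    std_beta = signs * std_mag * np.sqrt(r2 / np.sum(std_mag ** 2))
    raw_beta = std_beta / np.sqrt(2.0 * eaf * (1.0 - eaf))
    return eaf, raw_beta


def two_sample_pair(k: int = 150, n_exposure: int = 20_000,
                    n_outcome: int = 20_000, theta: float = 0.09,
                    r2_instruments: float = 0.064, seed: int = 0,
                    pleiotropy_mean: float = 0.0, pleiotropy_sd: float = 0.0,
                    pleiotropy_fraction: float = 1.0,
                    outlier_idx: Optional[Sequence[int]] = None,
                    outlier_scale: float = 1.0,
                    effect_dist: str = "normal",
                    exposure: str = "exposure",
                    outcome: str = "outcome") -> HarmonisedSet:
    """One simulated two-sample MR dataset under known truth.

    The exposure instruments explain ``r2_instruments`` of the exposure; the
    true causal effect is ``theta`` SD per SD.  Directional pleiotropy adds
    per-SNP outcome effects ``Normal(mean, sd)`` (outcome-beta scale,
    aligned to the exposure-increasing allele — the frame in which the
    Egger intercept is defined) to a fraction of the instruments,
    independent of the exposure effect sizes (the InSIDE configuration);
    ``outlier_scale`` multiplies the true outcome effect of the listed
    instruments (outlier contamination).  Exposure and outcome estimates
    are drawn independently (non-overlapping samples).
    """
    rng = np.random.default_rng([seed, 11])
    eaf, bx_true = simulate_instruments(k, r2_instruments, rng, effect_dist)
    scale = np.sqrt(2.0 * eaf * (1.0 - eaf))
    se_x = 1.0 / (scale * np.sqrt(n_exposure))
    se_y = 1.0 / (scale * np.sqrt(n_outcome))
    by_true = theta * bx_true
    if pleiotropy_sd > 0 or pleiotropy_mean != 0:
        n_plei = int(round(pleiotropy_fraction * k))
        alpha = rng.normal(pleiotropy_mean, pleiotropy_sd, size=n_plei)
        idx = rng.choice(k, size=n_plei, replace=False) \
            if n_plei < k else np.arange(k)
        by_true = by_true.copy()
        by_true[idx] += np.sign(bx_true[idx]) * alpha
    if outlier_idx is not None:
        by_true = by_true.copy()
        by_true[list(outlier_idx)] *= outlier_scale
    bx_hat = bx_true + rng.standard_normal(k) * se_x
    by_hat = by_true + rng.standard_normal(k) * se_y
    table = pd.DataFrame({
        "snp": [f"rs{i + 1}" for i in range(k)],
        "beta_exp": bx_hat, "se_exp": se_x,
        "beta_out": by_hat, "se_out": se_y,
        "eaf_exp": eaf, "eaf_out": eaf,
        "action": "kept",
    }, columns=HARMONISED_COLUMNS)
    return HarmonisedSet(table, exposure, outcome)


def negative_control_pair(k: int = 50, n: int = 20_000,
                          r2_instruments: float = 0.01,
                          shared_pleiotropy: float = 0.0,
                          shared_fraction: float = 0.5,
                          seed: int = 0) -> HarmonisedSet:
    """A temporally impossible pair: the outcome precedes the exposure and
    receives no causal effect from it.

    With ``shared_pleiotropy`` zero the exposure instruments are silent on
    the outcome (a clean negative control, expected null); a positive value
    gives a fraction of the instruments direct outcome effects of that
    standardised magnitude — the shared-pleiotropy pathway a negative
    control is designed to expose.
    """
    rng = np.random.default_rng([seed, 12])
    h = two_sample_pair(k=k, n_exposure=n, n_outcome=n, theta=0.0,
                        r2_instruments=r2_instruments, seed=seed,
                        pleiotropy_mean=shared_pleiotropy,
                        pleiotropy_sd=shared_pleiotropy / 2 if shared_pleiotropy else 0.0,
                        pleiotropy_fraction=shared_fraction,
                        exposure="late_factor", outcome="early_factor")
    return h


def polygenic_overlap_study(n: int = 20_000, m: int = 2_000,
                            h2_1: float = 0.3, h2_2: float = 0.3,
                            rg: float = 0.5, overlap_fraction: float = 1.0,
                            env_corr: float = 0.2, block_size: int = 25,
                            max_block_rho: float = 0.95, seed: int = 0):
    """Cohort-level polygenic simulation for LD score regression studies.

    Every SNP is causal for both traits with per-SNP effects correlated
    ``rg``.  Each trait's GWAS uses ``n`` individuals; a fraction
    ``overlap_fraction`` of them is shared between the two GWAS, and in the
    shared individuals the environmental noise of the two traits is
    correlated ``env_corr`` — together these drive the bivariate intercept
    of the cross-trait regression.  Returns ``(ztab1, ztab2, ld_table,
    panel)`` ready for :func:`repromr.ldsc.ldsc_h2` /
    :func:`repromr.ldsc.ldsc_rg`.
    """
    from .assoc import run_gwas
    from .ldsc import compute_ld_scores, munge
    from .simulate import Block, simulate_genotypes, TraitTable
    from .sumstats import CONTINUOUS

    if m % block_size:
        raise ValueError("m must be a multiple of block_size")
    rng = np.random.default_rng([seed, 13])
    n_shared = int(round(overlap_fraction * n))
    n_total = 2 * n - n_shared
    # graded LD strength across blocks so LD scores span a wide range
    # (the regression needs variation in l2 to separate slope and intercept)
    n_blocks = m // block_size
    rhos = np.linspace(0.0, max_block_rho, n_blocks)
    panel = simulate_genotypes(n_total, [Block(block_size, r) for r in rhos],
                               seed=seed, palindromic_fraction=0.0)
    G = panel.dosages.astype(np.float32)
    G -= G.mean(axis=0)
    G /= G.std(axis=0)

    b1 = rng.standard_normal(m)
    b2 = rg * b1 + np.sqrt(max(0.0, 1 - rg ** 2)) * rng.standard_normal(m)
    g1 = G @ (b1 * np.sqrt(h2_1 / m)).astype(np.float32)
    g2 = G @ (b2 * np.sqrt(h2_2 / m)).astype(np.float32)
    g1 = np.sqrt(h2_1) * (g1 - g1.mean()) / g1.std()
    g2 = np.sqrt(h2_2) * (g2 - g2.mean()) / g2.std()

    # cohort 1 = first n individuals, cohort 2 = last n; the overlap is the
    # middle n_shared, where the two traits share environmental noise
    e_shared = rng.standard_normal(n_total)
    e1 = rng.standard_normal(n_total)
    e2 = rng.standard_normal(n_total)
    rho_e = np.zeros(n_total)
    if n_shared:
        rho_e[n - n_shared:n] = env_corr
    noise1 = np.sqrt(np.abs(rho_e)) * e_shared + np.sqrt(1 - np.abs(rho_e)) * e1
    noise2 = np.sign(rho_e + 1e-300) * np.sqrt(np.abs(rho_e)) * e_shared \
        + np.sqrt(1 - np.abs(rho_e)) * e2
    y1 = g1 + np.sqrt(1 - h2_1) * noise1
    y2 = g2 + np.sqrt(1 - h2_2) * noise2
    y2[:n - n_shared] = np.nan   # cohort 2 only
    y1[n:] = np.nan              # cohort 1 only

    traits = TraitTable(
        pd.DataFrame({"trait1": y1, "trait2": y2}),
        {"trait1": CONTINUOUS, "trait2": CONTINUOUS},
        pd.DataFrame(index=range(n_total)), {})
    s1 = run_gwas(panel, traits, "trait1", covariates=())
    s2 = run_gwas(panel, traits, "trait2", covariates=())
    ld = compute_ld_scores(panel)
    return munge(s1, ld), munge(s2, ld), ld, panel
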