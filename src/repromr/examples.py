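"""Worked examples: published instrument-strength summaries.

Instrument summaries (exposure GWAS sample size, aggregate variance
explained and clumped instrument count) for eight reproductive-factor GWAS
performed in a large UK population cohort of women, together with the mean
F statistic each implies.  They serve as configuration defaults and as
recomputable worked examples for :func:`repromr.mr.mean_f_statistic`.
"""

from __future__ import annotations

import pandas as pd

from .mr import mean_f_statistic

# exposure label, GWAS N, aggregate r2 (as printed), clumped instrument
# count, published mean F (printed to two decimals)
INSTRUMENT_STRENGTH_ROWS = (
    ("menarche",  243_898, "0.064",   223, 74.95),
    ("menopause", 143_791, "0.047",    84, 85.08),
    ("afb",       203_606, "8.38e-3",  41, 41.97),
    ("alb",       203_356, "1.92e-3",   9, 43.46),
    ("n_births",  250_746, "1.68e-3",   9, 46.75),
    ("afs",       219_486, "9.44e-3",  53, 39.46),
    ("partners",  208_274, "6.36e-3",  34, 39.20),
    ("parous",    250_746, "8.59e-4",   4, 53.92),
)


def _half_ulp(printed: str) -> float:
    """Half the unit-in-last-place of a printed decimal (rounding band)."""
    mantissa, _, exp = printed.lower().partition("e")
    exponent = int(exp) if exp else 0
    decimals = len(mantissa.partition(".")[2])
    return 0.5 * 10.0 ** (exponent - decimals)


def instrument_strength_examples() -> pd.DataFrame:
    """Recompute the mean F statistic for each published row.

    The published r2 values are printed to limited precision, so the
    recomputed F agrees with the published one within the band implied by
    rounding the printed r2 (the ``f_lo``/``f_hi`` columns).
    """
    rows = []
    for trait, n, r2_text, k, f_pub in INSTRUMENT_STRENGTH_ROWS:
        r2 = float(r2_text)
        h = _half_ulp(r2_text)
        rows.append({
            "exposure": trait, "n": n, "r2": r2, "nsnp": k,
            "f_published": f_pub,
            "f_computed": mean_f_statistic(r2, n, k),
            "f_lo": mean_f_statistic(max(r2 - h, 0.0), n, k),
            "f_hi": mean_f_statistic(r2 + h, n, k),
        })
    return pd.DataFrame(rows)
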