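"""GWAS summary statistics: the in-memory container and the TSV dialect.

Every component of the package exchanges per-SNP association records through
one tab-delimited dialect with columns exactly::

    snp chr pos ea oa eaf beta se p n

where ``pos`` is 1-based, ``ea`` is the effect allele (the allele whose dosage
``beta`` refers to), ``eaf`` its frequency, and ``n`` the per-SNP analysed
sample size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats as sps

SUMSTATS_COLUMNS = ["snp", "chr", "pos", "ea", "oa", "eaf", "beta", "se", "p", "n"]

VALID_ALLELES = frozenset("ACGT")
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

CONTINUOUS = "continuous"
BINARY = "binary"

UNITS_RAW = "raw"
UNITS_SD = "sd"


def is_palindromic(ea: str, oa: str) -> bool:
    """True for strand-ambiguous (A/T or G/C) allele pairs."""
    return COMPLEMENT.get(ea) == oa


def pvalue_from_z(z: np.ndarray) -> np.ndarray:
    """Two-sided normal tail probability of a Wald z statistic."""
    return 2.0 * sps.norm.sf(np.abs(z))


@dataclass
class SummaryStats:
    """Per-SNP association records for one trait.

    Parameters
    ----------
    table:
        DataFrame with :data:`SUMSTATS_COLUMNS`.
    trait_id:
        Label of the trait the associations refer to.
    trait_type:
        ``"continuous"`` (beta in trait units) or ``"binary"`` (beta is a
        log-odds per effect allele).
    units:
        ``"raw"`` or ``"sd"`` once estimates have been standardised.
    """

    table: pd.DataFrame
    trait_id: str
    trait_type: str = CONTINUOUS
    units: str = UNITS_RAW

    def __post_init__(self) -> None:
        missing = [c for c in SUMSTATS_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"summary statistics missing columns: {missing}")
        self.table = self.table.loc[:, SUMSTATS_COLUMNS].reset_index(drop=True)
        if self.trait_type not in (CONTINUOUS, BINARY):
            raise ValueError(f"unknown trait type {self.trait_type!r}")
        if self.units not in (UNITS_RAW, UNITS_SD):
            raise ValueError(f"unknown units flag {self.units!r}")

    # -- basic accessors -------------------------------------------------
    @property
    def n_snps(self) -> int:
        return len(self.table)

    def zscores(self) -> np.ndarray:
        return self.table["beta"].to_numpy() / self.table["se"].to_numpy()

    def subset(self, snps) -> "SummaryStats":
        """Restrict to the given SNP ids (order of ``self.table`` kept)."""
        keep = self.table["snp"].isin(set(snps))
        return replace(self, table=self.table.loc[keep].reset_index(drop=True))

    # -- validation ------------------------------------------------------
    def validate(self, rel_tol: float = 1e-6) -> None:
        """Check the container invariants, raising ``ValueError`` on breach.

        Checks positive SEs, p in (0, 1], eaf in (0, 1), ACGT alleles and the
        consistency of p with |beta/se| to ``rel_tol`` relative precision.
        """
        t = self.table
        if (t["se"] <= 0).any():
            raise ValueError("non-positive standard errors")
        if ((t["p"] <= 0) | (t["p"] > 1)).any():
            raise ValueError("p-values outside (0, 1]")
        if ((t["eaf"] <= 0) | (t["eaf"] >= 1)).any():
            raise ValueError("effect-allele frequencies outside (0, 1)")
        alleles = set(t["ea"]).union(t["oa"])
        if not alleles <= VALID_ALLELES:
            raise ValueError(f"invalid alleles: {alleles - VALID_ALLELES}")
        expected = pvalue_from_z(self.zscores())
        ok = np.isclose(t["p"].to_numpy(), expected, rtol=rel_tol, atol=0.0)
        # p-values below float tiny are stored as the tiny; don't flag those
        ok |= (expected < 1e-300) & (t["p"].to_numpy() <= 1e-300)
        if not ok.all():
            raise ValueError("p-values inconsistent with beta/se")

    # -- I/O -------------------------------------------------------------
    def write_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path, trait_id: str, trait_type: str = CONTINUOUS,
                 units: str = UNITS_RAW) -> "SummaryStats":
        table = pd.read_csv(path, sep="\t")
        return cls(table=table, trait_id=trait_id, trait_type=trait_type,
                   units=units)


def build_table(snp, chrom, pos, ea, oa, eaf, beta, se, n) -> pd.DataFrame:
    """Assemble a sumstats table, deriving p from the Wald z statistic."""
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    with np.errstate(divide="ignore"):
        p = np.clip(pvalue_from_z(beta / se), np.finfo(float).tiny, 1.0)
    return pd.DataFrame({
        "snp": snp, "chr": chrom, "pos": pos, "ea": ea, "oa": oa,
        "eaf": np.asarray(eaf, dtype=float), "beta": beta, "se": se,
        "p": p, "n": n,
    })
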