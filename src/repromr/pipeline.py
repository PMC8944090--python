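"""Study-level orchestration: pair plan, per-pair MR with the sensitivity
suite, negative controls, split-sample meta-analysis and the full report.

The temporal pair plan encodes which factor can plausibly cause which:
earlier-occurring factors are exposures for later-occurring outcomes, pairs
without a clear ordering are tested in both directions, age at menopause is
additionally tested against earlier factors as an ovarian-reserve proxy, and
five fixed negative-control pairs (outcome occurring before the exposure)
probe shared pleiotropy.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import __version__
from .assoc import (GWS_THRESHOLD, CLUMP_KB, CLUMP_R2, InstrumentSet,
                    run_gwas, select_instruments, split_cohort)
from .ldsc import compute_ld_scores, ldsc_rg, munge
from .mr import (MRResult, SIMEX_I2_THRESHOLD, harmonise, mean_f_statistic,
                 mr_egger, mr_ivw, results_table, simex_egger,
                 weighted_median, weighted_mode)
from .sensitivity import mr_presso, steiger
from .simulate import (CausalConfig, DEFAULT_TRAITS, GenotypePanel,
                       TraitTable, Block, simulate_genotypes, simulate_traits)
from .sumstats import BINARY, SummaryStats

logger = logging.getLogger(__name__)

CATEGORIES = ("primary", "bidirectional", "reverse_menopause",
              "negative_control")

# Temporal strict order: menarche before everything; age at first sex before
# the childbearing factors; first birth before last birth before menopause.
DEFAULT_ORDER_EDGES = tuple(
    [("menarche", t) for t in DEFAULT_TRAITS if t != "menarche"]
    + [("afs", t) for t in ("afb", "alb", "n_births", "parous", "partners",
                            "menopause")]
    + [("afb", t) for t in ("alb", "n_births", "parous", "menopause")]
    + [("alb", "menopause")]
)

# Pairs without a defensible temporal ordering: analysed in both directions.
DEFAULT_BIDIRECTIONAL = (
    ("alb", "n_births"), ("alb", "partners"),
    ("menopause", "n_births"), ("menopause", "parous"),
    ("menopause", "partners"),
    ("n_births", "partners"), ("n_births", "parous"),
    ("parous", "partners"),
)

# Fixed negative controls: the outcome precedes the exposure, so any signal
# indicates shared pleiotropy rather than causation.
NEGATIVE_CONTROLS = (
    ("afb", "menarche"), ("afs", "menarche"), ("afb", "afs"),
    ("menopause", "afs"), ("alb", "menarche"),
)

REVERSE_MENOPAUSE_OUTCOMES = ("menarche", "afs", "afb")


@dataclass(frozen=True)
class PlanPair:
    exposure: str
    outcome: str
    category: str


@dataclass
class PairPlan:
    pairs: list

    def __post_init__(self) -> None:
        for cat in CATEGORIES:
            rows = [(p.exposure, p.outcome) for p in self.pairs
                    if p.category == cat]
            if len(rows) != len(set(rows)):
                raise ValueError(f"duplicate ordered pairs in category {cat!r}")
        n_neg = sum(p.category == "negative_control" for p in self.pairs)
        if n_neg not in (0, len(NEGATIVE_CONTROLS)):
            raise ValueError("negative-control list must be the fixed five "
                             "pairs (or omitted entirely)")

    def by_category(self, category: str) -> list:
        return [p for p in self.pairs if p.category == category]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(p) for p in self.pairs])


def _transitive_closure(edges, nodes):
    import graphlib
    ts = graphlib.TopologicalSorter({n: set() for n in nodes})
    succ: dict = {n: set() for n in nodes}
    for a, b in edges:
        ts.add(b, a)
        succ[a].add(b)
    try:
        order = list(ts.static_order())
    except graphlib.CycleError as err:
        raise ValueError("temporal order contains a cycle") from err
    closure = {n: set(succ[n]) for n in nodes}
    for n in reversed(order):
        for child in list(closure[n]):
            closure[n] |= closure[child]
    return closure


def build_pair_plan(trait_registry: Sequence[str] = DEFAULT_TRAITS,
                    temporal_order=DEFAULT_ORDER_EDGES,
                    bidirectional_pairs=DEFAULT_BIDIRECTIONAL,
                    include_reverse_menopause: bool = True,
                    include_negative_controls: bool = True) -> PairPlan:
    """Build the study's pair plan from the temporal partial order.

    Primary pairs are every (earlier, later) pair in the transitive closure
    of the order; each declared bidirectional pair contributes both
    directions; menopause is tested against earlier factors as an
    ovarian-reserve proxy; the negative-control category is the fixed five.
    """
    registry = list(trait_registry)
    for a, b in list(temporal_order) + list(bidirectional_pairs):
        for t in (a, b):
            if t not in registry:
                raise ValueError(f"trait {t!r} not in registry")
    closure = _transitive_closure(temporal_order, registry)
    pairs = [PlanPair(a, b, "primary")
             for a in registry for b in sorted(closure[a])]
    seen_primary = {(p.exposure, p.outcome) for p in pairs}
    for a, b in bidirectional_pairs:
        for exp, out in ((a, b), (b, a)):
            if (exp, out) in seen_primary:
                raise ValueError(
                    f"pair ({exp}, {out}) is both temporally ordered and "
                    "declared bidirectional")
            pairs.append(PlanPair(exp, out, "bidirectional"))
    if include_reverse_menopause:
        pairs += [PlanPair("menopause", out, "reverse_menopause")
                  for out in REVERSE_MENOPAUSE_OUTCOMES
                  if out in registry]
    if include_negative_controls:
        pairs += [PlanPair(a, b, "negative_control")
                  for a, b in NEGATIVE_CONTROLS]
    return PairPlan(pairs)


# ---------------------------------------------------------------------------
# per-pair execution
# ---------------------------------------------------------------------------

@dataclass
class PairReport:
    exposure: str
    outcome: str
    category: str
    status: str                       # ok | skipped | error
    results: list = field(default_factory=list)     # MRResult
    harmonised_k: int = 0
    mean_f: float = np.nan
    steiger: Optional[object] = None
    presso: Optional[object] = None
    provenance: dict = field(default_factory=dict)

    def result(self, method: str) -> Optional[MRResult]:
        for r in self.results:
            if r.method == method:
                return r
        return None


def run_pair(exposure_stats: SummaryStats, outcome_stats: SummaryStats,
             instruments: InstrumentSet, seed: int = 0,
             n_exposure: Optional[float] = None,
             n_outcome: Optional[float] = None,
             n_boot: int = 500, presso_n_sim: int = 1000,
             category: str = "primary") -> PairReport:
    """Run the full estimator and sensitivity suite for one pair.

    Harmonises instrument statistics, then IVW (+Q, mean F); with >= 3 SNPs
    adds MR-Egger (SIMEX when I2_GX < 0.90), weighted median and mode; with
    >= 4 adds MR-PRESSO; the Steiger test always runs.  Pairs with no
    instruments are reported as skipped.
    """
    report = PairReport(exposure_stats.trait_id, outcome_stats.trait_id,
                        category, status="ok")
    report.provenance = {
        "seed": seed, "p_threshold": instruments.p_threshold,
        "clump_r2": instruments.clump_r2, "clump_kb": instruments.clump_kb,
        "n_boot": n_boot, "presso_n_sim": presso_n_sim,
    }
    if instruments.k == 0:
        report.status = "skipped"
        report.provenance["reason"] = "no genome-wide significant instruments"
        return report
    exp_sub = exposure_stats.subset(instruments.snps)
    try:
        h = harmonise(exp_sub, outcome_stats)
    except ValueError as err:
        report.status = "skipped"
        report.provenance["reason"] = str(err)
        return report
    if h.k == 0:
        report.status = "skipped"
        report.provenance["reason"] = "no SNPs survived harmonisation"
        return report
    report.harmonised_k = h.k

    n_exp = n_exposure or float(exp_sub.table["n"].median())
    n_out = n_outcome or float(outcome_stats.table["n"].median())
    if n_exp > instruments.k + 1:
        report.mean_f = mean_f_statistic(instruments.r2_total, n_exp,
                                         instruments.k)

    report.results.append(mr_ivw(h))
    egger = mr_egger(h)
    report.results.append(egger)
    if not egger.skipped and egger.i2_gx < SIMEX_I2_THRESHOLD:
        report.results.append(simex_egger(h, seed=seed))
    report.results.append(weighted_median(h, n_boot=n_boot, seed=seed))
    report.results.append(weighted_mode(h, n_boot=n_boot, seed=seed))
    if h.k >= 4:
        report.presso = mr_presso(h, n_sim=presso_n_sim, seed=seed)
    if min(n_exp, n_out) > 3:
        report.steiger = steiger(h, n_exp, n_out)
    return report


# ---------------------------------------------------------------------------
# meta-analysis and split-sample workflow
# ---------------------------------------------------------------------------

@dataclass
class MetaResult:
    exposure: str
    outcome: str
    method: str
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    p: float
    estimates: tuple
    ses: tuple
    q: float
    q_p: float


def meta_fixed(result_a: MRResult, result_b: MRResult) -> MetaResult:
    """Fixed-effect inverse-variance pooling of two MR results for the same
    pair and method, with a between-study Q on 1 df."""
    if (result_a.exposure, result_a.outcome, result_a.method) != \
            (result_b.exposure, result_b.outcome, result_b.method):
        raise ValueError("results refer to different pairs or methods")
    est = np.array([result_a.estimate, result_b.estimate])
    se = np.array([result_a.se, result_b.se])
    w = 1.0 / se ** 2
    pooled = float(np.sum(w * est) / np.sum(w))
    pooled_se = float(1.0 / np.sqrt(np.sum(w)))
    q = float(np.sum(w * (est - pooled) ** 2))
    z = pooled / pooled_se
    return MetaResult(
        exposure=result_a.exposure, outcome=result_a.outcome,
        method=result_a.method, estimate=pooled, se=pooled_se,
        ci_low=pooled - 1.959963984540054 * pooled_se,
        ci_high=pooled + 1.959963984540054 * pooled_se,
        p=float(2.0 * sps.norm.sf(abs(z))),
        estimates=(result_a.estimate, result_b.estimate),
        ses=(result_a.se, result_b.se),
        q=q, q_p=float(sps.chi2.sf(q, 1)))


def run_split_sample_study(panel: GenotypePanel, traits: TraitTable,
                           plan: PairPlan, seed: int = 0,
                           p_threshold: float = GWS_THRESHOLD,
                           clump_r2: float = CLUMP_R2,
                           clump_kb: float = CLUMP_KB,
                           categories: Sequence[str] = ("primary",)) -> pd.DataFrame:
    """Split-sample MR: disjoint cohort halves, GWAS per half, each pair run
    in both half-assignments and pooled with a fixed-effect model.

    Clumping uses the full panel as a shared LD reference.  When one half
    yields no instruments for an exposure, the pair is run once with the
    instrumented half (mirroring sparse-instrument exposures such as age at
    last birth or parous status).
    """
    (panel_a, traits_a), (panel_b, traits_b) = split_cohort(panel, traits, seed)
    halves = {1: (panel_a, traits_a), 2: (panel_b, traits_b)}
    pairs = [p for p in plan.pairs if p.category in categories]
    traits_needed = sorted({p.exposure for p in pairs} |
                           {p.outcome for p in pairs})
    stats = {}
    for half, (pn, tr) in halves.items():
        for t in traits_needed:
            stats[(t, half)] = run_gwas(pn, tr, t)
    instruments = {key: select_instruments(s, panel, p_threshold, clump_r2,
                                           clump_kb)
                   for key, s in stats.items()}

    rows = []
    for pair in pairs:
        runs = []
        for exp_half, out_half in ((1, 2), (2, 1)):
            inst = instruments[(pair.exposure, exp_half)]
            if inst.k == 0:
                continue
            rep = run_pair(stats[(pair.exposure, exp_half)],
                           stats[(pair.outcome, out_half)], inst, seed=seed,
                           category=pair.category)
            ivw = rep.result("IVW")
            if ivw is not None and not ivw.skipped:
                runs.append((exp_half, ivw))
        if not runs:
            rows.append({"exposure": pair.exposure, "outcome": pair.outcome,
                         "n_runs": 0, "b": np.nan, "se": np.nan, "p": np.nan,
                         "q_between": np.nan, "q_p": np.nan,
                         "status": "no instruments in either half"})
        elif len(runs) == 1:
            ivw = runs[0][1]
            rows.append({"exposure": pair.exposure, "outcome": pair.outcome,
                         "n_runs": 1, "b": ivw.estimate, "se": ivw.se,
                         "p": ivw.p, "q_between": np.nan, "q_p": np.nan,
                         "status": f"single run (half {runs[0][0]} exposure)"})
        else:
            meta = meta_fixed(runs[0][1], runs[1][1])
            rows.append({"exposure": pair.exposure, "outcome": pair.outcome,
                         "n_runs": 2, "b": meta.estimate, "se": meta.se,
                         "p": meta.p, "q_between": meta.q, "q_p": meta.q_p,
                         "status": "meta-analysed"})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# full study
# ---------------------------------------------------------------------------

@dataclass
class StudyConfig:
    """Everything needed to run the synthetic study end to end."""

    causal: CausalConfig = field(default_factory=CausalConfig)
    n_individuals: int = 20_000
    n_blocks: int = 40
    block_size: int = 30
    block_rho: float = 0.4
    p_threshold: float = GWS_THRESHOLD
    clump_r2: float = CLUMP_R2
    clump_kb: float = CLUMP_KB
    ldsc_window_kb: float = 1000.0
    n_boot: int = 200
    presso_n_sim: int = 500
    run_ldsc: bool = True
    run_split_sample: bool = True
    seed: int = 0


@dataclass
class StudyReport:
    plan: PairPlan
    rg_matrix: pd.DataFrame
    mr_results: pd.DataFrame
    sensitivity: pd.DataFrame
    split_meta: pd.DataFrame
    instruments: Mapping[str, InstrumentSet]
    pair_reports: list
    manifest: dict


def run_full_study(config: StudyConfig,
                   out_dir: Optional[str] = None) -> StudyReport:
    """Simulate a cohort and execute the whole analysis plan.

    Stages: genotypes -> traits -> per-trait GWAS -> LD scores and the
    pairwise genetic-correlation matrix -> instrument selection -> pair-plan
    MR with the sensitivity suite (negative controls included) ->
    split-sample meta-analysis.  Per-pair failures are recorded, not fatal.
    """
    seed = config.seed
    blocks = [Block(config.block_size, config.block_rho)
              for _ in range(config.n_blocks)]
    panel = simulate_genotypes(config.n_individuals, blocks, seed)
    causal = config.causal
    if causal.seed != seed:
        from dataclasses import replace as _replace
        causal = _replace(causal, seed=seed)
    traits = simulate_traits(panel, causal)
    registry = list(causal.trait_ids)

    stats = {t: run_gwas(panel, traits, t) for t in registry}
    instruments = {t: select_instruments(stats[t], panel, config.p_threshold,
                                         config.clump_r2, config.clump_kb)
                   for t in registry}

    # genetic correlation matrix
    rg_matrix = pd.DataFrame(np.nan, index=registry, columns=registry)
    if config.run_ldsc:
        ld = compute_ld_scores(panel, config.ldsc_window_kb)
        ztabs = {}
        for t in registry:
            try:
                ztabs[t] = munge(stats[t], ld)
            except ValueError as err:
                logger.warning("munge failed for %s: %s", t, err)
        for i, t1 in enumerate(registry):
            rg_matrix.loc[t1, t1] = 1.0
            for t2 in registry[i + 1:]:
                if t1 not in ztabs or t2 not in ztabs:
                    continue
                try:
                    res = ldsc_rg(ztabs[t1], ztabs[t2], ld,
                                  n_overlap=config.n_individuals,
                                  pheno_corr=float(np.corrcoef(
                                      traits.values[t1].fillna(traits.values[t1].mean()),
                                      traits.values[t2].fillna(traits.values[t2].mean()))[0, 1]))
                    rg_matrix.loc[t1, t2] = rg_matrix.loc[t2, t1] = res.rg
                except ValueError as err:
                    logger.warning("ldsc_rg failed for (%s, %s): %s", t1, t2, err)

    plan = build_pair_plan(registry)
    pair_reports, mr_rows, sens_rows = [], [], []
    for pair in plan.pairs:
        rep = run_pair(stats[pair.exposure], stats[pair.outcome],
                       instruments[pair.exposure], seed=seed,
                       n_boot=config.n_boot,
                       presso_n_sim=config.presso_n_sim,
                       category=pair.category)
        pair_reports.append(rep)
        for r in rep.results:
            row = r.to_row()
            row.update({"category": pair.category, "status": rep.status,
                        "mean_f": rep.mean_f, "q": r.q, "q_p": r.q_p})
            (mr_rows if r.method == "IVW" else sens_rows).append(row)
            if r.method != "IVW":
                row["egger_intercept"] = r.egger_intercept
                row["egger_intercept_p"] = r.egger_intercept_p
                row["i2_gx"] = r.i2_gx
        if rep.status == "skipped":
            mr_rows.append({"exposure": pair.exposure, "outcome": pair.outcome,
                            "method": "IVW", "category": pair.category,
                            "status": "skipped"})
        if rep.presso is not None:
            sens_rows.append({
                "exposure": pair.exposure, "outcome": pair.outcome,
                "method": "MR-PRESSO", "category": pair.category,
                "p": rep.presso.global_p,
                "nsnp": rep.harmonised_k,
                "notes": f"outliers={rep.presso.outliers}"})
        if rep.steiger is not None:
            sens_rows.append({
                "exposure": pair.exposure, "outcome": pair.outcome,
                "method": "Steiger", "category": pair.category,
                "b": np.nan, "p": rep.steiger.p,
                "notes": f"direction_correct={rep.steiger.direction_correct}"})
    mr_results = pd.DataFrame(mr_rows)
    sensitivity = pd.DataFrame(sens_rows)

    split_meta = pd.DataFrame()
    if config.run_split_sample:
        split_meta = run_split_sample_study(panel, traits, plan, seed=seed,
                                            p_threshold=config.p_threshold,
                                            clump_r2=config.clump_r2,
                                            clump_kb=config.clump_kb)

    manifest = {
        "version": __version__, "seed": seed,
        "n_individuals": config.n_individuals,
        "n_snps": panel.n_snps,
        "p_threshold": config.p_threshold, "clump_r2": config.clump_r2,
        "clump_kb": config.clump_kb,
        "traits": registry,
        "instrument_counts": {t: instruments[t].k for t in registry},
    }
    report = StudyReport(plan, rg_matrix, mr_results, sensitivity, split_meta,
                         instruments, pair_reports, manifest)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        rg_matrix.to_csv(out / "rg_matrix.tsv", sep="\t")
        mr_results.to_csv(out / "mr_primary.tsv", sep="\t", index=False)
        sensitivity.to_csv(out / "mr_sensitivity.tsv", sep="\t", index=False)
        split_meta.to_csv(out / "split_sample_meta.tsv", sep="\t", index=False)
        plan.to_frame().to_csv(out / "pair_plan.tsv", sep="\t", index=False)
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
    return report
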