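"""Mutation, survival and clinical-category screens over patient groups.

The prevalent-state group is split by a driver gene's mutation status (A1 =
driver-WT, A2 = driver-MUT); per-gene mutation rates in the two strata feed
a rate-difference filter, Fisher exact tests and Benjamini-Hochberg FDR to
find co-occurring partners.  Each gene is also screened for survival impact
by two-group log-rank within a stratum, and subgroups are compared on
clinico-molecular category profiles by proportion tests, with bootstrap
resampling from a reference population as the non-randomness control.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests
from lifelines.statistics import logrank_test as _ll_logrank

from .io import AnalysisConfig, ClinicalTable, MutationTable, MISSING
from .binarize import PatientGroup

__all__ = [
    "split_by_mutation", "mutation_rates", "candidate_genes",
    "fisher_exact_2x2", "bh_adjust", "mutation_screen",
    "two_proportion_test", "k_proportion_test", "logrank_test",
    "survival_screen", "category_profile_compare", "bootstrap_nonrandomness",
    "BootstrapReport",
]

SCREEN_COLUMNS = ["gene_id", "rate_A1", "rate_A2", "rate_diff",
                  "p_fisher", "q_bh", "passed"]
SURVIVAL_COLUMNS = ["gene_id", "stratum", "endpoint", "n_mut", "n_wt",
                    "logrank_chi2", "p", "q_bh"]


# ---------------------------------------------------------------------------
# group dissection
# ---------------------------------------------------------------------------

def split_by_mutation(group: PatientGroup, gene: str, mut: MutationTable,
                      ) -> tuple[PatientGroup, PatientGroup, list[str]]:
    """Partition a group into WT and MUT strata for one gene.

    Returns ``(wt_group, mut_group, missing_samples)``; samples without a
    call for the gene are reported separately, never silently dropped.
    """
    if gene not in mut.status.columns:
        raise KeyError(f"gene {gene!r} not in mutation table")
    col = mut.status[gene].reindex(group.members).fillna(MISSING)
    wt = [s for s in group.members if col[s] == "WT"]
    mt = [s for s in group.members if col[s] == "MUT"]
    missing = [s for s in group.members if col[s] == MISSING]
    wt_g = PatientGroup(name=f"{group.name}|{gene}WT", members=wt,
                        defining_predicate=f"{group.defining_predicate} & {gene}=WT")
    mt_g = PatientGroup(name=f"{group.name}|{gene}MUT", members=mt,
                        defining_predicate=f"{group.defining_predicate} & {gene}=MUT")
    return wt_g, mt_g, missing


def mutation_rates(group: PatientGroup, mut: MutationTable) -> pd.Series:
    """Per-gene mutated fraction among group members, MISSING excluded.

    Genes with no callable member are absent from the result.
    """
    if not group.members:
        raise ValueError("empty group")
    sub = mut.status.reindex(group.members)
    n_mut = (sub == "MUT").sum(axis=0)
    n_called = (sub != MISSING).sum(axis=0) - sub.isna().sum(axis=0)
    rates = n_mut[n_called > 0] / n_called[n_called > 0]
    return rates.astype(float)


def candidate_genes(rates_a1: pd.Series, rates_a2: pd.Series,
                    cutoff: float = 0.05) -> list[str]:
    """Genes whose mutation-rate difference strictly exceeds the cutoff."""
    shared = rates_a1.index.intersection(rates_a2.index)
    diff = (rates_a2[shared] - rates_a1[shared]).abs()
    return sorted(diff.index[diff > cutoff])


# ---------------------------------------------------------------------------
# elementary tests
# ---------------------------------------------------------------------------

def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p for a 2x2 table of non-negative counts.

    Sums the hypergeometric probabilities of all tables with the observed
    margins whose probability does not exceed the observed one (within 1e-7
    relative slack, the convention of R's fisher.test).  A zero margin gives
    p = 1 by convention.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError(f"need a non-negative 2x2 table, got {table!r}")
    a = int(t[0, 0])
    r1, r2 = int(t[0].sum()), int(t[1].sum())
    c1 = int(t[:, 0].sum())
    n = r1 + r2
    if n == 0:
        raise ValueError("empty table")
    if 0 in (r1, r2, c1, n - c1):
        return 1.0
    support = np.arange(max(0, c1 - r2), min(r1, c1) + 1)
    pmf = sps.hypergeom.pmf(support, n, r1, c1)
    p_obs = pmf[support == a][0]
    p = float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())
    return min(p, 1.0)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def two_proportion_test(x1: int, n1: int, x2: int, n2: int,
                        yates: bool = True) -> tuple[float, float]:
    """Chi-square test of two proportions (R prop.test).

    Yates continuity correction is on by default, matching prop.test; pass
    ``yates=False`` for the plain Pearson chi-square.
    """
    for x, n in ((x1, n1), (x2, n2)):
        if n <= 0:
            raise ValueError("group size must be positive")
        if not 0 <= x <= n:
            raise ValueError(f"count {x} outside [0, {n}]")
    table = np.array([[x1, n1 - x1], [x2, n2 - x2]], dtype=float)
    if table.sum(axis=0).min() == 0:  # degenerate margin: no information
        return 0.0, 1.0
    chi2, p, _, _ = sps.chi2_contingency(table, correction=yates)
    return float(chi2), float(p)


def k_proportion_test(xs, ns) -> tuple[float, int, float]:
    """Chi-square test that k >= 2 proportions are equal (no correction)."""
    xs = np.asarray(xs, dtype=float)
    ns = np.asarray(ns, dtype=float)
    if xs.shape != ns.shape or xs.size < 2:
        raise ValueError("need matching count/size vectors of length >= 2")
    if (ns <= 0).any():
        raise ValueError("all group sizes must be positive")
    table = np.stack([xs, ns - xs])
    if table.sum(axis=1).min() == 0:
        return 0.0, int(xs.size - 1), 1.0
    chi2, p, dof, _ = sps.chi2_contingency(table, correction=False)
    return float(chi2), int(dof), float(p)


def logrank_test(times, events, labels) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi2, p).

    At each distinct event time the observed events in group 1 are compared
    with the hypergeometric expectation; chi2 = (O-E)^2/V on 1 df.  If no
    events occurred at all, p = 1 with a warning.
    """
    import warnings

    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    labels = np.asarray(labels)
    if (times < 0).any():
        raise ValueError("negative times")
    if not set(np.unique(events)) <= {0, 1}:
        raise ValueError("events must be 0/1")
    uniq = np.unique(labels)
    if uniq.size != 2:
        raise ValueError(f"need exactly two non-empty groups, got {uniq.tolist()}")
    if events.sum() == 0:
        warnings.warn("no events in either group; log-rank p set to 1")
        return 0.0, 1.0
    g1 = labels == uniq[0]
    r = _ll_logrank(times[g1], times[~g1], events[g1], events[~g1])
    return float(r.test_statistic), float(r.p_value)


# ---------------------------------------------------------------------------
# screens
# ---------------------------------------------------------------------------

def mutation_screen(a1: PatientGroup, a2: PatientGroup, mut: MutationTable,
                    cfg: AnalysisConfig) -> pd.DataFrame:
    """Rate-filter + Fisher + BH screen for genes co-occurring with the driver.

    Pipeline: per-stratum mutation rates -> genes with rate difference >
    ``cfg.rate_diff_cutoff`` -> two-sided Fisher exact per candidate -> BH
    over the candidate set only -> ``passed`` at ``cfg.fdr_cutoff``.  Rows
    are ordered by (q, p, gene id).
    """
    if set(a1.members) & set(a2.members):
        raise ValueError("strata overlap")
    r1 = mutation_rates(a1, mut)
    r2 = mutation_rates(a2, mut)
    cand = candidate_genes(r1, r2, cfg.rate_diff_cutoff)
    if not cand:
        return pd.DataFrame(columns=SCREEN_COLUMNS)
    rows = []
    for g in cand:
        s1 = mut.status[g].reindex(a1.members)
        s2 = mut.status[g].reindex(a2.members)
        # rows = driver status (A1, A2); columns = gene status (MUT, WT)
        tab = [[int((s1 == "MUT").sum()), int((s1 == "WT").sum())],
               [int((s2 == "MUT").sum()), int((s2 == "WT").sum())]]
        rows.append({"gene_id": g, "rate_A1": r1[g], "rate_A2": r2[g],
                     "rate_diff": r2[g] - r1[g],
                     "p_fisher": fisher_exact_2x2(tab)})
    df = pd.DataFrame(rows)
    df["q_bh"] = bh_adjust(df["p_fisher"].to_numpy())
    df["passed"] = df["q_bh"] < cfg.fdr_cutoff
    return (df.sort_values(["q_bh", "p_fisher", "gene_id"])
            .reset_index(drop=True)[SCREEN_COLUMNS])


def survival_screen(stratum: PatientGroup, mut: MutationTable,
                    clin: ClinicalTable, cfg: AnalysisConfig,
                    genes: list[str] | None = None) -> pd.DataFrame:
    """Per-gene log-rank of MUT vs WT survival within one stratum.

    Every gene with at least ``cfg.min_mutant_group`` mutants (and any WT)
    among the stratum members is tested on OS, and on DFS when present.
    Raw log-rank p-values are the headline screen; a BH column is included
    for reference.  Rows sorted by p.
    """
    members = [s for s in stratum.members if s in clin.data.index]
    endpoints = [("OS", "os_time", "os_event")]
    if "dfs_time" in clin.data.columns:
        endpoints.append(("DFS", "dfs_time", "dfs_event"))
    rows = []
    for g in (genes if genes is not None else mut.status.columns):
        col = mut.status[g].reindex(members)
        mut_ids = [s for s in members if col[s] == "MUT"]
        wt_ids = [s for s in members if col[s] == "WT"]
        if len(mut_ids) < cfg.min_mutant_group or not wt_ids:
            continue
        for ep, tcol, ecol in endpoints:
            sub = clin.data.loc[mut_ids + wt_ids]
            keep = sub[tcol].notna()
            sub = sub[keep]
            lab = np.array([s in set(mut_ids) for s in sub.index])
            if lab.all() or not lab.any():
                continue
            chi2, p = logrank_test(sub[tcol].to_numpy(float),
                                   sub[ecol].to_numpy(int), lab)
            rows.append({"gene_id": g, "stratum": stratum.name, "endpoint": ep,
                         "n_mut": len(mut_ids), "n_wt": len(wt_ids),
                         "logrank_chi2": chi2, "p": p})
    if not rows:
        return pd.DataFrame(columns=SURVIVAL_COLUMNS)
    df = pd.DataFrame(rows)
    df["q_bh"] = np.nan
    for ep in df["endpoint"].unique():
        m = df["endpoint"] == ep
        df.loc[m, "q_bh"] = bh_adjust(df.loc[m, "p"].to_numpy())
    return df.sort_values(["endpoint", "p", "gene_id"]).reset_index(drop=True)[
        SURVIVAL_COLUMNS]


# ---------------------------------------------------------------------------
# clinico-molecular category comparison and bootstrap control
# ---------------------------------------------------------------------------

def _level_counts(members: list[str], clin: ClinicalTable, cat: str) -> pd.Series:
    vals = clin.data[cat].reindex(members)
    vals = vals[vals.notna() & (vals != MISSING)]
    return vals.value_counts()


def category_profile_compare(g1: PatientGroup, g2: PatientGroup,
                             clin: ClinicalTable, cfg: AnalysisConfig,
                             ) -> pd.DataFrame:
    """Compare two groups' clinico-molecular category profiles.

    For each category present in the clinical table: a whole-table
    chi-square over the observed levels (``p``), plus per-level
    level-vs-rest two-proportion tests (``p_levels``).  MISSING entries are
    excluded; a category with a single observed level is flagged with p = 1.
    Continuity correction for the per-level tests follows
    ``cfg.proportion_correction`` (off by default).
    """
    if set(g1.members) & set(g2.members):
        raise ValueError("groups overlap")
    rows = []
    for cat in clin.categories:
        c1 = _level_counts(g1.members, clin, cat)
        c2 = _level_counts(g2.members, clin, cat)
        levels = sorted(set(c1.index) | set(c2.index))
        n1, n2 = int(c1.sum()), int(c2.sum())
        counts1 = {lv: int(c1.get(lv, 0)) for lv in levels}
        counts2 = {lv: int(c2.get(lv, 0)) for lv in levels}
        if len(levels) < 2 or n1 == 0 or n2 == 0:
            rows.append({"category": cat, "levels": levels,
                         "counts_g1": counts1, "counts_g2": counts2,
                         "n_g1": n1, "n_g2": n2, "test_chi2": 0.0, "p": 1.0,
                         "p_levels": {lv: 1.0 for lv in levels},
                         "degenerate": True})
            continue
        table = np.array([[counts1[lv] for lv in levels],
                          [counts2[lv] for lv in levels]], dtype=float)
        keep = table.sum(axis=0) > 0
        chi2, p, _, _ = sps.chi2_contingency(table[:, keep], correction=False)
        p_levels = {}
        for lv in levels:
            _, p_levels[lv] = two_proportion_test(
                counts1[lv], n1, counts2[lv], n2,
                yates=cfg.proportion_correction)
        rows.append({"category": cat, "levels": levels,
                     "counts_g1": counts1, "counts_g2": counts2,
                     "n_g1": n1, "n_g2": n2,
                     "test_chi2": float(chi2), "p": float(p),
                     "p_levels": p_levels, "degenerate": False})
    return pd.DataFrame(rows)


@dataclass
class BootstrapReport:
    """Null re-sampling control for the category comparison.

    ``design`` names the reference population (1 = all patients, 2 =
    driver-MUT, 3 = driver-WT).  Each replicate draws two pseudo-groups of
    the observed subgroup sizes with replacement from the reference and
    re-runs the category comparison; a mostly non-significant report means
    the observed subgroup differences are not a sampling artifact.
    """

    design: int
    reps: int
    alpha: float
    replicate_pvalues: list[dict[str, float]] = field(default_factory=list)
    frac_significant: list[float] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {"design": self.design, "reps": self.reps, "alpha": self.alpha,
                "replicate_pvalues": self.replicate_pvalues,
                "frac_significant": self.frac_significant}


def bootstrap_nonrandomness(reference: PatientGroup, g1: PatientGroup,
                            g2: PatientGroup, clin: ClinicalTable,
                            cfg: AnalysisConfig, seed: int,
                            design: int = 1) -> BootstrapReport:
    """Draw pseudo-subgroups from a reference population and re-test categories."""
    if len(g1) > len(reference) or len(g2) > len(reference):
        raise ValueError("subgroups larger than the reference population")
    rng = np.random.default_rng(seed)
    report = BootstrapReport(design=design, reps=cfg.bootstrap_reps, alpha=cfg.alpha)
    pool = np.asarray(reference.members)
    for rep in range(cfg.bootstrap_reps):
        s1 = rng.choice(pool, size=len(g1), replace=True)
        s2 = rng.choice(pool, size=len(g2), replace=True)
        # pseudo-groups may share draws; suffix disambiguates membership
        p1 = PatientGroup(name=f"boot{rep}_1",
                          members=[f"{s}#{i}" for i, s in enumerate(s1)])
        p2 = PatientGroup(name=f"boot{rep}_2",
                          members=[f"{s}#{i + len(s1)}" for i, s in enumerate(s2)])
        expanded = clin.data.loc[list(s1) + list(s2)].copy()
        expanded.index = p1.members + p2.members
        boot_clin = ClinicalTable(data=expanded)
        comp = category_profile_compare(p1, p2, boot_clin, cfg)
        pvals = dict(zip(comp["category"], comp["p"].astype(float)))
        report.replicate_pvalues.append(pvals)
        if pvals:
            report.frac_significant.append(
                float(np.mean([p < cfg.alpha for p in pvals.values()])))
        else:
            report.frac_significant.append(0.0)
    return report
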