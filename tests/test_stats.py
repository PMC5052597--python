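"""Mutation, survival and category screens against independent oracles."""

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from netstrat import (AnalysisConfig, PatientGroup, SimulationParams,
                      bh_adjust, bootstrap_nonrandomness, candidate_genes,
                      category_profile_compare, fisher_exact_2x2,
                      generate_cohort, k_proportion_test, logrank_test,
                      mutation_rates, mutation_screen, split_by_mutation,
                      survival_screen, two_proportion_test)
from netstrat.io import ClinicalTable, MutationTable


def fisher_oracle(a, b, c, d):
    """Exact-integer two-sided Fisher: enumerate all tables with the margins."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    if 0 in (r1, r2, c1, n - c1):
        return 1.0
    n_obs = comb(r1, a) * comb(r2, c1 - a)
    num = sum(comb(r1, x) * comb(r2, c1 - x)
              for x in range(max(0, c1 - r2), min(r1, c1) + 1)
              if comb(r1, x) * comb(r2, c1 - x) <= n_obs)
    return float(Fraction(num, comb(n, c1)))


def bh_oracle(pvals):
    """Step-up by the definition: adj_i = min_{j>=i} p_(j) * m / j, capped."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj_sorted = np.minimum.accumulate(
        (p[order] * m / np.arange(1, m + 1))[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj_sorted, 1.0)
    return out


def _mut_table(statuses):
    """statuses: dict gene -> list over samples S0..Sn-1 of WT/MUT/MISSING."""
    n = len(next(iter(statuses.values())))
    return MutationTable(status=pd.DataFrame(
        statuses, index=[f"S{i}" for i in range(n)]))


# ---------------------------------------------------------------------------
# group dissection
# ---------------------------------------------------------------------------

def test_split_by_mutation_partitions_and_reports_missing():
    mut = _mut_table({"G": ["MUT"] * 4 + ["WT"] * 4 + ["MISSING"] * 2})
    grp = PatientGroup(name="g", members=[f"S{i}" for i in range(10)])
    wt, mt, missing = split_by_mutation(grp, "G", mut)
    assert (len(wt), len(mt), len(missing)) == (4, 4, 2)
    assert set(wt.members) | set(mt.members) | set(missing) == set(grp.members)
    with pytest.raises(KeyError):
        split_by_mutation(grp, "ABSENT", mut)


def test_mutation_rates_excludes_missing_and_omits_uncalled():
    mut = _mut_table({"A": ["MUT"] * 19 + ["WT"] * 66,
                      "B": ["MISSING"] * 85,
                      "C": ["MUT"] * 2 + ["WT"] * 2 + ["MISSING"] * 81})
    grp = PatientGroup(name="g", members=[f"S{i}" for i in range(85)])
    rates = mutation_rates(grp, mut)
    assert rates["A"] == pytest.approx(19 / 85)          # the 22.35% case
    assert "B" not in rates.index
    assert rates["C"] == pytest.approx(0.5)
    with pytest.raises(ValueError):
        mutation_rates(PatientGroup(name="e", members=[]), mut)


def test_candidate_genes_strict_cutoff():
    r1 = pd.Series({"G1": 0.10, "G2": 0.10, "G3": 0.20})
    r2 = pd.Series({"G1": 0.16, "G2": 0.15, "G3": 0.20})
    assert candidate_genes(r1, r2, 0.05) == ["G1"]   # 0.06 in, exactly 0.05 out
    assert candidate_genes(r1, r1, 0.05) == []


# ---------------------------------------------------------------------------
# elementary tests vs oracles
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("table, expected", [
    ([[5, 5], [5, 5]], 1.0),
    ([[3, 0], [0, 3]], 0.1),                      # enumeration: .05+.05
    ([[19, 66], [8, 87]], 0.011621842303734515),  # rates 22.35% vs 8.42%
    ([[0, 10], [0, 12]], 1.0),                    # zero margin convention
])
def test_fisher_worked_examples(table, expected):
    assert fisher_exact_2x2(table) == pytest.approx(expected, rel=1e-7)


def test_fisher_matches_enumeration_and_scipy_on_random_tables(rng):
    for _ in range(300):
        t = rng.integers(0, 25, 4)
        p = fisher_exact_2x2(t.reshape(2, 2))
        assert p == pytest.approx(fisher_oracle(*t), rel=1e-7)
        if min(t[0] + t[1], t[2] + t[3]) > 0:
            assert p == pytest.approx(
                sps.fisher_exact(t.reshape(2, 2))[1], rel=1e-6)


@pytest.mark.parametrize("pvals, expected", [
    ([0.05], [0.05]),
    ([0.01, 0.04, 0.03, 0.02], [0.04, 0.04, 0.04, 0.04]),
    ([0.001, 0.5], [0.002, 0.5]),
])
def test_bh_worked_examples(pvals, expected):
    np.testing.assert_allclose(bh_adjust(pvals), expected, atol=1e-12)


def test_bh_matches_stepup_oracle_and_is_permutation_invariant(rng):
    for _ in range(200):
        p = rng.uniform(1e-6, 1.0, int(rng.integers(1, 50)))
        adj = bh_adjust(p)
        np.testing.assert_allclose(adj, bh_oracle(p), atol=1e-12)
        assert (np.diff(adj[np.argsort(p, kind="stable")]) >= -1e-12).all()
        perm = rng.permutation(p.size)
        np.testing.assert_allclose(bh_adjust(p[perm]), adj[perm], atol=1e-12)
    with pytest.raises(ValueError):
        bh_adjust([0.5, 0.0])


def test_two_proportion_worked_example_pins_correction_convention():
    # Asian-vs-rest: 11/19 vs 15/66; plain chi-square matches the printed
    # convention, Yates is conservative
    chi2, p = two_proportion_test(11, 19, 15, 66, yates=False)
    assert chi2 == pytest.approx(8.5936, abs=1e-3)
    assert p == pytest.approx(0.0033735, abs=1e-5)
    _, p_yates = two_proportion_test(11, 19, 15, 66, yates=True)
    assert p_yates > p
    assert p_yates == pytest.approx(0.008074, abs=1e-4)


def test_two_proportion_trivial_and_errors():
    chi2, p = two_proportion_test(5, 10, 5, 10, yates=False)
    assert chi2 == 0.0 and p == 1.0
    with pytest.raises(ValueError):
        two_proportion_test(5, 0, 1, 10)
    with pytest.raises(ValueError):
        two_proportion_test(11, 10, 1, 10)


def test_k_proportion_matches_pearson_chi_square(rng):
    chi2, df, p = k_proportion_test([5, 10, 15], [20, 20, 30])
    table = np.array([[5, 10, 15], [15, 10, 15]])
    chi2_ref, p_ref, df_ref, _ = sps.chi2_contingency(table, correction=False)
    assert (chi2, df, p) == pytest.approx((chi2_ref, df_ref, p_ref))
    # equal proportions: no signal
    assert k_proportion_test([2, 4, 6], [10, 20, 30])[2] == pytest.approx(1.0)
    with pytest.raises(ValueError):
        k_proportion_test([1, 1], [10, 0])


def test_logrank_worked_example_and_identical_groups():
    chi2, p = logrank_test([1, 2, 3, 4], [1, 1, 1, 1], ["A", "A", "B", "B"])
    assert chi2 == pytest.approx(49 / 17, rel=1e-6)       # hand-computed
    assert p == pytest.approx(0.089555, abs=1e-4)
    chi2_same, p_same = logrank_test([1, 2, 3, 1, 2, 3], [1] * 6,
                                     ["A"] * 3 + ["B"] * 3)
    assert chi2_same == pytest.approx(0.0, abs=1e-12) and p_same == 1.0


def test_logrank_invariances(rng):
    t = rng.exponential(10, 40)
    e = rng.integers(0, 2, 40)
    e[:5] = 1
    lab = np.array(["A"] * 20 + ["B"] * 20)
    chi2, _ = logrank_test(t, e, lab)
    chi2_swap, _ = logrank_test(t, e, np.where(lab == "A", "B", "A"))
    assert chi2 == pytest.approx(chi2_swap, rel=1e-9)
    chi2_scaled, _ = logrank_test(t * 3.7, e, lab)
    assert chi2 == pytest.approx(chi2_scaled, rel=1e-9)


def test_logrank_degenerate_cases():
    with pytest.warns(UserWarning, match="no events"):
        chi2, p = logrank_test([1, 2, 3, 4], [0, 0, 0, 0], ["A", "A", "B", "B"])
    assert p == 1.0
    with pytest.raises(ValueError):
        logrank_test([1, 2], [1, 1], ["A", "A"])


# ---------------------------------------------------------------------------
# screens
# ---------------------------------------------------------------------------

def test_mutation_screen_detects_planted_difference(cfg):
    rng = np.random.default_rng(11)
    n = 100
    planted = (["MUT"] * 5 + ["WT"] * 95, ["MUT"] * 25 + ["WT"] * 75)
    statuses = {"PLANTED": list(planted[0]) + list(planted[1])}
    for g in range(20):
        statuses[f"NULL{g}"] = list(
            np.where(rng.random(2 * n) < 0.15, "MUT", "WT"))
    mut = MutationTable(status=pd.DataFrame(
        statuses, index=[f"S{i}" for i in range(2 * n)]))
    a1 = PatientGroup(name="A1", members=[f"S{i}" for i in range(n)])
    a2 = PatientGroup(name="A2", members=[f"S{i}" for i in range(n, 2 * n)])
    out = mutation_screen(a1, a2, mut, cfg)
    row = out.set_index("gene_id").loc["PLANTED"]
    assert row["passed"]
    assert row["rate_A1"] == 0.05 and row["rate_A2"] == 0.25
    # BH applied over candidates only: q >= p with equality iff last rank
    assert (out["q_bh"] >= out["p_fisher"] - 1e-12).all()


def test_mutation_screen_single_candidate_q_equals_p(cfg):
    mut = _mut_table({"G": ["MUT"] * 3 + ["WT"] * 7 + ["WT"] * 10})
    a1 = PatientGroup(name="A1", members=[f"S{i}" for i in range(10)])
    a2 = PatientGroup(name="A2", members=[f"S{i}" for i in range(10, 20)])
    out = mutation_screen(a2, a1, mut, cfg)   # G mutated only in first 10
    assert len(out) == 1
    assert out["q_bh"].iloc[0] == pytest.approx(out["p_fisher"].iloc[0])


def test_mutation_screen_no_candidates_returns_empty(cfg):
    mut = _mut_table({"G": ["WT"] * 20})
    a1 = PatientGroup(name="A1", members=[f"S{i}" for i in range(10)])
    a2 = PatientGroup(name="A2", members=[f"S{i}" for i in range(10, 20)])
    assert len(mutation_screen(a1, a2, mut, cfg)) == 0
    with pytest.raises(ValueError, match="overlap"):
        mutation_screen(a1, a1, mut, cfg)


def _surv_clinical(times, events):
    n = len(times)
    return ClinicalTable(data=pd.DataFrame(
        {"os_time": times, "os_event": events},
        index=[f"S{i}" for i in range(n)]))


def test_survival_screen_filters_small_mutant_groups(cfg):
    mut = _mut_table({"RARE": ["MUT"] + ["WT"] * 19,
                      "COMMON": ["MUT"] * 8 + ["WT"] * 12})
    clin = _surv_clinical(np.arange(1.0, 21.0), [1] * 20)
    grp = PatientGroup(name="g", members=[f"S{i}" for i in range(20)])
    out = survival_screen(grp, mut, clin, cfg)
    assert set(out["gene_id"]) == {"COMMON"}   # 1 mutant < min_mutant_group=3


def test_survival_screen_recovers_planted_hazard(cfg):
    """HR=3 mutants die faster; planted gene ranks first in >=90% of seeds."""
    n, n_genes, hits = 150, 30, 0
    for seed in range(20):
        rng = np.random.default_rng(100 + seed)
        is_mut = rng.random(n) < 0.3
        lam = 0.01 * np.where(is_mut, 3.0, 1.0)
        t = rng.exponential(1 / lam)
        statuses = {"PLANTED": np.where(is_mut, "MUT", "WT")}
        for g in range(n_genes):
            statuses[f"NULL{g}"] = np.where(rng.random(n) < 0.3, "MUT", "WT")
        mut = MutationTable(status=pd.DataFrame(
            statuses, index=[f"S{i}" for i in range(n)]))
        clin = _surv_clinical(t, [1] * n)
        grp = PatientGroup(name="g", members=[f"S{i}" for i in range(n)])
        out = survival_screen(grp, mut, clin, cfg)
        if out.iloc[0]["gene_id"] == "PLANTED":
            hits += 1
    assert hits >= 18


def _clin_with_race(levels1, levels2):
    labels = levels1 + levels2
    n = len(labels)
    df = pd.DataFrame({"os_time": np.ones(n), "os_event": np.ones(n, int),
                       "race": labels}, index=[f"S{i}" for i in range(n)])
    g1 = PatientGroup(name="g1", members=[f"S{i}" for i in range(len(levels1))])
    g2 = PatientGroup(name="g2",
                      members=[f"S{i}" for i in range(len(levels1), n)])
    return ClinicalTable(data=df), g1, g2


def test_category_compare_reproduces_race_example(cfg):
    clin, g1, g2 = _clin_with_race(
        ["ASIAN"] * 11 + ["WHITE"] * 5 + ["OTHER"] * 3,
        ["ASIAN"] * 15 + ["WHITE"] * 48 + ["OTHER"] * 3)
    out = category_profile_compare(g1, g2, clin, cfg)
    row = out.set_index("category").loc["race"]
    assert row["n_g1"] == 19 and row["n_g2"] == 66
    assert row["p_levels"]["ASIAN"] == pytest.approx(0.0033735, abs=1e-5)
    total = sum(row["counts_g1"].values()) + sum(row["counts_g2"].values())
    assert total == 85  # conservation: level counts sum to group sizes


def test_category_compare_identical_distributions_flat(cfg):
    clin, g1, g2 = _clin_with_race(["ASIAN"] * 5 + ["WHITE"] * 5,
                                   ["ASIAN"] * 5 + ["WHITE"] * 5)
    out = category_profile_compare(g1, g2, clin, cfg)
    assert out["p"].tolist() == pytest.approx([1.0] * len(out))


def test_category_compare_single_level_flagged(cfg):
    clin, g1, g2 = _clin_with_race(["ASIAN"] * 6, ["ASIAN"] * 8)
    out = category_profile_compare(g1, g2, clin, cfg)
    row = out.set_index("category").loc["race"]
    assert row["degenerate"] and row["p"] == 1.0


def test_bootstrap_report_shape_and_determinism(small_cohort, cfg):
    clin = small_cohort.clinical
    members = clin.sample_ids
    ref = PatientGroup(name="ref", members=members)
    g1 = PatientGroup(name="g1", members=members[:20])
    g2 = PatientGroup(name="g2", members=members[20:50])
    r1 = bootstrap_nonrandomness(ref, g1, g2, clin, cfg, seed=5)
    r2 = bootstrap_nonrandomness(ref, g1, g2, clin, cfg, seed=5)
    assert r1.to_dict() == r2.to_dict()                  # same seed, same report
    assert len(r1.replicate_pvalues) == cfg.bootstrap_reps == 5
    # homogeneous reference: most categories non-significant in every replicate
    assert all(frac <= 0.5 for frac in r1.frac_significant)
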