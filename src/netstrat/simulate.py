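"""Synthetic gastric-cancer-like cohorts with planted ground truth.

The generator emulates every statistical structure the pipeline assumes: a
signaling network over gene/miRNA/TF nodes, per-sample binary network
states with one planted dominant state, bimodal log-scale expression whose
two modes are separated well beyond the noise (so largest-gap binarization
is consistent with high probability), a driver gene and a co-mutated
partner whose mutation rate depends on driver status inside the dominant
state, a planted survival gene with a multiplicative hazard effect,
clinical categories skewed in the partner-mutant subgroup, and cell lines
sampled around the group centroids.  Defaults mirror the cohort scale of
the TCGA stomach-adenocarcinoma analysis this package reimplements: 233
samples, a 64-entry network, a dominant state holding 180/233 of the
cohort, driver mutation rate 85/180 and partner rates 8.42% / 22.35%.

All randomness flows from one master seed through named substreams, so
adding a table never perturbs the existing ones.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from . import io as nio
from .io import (AnalysisConfig, ClinicalTable, ExpressionMatrix,
                 MutationTable, NetworkSpec, MISSING)
from .ccm import CellLineProfile

_STREAMS = {name: i for i, name in enumerate(
    ["network", "states", "expression", "mutations", "survival",
     "categories", "cell_lines", "missing"])}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([int(seed), _STREAMS[stream]])


def _default_skews() -> dict:
    # background vs partner-mutant-subgroup level probabilities per category;
    # lauren is deliberately unskewed (the one category the study found flat)
    return {
        "molecular_subtype": ({"CIN": 0.494, "MSI": 0.228, "GS": 0.189, "EBV": 0.089},
                              {"CIN": 0.80, "MSI": 0.10, "GS": 0.10, "EBV": 0.0}),
        "race": ({"ASIAN": 0.25, "WHITE": 0.65, "BLACK": 0.05, "OTHER": 0.05},
                 {"ASIAN": 0.60, "WHITE": 0.25, "BLACK": 0.05, "OTHER": 0.10}),
        "lauren": ({"INTESTINAL": 0.5, "DIFFUSE": 0.4, "MIXED": 0.1},
                   {"INTESTINAL": 0.5, "DIFFUSE": 0.4, "MIXED": 0.1}),
        "cimp": ({"CIMP_HIGH": 0.3, "CIMP_LOW": 0.3, "NON_CIMP": 0.4},
                 {"CIMP_HIGH": 0.65, "CIMP_LOW": 0.2, "NON_CIMP": 0.15}),
        "cn_cluster": ({"HIGH": 0.5, "LOW": 0.5}, {"HIGH": 0.85, "LOW": 0.15}),
        "msi": ({"MSI_HIGH": 0.2, "MSI_LOW": 0.2, "MSS": 0.6},
                {"MSI_HIGH": 0.55, "MSI_LOW": 0.2, "MSS": 0.25}),
    }


@dataclass
class SimulationParams:
    """Cohort-generation parameters; defaults are the study-scale conditions."""

    n_samples: int = 233
    n_network_nodes: int = 64
    n_background_features: int = 200
    dominant_state_fraction: float = 180 / 233
    expression_gap: float = 4.0          # log2 units between the two modes
    expression_noise: float = 0.5        # sd of each mode (gap = 8 sd)
    expression_baseline: float = 2.0     # low-mode mean, log2 scale
    driver_mut_rate: float = 85 / 180
    partner_rate_wt: float = 0.0842      # partner rate given driver-WT (q0)
    partner_rate_mut: float = 0.2235     # partner rate given driver-MUT (q1)
    n_background_mut_genes: int = 100    # sparse genome-wide tail
    background_mut_rate: float = 0.02    # keeps rate-filter selectivity ~3-4%
    n_common_mut_genes: int = 12         # frequently mutated genes (>=20% class)
    common_mut_rate: float = 0.25
    survival_gene_mut_rate: float = 0.30
    baseline_hazard: float = 1.0 / 1000  # per day; median OS ~ 693 days
    hazard_ratio: float = 3.0
    censoring_fraction: float = 0.4
    category_skews: dict = field(default_factory=_default_skews)
    n_cell_lines: int = 3                # per patient group
    cell_line_noise: float = 0.2         # sd around the group centroid, log2
    n_signature_genes: int = 5           # planted per direction in case lines
    signature_shift: float = 8.0         # log2 shift of planted signature genes
    missing_rate: float = 0.0            # MISSING injection into mutation calls
    seed: int = 0

    driver_gene: str = "TP53"
    partner_gene: str = "NRXN1"
    survival_gene: str = "CTNNB1"

    def __post_init__(self) -> None:
        if not 0 < self.dominant_state_fraction < 1:
            raise ValueError("dominant_state_fraction must be in (0,1)")
        if self.dominant_state_fraction * self.n_samples < 2:
            raise ValueError("dominant state would hold fewer than 2 samples")
        if self.expression_gap <= 0 or self.expression_noise <= 0:
            raise ValueError("expression gap and noise must be positive")
        if not 0 <= self.partner_rate_wt <= self.partner_rate_mut <= 1:
            raise ValueError("need 0 <= q0 <= q1 <= 1 for the partner rates")
        if self.hazard_ratio <= 0:
            raise ValueError("hazard_ratio must be positive")


@dataclass
class CohortTruth:
    """Planted ground truth, self-consistent with the emitted tables."""

    dominant_vector: tuple[int, ...]
    state_vectors: dict[str, tuple[int, ...]]
    dominant_members: list[str]
    driver_gene: str
    partner_gene: str
    survival_gene: str
    driver_mut_members: list[str]
    partner_mut_members: list[str]
    survival_mut_members: list[str]
    skew_group_members: list[str]        # dominant & driver-MUT & partner-MUT
    cell_line_groups: dict[str, str]
    signature_up: list[str]
    signature_down: list[str]


@dataclass
class SyntheticCohort:
    expression: ExpressionMatrix
    mutations: MutationTable
    clinical: ClinicalTable
    network: NetworkSpec
    cell_lines: list[CellLineProfile]
    truth: CohortTruth
    params: SimulationParams


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _make_network(p: SimulationParams) -> NetworkSpec:
    """Random connected DAG-like network with the study's kind mix (~53% gene,
    ~16% miRNA, ~31% TF)."""
    rng = _rng(p.seed, "network")
    n = p.n_network_nodes
    n_gene = max(3, round(0.53 * n))
    n_mirna = max(1, round(0.16 * n))
    n_tf = max(1, n - n_gene - n_mirna)
    n_gene = n - n_mirna - n_tf
    names = ([f"WNT{i:03d}" for i in range(1, n_gene + 1)]
             + [f"MIR{i:03d}" for i in range(1, n_mirna + 1)]
             + [f"TF{i:03d}" for i in range(1, n_tf + 1)])
    kinds = ["gene"] * n_gene + ["miRNA"] * n_mirna + ["TF"] * n_tf
    order = rng.permutation(n)
    names = [names[i] for i in order]
    kinds = [kinds[i] for i in order]
    edges = []
    for i in range(1, n):
        j = int(rng.integers(0, i))
        edges.append((names[j], names[i]))
    extra = rng.integers(0, n, size=(n // 2, 2))
    for j, i in extra:
        if j != i:
            edges.append((names[min(j, i)], names[max(j, i)]))
    edges = list(dict.fromkeys(edges))
    return NetworkSpec(nodes=list(zip(names, kinds)), edges=edges,
                       node_order=list(names))


def _make_states(p: SimulationParams, net: NetworkSpec,
                 sample_ids: list[str]) -> tuple[tuple[int, ...], dict]:
    rng = _rng(p.seed, "states")
    n_nodes = len(net.node_order)
    dominant = tuple(int(b) for b in rng.integers(0, 2, n_nodes))
    vectors: dict[str, tuple[int, ...]] = {}
    non_dominant: list[str] = []
    for s in sample_ids:
        if rng.random() < p.dominant_state_fraction:
            vectors[s] = dominant
        else:
            while True:
                v = tuple(int(b) for b in rng.integers(0, 2, n_nodes))
                if v != dominant:
                    break
            vectors[s] = v
            non_dominant.append(s)
    # guarantee both classes occupied at every node: a constant node means all
    # samples match the dominant bit there, so flipping it in one non-dominant
    # sample keeps that sample off the dominant state
    mat = np.array([vectors[s] for s in sample_ids])
    for j in range(n_nodes):
        if mat[:, j].min() == mat[:, j].max() and non_dominant:
            victim = non_dominant[int(rng.integers(0, len(non_dominant)))]
            v = list(vectors[victim])
            v[j] = 1 - v[j]
            vectors[victim] = tuple(v)
    return dominant, vectors


def _censor_upper(lam: float, frac: float) -> float:
    """Upper bound u of U(0,u) censoring so P(C < T) ~= frac under Exp(lam)."""
    if frac <= 0:
        return np.inf
    f = lambda u: (1 - np.exp(-lam * u)) / (lam * u) - frac
    return brentq(f, 1e-9 / lam, 1e6 / lam)


def generate_cohort(p: SimulationParams) -> SyntheticCohort:
    """Generate a full cohort; identical params (incl. seed) are byte-identical."""
    sample_ids = [f"S{i:04d}" for i in range(1, p.n_samples + 1)]
    net = _make_network(p)
    dominant, vectors = _make_states(p, net, sample_ids)
    dom_members = [s for s in sample_ids if vectors[s] == dominant]

    # expression: bimodal per network node, unimodal background; log2 scale
    rng = _rng(p.seed, "expression")
    n_nodes = len(net.node_order)
    bits = np.array([vectors[s] for s in sample_ids]).T       # nodes x samples
    net_vals = (p.expression_baseline + p.expression_gap * bits
                + rng.normal(0, p.expression_noise, bits.shape))
    bg_ids = [f"BG{i:04d}" for i in range(1, p.n_background_features + 1)]
    # per-feature biological level + the shared measurement noise sigma, so
    # the per-sample median picks up only O(sigma/sqrt(n_features)) jitter
    bg_mu = rng.normal(3.0, 1.0, p.n_background_features)
    bg_vals = bg_mu[:, None] + rng.normal(
        0, p.expression_noise, (p.n_background_features, p.n_samples))
    values = pd.DataFrame(np.vstack([net_vals, bg_vals]),
                          index=net.node_order + bg_ids, columns=sample_ids)
    kind_map = {"gene": "mRNA", "miRNA": "miRNA", "TF": "TF"}
    kinds = pd.Series([kind_map[k] for k in (net.node_kinds[n] for n in net.node_order)]
                      + ["mRNA"] * len(bg_ids), index=values.index)
    expr = ExpressionMatrix(values=values, feature_kinds=kinds,
                            transform="log2_x_plus_1")

    # mutations
    rng = _rng(p.seed, "mutations")
    dom_set = set(dom_members)
    driver = rng.random(p.n_samples) < p.driver_mut_rate
    partner = np.zeros(p.n_samples, dtype=bool)
    for i, s in enumerate(sample_ids):
        q = (p.partner_rate_mut if (driver[i] and s in dom_set)
             else p.partner_rate_wt)
        partner[i] = rng.random() < q
    surv = rng.random(p.n_samples) < p.survival_gene_mut_rate
    bgm_ids = [f"MGENE{i:03d}" for i in range(1, p.n_background_mut_genes + 1)]
    bgm = rng.random((p.n_samples, p.n_background_mut_genes)) < p.background_mut_rate
    cgm_ids = [f"CGENE{i:03d}" for i in range(1, p.n_common_mut_genes + 1)]
    cgm = rng.random((p.n_samples, p.n_common_mut_genes)) < p.common_mut_rate
    status = pd.DataFrame(
        np.where(np.column_stack([driver, partner, surv, bgm, cgm]), "MUT", "WT"),
        index=sample_ids,
        columns=[p.driver_gene, p.partner_gene, p.survival_gene]
        + bgm_ids + cgm_ids)
    if p.missing_rate > 0:
        rng_m = _rng(p.seed, "missing")
        mask = rng_m.random(status.shape) < p.missing_rate
        status = status.mask(pd.DataFrame(mask, index=status.index,
                                          columns=status.columns), MISSING)
    mut = MutationTable(status=status)

    # survival: exponential with hazard h0 * HR^(survival-gene mutant)
    rng = _rng(p.seed, "survival")
    haz = p.baseline_hazard * np.where(surv, p.hazard_ratio, 1.0)
    os_t = rng.exponential(1.0 / haz)
    dfs_t = rng.exponential(1.0 / (1.2 * haz))
    u = _censor_upper(p.baseline_hazard, p.censoring_fraction)
    os_c = rng.uniform(0, u, p.n_samples) if np.isfinite(u) else np.full(p.n_samples, np.inf)
    dfs_c = rng.uniform(0, u, p.n_samples) if np.isfinite(u) else np.full(p.n_samples, np.inf)
    clin = pd.DataFrame({
        "os_time": np.round(np.minimum(os_t, os_c), 1),
        "os_event": (os_t <= os_c).astype(int),
        "dfs_time": np.round(np.minimum(dfs_t, dfs_c), 1),
        "dfs_event": (dfs_t <= dfs_c).astype(int),
    }, index=sample_ids)

    # clinical categories, skewed inside dominant & driver-MUT & partner-MUT
    rng = _rng(p.seed, "categories")
    skew_members = [s for i, s in enumerate(sample_ids)
                    if s in dom_set and driver[i] and partner[i]]
    skew_set = set(skew_members)
    for cat, (bg_probs, skew_probs) in p.category_skews.items():
        levels = list(bg_probs)
        bg_p = np.array([bg_probs[l] for l in levels], dtype=float)
        sk_p = np.array([skew_probs[l] for l in levels], dtype=float)
        bg_p, sk_p = bg_p / bg_p.sum(), sk_p / sk_p.sum()
        draws = []
        for s in sample_ids:
            pr = sk_p if s in skew_set else bg_p
            draws.append(levels[int(rng.choice(len(levels), p=pr))])
        clin[cat] = draws
    clinical = ClinicalTable(data=clin)

    # cell lines around the prevalent / other group centroids (mRNA panel)
    rng = _rng(p.seed, "cell_lines")
    panel = net.genes()
    other_members = [s for s in sample_ids if s not in dom_set]
    centroids = {
        "prevalent": values.loc[panel, dom_members].mean(axis=1),
        "other": values.loc[panel, other_members].mean(axis=1)
        if other_members else values.loc[panel, dom_members].mean(axis=1) - p.expression_gap,
    }
    sig_pool = [g for g in bg_ids]
    sig_up = sig_pool[:p.n_signature_genes]
    sig_down = sig_pool[p.n_signature_genes:2 * p.n_signature_genes]
    bg_line_base = pd.Series(bg_mu, index=bg_ids)
    lines: list[CellLineProfile] = []
    cl_groups: dict[str, str] = {}
    n_case = max(1, p.n_cell_lines // 3)
    for grp in ("prevalent", "other"):
        for i in range(p.n_cell_lines):
            lid = f"CL_{grp.upper()}_{i + 1}"
            e_net = centroids[grp] + rng.normal(0, p.cell_line_noise, len(panel))
            e_bg = bg_line_base + rng.normal(0, p.cell_line_noise, len(bg_ids))
            profile = pd.concat([pd.Series(e_net.to_numpy(), index=panel), e_bg])
            is_case = grp == "prevalent" and i < n_case
            if is_case:
                profile[sig_up] += p.signature_shift
                profile[sig_down] -= p.signature_shift
            muts = {p.driver_gene: "MUT" if grp == "prevalent" else "WT",
                    p.partner_gene: "MUT" if is_case else "WT"}
            lines.append(CellLineProfile(cell_line_id=lid, expression=profile,
                                         mutation_status=muts))
            cl_groups[lid] = grp

    truth = CohortTruth(
        dominant_vector=dominant, state_vectors=vectors,
        dominant_members=dom_members,
        driver_gene=p.driver_gene, partner_gene=p.partner_gene,
        survival_gene=p.survival_gene,
        driver_mut_members=[s for i, s in enumerate(sample_ids) if driver[i]],
        partner_mut_members=[s for i, s in enumerate(sample_ids) if partner[i]],
        survival_mut_members=[s for i, s in enumerate(sample_ids) if surv[i]],
        skew_group_members=skew_members, cell_line_groups=cl_groups,
        signature_up=sig_up, signature_down=sig_down)
    return SyntheticCohort(expression=expr, mutations=mut, clinical=clinical,
                           network=net, cell_lines=lines, truth=truth, params=p)


# ---------------------------------------------------------------------------
# audit and persistence
# ---------------------------------------------------------------------------

def truth_audit(c: SyntheticCohort) -> list[str]:
    """Recount every planted quantity from the emitted tables.

    Returns a list of human-readable discrepancies; empty for a fresh cohort.
    """
    issues: list[str] = []
    t = c.truth
    dom = [s for s, v in t.state_vectors.items() if v == t.dominant_vector]
    if sorted(dom) != sorted(t.dominant_members):
        issues.append("dominant membership inconsistent with state vectors")
    status = c.mutations.status
    for gene, planted in ((t.driver_gene, t.driver_mut_members),
                          (t.partner_gene, t.partner_mut_members),
                          (t.survival_gene, t.survival_mut_members)):
        col = status[gene]
        observed = sorted(col.index[col == "MUT"])
        expect = sorted(s for s in planted if col[s] != MISSING)
        if observed != expect:
            issues.append(f"mutation calls for {gene} disagree with planted truth")
    if not set(t.skew_group_members) <= set(t.dominant_members):
        issues.append("skew group not inside the dominant group")
    for cat in c.clinical.categories:
        obs = set(c.clinical.data[cat].unique()) - {MISSING}
        if not obs:
            issues.append(f"category {cat} has no observed levels")
        elif not obs <= set(nio.CATEGORY_VOCAB[cat]):
            issues.append(f"category {cat} has out-of-vocabulary levels")
    for line in c.cell_lines:
        if line.cell_line_id not in t.cell_line_groups:
            issues.append(f"cell line {line.cell_line_id} missing from truth")
    return issues


def write_cohort(c: SyntheticCohort, outdir: str | Path) -> dict[str, Path]:
    """Write all cohort tables in the standard TSV formats plus a truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": outdir / "expression.tsv",
        "mutations": outdir / "mutations.tsv",
        "clinical": outdir / "clinical.tsv",
        "network": outdir / "network.tsv",
        "cell_lines_expr": outdir / "cell_lines_expression.tsv",
        "cell_lines_mut": outdir / "cell_lines_mutations.tsv",
        "truth": outdir / "truth.json",
    }
    nio.write_expression(c.expression, paths["expression"])
    nio.write_mutations(c.mutations, paths["mutations"])
    nio.write_clinical(c.clinical, paths["clinical"])
    nio.write_network(c.network, paths["network"])
    cl_expr = pd.DataFrame({l.cell_line_id: l.expression for l in c.cell_lines})
    cl_expr.to_csv(paths["cell_lines_expr"], sep="\t", index_label="gene_id",
                   float_format="%.10g")
    cl_mut = pd.DataFrame({l.cell_line_id: pd.Series(l.mutation_status)
                           for l in c.cell_lines}).T
    cl_mut.to_csv(paths["cell_lines_mut"], sep="\t", index_label="cell_line_id")
    truth = dataclasses.asdict(c.truth)
    truth["dominant_vector"] = list(truth["dominant_vector"])
    truth["state_vectors"] = {k: list(v) for k, v in truth["state_vectors"].items()}
    with open(paths["truth"], "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
    return paths
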