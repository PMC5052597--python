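"""Input/output, expression transforms and run configuration.

All tabular formats are plain TSV so that cohorts round-trip through text.
Expression matrices are features x samples with a header row of sample ids
and the feature id in the first column.  Mutation tables are accepted either
wide (samples x genes with 0/1/NA cells) or long (sample_id, gene_id,
status).  The clinical table carries survival endpoints (time in days plus a
0/1 event flag) and a fixed vocabulary of clinico-molecular categories.

Expression transforms follow the conventions of RNA-seq level-3 processing:
mRNA (and TF) features are log2(x+1) on RPKM, miRNA features log2(x+eps) on
RPM, followed by per-sample median centering in log space.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import networkx as nx
import yaml

FEATURE_KINDS = ("mRNA", "miRNA", "TF")
MUT_STATUSES = ("WT", "MUT", "MISSING")
MISSING = "MISSING"

#: clinical category columns and their declared level vocabularies
CATEGORY_VOCAB: dict[str, tuple[str, ...]] = {
    "molecular_subtype": ("CIN", "MSI", "GS", "EBV"),
    "race": ("ASIAN", "WHITE", "BLACK", "OTHER"),
    "lauren": ("INTESTINAL", "DIFFUSE", "MIXED"),
    "cimp": ("CIMP_HIGH", "CIMP_LOW", "NON_CIMP"),
    "cn_cluster": ("HIGH", "LOW"),
    "msi": ("MSI_HIGH", "MSI_LOW", "MSS"),
}


class NetstratError(Exception):
    """Base class for all package errors."""


class FormatError(NetstratError):
    """Malformed or inconsistent input file."""


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------

TRANSFORMS = ("raw", "log2_x_plus_1", "log2_x", "median_normalized")


@dataclass
class ExpressionMatrix:
    """Continuous feature x sample expression with provenance.

    ``values`` is a DataFrame indexed by feature id with sample-id columns;
    ``feature_kinds`` maps each feature to mRNA / miRNA / TF.  ``transform``
    records what has been applied to the raw scale.
    """

    values: pd.DataFrame
    feature_kinds: pd.Series
    transform: str = "raw"

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].tolist()
            raise FormatError(f"duplicate feature ids: {dups}")
        if self.values.columns.duplicated().any():
            dups = self.values.columns[self.values.columns.duplicated()].tolist()
            raise FormatError(f"duplicate sample ids: {dups}")
        self.feature_kinds = self.feature_kinds.reindex(self.values.index)
        bad = set(self.feature_kinds.dropna()) - set(FEATURE_KINDS)
        if bad:
            raise FormatError(f"unknown feature kinds: {sorted(bad)}")
        if self.transform not in TRANSFORMS:
            raise FormatError(f"unknown transform tag: {self.transform!r}")
        if self.transform != "raw" and not np.isfinite(self.values.to_numpy()).all():
            raise FormatError("non-finite values after transform")

    @property
    def feature_ids(self) -> list[str]:
        return self.values.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.values.columns.tolist()


@dataclass
class MutationTable:
    """Sample x gene mutation status with explicit MISSING handling.

    ``status`` holds strings in {WT, MUT, MISSING}; MISSING means no call is
    available for that (sample, gene) pair and is excluded from rate
    denominators downstream.
    """

    status: pd.DataFrame  # samples x genes

    def __post_init__(self) -> None:
        if self.status.index.duplicated().any() or self.status.columns.duplicated().any():
            raise FormatError("duplicate sample or gene ids in mutation table")
        bad = set(np.unique(self.status.to_numpy())) - set(MUT_STATUSES)
        if bad:
            raise FormatError(f"invalid mutation statuses: {sorted(bad)}")

    @property
    def sample_ids(self) -> list[str]:
        return self.status.index.tolist()

    @property
    def gene_ids(self) -> list[str]:
        return self.status.columns.tolist()


@dataclass
class ClinicalTable:
    """Survival endpoints plus categorical clinico-molecular annotations.

    ``data`` is indexed by sample id with columns os_time, os_event and
    optionally dfs_time, dfs_event, plus any subset of the declared category
    columns (levels from :data:`CATEGORY_VOCAB` or MISSING).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.index.duplicated().any():
            raise FormatError("duplicate sample ids in clinical table")
        for col in ("os_time", "os_event"):
            if col not in self.data.columns:
                raise FormatError(f"clinical table missing column {col!r}")
        for tcol, ecol in (("os_time", "os_event"), ("dfs_time", "dfs_event")):
            if tcol not in self.data.columns:
                continue
            t = pd.to_numeric(self.data[tcol], errors="raise")
            if (t < 0).any():
                raise FormatError(f"negative times in {tcol}")
            ev = set(pd.to_numeric(self.data[ecol], errors="raise").unique())
            if not ev <= {0, 1}:
                raise FormatError(f"non-binary events in {ecol}: {sorted(ev)}")
        for cat, vocab in CATEGORY_VOCAB.items():
            if cat in self.data.columns:
                bad = set(self.data[cat].dropna()) - set(vocab) - {MISSING}
                if bad:
                    raise FormatError(f"unknown {cat} levels: {sorted(bad)}")

    @property
    def sample_ids(self) -> list[str]:
        return self.data.index.tolist()

    @property
    def categories(self) -> list[str]:
        return [c for c in CATEGORY_VOCAB if c in self.data.columns]


@dataclass
class NetworkSpec:
    """Directed signaling network over gene / miRNA / TF nodes.

    ``node_order`` is the deterministic ordering used for state vectors
    (first appearance in the edge-list file by default).
    """

    nodes: list[tuple[str, str]]  # (id, kind)
    edges: list[tuple[str, str]]
    node_order: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [n for n, _ in self.nodes]
        if len(ids) != len(set(ids)):
            raise FormatError("duplicate node ids in network")
        if not self.node_order:
            self.node_order = list(ids)
        if sorted(self.node_order) != sorted(set(ids)):
            raise FormatError("node_order is not a permutation of node ids")
        idset = set(ids)
        for s, t in self.edges:
            if s not in idset or t not in idset:
                raise FormatError(f"edge endpoint not among nodes: ({s}, {t})")

    @property
    def node_kinds(self) -> dict[str, str]:
        return dict(self.nodes)

    def genes(self) -> list[str]:
        """mRNA gene nodes in node order (the default cell-line panel)."""
        kinds = self.node_kinds
        return [n for n in self.node_order if kinds[n] == "gene"]

    def to_graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for nid, kind in self.nodes:
            g.add_node(nid, kind=kind)
        g.add_edges_from(self.edges)
        return g


@dataclass
class AnalysisConfig:
    """Run configuration: screening cutoffs and simulation seed.

    Defaults are the analysis constants of the workflow: a 5% mutation-rate
    difference filter, FDR 0.15 significance, fold-change 50 for signature
    selection, five bootstrap replicates and alpha 0.05.
    """

    rate_diff_cutoff: float = 0.05
    fdr_cutoff: float = 0.15
    fold_change_cutoff: float = 50.0
    bootstrap_reps: int = 5
    alpha: float = 0.05
    min_mutant_group: int = 3
    rng_seed: int = 0
    proportion_correction: bool = False  # continuity correction for 2-group category tests

    def __post_init__(self) -> None:
        for name in ("rate_diff_cutoff", "fdr_cutoff", "alpha"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0,1), got {v}")
        if self.fold_change_cutoff <= 0:
            raise ValueError("fold_change_cutoff must be positive")
        if self.bootstrap_reps < 1 or self.min_mutant_group < 1:
            raise ValueError("bootstrap_reps and min_mutant_group must be >= 1")

    @classmethod
    def from_mapping(cls, d: Mapping) -> "AnalysisConfig":
        names = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in d.items() if k in names})


# ---------------------------------------------------------------------------
# expression readers / writers and transforms
# ---------------------------------------------------------------------------

_FLOAT_FMT = "%.10g"  # deterministic text round-trip


def read_expression(path: str | Path, kind_map: Mapping[str, str] | None = None,
                    transform: str = "raw") -> ExpressionMatrix:
    """Read a TSV expression matrix (header = sample ids, column 1 = feature id).

    ``kind_map`` assigns mRNA/miRNA/TF per feature; unmapped features default
    to mRNA.  ``transform`` declares the provenance of the stored values for
    matrices that are already log-transformed.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    if len(header) != len(set(header)):  # pandas would silently mangle these
        raise FormatError(f"{path}: duplicate sample columns")
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if df.index.duplicated().any():
        raise FormatError(f"{path}: duplicate feature ids")
    try:
        df = df.astype(float)
    except (TypeError, ValueError):
        for col in df.columns:
            bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
            if bad.any():
                row = df.index[bad][0]
                raise FormatError(f"{path}: non-numeric cell at row {row!r}, column {col!r}")
        raise
    kinds = pd.Series([(kind_map or {}).get(f, "mRNA") for f in df.index], index=df.index)
    return ExpressionMatrix(values=df, feature_kinds=kinds, transform=transform)


def write_expression(m: ExpressionMatrix, path: str | Path) -> None:
    m.values.to_csv(path, sep="\t", index_label="feature_id", float_format=_FLOAT_FMT)


def log_transform(m: ExpressionMatrix, mirna_eps: float = 1.0) -> ExpressionMatrix:
    """Apply the kind-specific log transforms to a raw matrix.

    mRNA/TF rows become log2(x+1); miRNA rows log2(x+eps), eps default 1 so
    zero counts stay at zero (log2(x) alone is undefined at x=0).
    """
    if m.transform != "raw":
        raise ValueError(f"expected raw matrix, got transform={m.transform!r}")
    vals = m.values.to_numpy(dtype=float)
    if np.isnan(vals).any():
        raise ValueError("NaN in expression values")
    if (vals < 0).any():
        raise ValueError("negative expression values cannot be log-transformed")
    is_mirna = (m.feature_kinds == "miRNA").to_numpy()
    out = np.empty_like(vals)
    out[~is_mirna] = np.log2(vals[~is_mirna] + 1.0)
    out[is_mirna] = np.log2(vals[is_mirna] + mirna_eps)
    df = pd.DataFrame(out, index=m.values.index, columns=m.values.columns)
    return ExpressionMatrix(values=df, feature_kinds=m.feature_kinds,
                            transform="log2_x_plus_1")


def median_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Center each sample column at median zero (log-scale subtraction)."""
    if m.values.empty:
        raise ValueError("cannot median-normalize an empty matrix")
    centered = m.values - m.values.median(axis=0)
    return ExpressionMatrix(values=centered, feature_kinds=m.feature_kinds,
                            transform="median_normalized")


# ---------------------------------------------------------------------------
# mutation / clinical / network readers and writers
# ---------------------------------------------------------------------------

def read_mutations(path: str | Path) -> MutationTable:
    """Read a mutation table, wide (0/1/NA matrix) or long (sample, gene, status)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = [c.lower() for c in df.columns]
    if cols[:3] == ["sample_id", "gene_id", "status"]:
        df.columns = cols
        bad = set(df["status"]) - set(MUT_STATUSES)
        if bad:
            raise FormatError(f"{path}: invalid statuses {sorted(bad)}")
        if df.duplicated(["sample_id", "gene_id"]).any():
            raise FormatError(f"{path}: duplicate (sample, gene) rows")
        wide = df.pivot(index="sample_id", columns="gene_id", values="status")
        wide = wide.fillna(MISSING)
        wide.index.name = None
        wide.columns.name = None
        return MutationTable(status=wide)
    wide = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    wide.index = wide.index.astype(str)
    mapping = {"0": "WT", "1": "MUT", "NA": MISSING, "": MISSING,
               "WT": "WT", "MUT": "MUT", MISSING: MISSING}
    out = wide.fillna(MISSING).map(lambda v: mapping.get(str(v).strip()))
    if out.isna().any().any():
        raise FormatError(f"{path}: unrecognized mutation cell values")
    return MutationTable(status=out)


def write_mutations(mut: MutationTable, path: str | Path) -> None:
    """Write the long-format mutation table (sample_id, gene_id, status)."""
    long = (mut.status.stack().rename("status").rename_axis(["sample_id", "gene_id"])
            .reset_index())
    long.to_csv(path, sep="\t", index=False)


def read_clinical(path: str | Path) -> ClinicalTable:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    for col in df.columns:
        if col.endswith(("_time", "_event")):
            df[col] = pd.to_numeric(df[col])
    return ClinicalTable(data=df)


def write_clinical(clin: ClinicalTable, path: str | Path) -> None:
    clin.data.to_csv(path, sep="\t", index_label="sample_id", float_format=_FLOAT_FMT)


def read_network(path: str | Path) -> NetworkSpec:
    """Read an edge-list TSV (source, source_kind, target, target_kind).

    Nodes are deduplicated in first-appearance order.  Self-loops are kept
    (with a warning); one id carrying two different kinds is an error.
    """
    import warnings

    df = pd.read_csv(path, sep="\t", dtype=str,
                     names=["source", "source_kind", "target", "target_kind"],
                     header=None, comment="#")
    kinds: dict[str, str] = {}
    order: list[str] = []
    edges: list[tuple[str, str]] = []
    for _, row in df.iterrows():
        for nid, kind in ((row.source, row.source_kind), (row.target, row.target_kind)):
            if nid in kinds:
                if kinds[nid] != kind:
                    raise FormatError(
                        f"{path}: node {nid!r} declared with kinds "
                        f"{kinds[nid]!r} and {kind!r}")
            else:
                kinds[nid] = kind
                order.append(nid)
        if row.source == row.target:
            warnings.warn(f"self-loop retained on node {row.source!r}")
        edges.append((row.source, row.target))
    return NetworkSpec(nodes=[(n, kinds[n]) for n in order], edges=edges,
                       node_order=order)


def write_network(net: NetworkSpec, path: str | Path) -> None:
    kinds = net.node_kinds
    rows = [(s, kinds[s], t, kinds[t]) for s, t in net.edges]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, header=False)


def read_config(path: str | Path) -> AnalysisConfig:
    """Read an AnalysisConfig from a YAML key-value file."""
    with open(path) as fh:
        d = yaml.safe_load(fh) or {}
    return AnalysisConfig.from_mapping(d)


def write_config(cfg: AnalysisConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dataclasses.asdict(cfg), fh, sort_keys=True)
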