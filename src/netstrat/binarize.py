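"""Largest-gap expression binarization and network-state enumeration.

Each feature is thresholded at the lower member of the widest gap between
adjacent values in its ascending sort ("edge detection"): values <= cutoff
become 0, values > cutoff become 1.  A network state is the ordered binary
vector over the signaling network's nodes; samples sharing a vector share a
state, and the state holding the most samples defines the prevalent patient
group that downstream mutation and survival screens dissect.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, NetworkSpec, NetstratError


class StateTieError(NetstratError):
    """Raised when two states tie for the most members."""


@dataclass
class BinaryMatrix:
    """Per-feature binarized expression with the cutoffs that produced it."""

    bits: pd.DataFrame      # features x samples, int8 0/1
    cutoffs: pd.Series      # per-feature threshold

    def __post_init__(self) -> None:
        vals = set(np.unique(self.bits.to_numpy()))
        if not vals <= {0, 1}:
            raise NetstratError(f"non-binary entries: {sorted(vals)}")

    @property
    def feature_ids(self) -> list[str]:
        return self.bits.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.bits.columns.tolist()


@dataclass
class NetworkState:
    """One observed 0/1 vector over the network node order and its samples."""

    state_vector: tuple[int, ...]
    state_label: int            # 1 = most populated
    members: list[str]

    @property
    def count(self) -> int:
        return len(self.members)


@dataclass
class PatientGroup:
    """A named set of cohort samples defined by a state and/or mutation predicate."""

    name: str
    members: list[str]
    defining_predicate: str = ""

    def __post_init__(self) -> None:
        if len(set(self.members)) != len(self.members):
            raise NetstratError(f"group {self.name!r} has duplicate members")

    def __len__(self) -> int:
        return len(self.members)


def binarize_feature(values: np.ndarray | list[float]) -> tuple[float, np.ndarray]:
    """Threshold one feature at the largest adjacent gap of its sorted values.

    Returns ``(cutoff, bits)`` where ``cutoff`` is the lower member of the
    first maximal gap in the ascending sort and ``bits[i] = 1`` iff
    ``values[i] > cutoff``.  Ties among maximal gaps break to the lowest
    sorted position; a constant feature yields all-zero bits.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty value vector")
    if np.isnan(v).any():
        raise ValueError("NaN in value vector")
    s = np.sort(v)
    if s.size == 1 or s[-1] == s[0]:
        cutoff = float(s[0])
        return cutoff, np.zeros(v.shape, dtype=np.int8)
    gaps = np.diff(s)
    cutoff = float(s[int(np.argmax(gaps))])  # argmax returns first maximum
    return cutoff, (v > cutoff).astype(np.int8)


def binarize_matrix(m: ExpressionMatrix) -> BinaryMatrix:
    """Apply :func:`binarize_feature` independently to every feature row."""
    bits = np.empty(m.values.shape, dtype=np.int8)
    cutoffs = np.empty(m.values.shape[0])
    arr = m.values.to_numpy(dtype=float)
    for i, fid in enumerate(m.values.index):
        try:
            cutoffs[i], bits[i] = binarize_feature(arr[i])
        except ValueError as exc:
            raise ValueError(f"feature {fid!r}: {exc}") from exc
    return BinaryMatrix(
        bits=pd.DataFrame(bits, index=m.values.index, columns=m.values.columns),
        cutoffs=pd.Series(cutoffs, index=m.values.index, name="cutoff"),
    )


def enumerate_states(b: BinaryMatrix, net: NetworkSpec,
                     drop_missing: bool = False) -> list[NetworkState]:
    """Group samples by their binary vector over the network node order.

    States are labeled 1..k by descending member count, ties broken by
    lexicographic vector order, so State 1 is always the prevalent state.
    Network nodes absent from the matrix raise unless ``drop_missing``.
    """
    present = [n for n in net.node_order if n in b.bits.index]
    missing = [n for n in net.node_order if n not in b.bits.index]
    if missing and not drop_missing:
        raise KeyError(f"network nodes missing from binary matrix: {missing}")
    if not present:
        raise ValueError("no network nodes present in binary matrix")
    sub = b.bits.loc[present]
    groups: dict[tuple[int, ...], list[str]] = {}
    for sample in sub.columns:
        vec = tuple(int(x) for x in sub[sample].to_numpy())
        groups.setdefault(vec, []).append(sample)
    ordered = sorted(groups.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    return [NetworkState(state_vector=vec, state_label=i + 1, members=members)
            for i, (vec, members) in enumerate(ordered)]


def prevalent_group(states: list[NetworkState]) -> PatientGroup:
    """Return the unique maximal-count state's samples as Group prevalent.

    A tie for the maximum is an error: the stratification is only defined
    when one state dominates.
    """
    if not states:
        raise ValueError("empty state list")
    top = max(s.count for s in states)
    tied = [s for s in states if s.count == top]
    if len(tied) > 1:
        labels = [s.state_label for s in tied]
        raise StateTieError(f"states {labels} tie for most members (n={top})")
    s = tied[0]
    return PatientGroup(
        name="prevalent", members=list(s.members),
        defining_predicate=f"network state {''.join(map(str, s.state_vector))}")


# ---------------------------------------------------------------------------
# text export
# ---------------------------------------------------------------------------

def write_binary_matrix(b: BinaryMatrix, bits_path: str | Path,
                        cutoffs_path: str | Path) -> None:
    b.bits.to_csv(bits_path, sep="\t", index_label="feature_id")
    b.cutoffs.to_frame().to_csv(cutoffs_path, sep="\t", index_label="feature_id",
                                float_format="%.10g")


def write_states(states: list[NetworkState], path: str | Path) -> None:
    rows = [{"state_label": s.state_label,
             "vector": "".join(map(str, s.state_vector)),
             "n_members": s.count,
             "members": ",".join(s.members)} for s in states]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def flattened_table(b: BinaryMatrix, net: NetworkSpec) -> pd.DataFrame:
    """Optional edge-flattened report: one column pair per directed edge.

    Duplicated node columns carry identical bits by construction, so state
    identity is defined over unique nodes; this table is presentational.
    """
    cols = {}
    for i, (s, t) in enumerate(net.edges):
        cols[f"{s}__e{i}"] = b.bits.loc[s]
        cols[f"{t}__e{i}"] = b.bits.loc[t]
    return pd.DataFrame(cols).T
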