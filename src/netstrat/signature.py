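"""Fold-change signatures for drug connectivity queries.

With only a handful of cell lines per group, differential expression by
p-value is underpowered; instead genes are selected by the linear fold
change between the case and control group means on log2 expression, with a
symmetric cutoff (FC > c up, FC < 1/c down, default c = 50).  The up/down
lists are written as plain ``.grp`` text files, the query format of
connectivity-map style tools.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .ccm import CellLineProfile


@dataclass
class SignatureResult:
    fold_changes: pd.Series           # gene -> linear FC (case over control)
    up_genes: list[str]
    down_genes: list[str]
    cutoff: float

    def __post_init__(self) -> None:
        if set(self.up_genes) & set(self.down_genes):
            raise ValueError("up and down lists overlap")


def fold_changes(case: list[CellLineProfile], control: list[CellLineProfile],
                 genes: list[str]) -> pd.Series:
    """Linear fold change 2^(mean log2 case - mean log2 control) per gene.

    Genes missing from any profile are omitted (with a warning) rather than
    imputed.
    """
    import warnings

    if not case or not control:
        raise ValueError("both case and control must be nonempty")
    kept, dropped = [], []
    for g in genes:
        if all(g in p.expression.index for p in case + control):
            kept.append(g)
        else:
            dropped.append(g)
    if dropped:
        warnings.warn(f"genes missing from some profiles, omitted: {dropped}")
    case_mean = np.mean([[p.expression[g] for g in kept] for p in case], axis=0)
    ctrl_mean = np.mean([[p.expression[g] for g in kept] for p in control], axis=0)
    return pd.Series(2.0 ** (case_mean - ctrl_mean), index=kept, name="fold_change")


def select_signature(fc: pd.Series, cutoff: float = 50.0) -> SignatureResult:
    """Strictly threshold fold changes into up (> cutoff) and down (< 1/cutoff)."""
    if cutoff <= 1:
        raise ValueError("cutoff must exceed 1")
    up = sorted(fc.index[fc > cutoff])
    down = sorted(fc.index[fc < 1.0 / cutoff])
    return SignatureResult(fold_changes=fc, up_genes=up, down_genes=down,
                           cutoff=cutoff)


def write_grp(sig: SignatureResult, up_path: str | Path,
              down_path: str | Path) -> None:
    """Write up/down gene lists, one uppercase identifier per line, no header."""
    for genes, path in ((sig.up_genes, up_path), (sig.down_genes, down_path)):
        with open(path, "w") as fh:
            for g in genes:
                fh.write(f"{g.upper()}\n")


def read_grp(path: str | Path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def write_signature_table(sig: SignatureResult, path: str | Path) -> None:
    calls = pd.Series("-", index=sig.fold_changes.index)
    calls[sig.up_genes] = "UP"
    calls[sig.down_genes] = "DOWN"
    df = pd.DataFrame({"gene_id": sig.fold_changes.index,
                       "log2_fc": np.log2(sig.fold_changes.to_numpy()),
                       "linear_fc": sig.fold_changes.to_numpy(),
                       "call": calls.to_numpy()})
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
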