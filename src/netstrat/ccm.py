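"""Correlation classification: align cell lines to patient groups.

Each cell line is assigned to the patient group whose expression profile it
best matches by Spearman rank correlation over a gene panel (by default the
network's mRNA gene nodes, since cell-line panels are mRNA).  The group
profile is the per-gene mean over group members (centroid); a mean of
per-patient correlations is available behind ``method="mean_corr"``.
Correlation is computed on continuous log-scale expression, not on the
binarized values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import ExpressionMatrix, MutationTable, MISSING
from .binarize import PatientGroup


@dataclass
class CellLineProfile:
    """One cell line's log-scale expression and per-gene mutation status."""

    cell_line_id: str
    expression: pd.Series                 # gene -> log2 expression
    mutation_status: dict[str, str] = field(default_factory=dict)

    def covers(self, panel: list[str]) -> bool:
        return all(g in self.expression.index for g in panel)


@dataclass
class AssignmentResult:
    cell_line_id: str
    assigned_group: str                   # group name or "UNASSIGNED"
    rho_per_group: dict[str, float]
    margin: float


def group_centroid(group: PatientGroup, expr: ExpressionMatrix,
                   panel: list[str]) -> pd.Series:
    """Per-gene mean expression over the group members, restricted to the panel."""
    if not group.members:
        raise ValueError("empty group")
    missing = [g for g in panel if g not in expr.values.index]
    if missing:
        raise KeyError(f"panel genes absent from expression matrix: {missing}")
    absent = [s for s in group.members if s not in expr.values.columns]
    if absent:
        raise KeyError(f"group members absent from expression matrix: {absent}")
    return expr.values.loc[panel, group.members].mean(axis=1)


def spearman_rho(x, y) -> float:
    """Spearman rank correlation (Pearson on average ranks, ties averaged)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need equal-length vectors of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Spearman correlation undefined for a constant vector")
    return float(sps.spearmanr(x, y).statistic)


def assign_cell_lines(lines: list[CellLineProfile], groups: list[PatientGroup],
                      expr: ExpressionMatrix, panel: list[str],
                      method: str = "centroid") -> list[AssignmentResult]:
    """Assign each line to the argmax-correlation group.

    Lines whose expression does not cover the panel are skipped (logged via
    warning).  An exact tie in rho leaves the line UNASSIGNED.
    """
    import warnings

    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if len(panel) < 3:
        raise ValueError("panel must contain at least three genes")
    if method not in ("centroid", "mean_corr"):
        raise ValueError(f"unknown method {method!r}")
    centroids = {g.name: group_centroid(g, expr, panel) for g in groups}
    results = []
    for line in lines:
        if not line.covers(panel):
            warnings.warn(f"cell line {line.cell_line_id!r} lacks panel genes; skipped")
            continue
        v = line.expression[panel].to_numpy(dtype=float)
        rhos: dict[str, float] = {}
        for g in groups:
            if method == "centroid":
                rhos[g.name] = spearman_rho(v, centroids[g.name].to_numpy())
            else:
                per_patient = [
                    spearman_rho(v, expr.values.loc[panel, s].to_numpy())
                    for s in g.members]
                rhos[g.name] = float(np.mean(per_patient))
        ranked = sorted(rhos.items(), key=lambda kv: (-kv[1], kv[0]))
        best, second = ranked[0], ranked[1]
        if best[1] == second[1]:
            warnings.warn(f"cell line {line.cell_line_id!r}: rho tie; unassigned")
            results.append(AssignmentResult(line.cell_line_id, "UNASSIGNED",
                                            rhos, 0.0))
        else:
            results.append(AssignmentResult(line.cell_line_id, best[0], rhos,
                                            best[1] - second[1]))
    return results


def read_cell_lines(expr_path: str | Path,
                    mut_path: str | Path | None = None) -> list[CellLineProfile]:
    """Read a cell-line panel: expression TSV (genes x lines) + optional mutation TSV."""
    expr = pd.read_csv(expr_path, sep="\t", index_col=0)
    muts: dict[str, dict[str, str]] = {}
    if mut_path is not None:
        m = pd.read_csv(mut_path, sep="\t", index_col=0, dtype=str)
        for line_id in m.index:
            muts[line_id] = m.loc[line_id].fillna(MISSING).to_dict()
    return [CellLineProfile(cell_line_id=c, expression=expr[c].astype(float),
                            mutation_status=muts.get(c, {}))
            for c in expr.columns]


def write_assignments(results: list[AssignmentResult], path: str | Path) -> None:
    group_names = sorted({g for r in results for g in r.rho_per_group})
    rows = []
    for r in results:
        row = {"cell_line_id": r.cell_line_id, "assigned_group": r.assigned_group,
               "margin": r.margin}
        row.update({f"rho_{g}": r.rho_per_group.get(g, np.nan) for g in group_names})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.10g")
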