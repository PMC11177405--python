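"""Expression ingestion, clustering order, subgenome contributions,
homeolog pattern correlation, and salt-stress regulation calls."""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist

__all__ = [
    "ExpressionMatrix",
    "RegulationCall",
    "read_expression",
    "write_expression",
    "cluster_heatmap_order",
    "subgenome_contribution",
    "salt_regulation_calls",
    "homeolog_expression_correlation",
    "DEV_CONDITIONS",
]

#: developmental condition dialect (tissues/stages)
DEV_CONDITIONS = (
    "GS", "C", "YL", "SL", "S", "R", "B", "F", "ESD", "EMSD", "LMSD", "LSD",
)

_SALT_RE = re.compile(r"^(?P<organ>[A-Za-z]+)_(?P<arm>ctrl|salt)$")


@dataclass
class ExpressionMatrix:
    values: pd.DataFrame  # genes x conditions, non-negative

    def __post_init__(self) -> None:
        df = self.values
        if df.index.duplicated().any():
            dup = df.index[df.index.duplicated()][0]
            raise ValueError(f"duplicate gene id {dup!r}")
        if df.columns.duplicated().any():
            raise ValueError("duplicate condition labels")
        if df.isna().any().any():
            r, c = next(zip(*np.where(df.isna().values)))
            raise ValueError(
                f"missing value at row {df.index[r]!r} column {df.columns[c]!r}"
            )
        if (df.values < 0).any():
            raise ValueError("negative expression value")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def conditions(self) -> list[str]:
        return list(self.values.columns)

    def developmental_conditions(self) -> list[str]:
        return [c for c in self.conditions if not _SALT_RE.match(c)]

    def salt_pairs(self) -> dict[str, tuple[str, str]]:
        """organ -> (control column, stress column)."""
        arms: dict[str, dict[str, str]] = {}
        for c in self.conditions:
            m = _SALT_RE.match(c)
            if m:
                arms.setdefault(m["organ"], {})[m["arm"]] = c
        pairs = {}
        for organ, d in sorted(arms.items()):
            if set(d) != {"ctrl", "salt"}:
                raise ValueError(f"unpaired salt columns for organ {organ!r}")
            pairs[organ] = (d["ctrl"], d["salt"])
        return pairs


@dataclass
class RegulationCall:
    gene: str
    organ: str
    log2_fc: float  # stress vs control (negative = down)
    label: str  # down | up | unchanged


def read_expression(path: str | Path) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionMatrix(df.astype(float))


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.values.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Heatmap clustering order
# ---------------------------------------------------------------------------

def _zscore_rows(x: np.ndarray) -> tuple[np.ndarray, list[int]]:
    mean = x.mean(axis=1, keepdims=True)
    std = x.std(axis=1, keepdims=True)
    flat = np.where(std[:, 0] == 0)[0].tolist()
    std[std == 0] = 1.0
    return (x - mean) / std, flat


def _leaf_order(Z: np.ndarray, n: int) -> list[int]:
    """Recursive smaller-cluster-first leaf ordering of a linkage tree."""
    sizes = {i: 1 for i in range(n)}
    children = {}
    for k, row in enumerate(Z):
        a, b = int(row[0]), int(row[1])
        node = n + k
        children[node] = (a, b)
        sizes[node] = sizes[a] + sizes[b]

    def expand(node: int) -> list[int]:
        if node < n:
            return [node]
        a, b = children[node]
        first, second = (a, b) if (sizes[a], a) <= (sizes[b], b) else (b, a)
        return expand(first) + expand(second)

    return expand(n + len(Z) - 1)


def cluster_heatmap_order(
    matrix: ExpressionMatrix,
    metric: str = "euclidean",
    method: str = "average",
    zscore: bool = True,
) -> dict:
    """Average-linkage clustering of rows and columns (display convention:
    rows z-scored before distances).  Returns orders and merge trees."""
    df = matrix.values
    if len(df) < 2:
        raise ValueError("need at least 2 rows to cluster")
    x = df.values.astype(float)
    notes = []
    if zscore:
        x, flat = _zscore_rows(x)
        if flat:
            notes.append(
                f"constant rows z-scored to zeros: {[df.index[i] for i in flat]}"
            )
    row_Z = linkage(pdist(x, metric=metric), method=method)
    row_order = [df.index[i] for i in _leaf_order(row_Z, x.shape[0])]
    if x.shape[1] >= 2:
        col_Z = linkage(pdist(x.T, metric=metric), method=method)
        col_order = [df.columns[i] for i in _leaf_order(col_Z, x.shape[1])]
    else:
        col_Z = np.empty((0, 4))
        col_order = list(df.columns)
    return {
        "row_order": row_order,
        "col_order": col_order,
        "row_linkage": row_Z,
        "col_linkage": col_Z,
        "notes": notes,
    }


# ---------------------------------------------------------------------------
# Subgenome contributions
# ---------------------------------------------------------------------------

def subgenome_contribution(
    matrix: ExpressionMatrix,
    gene_subgenome: Mapping[str, str],
    exclusions: Iterable[str] = (),
    conditions: Sequence[str] | None = None,
    subgenomes: Sequence[str] = ("G1", "G2", "G3"),
) -> pd.DataFrame:
    """Percentage of total expression contributed by each subgenome.

    Raw (non-normalized) values are summed per subgenome per condition.
    Genes in ``exclusions`` or without a subgenome assignment in
    ``gene_subgenome`` are dropped.  All-zero conditions are returned as
    NaN with a flag column.
    """
    excl = set(exclusions)
    conds = list(conditions) if conditions is not None else matrix.conditions
    rows = [
        g
        for g in matrix.genes
        if g not in excl and gene_subgenome.get(g) in subgenomes
    ]
    if not rows:
        raise ValueError("no genes left after exclusions")
    sub = matrix.values.loc[rows, conds]
    assign = pd.Series({g: gene_subgenome[g] for g in rows})
    sums = sub.groupby(assign).sum()
    sums = sums.reindex(subgenomes, fill_value=0.0)
    total = sums.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = 100.0 * sums / total
    pct.loc[:, total == 0] = np.nan
    out = pct.T
    out["undefined"] = (total == 0).values
    return out


# ---------------------------------------------------------------------------
# Salt-stress regulation calls
# ---------------------------------------------------------------------------

def salt_regulation_calls(
    matrix: ExpressionMatrix,
    fc_threshold: float = 1.5,
    pseudocount: float = 1.0,
) -> tuple[list[RegulationCall], dict]:
    """Fold-change calls on paired control/stress columns per organ.

    FC = (control + pc) / (stress + pc); ``down`` when FC >= threshold,
    ``up`` when 1/FC >= threshold, otherwise ``unchanged``.
    """
    pairs = matrix.salt_pairs()
    if not pairs:
        raise ValueError("no paired salt control/stress columns found")
    calls = []
    down_by_organ: dict[str, list[str]] = {o: [] for o in pairs}
    any_up = False
    for organ, (ctrl, salt) in pairs.items():
        c = matrix.values[ctrl] + pseudocount
        s = matrix.values[salt] + pseudocount
        fc = c / s
        for gene in matrix.genes:
            f = float(fc[gene])
            if f >= fc_threshold:
                label = "down"
                down_by_organ[organ].append(gene)
            elif 1.0 / f >= fc_threshold:
                label = "up"
                any_up = True
            else:
                label = "unchanged"
            calls.append(
                RegulationCall(
                    gene=gene,
                    organ=organ,
                    log2_fc=-math.log2(f),
                    label=label,
                )
            )
    summary = {
        "down_by_organ": {o: sorted(g) for o, g in down_by_organ.items()},
        "any_upregulated": any_up,
    }
    return calls, summary


# ---------------------------------------------------------------------------
# Homeolog pattern correlation
# ---------------------------------------------------------------------------

def homeolog_expression_correlation(
    groups: Mapping[str, Sequence[str]],
    matrix: ExpressionMatrix,
    min_r: float = 0.8,
    conditions: Sequence[str] | None = None,
) -> dict:
    """Per-group pairwise Pearson r over developmental conditions and a
    shared-pattern flag (min pairwise r >= min_r)."""
    conds = (
        list(conditions)
        if conditions is not None
        else matrix.developmental_conditions()
    )
    out = {}
    for name, members in groups.items():
        missing = [m for m in members if m not in matrix.values.index]
        if missing:
            raise KeyError(f"group {name}: genes not in matrix: {missing}")
        sub = matrix.values.loc[list(members), conds]
        pairs = {}
        undefined = []
        rs = []
        mem = list(members)
        for i in range(len(mem)):
            for j in range(i + 1, len(mem)):
                a = sub.loc[mem[i]].values
                b = sub.loc[mem[j]].values
                if a.std() == 0 or b.std() == 0:
                    pairs[(mem[i], mem[j])] = math.nan
                    undefined.append((mem[i], mem[j]))
                    continue
                r = float(np.corrcoef(a, b)[0, 1])
                pairs[(mem[i], mem[j])] = r
                rs.append(r)
        flag = bool(rs) and not undefined and min(rs) >= min_r
        out[name] = {"pairwise_r": pairs, "shared_pattern": flag, "undefined": undefined}
    return out
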