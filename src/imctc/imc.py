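"""Imaging mass cytometry table analytics.

Operates on cell(mask) x marker ion-count tables: mask quality filters
(area 40-200 px inclusive, DNA intercalator count >= 4), arcsinh transform
(cofactor 1), per-marker 99th-percentile normalisation, Phenograph-style
graph clustering (kNN -> Jaccard edge weights -> Louvain modularity), a
hierarchical manual gating tree read from YAML, and marker summary /
Spearman correlation statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import NamedTuple

import networkx as nx
import numpy as np
import pandas as pd
import yaml
from scipy import stats
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "GateNode",
    "GateTree",
    "load_gate_tree",
    "default_gate_tree",
    "filter_masks",
    "arcsinh_transform",
    "percentile_normalize",
    "NormalizedTable",
    "cluster_graph",
    "apply_gates",
    "marker_stats",
    "MarkerStats",
]

UNGATED = "ungated"


# ---------------------------------------------------------------------------
# Mask QC


def filter_masks(
    table: pd.DataFrame,
    area_range: tuple[float, float] = (40.0, 200.0),
    min_dna1: float = 4.0,
    protected_populations: tuple[str, ...] = ("im.CTC", "epi.CTC"),
) -> pd.DataFrame:
    """Drop poorly segmented / non-nucleated masks.

    Keeps rows with area in ``area_range`` (inclusive at both ends) and DNA1
    >= ``min_dna1``.  Rows whose ``population`` column marks a pre-identified
    CTC (matched from the immunofluorescence scan) bypass the filter, since
    only the remaining masks are being triaged.
    """
    missing = {"area", "DNA1"} - set(table.columns)
    if missing:
        raise ValueError(f"table missing columns: {missing}")
    lo, hi = area_range
    keep = (table["area"] >= lo) & (table["area"] <= hi) & (table["DNA1"] >= min_dna1)
    if "population" in table.columns:
        keep |= table["population"].isin(protected_populations)
    return table[keep]


def arcsinh_transform(x, cofactor: float = 1.0):
    """Elementwise asinh(x / cofactor), the standard cytometry variance-
    stabilising transform."""
    if cofactor <= 0:
        raise ValueError("cofactor must be positive")
    return np.arcsinh(np.asarray(x, dtype=float) / cofactor)


class NormalizedTable(NamedTuple):
    table: pd.DataFrame
    zero_percentile_markers: list[str]


def percentile_normalize(
    table: pd.DataFrame, markers: list[str], p: float = 99.0
) -> NormalizedTable:
    """Scale each marker column by its p-th percentile (linear interpolation).

    Values above the percentile stay above 1 (no clipping).  Columns whose
    percentile is 0 are left unscaled and reported in
    ``zero_percentile_markers``.
    """
    if not 0.0 < p <= 100.0:
        raise ValueError("percentile must lie in (0, 100]")
    if len(table) == 0:
        raise ValueError("cannot normalise an empty table")
    out = table.copy()
    flagged = []
    for m in markers:
        q = float(np.percentile(table[m].to_numpy(dtype=float), p))
        if q == 0.0:
            flagged.append(m)
        else:
            out[m] = table[m] / q
    return NormalizedTable(out, flagged)


# ---------------------------------------------------------------------------
# Graph clustering (Phenograph-style)


def cluster_graph(
    table: pd.DataFrame,
    markers: list[str],
    k_neighbors: int = 30,
    seed: int = 0,
    resolution: float = 0.2,
) -> np.ndarray:
    """kNN -> Jaccard -> Louvain community labels per cell.

    Builds the Euclidean k-nearest-neighbour graph on the marker columns,
    reweights each edge by the Jaccard overlap of the endpoints' neighbour
    sets, and maximises modularity with seeded Louvain.  Labels are renumbered
    by first appearance so identical seeds give identical outputs.

    ``resolution`` controls the modularity granularity.  The default (0.2)
    is below the textbook 1.0 because at resolution 1 Louvain fragments a
    single homogeneous population's dense kNN graph into arbitrary
    sub-communities; a low resolution keeps each population whole while
    never merging populations whose kNN graphs are disconnected (merging
    unconnected communities cannot raise modularity at any resolution).
    """
    X = table[markers].to_numpy(dtype=float)
    n = len(X)
    if k_neighbors >= n:
        raise ValueError("k_neighbors must be smaller than the number of cells")
    nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(X)
    _, idx = nn.kneighbors(X)
    neigh = [set(row) for row in idx]  # includes self; symmetric in Jaccard
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for u in range(n):
        for v in idx[u]:
            v = int(v)
            if v == u or g.has_edge(u, v):
                continue
            inter = len(neigh[u] & neigh[v])
            union = len(neigh[u] | neigh[v])
            w = inter / union
            if w > 0:
                g.add_edge(u, v, weight=w)
    communities = nx.community.louvain_communities(
        g, weight="weight", seed=seed, resolution=resolution
    )
    labels = np.empty(n, dtype=int)
    for ci, members in enumerate(communities):
        labels[list(members)] = ci
    # stable relabel: community id by first cell index
    order = {}
    out = np.empty(n, dtype=int)
    for i, lab in enumerate(labels):
        if lab not in order:
            order[lab] = len(order)
        out[i] = order[lab]
    return out


# ---------------------------------------------------------------------------
# Hierarchical gating

_OPS = {
    ">": np.greater,
    ">=": np.greater_equal,
    "<": np.less,
    "<=": np.less_equal,
}


@dataclass(frozen=True)
class GateNode:
    name: str
    parent: str | None
    rules: tuple[tuple[str, str, float], ...]  # (marker, op, threshold)

    def matches(self, row: pd.Series) -> bool:
        return all(_OPS[op](row[m], thr) for m, op, thr in self.rules)


@dataclass(frozen=True)
class GateTree:
    """Ordered gate nodes; thresholds apply to arcsinh-transformed counts."""

    nodes: tuple[GateNode, ...]
    cofactor: float = 1.0

    def __post_init__(self) -> None:
        names = [n.name for n in self.nodes]
        if len(set(names)) != len(names):
            raise ValueError("gate names must be unique")
        by_name = {n.name: n for n in self.nodes}
        for node in self.nodes:
            if node.parent is not None and node.parent not in by_name:
                raise ValueError(f"gate {node.name!r} has unknown parent {node.parent!r}")
            # walk to root, bounded by node count, to reject cycles
            seen = {node.name}
            cur = node.parent
            while cur is not None:
                if cur in seen:
                    raise ValueError(f"gate tree contains a cycle through {cur!r}")
                seen.add(cur)
                cur = by_name[cur].parent

    def children(self, name: str | None) -> list[GateNode]:
        return [n for n in self.nodes if n.parent == name]

    def markers(self) -> set[str]:
        return {m for n in self.nodes for m, _, _ in n.rules}


def _parse_rule(marker: str, spec: str) -> tuple[str, str, float]:
    for op in (">=", "<=", ">", "<"):
        if spec.strip().startswith(op):
            return (marker, op, float(spec.strip()[len(op):]))
    raise ValueError(f"cannot parse gate rule {spec!r} for marker {marker!r}")


def load_gate_tree(source) -> GateTree:
    """Load a gate tree from a YAML mapping with keys ``cofactor`` and
    ``gates`` (list of {name, parent, rules: {marker: '>= value', ...}})."""
    if hasattr(source, "read"):
        doc = yaml.safe_load(source)
    else:
        with open(source) as fh:
            doc = yaml.safe_load(fh)
    nodes = tuple(
        GateNode(
            name=g["name"],
            parent=g.get("parent"),
            rules=tuple(_parse_rule(m, s) for m, s in g.get("rules", {}).items()),
        )
        for g in doc["gates"]
    )
    return GateTree(nodes, cofactor=float(doc.get("cofactor", 1.0)))


def default_gate_tree() -> GateTree:
    """The packaged leukocyte gating scheme (CD45/CD3/CD14/CD20/CD56/CD68
    with CK8/18 exclusion; CD4/CD8 resolved within CD3+)."""
    ref = resources.files("imctc.resources").joinpath("gates.yaml")
    with ref.open() as fh:
        return load_gate_tree(fh)


def apply_gates(table: pd.DataFrame, gates: GateTree) -> pd.Series:
    """Assign each cell the deepest gate it satisfies.

    Marker values are arcsinh-transformed with the tree's cofactor before
    evaluating thresholds.  Cells descend from the root; among a node's
    children the first whose rules all hold wins.  A cell matching an
    internal node but none of its children keeps the internal node's label
    (e.g. 'T cell' for CD3+ CD4- CD8- cells); cells matching no top-level
    gate are labelled 'ungated'.
    """
    markers = sorted(gates.markers())
    missing = set(markers) - set(table.columns)
    if missing:
        raise ValueError(f"table missing gate markers: {missing}")
    tf = pd.DataFrame(
        {m: arcsinh_transform(table[m], gates.cofactor) for m in markers},
        index=table.index,
    )

    def descend(row: pd.Series, parent: str | None) -> str | None:
        for node in gates.children(parent):
            if node.matches(row):
                deeper = descend(row, node.name)
                return deeper if deeper is not None else node.name
        return None

    labels = tf.apply(lambda row: descend(row, None) or UNGATED, axis=1)
    labels.name = "gate"
    return labels


# ---------------------------------------------------------------------------
# Marker statistics


class MarkerStats(NamedTuple):
    summaries: pd.DataFrame
    spearman: pd.DataFrame


def marker_stats(
    table: pd.DataFrame,
    label_column: str,
    group_a: str,
    group_b: str,
    markers: list[str],
) -> MarkerStats:
    """Per-group marker distribution summaries and a Spearman correlation
    matrix over both groups pooled (average ranks under ties; symmetric,
    unit diagonal)."""
    present = set(table[label_column])
    for g in (group_a, group_b):
        if g not in present:
            raise ValueError(f"label {g!r} not present in column {label_column!r}")
    sub = table[table[label_column].isin([group_a, group_b])]
    summaries = (
        sub.groupby(label_column)[markers]
        .agg(["mean", "median", "std"])
        .stack(level=0, future_stack=True)
        .rename_axis([label_column, "marker"])
        .reset_index()
    )
    X = sub[markers].to_numpy(dtype=float)
    if len(markers) == 1:
        corr = np.ones((1, 1))
    elif len(markers) == 2:
        rho = float(stats.spearmanr(X[:, 0], X[:, 1]).statistic)
        corr = np.array([[1.0, rho], [rho, 1.0]])
    else:
        corr = np.asarray(stats.spearmanr(X).statistic)
    np.fill_diagonal(corr, 1.0)
    spearman = pd.DataFrame(corr, index=markers, columns=markers)
    return MarkerStats(summaries, spearman)
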