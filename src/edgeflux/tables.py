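"""Score tables across conditions and the comparative workflow on them.

Edge-flux tables (interactions x conditions) and term-score tables
(functional terms x conditions) let standard comparative statistics —
filtering, variance ranking, hierarchical clustering, heatmaps — run at the
interactome rather than genome level.  Selected rows map back to a network:
the extracted subnetwork contains exactly the selected interactions, never
a neighbor expansion.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.spatial.distance as ssd

from . import dataset as ds
from .network import Edge, InteractionNetwork
from .terms import InteractionAnnotation, term_walk_scores
from .walk import DEFAULT_MAX_ITER, DEFAULT_Q, DEFAULT_TOL, baseline_walk, edge_flux

logger = logging.getLogger("edgeflux")

EDGE_META = ["source", "target", "directedness", "type"]
TERM_META = ["term", "name", "level", "edge_count"]

__all__ = [
    "EdgeFluxTable",
    "TermScoreTable",
    "run_conditions",
    "filter_rows",
    "parse_filter_expression",
    "rank_by_variance",
    "hierarchical_cluster",
    "ClusterResult",
    "extract_subnetwork",
    "extract_term_subnetwork",
]


class _ScoreTable:
    """Shared behavior: metadata columns first, then one column per
    condition; undefined cells are NaN and excluded from all statistics."""

    meta_columns: list[str] = []
    id_column: str = ""

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in self.meta_columns if c not in frame.columns]
        if missing:
            raise ValueError(f"table missing metadata columns {missing}")
        cond = [c for c in frame.columns if c not in self.meta_columns]
        self.frame = frame[self.meta_columns + cond].reset_index(drop=True)

    @property
    def condition_columns(self) -> list[str]:
        return [c for c in self.frame.columns if c not in self.meta_columns]

    @property
    def row_ids(self) -> pd.Series:
        raise NotImplementedError

    def __len__(self) -> int:
        return len(self.frame)

    def _wrap(self, frame: pd.DataFrame):
        return type(self)(frame)

    def to_tsv(self, path, header_lines: Sequence[str] = ()) -> None:
        with open(path, "w") as fh:
            for line in header_lines:
                fh.write(f"# {line}\n")
            self.frame.to_csv(fh, sep="\t", index=False, na_rep="NA",
                              float_format="%.10g")

    @classmethod
    def from_tsv(cls, path):
        frame = pd.read_csv(path, sep="\t", comment="#", na_values=["NA"],
                            keep_default_na=False)
        return cls(frame)


class EdgeFluxTable(_ScoreTable):
    """Interactions x conditions matrix of edge-flux scores."""

    meta_columns = EDGE_META
    id_column = "edge"

    @property
    def row_ids(self) -> pd.Series:
        def lab(row):
            if row["directedness"] == "directed":
                return f"{row['source']}->{row['target']}"
            a, b = sorted((row["source"], row["target"]))
            return f"{a}--{b}"
        return self.frame.apply(lab, axis=1)

    def edge_keys(self) -> list[tuple]:
        out = []
        for _, row in self.frame.iterrows():
            directed = row["directedness"] == "directed"
            if directed:
                out.append((row["source"], row["target"], True))
            else:
                a, b = sorted((row["source"], row["target"]))
                out.append((a, b, False))
        return out


class TermScoreTable(_ScoreTable):
    """Functional terms x conditions matrix of term walk scores."""

    meta_columns = TERM_META
    id_column = "term"

    @property
    def row_ids(self) -> pd.Series:
        return self.frame["term"].astype(str)


def run_conditions(network: InteractionNetwork,
                   data: ds.DataSet,
                   columns: Sequence[str],
                   transform: str = "up",
                   q: float = DEFAULT_Q,
                   tol: float = DEFAULT_TOL,
                   max_iter: int = DEFAULT_MAX_ITER,
                   log_base: float = math.e,
                   annotation: InteractionAnnotation | None = None,
                   ) -> tuple[EdgeFluxTable, TermScoreTable | None]:
    """One biased walk per data column against a single cached baseline.

    Returns the edge table and, when interaction annotations are supplied,
    the term table.  Per-column iteration counts go to the log.
    """
    for col in columns:
        if col not in data.frame.columns:
            raise KeyError(f"no data column {col!r}")
    base = baseline_walk(network, q=q, tol=tol, max_iter=max_iter)
    edge_keys = network.canonical_edge_keys()
    key_to_edges: dict[tuple, list[Edge]] = {}
    for e in network.edges:
        key_to_edges.setdefault(e.key, []).append(e)
    ef_cols: dict[str, list[float]] = {}
    term_cols: dict[str, dict[str, float]] = {}
    term_meta = None
    for col in columns:
        try:
            weights = ds.to_weights(data, col, transform=transform,
                                    nodes=network.nodes)
            flux = edge_flux(network, weights, q=q, tol=tol,
                             max_iter=max_iter, log_base=log_base,
                             baseline=base)
        except Exception as exc:
            raise type(exc)(f"column {col!r}: {exc}") from exc
        logger.info("column %s: weighted walk converged in %d iterations "
                    "(residual %.2e)", col, flux.walk_weighted.iterations,
                    flux.walk_weighted.residual)
        ef_cols[col] = [flux.ef[k] for k in edge_keys]
        if annotation is not None:
            scores = term_walk_scores(network, weights, annotation,
                                      flux=flux)
            term_cols[col] = scores.score
            term_meta = scores
    key_pos = {k: i for i, k in enumerate(edge_keys)}
    rows = []
    for key in edge_keys:
        for e in key_to_edges[key]:
            rows.append({
                "source": e.source if e.directed else key[0],
                "target": e.target if e.directed else key[1],
                "directedness": "directed" if e.directed else "undirected",
                "type": e.etype,
                **{col: ef_cols[col][key_pos[key]] for col in columns},
            })
    ef_frame = pd.DataFrame(rows, columns=EDGE_META + list(columns))
    ef_table = EdgeFluxTable(ef_frame)
    term_table = None
    if annotation is not None and term_meta is not None:
        terms = sorted(term_meta.score)
        tf = pd.DataFrame({
            "term": terms,
            "name": [term_meta.term_names.get(t, "") for t in terms],
            "level": [term_meta.levels.get(t, math.inf)
                      if term_meta.levels else math.inf for t in terms],
            "edge_count": [term_meta.edge_count.get(t, 0) for t in terms],
            **{col: [term_cols[col].get(t, math.nan) for t in terms]
               for col in columns},
        })
        term_table = TermScoreTable(tf)
    return ef_table, term_table


_CLAUSE_RE = re.compile(
    r"^\s*(?P<col>[^<>=!]+?)\s*(?P<op>>=|<=|==|!=|>|<)\s*(?P<val>-?\d+(\.\d+)?([eE][+-]?\d+)?)\s*$")

_OPS = {
    ">": np.greater, "<": np.less, ">=": np.greater_equal,
    "<=": np.less_equal, "==": np.equal, "!=": np.not_equal,
}


def parse_filter_expression(expr: str) -> tuple[list[tuple[str, str, float]], str]:
    """Parse e.g. ``"cond_a > 2.25 or cond_b > 1.70"``.

    Clauses are joined by a single combinator (all ``and`` or all ``or``).
    """
    lowered = expr.lower()
    if " or " in lowered and " and " in lowered:
        raise ValueError("mixing 'and' with 'or' is not supported; "
                         "chain two filters instead")
    combine = "or" if " or " in lowered else "and"
    parts = re.split(r"\s+(?:or|and|OR|AND)\s+", expr)
    clauses = []
    for part in parts:
        m = _CLAUSE_RE.match(part)
        if not m:
            raise ValueError(f"cannot parse filter clause {part!r}")
        clauses.append((m["col"].strip(), m["op"], float(m["val"])))
    return clauses, combine


def filter_rows(table, clauses: Sequence[tuple[str, str, float]],
                combine: str = "and"):
    """Keep rows satisfying threshold clauses (AND/OR combined).

    Each clause is (column, operator, threshold); an undefined (NaN) cell
    never satisfies a clause.  Idempotent for a fixed predicate.
    """
    if combine not in ("and", "or"):
        raise ValueError(f"combine must be 'and' or 'or', got {combine!r}")
    if not clauses:
        raise ValueError("no filter clauses given")
    masks = []
    for col, op, threshold in clauses:
        if col not in table.frame.columns:
            raise KeyError(f"unknown column {col!r} in filter")
        if op not in _OPS:
            raise ValueError(f"unknown operator {op!r}")
        vals = pd.to_numeric(table.frame[col], errors="coerce")
        with np.errstate(invalid="ignore"):
            mask = _OPS[op](vals.to_numpy(), threshold)
        mask &= ~np.isnan(vals.to_numpy())
        masks.append(mask)
    combined = masks[0]
    for m in masks[1:]:
        combined = (combined | m) if combine == "or" else (combined & m)
    return table._wrap(table.frame[combined])


def rank_by_variance(table, top_k: int):
    """Rows sorted by sample variance across defined cells, descending.

    The most condition-dependent interactions or terms come first.  Ties
    break by row identifier (lexicographic); undefined cells are excluded
    from the variance.
    """
    if top_k < 1:
        raise ValueError(f"top_k must be >= 1, got {top_k}")
    cond = table.condition_columns
    if len(cond) < 2:
        raise ValueError("variance ranking needs at least 2 condition columns")
    values = table.frame[cond].apply(pd.to_numeric, errors="coerce")
    variances = values.var(axis=1, ddof=1, skipna=True).fillna(0.0)
    ids = table.row_ids
    order = sorted(range(len(table.frame)),
                   key=lambda i: (-variances.iloc[i], str(ids.iloc[i])))
    return table._wrap(table.frame.iloc[order[:top_k]])


@dataclass
class ClusterResult:
    row_ids: list[str]        # leaf order
    newick: str
    linkage_matrix: np.ndarray
    dropped: list[str]


def _to_newick(node, labels, parent_height: float) -> str:
    length = parent_height - (0.0 if node.is_leaf() else node.dist)
    if node.is_leaf():
        name = re.sub(r"[\s,:;()\[\]']", "_", str(labels[node.id]))
        return f"{name}:{parent_height:.10g}"
    left = _to_newick(node.left, labels, node.dist)
    right = _to_newick(node.right, labels, node.dist)
    return f"({left},{right}):{length:.10g}"


def hierarchical_cluster(table, metric: str = "euclidean",
                         linkage: str = "average") -> ClusterResult:
    """Agglomerative clustering of table rows.

    Rows with any undefined cell are dropped first (imputing would
    fabricate scores).  Returns the leaf order and a newick dendrogram
    whose branch lengths are merge heights.
    """
    if metric not in ("euclidean", "correlation"):
        raise ValueError(f"metric must be 'euclidean' or 'correlation', got {metric!r}")
    if linkage not in ("average", "complete"):
        raise ValueError(f"linkage must be 'average' or 'complete', got {linkage!r}")
    cond = table.condition_columns
    values = table.frame[cond].apply(pd.to_numeric, errors="coerce")
    complete_mask = ~values.isna().any(axis=1)
    dropped = [str(i) for i in table.row_ids[~complete_mask]]
    if dropped:
        logger.warning("hierarchical_cluster: dropping %d row(s) with "
                       "undefined cells", len(dropped))
    values = values[complete_mask]
    ids = [str(i) for i in table.row_ids[complete_mask]]
    if len(values) < 2:
        raise ValueError("need at least 2 complete rows to cluster")
    dist = ssd.pdist(values.to_numpy(), metric=metric)
    dist = np.clip(dist, 0.0, None)  # correlation pdist can return -eps
    Z = sch.linkage(dist, method=linkage)
    order = sch.leaves_list(Z)
    tree = sch.to_tree(Z)
    newick = "(" + _to_newick(tree.left, ids, tree.dist) + "," + \
        _to_newick(tree.right, ids, tree.dist) + ");"
    return ClusterResult(row_ids=[ids[i] for i in order], newick=newick,
                         linkage_matrix=Z, dropped=dropped)


def extract_subnetwork(edge_keys: Iterable[tuple],
                       network: InteractionNetwork,
                       node_attributes: Mapping[str, Mapping[str, object]] | None = None,
                       ) -> tuple[InteractionNetwork, dict[str, dict]]:
    """Subnetwork containing exactly the selected edges.

    No neighbor expansion: the edge set equals the selection.  Node
    attributes (e.g. expression values for coloring) are restricted to the
    nodes actually present.  Unknown edges and empty selections are errors.
    """
    wanted = list(edge_keys)
    if not wanted:
        raise ValueError("empty edge selection")
    by_key: dict[tuple, list[Edge]] = {}
    for e in network.edges:
        by_key.setdefault(e.key, []).append(e)
    picked: list[Edge] = []
    for key in wanted:
        a, b, directed = key
        k = (a, b, True) if directed else (*sorted((a, b)), False)
        if k not in by_key:
            raise KeyError(f"edge {k} not present in the network")
        picked.extend(by_key[k])
    sub = InteractionNetwork(picked)
    attrs = {}
    if node_attributes:
        attrs = {n: dict(node_attributes[n])
                 for n in sub.nodes if n in node_attributes}
    return sub, attrs


def extract_term_subnetwork(terms: Iterable[str],
                            annotation: InteractionAnnotation,
                            network: InteractionNetwork,
                            node_attributes=None):
    """Subnetwork of all edges carrying any of the selected terms."""
    keys = annotation.edges_for_terms(terms)
    if not keys:
        raise ValueError("no network edge carries the selected term(s)")
    return extract_subnetwork(keys, network, node_attributes)
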