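"""Protein-interaction graph construction and hub-gene selection.

The prioritized gene set is induced on a confidence-scored interaction
network (edges kept at score >= 0.4, the conventional "medium confidence"
cut), three node centralities are computed — degree, harmonic closeness and
unnormalized shortest-path betweenness — and the key genes are the
intersection of the three top-k rankings (k = 100 by default).

Centrality conventions
----------------------
* closeness is the harmonic variant, ``sum_{u != v} 1 / d(u, v)`` with
  unreachable pairs contributing zero, so it is well defined on the
  disconnected graphs a confidence-filtered network always produces;
* betweenness is Brandes-style pair counting, endpoints excluded,
  unnormalized (rankings are invariant to the usual normalizations);
* shortest paths are unweighted — scores only gate edge existence.

Shortest-path computations are delegated to igraph's C implementations;
the test suite checks them against a naive all-pairs BFS enumeration.
"""

from __future__ import annotations

from dataclasses import dataclass

import igraph as ig
import numpy as np
import pandas as pd

from .exceptions import ParameterError, ValidationError

__all__ = [
    "PpiNetwork",
    "build_ppi_graph",
    "compute_centralities",
    "select_key_genes",
    "KeyGeneResult",
]


@dataclass
class PpiNetwork:
    """Undirected scored interaction network.

    ``edges`` maps a lexicographically sorted gene pair to a confidence
    score in [0, 1].  Nodes without edges are isolated, mirroring the many
    proteins real interaction databases leave unconnected at medium
    confidence.
    """

    nodes: tuple[str, ...]
    edges: dict[tuple[str, str], float]

    def __post_init__(self):
        node_set = set(self.nodes)
        for (a, b), score in self.edges.items():
            if a == b:
                raise ParameterError(f"self-loop on {a}")
            if a > b:
                raise ParameterError(f"edge ({a}, {b}) not stored in sorted order")
            if not (a in node_set and b in node_set):
                raise ParameterError(f"edge ({a}, {b}) references unknown node")
            if not 0.0 <= score <= 1.0:
                raise ParameterError(f"edge score outside [0, 1]: {score}")

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def degree(self) -> dict[str, int]:
        deg = {n: 0 for n in self.nodes}
        for a, b in self.edges:
            deg[a] += 1
            deg[b] += 1
        return deg

    def edge_table(self) -> pd.DataFrame:
        rows = sorted(self.edges.items())
        return pd.DataFrame(
            [(a, b, s) for (a, b), s in rows],
            columns=["protein1", "protein2", "score"],
        )

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for (a, b), s in self.edges.items():
            g.add_edge(a, b, score=s)
        return g

    def to_igraph(self) -> tuple[ig.Graph, list[str]]:
        order = sorted(self.nodes)
        index = {n: i for i, n in enumerate(order)}
        g = ig.Graph(n=len(order))
        g.add_edges([(index[a], index[b]) for a, b in self.edges])
        return g, order


def build_ppi_graph(
    edge_table: pd.DataFrame,
    candidate_genes: set[str],
    score_min: float = 0.4,
    strict: bool = False,
) -> PpiNetwork:
    """Induce the candidate genes on a scored edge table.

    Keeps edges with both endpoints in ``candidate_genes`` and score
    ``>= score_min`` (``> score_min`` with ``strict=True``, for readings of
    "medium confidence" as a strict inequality).  Duplicate undirected
    edges collapse to the maximum score; self-loops are dropped; isolated
    candidates stay in the node set.
    """
    from .evidence import normalize_symbol

    if not 0.0 <= score_min <= 1.0:
        raise ValidationError(f"score_min must be in [0, 1], got {score_min}")
    scores = edge_table["score"].to_numpy(dtype=float)
    if np.any(~np.isfinite(scores)) or scores.min(initial=0.0) < 0.0 or scores.max(initial=0.0) > 1.0:
        raise ValidationError("edge scores must be finite and in [0, 1]")

    candidates = {normalize_symbol(g) for g in candidate_genes}
    edges: dict[tuple[str, str], float] = {}
    for p1, p2, s in zip(edge_table["protein1"], edge_table["protein2"], scores):
        a, b = normalize_symbol(p1), normalize_symbol(p2)
        if a == b or a not in candidates or b not in candidates:
            continue
        if (s > score_min) if strict else (s >= score_min):
            key = (a, b) if a < b else (b, a)
            if key not in edges or s > edges[key]:
                edges[key] = float(s)
    return PpiNetwork(nodes=tuple(sorted(candidates)), edges=edges)


def compute_centralities(net: PpiNetwork) -> pd.DataFrame:
    """Degree, harmonic closeness and betweenness with per-measure ranks.

    Ranks run 1..n per measure, higher score first, ties broken by gene
    symbol ascending.
    """
    if len(net.nodes) == 0:
        raise ValidationError("network has no nodes")
    g, order = net.to_igraph()
    degree = np.asarray(g.degree(), dtype=float)
    if g.ecount() == 0:
        closeness = np.zeros(len(order))
        betweenness = np.zeros(len(order))
    else:
        closeness = np.asarray(g.harmonic_centrality(normalized=False), dtype=float)
        betweenness = np.asarray(g.betweenness(directed=False), dtype=float)
    # isolated vertices: igraph reports 0 for both, matching the convention
    table = pd.DataFrame(
        {
            "gene": order,
            "degree": degree.astype(int),
            "closeness": closeness,
            "betweenness": betweenness,
        }
    ).set_index("gene")
    for measure in ("degree", "closeness", "betweenness"):
        ordering = table.sort_values(
            [measure, "gene"], ascending=[False, True], kind="mergesort"
        ).index
        ranks = pd.Series(np.arange(1, len(ordering) + 1), index=ordering)
        table[f"{measure}_rank"] = ranks
    return table


@dataclass(frozen=True)
class KeyGeneResult:
    """Top-k lists per centrality measure and their intersection."""

    top_degree: tuple[str, ...]
    top_closeness: tuple[str, ...]
    top_betweenness: tuple[str, ...]
    key_genes: frozenset[str]

    @property
    def top_lists(self) -> dict[str, tuple[str, ...]]:
        return {
            "degree": self.top_degree,
            "closeness": self.top_closeness,
            "betweenness": self.top_betweenness,
        }


def select_key_genes(
    table: pd.DataFrame, k: int = 100, keep_ties: bool = False
) -> KeyGeneResult:
    """Intersect the top-k genes of the three centrality rankings.

    Ties at the k boundary are broken by gene symbol (deterministic);
    ``keep_ties=True`` instead keeps every gene tied with the k-th score.
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    flat = table.reset_index() if "gene" not in table.columns else table.copy()
    tops = {}
    for measure in ("degree", "closeness", "betweenness"):
        ordered = flat.sort_values(
            [measure, "gene"], ascending=[False, True], kind="mergesort"
        )
        names = list(ordered["gene"])
        if keep_ties and len(names) > k:
            cutoff = ordered[measure].iloc[k - 1]
            n_keep = int((ordered[measure] >= cutoff).sum())
            tops[measure] = tuple(names[:n_keep])
        else:
            tops[measure] = tuple(names[:k])
    key = frozenset(tops["degree"]) & frozenset(tops["closeness"]) & frozenset(
        tops["betweenness"]
    )
    return KeyGeneResult(
        top_degree=tops["degree"],
        top_closeness=tops["closeness"],
        top_betweenness=tops["betweenness"],
        key_genes=key,
    )
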