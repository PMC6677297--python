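"""Connectivity of interface structural space.

The IS-score is asymmetric (it is normalized by the *query* interface
length), so similarity relations form a directed graph: nodes are
interfaces, and an edge points from template t to query q whenever
score[q][t] meets the threshold. Connectivity is summarized by the fraction
of ordered node pairs within k directed steps, n_k / (N·(N−1)), and by the
size of the largest strongly connected component of the k-step closure.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd


@dataclass
class ScoreMatrix:
    """Asymmetric IS-score matrix: ``score[q, t]`` has q as query and t as
    template. The diagonal is undefined; missing entries (skipped
    alignments) are NaN and treated as below any threshold."""

    ids: list[str]
    score: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.ids)
        if n < 2 or self.score.shape != (n, n):
            raise ValueError("score matrix must be NxN over >= 2 ids")

    @classmethod
    def from_long(cls, df: pd.DataFrame) -> "ScoreMatrix":
        """Build from long-format columns (query, template, IS_score)."""
        ids = sorted(set(df["query"]) | set(df["template"]))
        idx = {v: i for i, v in enumerate(ids)}
        mat = np.full((len(ids), len(ids)), np.nan)
        for _, row in df.iterrows():
            mat[idx[row["query"]], idx[row["template"]]] = row["IS_score"]
        return cls(ids=ids, score=mat)

    def to_long(self) -> pd.DataFrame:
        rows = []
        for qi, q in enumerate(self.ids):
            for ti, t in enumerate(self.ids):
                if qi != ti and np.isfinite(self.score[qi, ti]):
                    rows.append({"query": q, "template": t,
                                 "IS_score": self.score[qi, ti]})
        return pd.DataFrame(rows)


def build_digraph(
    scores: ScoreMatrix, threshold: float, inclusive: bool = True
) -> nx.DiGraph:
    """Threshold digraph: edge template→query iff score[q][t] >= threshold
    (inclusive by default). No self-edges; NaN never makes an edge."""
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    g = nx.DiGraph()
    g.add_nodes_from(scores.ids)
    g.graph["threshold"] = threshold
    n = len(scores.ids)
    for qi in range(n):
        for ti in range(n):
            if qi == ti:
                continue
            s = scores.score[qi, ti]
            if not np.isfinite(s):
                continue
            if (s >= threshold) if inclusive else (s > threshold):
                g.add_edge(scores.ids[ti], scores.ids[qi])
    return g


def _reachable_within(graph: nx.DiGraph, source, k: int) -> set:
    """Nodes (excluding source) within k directed steps of source (BFS)."""
    seen = {source}
    frontier = [source]
    for _ in range(k):
        nxt = []
        for u in frontier:
            for v in graph.successors(u):
                if v not in seen:
                    seen.add(v)
                    nxt.append(v)
        if not nxt:
            break
        frontier = nxt
    seen.discard(source)
    return seen


def kth_neighbor_fraction(graph: nx.DiGraph, k: int) -> float:
    """Fraction of ordered pairs (u, v), u != v, with a directed path of
    length <= k: n_k / (N·(N−1))."""
    if k < 1:
        raise ValueError("k must be >= 1")
    n = graph.number_of_nodes()
    if n < 2:
        return 0.0
    n_k = sum(len(_reachable_within(graph, u, k)) for u in graph.nodes)
    return n_k / (n * (n - 1))


def k_closure(graph: nx.DiGraph, k: int) -> nx.DiGraph:
    """Digraph with edge u→v iff directed distance(u, v) <= k in the input."""
    if k < 1:
        raise ValueError("k must be >= 1")
    g = nx.DiGraph()
    g.add_nodes_from(graph.nodes)
    for u in graph.nodes:
        for v in _reachable_within(graph, u, k):
            g.add_edge(u, v)
    return g


def largest_scc_fraction(graph: nx.DiGraph, k: int = 1) -> float:
    """Relative size of the largest strongly connected component of the
    k-step closure (nodes mutually reachable within k steps)."""
    n = graph.number_of_nodes()
    if n == 0:
        return 0.0
    closed = k_closure(graph, k)
    largest = max((len(c) for c in nx.strongly_connected_components(closed)),
                  default=0)
    return largest / n


def sweep(
    scores: ScoreMatrix, thresholds, ks, inclusive: bool = True
) -> pd.DataFrame:
    """Long-format connectivity table over a threshold × k grid:
    (threshold, k, n_edges, pair_fraction, lscc_fraction)."""
    rows = []
    for thr in thresholds:
        g = build_digraph(scores, thr, inclusive)
        for k in ks:
            rows.append(
                {
                    "threshold": thr,
                    "k": int(k),
                    "n_edges": g.number_of_edges(),
                    "pair_fraction": kth_neighbor_fraction(g, int(k)),
                    "lscc_fraction": largest_scc_fraction(g, int(k)),
                }
            )
    return pd.DataFrame(rows)
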