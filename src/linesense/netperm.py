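"""Candidate-gene subnetworks over a global interaction graph, with a
one-bridge-gene allowance and a permutation test on the largest subnetwork.

A *bridge* (computationally recruited) gene is a non-candidate adjacent to
at least two mapped candidates; retained edges are candidate-candidate and
candidate-bridge (never bridge-bridge, which would chain two missing genes
between candidates).  The size statistic is the node count of the largest
connected component, candidates plus bridges.  Significance comes from
resampling n genes uniformly without replacement from the mappable
universe, recomputing the largest size each time, and reporting
``p = (A + 1) / (N_perm + 1)`` where A counts permutations whose largest
size is greater than or equal to the observed one.

The permutation loop runs on a dense boolean adjacency matrix for speed;
its construction is equivalent to the networkx-based
:func:`bridged_subnetworks` (asserted in the test suite).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components as _cc

from .errors import DataError

logger = logging.getLogger(__name__)

HUB_DEGREE = 11  # a hub has more than ten connections


@dataclass
class SubnetworkComponent:
    nodes: list[str]
    candidate_nodes: list[str]
    bridge_nodes: list[str]
    edges: list[tuple[str, str]]

    @property
    def size(self) -> int:
        return len(self.nodes)


@dataclass
class SubnetworkResult:
    components: list[SubnetworkComponent]
    n: int  # candidate genes mapped to the graph
    observed_size: int
    n_perm: int = 0
    A: int = 0  # permutations with size >= observed
    p: float | None = None
    seed: int | None = None
    perm_sizes: np.ndarray | None = None


# ---------------------------------------------------------------------------


def build_graph(edges: Iterable[Sequence[str]] | pd.DataFrame) -> nx.Graph:
    """Undirected simple graph from a two-column edge list; duplicate and
    reversed edges merge, self-loops are dropped (count logged)."""
    if isinstance(edges, pd.DataFrame):
        pairs = edges.iloc[:, :2].itertuples(index=False)
    else:
        pairs = iter(edges)
    g = nx.Graph()
    loops = 0
    empty = True
    for pair in pairs:
        u, v = pair[0], pair[1]
        empty = False
        if u == v:
            loops += 1
            continue
        g.add_edge(u, v)
    if empty:
        raise DataError("empty edge list")
    if loops:
        logger.info("dropped %d self-loop(s)", loops)
    return g


def bridged_subnetworks(graph: nx.Graph, candidates: Iterable[str]) -> list[SubnetworkComponent]:
    """Extract the candidate subnetworks with the one-missing-gene rule.

    Nodes are the mapped candidates plus every non-candidate adjacent to at
    least two of them; edges are candidate-candidate and candidate-bridge
    edges of the global graph.  Isolated candidates remain as singleton
    components.  Candidates absent from the graph are dropped (logged).
    """
    cand = set(candidates)
    if not cand:
        raise DataError("empty candidate set")
    mapped = cand & set(graph.nodes)
    dropped = len(cand) - len(mapped)
    if dropped:
        logger.info("%d candidate gene(s) not present in the interaction graph", dropped)
    if not mapped:
        raise DataError("no candidate gene maps to the interaction graph")

    bridges = {
        b
        for c in mapped
        for b in graph.neighbors(c)
        if b not in mapped and sum(1 for x in graph.neighbors(b) if x in mapped) >= 2
    }
    sub = nx.Graph()
    sub.add_nodes_from(mapped)
    sub.add_nodes_from(bridges)
    for u, v in graph.edges(mapped | bridges):
        if u in mapped and (v in mapped or v in bridges):
            sub.add_edge(u, v)
        elif v in mapped and u in bridges:
            sub.add_edge(u, v)

    comps = []
    for nodes in nx.connected_components(sub):
        nodes = set(nodes)
        comps.append(
            SubnetworkComponent(
                nodes=sorted(nodes),
                candidate_nodes=sorted(nodes & mapped),
                bridge_nodes=sorted(nodes & bridges),
                edges=sorted((min(u, v), max(u, v)) for u, v in sub.edges(nodes)),
            )
        )
    return comps


def largest_size(components: Sequence[SubnetworkComponent]) -> int:
    """Node count (candidates + bridges) of the largest subnetwork."""
    if not components:
        raise DataError("no components")
    return max(c.size for c in components)


def largest_component(components: Sequence[SubnetworkComponent]) -> SubnetworkComponent:
    """The largest subnetwork; ties break by more edges, then by the
    lexicographically smallest node list (reporting only — the size
    statistic itself is tie-free)."""
    if not components:
        raise DataError("no components")
    return min(components, key=lambda c: (-c.size, -len(c.edges), c.nodes))


# ---------------------------------------------------------------------------
# fast permutation machinery


class _DenseBridgeSizer:
    """Largest bridged-subnetwork size from a dense boolean adjacency."""

    def __init__(self, graph: nx.Graph, universe: Sequence[str]):
        self.nodes = list(universe)
        self.index = {n: i for i, n in enumerate(self.nodes)}
        self.adj = nx.to_numpy_array(graph, nodelist=self.nodes, dtype=bool)

    def largest(self, cand_idx: np.ndarray) -> int:
        n = self.adj.shape[0]
        c = np.zeros(n, dtype=bool)
        c[cand_idx] = True
        counts = self.adj[:, cand_idx].sum(axis=1)
        bridges = (~c) & (counts >= 2)
        keep = np.flatnonzero(c | bridges)
        sub = self.adj[np.ix_(keep, keep)].copy()
        cb = c[keep]
        sub[np.ix_(~cb, ~cb)] = False  # bridge-bridge edges excluded
        _, labels = _cc(csr_matrix(sub), directed=False)
        return int(np.bincount(labels).max()) if len(labels) else 0


def permutation_test(
    graph: nx.Graph,
    n: int,
    observed_size: int,
    n_perm: int = 1000,
    seed: int | None = None,
    universe: Sequence[str] | None = None,
) -> SubnetworkResult:
    """Permutation null for the largest bridged-subnetwork size.

    Each replicate draws ``n`` distinct genes uniformly from the mappable
    universe (default: all graph nodes), rebuilds the bridged subnetworks
    and records the largest size; ties with the observed size count toward
    A.  ``p = (A + 1) / (n_perm + 1)``.
    """
    universe = sorted(universe) if universe is not None else sorted(graph.nodes)
    if n > len(universe):
        raise DataError(f"cannot sample {n} genes from a universe of {len(universe)}")
    if n < 1 or n_perm < 1:
        raise DataError("n and n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    sizer = _DenseBridgeSizer(graph, universe)
    sizes = np.empty(n_perm, dtype=int)
    m = len(universe)
    for i in range(n_perm):
        cand_idx = rng.choice(m, size=n, replace=False)
        sizes[i] = sizer.largest(cand_idx)
    A = int((sizes >= observed_size).sum())
    return SubnetworkResult(
        components=[],
        n=n,
        observed_size=observed_size,
        n_perm=n_perm,
        A=A,
        p=(A + 1) / (n_perm + 1),
        seed=seed,
        perm_sizes=sizes,
    )


def subnetwork_significance(
    graph: nx.Graph,
    candidates: Iterable[str],
    n_perm: int = 1000,
    seed: int | None = None,
    universe: Sequence[str] | None = None,
) -> SubnetworkResult:
    """Build the observed bridged subnetworks and run the permutation test
    with n equal to the number of mapped candidate genes."""
    comps = bridged_subnetworks(graph, candidates)
    mapped = sum(len(c.candidate_nodes) for c in comps)
    obs = largest_size(comps)
    res = permutation_test(graph, mapped, obs, n_perm=n_perm, seed=seed, universe=universe)
    res.components = comps
    return res


# ---------------------------------------------------------------------------
# hubs


def classify_hubs(
    component: SubnetworkComponent,
    *,
    scope: str = "subnetwork",
    graph: nx.Graph | None = None,
) -> pd.DataFrame:
    """Per-node degree and hub flag (more than ten connections).

    ``scope='subnetwork'`` (default) counts connections within the
    component; ``scope='global'`` counts degree in the supplied global
    graph.
    """
    if scope not in ("subnetwork", "global"):
        raise DataError(f"unknown hub scope {scope!r}")
    if scope == "global" and graph is None:
        raise DataError("global hub scope requires the global graph")
    if scope == "subnetwork":
        deg = {node: 0 for node in component.nodes}
        for u, v in component.edges:
            deg[u] += 1
            deg[v] += 1
    else:
        deg = {node: graph.degree(node) for node in component.nodes}
    out = pd.DataFrame(
        {
            "gene_id": component.nodes,
            "role": [
                "candidate" if g in set(component.candidate_nodes) else "bridge"
                for g in component.nodes
            ],
            "degree": [deg[g] for g in component.nodes],
        }
    )
    out["hub"] = out["degree"] >= HUB_DEGREE
    return out
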