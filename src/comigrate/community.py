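"""Module detection on yearly co-occurrence networks.

Newman–Girvan modularity for unweighted, undirected graphs,

    Q = sum_c [ L_c / m - (d_c / (2 m))^2 ],

with ``m`` the number of edges, ``L_c`` the edges inside module ``c`` and
``d_c`` the total degree of its nodes.  Partitions come from the Louvain
multilevel heuristic; because the heuristic depends on vertex visiting
order, :func:`louvain` runs several restarts under a seeded vertex
permutation and keeps the highest-Q partition, so identical seeds give
identical results.  Networks with ``Q > 0.3`` are conventionally considered
strongly modular.
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass
from pathlib import Path

import igraph as ig
import numpy as np
import pandas as pd

from .network import CoocNetwork

__all__ = ["ModulePartition", "modularity_Q", "louvain", "STRONG_MODULARITY_Q"]

log = logging.getLogger(__name__)

#: conventional threshold for a strong modular subdivision
STRONG_MODULARITY_Q = 0.3


def _as_nodes_edges(network) -> tuple[list, list[tuple]]:
    if isinstance(network, CoocNetwork):
        nodes = list(network.species)
        edges = network.edge_list()
    else:  # (nodes, edges) pair
        nodes, edges = network
        nodes = list(nodes)
        edges = [tuple(e) for e in edges]
    return nodes, edges


def modularity_Q(network, assignment: dict) -> float:
    """Modularity of ``assignment`` (node → module label) on the network.

    Accepts a :class:`~comigrate.network.CoocNetwork` or a
    ``(nodes, edges)`` pair.  Raises on edgeless graphs (Q undefined) and on
    assignments that do not cover every node.
    """
    nodes, edges = _as_nodes_edges(network)
    missing = [n for n in nodes if n not in assignment]
    if missing:
        raise ValueError(f"assignment misses nodes: {missing}")
    m = len(edges)
    if m == 0:
        raise ValueError("modularity undefined on a graph with no edges")
    within: dict = {}
    degree_sum: dict = {}
    for u, v in edges:
        cu, cv = assignment[u], assignment[v]
        if cu == cv:
            within[cu] = within.get(cu, 0) + 1
        degree_sum[cu] = degree_sum.get(cu, 0) + 1
        degree_sum[cv] = degree_sum.get(cv, 0) + 1
    q = 0.0
    for c in set(assignment[n] for n in nodes):
        lc = within.get(c, 0)
        dc = degree_sum.get(c, 0)
        q += lc / m - (dc / (2.0 * m)) ** 2
    return q


@dataclass(frozen=True)
class ModulePartition:
    """One year's species → module labelling and its modularity."""

    year: int
    assignment: dict
    Q: float
    n_modules: int
    seed: int
    restarts: int

    @property
    def is_strongly_modular(self) -> bool:
        return self.Q > STRONG_MODULARITY_Q

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.assignment.items()), columns=["species", "module"]
        )

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def louvain(network, seed: int = 0, restarts: int = 20, year: int | None = None
            ) -> ModulePartition:
    """Best-of-restarts Louvain partition of an unweighted network.

    Each restart relabels the vertices by a seeded permutation (changing the
    order in which the greedy local-moving phase visits them) and reseeds the
    graph library's RNG, then the multilevel algorithm runs to convergence.
    The restart with the highest modularity — re-evaluated independently by
    :func:`modularity_Q` — wins; ties keep the earliest restart, so the
    result is a pure function of ``(network, seed, restarts)``.

    Isolated nodes form singleton modules (logged).
    """
    nodes, edges = _as_nodes_edges(network)
    if len(edges) == 0:
        raise ValueError("cannot partition a graph with no edges")
    if year is None:
        year = network.year if isinstance(network, CoocNetwork) else -1
    n = len(nodes)
    index = {v: i for i, v in enumerate(nodes)}
    eidx = [(index[u], index[v]) for u, v in edges]
    deg = np.zeros(n, dtype=int)
    for u, v in eidx:
        deg[u] += 1
        deg[v] += 1
    isolated = [nodes[i] for i in np.flatnonzero(deg == 0)]
    if isolated:
        log.info("year %s: isolated nodes form singleton modules: %s", year, isolated)

    rng = np.random.default_rng(seed)
    best_assignment = None
    best_q = -np.inf
    for _ in range(max(1, restarts)):
        perm = rng.permutation(n)
        # python-igraph draws its randomness from the stdlib `random` module
        random.seed(int(rng.integers(0, 2**31 - 1)))
        g = ig.Graph(
            n=n, edges=[(int(perm[u]), int(perm[v])) for u, v in eidx]
        )
        membership = g.community_multilevel().membership
        assignment = {v: int(membership[perm[i]]) for v, i in index.items()}
        q = modularity_Q((nodes, edges), assignment)
        if q > best_q + 1e-12:
            best_q = q
            best_assignment = assignment
    # never worse than the trivial single-module partition (Q = 0)
    trivial = {v: 0 for v in nodes}
    if best_q < 0.0:
        best_q = modularity_Q((nodes, edges), trivial)
        best_assignment = trivial
    labels = sorted(set(best_assignment.values()))
    relabel = {old: new for new, old in enumerate(labels)}
    best_assignment = {v: relabel[c] for v, c in best_assignment.items()}
    return ModulePartition(
        year=year,
        assignment=best_assignment,
        Q=best_q,
        n_modules=len(labels),
        seed=seed,
        restarts=restarts,
    )
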