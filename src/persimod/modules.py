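"""Persistent disease modules.

The n-th persistent disease module is the union of the n-dimensional holes
that persist over all p-value thresholds. For n = 0 this is the largest
connected component (LCC) of the hit-induced subnetwork — the classical
observable disease module; smaller final components are excluded. For
n >= 1 it is the union of the representative cycles of the essential
n-dimensional classes. Representatives of homology classes are not unique;
the deterministic filtration order fixes them reproducibly, which is
recorded in the module metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import pandas as pd

from .filtration import SimplexStream, induced_subgraph, _logp_map
from .io import largest_connected_component
from .persistence import PersistenceDiagram, essential_classes


@dataclass
class PersistentModule:
    """A concrete subnetwork assembled from essential homology classes."""

    dim: int
    nodes: set[str]
    edges: set[tuple[str, str]]
    class_ids: list[str]
    node_logp: dict[str, float]
    per_class: dict[str, tuple[int, int]] = field(default_factory=dict)
    note: str = ""

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def edge_frame(self) -> pd.DataFrame:
        rows = sorted(self.edges)
        return pd.DataFrame(
            {
                "gene_a": [a for a, _ in rows],
                "gene_b": [b for _, b in rows],
            }
        )

    def node_frame(self) -> pd.DataFrame:
        rows = sorted(self.nodes)
        return pd.DataFrame(
            {
                "gene": rows,
                "log10_p": [self.node_logp.get(g) for g in rows],
            }
        )


def persistent_module(
    diagram: PersistenceDiagram,
    stream: SimplexStream,
    network: nx.Graph,
    hits,
    dim: int,
) -> PersistentModule:
    """Extract the dim-th persistent disease module.

    dim = 0 returns the LCC of the hit-induced subgraph. dim >= 1 returns
    the union over essential classes of their representative cycles: the
    edge set is the union of vertex pairs within each representative
    simplex, the node set the union of their endpoints.

    Raises
    ------
    ValueError
        If dim >= stream.maxdim (homology was not computed there).
    """
    if dim >= stream.maxdim:
        raise ValueError(
            f"dim {dim} >= maxdim {stream.maxdim}: homology not computed there"
        )
    logp = _logp_map(hits)
    if dim == 0:
        lcc = largest_connected_component(induced_subgraph(network, logp, float("inf")))
        nodes = set(lcc.nodes)
        edges = {tuple(sorted(e)) for e in lcc.edges}
        module = PersistentModule(
            dim=0,
            nodes=nodes,
            edges=edges,
            class_ids=["0:lcc"],
            node_logp={g: logp[g] for g in nodes},
            per_class={"0:lcc": (len(nodes), len(edges))},
            note="LCC of the hit-induced subnetwork (smaller final components excluded)",
        )
        return module
    nodes: set[str] = set()
    edges: set[tuple[str, str]] = set()
    class_ids: list[str] = []
    per_class: dict[str, tuple[int, int]] = {}
    for i, pair in enumerate(essential_classes(diagram, dim)):
        cid = f"{dim}:{i}"
        c_nodes: set[str] = set()
        c_edges: set[tuple[str, str]] = set()
        for simplex in pair.representative:
            c_nodes.update(simplex)
            for a, b in combinations(sorted(simplex), 2):
                c_edges.add((a, b))
        nodes |= c_nodes
        edges |= c_edges
        class_ids.append(cid)
        per_class[cid] = (len(c_nodes), len(c_edges))
    return PersistentModule(
        dim=dim,
        nodes=nodes,
        edges=edges,
        class_ids=class_ids,
        node_logp={g: logp[g] for g in nodes if g in logp},
        per_class=per_class,
        note="union of reduction representatives; homology representatives are not unique",
    )


def module_summary(module: PersistentModule) -> dict:
    """Compact summary record: dimension, node/edge/class counts and
    per-class (node, edge) sizes."""
    return {
        "dim": module.dim,
        "n_nodes": module.n_nodes,
        "n_edges": module.n_edges,
        "n_classes": len(module.class_ids),
        "class_sizes": {cid: list(module.per_class[cid]) for cid in module.class_ids},
    }
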