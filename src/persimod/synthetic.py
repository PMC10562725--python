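"""Synthetic PPI-like studies with planted topological ground truth.

Real interactomes are scale-free; networks here are grown by preferential
attachment from an initial complete seed graph. On top of the network the
generator plants (a) a connected component of hit genes (ground truth for
the LCC / 0-dimensional module) and (b) chordless cycles of fresh nodes,
each attached to the rest of the network by a single bridge edge so that it
contributes exactly one essential 1-dimensional class and cannot be filled
by triangles. Hit p-values are drawn uniformly in log10 space — published
association p-values span many orders of magnitude, down to ~1e-695 in
large meta-analyses — strictly below the genome-wide threshold 5e-8.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import numpy as np

from .io import GENOME_WIDE_LOG10P, GwasHits, logp_to_pstring


@dataclass
class CycleTruth:
    """One planted chordless cycle: its node order, edges and bridge."""

    nodes: list[str]
    edges: list[tuple[str, str]]
    anchor: str  # existing node the bridge attaches to
    bridge: tuple[str, str]


@dataclass
class SyntheticStudy:
    network: nx.Graph
    hits: GwasHits
    cycles: list[CycleTruth]
    component: set[str]
    params: dict
    seed: int

    def truth_manifest(self) -> dict:
        return {
            "seed": self.seed,
            "params": self.params,
            "planted_cycles": [
                {
                    "nodes": c.nodes,
                    "edges": [list(e) for e in c.edges],
                    "anchor": c.anchor,
                    "bridge": list(c.bridge),
                }
                for c in self.cycles
            ],
            "planted_component": sorted(self.component),
        }


def generate_scale_free_network(n: int, m: int, seed: int) -> nx.Graph:
    """Preferential-attachment network: complete graph on m+1 nodes, then
    each new node attaches to m distinct existing nodes with probability
    proportional to degree. Edge count is C(m+1, 2) + (n - m - 1) * m and
    the graph is connected by construction. Nodes are labelled G0000..."""
    if m < 1 or n < m + 1:
        raise ValueError("need n >= m + 1 >= 2")
    initial = nx.complete_graph(m + 1)
    g = nx.barabasi_albert_graph(n, m, seed=seed, initial_graph=initial)
    mapping = {i: f"G{i:04d}" for i in g.nodes}
    return nx.relabel_nodes(g, mapping)


def plant_chordless_cycles(
    network: nx.Graph, lengths: Sequence[int], seed: int
) -> tuple[nx.Graph, list[CycleTruth]]:
    """Attach, per requested length L >= 4, a fresh chordless L-cycle via a
    single bridge edge to a uniformly chosen existing node.

    Fresh cycle nodes have no other edges, so the cycles stay chordless and
    each bridge creates no new cycle; every planted cycle contributes
    exactly one independent loop.
    """
    if network.number_of_nodes() == 0:
        raise ValueError("empty network")
    if any(length < 4 for length in lengths):
        raise ValueError("cycle lengths must be >= 4")
    rng = np.random.default_rng(seed)
    g = network.copy()
    existing = sorted(network.nodes)
    truths: list[CycleTruth] = []
    for idx, length in enumerate(lengths):
        nodes = [f"CYC{idx}_{j:02d}" for j in range(length)]
        edges = [
            tuple(sorted((nodes[j], nodes[(j + 1) % length]))) for j in range(length)
        ]
        g.add_edges_from(edges)
        anchor = existing[int(rng.integers(len(existing)))]
        bridge = tuple(sorted((anchor, nodes[0])))
        g.add_edge(*bridge)
        truths.append(CycleTruth(nodes=nodes, edges=edges, anchor=anchor, bridge=bridge))
    return g, truths


def _pick_connected_component(
    network: nx.Graph, size: int, forbidden: set[str], rng: np.random.Generator
) -> set[str]:
    """Breadth-first ball of the requested size around a random start node."""
    candidates = sorted(set(network.nodes) - forbidden)
    start = candidates[int(rng.integers(len(candidates)))]
    chosen = [start]
    seen = {start}
    frontier = [start]
    while frontier and len(chosen) < size:
        nxt = []
        for node in frontier:
            for nb in sorted(network.neighbors(node)):
                if nb not in seen and nb not in forbidden:
                    seen.add(nb)
                    chosen.append(nb)
                    nxt.append(nb)
                    if len(chosen) >= size:
                        return set(chosen)
        frontier = nxt
    return set(chosen)


def assign_synthetic_pvalues(
    network: nx.Graph,
    planted: Sequence[str],
    n_background_hits: int,
    log10p_range: tuple[float, float] = (-100.0, GENOME_WIDE_LOG10P),
    seed: int = 0,
) -> GwasHits:
    """Give every planted node plus n_background_hits uniformly chosen other
    nodes a log10 p drawn uniformly from log10p_range (upper bound at most
    log10(5e-8)); values are jittered to be distinct."""
    lo, hi = log10p_range
    if hi > GENOME_WIDE_LOG10P + 1e-12:
        raise ValueError("log10p_range upper bound must be <= log10(5e-8)")
    if lo >= hi:
        raise ValueError("log10p_range must be a nonempty interval")
    rng = np.random.default_rng(seed)
    planted = list(dict.fromkeys(planted))
    others = sorted(set(network.nodes) - set(planted))
    if n_background_hits > len(others):
        raise ValueError(
            f"n_background_hits {n_background_hits} exceeds {len(others)} available nodes"
        )
    background = (
        [others[i] for i in rng.choice(len(others), size=n_background_hits, replace=False)]
        if n_background_hits
        else []
    )
    genes = planted + sorted(background)
    values = lo + (hi - lo) * rng.random(len(genes))
    # enforce distinctness (collisions are measure-zero but jitter anyway)
    used: set[float] = set()
    hits = GwasHits()
    for gene, v in zip(genes, values):
        while v in used or v > hi:
            v = v - 1e-9 * (1 + rng.random())
        used.add(v)
        hits.logp[gene] = float(v)
        hits.p_string[gene] = logp_to_pstring(float(v))
    return hits


def generate_study(
    n_nodes: int = 250,
    m: int = 2,
    cycle_lengths: Sequence[int] = (4, 5, 6),
    component_size: int = 20,
    n_background_hits: int = 10,
    log10p_range: tuple[float, float] = (-100.0, GENOME_WIDE_LOG10P),
    seed: int = 0,
) -> SyntheticStudy:
    """Full synthetic study: scale-free network + planted chordless cycles
    + a planted connected hit component + sparse background hits, with a
    ground-truth manifest.

    Defaults give a 250-node preferential-attachment network (m = 2), three
    planted cycles of lengths 4-6, a 20-node connected hit component and
    background hits on 4% of nodes, with log10 p uniform on [-100, -7.30].
    """
    rng = np.random.default_rng(seed)
    base = generate_scale_free_network(n_nodes, m, seed=int(rng.integers(2**31 - 1)))
    network, cycles = plant_chordless_cycles(
        base, cycle_lengths, seed=int(rng.integers(2**31 - 1))
    )
    cycle_nodes = [v for c in cycles for v in c.nodes]
    component: set[str] = set()
    if component_size:
        component = _pick_connected_component(
            base, component_size, forbidden=set(cycle_nodes), rng=rng
        )
    planted = cycle_nodes + sorted(component)
    hits = assign_synthetic_pvalues(
        network,
        planted,
        n_background_hits,
        log10p_range=log10p_range,
        seed=int(rng.integers(2**31 - 1)),
    )
    params = {
        "n_nodes": n_nodes,
        "m": m,
        "cycle_lengths": list(cycle_lengths),
        "component_size": component_size,
        "n_background_hits": n_background_hits,
        "log10p_range": list(log10p_range),
    }
    return SyntheticStudy(
        network=network,
        hits=hits,
        cycles=cycles,
        component=component,
        params=params,
        seed=seed,
    )
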