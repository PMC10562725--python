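"""Flag-complex filtration of the hit-induced PPI subnetwork.

The simplicial complex is the clique (flag) complex of the subgraph induced
by the GWAS hits: genes are 0-simplices, interactions 1-simplices, and every
k-clique a (k-1)-simplex. Each vertex carries its hit's log10 p-value, and a
simplex enters the filtration at the maximum value over its vertices (the
lower-star / vertex-function convention), so the sublevel complex at
threshold delta is exactly the clique complex of the subgraph induced by
genes with log10 p <= delta.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterator, NamedTuple

import networkx as nx
import pandas as pd

from .io import GENOME_WIDE_LOG10P, GwasHits


class FilteredSimplex(NamedTuple):
    """A simplex (sorted vertex tuple) with its filtration value."""

    vertices: tuple[str, ...]
    value: float

    @property
    def dim(self) -> int:
        return len(self.vertices) - 1


def _logp_map(hits) -> dict[str, float]:
    return hits.logp if isinstance(hits, GwasHits) else dict(hits)


@dataclass
class SimplexStream:
    """Face-closed list of filtered simplices in filtration order.

    The order is non-decreasing in value with ties broken by (dim, lexical
    vertex tuple), so every face precedes its cofaces and the stream prefix
    with value <= delta is the sublevel clique complex truncated at
    ``maxdim``.
    """

    simplices: list[FilteredSimplex]
    maxdim: int
    value_set: tuple[float, ...]
    _index: dict[tuple[str, ...], int] = field(default=None, repr=False, compare=False)

    def __len__(self) -> int:
        return len(self.simplices)

    def __iter__(self) -> Iterator[FilteredSimplex]:
        return iter(self.simplices)

    @property
    def index(self) -> dict[tuple[str, ...], int]:
        if self._index is None:
            self._index = {s.vertices: i for i, s in enumerate(self.simplices)}
        return self._index

    def prefix(self, delta: float) -> list[FilteredSimplex]:
        """Simplices with value <= delta (a face-closed subcomplex)."""
        return [s for s in self.simplices if s.value <= delta]

    def counts_by_dim(self) -> dict[int, int]:
        out: dict[int, int] = {}
        for s in self.simplices:
            out[s.dim] = out.get(s.dim, 0) + 1
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "dim": [s.dim for s in self.simplices],
                "vertices": [";".join(s.vertices) for s in self.simplices],
                "log10_p": [s.value for s in self.simplices],
            }
        )

    def validate(self) -> None:
        """Raise ValueError if face-closure or ordering is violated."""
        idx = self.index
        prev_key = None
        for i, s in enumerate(self.simplices):
            key = (s.value, s.dim, s.vertices)
            if prev_key is not None and key < prev_key:
                raise ValueError(f"stream order violated at position {i}")
            prev_key = key
            if s.dim > 0:
                for face in combinations(s.vertices, len(s.vertices) - 1):
                    j = idx.get(face)
                    if j is None or j >= i:
                        raise ValueError(
                            f"face {face} of {s.vertices} missing or out of order"
                        )


def induced_subgraph(network: nx.Graph, hits, delta: float) -> nx.Graph:
    """Subgraph induced by hit genes with log10 p <= delta."""
    logp = _logp_map(hits)
    keep = [g for g, v in logp.items() if v <= delta and g in network]
    return network.subgraph(keep).copy()


def build_flag_filtration(
    network: nx.Graph,
    hits,
    delta_max: float = GENOME_WIDE_LOG10P,
    maxdim: int = 2,
) -> SimplexStream:
    """Build the filtered flag complex of the hit-induced subgraph.

    Every clique of size <= maxdim + 1 of the subgraph induced by hits with
    log10 p <= delta_max becomes a simplex valued at the maximum member
    log10 p. Only PPI edges ever enter the complex; there is no Rips-style
    completion between non-interacting genes.

    Parameters
    ----------
    maxdim
        Maximum simplex dimension retained; homology is then reliable in
        dimensions 0..maxdim-1. Must be >= 1.
    """
    if maxdim < 1:
        raise ValueError("maxdim must be >= 1")
    logp = _logp_map(hits)
    sub = induced_subgraph(network, logp, delta_max)
    simplices: list[FilteredSimplex] = []
    for clique in nx.enumerate_all_cliques(sub):
        if len(clique) > maxdim + 1:
            break
        verts = tuple(sorted(clique))
        value = max(logp[v] for v in verts)
        simplices.append(FilteredSimplex(verts, value))
    simplices.sort(key=lambda s: (s.value, s.dim, s.vertices))
    value_set = tuple(sorted({s.value for s in simplices}))
    return SimplexStream(simplices=simplices, maxdim=maxdim, value_set=value_set)


def write_stream(stream: SimplexStream, target, comment: str | None = None) -> None:
    """Dump the stream as TSV (dim, vertices, log10_p) in filtration order."""
    df = stream.to_frame()
    if hasattr(target, "write"):
        if comment:
            target.write(f"# {comment}\n")
        df.to_csv(target, sep="\t", index=False)
    else:
        with open(target, "w", encoding="utf-8") as fh:
            if comment:
                fh.write(f"# {comment}\n")
            df.to_csv(fh, sep="\t", index=False)
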