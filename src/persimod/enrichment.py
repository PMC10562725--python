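"""Offline over-representation analysis against GMT gene-set collections.

Per term, the hypergeometric upper-tail probability P(X >= k) of drawing k
module genes from a set of size K out of a universe of N genes is computed,
followed by Benjamini-Hochberg adjustment across terms. Gene sets are
supplied as GMT snapshots, keeping results reproducible without web
services; the natural universe is the set of all PPI network genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class GeneSetCollection:
    """Named gene sets (term -> gene set) with a source label."""

    sets: dict[str, set[str]]
    source: str = ""

    def __len__(self) -> int:
        return len(self.sets)


def read_gmt(source) -> GeneSetCollection:
    """Read a standard GMT stream: term, description, member genes...

    Duplicate genes within a term are collapsed. Raises ValueError on an
    empty stream or a line with fewer than three fields (naming the line).
    """
    if hasattr(source, "read"):
        lines = source.read().splitlines()
        label = getattr(source, "name", "")
    else:
        with open(source, "r", encoding="utf-8") as fh:
            lines = fh.read().splitlines()
        label = str(source)
    sets: dict[str, set[str]] = {}
    n_data = 0
    for lineno, line in enumerate(lines, start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"line {lineno}: GMT line needs >= 3 fields")
        term = fields[0].strip()
        genes = {g.strip() for g in fields[2:] if g.strip()}
        if not genes:
            raise ValueError(f"line {lineno}: gene set {term!r} is empty")
        sets[term] = genes
        n_data += 1
    if n_data == 0:
        raise ValueError("empty GMT input")
    return GeneSetCollection(sets=sets, source=label)


def bh_adjust(pvalues: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    arr = np.asarray(list(pvalues), dtype=float)
    if arr.size == 0:
        return arr
    if np.any((arr < 0) | (arr > 1)) or np.any(np.isnan(arr)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(arr, method="fdr_bh")[1]


def overrepresentation(
    query: Iterable[str],
    universe: Iterable[str],
    collection: GeneSetCollection,
) -> pd.DataFrame:
    """Hypergeometric over-representation of a gene list against a collection.

    Returns a DataFrame with columns term, overlap, set_size, query_size,
    universe_size, p, p_adj, sorted by p. Terms with no genes in the
    universe are skipped with a warning. The query must be contained in the
    universe.
    """
    query = set(query)
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    if not query <= universe:
        extra = sorted(query - universe)[:5]
        raise ValueError(f"query genes outside universe, e.g. {extra}")
    n = len(query)
    N = len(universe)
    rows = []
    for term, genes in collection.sets.items():
        in_universe = genes & universe
        K = len(in_universe)
        if K == 0:
            warnings.warn(f"term {term!r} has no genes in the universe; skipped")
            continue
        k = len(query & in_universe)
        # upper tail P(X >= k) for X ~ Hypergeom(N, K, n)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append((term, k, K, n, N, min(p, 1.0)))
    df = pd.DataFrame(
        rows, columns=["term", "overlap", "set_size", "query_size", "universe_size", "p"]
    )
    if len(df):
        df["p_adj"] = bh_adjust(df["p"])
        df = df.sort_values(["p", "term"], kind="mergesort").reset_index(drop=True)
    else:
        df["p_adj"] = []
    return df
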