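"""Readers, writers and mapping rules for PPI networks and GWAS association data.

The protein-protein interaction (PPI) network is held as an undirected simple
:class:`networkx.Graph` over gene symbols. GWAS hits are genes mapped from
genome-wide-significant loci; each gene carries the minimum p-value over the
loci mapped onto it, stored on the log10 scale (``LogP``) because published
association p-values can be far below the double-precision underflow limit
(values around 1e-695 occur in large meta-analyses).
"""

from __future__ import annotations

import logging
import math
import re
from collections import Counter
from dataclasses import dataclass, field
from decimal import Decimal, InvalidOperation
from typing import IO, Iterable, Sequence

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

#: log10 of the standard genome-wide significance threshold p = 5e-8.
GENOME_WIDE_LOG10P: float = math.log10(5e-8)

_GENE_FIELD_SPLIT = re.compile(r",| - ")


def parse_pvalue(p_string: str) -> float:
    """Parse a p-value string into its log10 value (``LogP``).

    The mantissa and decimal exponent are separated textually via
    :class:`decimal.Decimal`, so p-values that underflow IEEE doubles
    (e.g. ``"3e-695"``) are handled exactly: the result is
    ``log10(mantissa) + exponent`` with the mantissa in ``[1, 10)``.

    Raises
    ------
    ValueError
        If the string is not a finite decimal/scientific number, or the
        value is outside ``(0, 1]``.
    """
    text = str(p_string).strip()
    try:
        d = Decimal(text)
    except InvalidOperation as exc:
        raise ValueError(f"unparseable p-value: {p_string!r}") from exc
    if not d.is_finite():
        raise ValueError(f"p-value must be finite: {p_string!r}")
    if d <= 0:
        raise ValueError(f"p-value must be > 0: {p_string!r}")
    if d > 1:
        raise ValueError(f"p-value must be <= 1: {p_string!r}")
    exponent = d.adjusted()
    mantissa = d.scaleb(-exponent)  # in [1, 10)
    return math.log10(float(mantissa)) + exponent


def logp_to_pstring(logp: float, digits: int = 6) -> str:
    """Format a LogP back into a scientific-notation p-value string.

    Safe for values far below the float underflow limit.
    """
    if logp > 0:
        raise ValueError("LogP must be <= 0")
    exponent = math.floor(logp)
    mantissa = 10.0 ** (logp - exponent)
    # rounding can push the mantissa to 10.0
    if round(mantissa, digits) >= 10.0:
        mantissa /= 10.0
        exponent += 1
    return f"{mantissa:.{digits}f}e{exponent:d}"


@dataclass
class GwasLocusRecord:
    """One association-table row: a variant, its mapped gene(s), and the
    p-value exactly as printed."""

    variant_id: str
    mapped_genes: list[str]
    p_string: str

    def __post_init__(self) -> None:
        # validates 0 < p <= 1; raises ValueError otherwise
        self.log10_p = parse_pvalue(self.p_string)


@dataclass
class GwasHits:
    """Gene -> LogP table of GWAS hits surviving the mapping rules.

    ``logp`` maps each gene to the log10 of its minimum p-value across loci;
    ``p_string`` keeps the original printed p-value of that minimum;
    ``drop_counts`` records why candidate genes/loci were discarded.
    """

    logp: dict[str, float] = field(default_factory=dict)
    p_string: dict[str, str] = field(default_factory=dict)
    drop_counts: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.logp)

    def __contains__(self, gene: str) -> bool:
        return gene in self.logp

    @property
    def genes(self) -> set[str]:
        return set(self.logp)

    def to_frame(self) -> pd.DataFrame:
        rows = sorted(self.logp.items(), key=lambda kv: (kv[1], kv[0]))
        return pd.DataFrame(
            {
                "gene": [g for g, _ in rows],
                "p_value": [self.p_string.get(g, logp_to_pstring(v)) for g, v in rows],
                "log10_p": [v for _, v in rows],
            }
        )


def _open_maybe(source) -> tuple[IO[str], bool]:
    if hasattr(source, "read"):
        return source, False
    return open(source, "r", encoding="utf-8"), True


def read_ppi_edgelist(source, header: bool = False) -> nx.Graph:
    """Read a two-column (whitespace/tab) gene-symbol edge list.

    Lines starting with ``#`` are comments. Self-loops and duplicate edges
    are dropped; the counts are logged and stored in ``G.graph``.

    Raises
    ------
    ValueError
        On empty input, or on a data line with fewer than two fields
        (the error names the line number).
    """
    fh, close = _open_maybe(source)
    graph = nx.Graph()
    n_self, n_dup, n_lines = 0, 0, 0
    try:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if header and n_lines == 0:
                n_lines += 1
                continue
            fields = line.split()
            if len(fields) < 2:
                raise ValueError(
                    f"line {lineno}: expected >= 2 fields, got {len(fields)}"
                )
            a, b = fields[0].strip(), fields[1].strip()
            n_lines += 1
            if a == b:
                n_self += 1
                continue
            if graph.has_edge(a, b):
                n_dup += 1
                continue
            graph.add_edge(a, b)
    finally:
        if close:
            fh.close()
    if n_lines == 0 or (header and n_lines == 1 and graph.number_of_nodes() == 0):
        raise ValueError("empty PPI edge list")
    if graph.number_of_edges() == 0 and graph.number_of_nodes() == 0:
        raise ValueError("PPI edge list contains no usable edges")
    if n_self or n_dup:
        logger.info(
            "read_ppi_edgelist: dropped %d self-loops, %d duplicate edges", n_self, n_dup
        )
    graph.graph["dropped_self_loops"] = n_self
    graph.graph["dropped_duplicate_edges"] = n_dup
    return graph


def write_ppi_edgelist(network: nx.Graph, target, comment: str | None = None) -> None:
    """Write the network as a two-column TSV; round-trips with the reader."""
    fh, close = (target, False) if hasattr(target, "write") else (
        open(target, "w", encoding="utf-8"),
        True,
    )
    try:
        if comment:
            fh.write(f"# {comment}\n")
        for a, b in sorted(tuple(sorted(e)) for e in network.edges()):
            fh.write(f"{a}\t{b}\n")
    finally:
        if close:
            fh.close()


def split_gene_field(text: str) -> list[str]:
    """Split a catalog-style multi-gene field on commas and on ``" - "``,
    returning the distinct trimmed symbols in order of first appearance."""
    seen: dict[str, None] = {}
    for part in _GENE_FIELD_SPLIT.split(str(text)):
        g = part.strip()
        if g:
            seen.setdefault(g, None)
    return list(seen)


def read_gwas_catalog(source) -> list[GwasLocusRecord]:
    """Read an association table (dialect A): TSV with columns
    ``variant_id``, ``mapped_genes``, ``p_value``."""
    df = pd.read_csv(source, sep="\t", dtype=str, comment="#")
    required = {"variant_id", "mapped_genes", "p_value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        records.append(
            GwasLocusRecord(
                variant_id=str(row.variant_id),
                mapped_genes=split_gene_field(row.mapped_genes),
                p_string=str(row.p_value),
            )
        )
    return records


def read_gene_pvalue_table(source) -> list[GwasLocusRecord]:
    """Read a two-column ``gene``, ``p_value`` TSV (dialect B) as one
    single-gene locus record per row."""
    df = pd.read_csv(source, sep="\t", dtype=str, comment="#")
    if not {"gene", "p_value"} <= set(df.columns):
        raise ValueError("expected columns 'gene' and 'p_value'")
    return [
        GwasLocusRecord(
            variant_id=str(row.gene), mapped_genes=[str(row.gene).strip()], p_string=str(row.p_value)
        )
        for row in df.itertuples(index=False)
    ]


def map_gwas_to_hits(
    records: Sequence[GwasLocusRecord],
    network: nx.Graph,
    log10p_threshold: float = GENOME_WIDE_LOG10P,
) -> GwasHits:
    """Apply the locus-to-gene mapping rules.

    Loci annotated with more than two genes are discarded. Each surviving
    gene receives the minimum p-value over all loci mapping to it. Genes
    absent from the network, and genes whose minimum p exceeds the
    significance threshold, are dropped. All arithmetic is on the log10
    scale; the original p-value string of the winning locus is retained.
    """
    drops: Counter[str] = Counter()
    best: dict[str, tuple[float, str]] = {}
    for rec in records:
        if len(rec.mapped_genes) > 2:
            drops["locus_too_many_genes"] += 1
            continue
        for gene in rec.mapped_genes:
            gene = gene.strip()
            if not gene:
                continue
            cur = best.get(gene)
            if cur is None or rec.log10_p < cur[0]:
                best[gene] = (rec.log10_p, rec.p_string)
    hits = GwasHits()
    for gene in sorted(best):
        logp, pstr = best[gene]
        if gene not in network:
            drops["gene_not_in_network"] += 1
            continue
        if logp > log10p_threshold:
            drops["gene_above_threshold"] += 1
            continue
        hits.logp[gene] = logp
        hits.p_string[gene] = pstr
    hits.drop_counts = dict(drops)
    if drops:
        logger.info("map_gwas_to_hits: drops %s", dict(drops))
    return hits


def largest_connected_component(
    network: nx.Graph, restrict_to: Iterable[str] | None = None
) -> nx.Graph:
    """Induced subgraph on the largest connected component.

    If ``restrict_to`` is given, the component is taken within the subgraph
    induced by those nodes. Size ties are broken by the lexicographically
    smallest member node. An empty node set yields an empty graph.
    """
    sub = network if restrict_to is None else network.subgraph(
        set(restrict_to) & set(network.nodes)
    )
    comps = list(nx.connected_components(sub))
    if not comps:
        return nx.Graph()
    best = min(comps, key=lambda c: (-len(c), min(c)))
    return network.subgraph(best).copy()


def write_hit_table(hits: GwasHits, target) -> None:
    """Write the hit table as TSV with columns gene, p_value, log10_p."""
    hits.to_frame().to_csv(target, sep="\t", index=False)
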