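"""Degree-preserving randomized significance testing.

The observed statistic (LCC size, or persistent-module size for a chosen
dimension) is compared with its distribution over random node sets matched
to the seed genes' degree profile. Degrees are matched by geometric
(base-2) bins — exact-degree matching is infeasible for high-degree hubs —
and sparse bins are merged downward. The z-score is
(observed - mean) / sd with the population standard deviation, and the
empirical p-value is add-one smoothed and right-tailed: modules larger than
chance are the hypothesis.

Random node sets need filtration values to run the persistence pipeline;
by default the observed multiset of log10 p-values is randomly permuted
onto the sampled nodes (preserving the p-value spectrum while randomizing
topology). Alternatively all sampled nodes can enter at the significance
threshold ("threshold" mode).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

from .filtration import build_flag_filtration
from .io import GENOME_WIDE_LOG10P, GwasHits, largest_connected_component
from .modules import persistent_module
from .persistence import compute_persistence

STATISTICS = ("lcc_size", "module_size")


@dataclass
class DegreeBinning:
    """Partition of network nodes into degree bins.

    ``bins`` maps a bin label (its lower degree bound) to a sorted node
    list; every node appears in exactly one bin.
    """

    bins: dict[int, list[str]]
    bin_of: dict[str, int]
    min_bin_size: int


@dataclass
class NullResult:
    statistic: str
    dim: int | None
    observed: float
    samples: list[float]
    mean: float
    sd: float
    z: float | None
    p_empirical: float
    n_reps: int
    seed: int | None

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "dim": self.dim,
            "observed": self.observed,
            "n_reps": self.n_reps,
            "mean": self.mean,
            "sd": self.sd,
            "z": self.z,
            "p_empirical": self.p_empirical,
            "seed": self.seed,
        }


def build_degree_binning(network: nx.Graph, min_bin_size: int = 10) -> DegreeBinning:
    """Geometric base-2 degree bins [1], [2,3], [4,7], ...

    Bins with fewer than ``min_bin_size`` nodes are merged with the next
    lower bin (the lowest bin, if sparse, merges upward), so the result is
    always a partition of all nodes into bins of >= min_bin_size nodes
    whenever the network itself is that large.
    """
    if min_bin_size < 1:
        raise ValueError("min_bin_size must be >= 1")
    if network.number_of_nodes() == 0:
        raise ValueError("empty network")
    raw: dict[int, list[str]] = {}
    for node, deg in network.degree():
        label = 0 if deg == 0 else 2 ** int(math.floor(math.log2(deg)))
        raw.setdefault(label, []).append(node)
    labels = sorted(raw)
    merged: list[tuple[int, list[str]]] = []
    for label in labels:
        merged.append((label, sorted(raw[label])))
    # merge sparse bins into the next lower bin, highest first
    i = len(merged) - 1
    while i > 0:
        if len(merged[i][1]) < min_bin_size:
            lo_label, lo_nodes = merged[i - 1]
            merged[i - 1] = (lo_label, sorted(lo_nodes + merged[i][1]))
            del merged[i]
        i -= 1
    # the lowest bin merges upward if still sparse
    while len(merged) > 1 and len(merged[0][1]) < min_bin_size:
        hi_label, hi_nodes = merged[1]
        merged[1] = (merged[0][0], sorted(merged[0][1] + hi_nodes))
        del merged[0]
    bins = {label: nodes for label, nodes in merged}
    bin_of = {n: label for label, nodes in bins.items() for n in nodes}
    return DegreeBinning(bins=bins, bin_of=bin_of, min_bin_size=min_bin_size)


def sample_matched_nodeset(
    binning: DegreeBinning, seeds: Iterable[str], rng: np.random.Generator
) -> set[str]:
    """Sample, per degree bin, as many nodes (without replacement) as the
    seed set holds in that bin; the result has the seed set's size and
    per-bin degree profile."""
    seeds = set(seeds)
    need: dict[int, int] = {}
    for s in seeds:
        if s not in binning.bin_of:
            raise ValueError(f"seed {s!r} not in the binned network")
        label = binning.bin_of[s]
        need[label] = need.get(label, 0) + 1
    out: set[str] = set()
    for label in sorted(need):
        pool = binning.bins[label]
        k = need[label]
        if k > len(pool):
            raise ValueError(f"bin {label} has {len(pool)} nodes, need {k}")
        idx = rng.choice(len(pool), size=k, replace=False)
        out.update(pool[i] for i in idx)
    return out


def z_score(observed: float, samples: Sequence[float]) -> float:
    """(observed - mean) / population sd of the null samples."""
    if len(samples) < 2:
        raise ValueError("need >= 2 null samples for a z-score")
    arr = np.asarray(samples, dtype=float)
    sd = float(arr.std())  # population sd, matching sigma_rnd
    if sd == 0:
        raise ValueError("degenerate null: sd = 0")
    return float((observed - arr.mean()) / sd)


def empirical_pvalue(observed: float, samples: Sequence[float]) -> float:
    """Add-one smoothed right-tail empirical p:
    (1 + #{samples >= observed}) / (1 + n)."""
    if len(samples) < 1:
        raise ValueError("need >= 1 null sample")
    ge = sum(1 for s in samples if s >= observed)
    return (1 + ge) / (1 + len(samples))


def _statistic_value(
    network: nx.Graph,
    logp: dict[str, float],
    statistic: str,
    dim: int,
) -> float:
    if statistic == "lcc_size":
        lcc = largest_connected_component(network, logp)
        return float(lcc.number_of_nodes())
    if statistic == "module_size":
        maxdim = max(dim + 1, 1)
        stream = build_flag_filtration(network, logp, delta_max=math.inf, maxdim=maxdim)
        diagram = compute_persistence(stream)
        module = persistent_module(diagram, stream, network, logp, dim)
        return float(module.n_nodes)
    raise ValueError(f"unknown statistic {statistic!r}; use one of {STATISTICS}")


def null_distribution(
    network: nx.Graph,
    hits,
    statistic: str = "lcc_size",
    dim: int = 1,
    n_reps: int = 1000,
    rng: np.random.Generator | int | None = None,
    binning: DegreeBinning | None = None,
    min_bin_size: int = 10,
    p_mode: str = "permute",
    p_threshold: float = GENOME_WIDE_LOG10P,
) -> NullResult:
    """Degree-preserving null distribution of a module statistic.

    For each of ``n_reps`` repetitions a node set matched to the hit genes'
    degree profile is drawn, filtration values are assigned per ``p_mode``
    ("permute": observed log10-p multiset randomly permuted onto the
    sampled nodes; "threshold": all at the significance threshold), the
    statistic is recomputed through the full pipeline, and the observed
    value is summarized against the sample with a z-score and an add-one
    right-tail empirical p-value.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if p_mode not in ("permute", "threshold"):
        raise ValueError("p_mode must be 'permute' or 'threshold'")
    if statistic == "module_size" and dim < 0:
        raise ValueError("module statistic needs dim >= 0")
    logp = hits.logp if isinstance(hits, GwasHits) else dict(hits)
    seed = rng if isinstance(rng, int) else None
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    observed = _statistic_value(network, logp, statistic, dim)
    if binning is None:
        binning = build_degree_binning(network, min_bin_size=min_bin_size)
    values = np.array(sorted(logp.values()))
    samples: list[float] = []
    for _ in range(n_reps):
        nodes = sorted(sample_matched_nodeset(binning, logp, gen))
        if p_mode == "permute":
            assigned = dict(zip(nodes, gen.permutation(values)))
        else:
            assigned = {v: p_threshold for v in nodes}
        samples.append(_statistic_value(network, assigned, statistic, dim))
    arr = np.asarray(samples, dtype=float)
    sd = float(arr.std())
    z = None
    if n_reps >= 2 and sd > 0:
        z = float((observed - arr.mean()) / sd)
    return NullResult(
        statistic=statistic,
        dim=dim if statistic == "module_size" else None,
        observed=observed,
        samples=samples,
        mean=float(arr.mean()),
        sd=sd,
        z=z,
        p_empirical=empirical_pvalue(observed, samples),
        n_reps=n_reps,
        seed=seed,
    )
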