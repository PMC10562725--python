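"""Persistent homology over Z/2Z of a simplex stream.

The pairing is computed by standard left-to-right column reduction of the
boundary matrix in filtration order, with sparse columns held as Python sets
(symmetric difference = chain addition over GF(2)). Alongside the reduced
matrix R we carry the basis-change matrix V (R = D V), which yields
representative cycles: a finite pair's representative is the destroyer's
reduced boundary column (a cycle whose maximal simplex is the birth
simplex), and an essential class's representative is the creator's V-column
(a cycle containing the creator simplex).

A dense GF(2) Gaussian-elimination Betti-number oracle is provided as an
independent correctness surface; it never shares code with the reduction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd

from .filtration import FilteredSimplex, SimplexStream

INFINITY: float = math.inf


@dataclass(frozen=True)
class PersistencePair:
    """A birth/death pair with its representative cycle.

    ``death`` is ``math.inf`` for essential classes (holes that persist over
    all thresholds); those have no death simplex. The representative is a
    set of vertex tuples of dimension ``dim`` forming a cycle (empty
    boundary over Z/2Z) whose maximum filtration value equals ``birth``.
    """

    dim: int
    birth: float
    death: float
    birth_simplex: FilteredSimplex
    death_simplex: FilteredSimplex | None
    representative: frozenset[tuple[str, ...]]

    @property
    def essential(self) -> bool:
        return math.isinf(self.death)

    @property
    def persistence(self) -> float:
        return self.death - self.birth


@dataclass
class PersistenceDiagram:
    pairs: list[PersistencePair]
    zero_bars_kept: bool
    value_set: tuple[float, ...]
    maxdim: int

    def in_dim(self, dim: int) -> list[PersistencePair]:
        return [p for p in self.pairs if p.dim == dim]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "dim": [p.dim for p in self.pairs],
                "birth_log10p": [p.birth for p in self.pairs],
                "death_log10p": [
                    "inf" if p.essential else p.death for p in self.pairs
                ],
                "birth_simplex": [";".join(p.birth_simplex.vertices) for p in self.pairs],
                "death_simplex": [
                    ";".join(p.death_simplex.vertices) if p.death_simplex else ""
                    for p in self.pairs
                ],
                "representative": [
                    ";".join("|".join(s) for s in sorted(p.representative))
                    for p in self.pairs
                ],
            }
        )


@dataclass
class BettiCurve:
    """Betti number beta_dim evaluated on a sorted threshold grid.

    A pair contributes at thresholds with birth <= delta < death; essential
    pairs contribute at every delta >= birth.
    """

    dim: int
    thresholds: list[float]
    counts: list[int]


def compute_persistence(
    stream: SimplexStream, keep_zero_bars: bool = False
) -> PersistenceDiagram:
    """Column-reduce the GF(2) boundary matrix of the stream.

    Every simplex is either a creator (births a class of its own dimension)
    or a destroyer (kills a class one dimension down). Pairs are reported
    for dimensions 0..maxdim-1; creators of dimension maxdim are discarded
    because their essentiality cannot be decided without (maxdim+1)-cells.
    Zero-persistence pairs (birth == death, an artifact of vertex-value ties
    along edges) are dropped unless ``keep_zero_bars``.

    Raises
    ------
    ValueError
        If the stream violates face-closure or ordering.
    """
    stream.validate()
    simplices = stream.simplices
    index = stream.index
    n = len(simplices)

    reduced: dict[int, set[int]] = {}  # column -> reduced boundary (R)
    basis: dict[int, set[int]] = {}  # column -> V-column (chain of own dim)
    pivot_of: dict[int, int] = {}  # low index -> column owning it
    pair_of: dict[int, int] = {}  # creator index -> destroyer index

    for j, s in enumerate(simplices):
        if s.dim == 0:
            boundary: set[int] = set()
        else:
            boundary = {index[f] for f in combinations(s.vertices, len(s.vertices) - 1)}
        col = set(boundary)
        v_col = {j}
        while col:
            low = max(col)
            owner = pivot_of.get(low)
            if owner is None:
                break
            col ^= reduced[owner]
            v_col ^= basis[owner]
        if col:
            low = max(col)
            pivot_of[low] = j
            reduced[j] = col
            basis[j] = v_col
            pair_of[low] = j
        else:
            basis[j] = v_col

    pairs: list[PersistencePair] = []
    for i, s in enumerate(simplices):
        if i in reduced:  # destroyer column, not a creator
            continue
        j = pair_of.get(i)
        if j is not None:
            birth, death = s.value, simplices[j].value
            if birth == death and not keep_zero_bars:
                continue
            rep = frozenset(simplices[k].vertices for k in reduced[j])
            pairs.append(
                PersistencePair(
                    dim=s.dim,
                    birth=birth,
                    death=death,
                    birth_simplex=s,
                    death_simplex=simplices[j],
                    representative=rep,
                )
            )
        else:
            if s.dim >= stream.maxdim:
                continue  # essentiality undecidable at this truncation
            rep = frozenset(simplices[k].vertices for k in basis[i])
            pairs.append(
                PersistencePair(
                    dim=s.dim,
                    birth=s.value,
                    death=INFINITY,
                    birth_simplex=s,
                    death_simplex=None,
                    representative=rep,
                )
            )
    pairs.sort(key=lambda p: (p.dim, p.birth, p.death, p.birth_simplex.vertices))
    return PersistenceDiagram(
        pairs=pairs,
        zero_bars_kept=keep_zero_bars,
        value_set=stream.value_set,
        maxdim=stream.maxdim,
    )


def _gf2_rank(mat: np.ndarray) -> int:
    """Rank of a boolean matrix over GF(2) by Gaussian elimination."""
    m = mat.copy()
    rank = 0
    n_rows = m.shape[0]
    for col in range(m.shape[1]):
        sub = np.nonzero(m[rank:, col])[0]
        if sub.size == 0:
            continue
        piv = rank + sub[0]
        if piv != rank:
            m[[rank, piv]] = m[[piv, rank]]
        others = np.nonzero(m[:, col])[0]
        others = others[others != rank]
        if others.size:
            m[others] ^= m[rank]
        rank += 1
        if rank == n_rows:
            break
    return rank


ORACLE_SIMPLEX_GUARD = 5000


def betti_numbers_oracle(stream: SimplexStream, delta: float) -> list[int]:
    """Betti numbers beta_0..beta_{maxdim-1} of the sublevel complex at
    delta, by dense GF(2) rank computation on the boundary matrices.

    Independent of the reduction algorithm; intended for small complexes
    (raises if the prefix exceeds ~5,000 simplices).
    """
    prefix = stream.prefix(delta)
    if len(prefix) > ORACLE_SIMPLEX_GUARD:
        raise ValueError(
            f"prefix has {len(prefix)} simplices (> {ORACLE_SIMPLEX_GUARD}); "
            "use compute_persistence for large complexes"
        )
    by_dim: dict[int, list[tuple[str, ...]]] = {}
    for s in prefix:
        by_dim.setdefault(s.dim, []).append(s.vertices)
    pos: dict[int, dict[tuple[str, ...], int]] = {
        d: {v: i for i, v in enumerate(vs)} for d, vs in by_dim.items()
    }

    def boundary_rank(dim: int) -> int:
        # rank of d_dim : C_dim -> C_{dim-1}
        cols = by_dim.get(dim, [])
        rows = by_dim.get(dim - 1, [])
        if dim == 0 or not cols or not rows:
            return 0
        mat = np.zeros((len(rows), len(cols)), dtype=bool)
        row_pos = pos[dim - 1]
        for jcol, verts in enumerate(cols):
            for face in combinations(verts, len(verts) - 1):
                mat[row_pos[face], jcol] = True
        return _gf2_rank(mat)

    betti = []
    for dim in range(stream.maxdim):
        n_d = len(by_dim.get(dim, []))
        betti.append(n_d - boundary_rank(dim) - boundary_rank(dim + 1))
    return betti


def betti_curve(
    diagram: PersistenceDiagram, dim: int, thresholds: Sequence[float]
) -> BettiCurve:
    """Evaluate beta_dim(delta) on a sorted threshold grid from the diagram."""
    thresholds = list(thresholds)
    if thresholds != sorted(thresholds):
        raise ValueError("thresholds must be sorted")
    pairs = diagram.in_dim(dim)
    counts = [
        sum(1 for p in pairs if p.birth <= t < p.death) for t in thresholds
    ]
    return BettiCurve(dim=dim, thresholds=thresholds, counts=counts)


def essential_classes(diagram: PersistenceDiagram, dim: int) -> list[PersistencePair]:
    """Pairs of the given dimension with infinite death, sorted by birth."""
    out = [p for p in diagram.in_dim(dim) if p.essential]
    out.sort(key=lambda p: (p.birth, p.birth_simplex.vertices))
    return out


def write_diagram(diagram: PersistenceDiagram, target, comment: str | None = None) -> None:
    """Diagram CSV: dim, birth, death ('inf' for essential), simplices,
    representative edges 'A|B' joined by ';'."""
    df = diagram.to_frame()
    if hasattr(target, "write"):
        if comment:
            target.write(f"# {comment}\n")
        df.to_csv(target, index=False)
    else:
        with open(target, "w", encoding="utf-8") as fh:
            if comment:
                fh.write(f"# {comment}\n")
            df.to_csv(fh, index=False)


def write_betti_curves(
    diagram: PersistenceDiagram, target, thresholds: Sequence[float] | None = None,
    comment: str | None = None,
) -> None:
    """Betti-curve CSV over the filtration value set (or a given grid)."""
    grid = sorted(thresholds) if thresholds is not None else list(diagram.value_set)
    data = {"threshold_log10p": grid}
    for dim in range(diagram.maxdim):
        data[f"betti{dim}"] = betti_curve(diagram, dim, grid).counts
    df = pd.DataFrame(data)
    if hasattr(target, "write"):
        if comment:
            target.write(f"# {comment}\n")
        df.to_csv(target, index=False)
    else:
        with open(target, "w", encoding="utf-8") as fh:
            if comment:
                fh.write(f"# {comment}\n")
            df.to_csv(fh, index=False)
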