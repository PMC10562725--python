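"""GF(2) persistence: pairing, representatives, Betti curves, oracle."""

import math
from itertools import combinations

import networkx as nx
import numpy as np
import pytest

from persimod.filtration import FilteredSimplex, SimplexStream, build_flag_filtration
from persimod.persistence import (
    betti_curve,
    betti_numbers_oracle,
    compute_persistence,
    essential_classes,
)


def _random_valued_graph(rng, n, p):
    g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
    g = nx.relabel_nodes(g, {i: f"V{i:02d}" for i in g})
    vals = rng.permutation(np.linspace(-40, -8, len(g)))
    return g, {v: float(x) for v, x in zip(sorted(g.nodes), vals)}


def _boundary_of_chain(chain):
    """Boundary of a set of simplices over Z/2Z (symmetric difference)."""
    out = set()
    for simplex in chain:
        if len(simplex) == 1:
            continue
        for face in combinations(simplex, len(simplex) - 1):
            out ^= {face}
    return out


class TestSmallComplexes:
    def test_c4_one_component_one_loop(self, c4):
        g, hits = c4
        stream = build_flag_filtration(g, hits, delta_max=0, maxdim=2)
        diagram = compute_persistence(stream)
        d0 = essential_classes(diagram, 0)
        d1 = essential_classes(diagram, 1)
        assert len(d0) == 1 and d0[0].birth == min(hits.values())
        assert len(d1) == 1 and d1[0].birth == max(hits.values())
        finite = [p for p in diagram.pairs if not p.essential]
        assert finite == []  # all finite bars here are zero-persistence
        # oracle agrees on circle homology
        assert betti_numbers_oracle(stream, 0.0) == [1, 1]

    def test_filled_triangle_kills_loop(self, triangle):
        g, hits = triangle
        stream = build_flag_filtration(g, hits, delta_max=0, maxdim=2)
        diagram = compute_persistence(stream)
        assert len(essential_classes(diagram, 0)) == 1
        assert essential_classes(diagram, 1) == []
        assert betti_numbers_oracle(stream, 0.0) == [1, 0]

    def test_two_disjoint_edges_two_components(self):
        g = nx.Graph([("A", "B"), ("C", "D")])
        hits = {"A": -12.0, "B": -11.0, "C": -10.0, "D": -9.0}
        stream = build_flag_filtration(g, hits, delta_max=0, maxdim=2)
        diagram = compute_persistence(stream)
        assert len(essential_classes(diagram, 0)) == 2

    def test_bridged_five_cycles_betti(self):
        # two 5-cycles joined by a path: one component, two loops
        g = nx.cycle_graph([f"A{i}" for i in range(5)])
        g.update(nx.cycle_graph([f"B{i}" for i in range(5)]))
        g.add_edge("A0", "B0")
        hits = {v: -20.0 + i for i, v in enumerate(sorted(g.nodes))}
        stream = build_flag_filtration(g, hits, delta_max=0, maxdim=2)
        assert betti_numbers_oracle(stream, 0.0) == [1, 2]
        diagram = compute_persistence(stream)
        assert len(essential_classes(diagram, 0)) == 1
        assert len(essential_classes(diagram, 1)) == 2

    def test_zero_bars_kept_on_request(self, c4):
        g, hits = c4
        stream = build_flag_filtration(g, hits, delta_max=0, maxdim=2)
        diagram = compute_persistence(stream, keep_zero_bars=True)
        d0 = diagram.in_dim(0)
        assert len(d0) == 4  # one bar per vertex when zero bars kept
        assert sum(1 for p in d0 if p.essential) == 1

    def test_face_closure_violation_raises(self):
        stream = SimplexStream(
            simplices=[
                FilteredSimplex(("A",), -10.0),
                FilteredSimplex(("A", "B"), -9.0),  # vertex B missing
            ],
            maxdim=1,
            value_set=(-10.0, -9.0),
        )
        with pytest.raises(ValueError):
            compute_persistence(stream)


class TestRepresentatives:
    @pytest.mark.parametrize("trial", range(8))
    def test_representatives_are_cycles_born_at_birth(self, trial):
        rng = np.random.default_rng(200 + trial)
        g, hits = _random_valued_graph(rng, 12, 0.35)
        stream = build_flag_filtration(g, hits, delta_max=0, maxdim=3)
        diagram = compute_persistence(stream)
        for pair in diagram.pairs:
            assert pair.representative, "representative must be nonempty"
            assert all(len(s) == pair.dim + 1 for s in pair.representative)
            assert _boundary_of_chain(pair.representative) == set()
            vals = {stream.index[s] for s in pair.representative}
            max_val = max(stream.simplices[i].value for i in vals)
            assert max_val == pair.birth

    def test_c4_representative_is_the_square(self, c4):
        g, hits = c4
        stream = build_flag_filtration(g, hits, delta_max=0, maxdim=2)
        diagram = compute_persistence(stream)
        (loop,) = essential_classes(diagram, 1)
        assert loop.representative == frozenset(
            {("A", "B"), ("B", "C"), ("C", "D"), ("A", "D")}
        )


class TestOracleEquivalence:
    """Persistence-derived Betti curves must match the independent dense
    GF(2) rank oracle at every filtration value."""

    @pytest.mark.parametrize("trial", range(25))
    def test_random_graphs(self, trial):
        rng = np.random.default_rng(300 + trial)
        n = int(rng.integers(5, 15))
        p = 0.2 + 0.3 * float(rng.random())
        g, hits = _random_valued_graph(rng, n, p)
        stream = build_flag_filtration(g, hits, delta_max=0, maxdim=3)
        if len(stream) == 0:
            return
        diagram = compute_persistence(stream)
        for delta in stream.value_set:
            expected = betti_numbers_oracle(stream, delta)
            got = [betti_curve(diagram, d, [delta]).counts[0] for d in range(3)]
            assert got == expected

    def test_oracle_guard(self):
        g = nx.complete_graph([f"V{i:03d}" for i in range(30)])
        hits = {v: -10.0 - i for i, v in enumerate(sorted(g.nodes))}
        stream = build_flag_filtration(g, hits, delta_max=0, maxdim=3)
        # K30 truncated at dim 3 has C(30,1)+...+C(30,4) > 5000 simplices
        with pytest.raises(ValueError, match="compute_persistence"):
            betti_numbers_oracle(stream, 0.0)


class TestStructuralInvariants:
    @pytest.mark.parametrize("trial", range(8))
    def test_euler_characteristic(self, trial):
        rng = np.random.default_rng(400 + trial)
        g, hits = _random_valued_graph(rng, 11, 0.3)
        if max((len(c) for c in nx.find_cliques(g)), default=0) > 4:
            return  # clique number exceeds maxdim + 1: truncation breaks Euler
        stream = build_flag_filtration(g, hits, delta_max=0, maxdim=3)
        if len(stream) == 0:
            return
        diagram = compute_persistence(stream)
        for delta in stream.value_set:
            prefix = stream.prefix(delta)
            chi_simplices = sum((-1) ** s.dim for s in prefix)
            chi_betti = sum(
                (-1) ** d * betti_curve(diagram, d, [delta]).counts[0]
                for d in range(3)
            )
            assert chi_simplices == chi_betti

    @pytest.mark.parametrize("trial", range(8))
    def test_dim0_essentials_equal_components(self, trial):
        rng = np.random.default_rng(500 + trial)
        g, hits = _random_valued_graph(rng, 13, 0.18)
        stream = build_flag_filtration(g, hits, delta_max=0, maxdim=2)
        if len(stream) == 0:
            return
        diagram = compute_persistence(stream)
        assert len(essential_classes(diagram, 0)) == nx.number_connected_components(g)

    @pytest.mark.parametrize("trial", range(8))
    def test_monotone_transform_invariance(self, trial):
        """A strictly increasing rescaling of the vertex values (the raw-p
        vs log-p robustness check) must leave pairings and essential counts
        unchanged."""
        rng = np.random.default_rng(600 + trial)
        g, hits = _random_valued_graph(rng, 12, 0.35)
        transformed = {v: math.exp(x / 10.0) - 5.0 for v, x in hits.items()}
        d1 = compute_persistence(build_flag_filtration(g, hits, 0, maxdim=3))
        d2 = compute_persistence(build_flag_filtration(g, transformed, 10.0, maxdim=3))
        key = lambda d: sorted(
            (p.dim, p.birth_simplex.vertices,
             p.death_simplex.vertices if p.death_simplex else None)
            for p in d.pairs
        )
        assert key(d1) == key(d2)
        for dim in range(3):
            assert len(essential_classes(d1, dim)) == len(essential_classes(d2, dim))

    def test_finite_values_in_value_set(self, c4):
        g, hits = c4
        stream = build_flag_filtration(g, hits, delta_max=0, maxdim=2)
        diagram = compute_persistence(stream, keep_zero_bars=True)
        for p in diagram.pairs:
            assert p.birth in stream.value_set
            if not p.essential:
                assert p.death in stream.value_set


class TestBettiCurve:
    def test_half_open_convention(self):
        # two early components merged by a late connector: a positive
        # finite dim-0 bar (-11, -8), counted for birth <= delta < death
        g = nx.Graph([("A", "C"), ("B", "C")])
        hits = {"A": -12.0, "B": -11.0, "C": -8.0}
        stream = build_flag_filtration(g, hits, delta_max=0, maxdim=2)
        diagram = compute_persistence(stream)
        finite = [p for p in diagram.in_dim(0) if not p.essential]
        assert [(p.birth, p.death) for p in finite] == [(-11.0, -8.0)]
        curve = betti_curve(diagram, 0, [-12.0, -11.0, -8.0])
        assert curve.counts == [1, 2, 1]

    def test_essential_counts_forever(self, c4):
        g, hits = c4
        stream = build_flag_filtration(g, hits, delta_max=0, maxdim=2)
        diagram = compute_persistence(stream)
        curve = betti_curve(diagram, 1, [-10.0, -8.5, 0.0])
        assert curve.counts == [0, 1, 1]

    def test_empty_diagram_zero(self):
        from persimod.persistence import PersistenceDiagram

        diagram = PersistenceDiagram(pairs=[], zero_bars_kept=False, value_set=(), maxdim=2)
        assert betti_curve(diagram, 0, [-1.0, 0.0]).counts == [0, 0]

    def test_unsorted_thresholds_rejected(self, c4):
        g, hits = c4
        stream = build_flag_filtration(g, hits, delta_max=0, maxdim=2)
        diagram = compute_persistence(stream)
        with pytest.raises(ValueError):
            betti_curve(diagram, 0, [0.0, -1.0])
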