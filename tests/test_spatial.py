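"""Local areas, edge-to-node ratios, expansion and group comparison."""

import dataclasses
import itertools

import networkx as nx
import numpy as np
import pytest
from shapely.geometry import Polygon, box

from famnet.genotypes import Individual, consolidate_individuals
from famnet.parentage import (ParentageConfig, assign_parentage,
                              reconstruct_unsampled_parents)
from famnet.pednet import build_network
from famnet.centrality import centrality_table
from famnet.simulate import (AreaCluster, SimulationConfig,
                             apply_sampling_and_error,
                             draw_allele_frequencies, simulate_population)
from famnet.spatial import (LocalArea, area_report, assign_local_areas,
                            compare_area_groups, edge_to_node_ratio,
                            first_neighbor_expansion)


def ind(iid, x=None, y=None, sampled=True, sex="F"):
    return Individual(iid, {"L01": (1, 1)}, sex, sampled=sampled, x=x, y=y)


SQUARE = LocalArea("sq", geometry=box(0, 0, 10, 10))


class TestAssignment:
    def test_point_inside_is_assigned(self):
        assert assign_local_areas([ind("a", 5, 5)], [SQUARE]) == {"a": "sq"}

    def test_boundary_is_inclusive(self):
        assert assign_local_areas([ind("a", 0, 5)], [SQUARE]) == {"a": "sq"}

    def test_point_outside_unassigned(self):
        assert assign_local_areas([ind("a", 20, 5)], [SQUARE]) == {}

    def test_inferred_without_coordinates_unassigned(self):
        ghost = ind("g", sampled=False)
        assert assign_local_areas([ghost], [SQUARE]) == {}

    def test_overlapping_polygons_raise(self):
        other = LocalArea("ov", geometry=box(5, 5, 15, 15))
        with pytest.raises(ValueError, match="multiple areas"):
            assign_local_areas([ind("a", 7, 7)], [SQUARE, other])

    def test_explicit_member_lists(self):
        area = LocalArea("m", members=["a", "b"])
        got = assign_local_areas([ind("a"), ind("b"), ind("c")], [area])
        assert got == {"a": "m", "b": "m"}


class TestRatio:
    def _net(self, edges, nodes):
        g = nx.DiGraph()
        g.add_nodes_from(nodes)
        g.add_edges_from(edges)
        return g

    def test_no_internal_edges_gives_zero(self):
        g = self._net([("X", "Y")], ["A", "B", "X", "Y"])
        member = {"A": "z", "B": "z"}
        assert edge_to_node_ratio(g, member, "z") == 0.0

    def test_direct_count_example(self):
        g = self._net([("A", "B"), ("A", "C")], ["A", "B", "C"])
        member = {"A": "z", "B": "z", "C": "z"}
        assert edge_to_node_ratio(g, member, "z") == pytest.approx(2 / 3)

    def test_empty_area_flagged_nan(self):
        g = self._net([], ["A"])
        with pytest.warns(UserWarning, match="undefined"):
            assert np.isnan(edge_to_node_ratio(g, {}, "nowhere"))

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(37)
        for _ in range(20):
            nodes = [f"n{i}" for i in range(12)]
            edges = [(a, b) for a, b in
                     itertools.permutations(nodes, 2) if rng.random() < 0.1]
            g = self._net(edges, nodes)
            members = {v: "z" for v in nodes if rng.random() < 0.5}
            if not members:
                continue
            brute = sum(1 for a, b in edges if a in members and b in members)
            got = edge_to_node_ratio(g, members, "z")
            assert got == pytest.approx(brute / len(members))
            assert got <= 2.0 + 1e-12


class TestExpansion:
    def test_isolated_members_expand_to_nothing(self):
        g = nx.DiGraph()
        g.add_nodes_from(["A", "B"])
        rep = first_neighbor_expansion(g, {"A": "z", "B": "z"}, "z")
        assert rep.expanded_nodes == 2
        assert rep.expanded_edges == 0
        assert rep.pct_members_in_largest_cluster == 50.0

    def test_dam_with_three_outside_offspring(self):
        g = nx.DiGraph([("D", "o1"), ("D", "o2"), ("D", "o3")])
        rep = first_neighbor_expansion(g, {"D": "z"}, "z")
        assert rep.expanded_nodes == 4
        assert rep.expanded_edges == 3
        assert rep.pct_members_in_largest_cluster == 100.0

    def test_matches_brute_force_subgraph_extraction(self):
        rng = np.random.default_rng(41)
        for _ in range(20):
            nodes = [f"n{i}" for i in range(12)]
            edges = [(a, b) for a, b in
                     itertools.permutations(nodes, 2) if rng.random() < 0.08]
            g = nx.DiGraph()
            g.add_nodes_from(nodes)
            g.add_edges_from(edges)
            members = {v for v in nodes if rng.random() < 0.4} or {nodes[0]}
            rep = first_neighbor_expansion(
                g, {m: "z" for m in members}, "z")
            expanded = set(members)
            for a, b in edges:
                if a in members:
                    expanded.add(b)
                if b in members:
                    expanded.add(a)
            internal = [(a, b) for a, b in edges
                        if a in expanded and b in expanded]
            assert rep.expanded_nodes == len(expanded)
            assert rep.expanded_edges == len(internal)

    def test_expansion_idempotent_on_internal_edges(self):
        g = nx.DiGraph([("D", "o1"), ("o1", "o2"), ("X", "Y")])
        first = first_neighbor_expansion(g, {"D": "z", "o1": "z"}, "z")
        again = first_neighbor_expansion(
            g, {"D": "z", "o1": "z", "o2": "z"}, "z")
        assert again.expanded_nodes == first.expanded_nodes
        assert again.expanded_edges == first.expanded_edges


class TestGroupComparison:
    def _setup(self, seed=0, n_areas=6):
        rng = np.random.default_rng(seed)
        g = nx.DiGraph()
        membership = {}
        for a in range(n_areas):
            nodes = [f"a{a}n{i}" for i in range(6)]
            g.add_nodes_from(nodes)
            for i in range(a):           # more internal edges in later areas
                g.add_edge(nodes[i % 6], nodes[(i + 1) % 6])
            membership.update({v: f"area{a}" for v in nodes})
        table = centrality_table(g)
        return g, membership, table

    def test_high_and_low_groups_labelled(self):
        g, membership, table = self._setup()
        reports = area_report(g, membership)
        comp = compare_area_groups(table, membership, reports, k=2)
        assert len(comp.high_areas) == len(comp.low_areas) == 2
        assert set(comp.high_areas).isdisjoint(comp.low_areas)
        ratios = reports.table.set_index("area_id")["ratio"]
        assert min(ratios[comp.high_areas]) >= max(ratios[comp.low_areas])

    def test_identical_distributions_give_zero_difference(self):
        g, membership, table = self._setup()
        flat = table.copy()
        for c in flat.columns:
            flat[c] = 1.0 * np.arange(len(flat)) % 3
        reports = area_report(g, membership)
        comp = compare_area_groups(flat, membership, reports, k=2)
        s = comp.group_summaries.set_index(["group", "measure"])
        # same per-area layout of values -> equal group means
        for m in ("alpha",):
            assert s.loc[("high", m), "mean"] == pytest.approx(
                s.loc[("low", m), "mean"], abs=0.5)

    def test_constant_measure_has_undefined_correlation(self):
        g, membership, table = self._setup()
        table = table.copy()
        table["alpha"] = 1.0
        reports = area_report(g, membership)
        with pytest.warns(UserWarning, match="undefined"):
            comp = compare_area_groups(table, membership, reports, k=2)
        assert "alpha" in comp.undefined_correlations
        assert np.isnan(comp.correlations["alpha"])


def philopatry_scenario(seed):
    """Two philopatric and two dispersing clusters, full error-free
    sampling.  Dispersal scales (30/50 map units at philopatry 0.1) exceed
    the 20 x 20 area boxes, so dispersing offspring genuinely leave their
    natal area, while philopatric offspring (effective scale 3/5) stay."""
    layout = (
        AreaCluster("phil_a", (25.0, 85.0), 4.0, philopatry=0.9),
        AreaCluster("phil_b", (85.0, 85.0), 4.0, philopatry=0.9),
        AreaCluster("disp_a", (25.0, 25.0), 4.0, philopatry=0.1),
        AreaCluster("disp_b", (85.0, 25.0), 4.0, philopatry=0.1),
    )
    cfg = SimulationConfig(
        n_founders=64, n_generations=3, seed=seed, area_layout=layout,
        sampling_fraction=1.0, dropout_rate=0.0, false_allele_rate=0.0,
        locus_failure_rate=0.0, replicate_fraction=0.0)
    freqs = draw_allele_frequencies(cfg.n_loci, cfg.alleles_per_locus,
                                    seed + 2000)
    pop = simulate_population(cfg, freqs)
    samples = apply_sampling_and_error(pop, cfg, freqs)
    res = consolidate_individuals(samples)
    ped = assign_parentage(res.individuals, freqs,
                           ParentageConfig(error_rate=0.0))
    ped = reconstruct_unsampled_parents(ped, res.individuals, freqs)
    g = build_network(ped, res.individuals)
    areas = [LocalArea(c.label, geometry=box(c.center[0] - 10,
                                             c.center[1] - 10,
                                             c.center[0] + 10,
                                             c.center[1] + 10))
             for c in layout]
    membership = assign_local_areas(res.individuals, areas)
    return g, membership, res


def test_philopatric_areas_have_higher_ratios_majority_of_seeds():
    """Simulation oracle: offspring settling near the dam keeps family
    edges inside the area, so philopatric clusters must out-score
    dispersing clusters in edge-to-node ratio for a majority of seeds, and
    the area-level ratio-eccentricity relationship is negative in the
    majority (cohesive family areas sit nearer the network core)."""
    wins = 0
    ecc_negative = 0
    for seed in range(20):
        g, membership, res = philopatry_scenario(seed)
        reports = area_report(g, membership)
        t = reports.table.set_index("area_id")
        phil = t.loc[[a for a in t.index if a.startswith("phil")], "ratio"]
        disp = t.loc[[a for a in t.index if a.startswith("disp")], "ratio"]
        if len(phil) and len(disp) and phil.mean() > disp.mean():
            wins += 1
        # node centralities over the primary (largest) component, where
        # eccentricity meaningfully ranks core vs peripheral positions
        main = max(nx.weakly_connected_components(g), key=len)
        table = centrality_table(g.subgraph(main))
        comp = compare_area_groups(table, membership, reports, k=2)
        r = comp.correlations.get("eccentricity")
        if r is not None and r == r and r < 0:
            ecc_negative += 1
    assert wins > 10
    assert ecc_negative > 10
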