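"""The directed familial network.

Nodes are individuals (sampled, or inferred unsampled parents); edges run
from parent to offspring, two per pedigree row.  Sampled individuals
therefore always have in-degree 2 and inferred individuals in-degree 0 —
parents of inferred individuals cannot themselves be inferred.  The
network is unweighted and acyclic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import networkx as nx

from .genotypes import Individual
from .parentage import PedigreeTable

__all__ = [
    "build_network",
    "connected_components",
    "validate_familial_invariants",
    "ComponentReport",
    "write_graphml",
    "write_edge_list_csv",
    "write_node_table_csv",
]


def build_network(pedigree: PedigreeTable,
                  individuals: Sequence[Individual]) -> nx.DiGraph:
    """Build the parent->offspring graph from a pedigree table.

    The node set is all supplied (sampled) individuals plus every parent id
    appearing in the table; each pedigree row contributes its dam and sire
    edge.  Node attributes: ``sampled`` flag, ``sex``, and for sampled
    nodes ``x``/``y`` coordinates and local-area label when known.  A cycle
    is a contract violation and raises with the offending cycle named.
    """
    g = nx.DiGraph()
    for ind in individuals:
        g.add_node(ind.individual_id, sampled=True, sex=ind.sex,
                   x=ind.x, y=ind.y, area=ind.area)
    for _, row in pedigree.df.iterrows():
        for slot in ("dam", "sire"):
            pid = row[f"{slot}_id"]
            if pid not in g:
                sex = pedigree.inferred_sex.get(
                    pid, "F" if slot == "dam" else "M")
                g.add_node(pid, sampled=bool(row[f"{slot}_sampled"]), sex=sex,
                           x=None, y=None, area=None)
            if pid == row["offspring_id"]:
                raise ValueError(f"self-parentage at {pid}")
            g.add_edge(pid, row["offspring_id"])
    if not nx.is_directed_acyclic_graph(g):
        cycle = nx.find_cycle(g)
        raise ValueError(f"familial network contains a cycle: {cycle}")
    return g


def validate_familial_invariants(g: nx.DiGraph) -> None:
    """Assert the structural contract of a full-assignment network:
    sampled in-degree exactly 2, inferred in-degree 0, and each node's
    in-edges from one female and one male."""
    for node, data in g.nodes(data=True):
        indeg = g.in_degree(node)
        if data.get("sampled") and indeg != 2:
            raise AssertionError(f"sampled node {node} has in-degree {indeg}")
        if not data.get("sampled") and indeg != 0:
            raise AssertionError(f"inferred node {node} has in-degree {indeg}")
        sexes = sorted(g.nodes[p].get("sex") for p in g.predecessors(node))
        if indeg == 2 and sexes != ["F", "M"]:
            raise AssertionError(f"node {node} parents are not one F + one M")


@dataclass
class ComponentReport:
    """Weakly connected component structure of the familial network."""

    n_components: int
    sizes: list[int]                # descending
    largest_share_pct: float | None  # largest/total x 100, 1 decimal

    @classmethod
    def from_sizes(cls, sizes: Sequence[int]) -> "ComponentReport":
        sizes = sorted((int(s) for s in sizes), reverse=True)
        total = sum(sizes)
        share = round(sizes[0] / total * 100.0, 1) if total else None
        return cls(n_components=len(sizes), sizes=list(sizes),
                   largest_share_pct=share)

    @property
    def total_nodes(self) -> int:
        return sum(self.sizes)


def connected_components(g: nx.DiGraph) -> ComponentReport:
    """Component structure under weak connectivity (direction ignored)."""
    if g.number_of_nodes() == 0:
        return ComponentReport(0, [], None)
    sizes = [len(c) for c in nx.weakly_connected_components(g)]
    return ComponentReport.from_sizes(sizes)


# ---------------------------------------------------------------------------
# exports
# ---------------------------------------------------------------------------

def write_graphml(g: nx.DiGraph, path) -> None:
    h = g.copy()
    for _, data in h.nodes(data=True):  # GraphML cannot carry None values
        for k in [k for k, v in data.items() if v is None]:
            del data[k]
    nx.write_graphml(h, path)


def write_edge_list_csv(g: nx.DiGraph, path) -> None:
    import csv

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["parent_id", "offspring_id"])
        for u, v in sorted(g.edges()):
            w.writerow([u, v])


def write_node_table_csv(g: nx.DiGraph, path) -> None:
    import csv

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["node_id", "sampled", "sex", "x", "y", "area"])
        for node in sorted(g.nodes):
            d = g.nodes[node]
            w.writerow([node, int(bool(d.get("sampled"))), d.get("sex", ""),
                        "" if d.get("x") is None else repr(d["x"]),
                        "" if d.get("y") is None else repr(d["y"]),
                        d.get("area") or ""])
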