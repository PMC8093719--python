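"""Spatial application: local areas, edge-to-node ratios and group
comparisons.

A local area is a labelled polygon (or explicit member list) holding the
sampled individuals located inside it; inferred individuals have no
coordinates and never belong to an area.  The cohesion index of an area is
its edge-to-node ratio: parent-offspring edges internal to the area divided
by member count.  Because every sampled node has in-degree at most 2 and
internal edges must end on a member, the ratio is bounded by 2.  First-
neighbor expansion pulls in everything one edge away (capturing inferred
parents) and reports how much of the area coheres into one cluster; the
high-ratio and low-ratio areas are then compared on their members'
centrality profiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from shapely.geometry import Point, shape
from shapely.geometry.base import BaseGeometry

from .genotypes import Individual

__all__ = [
    "LocalArea",
    "AreaReport",
    "GroupComparison",
    "read_geojson_areas",
    "assign_local_areas",
    "edge_to_node_ratio",
    "first_neighbor_expansion",
    "area_report",
    "compare_area_groups",
]


@dataclass
class LocalArea:
    """A local area: polygon geometry or an explicit member list."""

    area_id: str
    geometry: BaseGeometry | None = None
    members: list[str] | None = None

    def __post_init__(self) -> None:
        if (self.geometry is None) == (self.members is None):
            raise ValueError(
                f"area {self.area_id}: exactly one of geometry or members")
        if self.geometry is not None and self.geometry.is_empty:
            raise ValueError(f"area {self.area_id}: degenerate geometry")


def read_geojson_areas(path, id_property: str = "area_id") -> list[LocalArea]:
    """Read local-area polygons from a GeoJSON FeatureCollection; the area
    label comes from ``id_property`` (falling back to the feature id)."""
    import json

    with open(path) as fh:
        doc = json.load(fh)
    areas = []
    for k, feature in enumerate(doc.get("features", [])):
        label = (feature.get("properties", {}).get(id_property)
                 or feature.get("id") or f"area{k + 1}")
        areas.append(LocalArea(area_id=str(label),
                               geometry=shape(feature["geometry"])))
    return areas


# ---------------------------------------------------------------------------
# membership
# ---------------------------------------------------------------------------

def assign_local_areas(individuals: Sequence[Individual],
                       areas: Sequence[LocalArea]) -> dict[str, str]:
    """Assign sampled individuals to local areas.

    Polygon areas use boundary-inclusive point-in-polygon containment;
    explicit member lists are taken as-is.  Inferred individuals (no
    coordinates) and individuals outside every polygon stay unassigned.  A
    point claimed by two areas is a conflict and raises with the conflicts
    listed.
    """
    membership: dict[str, str] = {}
    conflicts: list[tuple[str, str, str]] = []
    explicit = {m: a.area_id for a in areas if a.members is not None
                for m in a.members}
    polys = [a for a in areas if a.geometry is not None]
    for ind in individuals:
        claims = []
        if ind.individual_id in explicit:
            claims.append(explicit[ind.individual_id])
        if (ind.sampled and ind.x is not None and ind.y is not None
                and np.isfinite(ind.x) and np.isfinite(ind.y)):
            pt = Point(ind.x, ind.y)
            claims += [a.area_id for a in polys if a.geometry.covers(pt)]
        claims = sorted(set(claims))
        if len(claims) > 1:
            conflicts.append((ind.individual_id, claims[0], claims[1]))
        elif claims:
            membership[ind.individual_id] = claims[0]
    if conflicts:
        raise ValueError(f"individuals claimed by multiple areas: {conflicts}")
    return membership


# ---------------------------------------------------------------------------
# edge-to-node ratio and first-neighbor expansion
# ---------------------------------------------------------------------------

def _area_members(membership: Mapping[str, str], area_id: str) -> set[str]:
    return {i for i, a in membership.items() if a == area_id}


def edge_to_node_ratio(network: nx.DiGraph, membership: Mapping[str, str],
                       area_id: str) -> float:
    """Internal parent-offspring edges of the area divided by its member
    count; the familial-cohesion index.  Bounded above by 2 (each internal
    edge is an in-edge of a member, and in-degree is at most 2).  An empty
    area is undefined: returns NaN with a warning."""
    members = _area_members(membership, area_id)
    if not members:
        warnings.warn(f"area {area_id} has no members; ratio undefined",
                      stacklevel=2)
        return float("nan")
    internal = sum(1 for u, v in network.edges()
                   if u in members and v in members)
    ratio = internal / len(members)
    assert ratio <= 2.0 + 1e-12, f"edge-to-node ratio {ratio} exceeds bound 2"
    return ratio


@dataclass
class ExpansionReport:
    area_id: str
    n_members: int
    expanded_nodes: int
    expanded_edges: int
    expanded_ratio: float
    pct_members_in_largest_cluster: float


def first_neighbor_expansion(network: nx.DiGraph,
                             membership: Mapping[str, str],
                             area_id: str) -> ExpansionReport:
    """Expand the area by its first neighbors (all in- and out-neighbors,
    which is how coordinate-less inferred parents enter) and report the
    expanded edge-to-node ratio plus the share of the area's own members
    that fall in the largest weak component of the expanded subnetwork."""
    members = _area_members(membership, area_id)
    if not members:
        raise ValueError(f"area {area_id} has no members")
    present = {m for m in members if m in network}
    expanded = set(present)
    for m in present:
        expanded |= set(network.predecessors(m))
        expanded |= set(network.successors(m))
    sub = network.subgraph(expanded)
    n_edges = sub.number_of_edges()
    comps = list(nx.weakly_connected_components(sub)) if expanded else []
    in_largest = 0
    if comps:
        largest = max(comps, key=lambda c: (len(c), sorted(c)[0]))
        in_largest = len(members & largest)
    return ExpansionReport(
        area_id=area_id,
        n_members=len(members),
        expanded_nodes=len(expanded),
        expanded_edges=n_edges,
        expanded_ratio=n_edges / len(expanded) if expanded else float("nan"),
        pct_members_in_largest_cluster=round(
            in_largest / len(members) * 100.0, 1),
    )


@dataclass
class AreaReport:
    """Per-area cohesion summary across all local areas."""

    table: pd.DataFrame   # area_id, n, internal_edges, ratio, expanded_*, group

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def area_report(network: nx.DiGraph,
                membership: Mapping[str, str]) -> AreaReport:
    """Edge-to-node ratio and first-neighbor expansion for every area with
    at least one member; ratios reported to 2 decimals alongside the raw
    values."""
    rows = []
    for area_id in sorted(set(membership.values())):
        members = _area_members(membership, area_id)
        ratio = edge_to_node_ratio(network, membership, area_id)
        exp = first_neighbor_expansion(network, membership, area_id)
        rows.append({
            "area_id": area_id,
            "n": len(members),
            "internal_edges": int(round(ratio * len(members))),
            "ratio": round(ratio, 2),
            "expanded_nodes": exp.expanded_nodes,
            "expanded_edges": exp.expanded_edges,
            "expanded_ratio": round(exp.expanded_ratio, 2),
            "pct_in_largest_cluster": exp.pct_members_in_largest_cluster,
            "group": "none",
        })
    return AreaReport(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# high/low group comparison
# ---------------------------------------------------------------------------

@dataclass
class GroupComparison:
    """High- vs low-ratio area groups and ratio-centrality relationships."""

    high_areas: list[str]
    low_areas: list[str]
    group_summaries: pd.DataFrame     # group x measure distribution stats
    correlations: dict[str, float]    # measure -> Pearson r (area ratio vs area mean)
    undefined_correlations: list[str] = field(default_factory=list)


def compare_area_groups(centralities: pd.DataFrame,
                        membership: Mapping[str, str],
                        reports: AreaReport,
                        k: int = 4,
                        measures: Sequence[str] | None = None
                        ) -> GroupComparison:
    """Label the k highest- and k lowest-ratio areas and compare them.

    For each centrality measure, reports mean/median/quartiles over the
    member nodes of each group, and the Pearson correlation between area
    edge-to-node ratio and the area mean of the measure across all areas.
    No hypothesis tests — descriptive contrasts only.  Constant ratios (or
    a measure constant across areas) leave the correlation undefined
    (NaN), flagged in ``undefined_correlations``.
    """
    from scipy.stats import pearsonr

    table = reports.table
    if len(table) < 2 * k:
        raise ValueError(f"need >= {2 * k} areas for k={k} per group, "
                         f"have {len(table)}")
    if measures is None:
        measures = [c for c in centralities.columns
                    if c not in ("in_degree", "out_degree")]

    ranked = table.sort_values(["ratio", "area_id"],
                               ascending=[False, True])["area_id"]
    high = sorted(ranked.head(k))
    low = sorted(ranked.tail(k))
    table.loc[table["area_id"].isin(high), "group"] = "high"
    table.loc[table["area_id"].isin(low), "group"] = "low"

    rows = []
    for group, areas in (("high", high), ("low", low)):
        nodes = [i for i, a in membership.items()
                 if a in areas and i in centralities.index]
        sub = centralities.loc[nodes, list(measures)]
        for m in measures:
            vals = sub[m].astype(float)
            rows.append({
                "group": group, "measure": m, "n_nodes": len(vals),
                "mean": vals.mean(), "median": vals.median(),
                "q1": vals.quantile(0.25), "q3": vals.quantile(0.75),
            })
    summaries = pd.DataFrame(rows)

    # ratio vs area-mean correlations over all areas
    area_means = {}
    for area_id in table["area_id"]:
        nodes = [i for i, a in membership.items()
                 if a == area_id and i in centralities.index]
        area_means[area_id] = centralities.loc[nodes, list(measures)].mean()
    means = pd.DataFrame(area_means).T.loc[table["area_id"]]
    ratios = table.set_index("area_id")["ratio"].astype(float)

    corr: dict[str, float] = {}
    undefined: list[str] = []
    for m in measures:
        x, y = ratios.to_numpy(), means[m].to_numpy(dtype=float)
        ok = np.isfinite(x) & np.isfinite(y)
        if ok.sum() < 3 or np.std(x[ok]) == 0 or np.std(y[ok]) == 0:
            corr[m] = float("nan")
            undefined.append(m)
            warnings.warn(f"ratio-{m} correlation undefined "
                          "(constant or insufficient values)", stacklevel=2)
            continue
        corr[m] = float(pearsonr(x[ok], y[ok]).statistic)
    return GroupComparison(high_areas=high, low_areas=low,
                           group_summaries=summaries, correlations=corr,
                           undefined_correlations=undefined)
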