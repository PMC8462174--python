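"""Directed multifunctionality network assembled from DistLM results.

Sources (trait clusters, environmental characteristics) point at the
ecosystem functions they help explain; each edge carries the summed
sequential R^2 of that predictor for that function, and node size is the
number of links (out-degree for sources, in-degree for functions).  By
construction the network is bipartite: no source-source or
function-function edges exist.
"""

from __future__ import annotations

from typing import Mapping

import networkx as nx
import pandas as pd

from .distlm import DistLMReport
from .tables import ValidationError

ROLE_OF_STAGE = {"traits": "cluster", "environment": "environment"}


def assemble(report: DistLMReport, aliases: Mapping[str, str] | None = None) -> nx.DiGraph:
    """Build the directed source -> function network from a report.

    One edge per (base predictor, function) with positive summed
    sequential R^2; functions with no retained predictor remain as
    isolated nodes of size 0.  ``aliases`` relabels predictor nodes
    (e.g. ``c1`` -> ``small mobile top 2 cm dwellers``).
    """
    aliases = dict(aliases or {})
    known = {s.column.base_variable for r in report.results.values() for s in r.steps}
    known |= set(report.results)
    unknown = set(aliases) - known
    if unknown:
        raise ValidationError(f"alias references unknown node(s): {sorted(unknown)}")
    net = nx.DiGraph()
    for fname in report.results:
        net.add_node(fname, role="function")
    for fname, res in report.results.items():
        weights: dict[str, float] = {}
        roles: dict[str, str] = {}
        for s in res.steps:
            base = aliases.get(s.column.base_variable, s.column.base_variable)
            weights[base] = weights.get(base, 0.0) + s.delta_r2
            roles[base] = ROLE_OF_STAGE[s.stage]
        for base, w in weights.items():
            if w <= 0:
                continue
            if base not in net:
                net.add_node(base, role=roles[base])
            net.add_edge(base, fname, weight=float(w))
    for node in net.nodes:
        role = net.nodes[node]["role"]
        net.nodes[node]["size"] = float(
            net.in_degree(node) if role == "function" else net.out_degree(node)
        )
    return net


def connectivity_summary(net: nx.DiGraph) -> pd.DataFrame:
    """Per-node connection counts and summed incident variance explained.

    Sorted by degree descending, then node name; for a function node the
    weight sum equals that function's total R^2 (row C of the report).
    """
    rows = []
    for node in net.nodes:
        role = net.nodes[node]["role"]
        if role == "function":
            degree = net.in_degree(node)
            weight = sum(d["weight"] for _, _, d in net.in_edges(node, data=True))
        else:
            degree = net.out_degree(node)
            weight = sum(d["weight"] for _, _, d in net.out_edges(node, data=True))
        rows.append((node, role, int(degree), float(weight)))
    rows.sort(key=lambda r: (-r[2], r[0]))
    return pd.DataFrame(rows, columns=["node", "role", "degree", "weight_sum"])
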