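"""Jaccard-weighted trait network, modularity clustering, cluster abundances.

Significant positive cooccurrence pairs become edges of an undirected
species network weighted by Jaccard similarity; Louvain-style modularity
optimization partitions it into trait clusters of functionally similar
species.  Retained clusters are converted to per-sample abundance
predictors by summing member-species abundances.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np

from .cooccurrence import PairAssociation
from .tables import SampleMatrix, ValidationError

logger = logging.getLogger("mfnet")


@dataclass
class Partition:
    """Assignment of every network node to a trait cluster.

    ``Q`` is the weighted modularity of the partition; ``excluded`` lists
    nodes dropped by the exclusion rule (small clusters, isolates).
    """

    cluster_of: dict[str, str]
    Q: float
    excluded: set[str] = field(default_factory=set)

    def members(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for node in sorted(self.cluster_of, key=str):
            out.setdefault(self.cluster_of[node], []).append(node)
        return out


@dataclass
class ClusterAbundanceTable:
    """Per-sample summed abundances of retained trait clusters."""

    matrix: SampleMatrix
    provenance: dict[str, list[str]]   # cluster -> member species


def build_trait_network(
    assocs: Sequence[PairAssociation],
    all_species: Sequence[str],
) -> nx.Graph:
    """Assemble the species network: nodes = all species (isolates kept),
    edges = significant positive pairs weighted by Jaccard coefficient."""
    net = nx.Graph()
    known = set(all_species)
    net.add_nodes_from(all_species)
    seen: set[tuple[str, str]] = set()
    for r in assocs:
        key = tuple(sorted((r.species_a, r.species_b)))
        if key in seen:
            raise ValidationError(f"duplicate pair in associations: {key}")
        seen.add(key)
        unknown = {r.species_a, r.species_b} - known
        if unknown:
            raise ValidationError(f"association references unknown species: {sorted(unknown)}")
        if r.significant:
            net.add_edge(r.species_a, r.species_b, weight=float(r.jaccard))
    return net


def modularity_score(net: nx.Graph, part: Partition | Mapping[str, str]) -> float:
    """Weighted Newman–Girvan modularity of a partition.

    Q = sum_c [ w_c / W - (s_c / 2W)^2 ] with w_c the intra-cluster edge
    weight, s_c the summed strength of cluster members and W the total
    edge weight; invariant under uniform rescaling of weights.
    """
    cluster_of = part.cluster_of if isinstance(part, Partition) else dict(part)
    missing = set(net.nodes) - set(cluster_of)
    if missing:
        raise ValidationError(f"nodes missing from partition: {sorted(missing)}")
    communities: dict[str, set] = {}
    for node in net.nodes:
        communities.setdefault(cluster_of[node], set()).add(node)
    return nx.community.modularity(net, communities.values(), weight="weight")


def _canonical(cluster_of: Mapping[str, str]) -> tuple[dict[str, str], tuple[int, ...]]:
    """Relabel clusters c1, c2, ... in order of first appearance over
    lexicographically sorted nodes; returns the relabelled map and the
    assignment tuple used for deterministic tie-breaking."""
    nodes = sorted(cluster_of, key=str)
    relabel: dict[str, int] = {}
    assignment = []
    for node in nodes:
        old = cluster_of[node]
        if old not in relabel:
            relabel[old] = len(relabel) + 1
        assignment.append(relabel[old])
    return {n: f"c{relabel[cluster_of[n]]}" for n in nodes}, tuple(assignment)


def detect_clusters(
    net: nx.Graph,
    resolution: float = 1.0,
    seed: int = 0,
    restarts: int = 20,
) -> Partition:
    """Louvain modularity clustering with seeded restarts.

    The best-Q partition over ``restarts`` runs is returned; ties are
    broken by fewest clusters, then by lexicographically smallest
    canonical assignment.  Isolated nodes become singleton clusters.
    """
    if restarts < 1:
        raise ValidationError("restarts must be >= 1")
    if net.number_of_nodes() == 0:
        raise ValidationError("empty network")
    best: tuple | None = None
    for r in range(restarts):
        comms = nx.community.louvain_communities(
            net, weight="weight", resolution=resolution, seed=seed + r,
        )
        cluster_of = {node: i for i, comm in enumerate(comms) for node in comm}
        q = modularity_score(net, cluster_of)
        relabelled, assignment = _canonical(cluster_of)
        key = (-round(q, 12), len(comms), assignment)
        if best is None or key < best[0]:
            best = (key, relabelled, q)
    _, cluster_of, q = best
    return Partition(cluster_of=cluster_of, Q=q)


def aggregate_cluster_abundance(
    part: Partition,
    abundance: SampleMatrix,
    min_cluster_size: int = 2,
    node_to_column: Mapping[str, str] | None = None,
    how: str = "sum",
) -> ClusterAbundanceTable:
    """Sum member-species abundances per retained cluster.

    Clusters with fewer than ``min_cluster_size`` members (including
    singleton isolates) are dropped and logged — mirroring the exclusion
    of a disconnected single-species cluster from downstream modelling.
    When trait rows are finer than abundance columns (size classes), an
    explicit ``node_to_column`` mapping is required; name-prefix guessing
    is refused.  Columns mapped by several nodes of one cluster are
    counted once.  ``how='mean'`` averages instead of summing.
    """
    if how not in ("sum", "mean"):
        raise ValidationError("how must be 'sum' or 'mean'")
    mapping = dict(node_to_column) if node_to_column else {n: n for n in part.cluster_of}
    missing = [n for n, col in mapping.items() if col not in abundance.variable_ids]
    if missing:
        raise ValidationError(
            "partition species absent from abundance table: "
            + ", ".join(sorted(missing))
        )
    members = part.members()
    kept_cols: list[str] = []
    values = []
    provenance: dict[str, list[str]] = {}
    excluded = set(part.excluded)
    for cluster in members:  # first-appearance order over sorted nodes
        nodes = [n for n in members[cluster] if n not in part.excluded]
        if len(nodes) < min_cluster_size:
            if nodes:
                logger.warning(
                    "dropping cluster %s (%d member(s) < min_cluster_size=%d): %s",
                    cluster, len(nodes), min_cluster_size, ", ".join(nodes),
                )
            excluded.update(nodes)
            continue
        cols = sorted({mapping[n] for n in nodes})
        block = np.column_stack([abundance.column(c) for c in cols])
        agg = block.sum(axis=1) if how == "sum" else block.mean(axis=1)
        kept_cols.append(cluster)
        values.append(agg)
        provenance[cluster] = nodes
    if not kept_cols:
        raise ValidationError("no cluster satisfies min_cluster_size")
    matrix = SampleMatrix(
        sample_ids=list(abundance.sample_ids),
        variable_ids=kept_cols,
        values=np.column_stack(values),
        kind="abundance",
    )
    part.excluded.update(excluded)
    return ClusterAbundanceTable(matrix=matrix, provenance=provenance)


def partition_to_frame(part: Partition):
    """Partition as a (node, cluster, excluded) table for CSV export."""
    import pandas as pd

    return pd.DataFrame(
        [(n, part.cluster_of[n], n in part.excluded)
         for n in sorted(part.cluster_of, key=str)],
        columns=["node", "cluster", "excluded"],
    )
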