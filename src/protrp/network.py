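"""Fuzzy similarity network over TR clusters.

Builds a weighted graph whose nodes are TR motif clusters and whose edge
weights are ensemble co-clustering confidences.  To keep the uniformly
high proline content of Pro-rich repeats from dominating similarity,
prolines are stripped from member consensus sequences before
vectorization; each cluster is represented by the mean of its members'
P-stripped dipeptide vectors.  Cluster vectors are unit-variance
normalized per column and compared all-against-all by Pearson
correlation distance, which drives the ensemble engine's co-clustering.
Edges below the confidence floor (0.04 by default) are removed, and
nodes isolated by edge filtering are dropped from the graph.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .autosome_tr import (ConsensusEnsembleClustering, EngineParams,
                          TRCluster, canonical_rotation, dipeptide_vector)

logger = logging.getLogger(__name__)


@dataclass
class NetworkParams:
    """Fuzzy-network construction settings (defaults follow the
    published network: 500 iterations, P<0.01, 12x12 grid, 32x32
    cartogram, 0.04 confidence floor, clusters of >= 3 members)."""

    min_edge_confidence: float = 0.04
    ensemble_iterations: int = 500
    p_value: float = 0.01
    grid: tuple[int, int] = (12, 12)
    cartogram_resolution: tuple[int, int] = (32, 32)
    min_cluster_members: int = 3
    subsample_fraction: float = 0.8
    null_replicates: int = 5
    seed: int = 0

    def engine(self) -> EngineParams:
        return EngineParams(
            ensemble_iterations=self.ensemble_iterations,
            p_value=self.p_value, grid=self.grid, topology="circle",
            cartogram_resolution=self.cartogram_resolution,
            subsample_fraction=self.subsample_fraction,
            null_replicates=self.null_replicates, seed=self.seed)


def strip_proline(consensus: str) -> str:
    """Remove all proline residues; may return an empty string (the
    cluster then contributes a zero vector, logged by the caller)."""
    return consensus.replace("P", "")


def cluster_vector(cluster: TRCluster) -> np.ndarray:
    """Mean of the members' P-stripped dipeptide vectors."""
    vecs = []
    for m in cluster.members:
        stripped = strip_proline(m)
        if len(stripped) < 2:
            logger.info("member %r empty after proline stripping: "
                        "zero vector", m)
            vecs.append(np.zeros(400))
        else:
            vecs.append(dipeptide_vector(stripped))
    return np.mean(vecs, axis=0)


def confidence_edges(conf: np.ndarray, min_confidence: float
                     ) -> list[tuple[int, int, float]]:
    """Edges retained from a co-clustering confidence matrix.

    An edge (i, j) is kept iff its confidence is at or above the floor
    ("less than the floor" is removed); self-edges never appear.  The
    filter is idempotent: re-applying it to the retained set changes
    nothing.
    """
    n = conf.shape[0]
    return [(i, j, float(conf[i, j]))
            for i in range(n) for j in range(i + 1, n)
            if conf[i, j] >= min_confidence]


def build_network(clusters: Sequence[TRCluster],
                  params: NetworkParams | None = None) -> nx.Graph:
    """Fuzzy cluster network over clusters with >= min members.

    Edge attribute ``confidence`` carries the engine's co-clustering
    confidence verbatim; edges with confidence < ``min_edge_confidence``
    are removed (exactly at the floor is retained) and isolated nodes are
    dropped.  Node attributes: ``member_count``, ``consensus_error``,
    ``master_consensus``.
    """
    params = params or NetworkParams()
    eligible = [c for c in clusters
                if c.size >= params.min_cluster_members]
    if len(eligible) < 2:
        raise ValueError("need at least two eligible clusters "
                         f"(>= {params.min_cluster_members} members)")
    X = np.vstack([cluster_vector(c) for c in eligible])
    # unit-variance normalization per column; constant columns dropped
    std = X.std(axis=0)
    keep = std > 0
    if not keep.all():
        logger.warning("%d constant columns dropped from normalization",
                       int((~keep).sum()))
    Xn = X[:, keep] / std[keep]
    est = ConsensusEnsembleClustering.from_engine_params(params.engine())
    est.set_params(metric="correlation")
    est.fit(Xn)
    conf = est.confidence_
    g = nx.Graph()
    for k, c in enumerate(eligible):
        g.add_node(_node_id(c, k),
                   member_count=c.size,
                   consensus_error=round(c.consensus_error, 4),
                   master_consensus=c.master_consensus)
    n = len(eligible)
    n_total = n * (n - 1) // 2
    for i, j, w in confidence_edges(conf, params.min_edge_confidence):
        g.add_edge(_node_id(eligible[i], i), _node_id(eligible[j], j),
                   confidence=round(w, 6))
    g.graph["n_possible_edges"] = n_total
    g.graph["n_removed_edges"] = n_total - g.number_of_edges()
    isolated = [v for v in g.nodes if g.degree(v) == 0]
    g.remove_nodes_from(isolated)
    g.graph["n_removed_nodes"] = len(isolated)
    return g


def _node_id(cluster: TRCluster, fallback: int) -> str:
    cid = cluster.cluster_id if cluster.cluster_id >= 0 else fallback
    return f"cluster_{cid}"


def prominence_tier(species_count: int, protein_count: int,
                    min_species: int = 10, min_proteins: int = 20) -> str:
    """Prominence of a cluster: 'large' when backed by >= 10 species AND
    >= 20 secreted proteins, 'intermediate' when exactly one criterion
    holds, 'small' otherwise."""
    hits = (species_count >= min_species) + (protein_count >= min_proteins)
    return {2: "large", 1: "intermediate", 0: "small"}[hits]


def retention_rate(cluster: TRCluster, class_defs,
                   match_fn=None) -> float:
    """Fraction of a cluster's member motifs captured by at least one
    TR class definition."""
    if match_fn is None:
        from .taxonomy import match_class

        match_fn = match_class
    if not cluster.members:
        raise ValueError("retention rate undefined for an empty cluster")
    hit = sum(1 for m in cluster.members
              if any(match_fn(m, d) for d in class_defs))
    return hit / len(cluster.members)


def annotate_nodes(g: nx.Graph, clusters: Sequence[TRCluster],
                   species_by_id: dict[str, str] | None = None,
                   class_defs=None,
                   parents_by_motif: dict[str, set[str]] | None = None,
                   ) -> None:
    """Attach species count, protein count, prominence tier and taxonomy
    retention rate to network nodes in place.

    ``parents_by_motif`` maps a canonicalized consensus to every parent
    protein carrying it, so counts include proteins collapsed by
    motif de-duplication.
    """
    by_node = {_node_id(c, k): c for k, c in enumerate(clusters)}
    for node in g.nodes:
        c = by_node.get(node)
        if c is None:
            continue
        parents = {d.parent_id for d in c.member_domains if d is not None}
        if parents_by_motif:
            for m in c.members:
                parents |= parents_by_motif.get(canonical_rotation(m),
                                                set())
        species = set()
        if species_by_id:
            species = {species_by_id[p] for p in parents
                       if p in species_by_id}
        g.nodes[node]["protein_count"] = len(parents)
        g.nodes[node]["species_count"] = len(species)
        g.nodes[node]["tier"] = prominence_tier(len(species), len(parents))
        if class_defs is not None:
            g.nodes[node]["retention_rate"] = round(
                retention_rate(c, class_defs), 4)


def write_graphml(g: nx.Graph, path: str | Path) -> None:
    nx.write_graphml(g, str(path))


def write_sif(g: nx.Graph, path: str | Path,
              relation: str = "co") -> None:
    """Cytoscape SIF export (node relation node per edge; isolated nodes
    on their own lines)."""
    with open(path, "w") as fh:
        for u, v in sorted(g.edges):
            fh.write(f"{u}\t{relation}\t{v}\n")
        for v in sorted(g.nodes):
            if g.degree(v) == 0:
                fh.write(f"{v}\n")


def node_table(g: nx.Graph) -> pd.DataFrame:
    """Node attributes as a TSV-ready table."""
    rows = [{"node": v, **g.nodes[v]} for v in sorted(g.nodes)]
    return pd.DataFrame(rows)
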