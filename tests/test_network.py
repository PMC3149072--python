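"""Fuzzy cluster network: proline stripping, cluster vectors, edge
filtering semantics, node annotations, and exports."""

import numpy as np
import pytest

import networkx as nx

from protrp.autosome_tr import TRCluster, dipeptide_index, dipeptide_vector
from protrp.network import (NetworkParams, build_network, cluster_vector,
                            confidence_edges, node_table, prominence_tier,
                            retention_rate, strip_proline, write_graphml,
                            write_sif)
from protrp.taxonomy import parse_class_def
from protrp.trdetect import TRDomain


def cluster(members, cid=0, error=0.0, parents=None):
    doms = None
    if parents is not None:
        doms = [TRDomain(parent_id=p, start=0, end=len(m) * 2,
                         period=len(m), copy_number=2.0, consensus=m,
                         domain_sequence=m * 2)
                for m, p in zip(members, parents)]
    return TRCluster(members=list(members), master_consensus=members[0],
                     consensus_error=error, cluster_id=cid,
                     member_domains=doms or [None] * len(members))


class TestStripProline:
    @pytest.mark.parametrize("consensus,expected", [
        ("PVPVK", "VVK"), ("PPPP", ""), ("AVYK", "AVYK"),
    ])
    def test_examples(self, consensus, expected):
        assert strip_proline(consensus) == expected


class TestClusterVector:
    def test_identical_members_equal_member_vector(self):
        c = cluster(["AVYKAVYK"] * 3)
        np.testing.assert_allclose(cluster_vector(c),
                                   dipeptide_vector("AVYKAVYK"))

    def test_disjoint_members_average(self):
        c = cluster(["AVAV", "KEKE"])
        v = cluster_vector(c)
        half_av = dipeptide_vector("AVAV") / 2
        assert v[dipeptide_index("AV")] == pytest.approx(
            half_av[dipeptide_index("AV")])
        assert v[dipeptide_index("KE")] == pytest.approx(
            dipeptide_vector("KEKE")[dipeptide_index("KE")] / 2)

    def test_all_proline_member_contributes_zeros(self):
        c = cluster(["PPPP", "AVAV"])
        v = cluster_vector(c)
        np.testing.assert_allclose(v, dipeptide_vector("AVAV") / 2)


class TestEdgeFilter:
    def conf(self, value):
        m = np.eye(3)
        m[0, 1] = m[1, 0] = value
        return m

    def test_exactly_at_floor_retained(self):
        edges = confidence_edges(self.conf(0.04), 0.04)
        assert (0, 1, 0.04) in edges

    def test_below_floor_removed(self):
        edges = confidence_edges(self.conf(0.039999), 0.04)
        assert all(e[:2] != (0, 1) for e in edges)

    def test_idempotent(self):
        conf = self.conf(0.5)
        kept = confidence_edges(conf, 0.04)
        filtered = np.eye(3)
        for i, j, w in kept:
            filtered[i, j] = filtered[j, i] = w
        assert confidence_edges(filtered, 0.04) == kept

    def test_no_self_edges(self):
        assert all(i != j for i, j, _ in
                   confidence_edges(np.eye(4), 0.0))


def motif_family(base, n, seed):
    """n variants of a base motif differing in one non-P position."""
    rng = np.random.default_rng(seed)
    out = [base]
    letters = "AVILKERT"
    while len(out) < n:
        pos = int(rng.integers(len(base)))
        if base[pos] == "P":
            continue
        sub = letters[int(rng.integers(len(letters)))]
        out.append(base[:pos] + sub + base[pos + 1:])
    return out[:n]


class TestBuildNetwork:
    def similar_and_alien(self):
        a = cluster(motif_family("AVYKEVYK", 5, 1), cid=0)
        b = cluster(motif_family("AVYKEVHK", 5, 2), cid=1)
        alien = cluster(motif_family("GDGDTWTW", 5, 3), cid=2)
        return [a, b, alien]

    def test_similar_pair_linked_alien_dropped(self):
        g = build_network(self.similar_and_alien(),
                          NetworkParams(seed=0))
        assert set(g.nodes) == {"cluster_0", "cluster_1"}
        assert g.number_of_edges() == 1
        assert g.graph["n_removed_nodes"] == 1

    def test_deterministic(self):
        g1 = build_network(self.similar_and_alien(), NetworkParams(seed=7))
        g2 = build_network(self.similar_and_alien(), NetworkParams(seed=7))
        assert nx.utils.graphs_equal(g1, g2)

    def test_small_clusters_excluded(self):
        small = cluster(["AVYK", "AVYE"], cid=3)  # < 3 members
        with pytest.raises(ValueError, match="eligible"):
            build_network([small, cluster(["GDGD"] * 2, cid=4)])

    def test_proline_placement_merges(self):
        # clusters identical after P-stripping co-cluster with full
        # confidence even though their proline placement differs
        a = cluster(["PAVYKEVYK"] * 3, cid=0)
        b = cluster(["APVYKEVYK"] * 3, cid=1)
        alien = cluster(motif_family("GDGDTWTW", 4, 5), cid=2)
        g = build_network([a, b, alien], NetworkParams(seed=1))
        assert g.has_edge("cluster_0", "cluster_1")
        assert g["cluster_0"]["cluster_1"]["confidence"] == 1.0

    def test_exports(self, tmp_path):
        g = build_network(self.similar_and_alien(), NetworkParams(seed=0))
        write_graphml(g, tmp_path / "net.graphml")
        back = nx.read_graphml(tmp_path / "net.graphml")
        assert set(back.nodes) == set(g.nodes)
        write_sif(g, tmp_path / "net.sif")
        lines = (tmp_path / "net.sif").read_text().strip().splitlines()
        assert lines == ["cluster_0\tco\tcluster_1"]
        table = node_table(g)
        assert set(table["node"]) == set(g.nodes)
        assert "member_count" in table.columns


class TestNodeAnnotations:
    @pytest.mark.parametrize("species,proteins,tier", [
        (10, 20, "large"),
        (12, 5, "intermediate"),
        (3, 30, "intermediate"),
        (3, 3, "small"),
    ])
    def test_prominence_tiers(self, species, proteins, tier):
        assert prominence_tier(species, proteins) == tier

    def test_retention_rate(self):
        defs = [parse_class_def("AVYK", name="avyk")]
        # AVYKG contains the motif, KAVY is a rotation, GDGD misses
        c = cluster(["AVYK", "AVYKG", "GDGD", "KAVY"])
        assert retention_rate(c, defs) == pytest.approx(3 / 4)

    def test_retention_bounds(self):
        defs = [parse_class_def("AVYK", name="avyk")]
        assert retention_rate(cluster(["AVYK"] * 3), defs) == 1.0
        assert retention_rate(cluster(["GGGG"] * 3), defs) == 0.0
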