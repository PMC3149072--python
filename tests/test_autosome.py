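"""Dipeptide vectors, cyclic alignment, master consensus, the ensemble
engine, and the recursive TR clustering framework."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import adjusted_rand_score

from _oracle import brute_cyclic_score
from protrp.autosome_tr import (AutoSOMETRClustering,
                                ConsensusEnsembleClustering, EngineParams,
                                QCParams, autosome_tr_cluster,
                                build_master_consensus, canonical_rotation,
                                cyclic_align_score, cyclic_rotations,
                                dipeptide_index, dipeptide_vector,
                                flag_outliers, member_error)

AA = "ACDEFGHIKLMNPQRSTVWY"


class TestDipeptideVector:
    def test_worked_example_counts(self):
        v = dipeptide_vector("PVPVKPVPVK", normalize=False)
        assert v[dipeptide_index("PV")] == 4
        assert v[dipeptide_index("VP")] == 2
        assert v[dipeptide_index("VK")] == 2
        assert v[dipeptide_index("KP")] == 1
        assert v.sum() == 9  # len - 1

    def test_worked_example_normalization(self):
        v = dipeptide_vector("PVPVKPVPVK")
        assert v[dipeptide_index("PV")] == pytest.approx(0.4)
        assert v.sum() == pytest.approx(9 / 10)

    def test_two_residues(self):
        v = dipeptide_vector("AA")
        assert v[dipeptide_index("AA")] == pytest.approx(0.5)

    def test_length_one_gives_zero_vector(self):
        assert dipeptide_vector("A").sum() == 0

    @given(st.text(alphabet=AA, min_size=2, max_size=40))
    @settings(max_examples=100, derandomize=True)
    def test_count_conservation(self, s):
        v = dipeptide_vector(s, normalize=False)
        assert v.sum() == len(s) - 1
        assert (v >= 0).all()


class TestCyclicOps:
    def test_rotation_equivalence_class(self):
        rots = cyclic_rotations("PVYK")
        assert set(rots) == {"PVYK", "VYKP", "YKPV", "KPVY"}
        assert canonical_rotation("PVYK") == "KPVY"

    def test_homopolymer_single_rotation(self):
        assert set(cyclic_rotations("AAAA")) == {"AAAA"}

    @given(st.text(alphabet=AA, min_size=1, max_size=12),
           st.integers(min_value=0, max_value=11))
    @settings(max_examples=100, derandomize=True)
    def test_canonical_invariant_under_rotation(self, s, k):
        k %= len(s)
        assert canonical_rotation(s[k:] + s[:k]) == canonical_rotation(s)

    @pytest.mark.parametrize("a,b,score,rot", [
        ("PVYK", "YKPV", 4, 2),
        ("PVYK", "AAAA", 0, 0),
        ("PVYKS", "PVYK", 4, 0),
    ])
    def test_align_examples(self, a, b, score, rot):
        assert cyclic_align_score(a, b) == (score, rot)

    @given(st.text(alphabet="PVYKS", min_size=2, max_size=8),
           st.text(alphabet="PVYKS", min_size=2, max_size=8))
    @settings(max_examples=150, derandomize=True)
    def test_align_matches_brute_force(self, a, b):
        assert cyclic_align_score(a, b)[0] == brute_cyclic_score(a, b)


class TestMasterConsensus:
    def test_identical_members(self):
        master, error, _ = build_master_consensus(["PVYK"] * 3)
        assert master == "PVYK"
        assert error == 0.0

    def test_single_substitution(self):
        master, error, per = build_master_consensus(
            ["PVYK", "PVYK", "PVHK"])
        assert master == "PVYK"
        assert error == pytest.approx((0 + 0 + 0.25) / 3)
        assert per == [0.0, 0.0, 0.25]

    def test_rotated_members_have_zero_error(self):
        master, error, _ = build_master_consensus(["PVYK", "VYKP"])
        assert error == 0.0

    def test_error_bounds(self, family_domains):
        domains, _ = family_domains
        members = [d.consensus for d in domains[:20]]
        _, error, per = build_master_consensus(members)
        assert 0.0 <= error <= 1.0
        assert all(0.0 <= e <= 1.0 for e in per)


class TestOutliers:
    def test_homogeneous_cluster_untouched(self):
        members = ["PVYKPVYK"] * 5
        master, _, per = build_master_consensus(members)
        kept, removed = flag_outliers(members, master, per, E=0.4)
        assert removed == []
        assert kept == list(range(5))

    def test_alien_member_removed(self):
        members = ["PVYKPVYK"] * 9 + ["GGGGGGGG"]
        master, _, per = build_master_consensus(members)
        kept, removed = flag_outliers(members, master, per, E=0.4)
        assert removed == [9]
        assert member_error("GGGGGGGG", master) > 0.8

    def test_pair_guard_prevents_emptying(self):
        members = ["PVYKPVYK", "GGGGGGGG"]
        master, _, per = build_master_consensus(members)
        kept, removed = flag_outliers(members, master, per, E=0.4)
        assert removed == []


class TestEnsembleEngine:
    def gaussian_groups(self, seed=42, n=15, d=20, sigma=0.05):
        rng = np.random.default_rng(seed)
        mu_a = np.r_[np.ones(d // 2), np.zeros(d - d // 2)]
        mu_b = 1 - mu_a
        return np.vstack([rng.normal(0, sigma, (n, d)) + mu_a,
                          rng.normal(0, sigma, (n, d)) + mu_b])

    def test_two_group_recovery(self):
        X = self.gaussian_groups()
        est = ConsensusEnsembleClustering(random_state=1).fit(X)
        conf = est.confidence_
        n = 15
        within = np.concatenate([
            conf[:n, :n][np.triu_indices(n, 1)],
            conf[n:, n:][np.triu_indices(n, 1)]])
        between = conf[:n, n:].ravel()
        assert len(set(est.labels_[:n])) == 1
        assert len(set(est.labels_[n:])) == 1
        assert est.labels_[0] != est.labels_[-1]
        assert within.min() >= 0.9
        assert between.max() <= 0.1

    def test_identical_vectors_one_cluster(self):
        X = np.ones((6, 10))
        est = ConsensusEnsembleClustering(random_state=0).fit(X)
        assert len(set(est.labels_)) == 1
        assert est.confidence_.min() == 1.0

    def test_deterministic_under_seed(self):
        X = self.gaussian_groups(seed=3)
        a = ConsensusEnsembleClustering(random_state=9).fit(X)
        b = ConsensusEnsembleClustering(random_state=9).fit(X)
        assert np.array_equal(a.labels_, b.labels_)
        assert np.array_equal(a.confidence_, b.confidence_)

    def test_confidence_matrix_contract(self):
        X = self.gaussian_groups(seed=8)
        conf = ConsensusEnsembleClustering(random_state=2).fit(X).confidence_
        assert np.allclose(conf, conf.T)
        assert (conf >= 0).all() and (conf <= 1).all()
        assert np.allclose(np.diag(conf), 1.0)

    def test_single_input_singleton(self):
        est = ConsensusEnsembleClustering().fit(np.ones((1, 4)))
        assert list(est.labels_) == [0]

    def test_sklearn_params_round_trip(self):
        est = ConsensusEnsembleClustering(p_value=0.05, random_state=7)
        clone = ConsensusEnsembleClustering(**est.get_params())
        assert clone.get_params() == est.get_params()


class TestRecursiveClustering:
    def test_identical_consensi_single_cluster(self):
        clusters, singles = autosome_tr_cluster(["PVYKA"] * 12)
        assert len(clusters) == 1
        assert clusters[0].consensus_error == 0.0
        assert singles == []

    def test_mutually_dissimilar_all_singletons(self):
        motifs = ["PVPVPVPV", "GKGKGKGK", "ATATATAT", "LDLDLDLD",
                  "QRQRQRQR"]
        for a in motifs:
            for b in motifs:
                if a != b:
                    assert brute_cyclic_score(a, b) <= 2
        clusters, singles = autosome_tr_cluster(motifs)
        assert clusters == []
        assert singles == [0, 1, 2, 3, 4]

    def test_family_recovery(self, family_domains):
        domains, labels = family_domains
        clusters, singles = autosome_tr_cluster(
            domains, engine=EngineParams(seed=1))
        assert len(clusters) >= 5
        pred = {}
        for cid, cl in enumerate(clusters):
            for i in cl._member_indices:
                pred[i] = cid
        predicted = [pred.get(i, -100 - i) for i in range(len(domains))]
        assert adjusted_rand_score(labels, predicted) >= 0.9

    def test_emitted_error_thresholds(self, family_domains):
        domains, _ = family_domains
        clusters, _ = autosome_tr_cluster(domains,
                                          engine=EngineParams(seed=1))
        for cl in clusters:
            assert cl.consensus_error <= 0.4
            if cl.depth >= 1:
                assert cl.consensus_error <= 0.3

    def test_partition_property(self, family_domains):
        domains, _ = family_domains
        est = AutoSOMETRClustering(random_state=1).fit(domains)
        accounted = sorted(
            [i for cl in est.clusters_ for i in cl._member_indices]
            + [i for cl in est.clusters_ for i in cl._removed_indices]
            + est.singletons_)
        assert accounted == list(range(len(domains)))

    def test_cyclic_invariance_of_membership(self, family_domains):
        # vectors come from the (unrotated) domain sequences and the QC
        # alignment is cyclic, so the phase in which a consensus is
        # stored must not affect cluster membership at all
        import dataclasses

        domains, _ = family_domains
        rng = np.random.default_rng(0)
        rotated = []
        for d in domains:
            k = int(rng.integers(0, d.period))
            rotated.append(dataclasses.replace(
                d, consensus=d.consensus[k:] + d.consensus[:k]))
        base, sb = autosome_tr_cluster(domains,
                                       engine=EngineParams(seed=4))
        rot, sr = autosome_tr_cluster(rotated,
                                      engine=EngineParams(seed=4))
        assert [c._member_indices for c in base] == \
            [c._member_indices for c in rot]
        assert sb == sr

    def test_rerun_identical(self, family_domains):
        domains, _ = family_domains
        a, sa = autosome_tr_cluster(domains, engine=EngineParams(seed=5))
        b, sb = autosome_tr_cluster(domains, engine=EngineParams(seed=5))
        assert [c.members for c in a] == [c.members for c in b]
        assert sa == sb

    def test_qc_params_validation(self):
        with pytest.raises(ValueError):
            QCParams(homology_threshold=0.2, strict_threshold=0.3)
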