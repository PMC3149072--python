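"""Cyclic-permutation-aware clustering of tandem-repeat consensus motifs.

Tandem-repeat motifs are low-complexity sequences for which alignment
scores are weakly informative, and the same repeat can be reported in any
cyclic phase (PVYK = VYKP = YKPV = KPVY).  This module clusters TR
domains in three coupled layers:

1. every TR domain becomes a dipeptide compositional vector: counts of
   the 400 ordered residue pairs over the domain sequence, normalized by
   the domain length.  Dipeptides capture adjacent-residue context and
   are nearly invariant to repeat phase;
2. an ensemble clustering engine partitions the vectors and reports, for
   every pair, the fraction of ensemble iterations in which they
   co-clustered (the co-clustering confidence);
3. each compositional cluster is quality-controlled at the sequence
   level: members are rotated into a maximal-agreement cyclic frame, a
   column-majority master consensus is built, and the cluster is accepted
   only when the mean mismatch fraction of members against that master
   (the consensus error) meets a homology threshold ``E``.  Failing
   clusters are recursively re-clustered with a stricter threshold until
   they pass or fall below a minimum size.

The ensemble engine here is a consensus-clustering scheme: per iteration
it subsamples rows, links pairs whose Euclidean distance falls below the
engine p-value quantile of a column-permutation null, and takes connected
components.  Grid/topology/cartogram settings of self-organizing-map
engines are accepted for interface compatibility but have no effect on
this engine.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import pdist, squareform
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans

from .seqio import AMINO_ACIDS
from .trdetect import TRDomain, _column_consensus

logger = logging.getLogger(__name__)

_AA_INDEX = {aa: k for k, aa in enumerate(AMINO_ACIDS)}
N_DIPEPTIDES = 400


# ---------------------------------------------------------------------------
# dipeptide compositional vectors

def dipeptide_vector(domain_sequence: str, normalize: bool = True
                     ) -> np.ndarray:
    """Dipeptide compositional vector of a TR domain sequence.

    Counts every ordered adjacent residue pair (no wraparound) and, when
    ``normalize`` is true, divides by the full domain length ``L`` (so
    the normalized entries sum to ``(L-1)/L``).  A length-1 input yields
    an all-zero vector with a logged warning.
    """
    if not domain_sequence:
        raise ValueError("empty domain sequence")
    v = np.zeros(N_DIPEPTIDES)
    L = len(domain_sequence)
    if L == 1:
        logger.warning("length-1 domain sequence: zero dipeptide vector")
        return v
    for a, b in zip(domain_sequence, domain_sequence[1:]):
        ia, ib = _AA_INDEX.get(a), _AA_INDEX.get(b)
        if ia is None or ib is None:
            raise ValueError(
                f"non-standard residue in {a + b!r}: dipeptide vectors "
                "are defined over the 20 amino acids")
        v[20 * ia + ib] += 1.0
    if normalize:
        v /= L
    return v


def dipeptide_name(index: int) -> str:
    """Residue pair for a vector index (e.g., index of 'PV')."""
    return AMINO_ACIDS[index // 20] + AMINO_ACIDS[index % 20]


def dipeptide_index(pair: str) -> int:
    return 20 * _AA_INDEX[pair[0]] + _AA_INDEX[pair[1]]


# ---------------------------------------------------------------------------
# cyclic string operations

def cyclic_rotations(consensus: str) -> list[str]:
    """All rotations of a motif, in shift order (shift 0 first)."""
    if not consensus:
        raise ValueError("empty consensus")
    return [consensus[k:] + consensus[:k] for k in range(len(consensus))]


def canonical_rotation(consensus: str) -> str:
    """Lexicographically smallest rotation: the phase-free canonical form
    of a repeat motif."""
    return min(cyclic_rotations(consensus))


def cyclic_align_score(a: str, b: str) -> tuple[int, int]:
    """Best match count of ``a`` against all cyclic rotations of ``b``.

    Equal lengths are compared position-wise; unequal lengths are
    compared over the shorter length at every rotation of ``b`` crossed
    with every sliding offset of the longer sequence.  Returns ``(score,
    rotation)`` where ``rotation`` is the rotation shift of ``b``; ties
    break to the smallest rotation index, then the smallest offset.
    """
    if not a or not b:
        raise ValueError("empty input")
    best = (-1, 0)
    la, lb = len(a), len(b)
    for k, rb in enumerate(cyclic_rotations(b)):
        if la >= lb:
            offsets = range(la - lb + 1)
            for o in offsets:
                sc = sum(1 for x, y in zip(a[o:o + lb], rb) if x == y)
                if sc > best[0]:
                    best = (sc, k)
        else:
            for o in range(lb - la + 1):
                sc = sum(1 for x, y in zip(a, rb[o:o + la]) if x == y)
                if sc > best[0]:
                    best = (sc, k)
    return best


def _align_to_reference(member: str, ref: str) -> tuple[int, int]:
    """Best (rotation, offset) placing ``member`` on the columns of
    ``ref``; offset is where the overlap window starts on the longer of
    the two."""
    best = (-1, 0, 0)
    lm, lr = len(member), len(ref)
    for k, rm in enumerate(cyclic_rotations(member)):
        if lm <= lr:
            for o in range(lr - lm + 1):
                sc = sum(1 for x, y in zip(rm, ref[o:o + lm]) if x == y)
                if sc > best[0]:
                    best = (sc, k, o)
        else:
            for o in range(lm - lr + 1):
                sc = sum(1 for x, y in zip(rm[o:o + lr], ref) if x == y)
                if sc > best[0]:
                    best = (sc, k, o)
    return best[1], best[2]


def build_master_consensus(members: Sequence[str]
                           ) -> tuple[str, float, list[float]]:
    """Master consensus and consensus error of a motif cluster.

    Members are rotated (and, for unequal lengths, offset) into the
    cyclic frame of maximal aggregate cyclic-alignment score, the master
    is the column-majority string over that frame, and the consensus
    error is the mean over members of their mismatch fraction against the
    master (mismatched positions / compared positions).

    Returns ``(master, error, per_member_errors)``.
    """
    members = list(members)
    if len(members) < 2:
        raise ValueError("need at least two members")
    # reference = member with maximal total agreement to the others
    totals = []
    for j, m in enumerate(members):
        t = sum(cyclic_align_score(other, m)[0]
                for jj, other in enumerate(members) if jj != j)
        totals.append(t)
    ref_idx = int(np.argmax(totals))
    ref = members[ref_idx]
    lr = len(ref)
    columns: list[list[str]] = [[] for _ in range(lr)]
    placements: list[tuple[str, int]] = []  # (rotated overlap, col start)
    for m in members:
        k, o = _align_to_reference(m, ref)
        rm = m[k:] + m[:k]
        if len(m) <= lr:
            placements.append((rm, o))
            for c, ch in enumerate(rm):
                columns[o + c].append(ch)
        else:
            window = rm[o:o + lr]
            placements.append((window, 0))
            for c, ch in enumerate(window):
                columns[c].append(ch)
    master = "".join(_column_consensus(col) if col else "-"
                     for col in columns)
    per_member = []
    for window, o in placements:
        compared = len(window)
        mism = sum(1 for c, ch in enumerate(window)
                   if ch != master[o + c])
        per_member.append(mism / compared if compared else 0.0)
    error = float(np.mean(per_member))
    return master, error, per_member


def member_error(member: str, master: str) -> float:
    """Mismatch fraction of one motif against a master consensus, in the
    best cyclic frame."""
    lo = min(len(member), len(master))
    score, _ = cyclic_align_score(member, master)
    return 1.0 - score / lo


# ---------------------------------------------------------------------------
# cluster containers and QC

@dataclass
class QCParams:
    """Homology quality-control thresholds."""

    homology_threshold: float = 0.4   # E, stage-one acceptance
    strict_threshold: float = 0.3     # stricter E for recursive stages
    min_cluster_size: int = 10
    outlier_factor: float = 2.0       # member removed when error > factor*E

    def __post_init__(self) -> None:
        if not 0 < self.strict_threshold <= self.homology_threshold < 1:
            raise ValueError("require 0 < strict_E <= E < 1")


@dataclass
class EngineParams:
    """Ensemble-engine settings.

    ``ensemble_iterations``, ``p_value`` and ``seed`` drive the engine;
    ``grid``, ``topology`` and ``cartogram_resolution`` describe
    self-organizing-map engines and are accepted for configuration
    compatibility only.
    """

    ensemble_iterations: int = 100
    p_value: float = 0.01
    grid: tuple[int, int] = (20, 20)
    topology: str = "circle"
    cartogram_resolution: tuple[int, int] = (64, 64)
    subsample_fraction: float = 0.8
    null_replicates: int = 5
    seed: int = 0


STAGE2_ENGINE = EngineParams(grid=(10, 10))


@dataclass
class TRCluster:
    """A cluster of TR consensus motifs."""

    members: list[str]
    master_consensus: str
    consensus_error: float
    removed_members: list[str] = field(default_factory=list)
    member_domains: list[TRDomain | None] = field(default_factory=list)
    removed_domains: list[TRDomain | None] = field(default_factory=list)
    depth: int = 0
    cluster_id: int = -1

    @property
    def size(self) -> int:
        return len(self.members)


def flag_outliers(members: Sequence[str], master: str,
                  per_member_errors: Sequence[float],
                  E: float, factor: float = 2.0
                  ) -> tuple[list[int], list[int]]:
    """Indices of members kept/removed by the outlier rule.

    A member is flagged when its mismatch fraction against the master
    exceeds ``factor * E``.  Removal that would leave fewer than two
    members is suppressed (the guard case is logged).
    """
    removed = [j for j, e in enumerate(per_member_errors)
               if e > factor * E]
    if len(members) - len(removed) < 2 and removed:
        logger.info("outlier removal suppressed: would leave <2 members")
        return list(range(len(members))), []
    kept = [j for j in range(len(members)) if j not in set(removed)]
    return kept, removed


# ---------------------------------------------------------------------------
# ensemble engine (sklearn estimator)

class ConsensusEnsembleClustering(BaseEstimator, ClusterMixin):
    """Ensemble clustering with co-clustering confidence.

    Per iteration, rows are subsampled, pairs are linked when their
    Euclidean distance is at or below the ``p_value`` quantile of a
    column-permutation null distribution, and clusters are the connected
    components of the link graph.  The confidence matrix entry (i, j) is
    the fraction of iterations containing both i and j in which they
    co-clustered; the final flat partition connects pairs with confidence
    >= 0.5.

    Parameters
    ----------
    n_iterations : int
        Ensemble iterations.
    p_value : float
        Quantile of the permutation-null distance distribution used as
        the linking threshold.
    subsample_fraction : float
        Fraction of rows drawn (without replacement) per iteration.
    null_replicates : int
        Column-permutation replicates pooled into the null per iteration.
    unit_variance : bool
        Normalize feature columns to unit variance before clustering.
    random_state : int
        Seed for all stochastic steps (the estimator is deterministic for
        a fixed seed).

    Attributes
    ----------
    labels_ : ndarray of shape (n,)
        Flat partition labels.
    confidence_ : ndarray of shape (n, n)
        Symmetric co-clustering confidence in [0, 1] with unit diagonal.
    """

    def __init__(self, n_iterations: int = 100, p_value: float = 0.01,
                 subsample_fraction: float = 0.8, null_replicates: int = 5,
                 unit_variance: bool = False, metric: str = "euclidean",
                 random_state: int = 0):
        self.n_iterations = n_iterations
        self.p_value = p_value
        self.subsample_fraction = subsample_fraction
        self.null_replicates = null_replicates
        self.unit_variance = unit_variance
        self.metric = metric
        self.random_state = random_state

    @classmethod
    def from_engine_params(cls, params: EngineParams, unit_variance=False):
        return cls(n_iterations=params.ensemble_iterations,
                   p_value=params.p_value,
                   subsample_fraction=params.subsample_fraction,
                   null_replicates=params.null_replicates,
                   unit_variance=unit_variance,
                   random_state=params.seed)

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-dimensional")
        n = X.shape[0]
        if n < 2:
            self.labels_ = np.zeros(n, dtype=int)
            self.confidence_ = np.ones((n, n))
            return self
        Xn = X.copy()
        if self.unit_variance:
            std = Xn.std(axis=0)
            nz = std > 0
            Xn[:, nz] = Xn[:, nz] / std[nz]
        co = np.zeros((n, n))
        together = np.zeros((n, n))
        # a 2-row subsample is degenerate (column permutations of two
        # rows preserve their distance, voiding the null): keep >= 3
        m = min(n, max(3, int(round(self.subsample_fraction * n))))
        for t in range(self.n_iterations):
            rng = np.random.default_rng([int(self.random_state) & 0x7FFFFFFF,
                                         t])
            idx = np.sort(rng.choice(n, size=m, replace=False))
            Xs = Xn[idx]
            d = self._distances(Xs)
            null = []
            for _ in range(self.null_replicates):
                perm = np.argsort(rng.random(Xs.shape), axis=0)
                Xp = np.take_along_axis(Xs, perm, axis=0)
                null.append(self._distances(Xp))
            tau = float(np.quantile(np.concatenate(null), self.p_value))
            adj = squareform(d <= tau + 1e-12).astype(np.int8)
            _, labels = connected_components(csr_matrix(adj), directed=False)
            same = labels[:, None] == labels[None, :]
            co[np.ix_(idx, idx)] += same
            together[np.ix_(idx, idx)] += 1
        with np.errstate(invalid="ignore", divide="ignore"):
            conf = np.where(together > 0, co / np.maximum(together, 1), 0.0)
        np.fill_diagonal(conf, 1.0)
        conf = (conf + conf.T) / 2.0
        self.confidence_ = conf
        final_adj = (conf >= 0.5).astype(np.int8)
        _, self.labels_ = connected_components(csr_matrix(final_adj),
                                               directed=False)
        return self

    def _distances(self, X: np.ndarray) -> np.ndarray:
        d = pdist(X, metric=self.metric)
        # correlation distance is undefined for constant rows; treat
        # such rows as maximally distant from everything
        return np.nan_to_num(d, nan=2.0)

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


def ensemble_cluster(vectors: Iterable[np.ndarray],
                     engine: EngineParams | None = None
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Functional wrapper: partition labels and co-clustering confidence
    matrix for a list of dipeptide vectors."""
    engine = engine or EngineParams()
    X = np.vstack([np.asarray(v, dtype=float) for v in vectors])
    est = ConsensusEnsembleClustering.from_engine_params(engine)
    est.fit(X)
    return est.labels_, est.confidence_


# ---------------------------------------------------------------------------
# recursive TR clustering (sklearn estimator)

class AutoSOMETRClustering(BaseEstimator, ClusterMixin):
    """Two-phase recursive clustering of TR consensus motifs.

    Stage one clusters all dipeptide vectors with the ensemble engine.
    Each resulting compositional cluster is quality-controlled: master
    consensus, consensus error, outlier removal, and acceptance when the
    lower of the before/after-removal errors meets the homology threshold
    ``E`` (0.4 by default).  Failing clusters are re-clustered (members
    plus any flagged outliers) with stage-two engine settings, recursing
    until every emitted cluster meets the stricter threshold (0.3) or the
    cluster falls below the minimum size (10), in which case unresolvable
    groups disband into singletons.

    ``fit`` accepts a list of :class:`TRDomain` (vectors computed on the
    domain sequence, QC on the consensus) or plain motif strings.

    Attributes
    ----------
    labels_ : ndarray of shape (n,)
        Cluster index per input (-1 for singletons).
    clusters_ : list of TRCluster
    singletons_ : list of int
        Input indices emitted as singletons.
    confidence_ : ndarray
        Stage-one co-clustering confidence matrix.
    """

    def __init__(self, homology_threshold: float = 0.4,
                 strict_threshold: float = 0.3, min_cluster_size: int = 10,
                 outlier_factor: float = 2.0,
                 stage1_engine: EngineParams | None = None,
                 stage2_engine: EngineParams | None = None,
                 max_depth: int = 32, random_state: int = 0):
        self.homology_threshold = homology_threshold
        self.strict_threshold = strict_threshold
        self.min_cluster_size = min_cluster_size
        self.outlier_factor = outlier_factor
        self.stage1_engine = stage1_engine
        self.stage2_engine = stage2_engine
        self.max_depth = max_depth
        self.random_state = random_state

    # -- helpers ---------------------------------------------------------
    def _engines(self) -> tuple[EngineParams, EngineParams]:
        e1 = self.stage1_engine or EngineParams(seed=self.random_state)
        e2 = self.stage2_engine or EngineParams(
            grid=(10, 10), seed=self.random_state)
        return e1, e2

    def _qc(self) -> QCParams:
        return QCParams(homology_threshold=self.homology_threshold,
                        strict_threshold=self.strict_threshold,
                        min_cluster_size=self.min_cluster_size,
                        outlier_factor=self.outlier_factor)

    def fit(self, X, y=None):
        domains: list[TRDomain | None] = []
        consensi: list[str] = []
        for x in X:
            if isinstance(x, TRDomain):
                domains.append(x)
                consensi.append(x.consensus)
            else:
                domains.append(None)
                consensi.append(str(x))
        vectors = np.vstack([
            dipeptide_vector(d.domain_sequence if d is not None else c)
            for d, c in zip(domains, consensi)])
        n = len(consensi)
        self.clusters_ = []
        self.singletons_ = []
        self.labels_ = np.full(n, -1, dtype=int)
        if n == 0:
            self.confidence_ = np.zeros((0, 0))
            return self
        if n == 1:
            self.singletons_ = [0]
            self.confidence_ = np.ones((1, 1))
            return self
        self._consensi = consensi
        self._domains = domains
        self._vectors = vectors
        self._recurse(list(range(n)), depth=0)
        for cid, cl in enumerate(self.clusters_):
            cl.cluster_id = cid
            for idx in cl._member_indices:
                self.labels_[idx] = cid
        self.singletons_ = sorted(set(self.singletons_))
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_

    def _recurse(self, indices: list[int], depth: int) -> None:
        e1, e2 = self._engines()
        engine = e1 if depth == 0 else e2
        engine_seeded = EngineParams(
            ensemble_iterations=engine.ensemble_iterations,
            p_value=engine.p_value, grid=engine.grid,
            topology=engine.topology,
            cartogram_resolution=engine.cartogram_resolution,
            subsample_fraction=engine.subsample_fraction,
            null_replicates=engine.null_replicates,
            seed=(engine.seed + 1009 * depth) & 0x7FFFFFFF)
        est = ConsensusEnsembleClustering.from_engine_params(engine_seeded)
        labels = est.fit_predict(self._vectors[indices])
        if depth == 0:
            self.confidence_ = est.confidence_
        groups: dict[int, list[int]] = {}
        for local, lab in enumerate(labels):
            groups.setdefault(int(lab), []).append(indices[local])
        group_list = list(groups.values())
        if len(group_list) == 1 and depth > 0:
            # engine made no progress; force a deterministic bisection
            group_list = self._bisect(indices, depth)
            if len(group_list) == 1:
                self._disband(indices)
                return
        for grp in group_list:
            self._evaluate_group(grp, depth)

    def _bisect(self, indices: list[int], depth: int) -> list[list[int]]:
        if len(indices) < 2:
            return [indices]
        km = KMeans(n_clusters=2, n_init=1,
                    random_state=(self.random_state + depth) & 0x7FFFFFFF)
        lab = km.fit_predict(self._vectors[indices])
        g0 = [i for i, l in zip(indices, lab) if l == 0]
        g1 = [i for i, l in zip(indices, lab) if l == 1]
        if not g0 or not g1:
            return [indices]
        return [g0, g1]

    def _evaluate_group(self, grp: list[int], depth: int) -> None:
        qc = self._qc()
        E = qc.homology_threshold if depth == 0 else qc.strict_threshold
        if len(grp) == 1:
            self.singletons_.append(grp[0])
            return
        members = [self._consensi[i] for i in grp]
        master, error, per_member = build_master_consensus(members)
        kept_idx, removed_idx = flag_outliers(
            members, master, per_member, E, qc.outlier_factor)
        if error <= E:
            self._emit(grp, [], master, error, depth)
            return
        if removed_idx:
            kept_members = [members[j] for j in kept_idx]
            master2, error2, _ = build_master_consensus(kept_members)
            if error2 <= E:
                self._emit([grp[j] for j in kept_idx],
                           [grp[j] for j in removed_idx],
                           master2, error2, depth)
                return
        if len(grp) < qc.min_cluster_size or depth + 1 > self.max_depth:
            self._disband(grp)
            return
        self._recurse(grp, depth + 1)

    def _emit(self, member_idx: list[int], removed_idx: list[int],
              master: str, error: float, depth: int) -> None:
        cl = TRCluster(
            members=[self._consensi[i] for i in member_idx],
            master_consensus=master,
            consensus_error=error,
            removed_members=[self._consensi[i] for i in removed_idx],
            member_domains=[self._domains[i] for i in member_idx],
            removed_domains=[self._domains[i] for i in removed_idx],
            depth=depth)
        cl._member_indices = member_idx
        cl._removed_indices = removed_idx
        self.clusters_.append(cl)

    def _disband(self, indices: list[int]) -> None:
        self.singletons_.extend(indices)


def autosome_tr_cluster(domains: Sequence[TRDomain | str],
                        qc: QCParams | None = None,
                        engine: EngineParams | None = None,
                        stage2_engine: EngineParams | None = None,
                        ) -> tuple[list[TRCluster], list[int]]:
    """Functional wrapper around :class:`AutoSOMETRClustering`.

    Returns the emitted clusters and the indices of singleton inputs.
    """
    qc = qc or QCParams()
    engine = engine or EngineParams()
    est = AutoSOMETRClustering(
        homology_threshold=qc.homology_threshold,
        strict_threshold=qc.strict_threshold,
        min_cluster_size=qc.min_cluster_size,
        outlier_factor=qc.outlier_factor,
        stage1_engine=engine,
        stage2_engine=stage2_engine,
        random_state=engine.seed)
    est.fit(list(domains))
    return est.clusters_, est.singletons_


def clusters_to_table(clusters: Sequence[TRCluster]):
    """Cluster membership as a DataFrame (cluster id, member consensus,
    parent protein, error)."""
    import pandas as pd

    rows = []
    for cl in clusters:
        for m, d in zip(cl.members, cl.member_domains):
            rows.append({
                "cluster_id": cl.cluster_id,
                "consensus": m,
                "parent_id": d.parent_id if d is not None else "",
                "master_consensus": cl.master_consensus,
                "consensus_error": round(cl.consensus_error, 4),
                "depth": cl.depth,
            })
    return pd.DataFrame(rows, columns=[
        "cluster_id", "consensus", "parent_id", "master_consensus",
        "consensus_error", "depth"])
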