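"""Signed modularity maximization, allegiance, and consensus clustering.

The quality function is the signed modularity Q* with an asymmetric
treatment of negative weights (Rubinov-Sporns style): positive weights
contribute at full scale (normalized by the total positive weight v+),
negative weights are down-weighted by the total weight v+ + v-:

    Q* = (1/v+) sum_ij (w+_ij - g e+_ij) d_ij
       - (1/(v+ + v-)) sum_ij (w-_ij - g e-_ij) d_ij

with w+_ij = max(w_ij, 0), w-_ij = -min(w_ij, 0), strengths
s+-_i = sum_j w+-_ij, totals v+- = sum_ij w+-_ij, chance expectation
e+-_ij = s+-_i s+-_j / v+- (zero when v+- = 0), resolution parameter g,
and d_ij = 1 iff nodes i, j share a community.

Partitions are plain integer label vectors; ``canonical_partition``
renumbers labels by first appearance so equality tests are structural.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .betaseries import WeightedNetwork

__all__ = [
    "ModularityValue",
    "AllegianceMatrix",
    "ConsensusError",
    "canonical_partition",
    "partitions_equal",
    "signed_modularity_matrix",
    "modularity_qstar",
    "louvain_partition",
    "allegiance_from_partitions",
    "consensus_partition",
    "subject_consensus",
    "group_consensus",
    "match_labels",
]

_MOVE_TOL = 1e-12


@dataclass
class ModularityValue:
    qstar: float
    gamma: float
    partition: np.ndarray


@dataclass
class AllegianceMatrix:
    """Pairwise co-assignment probability matrix.

    ``source`` records what the probability is over: repeated Louvain
    iterations of one subject, or subjects at the group level.
    """

    p: np.ndarray
    source: str = "subject-iterations"

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        if np.any(self.p < -1e-12) or np.any(self.p > 1 + 1e-12):
            raise ValueError("allegiance entries must lie in [0, 1]")

    @property
    def n_regions(self) -> int:
        return self.p.shape[0]


class ConsensusError(RuntimeError):
    """Consensus clustering failed to converge; carries the last agreement matrix."""

    def __init__(self, message: str, agreement: np.ndarray):
        super().__init__(message)
        self.agreement = agreement


def canonical_partition(labels: np.ndarray) -> np.ndarray:
    """Renumber community labels 0..k-1 by order of first appearance."""
    labels = np.asarray(labels, dtype=int)
    _, first, inverse = np.unique(labels, return_index=True, return_inverse=True)
    order = np.argsort(np.argsort(first))
    return order[inverse]


def partitions_equal(a: np.ndarray, b: np.ndarray) -> bool:
    """Structural equality (invariant to label permutation)."""
    return np.array_equal(canonical_partition(a), canonical_partition(b))


def _signed_split(w: np.ndarray):
    wp = np.where(w > 0, w, 0.0)
    wn = np.where(w < 0, -w, 0.0)
    return wp, wn


def signed_modularity_matrix(net: WeightedNetwork, gamma: float) -> np.ndarray:
    """Dense matrix B with Q*(partition) = sum of B over within-community pairs."""
    wp, wn = _signed_split(net.w)
    vp, vn = wp.sum(), wn.sum()
    B = np.zeros_like(net.w)
    if vp > 0:
        sp = wp.sum(axis=1)
        B += (wp - gamma * np.outer(sp, sp) / vp) / vp
    if vn > 0:
        sn = wn.sum(axis=1)
        B -= (wn - gamma * np.outer(sn, sn) / vn) / (vp + vn)
    return B


def modularity_qstar(net: WeightedNetwork, labels: np.ndarray, gamma: float) -> float:
    """Evaluate Q* of a partition (see module docstring for the definition)."""
    labels = np.asarray(labels, dtype=int)
    if labels.size != net.n_regions:
        raise ValueError("partition length must match network size")
    delta = labels[:, None] == labels[None, :]
    wp, wn = _signed_split(net.w)
    vp, vn = wp.sum(), wn.sum()
    q = 0.0
    if vp > 0:
        sp = wp.sum(axis=1)
        ep = np.outer(sp, sp) / vp
        q += ((wp - gamma * ep) * delta).sum() / vp
    if vn > 0:
        sn = wn.sum(axis=1)
        en = np.outer(sn, sn) / vn
        q -= ((wn - gamma * en) * delta).sum() / (vp + vn)
    return float(q)


def _louvain_phase(B: np.ndarray, rng: np.random.Generator) -> tuple[np.ndarray, bool]:
    """Greedy node moves on modularity matrix B until no move improves.

    Nodes are visited in a seeded random order each pass; ties in the
    move gain are broken toward the lowest community index encountered.
    """
    n = B.shape[0]
    labels = np.arange(n)
    moved_any = False
    improved = True
    while improved:
        improved = False
        for i in rng.permutation(n):
            row = B[i].copy()
            row[i] = 0.0  # self-term is partition-invariant
            gains = np.bincount(labels, weights=row, minlength=n)
            cur = labels[i]
            best = int(np.argmax(gains))
            if best != cur and gains[best] > gains[cur] + _MOVE_TOL:
                labels[i] = best
                improved = moved_any = True
    return canonical_partition(labels), moved_any


def _louvain_on_matrix(B: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    labels = np.arange(B.shape[0])
    Bcur = B
    while True:
        phase_labels, moved = _louvain_phase(Bcur, rng)
        labels = phase_labels[labels]
        if not moved:
            return canonical_partition(labels)
        k = phase_labels.max() + 1
        onehot = np.eye(k)[phase_labels]
        Bcur = onehot.T @ Bcur @ onehot


def louvain_partition(net: WeightedNetwork, gamma: float = 1.0, seed: int = 0) -> ModularityValue:
    """One run of the generalized (signed, two-phase) Louvain algorithm.

    Greedy node moves in seeded random order followed by community
    aggregation, repeated until no move improves Q*.  Deterministic
    given ``seed``; the returned ``qstar`` is re-evaluated exactly with
    :func:`modularity_qstar` on the final partition.
    """
    rng = np.random.default_rng(seed)
    B = signed_modularity_matrix(net, gamma)
    labels = _louvain_on_matrix(B, rng)
    return ModularityValue(qstar=modularity_qstar(net, labels, gamma), gamma=gamma,
                           partition=labels)


def allegiance_from_partitions(
    partitions: list[np.ndarray], source: str = "subject-iterations"
) -> AllegianceMatrix:
    """Fraction of partitions in which each region pair shares a community."""
    if not partitions:
        raise ValueError("need at least one partition")
    stack = np.asarray([np.asarray(p, int) for p in partitions])
    if stack.ndim != 2:
        raise ValueError("all partitions must have the same length")
    n = stack.shape[1]
    p = np.zeros((n, n))
    for lab in stack:
        p += lab[:, None] == lab[None, :]
    p /= stack.shape[0]
    np.fill_diagonal(p, 1.0)
    return AllegianceMatrix(p=p, source=source)


def consensus_partition(
    a: AllegianceMatrix,
    tau: float = 0.5,
    reps: int = 100,
    gamma: float = 1.0,
    seed: int = 0,
    max_iter: int = 50,
) -> np.ndarray:
    """Iterative consensus clustering of an agreement/allegiance matrix.

    Entries below ``tau`` are zeroed, the thresholded matrix is
    re-partitioned ``reps`` times with the signed Louvain algorithm, the
    agreement matrix is rebuilt, and the cycle repeats until all
    ``reps`` partitions coincide.  Components disconnected by the
    threshold are free to become separate (possibly singleton)
    communities.
    """
    if not 0 <= tau < 1:
        raise ValueError("tau must be in [0, 1)")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    d = a.p.copy()
    for _ in range(max_iter):
        dt = np.where(d < tau, 0.0, d)
        np.fill_diagonal(dt, 0.0)
        net = WeightedNetwork(w=dt)
        parts = [
            louvain_partition(net, gamma=gamma, seed=int(rng.integers(2**31))).partition
            for _ in range(reps)
        ]
        if all(partitions_equal(parts[0], p) for p in parts[1:]):
            return canonical_partition(parts[0])
        d = allegiance_from_partitions(parts).p
    raise ConsensusError(f"consensus did not converge in {max_iter} iterations", d)


def subject_consensus(
    net: WeightedNetwork,
    gamma: float = 1.0,
    n_iter: int = 1000,
    tau: float = 0.5,
    seed: int = 0,
    consensus_reps: int = 100,
    consensus_gamma: float = 1.0,
) -> tuple[np.ndarray, AllegianceMatrix]:
    """Subject-level pipeline: repeated Louvain -> allegiance -> consensus.

    The analysis resolution ``gamma`` applies to the connectivity
    matrix; the consensus re-clustering of the (nonnegative) agreement
    matrix runs at ``consensus_gamma`` = 1, the standard toolbox
    convention, so that agreement blocks are not fragmented at high
    analysis resolutions.
    """
    rng = np.random.default_rng(seed)
    parts = [
        louvain_partition(net, gamma=gamma, seed=int(rng.integers(2**31))).partition
        for _ in range(n_iter)
    ]
    alleg = allegiance_from_partitions(parts, source="subject-iterations")
    cons = consensus_partition(
        alleg, tau=tau, reps=min(consensus_reps, max(n_iter, 1)),
        gamma=consensus_gamma, seed=int(rng.integers(2**31)),
    )
    return cons, alleg


def group_consensus(
    subject_partitions: list[np.ndarray],
    tau: float = 0.5,
    consensus_gamma: float = 1.0,
    seed: int = 0,
    consensus_reps: int = 100,
) -> tuple[np.ndarray, AllegianceMatrix]:
    """Group-level pipeline over subject consensus partitions.

    The across-subject allegiance matrix (fraction of subjects placing a
    region pair in the same community) is consensus-clustered with the
    same procedure and ``tau`` as the subject level.
    """
    alleg = allegiance_from_partitions(subject_partitions, source="group-subjects")
    cons = consensus_partition(
        alleg, tau=tau, reps=consensus_reps, gamma=consensus_gamma, seed=seed
    )
    return cons, alleg


def match_labels(reference: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Relabel ``target`` to maximally overlap ``reference``.

    Solves the optimal assignment on the label contingency table;
    membership structure is unchanged.  Target communities that get no
    reference match keep fresh labels above the reference range.
    """
    reference = np.asarray(reference, int)
    target = np.asarray(target, int)
    if reference.size != target.size:
        raise ValueError("partitions must have equal length")
    ref_labels = np.unique(reference)
    tgt_labels = np.unique(target)
    C = np.zeros((ref_labels.size, tgt_labels.size))
    for a, ra in enumerate(ref_labels):
        for b, tb in enumerate(tgt_labels):
            C[a, b] = np.sum((reference == ra) & (target == tb))
    rows, cols = linear_sum_assignment(-C)
    mapping: dict[int, int] = {}
    for a, b in zip(rows, cols):
        if C[a, b] > 0:
            mapping[tgt_labels[b]] = ref_labels[a]
    fresh = int(max(ref_labels.max(), tgt_labels.max())) + 1
    out = np.empty_like(target)
    for tb in tgt_labels:
        if tb not in mapping:
            mapping[tb] = fresh
            fresh += 1
    for i, lab in enumerate(target):
        out[i] = mapping[lab]
    return out
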