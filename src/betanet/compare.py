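"""Community-level inference: Q_c* selection and allegiance comparisons.

Communities from the group partition are screened by their subject-level
modularity contribution Q_c* (the restriction of the Q* double sums to
node pairs within the community, same normalizers as the full network)
against size-matched random region sets.  Within- and between-community
allegiance differences between conditions are tested with a paired t
statistic whose null distribution comes from Monte-Carlo relabeling of
subject-level condition assignments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .betaseries import WeightedNetwork
from .community import AllegianceMatrix, allegiance_from_partitions

__all__ = [
    "CommunitySet",
    "CommunitySelection",
    "AllegianceComparison",
    "community_qstar_contribution",
    "select_communities",
    "community_allegiance_difference",
    "bh_fdr",
]


@dataclass
class CommunitySet:
    """Map community label -> region index array, from a group partition."""

    communities: dict[int, np.ndarray]
    n_regions: int

    @classmethod
    def from_partition(cls, labels: np.ndarray) -> "CommunitySet":
        labels = np.asarray(labels, int)
        comms = {int(c): np.flatnonzero(labels == c) for c in np.unique(labels)}
        return cls(communities=comms, n_regions=labels.size)

    def is_singleton(self, label: int) -> bool:
        return self.communities[label].size == 1

    def nonsingleton_labels(self) -> list[int]:
        return [c for c, m in self.communities.items() if m.size > 1]


@dataclass
class CommunitySelection:
    labels: list[int]
    observed: np.ndarray
    null_percentile: np.ndarray  # per community, the percentile cutoff of its null
    percentile: float
    selected: np.ndarray  # bool per community

    def selected_labels(self) -> list[int]:
        return [c for c, s in zip(self.labels, self.selected) if s]


@dataclass
class AllegianceComparison:
    """Permutation-test results for every community pair (incl. self-pairs)."""

    table: pd.DataFrame  # community_a, community_b, n_pairs, t, z, p, fdr_significant
    n_perm: int

    def significant(self) -> pd.DataFrame:
        return self.table[self.table.fdr_significant]


def community_qstar_contribution(
    net: WeightedNetwork, labels: np.ndarray, community: np.ndarray, gamma: float
) -> float:
    """Q_c*: the community's additive contribution to Q*.

    Restricts both double sums of the Q* definition to i, j inside
    ``community`` (keeping the full-network normalizers v+ and v+ + v-),
    so that contributions over the communities of any partition sum to
    the partition's Q*.  ``labels`` supplies the sub-structure inside
    the region set: pairs are counted only when co-assigned, which for a
    community of the partition itself means all pairs.
    """
    community = np.asarray(community, int)
    if community.size == 0:
        raise ValueError("community must be non-empty")
    labels = np.asarray(labels, int)
    w = net.w[np.ix_(community, community)]
    sub = labels[community]
    delta = sub[:, None] == sub[None, :]
    wp_full = np.where(net.w > 0, net.w, 0.0)
    wn_full = np.where(net.w < 0, -net.w, 0.0)
    vp, vn = wp_full.sum(), wn_full.sum()
    q = 0.0
    if vp > 0:
        sp = wp_full.sum(axis=1)
        ep = np.outer(sp[community], sp[community]) / vp
        wp = np.where(w > 0, w, 0.0)
        q += ((wp - gamma * ep) * delta).sum() / vp
    if vn > 0:
        sn = wn_full.sum(axis=1)
        en = np.outer(sn[community], sn[community]) / vn
        wn = np.where(w < 0, -w, 0.0)
        q -= ((wn - gamma * en) * delta).sum() / (vp + vn)
    return float(q)


def select_communities(
    nets_by_condition: dict[str, list[WeightedNetwork]],
    group_partition: np.ndarray,
    gamma: float,
    n_null: int = 1000,
    percentile: float = 99.0,
    seed: int = 0,
    condition: str | None = None,
) -> CommunitySelection:
    """Screen communities by subject-level Q_c* against size-matched nulls.

    Observed statistic: mean over subject networks of Q_c* computed on
    the group community's region set.  Null: the same statistic for
    uniformly resampled region sets of the same size (without
    replacement), ``n_null`` draws pooled across subjects.  A community
    is selected when its observed statistic exceeds the ``percentile``
    of its null distribution.
    """
    if n_null < 1:
        raise ValueError("n_null must be >= 1")
    if not 50 < percentile < 100:
        raise ValueError("percentile must be in (50, 100)")
    nets = (
        nets_by_condition[condition]
        if condition is not None
        else [n for c in sorted(nets_by_condition) for n in nets_by_condition[c]]
    )
    cs = CommunitySet.from_partition(group_partition)
    rng = np.random.default_rng(seed)
    n_regions = cs.n_regions
    labels = sorted(cs.communities)
    observed = np.array([
        np.mean([
            community_qstar_contribution(net, group_partition, cs.communities[c], gamma)
            for net in nets
        ])
        for c in labels
    ])
    cutoffs = np.empty(len(labels))
    for idx, c in enumerate(labels):
        size = cs.communities[c].size
        null = np.empty(n_null)
        for k in range(n_null):
            members = rng.choice(n_regions, size=size, replace=False)
            # random sets are scored as one coherent community
            fake_labels = np.zeros(n_regions, int)
            null[k] = np.mean([
                community_qstar_contribution(net, fake_labels, members, gamma)
                for net in nets
            ])
        cutoffs[idx] = np.percentile(null, percentile)
    return CommunitySelection(
        labels=labels,
        observed=observed,
        null_percentile=cutoffs,
        percentile=percentile,
        selected=observed > cutoffs,
    )


def _pair_vectors(
    p: np.ndarray, communities: dict[int, np.ndarray], a: int, b: int
) -> np.ndarray:
    """Below-diagonal allegiance values for a community (self) pair.

    Within pairs (a == b): unordered region pairs inside the community.
    Between pairs: all cross-community region pairs (each once).
    """
    ma, mb = communities[a], communities[b]
    if a == b:
        ii, jj = np.triu_indices(ma.size, k=1)
        return p[ma[ii], ma[jj]]
    return p[np.ix_(ma, mb)].ravel()


def _pair_stat(va: np.ndarray, vb: np.ndarray) -> float:
    """Paired t across conditions; simple difference when only one pair."""
    if va.size == 1:
        return float(va[0] - vb[0])
    d = va - vb
    sd = d.std(ddof=1)
    if sd == 0:
        return np.nan
    return float(d.mean() / (sd / np.sqrt(d.size)))


def community_allegiance_difference(
    subject_partitions_a: list[np.ndarray],
    subject_partitions_b: list[np.ndarray],
    communities: CommunitySet,
    n_perm: int = 50_000,
    seed: int = 0,
    labels: list[int] | None = None,
) -> AllegianceComparison:
    """Monte-Carlo test of condition differences in community allegiance.

    For each community pair, the vector of group-level allegiance values
    (within- or between-community region pairs, below the diagonal) is
    compared between conditions with a paired t statistic.  The null
    distribution is built by independently swapping each subject's
    condition labels with probability 1/2, rebuilding both group
    allegiance matrices, and recomputing the statistics; z-scores are
    (T_true - mu_null) / sd_null and two-tailed p-values use the add-one
    convention.  Identical matrices (zero-variance differences) return
    z = 0, p = 1 with a warning.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if len(subject_partitions_a) != len(subject_partitions_b):
        raise ValueError("conditions must share the same subjects")
    n_subj = len(subject_partitions_a)
    rng = np.random.default_rng(seed)
    pa = allegiance_from_partitions(subject_partitions_a, source="group-subjects").p
    pb = allegiance_from_partitions(subject_partitions_b, source="group-subjects").p
    labels = labels if labels is not None else sorted(communities.communities)
    pairs = [(a, b) for i, a in enumerate(labels) for b in labels[i:]]

    t_true = np.array([
        _pair_stat(_pair_vectors(pa, communities.communities, a, b),
                   _pair_vectors(pb, communities.communities, a, b))
        for a, b in pairs
    ])

    null = np.empty((n_perm, len(pairs)))
    stack_a = np.asarray(subject_partitions_a)
    stack_b = np.asarray(subject_partitions_b)
    for k in range(n_perm):
        swap = rng.random(n_subj) < 0.5
        na = np.where(swap[:, None], stack_b, stack_a)
        nb = np.where(swap[:, None], stack_a, stack_b)
        qa = allegiance_from_partitions(list(na)).p
        qb = allegiance_from_partitions(list(nb)).p
        for j, (a, b) in enumerate(pairs):
            null[k, j] = _pair_stat(_pair_vectors(qa, communities.communities, a, b),
                                    _pair_vectors(qb, communities.communities, a, b))

    rows = []
    degenerate = False
    for j, (a, b) in enumerate(pairs):
        tj = t_true[j]
        nj = null[:, j]
        nj = nj[np.isfinite(nj)]
        if not np.isfinite(tj) or nj.size == 0 or nj.std(ddof=1) == 0:
            degenerate = True
            z, p = 0.0, 1.0
            tj = 0.0 if not np.isfinite(tj) else tj
        else:
            z = (tj - nj.mean()) / nj.std(ddof=1)
            p = (np.sum(np.abs(nj) >= abs(tj)) + 1) / (nj.size + 1)
        na_, nb_ = communities.communities[a].size, communities.communities[b].size
        n_pairs = na_ * (na_ - 1) // 2 if a == b else na_ * nb_
        rows.append({"community_a": a, "community_b": b, "n_pairs": n_pairs,
                     "t": tj, "z": z, "p": p})
    if degenerate:
        warnings.warn("zero-variance allegiance differences; z = 0, p = 1 reported")
    table = pd.DataFrame(rows)
    table["fdr_significant"] = bh_fdr(table.p.to_numpy(), q=0.05)
    return AllegianceComparison(table=table, n_perm=n_perm)


def bh_fdr(pvals: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up significance flags at level q."""
    pvals = np.asarray(pvals, float)
    if np.any((pvals < 0) | (pvals > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, *_ = multipletests(pvals, alpha=q, method="fdr_bh")
    return reject
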