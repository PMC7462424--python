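"""Region-level allegiance-profile inference across the resolution sweep.

A region's allegiance profile is its row of the group allegiance matrix
(self entry excluded).  Between-condition dissimilarity is the negated
Fisher Z of the Pearson correlation between the two profiles (larger =
more dissimilar).  Significance per region and gamma step comes from
Monte-Carlo reshuffling of subject condition labels; per-region counts
of significant steps are modeled with a negative-binomial distribution,
and regions whose counts exceed the fitted tail (by a combined QQ
residual and tail-probability rule) are flagged as outliers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .betaseries import FISHER_R_CLAMP
from .community import allegiance_from_partitions

__all__ = [
    "DissimilarityProfile",
    "NegativeBinomialFit",
    "OutlierResult",
    "profile_dissimilarity",
    "region_sweep",
    "fit_negative_binomial",
    "detect_outlier_regions",
]


@dataclass
class DissimilarityProfile:
    gammas: np.ndarray
    observed: np.ndarray  # regions x gammas (NaN where undefined)
    z: np.ndarray
    p: np.ndarray  # one-tailed
    counts: np.ndarray  # per region, steps with p < alpha
    alpha: float


@dataclass
class NegativeBinomialFit:
    """Fitted count distribution: NB(r, p) or its Poisson boundary fallback."""

    r: float  # size / dispersion parameter (inf => Poisson fallback)
    p: float  # success probability
    mean: float
    kind: str  # "nbinom" | "poisson" | "degenerate"

    @property
    def dist(self):
        if self.kind == "nbinom":
            return stats.nbinom(self.r, self.p)
        if self.kind == "poisson":
            return stats.poisson(self.mean)
        return stats.randint(int(self.mean), int(self.mean) + 1)  # point mass

    def ppf(self, q):
        return self.dist.ppf(q)

    def sf_at_or_above(self, count):
        """Upper-tail probability P(X >= count)."""
        return self.dist.sf(np.asarray(count) - 1)


@dataclass
class OutlierResult:
    counts: np.ndarray
    p_obs: np.ndarray
    qq_observed: np.ndarray  # sorted counts
    qq_fitted: np.ndarray  # fitted quantiles at plotting positions
    qq_residual_by_region: np.ndarray
    flagged: np.ndarray  # bool per region


def profile_dissimilarity(pa: np.ndarray, pb: np.ndarray, region: int) -> float:
    """Negated Fisher Z of the correlation of one region's allegiance profile.

    The region's row is correlated across the two group allegiance
    matrices, excluding the self entry; identical profiles give the
    clamped minimum (most similar), zero correlation gives 0.  Returns
    NaN when either profile has zero variance (dissimilarity undefined).
    """
    pa = np.asarray(pa, float)
    pb = np.asarray(pb, float)
    if pa.shape != pb.shape:
        raise ValueError("allegiance matrices must share dimensions")
    mask = np.ones(pa.shape[0], dtype=bool)
    mask[region] = False
    va, vb = pa[region, mask], pb[region, mask]
    if va.std() == 0 or vb.std() == 0:
        return np.nan
    r = np.clip(np.corrcoef(va, vb)[0, 1], -FISHER_R_CLAMP, FISHER_R_CLAMP)
    return float(-np.arctanh(r))


def _all_dissimilarities(pa: np.ndarray, pb: np.ndarray) -> np.ndarray:
    """Vectorized per-region profile dissimilarities (diagonal excluded)."""
    n = pa.shape[0]
    off = ~np.eye(n, dtype=bool)
    A = pa[off].reshape(n, n - 1)
    B = pb[off].reshape(n, n - 1)
    A = A - A.mean(axis=1, keepdims=True)
    B = B - B.mean(axis=1, keepdims=True)
    sa = np.sqrt((A * A).sum(axis=1))
    sb = np.sqrt((B * B).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (A * B).sum(axis=1) / (sa * sb)
    r = np.where((sa == 0) | (sb == 0), np.nan, r)
    r = np.clip(r, -FISHER_R_CLAMP, FISHER_R_CLAMP)
    return -np.arctanh(r)


def region_sweep(
    partitions_by_condition_gamma: dict[str, list[list[np.ndarray]]],
    gammas: np.ndarray,
    n_perm: int = 10_000,
    alpha: float = 0.05,
    seed: int = 0,
) -> DissimilarityProfile:
    """Dissimilarity z / p per region at every gamma, plus significance counts.

    ``partitions_by_condition_gamma[cond][gi]`` holds the subject-level
    partitions for that condition at grid step ``gi``.  The null at each
    step swaps each subject's condition labels with probability 1/2 and
    rebuilds both group allegiance matrices; the one-tailed p (add-one
    convention) tests for greater-than-null dissimilarity.  Undefined
    dissimilarities (zero-variance profiles) are excluded from counts.
    """
    conds = sorted(partitions_by_condition_gamma)
    if len(conds) != 2:
        raise ValueError("exactly two conditions required")
    ca, cb = conds
    gammas = np.asarray(gammas, float)
    rng = np.random.default_rng(seed)
    n_regions = len(partitions_by_condition_gamma[ca][0][0])
    n_steps = gammas.size
    observed = np.full((n_regions, n_steps), np.nan)
    zs = np.full((n_regions, n_steps), np.nan)
    ps = np.full((n_regions, n_steps), np.nan)
    for gi in range(n_steps):
        parts_a = np.asarray(partitions_by_condition_gamma[ca][gi])
        parts_b = np.asarray(partitions_by_condition_gamma[cb][gi])
        n_subj = parts_a.shape[0]
        # per-subject co-assignment matrices; any relabeling null is a
        # weighted average over these, so they are built once per step
        coa = (parts_a[:, :, None] == parts_a[:, None, :]).astype(float)
        cob = (parts_b[:, :, None] == parts_b[:, None, :]).astype(float)
        ca_flat = coa.reshape(n_subj, -1)
        cb_flat = cob.reshape(n_subj, -1)
        pa = coa.mean(axis=0)
        pb = cob.mean(axis=0)
        obs = _all_dissimilarities(pa, pb)
        swaps = (rng.random((n_perm, n_subj)) < 0.5).astype(float)
        qa_all = ((1 - swaps) @ ca_flat + swaps @ cb_flat) / n_subj
        qb_all = (swaps @ ca_flat + (1 - swaps) @ cb_flat) / n_subj
        null = np.empty((n_perm, n_regions))
        for k in range(n_perm):
            null[k] = _all_dissimilarities(
                qa_all[k].reshape(n_regions, n_regions),
                qb_all[k].reshape(n_regions, n_regions),
            )
        observed[:, gi] = obs
        with np.errstate(invalid="ignore"):
            mu = np.nanmean(null, axis=0)
            sd = np.nanstd(null, axis=0, ddof=1)
        for i in range(n_regions):
            if not np.isfinite(obs[i]):
                continue
            col = null[:, i]
            col = col[np.isfinite(col)]
            if col.size == 0 or sd[i] == 0:
                continue
            zs[i, gi] = (obs[i] - mu[i]) / sd[i]
            ps[i, gi] = (np.sum(col >= obs[i]) + 1) / (col.size + 1)
    counts = np.nansum(ps < alpha, axis=1).astype(int)
    return DissimilarityProfile(
        gammas=gammas, observed=observed, z=zs, p=ps, counts=counts, alpha=alpha
    )


def fit_negative_binomial(counts: np.ndarray) -> NegativeBinomialFit:
    """Maximum-likelihood negative-binomial fit to nonnegative counts.

    Parameterized by size ``r`` and success probability ``p`` with mean
    r (1-p)/p.  When the sample is not overdispersed (variance <= mean,
    the boundary of the NB family) the fit falls back to Poisson; an
    all-constant sample returns a degenerate point mass with a warning.
    """
    counts = np.asarray(counts)
    if counts.size < 10:
        raise ValueError("need at least 10 counts")
    if np.any(counts < 0) or not np.allclose(counts, np.round(counts)):
        raise ValueError("counts must be nonnegative integers")
    counts = counts.astype(int)
    mean = counts.mean()
    var = counts.var(ddof=1)
    if var == 0 or mean == 0:
        warnings.warn("degenerate count sample; returning point mass")
        return NegativeBinomialFit(r=np.inf, p=1.0, mean=mean, kind="degenerate")
    if var <= mean:
        return NegativeBinomialFit(r=np.inf, p=1.0, mean=mean, kind="poisson")

    def nll(log_r: float) -> float:
        r = np.exp(log_r)
        p = r / (r + mean)  # profile out the mean
        return -stats.nbinom.logpmf(counts, r, p).sum()

    r0 = mean**2 / (var - mean)  # method-of-moments start
    lo, hi = np.log(r0) - 8, np.log(r0) + 8
    res = optimize.minimize_scalar(nll, bounds=(lo, hi), method="bounded",
                                   options={"xatol": 1e-8})
    r = float(np.exp(res.x))
    p = r / (r + mean)
    return NegativeBinomialFit(r=r, p=p, mean=float(mean), kind="nbinom")


def detect_outlier_regions(
    counts: np.ndarray,
    fit: NegativeBinomialFit,
    iqr_multiplier: float = 2.0,
    p_obs_level: float = 0.05,
) -> OutlierResult:
    """Flag regions whose counts exceed the fitted distribution's tail.

    ``p_obs`` is P(X >= count) under the fit.  QQ residuals compare
    sorted observed counts to fitted quantiles at Hazen plotting
    positions (i - 0.5)/n; a region is flagged when its QQ residual
    exceeds ``iqr_multiplier`` times the interquartile range of all
    residuals AND its p_obs is below ``p_obs_level``.
    """
    counts = np.asarray(counts, int)
    n = counts.size
    p_obs = np.asarray(fit.sf_at_or_above(counts), float)
    order = np.argsort(counts, kind="stable")
    positions = (np.arange(1, n + 1) - 0.5) / n
    fitted_q = np.asarray(fit.ppf(positions), float)
    sorted_counts = counts[order].astype(float)
    residual_sorted = sorted_counts - fitted_q
    residual = np.empty(n)
    residual[order] = residual_sorted
    iqr = np.subtract(*np.percentile(residual, [75, 25]))
    threshold = iqr_multiplier * iqr if iqr > 0 else iqr_multiplier * 1.0
    flagged = (residual > threshold) & (p_obs < p_obs_level)
    return OutlierResult(
        counts=counts,
        p_obs=p_obs,
        qq_observed=sorted_counts,
        qq_fitted=fitted_q,
        qq_residual_by_region=residual,
        flagged=flagged,
    )
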