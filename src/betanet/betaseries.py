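"""Trial-level beta-series estimation and Fisher-z connectivity.

Implements the least-squares-separate (LS-S) scheme: one GLM per trial
with a regressor for the trial of interest plus a single combined
regressor for all other trials, optional nuisance covariates and an
intercept.  Censored volumes are removed from each trial GLM by row
deletion.  Trials whose response span contains two or more censored
volumes are scrubbed (their betas dropped before correlation).  Betas
are normalized per region within condition, correlated across retained
trials, Fisher-Z transformed and scaled by sqrt(N - 3) into z-scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .design import TrialDesign
from .hrf import stick_regressors

__all__ = [
    "BetaSeries",
    "WeightedNetwork",
    "build_lss_design",
    "estimate_beta_series",
    "scrub_trials",
    "normalize_within_condition",
    "compute_connectivity",
    "FISHER_R_CLAMP",
]

#: |r| is clamped to this before atanh to keep Fisher Z finite
FISHER_R_CLAMP = 1.0 - 1e-12


@dataclass
class BetaSeries:
    """Per-subject trial-level activation estimates for one condition set.

    ``betas`` is regions x trials over *all* trials of the design;
    ``condition`` maps each trial column to its condition; ``retained``
    flags trials that survived estimation and scrubbing.  Betas of
    non-retained trials may be NaN.
    """

    betas: np.ndarray  # regions x trials
    condition: np.ndarray  # per-trial condition label
    retained: np.ndarray  # per-trial bool

    def __post_init__(self) -> None:
        self.retained = np.asarray(self.retained, dtype=bool)
        self.condition = np.asarray(self.condition)

    @property
    def n_regions(self) -> int:
        return self.betas.shape[0]

    def n_retained(self, condition: str) -> int:
        return int(np.sum(self.retained & (self.condition == condition)))

    def retained_betas(self, condition: str) -> np.ndarray:
        """Regions x retained-trials matrix for one condition."""
        cols = self.retained & (self.condition == condition)
        return self.betas[:, cols]

    def copy(self) -> "BetaSeries":
        return BetaSeries(self.betas.copy(), self.condition.copy(), self.retained.copy())


@dataclass
class WeightedNetwork:
    """Symmetric signed connectivity matrix in Fisher z-score units."""

    w: np.ndarray
    n_obs: int = 0

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        if self.w.ndim != 2 or self.w.shape[0] != self.w.shape[1]:
            raise ValueError("connectivity matrix must be square")
        if not np.allclose(self.w, self.w.T, atol=1e-8):
            raise ValueError("connectivity matrix must be symmetric")
        if not np.all(np.isfinite(self.w)):
            raise ValueError("connectivity matrix must be finite")
        np.fill_diagonal(self.w, 0.0)

    @property
    def n_regions(self) -> int:
        return self.w.shape[0]


def build_lss_design(
    design: TrialDesign,
    trial_index: int,
    hrf_kw: dict | None = None,
    nuisance: np.ndarray | None = None,
) -> np.ndarray:
    """LS-S design matrix for one trial.

    Columns: [trial-of-interest regressor, combined all-other-trials
    regressor (if any), nuisance columns (if any), intercept]; one row
    per volume.
    """
    if not 0 <= trial_index < design.n_trials:
        raise IndexError(f"trial_index {trial_index} out of range")
    hrf_kw = hrf_kw or {}
    X = stick_regressors(design.onsets(), design.tr, design.n_volumes, **hrf_kw)
    cols = [X[:, trial_index]]
    others = np.delete(X, trial_index, axis=1)
    if others.shape[1]:
        cols.append(others.sum(axis=1))
    if nuisance is not None:
        nuisance = np.atleast_2d(np.asarray(nuisance, float))
        if nuisance.shape[0] != design.n_volumes:
            nuisance = nuisance.T
        for col in nuisance.T:
            if np.any(col != 0):  # all-zero covariates carry no information
                cols.append(col)
    cols.append(np.ones(design.n_volumes))
    return np.column_stack(cols)


def estimate_beta_series(
    timeseries: np.ndarray,
    design: TrialDesign,
    censor: np.ndarray | None = None,
    hrf_kw: dict | None = None,
    nuisance: np.ndarray | None = None,
) -> BetaSeries:
    """LS-S betas for every trial and region.

    For each trial: build the LS-S design, delete censored rows, solve
    ordinary least squares, and keep the trial-of-interest coefficient
    per region.  Rank-deficient trial designs (e.g. a fully censored
    trial) yield missing (NaN) betas, flagged as not retained.
    """
    ts = np.asarray(timeseries, dtype=float)
    if ts.shape[0] != design.n_volumes:
        raise ValueError(
            f"timeseries has {ts.shape[0]} rows, design expects {design.n_volumes}"
        )
    if censor is None:
        censor = np.ones(design.n_volumes, dtype=int)
    keep = np.asarray(censor, dtype=bool)
    if keep.size != design.n_volumes:
        raise ValueError("censor mask length must equal n_volumes")

    n_trials, n_regions = design.n_trials, ts.shape[1]
    betas = np.full((n_regions, n_trials), np.nan)
    ok = np.zeros(n_trials, dtype=bool)
    for t in range(n_trials):
        X = build_lss_design(design, t, hrf_kw=hrf_kw, nuisance=nuisance)[keep]
        # trial regressor must carry signal inside the retained rows
        if X.shape[0] < X.shape[1] or np.linalg.matrix_rank(X) < X.shape[1]:
            continue
        coef, *_ = np.linalg.lstsq(X, ts[keep], rcond=None)
        betas[:, t] = coef[0]
        ok[t] = True
    return BetaSeries(betas=betas, condition=design.conditions(), retained=ok)


def scrub_trials(
    bs: BetaSeries,
    design: TrialDesign,
    censor: np.ndarray,
    max_censored: int = 2,
) -> BetaSeries:
    """Drop trials whose response span contains >= ``max_censored`` censored volumes."""
    keep = np.asarray(censor, dtype=bool)
    out = bs.copy()
    for t in range(design.n_trials):
        start, stop = design.response_span(t)
        if np.sum(~keep[start:stop]) >= max_censored:
            out.retained[t] = False
    return out


def normalize_within_condition(bs: BetaSeries, ddof: int = 0) -> BetaSeries:
    """Center and scale each region's retained betas within each condition.

    Uses the population SD (``ddof=0``) by convention, configurable.
    Raises on a zero-variance region (degenerate input).
    """
    out = bs.copy()
    for cond in np.unique(bs.condition):
        cols = bs.retained & (bs.condition == cond)
        if cols.sum() < 2:
            raise ValueError(f"need >= 2 retained trials in condition {cond!r}")
        block = out.betas[:, cols]
        mu = block.mean(axis=1, keepdims=True)
        sd = block.std(axis=1, ddof=ddof, keepdims=True)
        dead = np.flatnonzero(sd.ravel() == 0)
        if dead.size:
            raise ValueError(
                f"zero-variance beta series in condition {cond!r} for region(s) {dead.tolist()}"
            )
        out.betas[:, cols] = (block - mu) / sd
    return out


def fisher_z(r: np.ndarray, n_obs: int) -> np.ndarray:
    """Fisher transform with clamping, scaled to z-scores by sqrt(N - 3)."""
    r = np.clip(np.asarray(r, float), -FISHER_R_CLAMP, FISHER_R_CLAMP)
    return np.arctanh(r) * np.sqrt(n_obs - 3)


def compute_connectivity(bs: BetaSeries, condition: str, min_trials: int = 5) -> WeightedNetwork:
    """Pairwise beta-series correlation network in Fisher z-score units.

    Pearson r over retained betas of ``condition``, Fisher-Z transformed
    and divided by the standard error 1/sqrt(N-3) where N is the number
    of retained betas; diagonal zeroed.
    """
    block = bs.retained_betas(condition)
    n = block.shape[1]
    if n < min_trials:
        raise ValueError(f"need >= {min_trials} retained trials, got {n}")
    r = np.corrcoef(block)
    if np.any(np.abs(r[~np.eye(r.shape[0], dtype=bool)]) >= FISHER_R_CLAMP):
        warnings.warn("correlations at +/-1 clamped before Fisher transform")
    z = fisher_z(r, n)
    np.fill_diagonal(z, 0.0)
    z = (z + z.T) / 2.0
    return WeightedNetwork(w=z, n_obs=n)
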