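"""Synthetic cohorts with planted community structure.

Stands in for a task-fMRI cohort: per-subject regional trial amplitude
series whose correlation structure follows two planted partitions (one
per task condition, largely shared, with a designated set of regions
changing membership), played out through an HRF on the TR grid with
volume noise and i.i.d. motion censoring.

The trial-amplitude generative model is a one-factor-per-community
model.  For a trial of a given condition, with that condition's planted
partition, region i's amplitude is

    x_i = sqrt(rho_w) * u_{c(i)} + sqrt(1 - rho_w) * eps_i,
    u_c  = sqrt(a) * g + sqrt(1 - a) * h_c,      a = rho_b / rho_w,

with g, h_c, eps_i independent standard normals, so the expected
trial-level correlation is rho_w within a community and rho_b between
communities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .design import TrialDesign
from .hrf import stick_regressors

__all__ = [
    "PlantedModel",
    "SubjectData",
    "SyntheticCohort",
    "generate_cohort",
    "generate_connectivity_cohort",
    "sample_noisy_partitions",
]


@dataclass
class PlantedModel:
    """Ground-truth network model generating a synthetic cohort.

    ``partition_a``/``partition_b`` are the condition-wise community
    label vectors; regions whose labels differ are the planted
    "flexible" set.  ``rho_within``/``rho_between`` are the target
    trial-level correlations, ``sigma_noise`` the volume-level noise SD
    relative to unit-amplitude trial responses, ``censor_rate`` the
    i.i.d. per-volume censoring probability.
    """

    n_regions: int
    partition_a: np.ndarray
    partition_b: np.ndarray
    rho_within: float = 0.6
    rho_between: float = 0.1
    sigma_noise: float = 1.0
    censor_rate: float = 0.04
    n_subjects: int = 33
    seed: int = 0
    effect_scale_by_community: dict[int, float] | None = None
    #: SD of subject-level jitter on atanh-scale correlations (connectivity
    #: fast path) and of per-subject amplitude noise heterogeneity
    subject_sigma: float = 0.0

    def __post_init__(self) -> None:
        self.partition_a = np.asarray(self.partition_a, dtype=int)
        self.partition_b = np.asarray(self.partition_b, dtype=int)
        if len(self.partition_a) != self.n_regions or len(self.partition_b) != self.n_regions:
            raise ValueError("partitions must have length n_regions")
        if not (0 <= self.rho_between < self.rho_within <= 1):
            raise ValueError("require 0 <= rho_between < rho_within <= 1")
        if not (0 <= self.censor_rate < 1):
            raise ValueError("censor_rate must be in [0, 1)")

    @property
    def changed_regions(self) -> np.ndarray:
        """Regions whose community membership differs between conditions."""
        from .community import match_labels

        b_matched = match_labels(self.partition_a, self.partition_b)
        return np.flatnonzero(self.partition_a != b_matched)

    def partition(self, condition: str) -> np.ndarray:
        return self.partition_a if condition == "A" else self.partition_b


@dataclass
class SubjectData:
    roi_timeseries: np.ndarray  # volumes x regions
    censor_mask: np.ndarray  # 1 = keep, 0 = censored
    ground_truth_betas: np.ndarray  # trials x regions
    design: TrialDesign


@dataclass
class SyntheticCohort:
    subjects: list[SubjectData]
    model: PlantedModel
    design: TrialDesign

    def __len__(self) -> int:
        return len(self.subjects)


def _trial_amplitudes(model: PlantedModel, design: TrialDesign,
                      rng: np.random.Generator) -> np.ndarray:
    """Draw the (trials x regions) ground-truth amplitude matrix."""
    rho_w, rho_b = model.rho_within, model.rho_between
    a = rho_b / rho_w if rho_w > 0 else 0.0
    n = model.n_regions
    amps = np.empty((design.n_trials, n))
    for t, trial in enumerate(design.trials):
        labels = model.partition(trial.condition)
        comms = np.unique(labels)
        g = rng.standard_normal()
        h = rng.standard_normal(comms.size)
        u = np.sqrt(a) * g + np.sqrt(1.0 - a) * h
        latent = u[np.searchsorted(comms, labels)]
        eps = rng.standard_normal(n)
        amps[t] = np.sqrt(rho_w) * latent + np.sqrt(1.0 - rho_w) * eps
    return amps


def generate_cohort(design: TrialDesign, model: PlantedModel) -> SyntheticCohort:
    """Simulate per-subject ROI time series from the planted model.

    Each subject draws independent trial amplitudes (the ground-truth
    betas), convolves them with the canonical HRF on the TR grid, adds
    i.i.d. Gaussian volume noise of SD ``sigma_noise``, and draws an
    i.i.d. censor mask at ``censor_rate``.
    """
    rng = np.random.default_rng(model.seed)
    X = stick_regressors(design.onsets(), design.tr, design.n_volumes)
    subjects = []
    for _ in range(model.n_subjects):
        betas = _trial_amplitudes(model, design, rng)
        ts = X @ betas
        if model.sigma_noise > 0:
            ts = ts + model.sigma_noise * rng.standard_normal(ts.shape)
        keep = (rng.random(design.n_volumes) >= model.censor_rate).astype(int)
        subjects.append(SubjectData(ts, keep, betas, design))
    return SyntheticCohort(subjects=subjects, model=model, design=design)


def _block_matrix(labels: np.ndarray, z_within: float, z_between: float,
                  effect_scale: dict[int, float] | None) -> np.ndarray:
    same = labels[:, None] == labels[None, :]
    w = np.where(same, z_within, z_between).astype(float)
    if effect_scale:
        for comm, scale in effect_scale.items():
            members = labels == comm
            block = np.outer(members, members)
            w[block] *= scale
    np.fill_diagonal(w, 0.0)
    return w


def generate_connectivity_cohort(model: PlantedModel, n_obs: int = 80):
    """Directly sample subject connectivity matrices (fast path).

    Bypasses time series: each subject/condition matrix is the planted
    block matrix (within-community weight ``atanh(rho_within)``,
    between ``atanh(rho_between)``, scaled by ``sqrt(n_obs - 3)`` to the
    z-score units of the estimation path) plus symmetric Gaussian noise
    of SD ``sigma_noise``.  Returns ``{condition: [w_subject, ...]}``.
    """
    from .betaseries import WeightedNetwork

    rng = np.random.default_rng(model.seed)
    scale = np.sqrt(max(n_obs - 3, 1))
    out: dict[str, list[WeightedNetwork]] = {"A": [], "B": []}
    for _ in range(model.n_subjects):
        for cond in ("A", "B"):
            labels = model.partition(cond)
            w = _block_matrix(
                labels,
                np.arctanh(model.rho_within) * scale,
                np.arctanh(model.rho_between) * scale,
                model.effect_scale_by_community if cond == "A" else None,
            )
            if model.sigma_noise > 0:
                noise = rng.standard_normal(w.shape) * model.sigma_noise
                noise = (noise + noise.T) / np.sqrt(2.0)
                np.fill_diagonal(noise, 0.0)
                w = w + noise
            out[cond].append(WeightedNetwork(w=w, n_obs=n_obs))
    return out


def sample_condition_partitions(
    labels_a: np.ndarray,
    labels_b: np.ndarray,
    n_subjects: int,
    flip_rate: float,
    penetrance: float = 0.5,
    seed: int = 0,
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Per-subject partition pairs with partially expressed membership change.

    Condition A partitions are noisy copies of ``labels_a``.  For
    condition B, each subject expresses each planted membership change
    (a region where ``labels_b`` differs) with probability
    ``penetrance`` and keeps the condition-A assignment otherwise;
    ``flip_rate`` label noise is then applied to both conditions.  This
    emulates the weak, partially penetrant reconfigurations seen in
    group data, where group allegiance differences emerge from a
    minority of subjects rather than a wholesale relabeling.
    """
    rng = np.random.default_rng(seed)
    labels_a = np.asarray(labels_a, int)
    labels_b = np.asarray(labels_b, int)
    changed = np.flatnonzero(labels_a != labels_b)
    parts_a, parts_b = [], []
    for _ in range(n_subjects):
        base_b = labels_a.copy()
        expressed = changed[rng.random(changed.size) < penetrance]
        base_b[expressed] = labels_b[expressed]
        parts_a.append(_flip_labels(labels_a, flip_rate, rng))
        parts_b.append(_flip_labels(base_b, flip_rate, rng))
    return parts_a, parts_b


def _flip_labels(labels: np.ndarray, flip_rate: float, rng: np.random.Generator) -> np.ndarray:
    comms = np.unique(labels)
    lab = labels.copy()
    for i in np.flatnonzero(rng.random(labels.size) < flip_rate):
        others = comms[comms != lab[i]]
        if others.size:
            lab[i] = rng.choice(others)
    return lab


def sample_noisy_partitions(
    labels: np.ndarray,
    n_samples: int,
    flip_rate: float,
    seed: int,
) -> list[np.ndarray]:
    """Noisy copies of a label vector (each region reassigned w.p. flip_rate).

    A cheap stand-in for subject-level consensus partitions: reassigned
    regions move to a community drawn uniformly from the other labels,
    emulating subject-level sampling noise around a group partition.
    """
    rng = np.random.default_rng(seed)
    labels = np.asarray(labels, dtype=int)
    comms = np.unique(labels)
    out = []
    for _ in range(n_samples):
        lab = labels.copy()
        flips = np.flatnonzero(rng.random(labels.size) < flip_rate)
        for i in flips:
            others = comms[comms != lab[i]]
            if others.size:
                lab[i] = rng.choice(others)
        out.append(lab)
    return out
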