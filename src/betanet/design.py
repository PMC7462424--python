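"""Event-related task designs for a two-condition comparison experiment.

The experiment this package models presents two intermixed stimulus
conditions (here called ``A`` and ``B``) in a single event-related run.
Each trial shows a stimulus drawn from a small set of numerosities for
500 ms, followed by a jittered inter-stimulus interval.  The design is
pseudo-random under run-length constraints: no more than ``max_run``
consecutive trials may share a condition, and none may share a
numerosity more than ``max_run`` in a row.  Numerosity and ISI cells are
counterbalanced across conditions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Trial",
    "TrialDesign",
    "InfeasibleDesignError",
    "generate_task_design",
    "DEFAULT_NUMEROSITIES",
    "DEFAULT_ISI_SET_MS",
]

DEFAULT_NUMEROSITIES = (2, 4, 6, 8)
DEFAULT_ISI_SET_MS = (3300, 4300, 5300, 6300, 7300)

#: seconds a single trial's hemodynamic response is taken to span
RESPONSE_SPAN_S = 13.1

#: stimulus duration in seconds
STIM_DURATION_S = 0.5


class InfeasibleDesignError(RuntimeError):
    """Raised when no constraint-satisfying trial order is found."""


@dataclass(frozen=True)
class Trial:
    index: int
    condition: str  # "A" or "B"
    numerosity: int
    onset: float  # seconds
    duration: float  # seconds
    isi: int  # milliseconds, interval following this trial


@dataclass
class TrialDesign:
    """Ordered event list plus the sampling grid it is played out on."""

    trials: list[Trial]
    tr: float
    n_volumes: int

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def conditions(self) -> np.ndarray:
        return np.array([t.condition for t in self.trials])

    def onsets(self) -> np.ndarray:
        return np.array([t.onset for t in self.trials])

    def trial_indices(self, condition: str) -> np.ndarray:
        return np.array(
            [i for i, t in enumerate(self.trials) if t.condition == condition],
            dtype=int,
        )

    def response_span(self, trial_index: int) -> tuple[int, int]:
        """Half-open volume range [start, stop) covered by a trial's response.

        A trial's response is taken to last ``RESPONSE_SPAN_S`` seconds from
        onset, so it spans ``ceil((onset + 13.1)/TR) - floor(onset/TR)``
        volumes (6 or 7 at TR = 2 s, depending on onset phase).
        """
        onset = self.trials[trial_index].onset
        start = int(np.floor(onset / self.tr))
        stop = int(np.ceil((onset + RESPONSE_SPAN_S) / self.tr))
        return start, min(stop, self.n_volumes)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "index": [t.index for t in self.trials],
                "condition": [t.condition for t in self.trials],
                "numerosity": [t.numerosity for t in self.trials],
                "onset_s": [t.onset for t in self.trials],
                "duration_s": [t.duration for t in self.trials],
                "isi_ms": [t.isi for t in self.trials],
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, tr: float = 2.0, n_volumes: int | None = None) -> "TrialDesign":
        df = pd.read_csv(path, sep="\t")
        trials = [
            Trial(int(r["index"]), str(r["condition"]), int(r["numerosity"]),
                  float(r["onset_s"]), float(r["duration_s"]), int(r["isi_ms"]))
            for r in df.to_dict("records")
        ]
        if n_volumes is None:
            last = trials[-1].onset
            n_volumes = int(np.ceil((last + RESPONSE_SPAN_S) / tr)) + 2
        return cls(trials=trials, tr=tr, n_volumes=n_volumes)


def max_run_length(values: Sequence) -> int:
    """Longest run of consecutive identical values."""
    best = run = 0
    prev = object()
    for v in values:
        run = run + 1 if v == prev else 1
        prev = v
        best = max(best, run)
    return best


def _build_tokens(
    n_per_condition: int,
    numerosities: Sequence[int],
    isi_set: Sequence[int],
    rng: np.random.Generator,
) -> list[tuple[str, int, int]]:
    """Counterbalanced (condition, numerosity, isi) multiset.

    Every (condition, numerosity) cell gets n_per_condition/|numerosities|
    trials; ISIs are spread over each cell as evenly as possible (exactly
    even whenever the cell count divides by |isi_set|, as with defaults).
    """
    per_cell = n_per_condition // len(numerosities)
    tokens: list[tuple[str, int, int]] = []
    for cond in ("A", "B"):
        for num in numerosities:
            reps, rem = divmod(per_cell, len(isi_set))
            isis = list(isi_set) * reps
            if rem:
                # remainder spread differs per cell but stays within the set
                extra = rng.choice(len(isi_set), size=rem, replace=False)
                isis += [isi_set[i] for i in extra]
            for isi in isis:
                tokens.append((cond, num, int(isi)))
    return tokens


def _ordered_attempt(
    tokens: list[tuple[str, int, int]],
    max_run: int,
    rng: np.random.Generator,
) -> list[tuple[str, int, int]] | None:
    """One greedy randomized construction; None on dead end.

    Draws each next trial uniformly from the remaining tokens whose
    condition and numerosity would not extend a run past ``max_run``,
    weighting token types by their remaining multiplicity.
    """
    remaining: dict[tuple[str, int], list[int]] = {}
    for cond, num, isi in tokens:
        remaining.setdefault((cond, num), []).append(isi)
    for isis in remaining.values():
        rng.shuffle(isis)

    order: list[tuple[str, int, int]] = []
    cond_run = num_run = 0
    last_cond: str | None = None
    last_num: int | None = None
    total = len(tokens)
    for _ in range(total):
        keys = [
            k for k, isis in remaining.items()
            if isis
            and not (k[0] == last_cond and cond_run >= max_run)
            and not (k[1] == last_num and num_run >= max_run)
        ]
        if not keys:
            return None
        weights = np.array([len(remaining[k]) for k in keys], dtype=float)
        k = keys[rng.choice(len(keys), p=weights / weights.sum())]
        isi = remaining[k].pop()
        cond, num = k
        cond_run = cond_run + 1 if cond == last_cond else 1
        num_run = num_run + 1 if num == last_num else 1
        last_cond, last_num = cond, num
        order.append((cond, num, isi))
    return order


def generate_task_design(
    n_trials_per_condition: int = 80,
    numerosities: Sequence[int] = DEFAULT_NUMEROSITIES,
    isi_set: Sequence[int] = DEFAULT_ISI_SET_MS,
    tr: float = 2.0,
    max_run: int = 3,
    seed: int = 0,
    lead_in_s: float = 6.0,
    max_attempts: int = 10_000,
) -> TrialDesign:
    """Generate a counterbalanced, run-constrained pseudo-random design.

    Parameters mirror the modeled experiment: 80 trials per condition,
    numerosities {2, 4, 6, 8}, ISIs 3,300-7,300 ms in 1,000-ms steps
    (mean 5,300 ms), no more than ``max_run`` consecutive trials sharing
    a condition or a numerosity.  Generation is by constrained random
    construction with restarts, capped at ``max_attempts``.

    Raises
    ------
    InfeasibleDesignError
        If no valid order is found within ``max_attempts`` restarts.
    ValueError
        If the trial count does not divide evenly over numerosities.
    """
    if not isi_set:
        raise ValueError("isi_set must be non-empty")
    if n_trials_per_condition % len(numerosities):
        raise ValueError(
            "n_trials_per_condition must be divisible by the number of numerosities"
        )
    if max_run < 1:
        raise ValueError("max_run must be >= 1")
    rng = np.random.default_rng(seed)
    tokens = _build_tokens(n_trials_per_condition, list(numerosities), list(isi_set), rng)

    order = None
    for _ in range(max_attempts):
        order = _ordered_attempt(tokens, max_run, rng)
        if order is not None:
            break
    if order is None:
        raise InfeasibleDesignError(
            f"no constraint-satisfying order found in {max_attempts} attempts "
            f"(max_run={max_run}, {len(tokens)} trials)"
        )

    trials = []
    onset = lead_in_s
    for i, (cond, num, isi) in enumerate(order):
        trials.append(Trial(i, cond, num, round(onset, 6), STIM_DURATION_S, isi))
        onset += STIM_DURATION_S + isi / 1000.0

    last = trials[-1].onset
    n_volumes = int(np.ceil((last + RESPONSE_SPAN_S) / tr)) + 2
    return TrialDesign(trials=trials, tr=tr, n_volumes=n_volumes)
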