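"""Delimited-text I/O for matrices, partitions, and configuration."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "write_matrix",
    "read_matrix",
    "write_partition",
    "read_partition",
    "write_cohort",
    "write_beta_series",
    "read_beta_series",
    "check_region_ids",
    "load_config",
    "save_config",
]

SYMMETRY_TOL = 1e-8


def _region_ids(n: int) -> list[str]:
    return [f"r{i:03d}" for i in range(n)]


def write_matrix(path, matrix: np.ndarray, region_ids: list[str] | None = None) -> None:
    """Square TSV with a region-id header row and column."""
    matrix = np.asarray(matrix, float)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValueError(f"matrix must be square, got shape {matrix.shape}")
    ids = region_ids or _region_ids(matrix.shape[0])
    pd.DataFrame(matrix, index=ids, columns=ids).to_csv(path, sep="\t")


def read_matrix(path, require_symmetric: bool = True) -> tuple[np.ndarray, list[str]]:
    """Read a square TSV matrix; checks finiteness and symmetry."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[0] != df.shape[1]:
        raise ValueError(f"matrix in {path} is not square: {df.shape[0]} x {df.shape[1]}")
    m = df.to_numpy(dtype=float)
    if np.any(~np.isfinite(m)):
        raise ValueError(f"matrix in {path} contains non-finite entries")
    if require_symmetric and not np.allclose(m, m.T, atol=SYMMETRY_TOL):
        raise ValueError(f"matrix in {path} is asymmetric beyond {SYMMETRY_TOL}")
    return m, list(df.index.astype(str))


def write_partition(path, labels: np.ndarray, region_ids: list[str] | None = None) -> None:
    labels = np.asarray(labels, int)
    ids = region_ids or _region_ids(labels.size)
    pd.DataFrame({"region_id": ids, "community": labels}).to_csv(path, sep="\t", index=False)


def read_partition(path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t")
    return df["community"].to_numpy(int), list(df["region_id"].astype(str))


def write_cohort(directory, cohort) -> None:
    """One volumes-x-regions TSV per subject plus a censor-mask TSV each."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    ids = _region_ids(cohort.subjects[0].roi_timeseries.shape[1])
    for i, subj in enumerate(cohort.subjects):
        pd.DataFrame(subj.roi_timeseries, columns=ids).to_csv(
            directory / f"timeseries_s{i:02d}.tsv", sep="\t", index=False
        )
        pd.DataFrame({"keep": subj.censor_mask}).to_csv(
            directory / f"censor_s{i:02d}.tsv", sep="\t", index=False
        )


def write_beta_series(path, bs, region_ids: list[str] | None = None) -> None:
    """Long-format TSV: one row per trial with condition and retained flag."""
    ids = region_ids or _region_ids(bs.betas.shape[0])
    df = pd.DataFrame(bs.betas.T, columns=ids)
    df.insert(0, "retained", bs.retained.astype(int))
    df.insert(0, "condition", bs.condition)
    df.insert(0, "trial", np.arange(bs.betas.shape[1]))
    df.to_csv(path, sep="\t", index=False)


def read_beta_series(path):
    from .betaseries import BetaSeries

    df = pd.read_csv(path, sep="\t")
    meta = ["trial", "condition", "retained"]
    ids = [c for c in df.columns if c not in meta]
    return BetaSeries(
        betas=df[ids].to_numpy(float).T,
        condition=df["condition"].to_numpy(),
        retained=df["retained"].to_numpy(bool),
    ), ids


def check_region_ids(ids_by_file: dict[str, list[str]]) -> list[str]:
    """Assert all files agree on region ids; returns the shared list."""
    items = list(ids_by_file.items())
    ref_name, ref = items[0]
    for name, ids in items[1:]:
        if ids != ref:
            raise ValueError(
                f"region-id mismatch between {ref_name} and {name}: "
                f"{ref[:3]}... vs {ids[:3]}..."
            )
    return ref


def load_config(path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        return yaml.safe_load(text)
    return json.loads(text)


def save_config(path, config: dict) -> None:
    path = Path(path)
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(config, sort_keys=True))
    else:
        path.write_text(json.dumps(config, indent=2, sort_keys=True))
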