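"""End-to-end orchestration of the synthetic connectivity analysis.

``run_pipeline`` executes simulate -> betas -> connect -> sweep ->
select-gamma -> partition -> communities -> compare -> regions on a
single configuration dictionary, writing delimited-text outputs and a
JSON/Markdown run report.  Every stochastic stage draws from its own
explicitly configured seed, so a run is a pure function of the
configuration: identical configs give bit-identical reports.
"""

from __future__ import annotations

import copy
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .betaseries import (
    compute_connectivity,
    estimate_beta_series,
    normalize_within_condition,
    scrub_trials,
)
from .community import group_consensus, subject_consensus
from .compare import CommunitySet, community_allegiance_difference, select_communities
from .design import generate_task_design
from .io import save_config, write_matrix, write_partition
from .regions import detect_outlier_regions, fit_negative_binomial, region_sweep
from .simulate import PlantedModel, generate_cohort
from .sweep import GammaGrid, run_group_sweep, select_gamma, vi_stability_curve

__all__ = ["DEFAULT_CONFIG", "make_config", "config_hash", "run_pipeline", "RunReport"]

STAGE_SEEDS = ("simulate", "sweep", "partition", "communities", "compare", "regions")

DEFAULT_CONFIG: dict = {
    "out_dir": "results/pipeline",
    "design": {
        "n_trials_per_condition": 80,
        "numerosities": [2, 4, 6, 8],
        "isi_set_ms": [3300, 4300, 5300, 6300, 7300],
        "tr": 2.0,
        "max_run": 3,
    },
    "model": {
        "n_regions": 60,
        "n_communities": 5,
        "n_changed_regions": 12,
        "rho_within": 0.6,
        "rho_between": 0.1,
        "sigma_noise": 1.0,
        "censor_rate": 0.04,
        "n_subjects": 20,
    },
    "grid": {"start": 0.2, "stop": 5.0, "step": 0.2},
    "sweep": {"n_repeats": 5, "subject_iters": 25, "vi_window_gamma": None},
    "partition": {"n_iter": 100, "tau": 0.5},
    "communities": {"n_null": 200, "percentile": 99.0},
    "compare": {"n_perm": 1000},
    "regions": {"n_perm": 500, "alpha": 0.05, "subject_iters": 25},
    "seeds": {s: 1000 + i for i, s in enumerate(STAGE_SEEDS)},
}


def make_config(overrides: dict | None = None) -> dict:
    """Deep-merge overrides into defaults and validate."""
    cfg = copy.deepcopy(DEFAULT_CONFIG)

    def merge(dst, src):
        for k, v in src.items():
            if isinstance(v, dict) and isinstance(dst.get(k), dict):
                merge(dst[k], v)
            else:
                dst[k] = v

    if overrides:
        merge(cfg, overrides)
    missing = [s for s in STAGE_SEEDS if cfg.get("seeds", {}).get(s) is None]
    if missing:
        raise ValueError(f"config missing seeds for stages: {missing}")
    return cfg


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, separators=(",", ":")).encode()
    ).hexdigest()


@dataclass
class RunReport:
    config: dict
    config_sha256: str
    version: str
    stages: dict

    def canonical_json(self) -> str:
        return json.dumps(
            {"config_sha256": self.config_sha256, "version": self.version,
             "stages": self.stages},
            sort_keys=True, separators=(",", ":"), default=_jsonable,
        )

    @property
    def report_hash(self) -> str:
        return hashlib.sha256(self.canonical_json().encode()).hexdigest()

    def to_markdown(self) -> str:
        lines = ["# Pipeline run report", "",
                 f"- version: {self.version}",
                 f"- config sha256: `{self.config_sha256}`",
                 f"- report hash: `{self.report_hash}`", ""]
        for name, summary in self.stages.items():
            lines.append(f"## {name}")
            for k, v in summary.items():
                lines.append(f"- {k}: {v}")
            lines.append("")
        return "\n".join(lines)


def _jsonable(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON-serializable: {type(o)}")


def _planted_model(mcfg: dict, n_trials_hint: int, seed: int) -> PlantedModel:
    """Build condition partitions with a designated changed-region set.

    Regions are split as evenly as possible into ``n_communities``;
    condition B moves the first ``n_changed_regions`` regions to the
    cyclically next community.
    """
    n = mcfg["n_regions"]
    k = mcfg["n_communities"]
    base = np.sort(np.arange(n) % k)
    part_b = base.copy()
    changed = np.arange(mcfg["n_changed_regions"])
    part_b[changed] = (base[changed] + 1) % k
    return PlantedModel(
        n_regions=n,
        partition_a=base,
        partition_b=part_b,
        rho_within=mcfg["rho_within"],
        rho_between=mcfg["rho_between"],
        sigma_noise=mcfg["sigma_noise"],
        censor_rate=mcfg["censor_rate"],
        n_subjects=mcfg["n_subjects"],
        seed=seed,
    )


def run_pipeline(
    config: dict | None = None,
    write_outputs: bool = True,
    stop_after: str | None = None,
) -> RunReport:
    """Execute the stages on one configuration; see module docstring.

    ``stop_after`` truncates the run after the named stage ("simulate",
    "connect", "select_gamma", "partition", "communities", "compare");
    the report then covers the stages that ran.
    """
    cfg = make_config(config if isinstance(config, dict) else None)
    out = Path(cfg["out_dir"])
    if write_outputs:
        out.mkdir(parents=True, exist_ok=True)
        save_config(out / "config.json", cfg)
    stages: dict[str, dict] = {}
    seeds = cfg["seeds"]

    def _finish() -> RunReport:
        report = RunReport(
            config=cfg, config_sha256=config_hash(cfg), version=__version__,
            stages=stages,
        )
        if write_outputs:
            (out / "report.json").write_text(report.canonical_json())
            (out / "report.md").write_text(report.to_markdown())
        return report

    # --- simulate ------------------------------------------------------
    dcfg = cfg["design"]
    design = generate_task_design(
        n_trials_per_condition=dcfg["n_trials_per_condition"],
        numerosities=dcfg["numerosities"],
        isi_set=dcfg["isi_set_ms"],
        tr=dcfg["tr"],
        max_run=dcfg["max_run"],
        seed=seeds["simulate"],
    )
    model = _planted_model(cfg["model"], design.n_trials, seeds["simulate"] + 1)
    cohort = generate_cohort(design, model)
    if write_outputs:
        design.to_tsv(out / "design.tsv")
    stages["simulate"] = {
        "n_trials": design.n_trials,
        "n_volumes": design.n_volumes,
        "n_subjects": len(cohort),
        "n_regions": model.n_regions,
        "mean_isi_ms": float(np.mean([t.isi for t in design.trials])),
    }
    if stop_after == "simulate":
        return _finish()

    # --- betas + connect ----------------------------------------------
    nets: dict[str, list] = {"A": [], "B": []}
    retained = {"A": [], "B": []}
    for si, subj in enumerate(cohort.subjects):
        bs = estimate_beta_series(subj.roi_timeseries, design, subj.censor_mask)
        bs = scrub_trials(bs, design, subj.censor_mask)
        bs = normalize_within_condition(bs)
        for cond in ("A", "B"):
            net = compute_connectivity(bs, cond)
            nets[cond].append(net)
            retained[cond].append(bs.n_retained(cond))
            if write_outputs:
                write_matrix(out / f"connectivity_s{si:02d}_{cond}.tsv", net.w)
    stages["betas"] = {
        "mean_retained_A": float(np.mean(retained["A"])),
        "mean_retained_B": float(np.mean(retained["B"])),
    }
    stages["connect"] = {"n_networks": sum(len(v) for v in nets.values())}
    if stop_after in ("betas", "connect"):
        return _finish()

    # --- sweep + select-gamma -----------------------------------------
    grid = GammaGrid(**cfg["grid"])
    swp = run_group_sweep(
        nets, grid,
        n_repeats=cfg["sweep"]["n_repeats"],
        subject_iters=cfg["sweep"]["subject_iters"],
        tau=cfg["partition"]["tau"],
        seed=seeds["sweep"],
    )
    # +/-3 grid steps by default, matching a 0.35 window at step 0.05
    window = cfg["sweep"]["vi_window_gamma"] or 7 * grid.step
    nvi_curve = vi_stability_curve(swp, window_gamma=window)
    gamma_star = select_gamma(swp)
    if write_outputs:
        swp.to_frame().to_csv(out / "sweep_flex_sd.tsv", sep="\t", index=False)
        pd.DataFrame({"gamma": grid.values, "mean_nvi": nvi_curve}).to_csv(
            out / "sweep_nvi.tsv", sep="\t", index=False
        )
    stages["sweep"] = {"n_gammas": len(grid), "n_repeats": swp.n_repeats}
    stages["select_gamma"] = {"gamma_star": gamma_star}
    if stop_after in ("sweep", "select_gamma", "select-gamma"):
        return _finish()

    # --- partition at gamma* ------------------------------------------
    rng = np.random.default_rng(seeds["partition"])
    subj_parts: dict[str, list[np.ndarray]] = {}
    group_parts: dict[str, np.ndarray] = {}
    for cond in ("A", "B"):
        subj_parts[cond] = [
            subject_consensus(
                net, gamma=gamma_star, n_iter=cfg["partition"]["n_iter"],
                tau=cfg["partition"]["tau"], seed=int(rng.integers(2**31)),
            )[0]
            for net in nets[cond]
        ]
        gp, alleg = group_consensus(
            subj_parts[cond], tau=cfg["partition"]["tau"], seed=int(rng.integers(2**31))
        )
        group_parts[cond] = gp
        if write_outputs:
            write_partition(out / f"group_partition_{cond}.tsv", gp)
            write_matrix(out / f"group_allegiance_{cond}.tsv", alleg.p)
    stages["partition"] = {
        cond: {
            "n_communities": int(np.unique(gp).size),
            "n_singletons": int(np.sum(np.bincount(gp) == 1)),
        }
        for cond, gp in group_parts.items()
    }
    if stop_after == "partition":
        return _finish()

    # --- communities (Q_c* selection) ---------------------------------
    selections = {}
    for cond in ("A", "B"):
        sel = select_communities(
            nets, group_parts[cond], gamma_star,
            n_null=cfg["communities"]["n_null"],
            percentile=cfg["communities"]["percentile"],
            seed=seeds["communities"], condition=cond,
        )
        selections[cond] = sel
    stages["communities"] = {
        cond: {"n_selected": int(sel.selected.sum()),
               "selected_labels": sel.selected_labels()}
        for cond, sel in selections.items()
    }
    if stop_after == "communities":
        return _finish()

    # --- compare (allegiance differences) ------------------------------
    compare_tables = {}
    for cond in ("A", "B"):
        labels = [
            c for c in selections[cond].selected_labels()
            if not CommunitySet.from_partition(group_parts[cond]).is_singleton(c)
        ]
        if len(labels) < 1:
            labels = CommunitySet.from_partition(group_parts[cond]).nonsingleton_labels()
        comp = community_allegiance_difference(
            subj_parts["A"], subj_parts["B"],
            CommunitySet.from_partition(group_parts[cond]),
            n_perm=cfg["compare"]["n_perm"], seed=seeds["compare"], labels=labels,
        )
        compare_tables[cond] = comp
        if write_outputs:
            comp.table.to_csv(out / f"allegiance_comparison_{cond}.tsv",
                              sep="\t", index=False)
    stages["compare"] = {
        cond: {
            "n_tests": int(len(comp.table)),
            "n_fdr_significant": int(comp.table.fdr_significant.sum()),
            "max_abs_z": float(comp.table.z.abs().max()),
        }
        for cond, comp in compare_tables.items()
    }
    if stop_after == "compare":
        return _finish()

    # --- regions across the sweep --------------------------------------
    rcfg = cfg["regions"]
    rng = np.random.default_rng(seeds["regions"])
    parts_by_cond_gamma = {"A": [], "B": []}
    for g in grid.values:
        for cond in ("A", "B"):
            parts_by_cond_gamma[cond].append([
                subject_consensus(
                    net, gamma=float(g), n_iter=rcfg["subject_iters"],
                    tau=cfg["partition"]["tau"], seed=int(rng.integers(2**31)),
                )[0]
                for net in nets[cond]
            ])
    prof = region_sweep(
        parts_by_cond_gamma, grid.values,
        n_perm=rcfg["n_perm"], alpha=rcfg["alpha"], seed=seeds["regions"] + 1,
    )
    fit = fit_negative_binomial(prof.counts)
    outliers = detect_outlier_regions(prof.counts, fit)
    if write_outputs:
        pd.DataFrame({
            "region": np.arange(prof.counts.size),
            "count": prof.counts,
            "p_obs": outliers.p_obs,
            "flagged": outliers.flagged,
        }).to_csv(out / "region_counts.tsv", sep="\t", index=False)
    stages["regions"] = {
        "nb_kind": fit.kind,
        "nb_mean": float(fit.mean),
        "n_flagged": int(outliers.flagged.sum()),
        "flagged_regions": np.flatnonzero(outliers.flagged).tolist(),
        "max_count": int(prof.counts.max()),
    }
    return _finish()
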