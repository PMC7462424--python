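# betanet

Task-evoked functional-network topology analysis: from trial-level
beta-series connectivity through signed-modularity consensus clustering,
allegiance-based community and region inference, and data-driven selection
of the structural resolution parameter.

## Who this is for

Researchers comparing whole-brain functional network architecture between
task conditions in event-related fMRI. Instead of asking "how much do two
regions communicate?" (raw connectivity), the pipeline asks "do they
belong to the same functional community?" (allegiance), which is more
robust to noise and to condition differences in raw connectivity strength.
Everything runs end-to-end on synthetic cohorts with planted community
structure, so the whole pipeline is testable without any data download;
user-supplied ROI time series, beta series, or connectivity matrices in
delimited-text form plug into the same stages.

## The model

**Beta-series connectivity.** Per trial, a least-squares-separate (LS-S)
GLM — one regressor for the trial of interest, one combining all other
trials, nuisance covariates, intercept — yields trial-level activation
betas per region. Trials whose response window contains ≥ 2 censored
volumes are scrubbed; betas are normalized per region within condition;
pairwise Pearson correlations over retained betas are Fisher-Z transformed
and scaled by √(N−3) into z-score networks.

**Signed modularity.** Networks are partitioned by a generalized Louvain
algorithm maximizing Q* with asymmetric treatment of negative weights:

    Q* = (1/v⁺) Σᵢⱼ (wᵢⱼ⁺ − γ eᵢⱼ⁺) δ(Mᵢ,Mⱼ) − (1/(v⁺+v⁻)) Σᵢⱼ (wᵢⱼ⁻ − γ eᵢⱼ⁻) δ(Mᵢ,Mⱼ)

with per-sign configuration nulls eᵢⱼ± = sᵢ± sⱼ±/v± and resolution
parameter γ. Subject level: 1,000 Louvain runs → allegiance matrix →
consensus clustering (τ = 0.5); group level: the across-subject allegiance
matrix is consensus-clustered the same way.

**Resolution selection.** γ is swept over 0.05–5.0 (step 0.05); the
working γ* maximizes the across-region SD of between-condition
flexibility — the balance point where some regions change community and
some stay.

**Inference.** Communities are screened by their subject-level modularity
contribution Q_c* against size-matched random-set nulls (99th percentile).
Within/between-community allegiance differences and per-region
allegiance-profile dissimilarities (negated Fisher Z of the profile
correlation) are tested against Monte-Carlo subject-relabeling nulls, with
BH-FDR over community pairs and, at the region level, counts of
significant γ steps modeled by a maximum-likelihood negative binomial with
QQ-based outlier flagging.

## Worked example

The numbered drivers under `analysis/` run each stage on synthetic cohorts
with planted structure and write tables under `results/analysis/`. Drivers
01–02 run the full estimation path (design → time series → LS-S betas →
scrubbing → normalization → connectivity) on a 12-subject, 40-region
cohort:

```
$ python analysis/01_simulate_cohort.py
design: 160 trials over 473 volumes (mean ISI 5300 ms)
cohort: 12 subjects x 40 regions

$ python analysis/02_estimate_connectivity.py
retained trials per condition: A 77.4, B 77.2 of 80
built 24 connectivity matrices -> results/analysis/connectivity_*.tsv
```

The design reproduces the modeled experiment's constants (160 trials, mean
ISI 5,300 ms, no more than 3 consecutive same-condition or same-numerosity
trials); at a 4% censoring rate, ~77 of 80 trials per condition survive
beta-scrubbing. Driver 03 demonstrates resolution selection on a cohort
where half the regions swap community between conditions:

```
$ python analysis/03_resolution_sweep.py
gamma:    0.25  0.50  0.75  1.00  1.25  1.50  1.75  2.00
flex SD:  0.00  0.00  0.51  0.51  0.51  0.51  0.51  0.48
block-separation transition (Q* oracle): gamma = 0.75
selected gamma* = 0.75
```

Below γ = 0.75 the planted blocks merge into one community in both
conditions and flexibility is zero; at the independently computed
block-separation transition the change is expressed and the flexibility SD
jumps to its half-flip maximum, so γ* lands exactly on the transition.
Driver 04 screens planted communities by Q_c* (all four exceed their
random-set nulls) and detects a planted within-community allegiance
increase (self-pair z = +4.67, p = 0.0005, against 2,000 relabelings).
Driver 05 runs the region-level sweep at the study-like geometry (202
regions, 33 subjects, 100 γ steps, five regions changing membership with
partial penetrance):

```
$ python analysis/05_region_profiles.py
count model: nbinom (r = 2.22, mean = 9.82)
planted changed regions: [0, 25, 60, 95, 130]
counts at planted regions: [79, 78, 77, 84, 77] (background max 20)
flagged regions: [0, 25, 60, 95, 130]
```

The five regions flagged as exceeding the negative-binomial tail are
exactly the five planted membership-changing regions.

The same stages are scriptable through a thin CLI
(`betanet simulate|betas|connect|sweep|select-gamma|partition|communities|compare|regions|run`,
with `--config`, `--seed`, `--out`).

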