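"""Shared configuration for the numbered analysis drivers.

A moderate synthetic cohort: 12 subjects, 40 regions in 4 planted
communities, 8 regions changing membership between conditions, default
event-related design (80 trials per condition).  All stages write under
results/analysis/.
"""

ANALYSIS_CONFIG = {
    "out_dir": "results/analysis",
    "model": {
        "n_regions": 40,
        "n_communities": 4,
        "n_changed_regions": 8,
        "rho_within": 0.6,
        "rho_between": 0.1,
        "sigma_noise": 1.0,
        "censor_rate": 0.04,
        "n_subjects": 12,
    },
    "grid": {"start": 0.25, "stop": 5.0, "step": 0.25},
    "sweep": {"n_repeats": 3, "subject_iters": 25},
    "partition": {"n_iter": 200, "tau": 0.5},
    "communities": {"n_null": 500, "percentile": 99.0},
    "compare": {"n_perm": 2000},
    "regions": {"n_perm": 200, "alpha": 0.05, "subject_iters": 25},
    "seeds": {"simulate": 1000, "sweep": 1001, "partition": 1002,
              "communities": 1003, "compare": 1004, "regions": 1005},
}
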