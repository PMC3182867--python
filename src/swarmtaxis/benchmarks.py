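"""Frozen benchmark experiments on the default calibrated configuration.

These are the package's standard study conditions: every function runs the
relevant ensemble from scratch on :func:`swarmtaxis.experiments.default_config`
and returns plain numbers.  The acceptance script and the acceptance tests
both call these, so the reported quantities always come from live simulation.

Ensemble sizes are the package's shipped study sizes: 100 rounds for the
mechanism comparison and the error-fraction estimates, 50 rounds per condition
for the sweeps.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
from scipy.stats import spearmanr

from .experiments import (
    SimulationConfig,
    default_config,
    mechanism_comparison,
    run_ensemble,
    sweep,
)

__all__ = [
    "NOISE_LEVELS",
    "GROUP_SIZES",
    "TAU_RANGE",
    "WEIGHT_SWEEP",
    "mechanism_benchmark",
    "error_fraction_benchmark",
    "weight_sweep_benchmark",
    "noise_benchmark",
    "alignment_benchmark",
    "tau_diversity_benchmark",
]

# internal noise levels (radians/step): default, strong, severe
NOISE_LEVELS = (0.05, 0.4, 0.8)
# group sizes for the size trends: small, default, large
GROUP_SIZES = (10, 40, 120)
# heterogeneous per-agent run lengths, uniform over this (inclusive) range
TAU_RANGE = (1, 48)
# fixed-weight sweep values spanning [0, 1]; 0.92 is the calibrated optimum
WEIGHT_SWEEP = (0.0, 0.15, 0.3, 0.45, 0.6, 0.75, 0.92, 1.0)


def mechanism_benchmark(n_rounds: int = 100, base_seed: int = 0) -> dict:
    """Matched-seed comparison of the three mechanisms on the default config.

    Returns per-mechanism mean error fractions (over uncensored runs), mean
    alignment, censor counts, and the one-sided rank-sum p-values for the
    orderings adaptive < fixed and fixed < independent.
    """
    config = default_config()
    cmp = mechanism_comparison(config, n_rounds, base_seed)
    d = config.straight_line_distance
    out: dict = {"rank_p": {k: v["p"] for k, v in cmp.rank_tests.items()}}
    for mech in ("independent", "fixed", "adaptive"):
        pl = cmp.path_lengths(mech)
        ok = np.isfinite(pl)
        df = cmp.records[cmp.records["mechanism"] == mech]
        out[mech] = {
            "mean_error_fraction": float(np.mean((pl[ok] - d) / d)) if ok.any() else np.nan,
            "median_path_length": float(np.median(pl[ok])) if ok.any() else np.nan,
            "mean_alignment": float(df["alignment"].mean()),
            "mean_weight": float(df["mean_weight"].mean()),
            "mean_n_clusters": float(df["n_clusters"].mean()),
            "n_censored": int((~ok).sum()),
            "n_rounds": int(len(pl)),
        }
    return out


def error_fraction_benchmark(n_rounds: int = 100, base_seed: int = 0) -> dict:
    """Ensemble-mean error fraction for the fixed (at its calibrated optimal
    weight) and adaptive mechanisms, matched seeds."""
    config = default_config()
    out = {}
    for mech in ("fixed", "adaptive"):
        cfg = replace(config, policy=replace(config.policy, mode=mech))
        agg = run_ensemble(cfg, n_rounds, base_seed).aggregate()
        out[mech] = {
            "mean_error_fraction": agg["mean_error_fraction"],
            "se_error_fraction": agg["se_error_fraction"],
            "n_censored": agg["n_censored"],
            "n_rounds": agg["n_rounds"],
        }
    return out


def weight_sweep_benchmark(
    n_rounds: int = 50, base_seed: int = 0, values=WEIGHT_SWEEP
) -> dict:
    """Fixed-weight sweep over [0, 1]: mean path length (censoring-bounded)
    and its standard error per weight value."""
    config = default_config()
    cfg = replace(config, policy=replace(config.policy, mode="fixed"))
    table = {}
    for w in values:
        c = replace(cfg, policy=replace(cfg.policy, fixed_w=float(w)))
        agg = run_ensemble(c, n_rounds, base_seed).aggregate()
        table[float(w)] = {
            "mean_path_length": agg["mean_median_path_length_bounded"],
            "se_path_length": agg["se_median_path_length_bounded"],
            "censor_rate": agg["censor_rate"],
        }
    ws = list(table)
    interior = [w for w in ws[1:-1]]
    w_best = min(interior, key=lambda w: table[w]["mean_path_length"])
    return {"table": table, "w_best": w_best}


def noise_benchmark(n_rounds: int = 50, base_seed: int = 0, levels=NOISE_LEVELS) -> dict:
    """Internal-noise sweep for all three mechanisms.

    Reports the censoring-bounded mean path length, alignment and censor rate
    per (mechanism, noise level), matched seeds across levels.
    """
    config = default_config()
    out: dict = {}
    for mech in ("independent", "fixed", "adaptive"):
        rows = {}
        for eta in levels:
            c = replace(
                config,
                motion=replace(config.motion, internal_noise_sd=float(eta)),
                policy=replace(config.policy, mode=mech),
            )
            agg = run_ensemble(c, n_rounds, base_seed).aggregate()
            rows[float(eta)] = {
                "mean_path_length": agg["mean_median_path_length_bounded"],
                "mean_alignment": agg["mean_alignment"],
                "censor_rate": agg["censor_rate"],
            }
        out[mech] = rows
    return out


def alignment_benchmark(n_rounds: int = 50, base_seed: int = 0, sizes=GROUP_SIZES) -> dict:
    """Group alignment versus group size for the interacting mechanisms,
    with the Spearman correlation of alignment against N."""
    config = default_config()
    out: dict = {}
    for mech in ("fixed", "adaptive"):
        rows = {}
        for n in sizes:
            c = replace(
                config, n_agents=int(n), policy=replace(config.policy, mode=mech)
            )
            agg = run_ensemble(c, n_rounds, base_seed).aggregate()
            rows[int(n)] = agg["mean_alignment"]
        vals = [rows[int(n)] for n in sizes]
        rho = spearmanr(list(sizes), vals).statistic
        out[mech] = {"by_size": rows, "spearman_vs_n": float(rho)}
    return out


def tau_diversity_benchmark(
    n_rounds: int = 100, base_seed: int = 0, tau_range=TAU_RANGE
) -> dict:
    """Heterogeneous run-length experiment: per-agent tau uniform over
    ``tau_range``; reports the fraction of uncensored rounds per mechanism."""
    config = default_config()
    out = {}
    for mech in ("independent", "fixed", "adaptive"):
        c = replace(
            config,
            tau_range=(int(tau_range[0]), int(tau_range[1])),
            policy=replace(config.policy, mode=mech),
        )
        agg = run_ensemble(c, n_rounds, base_seed).aggregate()
        out[mech] = {
            "uncensored_fraction": 1.0 - agg["censor_rate"],
            "mean_error_fraction": agg["mean_error_fraction"],
        }
    return out
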