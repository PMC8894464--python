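"""Seeded benchmark experiments on the synthetic systems.

These are the package's operating-characteristic measurements: causal
direction recovery on the unidirectionally forced logistic pair, false
positive rates on decoupled and linear-stochastic null pairs, and network
recovery on the mock ecosystem. The test-suite and the acceptance script
both run them; they are ordinary library functions so the same numbers are
reproducible from user code.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .io import preprocess_site
from .network import build_site_network, recovery_metrics, standardize_network
from .pipeline import CCMConfig, quantify_link
from .synthetic import (
    add_observation_layer,
    default_observation_spec,
    simulate_ar1,
    simulate_coupled_logistic,
    simulate_mock_ecosystem,
    two_species_spec,
)

__all__ = [
    "benchmark_config",
    "direction_recovery",
    "null_rates",
    "ecosystem_recovery",
    "coupling_strength_profile",
]

ECOSYSTEM_VARS = ("richness", "biomass", "no3", "po4", "temperature")


def benchmark_config(seed: int = 0) -> CCMConfig:
    """Protocol settings for benchmark runs.

    A 12-point library grid with 25 subsamples resolves the convergence
    tests at a fraction of the default cost; the bootstrap SE is skipped
    because the benchmarks score significance only.
    """
    return CCMConfig(n_L=12, n_subsamples=25, compute_se=False, seed=seed)


def _pair_rates(pairs, config) -> tuple[float, float]:
    fwd = rev = 0
    for seed, (x, y) in enumerate(pairs):
        fwd += quantify_link(x, y, config, cause_name="X", effect_name="Y",
                             seed=config.seed + seed).significant
        rev += quantify_link(y, x, config, cause_name="Y", effect_name="X",
                             seed=config.seed + seed).significant
    n = len(pairs)
    return fwd / n, rev / n


def direction_recovery(
    n_seeds: int = 30,
    n_steps: int = 400,
    beta: float = 0.1,
    seed: int = 0,
    config: CCMConfig | None = None,
) -> dict[str, float]:
    """Detection rates on the X-forces-Y logistic benchmark.

    Returns the fraction of seeds in which the true direction X -> Y and the
    absent direction Y -> X are flagged significant.
    """
    config = config or benchmark_config(seed)
    pairs = []
    for i in range(n_seeds):
        data, _ = simulate_coupled_logistic(
            two_species_spec(beta_yx=beta, process_noise_sd=0.005),
            n_steps, seed=seed * 100003 + i,
        )
        pairs.append((data["X"].to_numpy(), data["Y"].to_numpy()))
    fwd, rev = _pair_rates(pairs, config)
    return {"true_direction_rate": fwd, "reverse_direction_rate": rev}


def null_rates(
    n_seeds: int = 30,
    n_steps: int = 400,
    seed: int = 0,
    config: CCMConfig | None = None,
) -> dict[str, float]:
    """Per-direction false-positive rates on two null benchmarks.

    ``decoupled``: independent chaotic logistic maps; ``ar1``: independent
    AR(1) series (phi = 0.5), a linear-stochastic null without an attractor.
    """
    config = config or benchmark_config(seed)
    dec_pairs, ar_pairs = [], []
    for i in range(n_seeds):
        s = seed * 100003 + i
        data, _ = simulate_coupled_logistic(
            two_species_spec(beta_yx=0.0, process_noise_sd=0.005), n_steps, seed=s
        )
        dec_pairs.append((data["X"].to_numpy(), data["Y"].to_numpy()))
        ar_pairs.append(
            (simulate_ar1(n_steps, 0.5, seed=2 * s + 1),
             simulate_ar1(n_steps, 0.5, seed=2 * s + 2))
        )
    d_fwd, d_rev = _pair_rates(dec_pairs, config)
    a_fwd, a_rev = _pair_rates(ar_pairs, config)
    return {
        "decoupled_rate_xy": d_fwd,
        "decoupled_rate_yx": d_rev,
        "ar1_rate_xy": a_fwd,
        "ar1_rate_yx": a_rev,
    }


def ecosystem_recovery(
    n_seeds: int = 30,
    n_years: int = 40,
    seed: int = 0,
    config: CCMConfig | None = None,
) -> dict[str, float]:
    """Network recovery on the mock lake ecosystem with observation layer.

    Returns mean precision and recall of significant links against the
    ground-truth coupling network, and the rate at which links *into* the
    exogenous temperature variable (a structural impossibility) are flagged.
    """
    config = config or benchmark_config(seed)
    precisions, recalls = [], []
    t_flags = t_total = 0
    for i in range(n_seeds):
        s = seed * 100003 + i
        ds = simulate_mock_ecosystem(n_years, seed=s)
        ds = add_observation_layer(ds, default_observation_spec(seed=s + 1))
        processed = preprocess_site(ds.to_monthly_series(), ECOSYSTEM_VARS)
        net = build_site_network(
            processed, list(ECOSYSTEM_VARS),
            replace(config, seed=config.seed + i),
            exogenous={"temperature"}, site=f"seed{i}",
        )
        net = standardize_network(net)
        p, r = recovery_metrics(net, ds.truth)
        precisions.append(p)
        recalls.append(r)
        for (c, e), link in net.links.items():
            if e == "temperature":
                t_total += 1
                t_flags += link.significant
    return {
        "precision": float(np.mean(precisions)),
        "recall": float(np.mean(recalls)),
        "into_temperature_rate": t_flags / t_total,
    }


def coupling_strength_profile(
    betas: tuple[float, ...] = (0.02, 0.05, 0.1, 0.2),
    n_seeds: int = 10,
    n_steps: int = 400,
    seed: int = 0,
    config: CCMConfig | None = None,
) -> dict[float, float]:
    """Median linkage strength of the true direction as coupling grows."""
    config = config or benchmark_config(seed)
    out = {}
    for beta in betas:
        ls = []
        for i in range(n_seeds):
            data, _ = simulate_coupled_logistic(
                two_species_spec(beta_yx=beta, process_noise_sd=0.005),
                n_steps, seed=seed * 100003 + i,
            )
            res = quantify_link(
                data["X"].to_numpy(), data["Y"].to_numpy(), config,
                cause_name="X", effect_name="Y", seed=config.seed + i,
            )
            ls.append(res.LS)
        out[beta] = float(np.median(ls))
    return out
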