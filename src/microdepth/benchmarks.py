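"""Calibration and parameter-recovery benchmarks run on synthetic data.

These routines validate the statistical machinery under the emulated
survey design at desk scale (500 ASVs, libraries of 10k-50k reads):
type-I-error calibration of PERMANOVA and the random-forest permutation
test under null simulations, and recovery of planted depth effects and
correlation modules. Each returns plain floats so the results can be
reported or asserted directly.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .alpha import rf_importance
from .beta import bray_curtis, permanova
from .network import build_cooccurrence_network, detect_modules
from .partition import enrichment_classify
from .simulate import SimulationParams, simulate_dataset

# Desk-scale study conditions used across the benchmarks.
NULL_PARAMS = dict(n_asvs=500, library_size=10_000, depth_effect=0.0,
                   time_effect=0.0, module_strength=0.0, plot_sd=0.0,
                   fertility_link_strength=0.0)
# Power scenario = the null backdrop plus the planted depth effect, so the
# benchmark isolates the effect being detected.
POWER_PARAMS = {**NULL_PARAMS, "depth_effect": 4.0}
ENRICH_PARAMS = dict(n_plots=2, n_times=4, n_asvs=500, library_size=50_000,
                     depth_effect=8.0)
MODULE_PARAMS = dict(n_asvs=500, library_size=10_000)


def _seed_stream(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s) for s in ss.generate_state(n, dtype=np.uint32) % (2**31)]


def permanova_null_rejection_rate(n_replicates: int = 200, alpha: float = 0.05,
                                  n_permutations: int = 99,
                                  seed: int = 0) -> float:
    """Fraction of null simulations (all effects zero) where the layer term
    rejects at ``alpha``; should be ~alpha for a calibrated test."""
    seeds = _seed_stream(seed, 2 * n_replicates)
    rej = 0
    for i in range(n_replicates):
        params = SimulationParams(seed=seeds[2 * i], **NULL_PARAMS)
        table, meta, *_ = simulate_dataset(params)
        d = bray_curtis(table)
        res = permanova(d, meta, "layer + time", n_permutations,
                        seed=seeds[2 * i + 1])
        rej += res.terms[0].p <= alpha
    return rej / n_replicates


def rf_null_rejection_rate(n_datasets: int = 100, n_samples: int = 40,
                           n_predictors: int = 2, alpha: float = 0.05,
                           seed: int = 0) -> float:
    """Fraction of predictor tests rejecting at ``alpha`` when the response
    is independent of every predictor."""
    seeds = _seed_stream(seed, n_datasets)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    total = rej = 0
    cols = [f"x{j}" for j in range(n_predictors)]
    for i in range(n_datasets):
        X = pd.DataFrame(rng.normal(size=(n_samples, n_predictors)),
                         columns=cols)
        y = pd.Series(rng.normal(size=n_samples), index=X.index)
        for r in rf_importance(X, y, n_trees=50, n_response_permutations=19,
                               seed=seeds[i]):
            total += 1
            rej += r.p_value <= alpha
    return rej / total


def rf_signal_recovery_rate(n_seeds: int = 20, n_samples: int = 100,
                            seed: int = 0) -> float:
    """Fraction of seeds where the informative predictor out-ranks the
    noise predictor and reaches P <= 0.05 (response = x1 exactly)."""
    seeds = _seed_stream(seed, n_seeds)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2]))
    ok = 0
    for i in range(n_seeds):
        X = pd.DataFrame(rng.normal(size=(n_samples, 2)), columns=["x1", "x2"])
        y = X["x1"].copy()
        recs = {r.predictor: r
                for r in rf_importance(X, y, n_trees=100,
                                       n_response_permutations=19,
                                       seed=seeds[i])}
        ok += (recs["x1"].importance > recs["x2"].importance
               and recs["x1"].p_value <= 0.05)
    return ok / n_seeds


def permanova_power(n_replicates: int = 50, n_permutations: int = 199,
                    seed: int = 0) -> dict:
    """Layer-term detection under a 4-fold depth shift on 10% of ASVs.

    Returns the fraction of replicates with layer P <= 0.01, the fraction
    where layer r2 exceeds time r2 (time effect absent), and their means.
    """
    seeds = _seed_stream(seed, 2 * n_replicates)
    sig = order = 0
    r2_layer, r2_time = [], []
    for i in range(n_replicates):
        params = SimulationParams(seed=seeds[2 * i], **POWER_PARAMS)
        table, meta, *_ = simulate_dataset(params)
        res = permanova(bray_curtis(table), meta, "layer + time",
                        n_permutations, seed=seeds[2 * i + 1])
        terms = {t.term: t for t in res.terms}
        sig += terms["layer"].p <= 0.01
        order += terms["layer"].r2 > terms["time"].r2
        r2_layer.append(terms["layer"].r2)
        r2_time.append(terms["time"].r2)
    return {"significant_fraction": sig / n_replicates,
            "r2_order_fraction": order / n_replicates,
            "mean_layer_r2": float(np.mean(r2_layer)),
            "mean_time_r2": float(np.mean(r2_time))}


def enrichment_recovery_rate(n_replicates: int = 10, seed: int = 0) -> float:
    """Mean fraction of planted layer-shifted ASVs (8-fold, 8 samples per
    layer) that the enrichment classifier assigns to their true layer."""
    seeds = _seed_stream(seed, n_replicates)
    rates = []
    for i in range(n_replicates):
        params = SimulationParams(seed=seeds[i], **ENRICH_PARAMS)
        table, meta, _, _, truth = simulate_dataset(params)
        pred = {r.asv_id: r.enriched_in
                for r in enrichment_classify(table, meta, 0.05)}
        planted = truth["depth_affected"]
        rates.append(np.mean([pred[a] == l for a, l in planted.items()]))
    return float(np.mean(rates))


def module_recovery_rate(n_seeds: int = 20, ari_threshold: float = 0.9,
                         seed: int = 0) -> float:
    """Fraction of seeds where greedy modularity detection recovers the
    three planted modules at adjusted Rand index >= ``ari_threshold``
    (computed on planted ASVs present in the layer-S network)."""
    seeds = _seed_stream(seed, n_seeds)
    ok = 0
    for i in range(n_seeds):
        params = SimulationParams(seed=seeds[i], **MODULE_PARAMS)
        table, meta, _, _, truth = simulate_dataset(params)
        net = build_cooccurrence_network(table, meta, "S")
        modules, _ = detect_modules(net, seed=0)
        planted = truth["modules"]
        common = [n for n in net.nodes if n in planted]
        if len(common) < 2:
            continue
        ari = adjusted_rand_score([planted[n] for n in common],
                                  [modules[n] for n in common])
        ok += ari >= ari_threshold
    return ok / n_seeds


def binomial_interval(n: int, p: float = 0.05, level: float = 0.95):
    """Central exact binomial interval for the observed rejection rate."""
    from scipy import stats
    lo = stats.binom.ppf((1 - level) / 2, n, p) / n
    hi = stats.binom.ppf(1 - (1 - level) / 2, n, p) / n
    return float(lo), float(hi)
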