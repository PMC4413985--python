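"""Shared fixtures: small simulated studies and the standard pipeline chain."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from tudecay import differential, fitting, normalize, simulate


def make_truth_row(gene_id="g", k=np.log(2) / 60, s=None, pre=0):
    """Single-gene truth table with s/k = 1 unless a synthesis rate is given."""
    return pd.DataFrame(
        {
            "gene_id": [gene_id],
            "gene_class": ["background"],
            "k_neural": [k],
            "k_nonneural": [k],
            "synthesis_rate": [s if s is not None else k],
            "pre_count": [pre],
            "are_count": [0],
            "mir124_site_count": [0],
            "true_halflife_neural": [np.log(2) / k],
        }
    )


def run_pipeline(truth, config, tissue="neural", condition="control", noisy=True):
    """simulate -> measure -> spike-in normalize -> ratios (no trimmed-mean)."""
    clean = simulate.simulate_labeled_signal(truth, config, tissue, condition)
    if not noisy:
        return normalize.compute_chase_pulse_ratios(clean)
    measured = simulate.apply_measurement_model(clean, config)
    normed, _ = normalize.spikein_normalize(measured)
    return normalize.compute_chase_pulse_ratios(normed)


def knockdown_study(seed=1, n_genes=2000, n_replicates=3, stabilization=1.5):
    """Full knockdown-vs-control chain; returns dict of intermediate tables.

    Conditions: 10% of genes PRE-bearing, stabilization applied to them in the
    knockdown, multiplicative measurement noise (log-sd 0.15).
    """
    cfg = simulate.SimConfig(
        n_genes=n_genes,
        seed=seed,
        n_replicates=n_replicates,
        class_fractions={"neural_fate": 0.0, "localized": 0.0, "background": 1.0},
        pre_probability={"neural_fate": 0.0, "localized": 0.0, "background": 0.10},
        knockdown_stabilization=stabilization,
    )
    truth = simulate.sample_true_kinetics(cfg)
    parts = []
    for condition in ("knockdown", "control"):
        parts.append(run_pipeline(truth, cfg, condition=condition).data)
    ratios, _ = normalize.trimmed_mean_normalize(pd.concat(parts, ignore_index=True))
    fits = fitting.fit_ratio_table(ratios)
    agg = fitting.aggregate_table(fits)
    ratio = differential.half_life_ratio_table(
        agg.loc[agg["condition"] == "knockdown"],
        agg.loc[agg["condition"] == "control"],
    )
    values, labels = differential.halflife_sam_inputs(
        fits, "knockdown", "control", genes=ratio["gene_id"]
    )
    sam = differential.sam_two_class(values, labels, seed=seed)
    table, counts = differential.flag_differential(ratio, sam, fold=1.3, q_max=0.30)
    merged = table.merge(truth[["gene_id", "pre_count"]], on="gene_id")
    merged["is_target"] = merged["pre_count"] >= 1
    return {
        "config": cfg,
        "truth": truth,
        "fits": fits,
        "aggregated": agg,
        "calls": merged,
        "counts": counts,
    }


@pytest.fixture(scope="session")
def small_noisefree_study():
    """300 genes, no noise, no array scale: ideal measurements."""
    cfg = simulate.SimConfig(n_genes=300, seed=7, noise_sd=0.0, array_scale_sd=0.0)
    truth = simulate.sample_true_kinetics(cfg)
    return cfg, truth


@pytest.fixture(scope="session")
def noisy_study():
    """Default 2000-gene noisy study fitted end to end (criterion-level size)."""
    cfg = simulate.SimConfig(n_genes=2000, seed=1, n_replicates=2, noise_sd=0.15)
    truth = simulate.sample_true_kinetics(cfg)
    ratio_set = run_pipeline(truth, cfg)
    ratios, _ = normalize.trimmed_mean_normalize(ratio_set.data)
    fits = fitting.fit_ratio_table(ratios)
    agg = fitting.aggregate_table(fits)
    return {"config": cfg, "truth": truth, "fits": fits, "aggregated": agg}
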