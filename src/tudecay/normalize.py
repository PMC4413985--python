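"""Two-step normalization of pulse-chase labeled-signal intensities.

Step 1 (within a pulse-chase series): each array is rescaled so that its
spike-in signal matches the series average, removing per-array scale (labeling
yield, hybridization, scanning).  A series is one replicate's pulse + chase
arrays, i.e. all timepoints sharing (condition, tissue, replicate).

Step 2 (across experiments): per-replicate chase/pulse ratios are computed,
then each experiment's ratios at each timepoint are rescaled by a single
factor so that its 10%-trimmed mean matches the grand trimmed mean across
experiments.  Trimming (top and bottom 10% of ratio values by rank) affects
only the factor computation, never the output values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, DataError, NormalizationError
from .io import SAMPLE_KEYS, ExpressionMatrix

__all__ = [
    "spikein_normalize",
    "RatioSet",
    "compute_chase_pulse_ratios",
    "trimmed_mean_normalize",
    "pulse_abundance_compare",
]

log = logging.getLogger("tudecay")

SERIES_KEYS = ["condition", "tissue", "replicate"]


def spikein_normalize(
    matrix: ExpressionMatrix, stat: str = "mean"
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Equalize spike-in signal across the arrays of each pulse-chase series.

    Each array is multiplied by ``series spike-in mean / array spike-in mean``
    (``stat='median'`` swaps both statistics for medians).  Spike-in rows stay
    in the matrix, flagged; the recorded background floor is rescaled with its
    array.  Returns the normalized matrix and the per-array factors applied.
    """
    if stat not in ("mean", "median"):
        raise ConfigError(f"spike-in statistic must be mean or median, got {stat!r}")
    data = matrix.data.copy()
    spikes = data.loc[data["is_spikein"]]
    if spikes.empty:
        raise NormalizationError("no spike-in rows in matrix")

    agg = spikes.groupby(SAMPLE_KEYS, sort=False)["intensity"].agg(stat)
    if (agg <= 0).any() or agg.isna().any():
        raise NormalizationError("an array has no spike-in signal above zero")
    # every array must carry spike-ins
    n_arrays = len(matrix.samples)
    if len(agg) != n_arrays:
        raise NormalizationError("some arrays have no spike-in rows")

    per_array = agg.reset_index().rename(columns={"intensity": "spike_stat"})
    series_target = (
        per_array.groupby(SERIES_KEYS, sort=False)["spike_stat"]
        .agg(stat)
        .reset_index()
        .rename(columns={"spike_stat": "series_target"})
    )
    per_array = per_array.merge(series_target, on=SERIES_KEYS)
    per_array["factor"] = per_array["series_target"] / per_array["spike_stat"]

    data = data.merge(per_array[SAMPLE_KEYS + ["factor"]], on=SAMPLE_KEYS, how="left")
    data["intensity"] = data["intensity"] * data["factor"]
    if "background_floor" in data.columns:
        data["background_floor"] = data["background_floor"] * data["factor"]
    data = data.drop(columns="factor")
    return ExpressionMatrix(data, array_scales=matrix.array_scales), per_array


@dataclass
class RatioSet:
    """Per-replicate chase/pulse ratios plus below-detection exclusions.

    ``data`` columns: gene_id, condition, tissue, replicate, timepoint_min,
    ratio.  The time-0 ratio is identically 1 (pulse/pulse).  ``excluded``
    lists gene x replicate series dropped because the pulse signal was at or
    below the background floor (or zero).
    """

    data: pd.DataFrame
    excluded: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["gene_id", "condition", "tissue", "replicate", "reason"]
        )
    )


def compute_chase_pulse_ratios(matrix: ExpressionMatrix) -> RatioSet:
    """Chase/pulse ratios per gene per replicate series.

    The pulse is the timepoint-0 array of each series.  Genes whose pulse
    intensity is at/below the recorded background floor (or zero) are flagged
    below-detection for that series and excluded from the ratio output.
    """
    genes = matrix.gene_rows().copy()
    if (genes["timepoint_min"] == 0).sum() == 0:
        raise DataError("matrix has no timepoint-0 (pulse) arrays")

    pulse = genes.loc[genes["timepoint_min"] == 0, ["gene_id", *SERIES_KEYS, "intensity"]]
    pulse = pulse.rename(columns={"intensity": "pulse_intensity"})
    merged = genes.merge(pulse, on=["gene_id", *SERIES_KEYS], how="inner")

    if "background_floor" in genes.columns:
        floor0 = genes.loc[
            genes["timepoint_min"] == 0, ["gene_id", *SERIES_KEYS, "background_floor"]
        ].rename(columns={"background_floor": "pulse_floor"})
        merged = merged.merge(floor0, on=["gene_id", *SERIES_KEYS], how="left")
        merged["pulse_floor"] = merged["pulse_floor"].fillna(0.0)
    else:
        merged["pulse_floor"] = 0.0

    below = (merged["pulse_intensity"] <= merged["pulse_floor"]) | (
        merged["pulse_intensity"] <= 0
    )
    excluded = (
        merged.loc[below, ["gene_id", *SERIES_KEYS]]
        .drop_duplicates()
        .assign(reason="pulse_below_background")
        .reset_index(drop=True)
    )
    if len(excluded):
        log.warning(
            "%d gene/replicate series excluded: pulse at/below background", len(excluded)
        )
    kept = merged.loc[~below].copy()
    kept["ratio"] = kept["intensity"] / kept["pulse_intensity"]
    kept.loc[kept["timepoint_min"] == 0, "ratio"] = 1.0
    out = kept[["gene_id", *SERIES_KEYS, "timepoint_min", "ratio"]].reset_index(drop=True)
    return RatioSet(out, excluded)


def _trimmed_mean(values: np.ndarray, trim: float) -> float:
    if len(values) < 10:
        log.warning(
            "experiment has %d ratio values (<10); using untrimmed mean", len(values)
        )
        return float(np.mean(values))
    return float(stats.trim_mean(values, trim))


def trimmed_mean_normalize(
    ratios: pd.DataFrame,
    trim: float = 0.10,
    experiment_keys: tuple[str, ...] = ("condition", "tissue", "replicate"),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Equalize trimmed-mean ratios per timepoint across experiments.

    For each chase timepoint (> 0), each experiment's ratios are multiplied by
    one factor so that its trimmed mean equals the grand trimmed mean across
    experiments.  The top and bottom ``trim`` fractions of ratio values (by
    rank) are excluded from factor computation only.  Returns the normalized
    table and the factors applied.
    """
    if not 0 <= trim < 0.5:
        raise ConfigError("trim fraction must be in [0, 0.5)")
    keys = list(experiment_keys)
    experiments = ratios[keys].drop_duplicates()
    if len(experiments) < 2:
        raise DataError("trimmed-mean normalization requires >= 2 experiments")

    out = ratios.copy()
    factor_rows = []
    for t in sorted(ratios.loc[ratios["timepoint_min"] > 0, "timepoint_min"].unique()):
        at_t = out.loc[out["timepoint_min"] == t]
        means = at_t.groupby(keys, sort=False)["ratio"].apply(
            lambda v: _trimmed_mean(v.to_numpy(), trim)
        )
        grand = float(means.mean())
        for exp_key, m in means.items():
            exp_key = exp_key if isinstance(exp_key, tuple) else (exp_key,)
            factor = grand / m
            mask = out["timepoint_min"] == t
            for key, value in zip(keys, exp_key):
                mask &= out[key] == value
            out.loc[mask, "ratio"] = out.loc[mask, "ratio"] * factor
            factor_rows.append({**dict(zip(keys, exp_key)), "timepoint_min": t, "factor": factor})
    return out, pd.DataFrame(factor_rows)


def pulse_abundance_compare(
    pulse_a: ExpressionMatrix,
    pulse_b: ExpressionMatrix,
    label_a: str = "A",
    label_b: str = "B",
) -> pd.DataFrame:
    """Compare per-gene pulse-labeled signal between two genotypes/readouts.

    Experiment-level mean normalization uses above-background spots only; the
    per-gene averages then use all spots.  Output columns: gene_id,
    ``mean_<label>`` per side, per-replicate normalized columns, and
    ``ratio`` = mean_a / mean_b, suitable for SAM-style enrichment calls.
    """
    sides = {}
    for label, mat in ((label_a, pulse_a), (label_b, pulse_b)):
        genes = mat.gene_rows().copy()
        genes = genes.loc[genes["timepoint_min"] == 0]
        if genes.empty:
            raise DataError(f"{label}: no pulse (timepoint 0) arrays")
        floor = genes["background_floor"] if "background_floor" in genes.columns else 0.0
        genes["above"] = genes["intensity"] > floor
        norm_blocks = []
        for _, block in genes.groupby(SERIES_KEYS, sort=False):
            above = block.loc[block["above"], "intensity"]
            if above.empty:
                raise DataError(f"{label}: an array has no above-background spots")
            block = block.copy()
            block["norm_intensity"] = block["intensity"] / above.mean()
            norm_blocks.append(block)
        normed = pd.concat(norm_blocks, ignore_index=True)
        sides[label] = normed.groupby("gene_id")["norm_intensity"].agg(["mean", list])

    shared = sides[label_a].index.intersection(sides[label_b].index)
    if len(shared) == 0:
        raise DataError("gene universes are disjoint")
    out = pd.DataFrame(
        {
            "gene_id": shared,
            f"mean_{label_a}": sides[label_a].loc[shared, "mean"].to_numpy(),
            f"mean_{label_b}": sides[label_b].loc[shared, "mean"].to_numpy(),
            f"values_{label_a}": sides[label_a].loc[shared, "list"].to_numpy(),
            f"values_{label_b}": sides[label_b].loc[shared, "list"].to_numpy(),
        }
    )
    out["ratio"] = out[f"mean_{label_a}"] / out[f"mean_{label_b}"]
    return out.reset_index(drop=True)
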