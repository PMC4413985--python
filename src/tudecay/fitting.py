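"""Single-order exponential decay fitting and replicate aggregation.

The labeled signal of a transcript decaying first-order with rate constant k
follows E(t) = E0 exp(-k t), i.e. ln E(t) = ln E0 - k t.  Each gene's
chase/pulse ratio series is fitted by ordinary least squares of ln(ratio) on
chase time with a free intercept (the pulse point is noisy too); k is minus
the slope and t1/2 = ln2/k.  Fit quality is the adjusted R^2,
1 - (1 - R^2)(n-1)/(n-2); with the standard three timepoints this reduces to
1 - 2(1 - R^2), a degenerate but faithful statistic.

Classification: genes that barely decay (k <= 0, or fitted half-life at or
above a high-stability floor, 300 min by default) are censored as
``high_stability`` rather than reported numerically; remaining fits with
adjusted R^2 below threshold (0.75 default) are ``poor_fit``.  Replicates are
fitted independently and half-lives aggregated; a gene is reproducible when
the replicate standard deviation is at most 60% of the mean half-life.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DataError
from .normalize import SERIES_KEYS

__all__ = [
    "DecayFit",
    "fit_exponential_decay",
    "classify_fit",
    "fit_ratio_table",
    "aggregate_replicates",
    "aggregate_table",
    "summarize_dataset",
    "ct_to_relative_abundance",
]

log = logging.getLogger("tudecay")

LN2 = math.log(2.0)

STATUS_OK = "fit_ok"
STATUS_POOR = "poor_fit"
STATUS_HIGH = "high_stability"
STATUS_BELOW = "below_detection"


@dataclass
class DecayFit:
    """One replicate's decay fit for one gene."""

    gene_id: str
    k: float
    t_half: float
    r2_adj: float
    n_points: int
    status: str


def fit_exponential_decay(
    timepoints: Sequence[float],
    ratios: Sequence[float],
    gene_id: str = "",
    r2_threshold: float = 0.75,
    high_stability_min: float = 300.0,
    force_intercept: bool = False,
) -> DecayFit:
    """OLS fit of ln(ratio) on time; k = -slope, t1/2 = ln2/k.

    Points with non-positive ratio are dropped (they carry no log signal);
    fewer than 3 usable points yields ``below_detection`` with no fit values.
    ``force_intercept`` pins the line through ln(1) = 0 at t = 0 instead of
    fitting a free intercept.
    """
    t = np.asarray(timepoints, dtype=float)
    r = np.asarray(ratios, dtype=float)
    usable = np.isfinite(r) & (r > 0) & np.isfinite(t)
    t, r = t[usable], r[usable]
    n = len(t)
    if n < 3:
        return DecayFit(gene_id, math.nan, math.nan, math.nan, n, STATUS_BELOW)

    y = np.log(r)
    if force_intercept:
        # regression through the origin: y = slope * t
        slope = float(np.dot(t, y) / np.dot(t, t))
        fitted = slope * t
    else:
        tbar, ybar = t.mean(), y.mean()
        sxx = float(np.dot(t - tbar, t - tbar))
        slope = float(np.dot(t - tbar, y - ybar) / sxx)
        fitted = ybar + slope * (t - tbar)

    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        r2 = 1.0 if ss_res < 1e-12 else 0.0
    else:
        r2 = 1.0 - ss_res / ss_tot
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)

    k = -slope
    t_half = LN2 / k if k > 0 else math.inf
    fit = DecayFit(gene_id, k, t_half, r2_adj, n, STATUS_OK)
    return classify_fit(fit, r2_threshold, high_stability_min)


def classify_fit(
    fit: DecayFit, r2_threshold: float = 0.75, high_stability_min: float = 300.0
) -> DecayFit:
    """Assign fit status; idempotent.

    ``high_stability`` whenever k <= 0 or the fitted half-life reaches the
    high-stability floor — regardless of fit quality, since barely-decaying
    series produce low R^2 by construction.  ``poor_fit`` otherwise when
    adjusted R^2 is below threshold (inclusive pass at the threshold).
    """
    if fit.status == STATUS_BELOW:
        return fit
    if fit.k <= 0 or fit.t_half >= high_stability_min:
        return replace(fit, status=STATUS_HIGH)
    if fit.r2_adj < r2_threshold:
        return replace(fit, status=STATUS_POOR)
    return replace(fit, status=STATUS_OK)


def fit_ratio_table(
    ratios: pd.DataFrame,
    r2_threshold: float = 0.75,
    high_stability_min: float = 300.0,
    force_intercept: bool = False,
) -> pd.DataFrame:
    """Fit every gene x replicate series of a long-format ratio table.

    Output columns: gene_id, condition, tissue, replicate, k, t_half, r2_adj,
    n_points, status.
    """
    rows = []
    keys = ["gene_id", *SERIES_KEYS]
    for key, block in ratios.groupby(keys, sort=False):
        fit = fit_exponential_decay(
            block["timepoint_min"].to_numpy(),
            block["ratio"].to_numpy(),
            gene_id=key[0],
            r2_threshold=r2_threshold,
            high_stability_min=high_stability_min,
            force_intercept=force_intercept,
        )
        rows.append(
            {
                **dict(zip(keys, key)),
                "k": fit.k,
                "t_half": fit.t_half,
                "r2_adj": fit.r2_adj,
                "n_points": fit.n_points,
                "status": fit.status,
            }
        )
    out = pd.DataFrame(rows)
    n_ok = int((out["status"] == STATUS_OK).sum()) if len(out) else 0
    log.info("fitted %d series: %d fit_ok", len(out), n_ok)
    return out


def aggregate_replicates(fits: pd.DataFrame, cv_max: float = 0.60) -> dict:
    """Aggregate one gene's replicate fits into a half-life record.

    Only replicates with status ``fit_ok`` or ``high_stability`` enter.  Mean,
    sample SD (n-1 denominator) and cv are computed over finite half-lives; a
    gene with any high-stability replicate is flagged ``high_stability`` so it
    can be kept as a censored record for set analyses.  Reproducible iff
    cv <= ``cv_max`` with at least two finite replicate estimates.
    """
    usable = fits.loc[fits["status"].isin([STATUS_OK, STATUS_HIGH])]
    finite = usable.loc[np.isfinite(usable["t_half"]), "t_half"].to_numpy(float)
    high = bool((usable["status"] == STATUS_HIGH).any())
    n = len(finite)
    if n == 0:
        return {
            "mean_t_half": math.nan,
            "sd_t_half": math.nan,
            "cv": math.nan,
            "n_replicates": 0,
            "reproducible": False,
            "high_stability": high,
        }
    mean = float(np.mean(finite))
    if n == 1:
        log.debug("single usable replicate; reproducibility not assessable")
        return {
            "mean_t_half": mean,
            "sd_t_half": math.nan,
            "cv": math.nan,
            "n_replicates": 1,
            "reproducible": False,
            "high_stability": high,
        }
    sd = float(np.std(finite, ddof=1))
    cv = sd / mean
    return {
        "mean_t_half": mean,
        "sd_t_half": sd,
        "cv": cv,
        "n_replicates": n,
        "reproducible": bool(cv <= cv_max),
        "high_stability": high,
    }


def aggregate_table(
    fits: pd.DataFrame,
    cv_max: float = 0.60,
    group_keys: tuple[str, ...] = ("condition", "tissue"),
) -> pd.DataFrame:
    """Aggregate a fit table into per-gene half-life records per condition/tissue."""
    rows = []
    keys = ["gene_id", *group_keys]
    for key, block in fits.groupby(keys, sort=False):
        rows.append({**dict(zip(keys, key)), **aggregate_replicates(block, cv_max)})
    out = pd.DataFrame(rows)
    if len(out):
        log.info(
            "aggregated %d genes: %d reproducible",
            len(out),
            int(out["reproducible"].sum()),
        )
    return out


def fit_rate(
    fits: pd.DataFrame, r2_threshold: float = 0.75, level: str = "gene"
) -> float:
    """Fraction of mRNAs fitting the decay model with adjusted R^2 >= threshold.

    ``level='gene'`` counts a transcript as fitting when every one of its
    replicate series reaches the threshold (the unit real studies report);
    ``level='series'`` counts individual replicate fits.
    """
    passed = fits["r2_adj"] >= r2_threshold
    if level == "series":
        return float(passed.mean())
    if level == "gene":
        return float(passed.groupby(fits["gene_id"]).all().mean())
    raise DataError(f"unknown level {level!r}")


def summarize_dataset(records: pd.DataFrame, cv_flag: float = 0.30) -> dict:
    """Dataset-level summary of aggregated half-life records.

    Mean/median half-life exclude censored high-stability records (reported as
    NaN when nothing remains).  Also reports the fraction of genes whose
    replicate scatter reaches ``cv_flag`` (irreproducibility indicator) and
    histogram bins for distribution plots.
    """
    if records.empty:
        return {
            "n_genes": 0,
            "fraction_cv_ge_flag": math.nan,
            "mean_t_half": math.nan,
            "median_t_half": math.nan,
            "hist_edges": [],
            "hist_counts": [],
        }
    with_cv = records.loc[records["cv"].notna()]
    frac = float((with_cv["cv"] >= cv_flag).mean()) if len(with_cv) else math.nan
    stable_excluded = records.loc[
        ~records["high_stability"] & records["mean_t_half"].notna(), "mean_t_half"
    ]
    if len(stable_excluded):
        mean = float(stable_excluded.mean())
        median = float(stable_excluded.median())
        edges = np.arange(0.0, max(315.0, stable_excluded.max() + 15.0), 15.0)
        counts, edges = np.histogram(stable_excluded, bins=edges)
        hist_edges, hist_counts = edges.tolist(), counts.tolist()
    else:
        mean = median = math.nan
        hist_edges, hist_counts = [], []
    return {
        "n_genes": int(len(records)),
        "fraction_cv_ge_flag": frac,
        "mean_t_half": mean,
        "median_t_half": median,
        "hist_edges": hist_edges,
        "hist_counts": hist_counts,
    }


def ct_to_relative_abundance(
    ct_records: pd.DataFrame, reference_time: float = 0.0
) -> pd.DataFrame:
    """Delta-delta-Ct relative abundance series per gene.

    dCt(t) = Ct_target(t) - Ct_reference(t); ddCt(t) = dCt(t) - dCt(t_ref);
    abundance(t) = 2^(-ddCt(t)), so abundance(t_ref) = 1.  The output feeds
    :func:`fit_exponential_decay` unchanged.
    """
    out_rows = []
    for gene_id, block in ct_records.groupby("gene_id", sort=False):
        if block["ct_reference"].isna().any():
            raise DataError(f"gene {gene_id}: missing reference Ct")
        dct = block["ct_target"].to_numpy(float) - block["ct_reference"].to_numpy(float)
        times = block["timepoint_min"].to_numpy(float)
        at_ref = times == reference_time
        if not at_ref.any():
            raise DataError(f"gene {gene_id}: no Ct at reference time {reference_time}")
        ddct = dct - dct[at_ref][0]
        out_rows.append(
            pd.DataFrame(
                {
                    "gene_id": gene_id,
                    "timepoint_min": times,
                    "relative_abundance": np.power(2.0, -ddct),
                }
            )
        )
    return pd.concat(out_rows, ignore_index=True)
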