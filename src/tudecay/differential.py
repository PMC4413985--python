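"""Cross-condition stability comparison with SAM-style permutation q-values.

SAM (significance analysis of microarrays) scores each gene with a moderated
two-class statistic d = (mean_A - mean_B) / (s + s0), where s is the pooled
standard error and s0 a small positive "fudge" constant that damps the
statistic for genes with tiny variance.  s0 is chosen by the standard
percentile-minimization rule: among candidate percentiles of the s
distribution, pick the one minimizing the coefficient of variation of the
d-statistic's spread across s-quantile bins.  The null distribution comes from
permuting class labels (exhaustively when the design is small enough, seeded
uniform sampling otherwise) and per-gene q-values from the order-statistic FDR
estimate: for the rejection region |d| >= |d_i|, FDR = pi0 * (mean permuted
count) / (observed count), made monotone in |d|.

Also here: half-life ratio tables between reproducibility-filtered datasets,
fold+q differential calls, the Kolmogorov-Smirnov shift test between target
and non-target half-life-change CDFs, Mann-Whitney subset-distribution tests,
and rank-correlation bias diagnostics (uridine content, abundance, UTR length
against half-life).
"""

from __future__ import annotations

import logging
import math
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, DataError

__all__ = [
    "half_life_ratio_table",
    "sam_two_class",
    "flag_differential",
    "ks_shift_test",
    "subset_distribution_test",
    "bias_diagnostics",
]

log = logging.getLogger("tudecay")


def half_life_ratio_table(
    records_a: pd.DataFrame, records_b: pd.DataFrame, suffixes: tuple[str, str] = ("_a", "_b")
) -> pd.DataFrame:
    """Per-gene half-life ratio A/B over genes reproducible in both datasets."""
    fa = records_a.loc[records_a["reproducible"] & records_a["mean_t_half"].notna()]
    fb = records_b.loc[records_b["reproducible"] & records_b["mean_t_half"].notna()]
    merged = fa[["gene_id", "mean_t_half"]].merge(
        fb[["gene_id", "mean_t_half"]], on="gene_id", suffixes=suffixes
    )
    if merged.empty:
        raise DataError("no genes reproducible in both datasets")
    merged["ratio"] = merged[f"mean_t_half{suffixes[0]}"] / merged[f"mean_t_half{suffixes[1]}"]
    log.info("half-life ratio universe: %d genes", len(merged))
    return merged


# ---------------------------------------------------------------------------
# SAM
# ---------------------------------------------------------------------------


def _pooled_se(x_a: np.ndarray, x_b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n_a, n_b = x_a.shape[1], x_b.shape[1]
    r = x_a.mean(axis=1) - x_b.mean(axis=1)
    ss = ((x_a - x_a.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (x_b - x_b.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    s = np.sqrt((1.0 / n_a + 1.0 / n_b) * ss / (n_a + n_b - 2))
    return r, s


def _d_statistic(r: np.ndarray, s: np.ndarray, s0: float) -> np.ndarray:
    denom = s + s0
    d = np.zeros_like(r)
    nonzero = denom > 0
    d[nonzero] = r[nonzero] / denom[nonzero]
    # 0/0 -> 0 (no signal, no spread); x/0 -> signed large
    blown = (~nonzero) & (r != 0)
    d[blown] = np.sign(r[blown]) * np.inf
    return d


def estimate_s0(r: np.ndarray, s: np.ndarray, n_bins: int = 100) -> float:
    """Percentile-minimization fudge factor.

    Candidates are the 0..100th (step 5) percentiles of s.  For each candidate,
    d is recomputed and its median absolute deviation taken within s-quantile
    bins; the candidate minimizing the coefficient of variation of those MADs
    wins.  Degenerate spreads (all-zero s) give s0 = 0.
    """
    if np.all(s == 0):
        return 0.0
    candidates = np.percentile(s, np.arange(0, 101, 5))
    bins = min(n_bins, max(2, len(s) // 10))
    quantiles = np.quantile(s, np.linspace(0, 1, bins + 1))
    which = np.clip(np.searchsorted(quantiles, s, side="right") - 1, 0, bins - 1)
    best_s0, best_cv = 0.0, np.inf
    for s0 in candidates:
        d = _d_statistic(r, s, float(s0))
        mads = []
        for b in range(bins):
            db = d[which == b]
            db = db[np.isfinite(db)]
            if len(db):
                mads.append(stats.median_abs_deviation(db, scale="normal"))
        mads = np.asarray(mads)
        if len(mads) < 2 or mads.mean() == 0:
            continue
        cv = mads.std(ddof=0) / mads.mean()
        if cv < best_cv:
            best_cv, best_s0 = cv, float(s0)
    return best_s0


def _label_permutations(
    n: int, n_a: int, n_permutations: int, rng: np.random.Generator
) -> list[np.ndarray]:
    total = math.comb(n, n_a)
    if total < 2:
        raise DataError("fewer than 2 distinct label permutations possible")
    if total <= n_permutations:
        return [np.array(idx) for idx in combinations(range(n), n_a)]
    perms = []
    for _ in range(n_permutations):
        perms.append(rng.permutation(n)[:n_a])
    return perms


def sam_two_class(
    values: pd.DataFrame,
    labels: list[str],
    n_permutations: int = 1000,
    s0: float | None = None,
    seed: int | None = None,
    fdr_center: str = "median",
) -> pd.DataFrame:
    """Two-class unpaired SAM on a gene x sample value matrix.

    ``values``: genes in rows (index = gene ids), one column per sample;
    ``labels``: class label per column (exactly two distinct labels; the first
    label encountered is class A, d > 0 means A > B).  ``s0=None`` triggers
    percentile-minimization; pass a number to pin it.  Returns a frame with
    columns gene_id, d_stat, q_value; permutation count and s0 in ``.attrs``.
    """
    labels = list(labels)
    if len(labels) != values.shape[1]:
        raise DataError("one label per sample column required")
    uniq = list(dict.fromkeys(labels))
    if len(uniq) != 2:
        raise DataError(f"exactly two classes required, got {uniq}")
    lab = np.array(labels)
    idx_a = np.flatnonzero(lab == uniq[0])
    x = values.to_numpy(float)
    n = x.shape[1]
    n_a = len(idx_a)
    if n_a < 2 or n - n_a < 2:
        raise DataError("at least 2 replicates per class required")

    r, s = _pooled_se(x[:, idx_a], x[:, np.flatnonzero(lab == uniq[1])])
    s0_val = estimate_s0(r, s) if s0 is None else float(s0)
    d = _d_statistic(r, s, s0_val)

    rng = np.random.default_rng(seed)
    perms = _label_permutations(n, n_a, n_permutations, rng)
    d_null = np.empty((len(perms), len(d)))
    cols = np.arange(n)
    for i, pa in enumerate(perms):
        mask = np.zeros(n, dtype=bool)
        mask[pa] = True
        rp, sp = _pooled_se(x[:, cols[mask]], x[:, cols[~mask]])
        d_null[i] = _d_statistic(rp, sp, s0_val)

    q = _sam_q_values(d, d_null, center=fdr_center)
    out = pd.DataFrame({"gene_id": values.index, "d_stat": d, "q_value": q})
    out.attrs["s0"] = s0_val
    out.attrs["n_permutations"] = len(perms)
    log.info("SAM: %d genes, %d permutations, s0=%.4g", len(out), len(perms), s0_val)
    return out


def _sam_q_values(
    d: np.ndarray, d_null: np.ndarray, center: str = "median"
) -> np.ndarray:
    """Order-statistic FDR estimate with pi0 correction, monotone in |d|.

    For the rejection region |d| >= t the false-positive count is summarized
    over permutations by its median (the SAM program's reported default;
    ``center='mean'`` gives the mean instead).  The median is robust to the
    few label permutations that nearly reproduce the observed assignment.
    """
    m = len(d)
    q25, q75 = np.quantile(d_null, [0.25, 0.75])
    pi0 = min(1.0, float(np.mean((d >= q25) & (d <= q75))) / 0.5)

    abs_d = np.abs(d)
    obs_sorted = np.sort(abs_d)
    # per-permutation counts of |d*| >= t for t = each gene's |d|
    counts = np.empty((d_null.shape[0], m))
    for i in range(d_null.shape[0]):
        row = np.sort(np.abs(d_null[i]))
        counts[i] = m - np.searchsorted(row, abs_d, side="left")
    v = np.median(counts, axis=0) if center == "median" else counts.mean(axis=0)
    rcount = m - np.searchsorted(obs_sorted, abs_d, side="left")
    fdr = np.minimum(1.0, pi0 * v / np.maximum(rcount, 1))
    # q_i = min FDR over rejection regions containing gene i (thresholds <= |d_i|)
    order = np.argsort(abs_d)
    running = np.minimum.accumulate(fdr[order])
    q = np.empty(m)
    q[order] = running
    return q


def halflife_sam_inputs(
    fits: pd.DataFrame,
    condition_a: str,
    condition_b: str,
    genes: pd.Series | None = None,
    log_scale: bool = True,
) -> tuple[pd.DataFrame, list[str]]:
    """Gene x replicate half-life matrix + labels for a stability SAM run.

    Uses replicate fits with status ``fit_ok`` only, keeps genes with a
    complete replicate set in both conditions, and (by default) log2-transforms
    half-lives: replicate scatter in half-life is multiplicative, so the log
    scale homogenizes per-gene variance across the stability range.
    """
    ok = fits.loc[fits["status"] == "fit_ok"]
    frames, labels = [], []
    for label, cond in (("A", condition_a), ("B", condition_b)):
        wide = ok.loc[ok["condition"] == cond].pivot_table(
            index="gene_id", columns="replicate", values="t_half"
        )
        wide.columns = [f"{label}{c}" for c in wide.columns]
        frames.append(wide)
        labels.extend([label] * wide.shape[1])
    mat = pd.concat(frames, axis=1).dropna()
    if genes is not None:
        mat = mat.loc[mat.index.isin(set(genes))]
    if log_scale:
        mat = np.log2(mat)
    return mat, labels


def flag_differential(
    ratios: pd.DataFrame,
    q_values: pd.DataFrame,
    fold: float = 1.5,
    q_max: float = 0.30,
) -> tuple[pd.DataFrame, dict]:
    """Three-way stabilized/destabilized/unchanged call per gene.

    ``stabilized`` requires ratio >= fold and q <= q_max; ``destabilized``
    requires ratio <= 1/fold and q <= q_max.  Returns the per-gene table and
    summary counts.
    """
    if fold < 1:
        raise ConfigError("fold threshold must be >= 1")
    merged = ratios[["gene_id", "ratio"]].merge(
        q_values[["gene_id", "q_value"]], on="gene_id"
    )
    call = np.where(
        (merged["ratio"] >= fold) & (merged["q_value"] <= q_max),
        "stabilized",
        np.where(
            (merged["ratio"] <= 1.0 / fold) & (merged["q_value"] <= q_max),
            "destabilized",
            "unchanged",
        ),
    )
    merged["call"] = call
    counts = {
        "n_genes": int(len(merged)),
        "stabilized": int((merged["call"] == "stabilized").sum()),
        "destabilized": int((merged["call"] == "destabilized").sum()),
    }
    counts["fraction_differential"] = (
        (counts["stabilized"] + counts["destabilized"]) / counts["n_genes"]
        if counts["n_genes"]
        else math.nan
    )
    return merged, counts


def ks_shift_test(
    target_ratios: np.ndarray, nontarget_ratios: np.ndarray
) -> dict:
    """Two-sample KS test on half-life-change distributions, plus ECDF curves."""
    a = np.asarray(target_ratios, float)
    b = np.asarray(nontarget_ratios, float)
    if len(a) < 5 or len(b) < 5:
        raise DataError("both samples must have >= 5 observations")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise DataError("non-finite ratio in KS input")
    res = stats.ks_2samp(a, b, method="asymp")
    curves = {}
    for name, sample in (("target", a), ("nontarget", b)):
        xs = np.sort(sample)
        curves[name] = pd.DataFrame(
            {"ratio": xs, "ecdf": np.arange(1, len(xs) + 1) / len(xs)}
        )
    return {"D": float(res.statistic), "p": float(res.pvalue), "curves": curves}


def subset_distribution_test(
    subset_halflives: np.ndarray, all_halflives: np.ndarray
) -> dict:
    """Two-sided Mann-Whitney U of a gene subset against the full distribution."""
    sub = np.asarray(subset_halflives, float)
    universe = np.asarray(all_halflives, float)
    if len(sub) == 0:
        raise DataError("empty subset")
    if len(universe) <= len(sub):
        log.warning("comparison set not larger than subset")
    res = stats.mannwhitneyu(sub, universe, alternative="two-sided", method="auto")
    sub_med, uni_med = float(np.median(sub)), float(np.median(universe))
    direction = "below" if sub_med < uni_med else ("above" if sub_med > uni_med else "equal")
    return {
        "U": float(res.statistic),
        "p": float(res.pvalue),
        "subset_median": sub_med,
        "universe_median": uni_med,
        "direction": direction,
    }


def bias_diagnostics(
    half_lives: pd.Series, covariates: dict[str, pd.Series], min_genes: int = 20
) -> pd.DataFrame:
    """Spearman rank correlation of half-life against technical covariates.

    Returns one row per covariate with rho, p, n, and an ``undefined`` flag
    for degenerate (constant) covariates.  Also used for the no-bias checks:
    uridine content, pulse abundance, and 3'UTR length against half-life.
    """
    rows = []
    for name, cov in covariates.items():
        joined = pd.concat([half_lives.rename("t_half"), cov.rename("cov")], axis=1).dropna()
        if len(joined) < min_genes:
            raise DataError(f"covariate {name}: fewer than {min_genes} genes")
        if joined["cov"].nunique() == 1:
            rows.append({"covariate": name, "rho": math.nan, "p": math.nan,
                         "n": len(joined), "undefined": True})
            continue
        rho, p = stats.spearmanr(joined["t_half"], joined["cov"])
        rows.append({"covariate": name, "rho": float(rho), "p": float(p),
                     "n": len(joined), "undefined": False})
    return pd.DataFrame(rows)
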