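# Methods

## Overview

`tudecay` implements the computational half of a pulse-chase metabolic-labeling
("TU-decay") experiment: embryos incorporate a thiolated uridine analogue into
nascent RNA during a 1-hour pulse, the label is chased with excess uridine, and
labeled RNA is purified and quantified (microarray-style intensities) at the
end of the pulse and after 1-h and 3-h chases. The decline of labeled signal
over the chase reveals first-order decay kinetics per transcript. The package
covers normalization, half-life estimation, replicate aggregation, differential
stability between conditions or tissue readouts, 3'UTR cis-element enrichment,
and a synthetic data generator with known ground truth that makes every stage
testable without external downloads.

## Kinetic model

Transcripts are modeled with constant synthesis rate `s` (arbitrary units/min)
and first-order decay rate `k` (1/min), so `t1/2 = ln2/k`. The labeled pool at
the end of a pulse of length `tau` is

    L0 = (s/k) * (1 - exp(-k*tau))

(standard metabolic-labeling kinetics; reduces to `s*tau` for slow decay).
During the chase

    L(t) = L0 * exp(-k*t) + rho * (s/k) * (1 - exp(-k*t))

where `rho` in [0, 1) is the *recycling fraction*: the fraction of synthesis
that still enters the labeled pool during the chase, from incomplete precursor
saturation or recycling of label from degraded transcripts. `rho > 0` flattens
the decay curve and inflates fitted half-lives monotonically — this is the
artifact an actinomycin-D control chase (transcription arrest, modeled as
`rho = 0`) is designed to expose. `rho` has no well-measured value; the default
is 0 and the recycling analysis sweeps it explicitly.

A whole-embryo readout is the mixture `w * L_neural + (1-w) * L_nonneural`
with `w` the neural fraction of total signal (default 0.3), so whole-embryo
half-lives are aggregates across tissue pools and bracket the pool half-lives.
An RNAi knockdown condition divides `k` by a stabilization factor (default
1.5) for PRE-bearing transcripts, in the neural pool only.

## Normalization

Two steps, in order:

1. **Spike-in normalization** (within a pulse-chase series = one replicate's
   pulse + chase arrays): each array is rescaled so its mean spike-in
   intensity equals the across-array mean for the series. This removes
   per-array scale (labeling yield, hybridization, scanning) up to one
   constant per series, which cancels in chase/pulse ratios. A median variant
   is available (`--spikein-stat median`).
2. **Chase/pulse ratios, then trimmed-mean normalization across experiments**:
   per gene and replicate, `ratio(t) = I(t)/I(0)`; the time-0 ratio is 1 by
   construction. Genes whose pulse signal is at or below the recorded
   background floor are excluded as below-detection, never imputed. Each
   experiment's ratios at each chase timepoint are then rescaled by a single
   factor so its 10%-trimmed mean (top and bottom 10% of values by rank
   excluded from the factor computation only) matches the grand trimmed mean
   across experiments. The step is idempotent and experiments with fewer than
   10 values fall back to an untrimmed mean with a warning.

## Half-life estimation

`ln(ratio)` is regressed on chase time by ordinary least squares with a free
intercept (the pulse measurement is itself noisy; a forced-through-origin mode
exists). `k = -slope`, `t1/2 = ln2/k`. Fit quality is adjusted R²,
`1 - (1-R²)(n-1)/(n-2)`; with the standard three timepoints this is
`1 - 2(1-R²)` — degenerate but the faithful statistic for 3-point series.
Points with non-positive ratio carry no log signal and are dropped; fewer than
3 usable points yields `below_detection`.

Classification thresholds (config defaults): transcripts with `k <= 0` or
fitted `t1/2 >= 300` min are censored as `high_stability` regardless of R²
(barely-decaying series produce low R² by construction and their numeric
half-life is unreliable beyond the 180-min chase span); remaining fits with
adjusted R² `< 0.75` are `poor_fit`. Both cuts are inclusive at the boundary.
High-stability records are excluded from dataset mean/median half-life but are
retained as a censored category for set analyses when reproducible.

Replicates are fitted independently and aggregated: mean, sample SD (n−1),
and cv over finite half-lives; a gene is *reproducible* when `cv <= 0.60`
with at least two usable replicates. A pooled-points mode is available; the
per-replicate default is what makes replicate SDs of half-life meaningful.

The RT-qPCR path converts cycle thresholds by ΔΔCt: `dCt = Ct_target −
Ct_reference`, `abundance(t) = 2^−(dCt(t) − dCt(0))`, and feeds the same
fitting machinery; when Ct is constructed as `−log2(signal) + c` the two paths
agree exactly.

### Monotonicity caveat

"Raising every chase ratio never shortens the fitted half-life" holds for the
through-origin fit, whose slope weights on the chase points are non-negative.
It does not hold for the free-intercept fit: with timepoints 0/60/180 the
centered slope weights are (−80, −20, +100)/Σ, so raising only the 1-h point
steepens the fitted slope. The property test asserts the through-origin case.

## Differential stability

Per-gene half-life ratios (condition A / condition B) are computed over genes
reproducible in both datasets. Significance uses a re-implementation of SAM
(significance analysis of microarrays), two-class unpaired:

* `d = (mean_A − mean_B) / (s + s0)` with pooled standard error `s` and fudge
  factor `s0` chosen by percentile minimization (candidate percentiles of the
  `s` distribution; pick the one minimizing the coefficient of variation of
  the MAD of `d` across 100 `s`-quantile bins). `s0` can be pinned.
* The null comes from label permutations: exhaustive when the design allows no
  more than the requested number (all C(n, nA) splits, identity included),
  seeded uniform sampling otherwise.
* Per-gene q-values from the order-statistic FDR estimate: for the region
  `|d| >= |d_i|`, `FDR = pi0 * V / R` with `V` the **median** permutation
  false-positive count (the SAM program's reported default; the mean is
  available), `R` the observed count, and
  `pi0 = min(1, frac(d in [q25*, q75*]) / 0.5)` estimated from the permuted
  quartiles. q-values are made monotone in `|d|`.
* SAM input for stability comparisons is the per-replicate half-life matrix on
  **log2 scale**: replicate scatter in half-life is multiplicative, and the log
  transform homogenizes per-gene variance across the stability range (standard
  microarray practice). Raw scale is available (`log_scale=False`).

Calls: `stabilized` requires ratio ≥ fold **and** q ≤ q_max; `destabilized`
symmetric at 1/fold. Named presets mirror the analyses this pipeline serves:
1.5-fold for cross-tissue comparison, 1.3-fold with q ≤ 0.30 for knockdown
stabilization calls.

Distribution comparisons: two-sample Kolmogorov-Smirnov (asymptotic p, with
ECDF curve export) for target vs non-target half-life-change distributions;
two-sided Mann-Whitney U with tie correction for functional subsets against
the full half-life distribution. Bias diagnostics use Spearman rank
correlation of half-life against technical covariates (uridine content, pulse
abundance, 3'UTR length); constant covariates are reported as undefined, not
zero.

## Motif scanning and enrichment

Motifs are degenerate RNA patterns (IUPAC subset plus explicit `[..]`
classes), scanned with overlap on the sense strand only (mRNA context). A gene
"contains" an element iff it has at least one match (`min_count=1`).
Built-ins, stored in `src/tudecay/data/motifs.tsv` and fully overridable:

* **PRE** `UGUA[AUC]AUA` — the Pumilio recognition element (3 literal 8-mers).
* **ARE** `WAUUUAW` — a package-default AU-rich-element core heptamer; ARE
  catalogs differ and no single pattern is canonical.
* **miR124_seed** `GUGCCUU` — package-default 7-mer complementary to positions
  2–8 of mature miR-124 (`UAAGGCACGCGGUGAAUGCCA`); seed-match classes
  (6mer/7mer/8mer) differ across target databases.

Stability strata: low `t1/2 <= 75` min, high `t1/2 >= 80` min (inclusive;
genes between are excluded, so the sets are disjoint). Enrichment reports both
the *frequency ratio* — (set hit fraction)/(background hit fraction), the
statistic this kind of analysis informally calls an odds ratio — and the
classical odds ratio (Haldane 0.5 correction when a cell is zero), with a
two-sided Fisher exact p on the 2×2 table.

## Synthetic data generator

The generator emulates the structure of a replicated pulse-chase microarray
study: per-transcript labeled signal at 0/1/3-h chases, spike-in control rows
sharing each array's scale factor, biological replicates, a whole-embryo
mixture readout, and a knockdown condition.

Defaults (all in `SimConfig`, times in minutes):

| parameter | default | rationale |
|---|---|---|
| chase grid | 0, 60, 180 | the study design being emulated |
| pulse duration | 60 | idem |
| replicates | 2 | typical replicated microarray study |
| half-life log-medians (neural pool) | neural-fate 55, localized 120, background 75 | short-lived fate-regulator and long-lived localized classes bracketing the ≤75/≥80-min strata; background near the ~76-min mean of real neural measurements |
| half-life log-sd | 0.4–0.5 | ~2-fold spread, typical of decay datasets |
| non-neural pool | all classes 75 median | class structure is neural-specific |
| PRE probability | neural-fate 0.55, background 0.085, localized 0.03 | calibrated to the printed frequencies (20/36 low-stability fate mRNAs with a PRE; 8.5% background) |
| ARE / miR-124 probability | 0.25 / 0.15 | no stability association built in — these are the negative controls |
| noise | multiplicative lognormal, log-sd 0.15 per measurement | intensities are positive and heteroscedastic |
| array scale | lognormal, log-sd 0.25 | per-array yield/hybridization scale |
| mixture weight | 0.3 | neural tissue fraction of whole-embryo signal |
| knockdown stabilization | 1.5 | the fold regime the differential caller targets |
| UTR length | normal(400, 150), min 30 nt | typical fly 3'UTR scale |

All randomness flows from one seed through documented `SeedSequence`
substreams (0 kinetics, 1 class/motif assignment, 2 measurement, 3 UTR), so a
seed + config reproduces byte-identical outputs.

UTR synthesis inserts exactly the truth table's motif counts at
non-overlapping positions and rejects any candidate sequence whose full rescan
does not reproduce the counts for all three motifs, so flanking sequence is
guaranteed element-free.

**What the generator does not emulate** — probe-level array artifacts, dye
effects, sequence-dependent labeling efficiency, biological replicate-level
kinetic variation (replicates differ only through measurement noise, so
replicate cv is lower than real studies report), transcript families, and GO
structure. Passing tests therefore demonstrate correctness of the analysis
chain under the stated model, not robustness to every failure mode of real
arrays.

## Problem sizes used in tests and the acceptance script

Simulated studies use 2000 genes (recovery, knockdown) and 3000 genes
(enrichment) — enough for stable fractions and enrichment statistics while
keeping a full run in seconds. The knockdown comparison uses 3 biological
replicates per condition: with 2v2 only six label permutations exist and the
permutation FDR cannot resolve q below ~1/3, while 3v3 gives 20 exhaustive
splits and a meaningful q scale.

## Known limitations

* Single-exponential model only; no synthesis-degradation joint fits,
  multi-exponential decay, or bootstrap confidence intervals.
* Half-lives well beyond the chase span (≳300 min) are censored, not
  estimated; the bias for long half-lives grows with `t1/2`/span.
* The permutation q-value is coarse for small designs; exhaustive enumeration
  is used whenever possible.
* ARE and miR-124 site definitions are pragmatic defaults, not authoritative
  catalog reproductions; override them for real analyses.
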