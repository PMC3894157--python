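# Methods

## Scope and pipeline

The package analyses plate-reader fitness screens of deletion
libraries: raw OD600 time series → per-well growth rate and yield →
plate-wise wild-type normalization → sigma scores and phenotype classes
per condition → epistasis of double deletions and upstream-element
enrichment of phenotype classes. A synthetic-data generator produces
whole screens with known planted structure; all validation is against
that ground truth.

## Growth model of the generator

Wells follow a three-parameter logistic with an explicit lag:

    OD(t) = blank + od0                                   for t < lag
    OD(t) = blank + K / (1 + ((K − od0)/od0) e^{−r(t−lag)})  otherwise

with defaults od0 = 0.02, K_wt = 1.2 OD, r_wt = 0.40/h, lag = 2 h,
blank = 0.08 OD, sampled every 0.5 h. The logistic-with-lag is the
simplest model in which rate and yield are separately tunable, which is
what parameter-recovery testing needs. Runs last 36 h so that even
strains at a 0.8× rate multiplier reach a detectable stationary plateau
(a wild-type curve plateaus near 24 h; 0.8× rate mutants near 28 h).

Strain effects are multipliers on r and K. Lethal strains are held flat
at the inoculum (K = od0), mirroring the detection-based lethal call in
scoring. Double deletions are constructed as W_AB = W_A·W_B + ε per
parameter, so the multiplicative null is exact when ε = 0 and the
epistasis estimator has a true zero to recover.

Noise has three components, all defaults chosen once as realistic for
TECAN-class readers and kept fixed:

* additive Gaussian read noise, sd 0.005 OD, truncated at 0;
* biological-replicate variation: lognormal multipliers on r and K with
  CV 3% shared by all technical wells of a (strain, biological
  replicate);
* well-to-well culture variability (inoculum, plate position):
  independent lognormal multipliers with CV 3% per non-blank well,
  including wild-type wells.

The well-level component matters structurally: relative values are
normalized to the plate's wild-type mean, so without it the pooled
wild-type reference would have only read noise for spread and sigma
would be meaningless. Wild-type wells carry no strain- or
replicate-level effect — they are the reference.

Replicate layout: `n_tech_reps` (default 36) technical wells per strain
are split evenly across the biological replicates (default 3, so 12
wells per biological replicate), packed onto 96-well plates each
carrying 4 wild-type wells and 2 blanks. Seeding: one master seed;
per-plate and per-flank streams derive from `SeedSequence` entropy
words built by CRC-32 hashing of (condition, plate index) or gene name,
so any subset of the simulation is reproducible in isolation.

What the generator does **not** emulate: diauxic shifts, evaporation
and edge effects, condition-specific growth mechanisms, or correlated
day/batch effects beyond the replicate multipliers. Passing tests
therefore demonstrate correctness of the estimators under this noise
model, not robustness to every artefact of real plates.

## Growth-parameter extraction

Curves are blank-subtracted (mean of blank wells; else the per-well
minimum of the first three readings), clipped at zero and smoothed with
a running median (window 3) that removes single-point spikes without
biasing monotone segments.

**Yield** is the mean OD over the stationary plateau, defined as the
maximal suffix of time points where a 5-point least-squares derivative
stays at or below 5% of its maximum, with two robustness provisions:
the derivative is computed only over full interior windows (polynomial
edge fits let one noisy final reading flip both boundary estimates),
and a suffix break requires two consecutive above-threshold points so
isolated noise flips cannot abolish a real plateau. If no suffix of at
least 3 points exists the curve is flagged truncated and max(OD) is
reported.

**Rate** is the maximal specific growth rate from sliding 5-point
least-squares slopes of ln(OD + 1e−4) over points above a 0.01 OD
detection floor. Two biases of the naive "max window slope" estimator
are corrected:

* *curvature*: a finite window on a logistic underestimates r because
  the local slope is r(1 − OD/K); each window's slope is divided by
  (1 − OD_center/K̂) with K̂ the detected plateau, clipped to [0.5, 1];
* *extreme-value bias*: the maximum of ~40 noisy overlapping window
  slopes is upward-biased (about +16% at 0.005 OD noise). Instead, the
  exponential region is located as the windows whose smoothed slope
  exceeds half the smoothed maximum (restricted to OD ≤ 0.25·K̂, where
  the correction is reliable), and the corrected slopes in that region
  are combined by a precision-weighted mean with weights
  (OD·(1−OD/K̂))², the inverse variance of a log-slope under additive
  OD noise.

When no plateau exists the raw windowed slopes are used, which is exact
for a pure exponential. On noiseless logistic curves the extractor is
within 1% of the planted (r, K) across multipliers 0.8–1.25; at 0.005
OD noise the per-well error is ≈2.5% (rate) and ≈0.2% (yield) with
negligible bias.

A well whose maximum blank-subtracted OD stays below 0.05 is called
lethal (rate = yield = 0, flagged); wells listed in the plate map but
absent from the reads are carried as missing, never fabricated.

## Normalization and sigma scoring

Per plate, deletion-strain technical wells are averaged to one value
per (strain, biological replicate); every value is divided by the mean
of the plate's non-lethal wild-type wells, so wild-type relative values
average to 1 per plate by construction. Wild-type wells are kept
un-aggregated — one row per well — because they form the reference
distribution, and plate-level aggregation would collapse it to exactly
1.0.

Per condition, the wild-type reference pools all wild-type relative
values across plates; mu_WT and sd_WT are the sample mean and sd (n−1).
A strain's sigma uses the mean over its biological-replicate means; the
SEM over biological replicates is carried alongside but does not enter
sigma. Class boundaries (±2, ±3) assign ties to the more extreme class —
a measure-zero choice made deterministic. Condition summaries report
percentages over scored strains only, with lethal and missing counts
alongside, since the choice of denominator is a reporting convention.

Calibration: strains drawn from the wild-type distribution itself are
called non-normal (|σ| > 2) at the normal two-tail rate of 4.55%
(validated at n = 2000 within the binomial 95% CI, using a reference
sample large enough that its own estimation error is negligible).
Because deletion-strain values are means over ~36 wells while the
reference spread is that of single wells, real null strains are called
conservatively — the screen's design trades sensitivity for a simple,
distribution-free threshold.

## Epistasis

ε = W_AB − W_A·W_B per biological replicate (replicates paired by
label), then mean ± SEM (sd/√n). With n = 3 replicates the exact 95%
confidence interval is mean ± t_{0.975,2}·SEM = mean ± 4.30·SEM; the
normal-approximation ±2·SEM interval has only 82% coverage at n = 3 and
is reported for reference, not used as the calibration criterion.
Validation plants ε ∈ {0, −0.3} under the generator's replicate noise
model and checks ≥90% coverage of the t-interval plus unbiased recovery
of the aggravating mean.

## Motif statistics

Anchored elements are IUPAC consensi with a ±4 bp tolerance window
around their anchor. The four defaults (TTTT at −53 and −30, TATAWA at
−42, YYCAA at −13) are configurable stand-ins for the published
positional matrices of the conserved pol III upstream elements, which
are not distributed here; analyses depending on exact element
definitions should supply their own `MotifElement` tuples. Enrichment
of an element in a phenotype class is the hypergeometric upper tail
P(X ≥ k | N, K, n) over the universe of classified genes whose flank
covers the element window; it is exact (validated against complete
combinatorial enumeration for all N ≤ 12) and reported as −log10 p
without multiple-testing correction across element × class cells, which
is a display convention.

The de-novo scan tiles the upstream region (default −100…−1) with
non-overlapping 9 bp windows. Per window, every exact k-mer (4–8 bp)
present in at least two foreground sequences is scored by a one-sided
Fisher exact test on presence/absence between foreground and background
gene sets; the window's E-value is the minimum Fisher p times the
number of k-mers tested there (Bonferroni within window), and the
minimum-E motif is reported with a deterministic lexicographic
tie-break. Non-overlapping tiling is deliberate: step-1 windows
multiply the family of tests ninefold without a matching correction and
drive the null minimum E below 0.05 in over half of runs, while tiled
windows keep null scans non-significant in ≥90% of runs at the cost of
splitting a motif that straddles a tile boundary across two windows
(where it is still detected via its 4–5 bp sub-k-mers). Overlapping
scans remain available through `ScanConfig.step`.

## Numerical and degenerate-input conventions

Log floor 1e−4 inside ln(OD); detection floor 0.01 OD; these are
absolute, so rate invariance under OD rescaling holds to ~0.5% rather
than exactly. Hypergeometric p is clamped to (tiny, 1] before taking
−log10. A plate without wild-type wells, an all-lethal wild-type, a
degenerate (zero-spread) reference, fewer than 3 wild-type values,
fewer than 2 complete replicate triples, and overlapping
foreground/background sets are all hard errors; a blank above the
curve maximum, a short flank, or an unread mapped well degrade to
flagged results instead.

## Known limitations

* The rate estimator's curvature correction assumes logistic saturation;
  strongly diauxic or non-saturating curves fall back to uncorrected
  slopes and are flagged truncated.
* Sigma thresholds are fixed (±2, ±3), not per-strain tests; no
  multiple-testing control across strains is intended.
* The k-mer scan is an enumerative over-representation test, not a
  position-weight-matrix learner; it reports exact words, so degenerate
  motifs are found only through their conserved cores.
* Synthetic validation covers the generator's noise model only (see
  above); real screens add batch, edge and evaporation effects that the
  plate-wise wild-type normalization only partially absorbs.
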