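# Methods

## The screen model

A pooled shRNA dropout screen measures, for each hairpin *h*, how its
relative abundance in the cell pool changes under a drug arm relative to
vehicle. The analysis assumes barcode intensity on a log2 scale is, up to a
probe-specific offset, linear in log2 hairpin abundance, and models each
detected probe independently:

    y = β₀ + β_T·treated + β_t·timepoint + β_r·replicate + ε

over the post-selection samples of one cell line. `treated` pools every
drug dose into a single indicator — the screen design carries two doses, but
dose-specific differences are not modeled, matching the contrast the hit
thresholds are defined on. The treatment coefficient β_T is the log2
treated/vehicle fold change; a hairpin is called **depleted** when
β_T ≤ −0.58 (~1.5-fold drop) with p ≤ 0.01, both boundaries inclusive. No
multiple-testing correction is applied to the calls; a Benjamini–Hochberg
FDR column is emitted for reference only.

### Variance moderation

With only a handful of residual degrees of freedom per probe, per-probe
variance estimates are unstable. We use the standard empirical-Bayes
treatment: sample variances s²_g on d_g df are assumed to follow a scaled
F around a prior (d₀, s₀²), giving the posterior

    s̃²_g = (d₀·s₀² + d_g·s²_g) / (d₀ + d_g)

and a moderated t = β_T/(s̃_g·√v) on d₀ + d_g df. The hyper-parameters are
estimated by moment-matching the log sample variances (mean and variance of
e_g = log s²_g − ψ(d_g/2) + log(d_g/2), inverting the trigamma function by
Newton iteration). Degenerate cases follow the conventions of the R
reference implementation of this estimator: exactly-zero variances are
offset to 10⁻⁵ of the median rather than dropped (rank-preserving quantile
normalization pins the extreme-rank probes to identical values across
samples, so such probes do occur), and when the observed variances are no
more dispersed than sampling alone explains, d₀ = ∞ with s₀² the pooled mean
variance. During development the whole moderated path was checked against
limma's `lmFit`/`eBayes` on a shared instance and agrees to ~1e-13; the test
suite keeps an independent simulation oracle (known-prior recovery within
25%/10%) instead of an R dependency.

### Preprocessing conventions

The stage order is fixed: log2 → IQR QC → technical-replicate resolution →
quantile normalization → background/detection. Choices the data formats do
not pin down:

- **log2(x+1)** rather than log2(x), to tolerate zero intensities; the
  offset is configurable.
- **IQR rule is strict**: a sample is excluded iff its log2 IQR < 6; an IQR
  of exactly 6 is retained.
- **Replicate resolution** keeps the latest `acquisition_date`; ties break
  lexicographically on sample id so the result is deterministic.
- **Quantile normalization** maps each column's order statistics to the
  across-sample mean of order statistics; tied values within a column
  receive the mean of the reference values over their tied ranks. The
  "identical sorted vectors" property therefore holds exactly for tie-free
  columns.
- **Percentile convention** for the background threshold: linear
  interpolation between order statistics at rank 1 + (n−1)p (the numpy
  `linear` method). Background is estimated per T0 sample from
  negative-control probes, with the pooled-T0 estimate kept as a fallback
  (`bg_mode="pooled"`).
- **Detection majority is strict** (> 50% of T0 samples); a tie drops the
  probe. Negative controls never enter downstream modeling.
- Background filtering runs on normalized log2 values, since it follows
  normalization in the stage order.

### Vehicle-arm drift test

Hairpins can drift over time without any drug interaction (fitness effects
of the knockdown itself). A nested-model F statistic compares
intercept+replicate+timepoint against intercept+replicate on vehicle
post-selection samples, with significance by permutation: timepoint labels
are shuffled within each replicate block, and because F depends only on
which samples share a level, shuffles that reproduce the observed partition
(the identity and, with two timepoints, the global label swap) are redrawn.
p = (1 + #{F_perm ≥ F_obs})/(n_perm + 1), so the smallest attainable p is
1/(n_perm+1). Probes with residuals at rounding-noise level are assigned
F = 0.

## The synthetic screen

`simdata.simulate_screen` emulates the study conditions the pipeline
assumes: ~6,000 hairpins (3 per gene by default — the library's true
gene-to-hairpin multiplicity is not published, so 3 is a fixed free choice),
triplicate infections, vehicle plus two pooled drug doses, a shared
pre-selection harvest (T0) and two post-selection timepoints. Per-hairpin
log2 abundance evolves per sampled timepoint t ∈ {0, 1, 2}:

    a_h(t) = baseline_h + β_h·t + treated·γ_h·t

with baseline_h ~ N(0, 1) (library representation), β_h ~ N(0, 0.05)
(drug-independent fitness drift), and γ_h the planted drug interaction.
Abundances are renormalized per specimen, multinomially sampled at depth
6×10⁶ (the emulated screen infects 6 million cells per replicate), and
mapped to intensity as

    log2(count + 0.5) + affinity_h + offset + N(0, noise_sd²)

The per-probe affinity term (N(0, 5²) log2 units, constant across samples)
models hybridization-efficiency differences; it is absorbed by each probe's
intercept and exists to give arrays the wide dynamic range the IQR ≥ 6
sample-QC rule presupposes. Negative-control probes (300) are drawn from a
fixed Gaussian centered on the 5th percentile of real-probe intensity
(sd 0.25), independent of arm, so the background filter has a real floor to
work against: it removes the controls plus the lowest-signal hairpins
(~6% of probes in the default configuration).

Defaults: 100 of 6000 hairpins planted as depleted with γ = −2/3 per sampled
timepoint, i.e. an average treated−vehicle log2 difference of −1 across the
two post-selection timepoints (−⅔ at T1, −4/3 at T2); additive noise
sd 0.3. Under these conditions the screen thresholds recover ≥ 90% of
planted hairpins at near-zero empirical FDR (seeds 1–5), and all-neutral
screens keep the fraction of probes at p ≤ 0.01 inside the 99% binomial band
around 0.01 for both ordinary and moderated tests.

What the generator does **not** emulate: retroviral integration and
selection kinetics, PCR amplification bias, probe cross-hybridization and
sequence-dependent affinity structure, spatial array artifacts, or technical
rescans (the replicate-resolution stage is exercised by dedicated unit
fixtures instead). Passing the planted-recovery suite therefore shows the
statistics behave as designed under the assumed noise model, not that a real
screen's biology is reproduced.

## The synthetic cohort

`simdata.simulate_cohort` emulates the downstream tumor analysis: per-gene
normal reference N(8, 1), 131 tumors of which ~15% carry the index gene
shifted +3 SD (comfortably past the z ≥ 2 call boundary), exponential times
to biochemical recurrence with a 36-month median in the reference class and
a 3-fold hazard in the high class, and administrative censoring at the
(1 − censor_rate) quantile of the drawn event times (~30% censored).
Kaplan–Meier estimation and the log-rank test are delegated to lifelines;
tests verify them against closed forms (KM = empirical survival without
censoring; log-rank against a brute-force O/E/V tabulation, 49/17 on the
four-subject toy cohort). Tied censoring at an event time follows the
standard convention (censored after events).

The z-score classification treats "reduced" as z ≤ −2, symmetric with
"over" at z ≥ 2; the asymmetric literal reading (reduced iff z < 2) is
available by setting `lo`. Alteration percentages count the union of
samples altered in any category, so a sample both over-expressed and
amplified counts once; printed percentages round to one decimal while
internal values stay at full precision.

## Assay arithmetic

Percent-of-control viability is 100·mean(cond)/mean(control) with the SEM
propagated from the numerator's replicate spread only — the control row is
exactly 100. Caspase activity is normalized per condition by matched day-3
viability and then expressed relative to control (control ≡ 1). Relative
expression is 2^−ΔΔCt with ΔCt formed per replicate against the reference
gene; because the propagation method for fold-change uncertainty is a
convention, the SEM band is reported as the asymmetric envelope
2^−(ΔΔCt ± SEM(ΔCt)). All outputs are invariant to global rescaling of
luminescence and to adding a constant to every Ct.

## Problem sizes and determinism

The test suite runs the full 6,300-probe × 21-sample screen where the claim
under test concerns the default study conditions (recovery, calibration) and
a 660-probe scaled replica elsewhere; cohort simulations use n = 131
throughout. All randomness flows through `numpy.random.default_rng` seeded
from the config, and equal seeds give byte-identical artifacts (verified
down to file digests in the CLI tests).

## Known limitations

- One cell line per design; cross-line comparisons happen at the hit-table
  level (`cross_line_specificity`), not in a joint model.
- Replicates are fixed effects; no random-effect or duplicate-correlation
  structure.
- The drift test reports per-probe permutation p-values without pooling
  information across probes.
- No gene-level p-value combination: genes are summarized by counting
  qualifying probes.
- The GEO-style ingestion adapter maps array columns to sample-sheet rows
  via a user-supplied mapping; it does not parse vendor raw formats.
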