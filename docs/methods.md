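# Methods

This note documents the models, parameter choices and numerical conventions
behind `meaperf`, in the order the pipeline runs.

## Recording model and processing chain

Recordings are modelled as 16-channel extracellular voltage traces in µV at
25 kHz from a single-shank array with 100 µm electrode pitch, so channel
adjacency is index order. Processing is:

1. **Band-pass 300–3000 Hz**, 4th-order Butterworth applied
   forward-backward (`sosfiltfilt`). Zero-phase filtering avoids biasing
   spike trough times, which downstream matching and the coincidence window
   depend on. Band edges are configurable (`PipelineConfig.band_hz`).
2. **Common-average referencing (CAR)**: the per-sample mean across
   electrodes is subtracted from every channel. CAR and the band-pass are
   both linear, so their order is immaterial (tested). A consequence worth
   remembering when validating against ground truth: a spike confined to one
   of 16 channels keeps 15/16 of its amplitude on that channel and leaks
   −1/16 elsewhere.
3. **Detection** at `mean − 4·SD` per channel, one event per negative
   crossing, with the trough inside a 1 ms lockout taken as the event time.
   σ is the sample standard deviation of the full filtered channel, computed
   once before any excision; a robust (median/MAD) estimator is available
   (`robust_sigma`) but is not the default. Snippets span 0.4 ms before to
   1.0 ms after the trough (35 samples at 25 kHz). These window choices are
   conventional for rodent cortical units; results are insensitive to ±20 %
   changes because unit templates fit well inside the window.
4. **Artifact rejection.** Amplitude: any event whose snippet exceeds
   +300 µV or dips below −300 µV is dropped (boundary values are kept — the
   rule is an exclusion of strictly larger excursions). Coincidence: events
   within ±0.5 ms of each other are grouped; if a group covers a contiguous
   run of more than five shank positions, every event on that run is removed.
   The two filters commute (tested), and are applied amplitude-first.
5. **Sorting.** Snippets are projected onto their top 3 principal
   components and clustered with k-means for k = 2..5; k is chosen by
   silhouette score, falling back to k = 1 when no k reaches a silhouette of
   0.5 (splitting a single Gaussian cluster scores well below that).
   Clusters with fewer than 10 spikes are discarded. Ties break toward
   smaller k. This stands in for a commercial sorter with manual
   verification, which is not reproducible in code.
6. **Metrics.** Noise is the RMS of the channel after excising detected
   snippets. Vpp is max − min of a unit's mean waveform; SNR = Vpp/noise;
   spike rate = 1/median ISI. The median-ISI definition overestimates the
   mean rate of a Poisson train by 1/ln 2 ≈ 1.44× — it is a definition, not
   an estimator of the mean rate, and is applied as defined.

Electrodes with ≥ 1 sorted unit are *active*; device-level metric means
average over active electrodes only.

## Phase statistics

Weeks map to acute (1–5), sub-chronic (6–11) and chronic (12–16) phases;
the ranges are configuration, and a phase can be dropped entirely. The
acute assignment of week 0 (surgery-day) recordings is ambiguous in this
study design; the default ranges start at week 1 and week 0 raises, which
makes the ambiguity explicit at the call site.

- **AEY z-test**: pooled two-proportion z without continuity correction,
  one-tailed by default. This exact form reproduces, from the rounded
  printed proportions, the study's printed p-values (0.42 vs 0.35 at
  n = 1056 → p = 0.0005; 0.41 vs 0.37 at n = 880 → p = 0.043), which is how
  the choice was fixed. Proportions may be passed as rates with an n, so
  printed percentages can be used directly.
- **Outliers**: values beyond 3 MAD from the median are removed, with the
  MAD taken plainly (no 1.4826 consistency factor) — "3 median absolute
  deviations" is read literally; the scaled variant is a parameter. A zero
  MAD removes nothing and warns. Applied per metric within group × phase.
- **Omnibus + pairwise**: Kruskal–Wallis with tie correction (H = 0, p = 1
  for all-identical data); the pairwise follow-up family is Mann–Whitney
  rank-sum tests (Dunn's pooled-rank z available as an option — the source
  protocol names only the omnibus test and the FDR procedure, so the
  pairwise statistic is a documented choice). The family contains exactly
  the 9 allowed contrasts for 2 groups × 3 phases: 3 between-group
  within-phase and 6 within-group across-phase; cross-group cross-phase
  contrasts are refused by construction.
- **BKY FDR**: the two-stage adaptive linear step-up is implemented
  literally — stage 1 is BH at q′ = q/(1+q), the stage-1 rejection count r₁
  estimates m₀ = m − r₁ true nulls, and stage 2 reruns the step-up at
  thresholds i·q′/m₀. Adjusted values are defined so that `adjusted ≤ q`
  reproduces the flags. The implementation matches `statsmodels`'
  `fdr_tsbky` on random vectors (cross-checked in tests, never used as the
  implementation). Note that the two-stage procedure is *not* uniformly more
  powerful than plain BH at q: when stage 1 rejects nothing, BKY rejects
  nothing even if BH at q would reject — the guaranteed dominance is of
  stage 2 over stage 1.

## Radial immunohistochemistry quantification

Distances are measured from the implant-hole *boundary* (not centroid), so
irregular holes do not distort bins. The hole polygon is rasterized
(`polygon2mask`) and the Euclidean distance transform of the outside region
gives per-pixel distances; half a pixel is subtracted to refer distances to
the boundary rather than the nearest hole-pixel center. At the default
1 µm/px synthetic scale this sub-pixel convention keeps binned profiles of a
noiseless exponential image within 1 % of the annulus-weighted analytic bin
mean (verified against numerical integration).

Intensity bins are 50 µm wide to 700 µm (14 bins); the 650–700 µm bin is the
background. GFAP — constitutively expressed — normalizes as raw/background
(background → 1). IgG and CD68 — absent in healthy tissue — normalize as
(raw − background)/background (background → 0); the division keeps values
scale-free across exposure settings, and plain subtraction is available
where raw-intensity offsets are preferred, since "background adjusted to 0"
admits both readings. Neuron density uses counts per unmasked bin area
(µm²) to 500 µm, normalized to the 400–450 µm bin. Masked (artifact) pixels
are excluded from every statistic; a fully masked bin is flagged undefined
rather than imputed.

Group comparison is an equal-variance two-sample t-test per bin at p < 0.05,
skipping bins with fewer than 2 defined values per group. All 14 bins are
computed and written; the reporting flag marks 0–350 µm, the range where
implant-driven differences are expected.

Cell segmentation is out of scope: the pipeline consumes centroid lists
produced by a trained segmenter. A threshold-plus-connected-components blob
finder is bundled for synthetic fixtures only and is not suitable for
tissue.

## Gene-count normalization and differential expression

The count pipeline follows digital-counting (nCounter-style) convention:

1. **Positive-control normalization** rescales every probe in a sample by
   `reference / geomean(positive controls in that sample)`. The reference is
   the geometric mean across samples of those per-sample geometric means, so
   the factors' geometric mean is exactly 1; the arithmetic-mean reference
   (vendor convention) is an option. No data-dependent reference can make
   the normalized matrix exactly invariant to rescaling one sample — the
   output is invariant up to a single global constant, and everything
   downstream that matters (log2 fold change, Welch t, BH decisions) is
   invariant outright (tested).
2. **Background flagging**: per sample, mean + 2 SD (ddof = 1) of the
   negative controls; endogenous counts at or below background are flagged,
   inclusively, but never altered — no background subtraction step is
   defined in the source protocol, so flags are informational.
3. **Housekeeping normalization**: same construction on the housekeeping
   genes, applied to endogenous + housekeeping probes (RNA content).
4. **Low-count filter** on normalized counts: a gene is removed when the
   fraction of samples with fewer than 20 counts is ≥ 0.85. The
   complementary reading (kept only when ≥ 85 % of samples reach 20) is a
   config option (`rule="keep_if_high"`).
5. **DE**: Welch (unequal-variance, two-tailed) t per kept endogenous gene
   on log2(normalized + 1) — the log transform stabilizes variance for
   count data; raw-scale testing is an option — then BH at FDR 0.05.
   Log2FoldChange is computed on normalized group means (not the mean of
   per-sample logs).

## Synthetic-data generators

Every generator is a pure function of its parameters and a seed.

**Recordings** are band-limited Gaussian noise (filtered white noise,
rescaled per channel to the requested RMS exactly) with embedded biphasic
spike templates — 0.4 ms negative phase carrying 60 % of Vpp, 0.6 ms
repolarization carrying 40 % — firing as homogeneous Poisson processes with
a 1 ms refractory period. Default unit parameters (Vpp 30–45 µV in cohort
summaries, firing 1–5 Hz, noise 6–8 µV RMS) sit in the ranges typical of
awake-rat cortical recordings with this device class; recovery benchmarks
use Vpp 80 µV on 6 µV noise so the trough sits at 8σ, the regime where a
threshold detector should be essentially lossless. Artifacts are monophasic
negative half-sine deflections: amplitude artifacts 600 µV deep and 0.5 ms
wide on one channel (still > 300 µV after filtering and CAR), coincident
artifacts 150 µV on ≥ 6 adjacent channels jittered within 0.2 ms —
sub-threshold for the amplitude rule, so only the consecutive-electrode rule
can remove them. The generators do not model electrode degradation,
impedance drift, bursting, waveform drift or overlapping spikes.

**Cohorts** draw each electrode-week active state independently as
Bernoulli with a group × phase probability (defaults 0.32/0.42/0.37 for
treatment and 0.31/0.35/0.41 for control across acute/sub-chronic/chronic —
the study's observed yields); active records get plausible metric draws.
Independence across weeks is a simplification: real electrodes have strong
week-to-week autocorrelation, so passing tests show the accounting and the
tests are right, not that the design's power claims transfer to correlated
data.

**Images** realize `background + amplitude·exp(−d/λ)` around a polygonal
hole plus Gaussian noise, with nuclei placed uniformly outside a depletion
radius. Real immunohistology texture (cells, vessels, staining gradients)
is deliberately absent; the images exercise geometry, binning and
normalization, nothing more.

**Count panels** total 152 probes (132 endogenous, 6 housekeeping, 6
positive controls in a 4× geometric series, 8 negative controls), with
negative-binomial endogenous counts (var = µ + φµ², default dispersion
φ = 0.05), per-sample lognormal assay-efficiency and RNA-content factors
(SD 0.1) that the two normalizations are designed to remove, and Poisson
negative controls. At φ = 0 counts degenerate to rounded means, giving a
deterministic limit for tests. Null panels (all fold changes 1) mirror the
study's null DE outcome: under the global null BH rejects something in
about q = 5 % of panels, so "zero significant genes" is expected in about
95 % of seeds — a property the calibration checks measure rather than
assume.

## Problem sizes in the checks

The bundled checks use a 60 s, 16-channel, 25 kHz session for spike
recovery; 1000 replicates for the all-null family-rejection rate; 200 seeds
for null gene panels; 1800² px noiseless images at 1 µm/px for radial
accuracy; and 1000 random p-vectors for the FDR oracle comparison. These
sizes were chosen to make the binomial/Monte-Carlo error of each estimate
small relative to the property being checked while keeping the whole suite
fast on one CPU.

## Known limitations

- Unit identity is not tracked across sessions; each week is sorted
  independently, as in the study design.
- The silhouette-based choice of k is a pragmatic stand-in for manual
  curation; heavily overlapping units (amplitude ratio near 1) will merge.
- The coincidence rule removes genuine spikes that happen to coincide with
  a motion artifact on their channel run; on the synthetic benchmarks this
  loss stays below 1 %, but dense multi-unit data would lose more.
- Density profiles assume centroids are complete and unduplicated; no
  correction for segmentation errors is applied.
- The z-test on AEY treats electrode-weeks as independent Bernoulli trials,
  as the sample-size arithmetic implies; within-animal correlation would
  widen the true sampling variance.
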