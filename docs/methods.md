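# Methods

`condenscan` implements the quantitative core of a proximity-labeling
analysis of nuclear condensates: given paired APEX-labeled and input DNA
sequencing coverage, it scores each genomic region's enrichment, converts
that score into a physical distance-to-condensate through an
imaging-calibrated cubic, and calls regions *inside* the condensate when
their score exceeds the curve's inflection point. Around that core it
provides the co-occupancy classifications, perturbation statistics, puncta
quantifications, and interactor filters that such a study needs, plus a
seeded synthetic-data suite that generates every input with planted ground
truth.

## The enrich score

For windows of `window_size` bp (default 1 kb, built from 10-bp coverage
bins), the raw statistic is a depth-normalized log ratio

    r_w = log2((apex_cpm_w + pc) / (input_cpm_w + pc)),

with CPM = window counts per million mapped and pseudocount `pc = 0.5`.
The enrich score is `r` min–max scaled to [0, 1] between robust percentile
anchors (defaults: 1st and 99th percentiles of `r` over all windows),
clipped at both ends. The percentile anchors make the score robust to
outlier windows; CPM makes it invariant to library depth (multiplying
either library by any positive constant changes no score). Region-level
scores are length-weighted means over the windows a region overlaps.

Design note: the assay this reproduces reports a 0–1 score without giving
its formula; log-ratio-plus-robust-scaling is the package's own
definition, chosen to be depth-invariant, monotone in labeling intensity,
and to reproduce the reported score range. Both `r` and the scaled score
are exposed so either can be audited.

## Distance calibration and the inflection cutoff

FISH measurements give, per probe, a set of distances from the probed locus
to the nearest condensate. `build_calibration_points` pairs each probe's
mean distance with its region score; `fit_calibration` fits

    y = c0 + c1 x + c2 x^2 + c3 x^3

by ordinary least squares (at least 4 distinct scores required; coefficient
standard errors and residual sd are reported; the fit domain is the probes'
score range). The membership cutoff is the inflection point

    x* = -c2 / (3 c3),

the root of `y'' = 2 c2 + 6 c3 x`: beyond it the predicted distance stops
responding to further enrichment, i.e. the locus is already at the
condensate. `inflection_cutoff` verifies `y''(x*) ≈ 0`, requires `x*` to
lie in the fit domain, and stores it on the curve. Membership is strict:
a region is called inside the condensate iff its score is *greater than*
the cutoff.

The package ships the reference calibration reported for the RYBP
condensate assay, `y = 2.42 − 17.1x + 45x² − 38.8x³` with its published
cutoff 0.2924, as `REFERENCE_CURVE` / `REFERENCE_CUTOFF`. Note that the
closed-form inflection of those (rounded) printed coefficients is
45/(3·38.8) = 0.38660, not 0.2924; the package always reports the
closed-form inflection of whatever curve it fits and makes no attempt to
reconcile the two — with full-precision coefficients this is the only
self-consistent contract. Distance units are treated as micrometres
throughout (the y-axis unit is conventional for nuclear-scale FISH).

### Probe design matters

A practical finding reproduced by the simulations: if calibration probes
are chosen from *unbound* background regions, the ones selected at
low-but-nonzero scores are exactly the ones whose score is inflated by
counting noise (a winner's-curse error in x), while their true distance is
the background distance — points that sit far off the curve and bias the
fitted inflection. `select_probe_regions` therefore tiles evenly spaced
target scores over a candidate set, and the examples and acceptance runs
restrict candidates to bound (peak) regions. With that design, membership
recovery on synthetic data is exact even at realistic sequencing and
imaging noise.

## Co-occupancy classification

All interval logic is 0-based half-open; peak sets are sorted and merged on
construction (overlapping or bookended intervals collapse, as in `bedtools
merge`); overlap means ≥ 1 bp shared, strand-agnostic. Classes:

* **active** RYBP loci: H3K4me3 overlap and no H3K27me3; **repressive**:
  H3K27me3 overlap regardless of H3K4me3 (bivalent counts as repressive);
  **other**: neither.
* **RING1B-lacked / RING1B-enriched**: RYBP peaks overlapping WDR5 (the
  RYBP interval is the region unit), split by RING1B overlap. The two
  classes partition the base set exactly.
* **RYBP_WDR5 / RYBP_WDR5_RING1B**: condensate-member regions (score above
  cutoff) overlapping WDR5, split by RING1B; members without WDR5 are
  `other`.
* **Promoter classes** (TSS ± 2 kb by default): poised = RYBP ∧ K4 ∧ K27,
  active = RYBP ∧ K4 ∧ ¬K27.

Every classification is tested against per-base boolean-mask oracles.

## Perturbation statistics

* `region_signal` / `signal_matrix`: length-weighted means of binned
  coverage over regions, and fixed-width or region-scaled profile
  matrices (zero-padded with a warning at chromosome edges).
* `wilcoxon_one_tailed`: paired signed-rank test on after − before
  (paired is the default because the compared groups are the same loci in
  two conditions; an unpaired rank-sum fallback is available). Zero
  differences are dropped. For n ≤ 25 the exact null distribution is used
  (rank-polynomial convolution; full 2ⁿ enumeration with midranks when
  |d| values tie), otherwise a normal approximation with tie and
  continuity correction. The exact path is validated against sign-flip
  enumeration; the approximate path is calibrated to 0.05 ± 0.01 type-I
  error at the study's region counts (thousands of loci).
* `fraction_changed`: strict inequality, optional relative-change floor
  (default 0 — equality is never a change).
* `count_peak_changes`: retention by ≥ 1 bp overlap (peak boundaries
  jitter between conditions); `n_before = n_lost + n_retained` always.

## Differential expression (simplified stand-in)

A full count-model fit (edgeR/DESeq-style) is out of scope; the stand-in
is deliberately simple but calibrated:

1. median-of-ratios size factors (median ratio to gene-wise geometric
   means over genes expressed in all samples);
2. per-gene ordinary t-statistics on log2(normalized count + 1) with
   **trend-based empirical-Bayes variance moderation**: per-gene variances
   are shrunk toward a lowess trend of log-variance on average
   log-abundance, with prior degrees of freedom estimated by matching the
   spread of log variances against the chi-square spread expected from
   the residual degrees of freedom alone. The trend matters: counting
   noise makes low-abundance genes noisier on the log scale, and a
   constant prior understates their variance and inflates the far tail.
3. Benjamini–Hochberg FDR; fold changes are `log2((mean_B + pc)/(mean_A +
   pc))` on the normalized count scale.

An exact conditional binomial test on pooled normalized counts is retained
as `method="binomial"`. It is *not* the default because pooling across
replicates ignores biological variance: under negative-binomial noise with
dispersion d its z statistic is inflated by roughly sqrt(1 + d·µ), which
is strongly anticonservative for replicated data (at µ = 100, d = 0.05 the
nominal 1e-4 tail is hit ~100× too often). The moderated-t default keeps
the null false-discovery proportion at or below the nominal 0.05 in
simulation while detecting 4-fold changes at 3 vs 3 replicates with power
≈ 1.

Derived summaries: the totipotency-gene rule (FDR < 0.05 **and** fold
change strictly greater than 2 — an exactly 2-fold gene is excluded),
up/down splits among significant members of a gene set, and set-overlap
fractions.

## Imaging

Puncta are segmented by thresholding (Otsu, or mean + k·sd) followed by
fully-connected components (8-connectivity in 2D) with a minimum area of
4 px; centroids are intensity-weighted and reported in physical units.
Cross-channel pairing is greedy nearest-neighbour under a distance cap —
optimal matching is unnecessary at realistic puncta densities, and the
tests bound the gap against maximum bipartite matching on separated
instances. "Visible enrichment" of a second channel in a punctum is
operationalized as mean in-mask intensity > 2× the channel's frame median
(the ratio is a parameter; the underlying criterion in the imaging
literature is qualitative). Manders coefficients are the thresholded
variant: M1 is the fraction of channel-A intensity over A-positive pixels
that falls on B-positive pixels, and symmetrically for M2; thresholds
default to per-channel Otsu, and Costes auto-thresholding is deliberately
not implemented (deterministic thresholds keep the quantity testable).
Point-to-nearest-punctum distances use a KD-tree on physical-unit
centroids and support anisotropic pixel sizes.

## Interactome filters

Peptide-count IP-MS: partner iff peptides strictly exceed 2 *and* strictly
exceed 1.5× the control count. SILAC: partner iff intensity strictly
exceeds 1.5× control. Proteins absent from the control are treated as
control = 0 (the protocols don't address missing controls; this is the
permissive reading), so any positive intensity with no control signal
qualifies under the SILAC rule, while the absolute peptide floor still
applies for IP-MS. Both rules are monotone: raising a measurement never
removes a partner. IDR content is consumed as a per-residue annotation
(disorder prediction is a separate tool family) and summarized as
disordered-residue fractions with a descending ranking.

## The synthetic-data generators

All generators hang off a frozen `SimulationConfig`; a fixed seed yields
byte-identical outputs (each generator draws from its own
`default_rng([seed, stream])`). What they emulate, and the defaults:

* **Blueprint**: 180 loci of five classes (40 RYBP_WDR5, 40
  RYBP_WDR5_RING1B, 20 active-without-WDR5, 20 repressive, 60 background)
  of 2 kb each, placed on the 1-kb window grid of a 5-Mb single-chromosome
  genome with at least one empty window between loci. Each class carries a
  fixed, class-consistent occupancy table over the eight ChIP targets.
  Planted enrich scores are uniform per class: members 0.41–0.56,
  non-member RYBP classes 0.05–0.36, background 0. The member range sits
  above the truth curve's inflection (0.3866) with margin while keeping
  the truth cubic non-negative (the printed reference cubic goes negative
  beyond score ≈ 0.58, so "member" scores stop short of that);
  `true_distance = max(cubic(true_es), 0)`.
* **APEX tracks**: the expected per-window APEX CPM is constructed so that
  the scorer's raw statistic is *exactly affine* in the planted score,
  `r(es) = r0 + s·es` with dynamic range `s = 3` (8-fold maximum
  enrichment) and the offset `r0` solved numerically so CPMs total 1e6.
  This self-consistency construction means that in the noiseless limit the
  recovered score is an affine (order- and inflection-preserving) image of
  the truth, so the whole pipeline is exactly invertible: scoring,
  calibration, cutoff and membership all reproduce the blueprint with zero
  error. Counts are Poisson at the configured depth (default 2e7 reads
  over 5 Mb; `noiseless=True` returns expectations). The assay itself
  provides no physical link between labeling efficiency and score — this
  link is the package's modeling choice, made for testability.
* **FISH**: per probe, `max(0, Normal(cubic(true_es), sd))` with sd 0.1 µm
  over 50 cells (distances cannot be negative).
* **ChIP**: a peak exactly over every locus carrying the mark, tracks with
  background 1 and enrichment +8 expected counts per bin, Poisson or
  noiseless. The perturbed variant scales enrichment by 0.3 at exactly
  `round(fraction · n)` marked loci.
* **Counts**: negative binomial with variance µ + d·µ² (default dispersion
  0.05, Poisson at 0), gene means lognormal around 100, 3 replicates per
  condition; condensate-class genes carry planted depletion fold changes
  (0.25× for the active class, 4× derepression for the repressive class).
* **Images**: Gaussian spots (σ = 2 px, peak 100 over background 2,
  Gaussian read noise sd 1) at non-overlapping positions, channel
  membership Bernoulli per planted co-localization fraction, 0.1 µm
  pixels; the planted centroid/membership table is returned with the
  image.
* **MS tables**: planted partners comfortably above both calling rules,
  decoys constructed to fail at least one rule (too few peptides, ratio at
  or below threshold, or background-only).

What the generators do **not** emulate — and hence what passing tests do
not show about real data: mappability and GC bias, fragment-size effects,
peak-boundary jitter, overdispersion in ChIP coverage, chromatic shift and
uneven illumination in images, and shared-peptide ambiguity in proteomics.
The suite demonstrates that the *computations* are correct and calibrated,
not that the biological signal in any real dataset is this clean.

## Numerical choices and degenerate inputs

* Degenerate score profile (all windows identical) is an error, as is a
  cubic with `c3 = 0` (no inflection) or an inflection outside the fit
  domain.
* Scores exactly at the cutoff are non-members (strict "above").
* Equal before/after signal is not a decrease (strict `<`).
* All-zero count rows get log2FC 0 and p 1; all-zero paired differences
  give p 1 with a warning.
* Exact Wilcoxon switches to the tie-safe enumeration only up to n = 20
  (2ⁿ cost); beyond 25 the corrected normal approximation is used.
* Track resampling conserves the length-weighted signal integral to
  floating-point accuracy; uncovered bases count as zero signal.

## Problem sizes

Defaults were chosen so a full test run and the acceptance script each
complete in well under a minute on one core: 5-Mb genomes with 180 loci,
1,000-replicate null calibrations at 2,331 paired regions for the
signed-rank test, 100 simulations of 1,000 genes for the
differential-expression calibration, 1,000 random cubics for the
inflection oracle, and 100 seeded replicates for coefficient recovery.
These sizes are stated in the tests themselves and scale linearly if
larger runs are wanted.

## Known limitations

* The enrich-score formula and the labeling-efficiency link are this
  package's constructions; numbers produced on real data will match the
  original assay's published values only up to those definitions.
* The inflection cutoff is sensitive to probe placement and to the cubic
  family itself; the probe-design guidance above is essential in noisy
  regimes.
* The differential-expression stand-in has no per-gene dispersion model;
  genes with genuinely gene-specific overdispersion are handled only
  through the variance trend.
* Greedy punctum pairing can be suboptimal in pathological geometries
  (chains of near-cap spacings).
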