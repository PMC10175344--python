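# Methods

`methclass` implements a methylation-array analysis workflow for mixed
Illumina 450K/850K tumor cohorts: virtual-array construction, stratified
quantile normalization, probe blacklisting, UMAP + HDBSCAN methylation-class
discovery with reference matching, intensity-based copy-number calling
against copy-neutral references, cohort-level gain/loss frequency tracks,
and a 2×2 outcome association test.  This note records the models, the
parameters that matter, and the design choices made where more than one
reasonable option existed.

## Synthetic cohort model

Every stage is exercised on a generated cohort, so no downloads or binary
IDAT parsing are needed.  The generator emulates the statistical structure
the downstream analysis relies on; it does not attempt to reproduce
platform chemistry.

**Probes and designs.** `n_probes_per_array` probes per design are placed
uniformly at random on `n_chromosomes` equal-length chromosomes.  Exactly
`round(overlap_fraction × n_probes_per_array)` probes are shared between
the two designs, emulating the 450K ∩ 850K intersection.  Each probe gets
an Infinium stratum (`I-red`/`I-green`/`II` with probabilities
0.15/0.13/0.72, a rough sketch of real array composition) and independent
Bernoulli blacklist flags (defaults 4% sex, 5% SNP, 5% cross-reactive,
1% non-unique).  Flags are drawn independently of chromosome; the filter
consumes flags only, so nothing downstream depends on where flagged
probes sit.

**Beta model.** Each probe has a baseline beta of 0.1 or 0.85 (50/50),
mimicking the bimodal methylome.  Class signature probes — drawn from the
shared, unflagged pool so the signal survives intersection and filtering —
are shifted away from their baseline mode by `signature_beta_shift`
(default scenarios use 0.4).  Per-sample noise is Gaussian on the logit
scale (sd 0.3 by default; the logit keeps betas in (0,1)); betas are
clipped to [0.001, 0.999] and clipping is logged, never an error.  No
published estimate exists for the fraction of probes differentially
methylated between the tumor classes of interest, so class separability
is a free simulation parameter; the default (500 signature probes of
5,000, shift 0.4, noise sd 0.3) produces clearly separable but not
trivially separated classes.

**Intensities and copy number.** Total intensity `T` per probe/sample is
log-normal with mean `baseline_intensity` (default 5,000 fluorescence
units) and coefficient of variation `intensity_dispersion` (default
0.15).  A copy-number event multiplies `T` by `2^(±log2_effect)` on the
probes it covers, for the samples that carry it (per-sample Bernoulli
with the event's penetrance).  Channels are `M = beta·T`, `U = T − M`, so
`M + U = T` exactly and the beta ratio is unaffected by copy number —
CNV is recoverable from total intensity while betas stay interpretable.
Copy-neutral reference samples are simulated (signature- and event-free)
rather than drawn from a public control set, removing all external
dependencies.

**What the generator does not emulate.** Probe-type chemistry differences
beyond the stratum label, dye bias, background fluorescence, FFPE
artifacts, batch effects, correlated neighbourhood methylation, and
realistic genome geography (real chromosome lengths, CpG islands).
Passing tests therefore demonstrate the pipeline's statistical behaviour
under its stated assumptions, not performance on raw clinical arrays.

## Preprocessing

Matrices are processed in the order combine → normalize → filter → beta.

* **Virtual array** — probe sets of all contributing matrices are
  intersected; samples concatenated; probes ordered canonically by
  (chromosome in natural order, position, probe id).
* **Stratified quantile normalization** — within each probe-type stratum
  and each channel separately, each sample's values are mapped onto the
  cross-sample mean of the order statistics, assigned back by rank; ties
  receive the mean of the order statistics they span.  This is a
  deliberate simplification of the fixed-quantile interpolation full
  array pipelines apply (with their background correction and sex
  handling): sex probes are removed anyway, and the mean-quantile map is
  exactly testable — sorted per-stratum values are identical across
  samples after one pass, and the map is idempotent on tie-free data.
  (With ties, a tie block replaced by its group mean can reorder
  relative to neighbouring values on a second pass, so idempotence is
  exact only in the tie-free case — which continuous intensities are,
  almost surely.)  One sample is returned unchanged with a warning.
* **Filtering** — any probe with a sex / SNP / cross-reactive /
  non-unique flag is dropped; "not uniquely matching" is purely a
  manifest flag, no alignment is performed.
* **Beta** — `M / (M + U + 100)`; the offset 100 is the community
  convention and configurable.  With offset 0 and `M = U = 0`, beta is
  defined as 0 and logged.

## Class discovery

UMAP runs with `init = "random"`, `min_dist = 0.0`, `spread = 3.0`
(the parameters this analysis style uses for tumor methylation maps);
`n_neighbors` and `n_components` stay at the community defaults 15 and 2
(the embedding is visual; both configurable).  A seed is mandatory —
UMAP is stochastic, and recovery guarantees are quantified across seeds
rather than assumed exact.  HDBSCAN (`min_samples = 4`,
`min_cluster_size = 4`) runs on the embedding coordinates, confirming
the visual clusters; noise points get label −1.  All retained probes are
used by default; an optional top-variance probe preselection
(`top_variance_probes`) and a sensitivity switch that clusters the beta
matrix directly instead of the embedding (`cluster_on="betas"`) are
available but off by default.  The copy-neutral CNV control samples are
not part of the tumor cohort and are excluded from the embedding.

Discovered clusters are matched to previously published class labels by
majority vote among their labeled members; a cluster with no labeled
members, or whose majority label does not exceed purity 0.5, is NOVEL.
Majority rule is the minimal defensible threshold where none is
published.  The labeled reference cohort and the new samples are
embedded jointly (one map shows both populations).

## Copy-number calling

Per sample: total log2 intensity `log2(M + U + 1)` per probe; ordinary
least squares of the query on the copy-neutral reference samples plus
intercept (negative coefficients permitted; a flag enables non-negative
fitting); residuals median-centered so the genome-wide median is 0 —
this, with the intercept, makes profiles invariant to global intensity
scaling up to the pseudo-count nonlinearity, which decays as
~1/intensity (≈8·10⁻⁴ at intensity 10³, ≤10⁻⁶ at ≥10⁵).  Ratios are
aggregated into genomic bins — tiling windows of `target_bin_size`
merged left-to-right until each bin holds ≥ `min_probes_per_bin` probes
(defaults 50 kb / 15, the conumee-style values for real-scale manifests;
the sparse synthetic genome uses 2 Mb windows via configuration), with a
trailing deficient window merging left and under-populated chromosomes
excluded with a warning.  The per-bin value is the median member-probe
ratio.

Segmentation is a from-scratch circular binary segmentation: at each
step the circular two-arc split maximizing the pooled two-sample |t| is
found (arcs are scanned as `x[i:j]`, `i ≥ 1`, against their complement,
so every circular partition is visited exactly once; ties resolve to the
smallest `(i, j)`; a zero pooled variance with distinct means counts as
a perfect split).  The split is accepted if its seeded permutation
p-value — `(1 + #{permutation max |t| ≥ observed}) / (1 + B)` with
`B = 100` shuffles — is ≤ `seg_alpha = 0.01` and both arcs hold ≥ 2
bins; accepted splits recurse on the resulting linear sub-segments.
With B = 100 the smallest attainable p is 1/101 ≈ 0.0099, so at
α = 0.01 a split on pure noise is accepted only when the observed
statistic beats every permutation, giving the measured ~98% single-segment
rate on 50-bin N(0,1) input.  Segments with |mean| ≥ `call_threshold =
0.15` are called gain/loss per bin; the threshold follows common practice
for log2-ratio calling and is configurable — no published value exists
for this analysis.  Constant or too-short segments return unsplit; a
single bin is a single segment.

The reference set is an explicit required input (≥ 2 samples; the
pipeline also runs each reference against the others as a neutrality
diagnostic when ≥ 3 are present).

## Cohort summary tracks

Per group and per bin, `pct_gain = 100 × #(members called gain) /
n_members`; losses analogous.  Frequencies come from discrete
segment-derived calls, not averaged ratios, so the y-axis reads as
"percentage of samples altered"; segment calls rather than raw bin
ratios are the counting unit because segments are the published output
of the caller.  Samples without a CNV profile (e.g. the copy-neutral
controls) are excluded from the denominator.  Tracks over a union of
disjoint groups equal the size-weighted average of the group tracks,
exactly.  `compare_tracks` ranks bins by the larger of |Δpct_gain| and
|Δpct_loss|.

## Outcome statistic

`chi_square_2x2` implements the textbook statistic
`n(|ad − bc| − c₀)² / ((a+b)(c+d)(a+c)(b+d))` with `c₀ = n/2` under the
Yates correction (clamped at zero), p from χ²₁, rejecting tables with a
zero marginal.  The pipeline builds the table as NOVEL-cluster members
versus the remaining clustered samples against seizure-free status;
samples with missing outcome and the CNV controls are excluded.  The
demonstration cohort draws outcomes at seizure-free probability 0.38
for the CNV-rich unlabeled class versus 0.72–0.76 elsewhere, mirroring
the adverse-outcome contrast this kind of analysis is meant to surface.

## Demonstration cohort and problem sizes

The packaged demo (`demo_config`) uses 6,000 probes per design at 70%
overlap on 8 × 30 Mb chromosomes, five classes (9 + 14 + 16 + 11 labeled
reference samples, 21 unlabeled CNV-rich samples) and 8 copy-neutral
controls — a deliberately scaled-down sketch of a published-reference /
new-cases cohort that keeps a full end-to-end run under a minute.  The
unlabeled class carries whole-chromosome gains (penetrance 0.55 and
0.4), a half-penetrance distal-arm gain on chr5 (the "about half the
class carries the signature arm gain" motif), a whole-chromosome loss
and an arm loss; one labeled class carries a marginal 12%-penetrance
gain; the rest are flat.  Acceptance-style experiments use the sizes
stated in their tests (e.g. 5 × 20 samples with 500/5,000 signature
probes for recovery; 20 carriers with a ~300-probe arm event for CNV
recovery).

## Known limitations

* The quantile-normalization simplification means results will not match
  minfi's `preprocessQuantile` numerically on real data.
* CBS here uses the plain two-sample t over bins with a permutation
  test; no undo-splits pruning or weighting, so long chromosomes with
  many small shifts may over-segment relative to DNAcopy.
* Intensity-based calling has no tumor-purity or allele-specific
  modelling; subclonal events attenuate toward the call threshold.
* The retained-probe count of a real cohort depends on the real Illumina
  manifests and published cross-reactive lists, which are out of scope
  here; filtering behaviour is validated on generated flags instead.
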