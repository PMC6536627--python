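# Methods

## Design under analysis

The pipeline targets a two-factor between-subjects design: three inbred
mouse strains (B = C57BL/6J, N = C57BL/6NJ, D = DBA/2J) crossed with four
treatment histories — normal housing (NH), chronic mild stress (CMS), and
each of those followed by 15 minutes of acute restraint (NH-R, CMS-R).
Hippocampal expression is measured on the log2 scale, one array per
animal, four to five animals per strain-by-treatment cell. The biometric
arm measures plasma corticosterone, weekly fecal corticosterone
metabolites (fCORT), body-weight change over the chronic-stress period,
and organ weights at sacrifice.

## Template model and calling rules

Within each strain, the response of a transcript to stress history is
summarised by two binary templates over the ordered groups
(CMS, CMS-R, NH-R): transient 0:1:0 and sustained 1:1:0, with the
inverse patterns encoding down-regulation. The model is deliberately the
simplest one consistent with that encoding: log2 expression regressed on
the single binary indicator. This choice has two consequences that the
tests exploit:

1. the slope t-test (df = n − 2) is exactly the pooled-variance
   two-sample t-test grouping samples by the indicator, which provides an
   independent textbook oracle; and
2. the "inverse" down-regulation patterns are exactly the same fit with
   negated slope, so only two fits per transcript-strain are needed and
   direction is read off the sign of the best fit's slope.

NH samples take no part in template fitting — the templates are defined
over the three stress-exposed groups only — and are used solely in the
phenotype analyses.

A transcript passes in a strain when all of the following hold: best
template p ≤ 0.05 (nominal), Welch NH-R vs CMS-R contrast p < 0.05,
linear-scale relative change `2^(mean log2 CMS-R − mean log2 NH-R) − 1`
strictly greater than 10 % in magnitude, and the sign of that change
consistent with the fitted direction. The 10 % rule is applied on the
linear scale with a strict inequality, so a change of exactly 0.10
fails. BH q-values are computed per strain across all transcripts and
reported, but calling is by nominal p: with this design's power, FDR
control at 0.05 retains too few transcripts for a descriptive
cross-strain comparison, so the nominal threshold plus the effect-size
filter is the intended operating point. Ties between the two shapes
(equal p) are broken by larger |t|, then in favour of the transient
shape — deterministic and documented. Zero-variance transcripts return
p = 1 rather than erroring so that degenerate fixtures pass through.

The per-strain up/down split is tested against 50:50 with the 1-df
goodness-of-fit chi-square `(n_up − n_down)² / (n_up + n_down)`. There is
only one classification variable, so a goodness-of-fit test, not a test
of independence, is the applicable form.

## Overlap, concordance, clustering

Passing calls are partitioned into the seven exclusive Venn regions of
the three strain sets; pairwise regions exclude the triple region, the
convention under which the published per-region counts
(430 + 258 + 1363 + 9 + 31 + 130 + 6) sum to the published union of
2,227. Concordance between a pair or triple of strains counts, over the
transcripts passing in all requested strains, those with identical
direction in all of them. Shared transcripts are clustered by average
linkage on Euclidean distances between per-strain contrast vectors (one
signed log2 CMS-R − NH-R value per strain, three values per transcript)
rather than on the full sample matrix; this matches the strain-level
contrast display the analysis is after and stays defined under unequal
replicate counts. Input rows are sorted by transcript id before linkage
so leaf order is deterministic; the dendrogram is exported as Newick.

## Phenotype statistics

Because acute restraint does not affect body or organ weight, treatments
are pooled into CMSgroup (CMS, CMS-R) and NHgroup (NH, NH-R) for the
biometric analyses. Each measure is tested with a two-way Type III ANOVA
(strain × pooled group) with interaction. Type III sums of squares are
coding-dependent; sum-to-zero contrasts are used (the convention of
`car::Anova(type = 3)`, against which the implementation was verified).
Effect size is η² = SS_term / SS_total with SS_total the corrected total;
each η² lies in [0, 1]. Raw tissue weights are analysed without
body-weight correction. Plasma CORT is cleaned by a single-pass removal
of values more than 2 sample standard deviations (ddof = 1) from their
strain-by-treatment cell mean, computed on the full cell including the
candidate; cells smaller than 3 are left untouched, and the removal is
not iterated. Post hoc contrasts use Welch's unequal-variance t-test with
Welch–Satterthwaite degrees of freedom. The weekly fCORT table is
natural-log transformed (the base affects neither F nor p; natural log is
fixed for reproducibility of transformed values) and analysed as
strain × week with week categorical; within-animal correlation across
weeks is ignored by this model, a deliberate replication of the simple
two-factor analysis rather than a repeated-measures one.

## Enrichment

Over-representation of a target list against a background universe uses
the upper-tail hypergeometric test per category, with categories
restricted to their background members. The minimum-size rule ("at least
5 genes per category") is applied to the category's size within the
background, not to the overlap — the convention of the web services this
replaces — and categories below the floor are excluded *before* BH
correction, so the correction's m equals the number of tested categories.
Only the one-sided over-representation test is offered.

## Synthetic-data generator

The generator is first-class, tested code; it defines the conditions
under which the pipeline's statistical claims are validated.

**Expression.** Per-transcript baselines are uniform on 4–12 log2 units;
residuals are i.i.d. Gaussian (SD 0.25 log2 units by default), the
conventional noise model for RMA-normalised microarray intensities.
Planted effects shift the group means of the template's responsive groups
by ±1.0 log2 units; the NH group always sits at baseline. Defaults are
the emulated design: 25,858 transcripts, 3 strains × 4 treatments ×
5 replicates. Strain-unique planted fractions (B 0.017, N 0.010,
D 0.053) make the expected unique counts echo 430/258/1363 of 25,858;
the four multi-strain Venn regions get exact counts (9, 31, 130, 6) by
assigning contiguous transcript-index blocks rather than rejection
sampling, so fixtures can rely on exact region sizes. Direction biases
(up fraction B 0.5, N 0.7, D 0.3) reproduce the strain asymmetry in the
emulated data; for shared transcripts, the first strain of a region
anchors the direction and the others agree with the pairwise concordance
probability (B–N 1.0, B–D 0.10, N–D 0.115, echoing the 9/9, 3/31 and
15/130 same-direction counts). Template shape is drawn 50:50 per
transcript-strain.

**Phenotypes.** Animal-level tables with 6–8 animals per strain-treatment
cell by default (12–16 per pooled group), counterbalanced sacrifice day.
The per-strain fCORT baselines (B 1.77 ± 0.20, N 1.73 ± 0.27,
D 1.93 ± 0.22 assay units) and the 10.4 mg chronic-stress heart-weight
deficit are the emulated study's printed values. Remaining means are not
printed anywhere and were fixed once at field-realistic values for adult
female mice that respect the printed orderings: heart D (160 mg) > N
(145) > B (138); thymus N (60 mg) > B (45) > D (30); adrenal N (5.2 mg)
> B (4.6) > D (3.8); brain B ≈ N (0.47 g) > D (0.41 g); weight gain N
(3.5 g) > B (2.0) > D (1.5) with a 1.0 g chronic-stress attenuation in B
and N only; post-restraint plasma CORT N (420 ng/mL) ≈ D (410) > B (250)
with a +120 ng/mL cross-sensitization increment for the N strain's CMS-R
group. fCORT is simulated on the natural scale — the log transform is an
analysis step, mirroring the real order of operations — with a week-1
multiplicative elevation (×1.5) declining linearly to baseline at the
return week (4), flat thereafter.

**What the generator does not emulate.** Probe-level structure, RMA
normalisation and array-outlier removal (inputs are taken to be already
summarised log2 values); mean–variance dependence and heavy tails of
real array noise; correlation between transcripts; within-animal
correlation of weekly fCORT; estrus-cycle variation. Passing tests
therefore demonstrate correctness of the statistical machinery and
calibration under the assumed Gaussian model, not robustness to real
microarray artefacts.

## Numerical choices and degenerate inputs

* Zero-variance expression: template fit returns β = 0, p = 1.
* Welch with two zero-variance groups: t = 0, p = 1 when means agree;
  p = 0 with a warning when they differ.
* Constant ANOVA response: all sums of squares 0, p = 1.
* Empty design cells raise an error naming the cell; the model is not
  silently reduced.
* All randomness flows through `numpy.random.default_rng` seeded from the
  configuration; identical seed and config give byte-identical outputs,
  and the pipeline manifest records seed, config and package version.

## Problem sizes in tests and the acceptance script

Statistical suites run at sizes chosen to make their Monte Carlo error
small relative to the asserted bounds: 10,000 transcripts for null
calibration (3 binomial SE ≈ 0.0065 around 0.05), 6,000 transcripts
(~660 planted effects) for recovery, and 2,000 animals per group for the
heart-deficit and fCORT-baseline sampling checks (SE well under the
asserted 0.5 mg and 0.02 units). The acceptance script runs the
expression recovery at the full 25,858-transcript scale.

## Known limitations

* The fCORT ANOVA treats week as an independent between-subject factor;
  p-values for the week effect are anti-conservative under within-animal
  correlation.
* Calling at nominal p ≤ 0.05 is descriptive, not FDR-controlled; at
  25,858 transcripts a nontrivial share of single-strain calls are
  expected false positives, which is why cross-strain overlap counts on
  real data should be read qualitatively.
* The pipeline accepts arbitrary strain/treatment label sets, but the
  template definitions require the four treatment groups by name
  (NH, CMS, NH-R, CMS-R).
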