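# Methods

This note documents the models behind `inips`, the defaults and why they
were chosen, and what the synthetic studies do and do not show.

## Fragment-length model

Maternal and fetal insert lengths are two-component Gaussian mixtures
truncated to [60, 250] bp and discretized to integer base pairs
(probability mass ∝ density at each integer, renormalized):

| origin   | components                              |
|----------|------------------------------------------|
| maternal | 0.80·N(166, 9²) + 0.20·N(140, 14²)       |
| fetal    | 0.68·N(166, 9²) + 0.32·N(132, 8²)        |

The shared 166-bp component is the mono-nucleosomal peak; the
origin-specific short components encode the qualitative biology (fetal
excess below 150 bp, maximal around 125–135 bp; a broader maternal
sub-nucleosomal shoulder). No published parametric form exists for these
distributions, so the component locations/scales are calibration
choices, and the weights are set so the 125–135 bp window-probability
ratio is r ≈ 3.29 — the value at which the closed-form enrichment
relation reproduces the observed fold-changes (≈2.5× at the clinical
median FF of 14.6%, ≈3.3× over a 1–10% gradient, maternal decreases
≈1.3× and ≈1.10×). All parameters are overridable.

Working on the integer grid makes sampling, inclusive window filters and
analytic window probabilities exactly self-consistent; the discrete
window masses agree with continuity-corrected continuous integration to
~5·10⁻⁴ relative (tested).

## Genome model

Simulations run on hg19 chromosome lengths divided by a configurable
scale (default 500) with 20-kb bins — ~320 bins genome-wide, each bin
standing in for ~500 real bins. Chromosome *percentages* are
scale-invariant, and their sampling noise is governed by read depth, not
bin count, so z-score behaviour matches full scale; what the miniature
genome coarsens is only the GC-correction granularity. Per-bin GC is
Beta-distributed (concentration 300) around a chromosome-specific mean
(0.41 ± up to 0.04, drawn per chromosome), so GC composition differs
between chromosomes as in the real genome. A configurable fraction of
bins (default 3%) is N-masked and excluded from simulation and analysis.
`scale=1` gives a full-scale genome when needed.

## Sampling model

Fragment origin is Bernoulli(FF). Given origin, the bin is drawn with
probability ∝ bin length × copy weight × g(GC), where

* fetal trisomy multiplies the target chromosome's fetal weight by
  (1 + 0.5·m), m ∈ [0,1] the fraction of the placental lineage carrying
  the trisomy (m = 1: full trisomy);
* a maternal CNV multiplies the maternal weight by its copy ratio;
* g(GC) = clamp(1 + β(GC − 0.41), 0.2, 1.8), default β = 2, is a
  relative sampling weight (the clamp range exceeds 1, so it is a
  weight, not an acceptance probability) — a simple monotone bias that
  GC-LOESS should remove; its shape is a design choice, since only the
  use of LOESS correction is standard, not the bias form.

chrY is calibrated rather than length-weighted: per origin its total
weight is y·(autosomal weight sum)/(chrY length) per bin-length-and-g
share, with y = 0.170% for male-fetal fragments and 0.002% (a
misalignment floor) for any female-origin DNA. The scaling is arranged
so the *GC-corrected* expected %chrY is exactly FF·0.170% +
(1−FF)·0.002%, because the FF formula consumes corrected profiles. chrX
is plain length-weighted for both origins (a male fetus's single X is a
≤0.3% effect on the denominator and is ignored).

Fragment mode additionally draws a uniform start within the bin, an
insert length from the origin's pmf, MAPQ (90% at 60, 5% uniform 11–59,
5% uniform 0–10) and a 2% duplicate flag; these filter rates are
unreported in the field's pipelines and are configurable defaults.
Count mode draws per-(bin, origin) counts directly
(binomial origin split, then multinomials), storing per-bin rather than
per-chromosome counts so the GC-correction stage sees genuine simulated
bin counts. The two modes agree in distribution (tested at 4σ binomial
bounds per chromosome × origin × length-window cell). Coordinates are
0-based half-open; fragments belong to the bin containing their start.

## Size selection

A window is an inclusive [low, high] insert range; library-frame windows
subtract 90 bp of adapters (190–240 bp libraries ↔ 100–150 bp inserts).
The physical gel selects the *library* (≫ sequencing depth, effectively
the population) before sequencing, so count-mode selection with depth
renormalisation redraws the sample at full depth from the post-selection
distribution: the enriched origin mix FF' = FF·p_f/(FF·p_f+(1−FF)·p_m)
times the per-origin bin distributions, which selection (being
length-only) leaves unchanged. Modelling selection instead as thinning
of the sequenced reads plus resampling would cap the effective depth at
the window mass (~5% of reads) and invert the method's benefit; that
thinning model remains available via `renormalize_depth=False` (and is
what fragment mode does, since there the record set *is* the sequenced
reads). The analytic FF' predictor is the oracle both modes are tested
against.

The Methods-level gel window (100–150 bp) and the analysed enrichment
window (125–135 bp) are both supported; experiments default to 125–135,
where the fetal/maternal ratio is maximal (r: 2.68 / 3.29 / 1.62 for
115–125 / 125–135 / 135–145).

## Pipeline

Read filters: retain MAPQ > 10, length > 35 bp, non-duplicate (count
mode folds these in as uniform thinning). Binning by start coordinate;
GC rounded to 0.1%. Zero-read and N-bins are masked per sample. GC
correction fits a degree-1 LOESS (span 0.3, configurable; no span is
standard) of mean raw count vs rounded GC on unmasked, full-width
autosomal bins, evaluates it at every bin's GC, and sets
corrected = raw × median(raw)/fitted; non-positive fits mask the bin;
identical GC everywhere degrades to the identity with a warning.
Partial end-of-chromosome bins are excluded from the *fit* (their low
counts reflect width, not GC) but are corrected like all others.
Chromosome percentages divide each chromosome's corrected sum by the
all-autosome corrected total; %chrY deliberately uses the same
denominator so the chrY calibration and the FF formula share one
convention.

## Calling

z = (p − μ_ref)/σ_ref against ≥20 euploid references processed by the
same arm (selected references for the selected arm — required for
z ~ N(0,1) under selection). Classification: z > 4.00 affected,
z < 2.58 unaffected, both boundary values no-call (strict inequalities).
The "U-test" naming sometimes attached to this step is ambiguous; a
rank-based alternative (normal-approximated one-sample Mann–Whitney
against the reference vector) is available via `method="rank"` for
comparison, with the plain z-score as the primary method since printed
z values (2.7, 4.2, …) are on that scale. Trisomic fraction
2(p/μ_ref − 1) is clamped below at 0; mosaicism degree is trisomic FF ÷
total FF.

## Experiments

Cohort FFs are log-normal, parameterised by printed medians (cohort
studies report only medians and ranges; log-normal is the standard
positive-skew model for plasma FF): median 14.58% with log-sd 0.55 for
the 50-sample enrichment cohort (range ≈3–55%), median 8% with log-sd
0.4 for the 9-sample window comparison (range ≈4–15%). The gradient
study uses the fixed fractions {1,2,3,4,5,10}% × 30 samples. Depth is
5×10⁶ fragments/sample, at which the chr21-percentage CV is ≈0.4%, so
the threshold behaviour (unselected arm failing below FF ≈ 4%, selected
arm succeeding at 2%) *emerges* from the noise model rather than being
hard-coded. References are 100 arm-matched euploid male samples.
Gradient fold metrics use ground-truth origin fractions (the chrY
estimate is noise-dominated at FF = 1%); the enrichment-cohort and
window-comparison metrics use chrY estimates, as the measurements they
mirror did. Sensitivity/specificity use Clopper–Pearson 99% intervals;
no-calls count as non-detections by default (`no_call_policy="exclude"`
reproduces the clinical convention of resolving them).

## What the synthetic studies do not show

The simulator omits sequencing error, alignment artefacts, mappability
structure, the 10-bp periodicity fine structure of cfDNA lengths,
between-sample GC-bias variation, and gel-extraction efficiency curves
(the window is sharp). Passing tests therefore demonstrate the internal
consistency of the statistical machinery and that the printed
fold-changes/sensitivities follow from the calibrated length model —
not performance on real sequencing data. Clinical-scale
sensitivity/specificity tables from real cohorts are out of scope; only
the metric machinery (confusion matrices with 99% CIs) is provided.

## Numerical notes

All randomness flows through `numpy.random.Generator` seeded from the
sample spec or experiment config (child seeds via `SeedSequence`);
identical (config, seed) gives bit-identical results. FF estimates are
clamped to [0,1] with a warning when raw values stray outside (noise
near FF = 0). Degenerate inputs error loudly: empty selections,
all-masked bin tables, zero-variance references, non-finite z, adult-male
%chrY not exceeding the female background.
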