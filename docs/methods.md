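# Methods

This note documents the models and procedures implemented in `ctdnakit`,
the parameters that matter, the numerical choices made where the design was
genuinely open, and what the synthetic-data tests do and do not show.

## Somatic-candidate prioritization

Input is one variant-call list per cohort sample (flat TSV or VCF; AAF and
depth from per-sample fields, population MAF / region class / consequence /
gene from annotations — the package computes no annotation itself).
Non-SNV rows and malformed rows (AAF outside [0, 1], negative depth) are
dropped with logged counts before filtering.

Five per-call predicates define a likely-somatic candidate:

| rule       | predicate                          | boundary      |
|------------|------------------------------------|---------------|
| region     | `region_class == "exonic"`         | —             |
| AAF        | `aaf <= 0.35`                      | inclusive     |
| MAF        | `pop_maf is None or pop_maf < 0.01`| strict        |
| depth      | `depth >= 50`                      | inclusive     |
| recurrence | site carried by `<= 25%` of samples| strict `>` excludes |

Unannotated variants (no population MAF) pass the MAF rule: rarity filters
apply to annotated variants only. The recurrence fraction uses the exact
(chrom, pos, alt) site, counts distinct carrier samples, and divides by
**all** cohort samples, not just covered ones; this choice is configurable.
Recurrence is evaluated against the *input* cohort, which makes the kept
set independent of rule order and the filter idempotent; the fixed
application order (region → AAF → MAF → depth → recurrence) matters only
for the per-rule removal tallies, which are reported in that order. With
fewer than two samples the recurrence rule is undefined and the filter
refuses to run.

The mutation matrix collapses each (gene, sample) cell to the most severe
consequence present, ordered nonsense > missense > synonymous > other, and
reports per-consequence candidate totals — the inputs a waterfall plot
needs.

## Fold enrichment

`allele_proportions` divides each base count by the **stored total**, not
the four-base sum: pileup totals from real instruments include calls other
than A/T/C/G, so the stored total can exceed the sum, and proportions can
sum to slightly below 1. `fold_enrichment` ratios post- over pre-biopsy
proportions per base; a fold is *undefined* when the pre-biopsy count is
zero (blank in reports, never 0 or infinity). The mutant base is explicit
input and never inferred from variant nomenclature — assay strand and
transcript strand can disagree.

Results carry full precision. Two one-decimal renderings exist because
published tables are not always internally consistent about rounding:
`"round"` (half-up, the default — e.g. 3.894 → 3.9, 33.862 → 33.9) and
`"trunc"` (toward zero — e.g. 163.958 → 163.9). Undefined folds render
blank in both. A `thousands=` flag on the counts reader accepts grouping
marks in fixtures transcribed from print, where '.' sometimes appears as a
thousands separator.

## Fragmentomics

An electropherogram trace is modeled as a sum of Gaussian mass densities,
one per nucleosomal multimer order, fitted by bounded nonlinear least
squares (`scipy.optimize.least_squares`, TRF):

* amplitudes (mass areas) constrained ≥ 0;
* centers constrained to per-order windows — defaults [150, 175],
  [350, 410], [600, 660], [840, 900] bp for orders 1–4, spanning the
  mono- through tetra-nucleosome peak locations;
* widths bounded in [3, 150] bp;
* deterministic initialization (window midpoints, trapezoidal in-window
  area, width = 35% of the window), tight tolerances (1e-14), so identical
  inputs give bitwise-identical fits.

The Gaussian shape is a modeling choice: electropherogram peaks are
approximately Gaussian at this scale once log-size warping is neglected.
Fitted areas below `1e-7 × (1 + total trace mass)` are snapped to exactly
zero — the optimizer keeps parameters strictly inside bounds, which would
otherwise leave ~1e-10 ghost amplitudes on absent peaks and produce
astronomically large, meaningless ratios against them.

Molar amount = mass area / peak center length (molar ∝ mass/length; the
instrument proportionality constants cancel in every reported ratio). The
di/mono **molarity ratio** therefore equals 160/360 — not 1 — for two peaks
of equal mass area at 160 and 360 bp. A mass-area ratio is available as an
option. Mass above the last center window that the fitted components'
analytic tails do not explain is summarized as `long_tail_mass` rather than
fitted as discrete orders (no discrete peaks are resolvable above ~1 kb);
when a broad tail component overlaps the tetra-nucleosome window the
order-4 peak absorbs a few percent of the tail onset, so `long_tail_mass`
reads correspondingly low. No baseline is subtracted by default (synthetic
traces are baseline-free); `linear_baseline=True` adds a fitted `b0 + b1·s`
term for real traces.

`profile_excess` returns the pointwise `max(post − pre, 0)` trace (post
linearly resampled onto the pre grid when grids differ) and per-order
percent mass increases from independent ladder fits of the two profiles.

## Paired statistics

The Wilcoxon matched-pairs signed-rank test drops zero differences
(Wilcoxon's original policy, the mainstream default; Pratt's alternative is
not implemented), assigns average ranks to tied absolute differences, and
takes W = sum of ranks of positive differences. For n ≤ 20 nonzero pairs
the two-sided p is exact: the null distribution of W is built by
subset-sum dynamic programming over the doubled ranks (doubling makes
half-integer average ranks integral) and p = P(|W′ − μ| ≥ |W − μ|). Above
n = 20 a normal approximation with continuity correction and the standard
tie correction (Σ(t³ − t)/48 off the variance) is used. Quartiles use
linear interpolation between order statistics (numpy's default); published
IQR endpoints depend on this convention, which is why it is pinned and
documented.

`compare_timepoints` pairs each patient's t = 0 draw with each post-biopsy
timepoint, excluding a patient only from comparisons it lacks, and reports
n, median/IQR per arm, W and p per timepoint.

## Synthetic-data generators

All generators are pure functions of their config including one integer
seed (`numpy.random.default_rng`); the pipeline-level config derives one
child seed per stage from a master seed via `SeedSequence`. Defaults encode
the study conditions the analysis was built for.

**Variant cohorts** — per site: germline with probability 0.45, somatic
0.10, artifact 0.05, else absent. Germline sites are carried by a per-site
random fraction of samples at AAF ~ N(0.5, 0.04) for heterozygotes (or
near 1.0 for the one-third of carriers simulated homozygous) and are
database-annotated with probability 0.9, drawing a log-uniform MAF in
[0.01, 0.5]. Somatic sites are private to one sample with AAF uniform in
[0.02, 0.35]; artifacts are shared by at least `artifact_sample_fraction`
(default 0.4 > 0.25, so the recurrence rule fires) of samples at AAF
0.01–0.10. Depths are Gamma-Poisson with mean 700 (the study's mean coding
coverage scale) and dispersion 0.3. True class labels are returned for use
as test oracles.

**Amplicon pileups** — the true mutant proportion is
`ctdna_fraction × tissue_aaf`; each read reports its template base with
probability 1 − e and each other base with e/3 (the simplest symmetric
miscall model, consistent with the small off-target counts such assays
show); counts are multinomial at the configured depth, independently pre
and post. Defaults: tissue AAF 0.5, ctDNA fraction 0.01 pre / 0.20 post,
depth 235,000 (the assay's mean depth scale), e = 10⁻³. Simulated totals
equal the multinomial depth exactly; real-data readers must not assume
this. `expected_base_proportions` exposes the closed-form expectation —
note that for mutant proportions near or below e/3 the error floor biases
the raw proportion ratio away from the nominal ctDNA ratio, so the
estimand of the fold statistic is the ratio of *expected proportions under
the error model* (identical to the nominal ratio when e = 0).

**Ladder traces** — component k deposits mass `molar_k × center_k` as a
Gaussian (centers 165/380/630/870 bp, widths 12/22/30/38 bp), plus an
optional broad > 1 kb tail (center 1300, sd 250) and additive Gaussian
noise clipped at zero. Trapezoidal mass-to-molar back-conversion recovers
the configured molar amounts exactly on noise-free traces, which is what
makes round-trip testing of the fitter meaningful.

**Kinetics** — patient i has lognormal baseline B_i (median 3 ng/mL, sdlog
0.35, the pre-biopsy concentration scale) and lognormal release amplitude
A_i (median 1.8 ng/mL, sdlog 0.5, matching the observed median increases of
roughly 1–2 ng/mL); concentration at t minutes is
`B_i + A_i · r(t; τ_i) · (1 + ε)` with r rising linearly from 0 to 1 at
τ_i ~ Uniform(60, 120) min and flat after. The rise-to-plateau shape is an
explicit stand-in: the data constrain only that some patients peak at
60 min while others are still rising at 120 min, and no quantitative
release model is established. Noise (cv 0.10) multiplies the release term
only, so t = 0 returns the exact baseline; the noise factor is clipped at
zero, keeping concentrations strictly positive. DNA clearance (half-life
< 2 h) is deliberately not modeled.

## What the tests show — and do not

Synthetic inputs carry the *statistical structure* the analysis assumes,
not biological realism: no sequence-level reads, no real annotation, no
strand artifacts, no instrument sizing calibration, no clearance kinetics.
Passing round-trip and oracle tests therefore demonstrates that the
implementation computes its statistics correctly and recovers known
generative parameters under the stated models — not that those models
describe any particular patient cohort. The patient-level published
summaries (median concentrations, peak-area increases, the 188-candidate
cohort) derive from restricted clinical data and are intentionally not
reproduction targets; the five-locus pileup table shipped with the package
is the one patient-derived input small enough to carry in full, and its
fold computation is reproduced exactly.

Problem sizes used by the test suite (100 seeded cohorts of up to 8 × 200
sites, 500 amplicon replicates per condition at depth 10⁵, 100 noisy ladder
fits, exhaustive sign-vector enumeration to n = 12) were chosen so the full
suite exercises every stochastic claim while completing in well under a
minute per module.
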