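# ctdnakit

Analysis toolkit for biopsy-induced release of circulating tumor DNA (ctDNA)
in localized prostate cancer.

In primary prostate cancer the ctDNA fraction of plasma cell-free DNA
(ccfDNA) is normally too low to detect. A prostate biopsy wounds the organ
and transiently floods the circulation with prostate-derived DNA, opening a
short "molecular window" during which patient-specific somatic mutations
become measurable in blood. `ctdnakit` implements the computational stages
of that analysis for researchers working with tumor-informed liquid-biopsy
data:

* **Somatic-candidate prioritization** (`ctdnakit.variants`) — from cohort
  variant calls, keep exonic SNVs with alternative allele fraction (AAF)
  ≤ 0.35, population minor allele frequency (MAF) < 0.01 for annotated
  variants, depth ≥ 50 reads, and site recurrence ≤ 25% of samples
  (recurrent sites are treated as sequencing artifacts); emit the candidate
  set, per-rule removal tallies, and a gene × sample mutation matrix.
* **Fold enrichment** (`ctdnakit.enrichment`) — at each assayed somatic
  locus with pre/post-biopsy amplicon pileup counts, the fold enrichment of
  base *b* is

      fold(b) = (post_count_b / post_total) / (pre_count_b / pre_total)

  and the value at the known mutant base quantifies the ctDNA release.
  Folds are undefined (rendered blank, never 0 or ∞) where the pre-biopsy
  count is zero.
* **Fragmentomics** (`ctdnakit.fragmentomics`) — decompose an
  electropherogram-style size trace into the nucleosomal ladder
  (mono/di/tri/tetra-nucleosome Gaussian peaks near 165/380/630/870 bp plus
  a > 1 kb tail), convert mass areas to molar amounts (molar ∝ mass/length),
  and report the di/mono molarity ratio and the post-minus-pre excess
  profile.
* **Paired statistics** (`ctdnakit.stats`) — per-timepoint Wilcoxon
  matched-pairs signed-rank tests (exact two-sided p by full sign-vector
  enumeration up to n = 20) with median/IQR summaries of ccfDNA
  concentrations (ng/mL plasma).
* **Synthetic data** (`ctdnakit.simulate`) — seeded generators for every
  input: labeled variant cohorts (germline/somatic/artifact), multinomial
  amplicon pileups with a symmetric miscall model, nucleosomal-ladder
  traces, and injury-release concentration kinetics.

## Worked example

The package ships the pileup counts of five validated patient-specific
somatic variants (fixtures/table2_counts.tsv). Computing the mutant-allele
fold enrichment at the SPEN locus:

```python
from ctdnakit import fold_enrichment
from ctdnakit.io import load_table2_counts

spen = load_table2_counts()[0]
res = fold_enrichment(spen)
print(f"{res.gene}: pre {res.pre_proportion:.6f} -> post {res.post_proportion:.6f}, "
      f"fold {res.mutant_fold:.3f} (printed {res.rendered()[res.mutant_base]})")
```

```
SPEN: pre 0.000162 -> post 0.006031, fold 37.114 (printed 37.1)
```

The mutant T allele made up 0.016% of reads before the biopsy and 0.60%
after — a 37-fold ctDNA enrichment. Across the five loci the mutant folds
range from 3.9 to 164.

The same computation from the shell, plus a full synthetic pipeline run:

```sh
$ ctdnakit enrich --counts fixtures/table2_counts.tsv --out report.tsv
mutant fold range across 5 loci: 3.894 to 164

$ ctdnakit all --seed 7 --out-dir run
18 candidates from 544 calls (8 samples); removed: region=75, aaf=394, maf=0, depth=0, recurrence=57; ...
di/mono molarity ratio: pre 0.246, post 0.466
t=60 min (n=6): median 3.38 -> 4.55 ng/mL, W=21.0, p=0.03125
t=120 min (n=6): median 3.38 -> 4.99 ng/mL, W=21.0, p=0.03125
all reports written under run
```

The synthetic cohort keeps 18 somatic candidates after the filter cascade;
the simulated post-biopsy trace nearly doubles the di/mono nucleosome
molarity ratio (0.246 → 0.466); and with six patients the paired signed-rank
test reaches its minimum attainable two-sided p of 2/2⁶ = 0.03125 at every
post-biopsy timepoint. `run/` then contains the candidate table, mutation
matrix, enrichment report, ladder fits, excess profile and per-timepoint
comparison table as TSV/CSV.

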