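# circout

Circadian transcriptional-output analysis at transcription-factor binding
sites.

A core circadian activator such as CLOCK:BMAL1 binds thousands of
enhancers in the mouse liver, synchronously and during the day — yet its
target genes are transcribed heterogeneously: some cycle in phase with
binding, some in antiphase, many not at all. `circout` implements the
meta-analysis machinery needed to dissect that heterogeneity from standard
genomics inputs:

- **co-bound peak derivation** — intersect two factors' ChIP-Seq peak
  lists (≥ 1 shared base) into a high-confidence co-binding set, keeping
  the second list's coordinates;
- **peak → gene assignment** — a peak whose center lies between −10 kb of
  a gene's TSS and +1 kb of its TTS (strand-aware) targets that gene;
  nearest TSS wins among candidates; location categories TSS (±1 kb),
  extended promoter ([−10 kb, −1 kb)), gene body, intergenic;
- **transcriptional-output classification** — from 12-point/48-h nascent
  RNA series: rhythmic in-phase (peak in [ZT2, ZT12)), rhythmic
  out-of-phase, arrhythmic (only if the mRNA series is also arrhythmic —
  otherwise post-transcriptional), not expressed (mean < 1 read/bp), plus
  low-expression and no-signal catch-alls;
- **peak-centered signal** — deduplication, 5′ read extension, windowed
  per-base coverage scaled to reads/bp per 10⁸ reads, with per-assay
  window halfwidths (TF ±250 bp, histone marks ±1 kb, eRNA ±500 bp,
  nucleosome ±75 bp);
- **rhythm fitting** — harmonic (cosinor) regression
  x(t) = m + a·cos(2πt/24) + b·sin(2πt/24), amplitude √(a²+b²), phase the
  clock time of the fitted maximum, F-test of the harmonic terms;
- **cross-time-point normalization** — mean normalization against a
  reference site set and rank (quantile-style) normalization;
- **group statistics** — Kruskal-Wallis with Dunn post-hoc compact letter
  displays, two-way ANOVA on rhythm extrema, and the decile-based TF
  DNA-binding **variability index** VI = Σ_d sd(q_d)/mean(q_d) over
  deciles d = 0.1…0.9 of the per-group signal distributions;
- **synthetic data** — a seeded generator for genomes, co-bound peak
  sets, circadian series and read files with known ground truth, so the
  whole pipeline is testable end to end without downloads.

## Worked example

```python
from circout import (SimulationConfig, simulate_cohort, intersect_peaks,
                     assign_peaks, classify_peaks, fraction_report)
from circout.classify import class_counts

cfg = SimulationConfig(seed=42, n_genes=500)
genes, clock_peaks, bmal1_peaks, truth, nascent, mrna = simulate_cohort(cfg)

cobound = intersect_peaks(clock_peaks, bmal1_peaks)
print("co-bound peaks:", len(cobound))

assignments = assign_peaks(cobound, genes)
classified = classify_peaks(assignments, nascent, mrna)
counts = class_counts(classified)
print(counts[["count", "percent"]].round(1))
print(fraction_report(counts["count"].to_dict()))
```

prints

```
co-bound peaks: 500
                      count  percent
output_class
Rin_phi                 109     21.8
Ro_phi                   44      8.8
AR                      254     50.8
NE                       93     18.6
post_transcriptional      0      0.0
low_expression            0      0.0
no_signal                 0      0.0
{'rhythmic_percent': 31, 'out_of_phase_percent': 29, 'n_four_classes': 500, 'n_rhythmic': 153}
```

All 500 simulated co-bound peaks are recovered by the intersection; each
is assigned to its target gene and classified from the gene's nascent/mRNA
series. The class percentages recover the generator's planted proportions
(0.2/0.1/0.5/0.2), and `fraction_report` summarizes the headline numbers:
31% of target peaks are rhythmically transcribed, and 29% of those peak
out of phase with daytime factor binding.

The same steps are available from the shell:

```bash
circout simulate --seed 42 --out-dir cohort/
circout overlap cohort/peaks_a.bed cohort/peaks_b.bed -o cobound.bed
circout assign cobound.bed cohort/genes.tsv -o assignments.tsv
circout rhythm cohort/nascent.tsv -o fits.tsv
```

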