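# Methods

## Problem setting

A circadian transcription factor dimer binds a few thousand sites in a
tissue, almost all during the same daily window, yet its target genes
split into qualitatively different transcriptional outputs. Dissecting
this requires joining several genome-wide assays on a common spine — the
co-bound peak set — and comparing time-resolved signal between the output
groups. `circout` provides that spine as a library: interval operations,
signal aggregation, rhythm fitting, normalization, classification and
group statistics, each independently testable.

## Coordinates and interval semantics

All coordinates are 0-based half-open (BED convention). Overlap means at
least one shared base, so abutting intervals `[a,b)`/`[b,c)` do not
overlap. Peak intersection keeps the second list's coordinates,
deduplicated and sorted — the convention when one factor's peak calls are
treated as the reference coordinates of the co-bound set.

A peak is reduced to one anchor position for assignment: the
integer-floor midpoint by default, or an explicit summit offset
(`center="summit"`, offset carried in the score field). Gene assignment
tests the anchor against the strand-aware window `[TSS − 10 kb, TTS + 1 kb]`;
among multiple candidate genes the nearest TSS wins, with exact ties
resolved to the lexicographically smallest gene id. This tie rule is a
deliberate fixed choice: annotation tools resolve multi-gene hits
internally and undocumented, and a deterministic rule is a precondition
for reproducible peak tables. Location categories partition the window:
TSS = anchor within ±1 kb of the TSS; extended promoter = strand-aware
signed distance in [−10 kb, −1 kb); gene body = the rest. The
half-open/closed boundary choices exist only to make the categories a
true partition; moving a boundary by 1 bp moves a handful of peaks
between categories and nothing else.

## Signal extraction

Reads are deduplicated to one per (chrom, start, strand) — first
occurrence kept — and optionally extended from their 5′ end to a fragment
length (147 bp for mononucleosomes, 150 bp for run-on reads), clipped at
position 0. Window signal is per-base coverage: for a window of width
W = 2h + 1 centered on the peak anchor (clipped at the chromosome start,
in which case the clipped width is used),

    signal = (read-bases overlapping the window / W) / (library_size / 1e8),

i.e. reads/bp per 10⁸ sequenced reads. Counting overlapping bases rather
than read 5′ ends is the default because it is what "reads/bp" measures
for extended fragments; 5′-end counting is available (`mode="fiveprime"`)
for assays where fragment length is meaningless. Default halfwidths per
assay — TF/coactivator/Pol II ±250 bp, histone marks ±1000 bp, eRNA
±500 bp, nucleosome ±75 bp — reflect the characteristic footprint widths
of those signals and live in one dict (`signal.ASSAY_HALFWIDTHS`).

## Rhythm model

Rhythms are fit by least squares with a single 24-h harmonic,

    x(t) = m + a cos(2πt/T) + b sin(2πt/T),   T = 24 h,

giving mesor m, amplitude A = √(a² + b²) (half the fitted peak-to-trough
excursion) and phase φ = (T/2π)·atan2(b, a) mod T, the clock time of the
fitted maximum. On any uniform grid with ≥ 4 points per period the fit
recovers a pure harmonic exactly (to ~1e-15); this is asserted at 1e-9.
Significance is the F-test of the two harmonic terms against the
intercept-only model (df = 2, n − 3). A constant series returns amplitude
0, p = 1, and an undefined (None) phase. 48-h series (12 points × 4 h)
are fitted with the 24-h period across both cycles, which is what makes
"arrhythmic over 48 h" a testable statement. Replicates are averaged per
time point before fitting; per-replicate fits remain available for phase
dispersion estimates.

The rhythmicity call adds two gates to the F-test: fitted peak/trough
fold ≥ `min_fold` (default 1.5; the fold is ∞ when the fitted trough is
≤ 0) and mean level ≥ `min_level` (default 1 read/bp). The gates exist
because a significant but shallow or barely-expressed oscillation is not
a usable rhythm call; the source analyses that motivated these defaults
did not publish their exact thresholds, so all three are explicit
configuration with these stated defaults rather than hidden constants.
With the gates disabled, the F-test's type-I error on Gaussian white
noise is the nominal α (checked by simulation at 1000 series, ±2 points).

## Output classification

Peaks inherit their gene's class; genes are classified from the
12-point/48-h nascent series, with the mRNA series consulted only in the
arrhythmic branch:

1. no expression record → `no_signal`;
2. mean nascent < 1 read/bp → `NE` (not transcribed);
3. mean below the rhythm-test expression floor → `low_expression`;
4. nascent rhythmic → `Rin_phi` if fitted phase ∈ [ZT2, ZT12), else
   `Ro_phi`;
5. nascent arrhythmic → `post_transcriptional` if the mRNA series is
   rhythmic, else `AR`.

The mRNA gate in step 5 is an anti-false-positive filter: cycling mRNA on
flat transcription indicates post-transcriptional regulation, and such
genes would contaminate an "arrhythmically transcribed" group. The phase
window is half-open so the rhythmic classes are complementary; boundary
membership of ZT2/ZT12 is not decidable from data anyway (a fitted phase
lands exactly on a boundary with probability zero) and is fixed by
convention, configurable. Steps 2–3 are evaluated as mean-level bands
before the rhythm test — equivalent to testing them in flowchart order,
since they depend only on the mean. With the default floor equal to the
NE threshold the `low_expression` band is empty; it becomes active when a
stricter rhythm-test floor is configured.

Expression-matched control genes (default 125 per class) are drawn from
the non-target pool per class, accepted when a Kruskal-Wallis test cannot
distinguish control from target expression (p ≥ 0.05), and redrawn
otherwise up to a bounded retry count — a seeded, reproducible analogue
of matched-control selection.

## Normalizations

**Mean normalization** divides each time point by the mean signal over a
reference site set (e.g. the 40,000 strongest open-chromatin sites),
assuming the genome-wide level of the mark is constant over the day. By
construction the post-normalization reference-set mean is 1 at every time
point, and injected per-time scale factors cancel exactly.

**Rank normalization** (quantile-style) sorts each time-point column,
averages the order statistics across columns at each rank, and replaces
every value by the rank-average at its within-column rank. Ties receive
the mean of their tied ranks' reference values — the standard
quantile-normalization convention, which keeps the map well defined and
idempotent. Output columns share their sorted values (exactly, absent
ties) and hence their means.

## Variability index

For groups g (the four output classes) and deciles d ∈ {0.1,…,0.9}:
q_d(g) is the linear-interpolation quantile of group g's signal,
s_d the sample (n−1) standard deviation of {q_d(g)}, m_d their mean, and

    VI = Σ_d s_d / m_d.

Normalizing each decile by its own mean stops the upper deciles — where
signal and hence spread are largest — from dominating the sum. VI = 0 iff
all groups share identical decile vectors; VI is invariant under global
positive rescaling and group relabeling. Deciles are computed per group
(not on pooled data); the quantile and SD conventions are pinned by a
hand-computed worked example (three identical groups plus one doubled
group → VI = 3.6). Each group needs ≥ 10 values; a zero decile mean
flags the result undefined rather than producing an infinity.

## Group comparisons

Kruskal-Wallis is the omnibus test for signal differences between output
groups. Post-hoc pairs use Dunn's rank z-test with tie-corrected pooled
variance and Benjamini-Hochberg correction — implemented here directly
(z² equals the Kruskal-Wallis H statistic on two tie-free groups, which
the tests assert) — and are summarized as a compact letter display
(insert-and-absorb: a new letter set absorbs every earlier compatible
group, then subset sets are removed). When the omnibus test does not
reject, all groups share one letter. Rhythm-amplitude comparisons use a
two-way ANOVA (group × max/min extremum, type-II) via statsmodels, with
the per-replicate extrema of the 6-point rhythms as observations. The
editable core-clock exclusion list for "non-core-clock" re-analyses ships
as `circout/data/core_clock_genes.txt`.

## Synthetic data

The generator emulates the *structure* of the real analysis, not its
biology: one chromosome of non-overlapping genes; one co-bound peak pair
per gene, the reference factor's peak uniform in the assignment window
and the other factor's center jittered within ±50 bp (guaranteeing
overlap at the 200-bp default width); decoy peaks for each factor in
disjoint slots so they never co-bind. Expression is
mesor·(1 + rel_amp·cos(2π(t − φ)/24))·exp(ε), ε ~ N(0, σ²), with σ = 0.1,
rel_amp ∈ [0.5, 0.9], mesor ~ lognormal(ln 10, 0.5) floored at 1.5
reads/bp for expressed genes and uniform [0.05, 0.5] for NE genes —
levels and amplitudes a liver nascent-RNA dataset would call typical.
In-phase truth phases are uniform on [ZT2, ZT12), out-of-phase on the
complement. Default class proportions are 0.2/0.1/0.5/0.2 over the four
headline classes. Read sets place Poisson-distributed reads entirely
inside each window so the expected windowed signal equals the prescribed
truth; background reads are uniform.

What passing on this generator does **not** show: robustness to
overlapping or nested genes, multiple peaks per gene, non-sinusoidal
waveforms, heteroscedastic or autocorrelated noise, mappability and GC
artifacts, or replicate-level batch effects. Those require real data; the
generator demonstrates correctness of the machinery under its stated
model, exactly.

## Problem sizes and determinism

The reference synthetic cohort is 2000 genes (σ = 0.1, seed fixed), on
which the pipeline achieves per-class recall ≥ 0.98, class proportions
within 0.003 of truth and phase RMS ≈ 0.24 h — comfortably inside the
acceptance bands (≥ 0.9, ≤ 0.03, ≤ 1 h). Type-I calibration uses 1000
white-noise series. Every stochastic component takes a
`numpy.random.Generator` seed; replays are identical, and the pipeline's
report bundle (classified-peak table, class counts, fractions, rhythm
fits, manifest with config hash) is byte-identical across reruns of the
same configuration.

## Known limitations

- Genes are single spans; no exon/isoform structure, no GTF parsing.
- One gene per peak (nearest TSS); emitting all candidate hits is a
  planned switch but the reported tables are single-assignment.
- GRO-Seq signal is aggregated strand-agnostically.
- The Dunn + BH post-hoc choice is one of several defensible post-hoc
  procedures; it is configurable in spirit (the pairwise table is
  returned) but only this procedure drives the letter display.
- `select_matched_controls` matches on a single expression level per
  gene, not the full time profile.
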