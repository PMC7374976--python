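# Methods

## Data model and coordinates

The unit of analysis is a fixed-width genome window ("bin", default 500 bp;
the last bin of a chromosome may be shorter and is kept so bin arithmetic
matches chromosome lengths). Coordinates are 0-based half-open everywhere,
matching BED. The central container is a bins × samples count matrix with a
sample sheet (sample_id, pair_id, condition ∈ {tumor, normal}, subtype);
each pair has exactly one tumor and one normal member and both share a
subtype. A CG dinucleotide straddling a bin boundary is attributed to the
bin containing its C.

## Filtering and normalization

Bins are removed when (checked in this order, for the removal tallies):
their chromosome is excluded (chrX by default — sex-chromosome methylation
confounds with spay status in the intended design), they contain no CG
dinucleotide, or their raw count total across *all* samples is below 20.
"Total across samples" is the less aggressive of the two readings of a
low-signal cutoff phrased per-sample; it is exposed as `min_total`.
Filtering references raw counts; quantile normalization runs on the
filtered matrix.

Quantile normalization maps every sample's count distribution onto the
reference distribution of across-sample order-statistic means. Ties within
a column receive the mean of the reference values their ranks span. With
this tie rule the map is exactly idempotent on tie-free input; on integer
counts, averaged ties perturb the column multisets so repeated application
agrees only to a fraction of a count (the tests assert both).

## DMR classification

Each bin is scored on log2(normalized count + 1) under two grouping
schemes of the same 22 samples: condition (tumor vs normal) and subtype.
The building block is the one-way ANOVA decomposition; the method-of-
moments random-effects variance component

    σ̂_b² = max(0, (MSB − MSW) / n₀),  n₀ = (N − Σnᵢ²/N)/(k−1)

is reported per scheme. **Ranking, however, uses the noise-standardized
priority MSB/MSW** (an F statistic up to constants). The raw component's
sampling noise scales with a bin's total variance, so bins that are merely
noisy — or that carry true effects which a permutation null should *not*
recover — would be over-selected when ranks are cut at a quantile; the
ratio is pivotal for null bins regardless of their signal level, which
makes the top-q cut calibrated and priorities comparable across bins. This
is the package's own choice where a mixed-model "variance priority" is
underdetermined; the ordering intent (bins whose variance is dominated by
the grouping) is unchanged.

Ranks are dense and descending per scheme, ties broken by genomic order;
percentile = rank/n. With cutoff fraction q (0.05 strict — the package
treats the historical "top 5 % ↔ p < 0.01" correspondence as a heuristic
label, not a derived quantity — or 0.10 lenient), the top ⌊qn⌋ bins of each
scheme are candidates. A bin in one top set takes that class; a bin in both
takes the scheme with the smaller percentile rank, an exact tie going to
condition (documented tie-break; the rule is otherwise undefined). The two
classes are therefore mutually exclusive by construction and
|condition| + |subtype| ≤ 2⌈qn⌉.

Per-DMR statistics exploit the pairing: condition DMRs get a paired t-test
across the (tumor, normal) log2 values of the pairs and a fold change
log2(mean tumor / mean normal) on normalized counts (a pseudocount of 1 is
added to both means only when one is zero, keeping noise-free ratios
exact); direction is hyper iff log2fc > 0. Zero-variance differences give
p = 1 (no evidence) rather than an undefined t; fewer than 3 complete
pairs gives a missing p with a warning. Subtype DMRs use the most extreme
subtype (largest |mean − rest-mean| on the log2 scale) against the
remaining samples with Welch's t-test. BH adjustment runs within each
class; q-values are supplementary output since per-DMR raw p-values are
what the validation statistics use. Pseudocount 1 before log2 throughout.

PCA standardizes the selected DMR rows (z-score across samples) and
projects samples with full-SVD PCA; hierarchical clustering works on the
same z-scored submatrix (average linkage, Euclidean, both configurable)
and exports Newick.

## Feature annotation and DMG groups

Promoter = [TSS−1500, TSS+500) in the transcription direction; TTS window
= [TES−500, TES+500); introns are transcript minus exons; shores are CGI
±2 kb minus the CGI union (community-conventional extents — none of these
widths is canonical, all are parameters). A bin receives *every* genic
feature it overlaps by ≥1 bp (multi-label, no precedence — group
membership below requires knowing every feature touched); the CGI class is
single-valued with precedence CGI > shore > nonCGI; repeat overlap is a
flag; the nearest gene is by bin-midpoint-to-TSS distance with ties to the
lexicographically smaller gene id. Overlapping transcripts may each claim
a bin; DMG grouping is per gene independently.

A DMG's group string is the subset of {P, E, I} (canonical order P < E < I)
its DMRs touch — the seven non-empty subsets I, EI, P, E, PI, PEI, PE.
A TTS-only hit keeps the gene a DMG but contributes no letter; such genes
are reported as "TTS_only" rather than silently folded into a letter
group. `group_percentage_rollup` sums per-group percentages by letter
membership (e.g. intron-containing = I + EI + PI + PEI).

## Motif scanning and enrichment

Motifs are IUPAC consensus strings (PAX5-like GCAGCCAAGCGTGACC, 16 bp;
PAX6-like NGTGTTCAVTSAAGCGKAAA, 20 bp, ship as fixtures) or PWMs.
Consensus scanning requires every position to match its IUPAC class; an N
in the *sequence* matches nothing (conservative). Both strands are scanned
and reverse-strand hits are reported in forward coordinates. Overlapping
hits count once per offset; no merging.

PWM scores are log-odds in bits against a background composition
(uniform by default). The null distribution of the word score is computed
*exactly* by dynamic programming over column scores discretized to a
granularity of 10⁻³ bits (score-grid error ≤ width·granularity/2;
granularity configurable); scanning keeps offsets whose exact tail
probability is ≤ the motif's p-threshold (0.01 default). Zero-probability
PWM cells raise an error directing the user to a pseudocount rather than
silently regularizing.

Set-level enrichment dichotomizes each sequence as with/without ≥1 hit and
tests over-representation among targets with the one-sided cumulative
hypergeometric tail of the pooled 2×2 table — exact for a sampled
background; a cumulative binomial is available as an option. Targets are
the bin sequences of hyper- (resp. hypo-) methylated intron condition-DMRs
and the background pool is non-DMR intron bins, sampled to match the
targets' CpG-count (or GC) distribution by proportional allocation over
decile strata (with-replacement fallback, logged, when a stratum is
short): methylation changes concentrate in CpG-rich sequence, so an
unmatched background would confound motif content with CpG density.

## Expression and bisulfite validation

Expression contrasts are paired t-tests on log2(FPKM+1) with
log2fc = mean tumor − mean normal; a self-contained paired analysis is
used in place of external RNA-seq differential machinery because it
matches the design and the validation statistics. A gene's methylation
direction is the majority direction over its DMRs (tie → indeterminate);
it is called anti-correlated when expression shifts significantly
(p < 0.05) opposite to methylation, correlated when same-signed,
indeterminate otherwise.

Bisulfite validation consumes per-CG C/T counts; methylation percent is
100·C/(C+T), missing when coverage is zero. Paired t-tests run per site,
per region (pair-wise mean over sites first) or per region within each
subtype. Site significance uses raw p < 0.05 with direction from the mean
difference — site-level validation calls are conventionally reported
unadjusted, and the adjusted q-values remain available upstream.

## Synthetic data: what it emulates and what it does not

Defaults are the study conditions: 11 tumor/normal pairs, subtypes
simple/ductal/complex sized 4/4/3, 500-bp windows, 4 chromosomes of
2.5 Mb (20,000 bins; the last chromosome is chrX and never receives
planted effects, exercising the filter), 150 genes with 3–8 exons,
negative-binomial counts with mean 50 and size 10 (MBD-seq counts are
overdispersed, and no canonical noise model exists for them, so dispersion
is a knob), per-bin baseline means log-normal (σ=0.5), per-sample library
factors log-normal (σ=0.2) to make quantile normalization non-trivial.
200 planted condition bins (66 % hyper, effect ±1.5 log2 units applied to
all tumor samples; half placed wholly inside autosomal introns) and 200
planted subtype bins (effect applied to both members of every pair of one
subtype — tissue-type signal independent of malignancy). Chromosome
sequences are uniform ACGT with the PAX5-like consensus planted into 30 %
of hyper-intron-DMR bins and 5 % of all other bins, random offset and
strand. Expression is log-normal FPKM with tumors of anti-correlated
genes (80 % of genes owning planted intron bins) shifted 2² opposite to
their methylation direction. Bisulfite tables draw binomial C counts at
depth 1,000 for 16 CG sites in 14 pairs, 12 sites shifted +30 points in
tumors, with per-sample biological noise (sd 0.05 on the probability
scale).

The generator does **not** emulate: read-level error or mapping,
MBD-capture biophysics (counts are NB around a bin mean, not a function
of the bin's simulated CpG content), realistic genome composition or
repeat families, correlated methylation between neighboring bins, or
tumor purity/heterogeneity. Passing recovery tests therefore demonstrates
that the statistical machinery finds the planted structure under the
assumed noise model — not performance on real MBD-seq libraries, where
coverage biases and spatial correlation are material.

## Calibration checks and problem sizes

The regression harness (`methdiff.evaluation`) runs the full analysis at
the default 20,000-bin scale (seconds on one CPU): planted condition-DMR
sensitivity and class accuracy at q=0.05; recovery under a label-permutation
null; motif-enrichment power with 500 target / 2,000 background 500-bp
sequences at plant rates 0.30/0.05; bisulfite site recovery as medians
over 20 seeds.

The permutation null uses **balanced** within-pair swaps (exactly half the
pairs, rounding either way at random). Fully random per-pair swaps draw
near-identity assignments with non-trivial probability in an 11-pair
design (P ≈ 6.5 % of swapping ≤ 2 pairs), and under those the planted
effect genuinely survives, so "recovery at chance" is not a property any
statistic can have uniformly over unrestricted swaps. Balanced swaps are
the standard small-sample device that guarantees the condition axis is
destroyed; under them recovery sits at or below ~1 % against a chance
bound of ~9.6 %.

## Determinism

Every generator is a pure function of (config, seed); the master seed
spawns a fixed, named stream per stage, so stages are independently
reproducible and the end-to-end pipeline is bit-identical under a fixed
seed (the manifest records sha256 hashes to prove it).

## Known limitations

- Bins are treated as DMRs individually; adjacent significant bins are not
  merged into larger regions.
- The variance-priority classifier has no spatial model and no per-bin
  p-value; the top-q cut is a ranking, and the "strict/lenient"
  significance labels attached to it are heuristic.
- The hypergeometric enrichment test conditions on the realized background
  sample; different background draws give slightly different p-values.
- Single-end interval semantics only (no strand-specific methylation).
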