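# Methods

## Setting

Each library comes from one cell, so every SNP in it is either homozygous
or heterozygous; sister blastomeres of one embryo share their genotype at
every locus. Observations are strand-resolved nucleotide counts at
annotated SNP positions: alleles are expressed on the reference strand,
while the strand of an observation is the alignment strand of the read.
Internally coordinates are 0-based half-open; SNP positions are carried
1-based (as in VCF) and converted only at I/O boundaries.

## Locus selection

A (cell, locus) pair enters the allelic analysis when all five criteria
hold: ≥2 distinct nucleotides observed; the top non-reference nucleotide
equals the annotated alt; coverage ≥ `min_coverage` (default 25);
for every observed nucleotide the largest identical-alignment-position
group among its supporting reads is ≤ `max_dup_frac` (default 0.5) of
those reads; and the annotation supports transcription of one strand only.

Two conventions are ours where the rules admit readings: the duplicate
criterion pools strands (duplicates arise in PCR before strand selection),
and third/fourth nucleotides count toward coverage but never enter MAF or
ratios — if such a nucleotide is the second most frequent, the locus fails
the annotated-alt criterion instead. A consequence worth knowing: a
homozygous locus whose only minor read is a singleton fails the duplicate
criterion (one read trivially concentrates at one position), so singleton-
error loci drop out of both selection and calibration symmetrically.

## Heterozygosity calibration

The minor allele frequency of a (cell, locus) is min(ref, alt)/(ref+alt)
over strand-summed raw counts of the two annotated alleles. Control cells
from a near-homozygous line contribute every locus passing criteria 3–5 —
criterion 1 is deliberately not required, since single-nucleotide loci
(MAF 0) are the calibration substrate. The decision threshold is the
nearest-rank percentile (smallest pooled value whose empirical CDF ≥ p,
default p = 0.95) of the pooled MAF list; a locus is called heterozygous
iff its MAF strictly exceeds the threshold, otherwise homozygous toward
the majority allele. The construction is distribution-free: at least a
fraction p of calibration MAFs lie at or below the threshold, and on
exchangeable fresh homozygous loci the expected false-het rate is ≤ 1−p.
At least 100 pooled loci are required; ties at the threshold are resolved
toward homozygous (strict inequality). Sister-cell genotype discordance is
flagged, never auto-corrected.

## ASE against the strand-balance null

With a₁/b₁ the ref counts on +/− strands and a₂/b₂ the alt counts,
B = (a₁+b₂+1)/(a₂+b₁+1). Under unbiased strand assignment each read lands
in the numerator with probability ½ regardless of which allele it carries,
so under the null of balanced expression log₂B and the log₂ allelic ratio
(ref+1)/(alt+1) are identically distributed — B inherits the coverage
mixture, the pseudocount and the cell's library/instrument noise, without
responding to true allelic skew. The per-cell distribution D of log₂B over
all heterozygous loci (≥50 required) is therefore the empirical null.

The p-value of a locus with log₂ ratio r is the two-tailed rank statistic

    p = (1 + #{v ∈ D : |v − c| ≥ |r − c|}) / (n + 1),

with c the median of D; the add-one correction bounds p in [1/(n+1), 1].
Centering at the median (rather than at 0) absorbs residual global
reference bias; with IUB-masked alignment the median is ≈0 anyway.
D is pooled across coverage levels, matching the original procedure;
since B and the ratio share the coverage mixture, pooling is unbiased,
though it slightly over-weights low-coverage noise for high-coverage loci.
Loci with p < α (default 0.01) are called ASE; α ≥ 1 disables the test and
calls every locus (degenerate-threshold contract). The reported expected
false-positive count is #het × α. (In the original study's tables that
column does not equal #het × 0.01 and its formula is unstated; we report
the principled quantity rather than guess.)

## Allelic imbalance between sister cells

AI at a locus het-called in both cells of a pair is the ratio of
pseudocounted allelic ratios; a call requires AI > 2 or < 0.5 **and**
Pearson χ² (1 df, no Yates correction, raw counts) p < 0.05. Tables with
an expected cell < 5 are tested anyway but flagged; degenerate margins
give χ² = 0. For 4- and 8-cell embryos every within-embryo pair is tested
and a locus counts as AI for the embryo when any pair is significant (the
original design used two blastomeres; the generalisation is ours).
Expected AI false positives per embryo are estimated by margin-preserving
hypergeometric resampling of each tested table (50 draws/locus, seeded):
the summed probability that a null table passes both filters. Because the
FC filter passes null tables more easily at low coverage, this estimate
exceeds α × #tested and is honest about the joint rule.

## 3′UTR isoforms

Poly(T)-primed coverage decays going 5′ from each poly(A) site; the
generator and the predictor both treat ~1.5 kb as the practical support.
The predictor smooths the per-base track with a running median
(`smooth_window` = 50 nt), computes the ratio of upstream to downstream
means over `min_segment` = 100 nt windows at every position (zero-padded
past the track end), keeps local maxima of that ratio ≥ `min_step_ratio`
(= 3), and reports up to six sites, strongest first, with ≥100 nt
separation. Isoform abundance at a site is upstream mean − downstream
mean, in mean-coverage units (no conversion to transcript copies); the
proximal:distal ratio compares the most-proximal and most-distal sites.
The step-detection scheme itself is this package's design — the source
analysis describes the phenomenon, not an algorithm — and all thresholds
are exposed. Predicted positions are invariant to uniform coverage
scaling; position error is dominated by the smoothing window (≤50 nt for
≥90% of two-isoform genes at distal abundance ≥1 read/nt in the
regression tests).

Poly(A)-signal scanning reports the offset (motif start − cleavage
position) of the nearest canonical CPSF hexamer (AATAAA, ATTAAA — the
two canonical variants; the set is configurable) within ±50 nt, or
absent. The full offset distribution is reported rather than a fraction
at exactly −20. Cross-cell consensus greedily clusters per-cell ends
within 50 nt (single linkage on the sorted list) and keeps clusters
supported by ≥ half of the cells; consensus end and abundance are medians
over supporting cells.

## Expression summaries

RPM = count/total × 10⁶; expressed means RPM strictly > 0.1. Fold-change
flags compare group mean RPM with a 0.01-RPM pseudocount (zero handling is
unstated in the source; 0.01 is well below the expressed cutoff).
Inter-cell similarity is the Pearson correlation of log₂(RPM+1) (the
transform is our documented choice). Differential-expression significance
testing beyond FC flags is out of scope.

## The synthetic-data generator

Defaults are the study conditions: 4 embryos × 2 blastomeres, 2,000 SNP
loci, genotype mix 25/15/60% hom-ref/hom-alt/het, negative-binomial
coverage (mean 60, dispersion 5), 45% of het loci skewed (log₂ skew ~
N(0, 2)), 6% of het loci with per-cell re-drawn skew (AI), duplicate join
probability 0.3, unbiased strands, 12 control cells with 0.3% residual
heterozygosity (configurable, not asserted — the control line is only
"nearly" homozygous).

Homozygous-locus error is beta-binomial: a per-locus error rate with mean
`error_rate` = 0.02 and intraclass correlation `error_overdispersion`
= 0.1, then binomial counts. Pure per-base binomial error at ~0.01–0.02
concentrates MAF far below what makes an empirical threshold at ≥25 reads
interesting; locus-level overdispersion reproduces the regime where the
calibrated threshold (≈0.12 under these defaults; 0.066 in the original
ES-cell data) sits well above the mean error rate. Heterozygous counts
are binomial with ref probability logistic in the true log₂ skew; error
on het loci is neglected (second-order against the allele signal).

PCR duplicates: within a nucleotide's reads, each new read joins the
alignment position of a uniformly chosen earlier read with probability
`dup_rate`, so duplicate clusters grow proportionally to their size, as
reamplification does; the modal identical-position fraction is recorded.
3′ coverage is a sum of per-isoform exponential ramps (decay length
600 nt — the functional form is our choice; the source states only the
phenomenon and the ~1.5 kb horizon) with abundance ratio 5:1
proximal:distal and per-base Poisson noise, independent per cell; AATAAA
is planted 20 nt upstream of every true site. Expression counts are
Poisson around shared lognormal transcript abundances at 10⁷ reads per
cell — the deep-sequencing regime in which sister-cell correlations reach
0.99+; at 10⁶ reads sampling noise alone caps the correlation near 0.96.

One master seed spawns per-embryo and per-cell child seeds via
`numpy.random.SeedSequence`, so a configuration is byte-reproducible
file-for-file.

What the generator does *not* emulate — and hence what passing tests do
not show about real data: alignment artefacts and mapping bias toward the
reference allele, base-quality structure, transcript-level read
positioning (counts are drawn per locus, so linked SNPs on one transcript
are independent here), bursty transcription beyond the per-cell skew
re-draw, cross-contamination between cells, and genuine third-allele
segregation.

## Problem sizes and numerical choices

Tests and the acceptance script run at desk scale: 2,500 calibration loci
× 12 control cells, 5,000-locus fresh panels, 2,000-locus power panels,
60-gene UTR panels — sizes at which the binomial tolerances quoted in the
tests are meaningful and a full suite completes in about a minute. Fixed
seeds are used for regression-style recovery tests; tolerance bands are
3-SD binomial unless stated. Degenerate inputs are defined throughout:
zero-coverage loci are errors for MAF/ratios, χ² on degenerate margins is
0 with p = 1, zero-coverage tracks yield no UTR predictions, and the
empirical p-value can never be 0.

## Known limitations

- The calibrated threshold transfers only to cells with the same error
  law as the controls; the ES-control assumption is biological, not
  checked by the software.
- The strand-balance null assumes reads are assigned to strands
  independently of allele; a strand-specific protocol would break B.
- AI on >2-cell embryos multiplies pairwise tests without multiplicity
  correction (matching the per-pair reporting of the original tables).
- UTR abundance units are smoothed mean coverage; comparing ratios across
  genes assumes comparable 3′-bias decay.
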