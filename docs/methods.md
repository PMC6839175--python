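# Methods

## The question and the experimental design

The package studies how the products of a whole-genome resequencing
experiment — coverage, the variant call set, its quality, and genotype
accuracy — respond to mean sequencing depth. The design mirrors a
depth-titration study: sequence (here: simulate) a small cohort deeply,
thin the aligned reads to a ladder of lower depths, and re-run the
identical calling pipeline at every rung. Because every tier is a
subset of the tier above, differences between rungs isolate the effect
of depth from everything else.

## Synthetic cohort

`synthio` generates the full study scene as a pure function of a config
and a seed.

* **Reference.** Uniform random A/C/G/T, default 1 Mb in one
  chromosome. Default sizes throughout are chosen so a full titration
  runs in about a minute on one core while leaving thousands of truth
  variants for stable rates; they are stated with every result table.
* **Truth variants.** Binomial placement at density 1/300 per bp, split
  9:1 SNP:indel (indels 1–10 bp, insertions and deletions equally
  likely, anchored VCF representation). SNP alternates are transitions
  with odds `titv_bias : 1` (default 2.2, the whole-genome expectation
  for mammalian data), so the realized truth Ti/Tv converges to the
  configured bias.
* **Population structure.** Each variant gets an allele frequency drawn
  from Beta(0.5, 0.5) — a U-shaped standing-variation spectrum — and
  individuals receive Hardy–Weinberg diploid genotypes from it. Several
  groups of individuals drawn from one cohort therefore share a
  site-frequency spectrum, which is how the cross-"breed" overlap
  analysis is staged.
* **Reads.** Paired-end 150 bp, fragment length N(350, 50) (library
  geometry is a convention, not an inference), uniform fragment start,
  each fragment copied from one haplotype. Base qualities are a constant
  Q30 baseline; sequencing errors are injected at rate 0.001/base and
  the erroneous base gets a low quality (uniform Q2–Q20) with
  probability 0.8, which gives the read-QC rule realistic bite. Mapping
  quality is 60 with a 3% tail at 20–50. A configurable fraction
  (default 1%) of pairs are PCR duplicates: coordinate-exact restatements
  of another fragment with independent errors.
* **Known sites and chip.** A dbSNP-like list holds a Bernoulli(0.85)
  subset of truth (optionally plus decoy entries absent from truth); a
  chip panel holds true genotypes at a Bernoulli(0.2) subset of truth
  SNP sites with 2% missingness, alleles reported on the forward
  reference strand. The chip fraction is far above a real array's
  site density so that per-tier concordance estimates rest on hundreds
  of sites at desk scale.

What the simulator deliberately does **not** model: GC and mappability
bias (placement is uniform, the Lander–Waterman regime), alignment and
mapping error around indels, base-quality miscalibration, CNVs/SVs, sex
chromosomes. Indels are carried as read *tags* rather than as gapped
alignments: reads keep full-match placements and the caller genotypes
registered indel sites from tagged gapped-vs-ungapped support, so de
novo gap discovery is out of scope. Passing tests therefore demonstrate
correctness of the pipeline's statistics under idealized sequencing,
not robustness to real-data artifacts such as mismapping.

## Read processing

QC removes a read (and, pair-consistently, its mate) when strictly more
than 30% of its bases have quality <= 20. Trimming removes trailing
sub-Q20 bases from the read-orientation 3' end (the reference-left end
for reverse reads). Duplicate marking groups pairs by fragment outer
coordinates and strand configuration, keeping the highest summed base
quality (ties: lexicographically smallest name); duplicates are excluded
from depth, breadth and pileups. Downsampling draws one Bernoulli per
pair so mates never orphan. The ladder is *chained*: each proportion is
thinned from the next larger tier, making tiers nested subsets —
the reading of a chained strategy that guarantees monotone curves.
Coverage is computed with positions 1-based inclusive externally and
half-open 0-based internally; depth labels like 6.53X are 2-dp half-up
roundings of proportion x full depth, used only for labeling.

## Calling model

Genotype likelihoods and the exact allele-count posterior are described
in the README. Numerical choices: per-sample GLs are normalized (max
log-likelihood 0) before the convolution, and the AC=0 coefficient is
recomputed analytically in log space so deep hom-alt sites cannot
underflow the site quality. theta defaults to 0.001 (the
human/livestock heterozygosity convention), emission confidence to
phred 30. Genotypes are assigned per sample as the MAP of the GL times
a Hardy–Weinberg prior at the posterior-mean allele frequency.
Candidate sites need >= 2 non-reference reads in the calling unit; under
the Q40 error floor a single alt read can never reach confidence 30, so
the prefilter does not change the emitted set. At multiallelic pileups
the alternate with the highest summed base quality is kept; bases
matching neither allele contribute equally to all genotypes and drop
out. Rank-sum annotations use mid-ranks, tie-corrected variance and a
0.5 continuity correction, and are absent when either allele group is
empty; QD is absent when no sample carries an alternate allele.
HaplotypeScore is never computed — its standard filter clause is
honored and passes by the absent-annotation rule.

## Filtering and metrics

The standard hard-filter strings (SNPs:
`QD < 2.0 || FS > 60.0 || MQ < 40.0 || HaplotypeScore > 13.0 ||
MQRankSum < -12.5 || ReadPosRankSum < -8.0`; indels:
`QD < 2.0 || FS > 200.0 || ReadPosRankSum < -20.0`) are parsed into
clause lists; a record fails when any clause fires on a present
annotation, and failed records are retained with their status set.
Metrics are computed on PASS records by default (a flag includes all).
Discovery power uses the intersection with the full-tier set rather
than a raw count ratio, making it a true fraction that is 1 at the full
tier by construction. Novel rate uses positional membership in the
known list, the dbSNP-lookup convention. Single-sample discordance
divides chip-genotype mismatches by all common sites; multisample
discordance divides by common sites where the sample's call carries a
non-reference allele — the published definition of the two quantities
differs exactly this way, and the single-sample wording is ambiguous in
its source; mismatches/common-sites is the reading consistent with the
reported percentages.

## Curve analysis

The plateau of a curve is the smallest depth whose value reaches
(1 - epsilon) of the terminal value, epsilon defaulting to 0.005 so a
99.0-vs-99.4% coverage gap still reads as a plateau. The inflection is
the observed-grid point with the most negative change of forward slope
— no spline or fit, avoiding smoothing choices the data do not dictate;
for a saturating exponential this lands on the earliest interior tier,
and a piecewise-linear alternative is noted as future work. For the
uniform simulator, breadth tracks `1 - e^(-depth)`; it can sit a few
tenths of a percentage point *below* it at low depth because mates of
sub-300 bp fragments overlap, which the independence assumption ignores.

## Scale of the shipped experiments

The analysis drivers and the test suite run the full titration at 1 Mb
x 3 individuals x 12 tiers x 2 calling modes (about one minute), the
parameter-recovery scene at 1 Mb / 20X, replicate curve checks over 5
seeds, and the annotation/overlap analysis at 300 kb x 9 individuals.
The mean-curve monotonicity check for chip discordance allows a 0.002
absolute Monte-Carlo tolerance per step, the binomial noise of a
near-zero rate estimated from ~350 common sites per sample across 5
replicates.

## Known limitations

Uniform coverage overstates real breadth at a given depth (real genomes
have inaccessible and biased regions, so published plateau depths are
higher than the uniform model's); the caller does no local assembly,
realignment or recalibration; indel discovery is registered-site only;
chip allele translation (A/B strand conventions) is not modeled; the
discordance of callers on real data also reflects mapping artifacts
absent here.
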