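# Methods

## Scope and design

`pikapool` implements the analytical chain of a pooled-transcriptome SNP
discovery study of two populations: quality trimming of single-end reads,
mapping against reference transcript contigs, per-pool threshold calling,
cross-pool classification and divergence scoring, contig-level filters,
validation-panel statistics, and synonymous/non-synonymous
characterization of coding substitutions.  De novo assembly is out of
scope: the pipeline maps reads to *provided* reference contigs, and the
contig-redundancy step asks the assembly-overlap question (90 % similarity
over half the shorter sequence) by direct pairwise alignment rather than
re-assembly, which is transparent and testable.

Because pooled read sets of this kind are generally not deposited, the
package carries a first-class simulator; its defaults define the study
conditions used throughout the tests and the analysis drivers.

## The simulator

**Populations.** Two pools ("high" and "low") of n = 3 diploid individuals
each.  Variable sites are placed on the reference at a density of 0.003
sites per base (about one SNP per 330 bases, a typical transcriptome-wide
SNP density).  Each site draws a pair of population alt-allele frequencies
(f_high, f_low) from a regime mixture: both pools polymorphic
(Uniform(0,1) each, weight 0.70), one pool fixed (weight 0.25), fixed for
alternate alleles (weight 0.05).  The weights are a design choice — most
transcriptome variation is shared, truly fixed-different sites are rare —
and the downstream recovery metrics depend on the realized chromosome
samples, not on this mixture.  Genotypes are Binomial(2, f) per individual;
the truth table records the realized alt chromosome count out of 2n = 6
per pool, which is the quantity the pooled reads actually sample.

**Sequencing.** Single-end reads, uniform start positions, lengths
~Normal(260, 60) clipped at the transcript 3' end, floored at 30 bases;
reads are emitted until the total base count reaches depth × reference
length (default 30× per pool).  Only substitution errors are modelled
(default rate 0.002 per base, the scale of pyrosequencing substitution
error); homopolymer indels are deliberately absent because the mapper and
caller are substitutions-only — the simulator's error model matches the
pipeline it feeds.  Correct bases get Q30; error bases get Q10–Q30
uniform, so roughly half of all errors pass the caller's Q20 filter and
the quality threshold is exercised in both directions.  Read names carry
pool, contig, 1-based start, individual and chromosome copy, so mapping
and pileup stages can be scored against true origins.

**What the simulator does not emulate**, and what passing tests therefore
do not show: real 454 homopolymer indels, expression-level (coverage)
heterogeneity between transcripts, RNA-normalization artefacts, paralogy
and chimeric assembly in the reference, strand effects (reads are emitted
sense-strand), and contamination.  Recovery results on this bench
characterize the threshold logic, not robustness to those artefacts.

## Trimming

Order of operations: literal adapter stripping at the read ends → fixed
terminal trim (5 bases per end) → best Mott segment → length filter
(≥ 100 bases).  The Mott segment maximises Σ(0.05 − pᵢ) over per-base
error probabilities; ties prefer the longest, then leftmost segment, for
determinism.  The linear-time implementation is verified against an
exhaustive O(L²) substring argmax on random reads.  The 0.05 "quality
limit" interpretation follows the published modified-Mott convention; the
original tool's exact windowing is proprietary, so equivalence with it is
not claimed.

## Mapping and pileups

Exact k-mer seeding (k = 16, seeds every k bases plus one terminal seed)
proposes diagonals; ungapped extension scores matches over the overlap
window.  Acceptance requires identity ≥ 0.90 over the aligned span and
span ≥ 0.5 of the read length ("similarity" and "length fraction" in the
usual read-mapper sense).  Ties go to the lowest (contig, position);
reads with more than one best-scoring placement are flagged ambiguous and
excluded from pileups, preventing paralog-driven false SNPs.  Coordinates
are 0-based half-open internally and 1-based in all emitted tables.
Pileups store per-pool counts indexed by (position, base, quality), so any
base-quality threshold reduces to an array sum at call time.  An existing
SAM file can be ingested instead (identity from the NM tag, or per-base
comparison when absent) under the same acceptance rules.

## Calling and classification

A column is called in a pool iff quality-passing (≥ Q20) depth ≥ 8 and at
least two alleles each have ≥ 2 quality-passing reads and frequency ≥ 10 %
of the quality-passing depth.  The "central quality" threshold is applied
to the pileup base itself only — the simplest defensible reading of a
neighbourhood-quality parameter whose original semantics are undocumented.
Reported allele frequencies are renormalised over passing alleles, so they
sum to one.

Merging: called in both pools → category a; called in exactly one pool →
category b only when the other pool has quality-passing depth ≥ 8 and a
single quality-passing allele, otherwise *undetermined* — a low-coverage
pool would "appear fixed even if variation were present", and this
pipeline surfaces that case explicitly instead of absorbing it into b.
Columns called in neither pool, but monomorphic at adequate depth for
different alleles, are category c.  a + b + c + undetermined = total is an
enforced invariant (the pipeline raises if it ever fails).

Divergence D = |f_high(major) − f_low(major)| with the major allele taken
from combined-pool quality-passing counts (ties broken lexicographically);
sites with more than two passing alleles stay in the table but are
excluded from D and the transition/transversion ratio, which are biallelic
summaries.  D = 1 exactly ⇔ category c.

Panel selection takes determined biallelic sites with D ≥ 0.5 whose
200-base window, centred on the SNP, fits inside the contig and contains
no other merged SNP of any status — undetermined sites also disqualify a
window, since a hidden second variant breaks a melt assay regardless of
its classification status.

## Contig filters

The high-coverage set requires length ≥ 200 and mean coverage ≥ 5× in
*both* pools (the comparison operator is configurable; ≥ is the default
reading of "minimum coverage").  Elevation-unique contigs require ≥ 5× in
one pool and *zero* mapped reads from the other.  Redundancy classes come
from pairwise ungapped overlap: scoring match = 1 − s, mismatch = −s for
similarity threshold s = 0.9, the best-sum segment on a shared-k-mer
diagonal has identity > s iff its sum is positive; a contig pair are
partners when that segment covers ≥ 0.5 of the shorter contig.  This finds
the dominant overlap per diagonal; a longer lower-identity overlap that
still clears both thresholds could in principle be missed, which is
acceptable for the duplicate/subsequence structures the filter targets.

## Validation statistics

Hₑ is plain 2pq without the 2n/(2n−1) small-sample correction — a fully
heterozygous group must print Hₒ/Hₑ = 1.00/0.50, which the corrected
estimator cannot produce.  The exact HWE test enumerates heterozygote
counts conditional on allele counts with integer weights
multinomial(n; n_AA, n_Aa, n_aa)·2^n_Aa and sums the probabilities of
configurations no more probable than the observed one (probability-ordered
two-sided p); integer arithmetic makes the p-value exact.  The LD test is
a permutation test on the log-likelihood G of the genotype-pair
contingency table with p = (exceedances + 1)/(permutations + 1): exactly
reproducible under a seed, unlike Markov-chain approximations.  On small
samples G is heavily tied, so null p-values are conservative rather than
exactly uniform; the test suite checks type-I validity at several levels
instead of strict uniformity.  "Sequential Bonferroni" is Holm's
step-down: sort p-values, reject while p₍ᵢ₎ ≤ α/(m − i + 1), stop at the
first failure.

The apparent-fixation probability (1−q)²ⁿ + q²ⁿ is the chance that a pool
of n diploids samples only one allele at a site of population frequency q.
A companion Monte-Carlo variant additionally conditions on read depth and
the calling thresholds; it converges to the closed form as depth grows
provided 1/(2n) ≥ the minimum variant frequency (true for n = 3 and 10 %).

## Coding substitutions

Translation uses Biopython's codon tables; the vertebrate mitochondrial
code (ATA→Met, TGA→Trp, AGA/AGG→Stop) is the default, as the motivating
use is comparing mitochondrial ND5 haplotypes.  Codons with multiple
differences are classified at codon granularity — each differing site
inherits the whole-codon amino-acid comparison — and stop-gains are
flagged but counted as non-synonymous.  The published ND5 haplotypes exist
only as a figure, so the analysis driver uses a synthetic 30-codon
haplotype pair constructed to carry 8 substituted sites, 3 of them
non-synonymous; it demonstrates the classifier, not the organism's actual
sequence.

## Numerical and testing choices

All randomness flows from explicit integer seeds through numpy
Generators; sub-seeds are spawned via `SeedSequence`, and every generator
is bit-reproducible.  Frequency-threshold comparisons use float division;
for the count regimes involved (depth < 2³¹) a true ratio cannot cross the
10 % threshold through rounding, and the caller is tested for *exact*
agreement with an independent per-column checker on random columns.  The
default benchmark (200 transcripts × ~1 kb, 30× per pool, seed 0) runs the
full pipeline in well under a minute; detection is scored at site level —
a qualifying site (pool-sample polymorphic with minor frequency ≥ 0.1,
quality-passing depth ≥ 8 in both pools) counts as detected when any
qualifying pool calls it — with the stricter per-(site, pool) rate also
reported.  Misses concentrate at singleton sites (minor count 1 of 6,
expected minor read fraction 1/6) whose columns draw fewer than the
required 2–3 minor-allele reads; this is the intrinsic detection floor of
the thresholds at 30×, not an implementation artefact.

## Known limitations

Ungapped alignment (no indels, no splicing); forward-strand mapping only;
no duplicate-read handling; multiallelic sites excluded from divergence;
LD test limited to genotypic association within groups; the simulator's
panel generator draws Oregon-population frequencies around the discovery
mean with extra fixation as a stylised ascertainment effect, not a
calibrated demographic model.
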