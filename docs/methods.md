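# Methods

This note documents the models, parameter choices and numerical behaviour
of `trbkit`, and what the bundled simulator does and does not emulate.

## Coordinates and references

Germline alleles are stored ungapped together with a strictly increasing
map from ungapped index to the 1-based position on the gapped alignment
(IMGT unique numbering). SNP names such as `T285C` therefore refer to
gapped-frame positions and are stable across alleles with different gap
patterns. FASTA input accepts both the pipe-delimited IMGT header dialect
(gene\*allele in field 2, functionality in field 4) and bare
`>gene*allele` headers; `.` characters are treated as alignment gaps.

**Protocol windows.** A protocol supplies, per gene, the 1-based position N
at which the V primer ends; the protocol-restricted view of an allele is
its 3' subsequence starting after N. The full (5'RACE) protocol is the
identity. Primer coordinates are data (YAML), not code, because primer
tables belong to the amplification design, not to this package.

**Gene merging.** The distance between two genes under a protocol is the
minimum, over allele pairs, of a global alignment cost with unit
mismatch/insertion/deletion penalties in which leading gaps on either
sequence are free ("padded beginning"). Free leading gaps — and only
leading — match the comparison of 3' windows of unequal length; internal
and trailing gaps pay, so a dangling 3' tail is a real difference. Genes at
distance 0 are merged by transitive closure under a slash label; merging is
idempotent and monotone in window length (full ⊆ BIOMED-2 ⊆ Adaptive).

**Pattern collapsing.** Within a (merged) gene, alleles with identical
windows form one pattern group named `gene*bpNN`/`gene*apNN` with dense
two-digit numbering in allele order; the representative sequence is the
window of the member with the longest full reference, so downstream
alignment retains maximal context.

## Assignment

V references (pattern representatives) are scored against the read prefix
with a local score `matches − 3·mismatches` maximised over the aligned
length, vectorised over the reference bank; J references analogously
against the read suffix. All references achieving the maximal score are
reported — ties are information (the genotype filters require "single best
match" reads), never broken arbitrarily. The D segment is the longest
exact substring match of a D allele inside the region between the V and J
alignments, minimum 5 nt to report; no D mismatches are modelled because
D-mismatch reads are discarded before genotyping anyway.

V mismatches are recorded as `ref`+`IMGT position`+`alt` tokens only inside
the boundary window [window start + 5, 316]: positions within 5 nt of the
primer end (or sequence start) are too error-prone to trust, and positions
3' of IMGT 316 belong to the junction. Both bounds are configuration
constants.

The junction runs from the conserved FR3 cysteine codon (rightmost
codon-aligned TGT/TGC of the V reference) to three nucleotides past the
J-gene F/W-G-x-G motif. A read is *productive* when the junction length is
divisible by 3 and its translation contains no stop codon; a junction that
cannot be located leaves productivity unknown and the read outside both
strata. Because the junction starts on a codon boundary of the V frame, a
length indivisible by 3 is exactly a V-to-J frame shift.

## Genotyping

For one gene with per-allele unique-read counts, candidate genotypes are
all non-empty subsets of the top-4 observed alleles (additional alleles are
pooled into the error mass). Under a genotype with k alleles, carried
alleles have expected fraction (1−ε)/k and the mis-assignment probability ε
is shared equally by observed non-carried alleles; the genotype likelihood
is the multinomial at those fractions, the prior uniform, and the reported
`lk` is the base-10 log Bayes factor between best and runner-up genotype
(base 10 chosen for readability; "confident" defaults to lk ≥ 2). With a
single observed allele the model space is a single homozygous model and lk
is infinite. ε defaults to 0.01 for V and J genes. Genotyping uses only
reads with a single best V call and at most one in-window V mismatch; D
genotyping additionally requires ≥ 9 nt of exactly matched D sequence,
because shorter matches inside G-rich junctions are unreliable.

TRBD2 is deliberately *not* genotyped by this generic model alone: its
asymmetric mis-assignment is handled by the group model below.

## TRBD2 genotype groups

Across a population, the per-sample fraction of TRBD2*01 among unambiguous
TRBD2 assignments is tri-modal: homozygous *02 samples sit near the
*02→*01 error rate, heterozygotes near 0.5 (shifted by the asymmetric
errors), homozygous *01 samples just below 1. Samples are first split at
coarse cuts 0.2 / 0.8; each group's mean and sample SD (n−1 denominator)
define Gaussian modes, and the border between adjacent modes is their
equilibrium point — the x with equal tail probabilities
Φ((μ₁−x)/σ₁) = Φ((x−μ₂)/σ₂), solved in closed form as
x = (μ₁σ₂ + μ₂σ₁)/(σ₁+σ₂). One re-assignment pass by the new borders is
applied (an iterate-to-convergence mode exists, capped at 10 iterations,
but a single pass is the default behaviour). An empty coarse group is
reported absent and its border falls back to the coarse cut.

The group means estimate both error rates: ε₂₁ = μ(hom02) (fraction of
*01 calls in samples carrying only *02) and ε₁₂ = 1 − μ(hom01). The
corrected heterozygote *01 usage is the linear unmixing
t = (f̄_het − ε₂₁)/(1 − ε₁₂ − ε₂₁), i.e. the inverse of
f = t(1−ε₁₂) + (1−t)ε₂₁. This formula is this package's derivation; it
reduces to t = f̄ when both error rates vanish and is monotone in f̄.

## Deletions

Usage is computed on unique sequences; multi-call reads count fractionally
across their calls by default. For a gene, the reference rate P is the
smallest per-sample usage above the cutoff 0.0005 among samples not
themselves deletion candidates (operationally: samples whose own usage
exceeds the cutoff). The one-sided binomial tail Pr[Bin(N, P) ≤ X] is
compared to alpha = 0.01 Bonferroni-corrected over all tested
(sample, gene) pairs; alpha is a package default since no published
threshold exists for this locus. Flags describe the *expressed* repertoire:
a "deleted" gene may be silenced rather than structurally absent.

## Haplotyping

A heterozygous anchor gene (TRBJ1-6 by default; TRBD2 possible but
noisier) assigns each single-call read to a chromosome. Per gene-allele
with anchor counts (n₁, n₂), three data models are compared: present on
chromosome 1 only (each read's anchor flips with probability ε), on 2
only, or on both (anchors 50/50); `lk` is again the log₁₀ ratio of best to
runner-up. The anchor ε is data-driven for TRBD2 — 0.125 when *02
dominates the sample's TRBD2 calls, 0.04 when *01 does, matching the two
directions of the trimming-induced error — and 0.01 for TRBJ1-6. A
chromosome with no confidently assigned allele is `Del` when the gene is
confidently expressed from the other chromosome and every allele decision
cleared the lk threshold (default 2), otherwise `Unk`; genes with fewer
than 4 informative reads are `Unk` outright (an explicit floor, since very
small n makes every model fit). The absent-everywhere model is thus
expressed through the Del aggregation rather than as a fourth per-allele
likelihood. Swapping the anchor allele labels transposes the table exactly.

## Usage statistics

TRBJ family usage sums the member genes' fractional usage and TRBJ1 + TRBJ2
partition the J-assigned reads. Conditional P(J | D) uses reads whose
single D call matched more than 7 germline nucleotides — below that, D
identity inside G-rich junctions is guesswork — and restricts TRBD2 support
to TRBJ2 genes, the only family TRBD2 can rearrange with. Group
comparisons use the two-tailed Mann-Whitney U with Bonferroni correction
over the genes of one panel (not across panels), with significance stars at
0.05 / 0.01 / 0.001.

## The simulator

`simulate_population` draws, per individual, two haplotypes: each gene's
allele comes from configured population frequencies (independent draws per
chromosome, hence Hardy-Weinberg genotype proportions), TRBJ1-6 is coupled
to the same haplotype's TRBD2 allele with probability `d2_j16_ld` (default
0.9; *01 with *02 and vice versa), and genes listed in a deletion linkage
are removed in cis whenever the tag allele is drawn (default: TRBV4-3 and
TRBV3-2 ride with TRBV7-2*02). Reads pick a chromosome uniformly, a V gene
uniformly among the chromosome's present genes, TRBD2 with an
allele-dependent probability (0.55 for *01 chromosomes, 0.66 for *02,
giving homozygous *02 individuals higher TRBD2 and hence TRBJ2 usage),
and a J gene by configurable weights, restricted to TRBJ2 when the read
uses TRBD2. Segment ends are trimmed by truncated-geometric draws (means
1.2–1.8 nt, capped so the V cysteine and J motif survive), untemplated
nucleotides are Poisson-length (mean 3 per side) with G probability 0.45,
substitution errors are applied at 0.1% per base, and partial protocols
truncate the read at the configured V primer end. Output reads are
deduplicated to unique sequences; everything is reproducible from the seed.

The bundled toy germline (24 V genes, TRBD1 + both TRBD2 alleles with
their real 12/16 bp sequences, 13 J genes) deterministically encodes the
locus features the inference depends on: one identical gene pair (TRBV6-2
= TRBV6-3), one pair distinguishable only 5' of the BIOMED-2-like primer
(TRBV12-3/-4), one only 5' of the Adaptive-like window (TRBV3-1/-2),
biallelic TRBV7-2, TRBV24-1 and TRBJ1-6. Toy V windows are 60 nt — far
shorter than a real 290 nt V-REGION — so the IMGT-316 junction bound never
binds on toy data and is exercised as a configurable constant instead.

What the simulator does **not** emulate: thymic selection (productive and
non-functional reads share one generative distribution, which is precisely
why genotype-driven usage biases must appear in both strata), P-nucleotide
palindromes (subsumed by the insertion model), UMI/PCR artefacts and
chimeras (the chimera filter is exercised on constructed fixtures instead),
clonal expansion (reads are unique sequences), and real IMGT gap
structures. Passing tests therefore demonstrate the correctness of the
inference logic under the stated generative assumptions, not performance
on any particular instrument's error profile.

## Numerical and design choices

- The equilibrium-point closed form is exact for the tail-equality
  definition; tests verify agreement with a bisection root to 1e-9.
- Degenerate groups: a single-sample group has SD 0; sigmas are floored at
  1e-9 inside the border computation, which collapses the border to that
  group's mean — conservative and stable.
- The modality filter uses a histogram of carrier usage fractions with
  0.05-wide bins; a candidate passes with any carrier at ≥ 0.20 usage or
  two occupied bin-runs (≥ 2 samples each) separated by an empty bin. The
  bin width is chosen so a sequencing-artefact mode (~0.02) and a low
  heterozygous-carrier mode (~0.15) occupy non-adjacent bins. A
  dip-statistic alternative would be straightforward but is not needed at
  these population sizes.
- Candidate floor before filtering: ≥ 2 supporting reads and ≥ 1% of the
  gene's alignments, to keep candidate lists tractable.
- Novel alleles on merged genes are attributed to the first member gene as
  a coordinate frame; repertoire data cannot distinguish the members, and
  the ambiguity is inherent, not an implementation limit.
- Test and acceptance problem sizes (populations of 4–10 individuals at
  depth 1,000–3,000 unique reads, 3–8 seeded replicates per property) are
  the package's chosen trade-off between statistical resolution and a test
  suite that runs in about two minutes; the recovery thresholds (≥ 95%
  genotype and novel-allele recovery, zero false deletions, exact
  haplotype agreement on clean data) are asserted at full strength at
  those sizes.
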