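# trbkit

Germline variation inference for T-cell receptor beta (TRB) AIRR-seq
repertoires: personal genotypes, undocumented alleles, expressed-repertoire
gene deletions, and anchor-gene haplotypes, for full-length (5'RACE),
BIOMED-2 and Adaptive-style truncated sequencing protocols.

## The problem

The TRB locus is hard to genotype directly: it is repetitive, structurally
variable, and its reference directories are incomplete. But every T cell
carries a rearranged V(D)J sequence drawn from its owner's germline, so a
deep repertoire is itself a genotyping experiment — if one can handle the
ambiguities that V(D)J junctional processing and short amplicons introduce.
`trbkit` implements that inference chain for repertoire analysts:

- **Protocol-aware references.** Partial amplicons cannot distinguish all
  genes or alleles. Genes whose amplified windows are identical (distance 0
  under a global alignment with unit mismatch/indel cost and cost-free
  leading padding) are merged under slash labels (`TRBV6-2/TRBV6-3`), and
  alleles identical over the window collapse into *partial allelic
  variation groups* named `gene*bpNN` (BIOMED-2) or `gene*apNN` (Adaptive).
- **Native V/D/J assignment** onto the collapsed references, preserving
  ties as multi-calls, counting V mismatches only inside the boundary
  window used for allele discovery, and locating the D segment as the
  longest exact germline substring in the junction.
- **Undocumented allele discovery.** Recurrent identical mismatch patterns
  become candidates (named like `TRBV10-3*01_A47G`) and pass a filter
  battery: >= 5% exact support among the gene's alignments, >= 2 CDR3
  lengths and >= 2 TRBJ genes among supporting reads, no splice of two
  genes' alleles reproducing the candidate (chimera rule), no two SNPs
  within 4 adjacent positions, and a bi-/tri-modal population usage
  distribution. Passing candidates augment the reference for a second
  assignment pass.
- **Bayesian genotyping.** For allele counts *(n₁ … n_k)* of one gene, all
  genotypes G (non-empty subsets of the top-4 alleles) are scored by the
  multinomial likelihood with carried alleles at (1-ε)/|G| and a
  mis-assignment mass ε on the rest; the confidence `lk` is the log₁₀
  Bayes factor K between the best and runner-up genotype.
- **TRBD2 genotype groups.** The two TRBD2 alleles differ by one G/A SNP in
  a G-rich stretch; trimming plus G-biased N-addition mis-assigns *02 reads
  to *01 asymmetrically. The per-sample fraction of TRBD2*01 assignments is
  tri-modal across a population; borders between groups are the
  equilibrium points of adjacent Gaussian modes,
  x = (μ₁σ₂ + μ₂σ₁)/(σ₁ + σ₂), where Φ((μ₁−x)/σ₁) = Φ((x−μ₂)/σ₂).
  Group means give both mis-assignment rates and the corrected heterozygote
  usage t = (f̄ − ε₂₁)/(1 − ε₁₂ − ε₂₁).
- **Deletion tests.** A gene is deleted from a sample's expressed
  repertoire when Pr[Binomial(N, P) ≤ X] clears a Bonferroni-corrected
  alpha, with P the smallest usage above a 0.0005 cutoff among
  non-candidate samples.
- **Anchor haplotyping.** In samples heterozygous for TRBJ1-6 (or TRBD2),
  each read's anchor allele tags its chromosome; per gene-allele the counts
  (n₁, n₂) choose among on-1 / on-2 / on-both models with anchor flips at
  probability ε, yielding per-chromosome allele content, `Del` and `Unk`
  states with `lk` confidences.
- **Usage statistics.** Gene and TRBJ-family usage, conditional P(J | D)
  restricted to reads with > 7 nt of identified D (TRBD2 pairs only with
  TRBJ2), functional/non-functional stratification by junction frame, and
  two-tailed Mann-Whitney comparisons with per-panel Bonferroni correction.
- **A ground-truthed simulator** generating populations with genotypes in
  Hardy-Weinberg proportions, a TRBV7-2*02-linked TRBV4-3/TRBV3-2 deletion,
  TRBD2–TRBJ1-6 linkage disequilibrium, trimming, G-biased N-addition,
  substitution errors and protocol truncation — used by the test suite so
  no external data are needed.

## Worked example

```python
from trbkit.simulate import PopulationConfig, novel_spec
from trbkit.pipeline import run_pipeline

cfg = PopulationConfig(
    n_individuals=8, depth=1200, seed=42,
    novel_alleles=[novel_spec("TRBV10-3", "01", 47, 0.4)],
    j_usage={"TRBJ1-6": 6.0},
)
res = run_pipeline(cfg)

for c in res["candidates"]:
    if c.passed:
        print(c.name, round(c.support_fraction, 3))
m = res["d2_model"]
print("borders", [round(b, 3) for b in m.borders])
print("eps 01->02", round(m.eps_01_to_02, 3),
      "eps 02->01", round(m.eps_02_to_01, 3))
```

prints

```
TRBV10-3*01_A47G 0.56
borders [0.044, 0.857]
eps 01->02 0.025 eps 02->01 0.044
```

The planted SNP allele is recovered with its correct name and position
(support ≈ 0.56 in the strongest carrier — about half of that gene's
reads, as expected for a heterozygote). The TRBD2 group borders separate
the three genotype groups of this small population, and the mis-assignment
estimates show the asymmetry that G-biased junction processing creates
(*02→*01 exceeding *01→*02); with only eight individuals the group means
are noisy — the acceptance script measures the same quantities on a
786-sample population.

The same pipeline runs from the shell:

```
trbkit run --seed 42 --n-individuals 8 --depth 1200 --out out/
```

writing per-sample AIRR TSVs, genotype/deletion/haplotype/usage tables and
a run manifest. Per-stage subcommands (`simulate`, `assign`,
`collapse-reference`, `novel-alleles`, `genotype`, `d2-groups`,
`deletions`, `haplotype`, `usage`) expose each step separately.

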