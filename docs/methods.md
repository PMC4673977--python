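# Methods

## Model

`bsvar` calls diploid genotypes from bisulfite-converted reads and then
reports methylation conditional on those genotypes. All coordinates and
bases are handled in SAM forward orientation: a read from the Crick
bisulfite strand contributes the bases its alignment displays, and its
strand of origin is taken from the aligner tag (`ZS` BSMAP dialect, `XG`
Bismark dialect) or, failing both, from the FLAG orientation (counted and
reported, since FLAG-only assignment is unreliable for some protocols).

### Pileup

For the chromosome being processed, a matrix of shape
(length × 2 strands × 4 bases) accumulates read counts and summed Phred
qualities. The matrix is allocated when a chromosome's reads begin and
released after its calls are emitted, so peak memory follows the largest
chromosome. Reads enter the pileup if they are primary, non-duplicate,
non-QC-fail alignments with mapping quality ≥ 20 and a bisulfite-adjusted
mismatch rate ≤ 0.05 of aligned length; individual bases must reach
Phred 15. C→T differences on Watson-strand reads and G→A differences on
Crick-strand reads are expected conversions and are excluded from the
mismatch count. Overlapping mate pairs are merged before accumulation so a
sequenced molecule contributes one observation per position (the
higher-quality mate wins).

The mismatch ceiling of 0.05 deserves a note: with 100 bp reads at ~1%
sequencing error, a tighter ceiling (e.g. 0.02) rejects roughly a quarter
of the reads that carry a true SNP base — the SNP itself consumes one of
the two allowed mismatches — and preferentially rejects Crick reads over
C→T homozygotes, exactly the reads that disambiguate such sites. 0.05
keeps the filter meaningful for misplaced reads without biasing allele
depths; it is exposed as `--mismatch`.

### Bisulfite ambiguity

At any position the raw counts are partitioned into *effective*
(unambiguous) support and ambiguous observations:

| observation      | interpretation                      |
|------------------|-------------------------------------|
| Watson T         | genomic T **or** converted C        |
| Crick A          | genomic A **or** converted G        |
| everything else  | supports its own base               |

Candidate discovery uses effective counts only: the frequency of allele X
is effCount(X)/Σ effCount, so the four frequencies sum to 1 and ambiguous
reads influence neither numerator nor denominator. A site becomes a
candidate when total retained depth lies in [10, 1000] and some
non-reference allele has frequency ≥ 0.1 with ≥ 2 supporting effective
reads. The exclusion treatment (rather than splitting each ambiguous read
half-and-half across its two compatible alleles) was chosen because it
keeps the frequency a proper fraction of *informative* reads; an
equal-split denominator would dilute real variants at heavily converted
sites.

### Genotyper

The posterior over the ten unordered diploid genotypes is
P(G|D) ∝ P(G) · ∏ᵢ P(Dᵢ|G), computed in log space.

* **Prior.** Unnormalized weights: reference homozygote 0.9985, each
  heterozygote containing the reference 0.001, each non-reference
  homozygote 0.0005, genotypes without the reference allele
  0.001 × 0.0005; genotypes containing the transition partner of the
  reference are multiplied by 4 (transitions dominate transversions in
  vertebrate genomes). Weights are renormalized per site. At depth > 10
  the data dominate and the exact values are uncritical (the
  prior-robustness test varies the reference-homozygote weight across
  {0.99, 0.9985, 0.999} and observes > 99% argmax stability).
* **Error model.** One average error rate per site:
  ē = Σ_classes count·10^(−Q̄/10) / Σ count over the eight (strand, base)
  classes, clamped to [10⁻⁴, 0.5]. This replaces per-read error modeling
  and makes the likelihood a product of class terms raised to count
  powers.
* **Emission.** P(b|{a₁,a₂}) = ½p(b|a₁) + ½p(b|a₂) with
  p(b|a) = 1−ē if b=a else ē/3. An ambiguous observation emits as an
  equal split over its two compatible bases, e.g. for a Watson T,
  p(obs|a) = ½p(T|a) + ½p(C|a). The split makes ambiguous reads exactly
  uninformative between their two alleles (a wildcard), so for instance a
  fully converted unmethylated cytosine (Watson all T, Crick all C) is
  called CC on Crick evidence, while a genuine C→T homozygote (Crick all
  T) is called TT. When *both* strands are ambiguous (Watson T + Crick A)
  no genotype contrast survives; such sites fall back to the prior and
  are flagged LowQual.
* **Call.** Argmax genotype; ties break toward genotypes containing the
  reference, then alphabetically. Quality is
  round(−10·log₁₀(1−posterior)) capped at 1000; calls under Phred 10 are
  LowQual; confident homozygous-alt calls whose effective alt frequency
  is below 0.85 are LowFreq. Variant genotypes go to VCF 4.2 with
  INFO DP/ADF/ADR/AF and FORMAT GT/DP/GQ; homozygous-reference calls are
  not emitted. The final SNP set is the PASS records.

### Methylation extraction

After calling, a corrected chromosome sequence substitutes homozygous-alt
genotypes into the reference (heterozygotes keep the reference base when
present). Every covered cytosine of the corrected sequence yields one
record per strand: level = C/(C+T) over Watson reads on '+', G/(G+A) over
Crick reads on '−'. Context (CpG if the next base is G; CHG if C-H-G;
else CHH) is computed on the corrected sequence, complemented for Crick
cytosines; cytosines whose context window runs off the chromosome are
counted and skipped. Sites with a genotype call are flagged
genotype-corrected; sites whose call removes the cytosine produce no
record. Cytosines with zero informative reads are omitted from the
tables (the API returns a no-call object for them).

## Simulator

The generator emulates a desk-scale RRBS-like experiment and defines the
package's study conditions: a uniform-random 10 kb diploid genome, SNPs at
1 per kb (transition:transversion 2:1, half heterozygous, each
heterozygote placed on one haplotype), fixed per-context methylation
levels (CpG 0.8, CHG 0.05, CHH 0.02 — mammalian somatic-tissue-like),
bisulfite conversion 0.99, single-end 100 bp reads at 20× mean coverage
with uniform 1% sequencing error and the matching constant Phred quality
(so the average-error model is exactly calibrated). Per read: a haplotype
and a bisulfite strand are drawn uniformly; each cytosine on the strand of
origin survives as C with probability equal to its methylation level,
otherwise converts with probability 0.99; errors are applied afterwards.
Read start positions range over [−99, L−1] with clipping at the
chromosome ends (minimum 20 bp), which keeps mean coverage uniform across
the genome instead of ramping down at the edges. Everything derives from
one seeded generator, so outputs are byte-identical per seed.

What it does **not** model: RRBS fragment selection, PCR duplicates,
quality decay along reads, mapping error/ambiguity, indels, incomplete
conversion heterogeneity, paired-end fragments (pair handling is
exercised by hand-built alignments in the tests). Passing tests therefore
demonstrate the strand logic and the inference, not robustness to
alignment artifacts.

## Test design notes

* The genotyper is checked against an independent brute-force oracle
  (plain per-observation arithmetic over all ten genotypes) on 10,000
  random pileups: exact argmax agreement, posterior within 10⁻⁹.
* Rates near their bounds need enough Bernoulli trials: a 10 kb genome
  plants only ~10 SNPs, so the end-to-end false-negative/false-positive
  gate pools 40 fixed seeds (~420 truth sites; measured FNR ≈ 0.078,
  FPR ≈ 0.040), and the concordance check conditions on sites whose
  *discriminating* strand alone reaches the caller's minimum coverage —
  for a C/T contrast only Crick reads discriminate, so a site with 19
  Watson reads and 3 Crick reads is genuinely undetermined at this
  coverage, whatever the caller does.
* Methylation recovery is asserted as ≥ 99% of CC-genotype CpG sites
  within 3 binomial standard errors of the planted level (a 3σ bound over
  hundreds of sites is expected to fail at ~0.3% of them by chance).

## Known limitations

* Sites where one strand carries nearly all coverage lose most of their
  information to the conversion wildcard; one or two sequencing errors on
  the thin informative strand can then flip a call (observed as the
  dominant residual error mode at 20×). Deeper or strand-balanced
  coverage is the only remedy within this model.
* The average-error likelihood ignores per-read quality variation; with
  strongly mixed quality distributions per site it is only approximate.
* Heterozygous sites containing a cytosine report methylation from
  C/(C+T) counts that include reads of the non-cytosine allele; levels at
  such flagged sites are systematically compressed and should be read
  with the genotype in hand.
* No indel calling, no multi-sample joint calling, no CRAM, no gVCF.
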