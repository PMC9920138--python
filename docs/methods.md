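# Methods

## Scope and model

`sarcopred` operationalizes a cross-trait pleiotropy screen over published
GWAS summary statistics. It treats each summary-statistic record as a
signed per-allele effect β with standard error, p-value and sample size,
reported against a stated effect allele. No individual-level phenotype
data enter the analysis; the only individual-level input is a genotype
reference panel used for linkage disequilibrium (LD) and for risk-allele
counting.

### Allele harmonization

A variant is identified by rsid plus its unordered allele pair; chromosome
and position are carried when available (VCF convention: 1-based,
reference/alternate strings for indels) but are not part of identity, so
allele-pair tables without coordinates can drive the pipeline. Aligning a
record to the other allele of the pair negates β and changes nothing else;
the operation is an exact involution. Strand-ambiguous (A/T, C/G) SNPs
are matched by rsid and allele set only and reported in a warning — the
intended inputs all come from a single cohort on a single genome build,
where cross-strand mismatches are not expected; no strand flipping is
attempted.

p-values are parsed from text and kept alongside the parsed float. Values
that underflow `float` to 0.0 (exponents beyond ~1e-308) are clamped to
the smallest positive normal double; subnormal but representable values
(the packaged table contains 7.0e-319) are kept exactly as parsed.

### Two-stage selection

Stage one unions all variants below each source GWAS's *discovery*
threshold. The thresholds are per-source because the published designs
differ: 5×10⁻⁹ for the appendicular-lean-mass GWAS and 5×10⁻⁸ for the
handgrip and walking-pace GWASes.

Stage two groups evidence by trait *category* (strength, lean mass,
walking pace, adiposity, T2D). A category with several member GWASes —
five handgrip phenotypes, two lean-mass GWASes — is collapsed to the
record with the minimum p-value, ties broken by trait name. A discovery
variant is selected iff all three sarcopenia categories have p strictly
below the replication threshold (0.005, a plain fixed threshold without
multiplicity adjustment) and the signs of β×(benefit direction) agree
across the three. Benefit directions are +1 for strength/lean-mass/
walking-pace (higher is protective) and −1 for adiposity/T2D. A zero β
leaves the direction undefined; such variants are excluded and logged
rather than counted as consistent. Variants missing a category are
excluded with a logged reason. Direction consistency is judged purely on
β signs; p-values carry no sign information. The selected output records
the inferred protective allele — the allele whose aligned effects all
point in the benefit direction — and the construction is invariant to
which allele each input happened to use as its effect allele (tested by
re-running on fully flipped evidence).

### LD pruning

LD between two variants is the squared Pearson correlation of their
unphased dosage vectors over pairwise-complete samples (composite LD),
which needs no phase information and is invariant to which allele is
counted at either variant. Missing genotypes are dropped pairwise, never
imputed. A constant dosage vector leaves the correlation undefined; the
pair is treated as unlinked (r² = 0) and logged. Pruning is greedy
best-first: candidates ranked by ascending minimum p over the three
sarcopenia categories, each retained only if its r² with every
already-retained panel-covered candidate is ≤ 0.2. All pairs are tested
without a genomic-distance window — candidate sets are small (≲10³) and
correctness is preferred over speed. Candidates absent from the panel
cannot be LD-tested and pass through with a warning rather than being
dropped. The output is maximal for the greedy order: every pruned variant
conflicts with at least one retained one.

### Tier classification

Every selected variant is a sarcopenia predictor. It is upgraded to
sarcopenic obesity iff its body-fat p-value is < 0.005 *and* the risk
(non-protective) allele associates with higher adiposity, and further to
sarcopenic diabesity iff the same holds for T2D. The tiers are nested by
construction; a T2D hit without the body-fat condition is counted in the
T2D-associated tally but does not upgrade the tier. The NS marker in the
packaged table ("not significant", p > 0.005) is a distinct sentinel, not
a missing value; a hit requires strict p < 0.005, and the two boundary
conventions never disagree on any tabulated value. Loci are counted as
distinct gene labels — the packaged panel's 78 variants span 73 labels
(one gene appearing three times, three appearing twice). Auxiliary traits
are annotated the same way: a hit is p < 0.005, with the stored direction
saying whether the risk or the protective allele associates with the
higher trait value.

### Unweighted polygenic score and risk bands

An individual's score is the integer count of risk alleles over the scored
variant set (0/1/2 per variant). Missing genotypes contribute 0 — keeping
scores integer, as the band tables require — and are surfaced per sample
in a missingness count rather than mean-imputed. Banding sorts samples
ascending by (score, sample id); the secondary key makes tie-breaking
deterministic while allowing equal scores to straddle a band boundary, in
which case adjacent observed ranges can touch. The five groups differ in
size by at most one, remainder assigned to the lowest bands first (503
individuals → 101/101/101/100/100). The "low" band holds the fewest risk
alleles.

### Concordance

Gene-level evidence pairs the direction in which the protective allele
shifts the gene's expression in human tissue (one direction per gene; any
tissue-priority rule is delegated to the input table) with the direction
in which the mouse knockout shifts lean mass and strength (taken jointly;
a gene whose knockout moved the two phenotypes in opposite directions
would be recorded as unknown). Concordance means expression +1 with
knockout −1, or expression −1 with knockout +1; any unknown yields
"undetermined". The packaged knockout table names the 27 genes with
significant knockout effects; the 8 tested-but-non-significant genes are
synthetic placeholders (identities unpublished) and affect only the
tested-gene tally. The exercise-response table transcribes the published
up/down gene lists; the source prints one merged token ("TRIB1 WWP2") in
a 16-gene list, transcribed here as the two gene symbols, restoring the
stated count.

## Synthetic data generator

The generator emulates the study's two data sources at desk scale.

**Panel.** Haplotypes are latent-Gaussian: within each block of
`ld_block_size` variants the latent vector has exchangeable correlation
`ld_rho`; an allele indicator is the latent value falling below the
Φ⁻¹(f) quantile of the variant's frequency f (drawn uniformly from
`maf_range`), and two independent haplotypes sum to the dosage. This
gives exactly controllable allele frequencies (dosage sums are
Binomial(2n, f)), Hardy–Weinberg proportions, and a known block-diagonal
LD ground truth for pruning tests — at the cost of no realistic
recombination structure, no phasing realism and no population
stratification, so passing tests demonstrate the pipeline's logic, not
robustness to those real-data features.

**Summary statistics.** For GWAS sample size n and panel allele frequency
f, the per-allele Wald standard error for a standardized phenotype is
se = 1/√(2nf(1−f)); the observed β is the true effect plus N(0, se²)
noise and p is the two-sided normal tail of β/se. Planted pleiotropic
variants carry a true standardized effect of `effect_size` on every
strength/lean-mass/walking-pace trait, with one random sign per variant
applied through each trait's benefit direction so the planted variants
are direction-consistent by construction; configured subsets are also
loaded on body fat and T2D (defaults follow the 55/78 and 21/78 tier
proportions of the packaged panel). The binary T2D trait is generated on
the same standardized scale and merely labeled log-odds — the pipeline
consumes only signs and p-values, so liability-scale fidelity is
irrelevant to every downstream decision. Monomorphic variants are skipped
with a warning.

**Default conditions.** 503-sample panel (the size of the European
reference cohort the score tables target), 2000 variants in blocks of 10
at latent ρ = 0.3, MAF ∈ (0.05, 0.5), 20 pleiotropic + 30 single-trait
causal variants at standardized effect 0.04, and the published per-GWAS
sample sizes (1.8×10⁵–4.6×10⁵) from the trait-spec table. At those sample
sizes the planted effect is detected with essentially unit power
(z ≈ 12–27 depending on f), which is what makes exact-recovery checks
meaningful.

## Numerical and design notes

- Variant identity ignores allele order; the harmonization reference
  allele is the lexicographically smaller of the pair, making results
  independent of input ordering.
- Thresholds are strict (`p < t`) everywhere; the selection threshold
  stays a parameter so sensitivity checks (e.g. 0.005 → 0.05
  monotonicity) are one call away.
- `stratify` distributes the remainder to the *lowest* bands first; any
  fixed rule would do, but this one pins down the 101/101/101/100/100
  split exactly.
- Seeds: every stochastic routine takes its stream from
  `numpy.random.default_rng([seed, stream_id])`, so panel, effect
  planting and noise are independently reproducible from one integer.
- Problem sizes in the test suite and acceptance script (2000-variant
  studies, 10⁴-variant null calibrations) were chosen to make each
  statistical check sharp at desk scale — Monte-Carlo standard errors
  small relative to the tested margins — while keeping the whole suite in
  the seconds range.

## Known limitations

- Real band tables for a specific cohort depend on that cohort's
  genotypes; with an external VCF supplied the score module reproduces
  its banding procedure, but the packaged synthetic panels make no claim
  to reproduce any published allele-count ranges.
- The LD estimator is composite (dosage) r²; haplotype-phase-aware D′/r²
  is out of scope.
- No meta-analysis across the member GWASes of a category (minimum p, not
  inverse-variance pooling), mirroring the screened design rather than
  improving on it.
- No genome-build liftover, INFO-score filtering, or portal download
  clients; inputs are expected as local TSV/VCF.
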