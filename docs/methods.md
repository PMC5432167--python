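# Methods

This note documents the models, parameters and numerical choices behind
`famvar`, and what the synthetic-data generators do and do not emulate.

## Data model and coordinates

All positions are VCF-convention: 1-based, inclusive. Every site is
decomposed into biallelic (chrom, pos, ref, alt) records; a sample's
genotype for a decomposed record is its count of that alternate allele,
so a `1/2` call at a triallelic site is heterozygous for both derived
records and allele counts are conserved across the decomposition.
Ref/alt pairs are trimmed of shared suffix then shared prefix (keeping
the one-base VCF anchor), which makes the identity of an indel reported
with different padding well-defined. Full left-alignment against a
reference sequence is not performed: the pipeline consumes no FASTA,
and trimming suffices to canonicalize all records it produces or reads
back. Genotypes are treated as unphased diploid autosomal calls
(`0/1` ≡ `1/0`); phase separators are ignored because compound-het
phase is established from parental genotypes, not pipe characters.
Haploid or polyploid calls are rejected.

Missing annotations are `None`, never zero: a variant with no
population-frequency record is *novel*, which matters for the rarity
filter. INFO floats are quantized to 6 significant digits on both the
write and read path because htslib stores them in single precision;
this makes VCF round-trips exact for annotation values stated at that
precision or coarser.

## Prioritization cascade

Stages run in the fixed order **quality → consequence → rarity →
deleterious**, but each stage is a pure per-variant predicate, so the
surviving set is the intersection of the per-stage pass sets and is
order-independent; the per-stage report merely attributes each removal
to the first failing stage. Defaults (all configurable, YAML-loadable):

| parameter | default | meaning |
|---|---|---|
| `min_site_qual_single_strand` | 40 (Phred) | site quality floor |
| `min_site_qual_both_strands` | 30 (Phred) | relaxed floor when the alternate was seen on both strands |
| `min_gq`, `min_depth` | 30, 30 | per-genotype floors; failing calls degrade to missing |
| `max_maf` | 5×10⁻⁵ | "extremely rare" cutoff (0.005%), applied to every *present* frequency source |
| `common_maf_cutoff` | 0.01 | coarse common-variant bound, exposed for pre-filtering |
| `allowed_regions` | exonic, UTR3, UTR5, splice | region classes retained |
| `allowed_consequences` | all but synonymous/other | consequence classes retained |
| SIFT / PolyPhen | 0.05 / 0.5 | benign only when SIFT > 0.05 **and** PolyPhen < 0.5 |

Two deliberate choices: (i) a low-quality genotype call degrades to
missing instead of discarding the site, so the segregation policy — not
the filter — decides the site's fate; (ii) the deleteriousness stage
excludes a variant only when both predictors agree it is benign, so
unscored variants (all indels under these tools) pass. UTR and splice
classes are retained by default because prioritized recessive candidate
sets in this setting include them; a stricter coding-only configuration
is one flag away.

## Segregation models

Both models assume full penetrance of a recessive phenotype and are
applied to autosomes only (sex chromosomes and MT are excluded with a
logged notice — the models as stated are autosomal).

**Autosomal recessive.** A variant is consistent iff every affected
member is homozygous-alternate, every genotyped parent of an affected
is heterozygous (a homozygous-alternate parent would themselves be
affected), and no genotyped unaffected member is homozygous-alternate.
Under the default `strict` missing policy any missing genotype among
the evaluated members makes the verdict *indeterminate* (ranked as
non-consistent), reflecting a workflow in which every member is
re-genotyped by Sanger before segregation is declared; `permissive`
ignores missing members. A definite violation dominates missingness:
the verdict is *inconsistent* regardless of other missing calls.

**Compound heterozygote.** For a pair of variants in one gene, each
affected must be heterozygous for both. Phase is inferred from parental
origin: for each variant, the child's single alternate allele can only
have come from a heterozygous-carrier parent. The pair is *consistent*
when every feasible origin assignment is trans (one allele per parent),
*indeterminate* when both trans and cis explanations exist (e.g. both
parents carry both variants — likely under consanguinity), and
*inconsistent* when no parent can explain an allele (de novo) or only
cis assignments exist. An unaffected member carrying both alleles of
the pair excludes it. Screening reports consistent results only, AR
before CH, in deterministic (chrom, pos, alt) order, with per-sample
genotype evidence. De novo and dominant models are out of scope.

## Association panel

Given genotype counts (n00, n01, n11) per group, six contrasts are
collapsed to 2×2 tables with rows (case, control): codominant HET and
HOM vs the reference homozygote, dominant (00 vs 01+11), overdominant
(01 vs 00+11), recessive (11 vs 00+01) and allelic on chromosome counts
(2·hom + het). The test is the uncorrected Pearson χ² in its closed
2×2 form with df = 1; Yates continuity correction is available but off
by default, because the uncorrected statistic is what reproduces the
reference panel's printed values. Odds-ratio intervals are Woolf
(log-OR ± z₀.₉₇₅·SE); exact and mid-p intervals are not implemented.
The Haldane–Anscombe correction (+0.5 to all cells) is opt-in for
zero cells. A zero margin is an error naming the contrast.

**Orientation.** With the default `exposure="wildtype"`, the exposed
column is the wild-type reference class when it stands alone on one
side of the contrast (codominant rows, dominant, allelic) and the
contrast's own pure genotype class otherwise (overdominant: HET;
recessive: mutant homozygote). For a protective allele this yields
OR > 1 on the wild-type-anchored rows and OR < 1 on the recessive/
overdominant rows, matching the conventional presentation of such
panels. `exposure="mutant"` transposes the columns, mapping OR → 1/OR
and leaving χ² unchanged.

**Hardy–Weinberg.** Per group, q̂ = (2·n11 + n01)/(2n), expected counts
n·((1−q̂)², 2q̂(1−q̂), q̂²), χ² goodness of fit with df = 1 (three classes
minus one minus one estimated parameter). p < 0.05 is read as
significant disequilibrium. No multiple-testing correction is applied
anywhere in the panel.

**Display rounding** is half-up (via `decimal`) at per-row precision
matching the reference table's mixed printing (χ² at 3 decimals for the
codominant-HOM and recessive rows, 2 elsewhere; OR at 3 decimals for
overdominant). The JSON rendering keeps full double precision and is
the machine-readable source of truth.

## Synthetic data

**Cohorts.** Controls are multinomial draws from Hardy–Weinberg
probabilities at `allele_freq_controls` (default 0.625 — the control
frequency of the motivating locus — with 100 cases and 100 controls,
the validation-cohort design). Case probabilities are the control ones
tilted by genotype relative risks (r_het, r_hom) and renormalized; the
helper `relative_risks_for_case_fractions` inverts this to hit a target
case distribution in expectation. This deliberately models genotype
frequencies directly rather than a liability-threshold disease model —
it is the minimal structure able to reproduce a reported case/control
table, and nothing downstream depends on more.

**Family exomes.** The default pedigree is a 7-member nuclear family —
carrier parents and five children, two affected — of which five members
(parents, both affected, one healthy sibling) mirror the exome-sequenced
subset; the simulated VCF carries all seven so Mendelian checks cover
every child. Decoy variants get founder genotypes drawn at a per-variant
population frequency (uniform 0.05–0.5) and child genotypes by Mendelian
transmission (each parental allele with probability ½). Each decoy is
labelled with the cascade stage it is built to fail — annotations are
sampled per class (e.g. site quality 5–29 for quality-failures, ExAC
frequency log-uniform in 10⁻³–0.5 for rarity-failures, jointly benign
scores for deleteriousness-failures) while passing every earlier stage.
`fail_stage="none"` decoys satisfy every filter, and their transmissions
are resampled if they accidentally form an AR-consistent pattern, so the
truth-table guarantee "removed by the screen, not the cascade" holds by
construction; each decoy carries a unique gene symbol so no accidental
CH pair can arise. Planted signals are written directly: the AR plant is
an anchored 3-bp in-frame insertion (the shape of the motivating hit)
with parents HET, affected HOM-ALT, unaffected HET-or-HOM-REF; the CH
plant is a trans pair of damaging missense variants in one gene. The
per-exome variant count is set by `n_decoys` (500 in the shipped
configurations — large enough to exercise every stage with a testable
runtime, scaled down from the ~70,000-variant scale of a real exome).

What the generator does **not** emulate: linkage disequilibrium between
variants, autozygosity blocks from consanguinity, sequencing error or
genotype-caller artifacts, realistic gene/exon geometry, or the joint
annotation distributions of real exomes. Passing the planted-recovery
tests therefore demonstrates the correctness of the filtering and
segregation logic under the stated models, not robustness to real-data
messiness (e.g. population-specific frequency gaps, the very failure
mode the motivating study illustrates).

## Numerical and degenerate-input choices

* χ² p-values come from `scipy.stats.chi2.sf`; the 2×2 statistic uses
  the closed form, verified in tests against the generic Σ(obs−exp)²/exp
  route to 10⁻⁹.
* z for 95% intervals is the standard normal quantile 1.959963984540054.
* Empty matrices, zero margins, groups with zero individuals, pedigrees
  without an affected member, and affected members absent from the
  genotype matrix are validation errors, not silent results.
* Ties and ordering: all reported lists are sorted by (chrom, pos, alt);
  CH pairs are ordered canonically within the pair, so results are
  invariant under input sample/variant permutations.
* Every stochastic entry point takes an explicit integer seed; there is
  no module-level random state.

## Known limitations

* No linkage/LOD analysis or homozygosity mapping; single-family
  segregation evidence only.
* Penetrance is fixed at 1 for both models; a penetrance-relaxed mode
  is out of scope.
* The association module addresses one biallelic locus; no covariates,
  stratification, logistic regression or haplotype analysis.
* Indel normalization trims but does not left-align (no reference
  sequence is consumed).
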