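# Methods

This note records the models, algorithms, numerical choices and known
limitations of `qtlallele`, in the order the pipeline runs them.

## Synthetic study generator (`qtlallele.simulate`)

The generator produces the inputs the analysis assumes rather than a
coalescent-realistic population.

**Genotypes.** Each chromosome carries `n_blocks_per_chrom` LD blocks. A
block is either a single SNP (probability `single_snp_block_frac`,
default 0.4, so both single-SNP and multi-SNP marker classes appear in
realistic proportion) or `snps_per_block` SNPs (default 6) spaced 150 bp
apart. Founder haplotypes per block are built as a perfect phylogeny —
each SNP mutates exactly once on a random tree — so every within-block
SNP pair shows at most three gametic classes and hence |D′| = 1: blocks
are exact complete-LD units, the regime in which SNPLDB markers are
well-defined. Founder frequencies decay geometrically with a per-block
rate drawn from U(0.25, 0.75), which makes the common-haplotype count
vary between 2 and `min(founder_pool_size, snps_per_block + 1)` across
blocks. Accessions are fully homozygous: each samples one founder
haplotype per block, independently across blocks (no between-block LD).

**Population structure.** Accessions are assigned to maturity groups
(default six, sized 21/43/79/157/45/16 out of 361) and each group draws
its own haplotype frequencies from a Dirichlet centred on the founder
frequencies with concentration `mg_concentration` (default 60) — mild,
nonzero differentiation, the regime in which eigenvector correction is
appropriate but not strained.

**QTLs and phenotypes.** `n_qtls` blocks (default 30) whose
common-allele count lies in `alleles_per_qtl` get haplotype effects drawn
N(0, `qtl_effect_sd`²) and centred to frequency-weighted zero mean, so
effects carry both signs and the intercept is the population mean. With
`equalize_qtl_variance` every QTL is rescaled to contribute equal genetic
variance — used in power studies where "k loci jointly explaining X% of
variance" must mean k detectable loci. The genetic value of an accession
is the sum of its QTL allele effects. Environment, replication-within-
environment, genotype-by-environment (GxE) and error effects are all
Gaussian. The GxE and error variances are *solved from the realized
genetic variance* so that the entry-mean heritabilities hit their
targets: with σ²g realized and D = σ²g / h²_target,

    σ²gt = h²gei_target · D · n_t,
    σ²   = (1 − h²_target − h²gei_target) · D · n_t · n_r.

Feasibility is exactly `h²_target + h²gei_target ≤ 1`. Defaults: 2
environments, 4 replications, h² = 0.83, GEI h² = 0.12, trait mean 40.77
(percent seed-protein scale).

What the generator does **not** emulate: LD decay within blocks or
between adjacent blocks, genotyping error, missingness patterns of real
assays (missing data enter only through tests that inject them), linkage
between QTLs and flanking non-causal blocks beyond the block itself, and
selection history. Passing recovery tests on these data therefore shows
the estimators are correct under the stated model, not that they are
robust to real-data artefacts.

## SNP QC, imputation, SNPLDB assembly (`qtlallele.snpldb`)

Filtering drops SNPs with missing rate > 20%, heterozygosity rate > 20%
or MAF < 0.01 (a SNP at exactly the MAF floor is kept). Residual
heterozygous calls in the inbred panel are treated as noise and set
missing before imputation. Imputation is a k-nearest-haplotype majority
vote (k = 5 within a 20-SNP window, ties and isolated calls falling back
to the SNP's major allele): with fully homozygous lines, model-based
phasing adds nothing.

Block search is greedy left-to-right: a block absorbs the next SNP while
every pairwise |D′| inside the candidate block exceeds the threshold
(default 0.7) and the physical span stays within `max_span_bp` (default
200 kb; the span cap is a configurable guard, not a claim about the
original block definition). D′ uses homozygous calls as haplotypes, with
heterozygous or missing calls excluded pairwise; a monomorphic SNP makes
D′ undefined and is signalled. Haplotypes rarer than 0.01 are pooled
into the nearest common haplotype by Hamming distance (ties to the more
frequent), mirroring the MAF floor; allele codes are re-indexed by
descending pooled frequency, so code 0 is always the major allele.

## Trial analysis (`qtlallele.phenotype`)

The joint randomized-block ANOVA is computed closed-form for the
balanced case; genotype is tested against the GxE mean square and GxE
against error, following the expected mean squares with genotype and GxE
random. An unbalanced design triggers a warning and the analysis
proceeds on accession × environment cell means with harmonic-mean
replication — graceful degradation only, since the intended design is
balanced.

Variance components come from REML with genotype and GxE random. The
marginal covariance is block-diagonal by accession with identical blocks
`V = σ²I + σ²g·J + σ²gt·kron(I_nt, J_nr)`, so the restricted likelihood
is evaluated from one block's eigendecomposition; Nelder-Mead maximizes
it over the non-negative orthant starting from the method-of-moments
(EMS) solution, which is also the fallback on non-convergence. Negative
estimates truncate at zero. On balanced data with interior estimates,
REML and the EMS solution agree, which the tests exploit as a
cross-check.

Heritabilities are plug-in: single-environment
`h² = σ²g/(σ²g + σ²/n_r)`, multi-environment
`h² = σ²g/(σ²g + σ²gt/n_t + σ²/(n_t·n_r))`. The GEI share is reported on
the same entry-mean denominator, `h²gei = (σ²gt/n_t)/(denominator)`, so
the two shares sum to at most one. `GCV = 100·σg/μ`.

Maturity-group summary tables use accession means, 1-unit bins centred on
integers, and compact letters from pairwise Fisher-LSD comparisons at
α = 0.05 on the one-way ANOVA of accession means — the simplest
procedure consistent with standard GLM output; no specific
multiple-comparison method is implied by the letters.

## Restricted two-stage GWAS (`qtlallele.gwas`)

GSC(a, b) is the fraction of SNPLDB markers at which accessions a and b
carry the same allele. The top `n_eigenvectors` (default 10)
eigenvectors of the GSC matrix enter every model as fixed covariates.
The response is the accession × environment mean; environment is a fixed
factor.

Stage 1 tests each marker by the joint partial F of its allele main
dummies plus allele × environment (QEI) dummies over the covariate-only
model, keeping markers with p ≤ α₁ = 0.05. QEI enters stage 1 so that
QEI-only loci can survive preselection. Markers collinear with the
covariates are skipped with a warning.

Stage 2 is forward selection with backward elimination at the stay level
α₂ = 0.01. Candidate terms are per-marker main-effect groups and QEI
groups, entered separately; by default QEI terms of every preselected
marker are candidates even if the marker's main effect never enters
(`qei_pool="main_only"` restricts them to markers already in the model).
Ties in the entry test break by larger partial F, then smaller genomic
coordinate — determinism over elegance. The forward step refuses any
term that would push the model's marker R² (incremental over the
covariates, relative to total phenotypic SS) above the heritability cap,
and selection stops there; the cap invariant is asserted after every
step. Rank deficiency is handled by least-squares rank monitoring: a
term contributing no rank is unavailable.

The final joint fit (pseudoinverse) yields allele effects, re-expressed
as frequency-weighted zero-mean deviations per locus so the intercept is
the population mean and predictions are additive; QEI effects are
centred per environment the same way. Per-locus R² is the sequential SS
in selection order (telescoping to the joint increment, rescaled against
numerical drift) — a single non-overlapping number per locus. Per-locus
p-values are Type-III-style partial F tests of each term group against
the full model without it. Loci with main R² ≥ 1% are labelled LC
(large-contribution), below SC.

Known property: with no polygenic/kinship term (mixed-model association
is deliberately out of scope), unexplained heritable variance correlates
the per-accession residuals across environments and leaves the stepwise
scan mildly anti-conservative on heritable-but-unlinked phenotypes; on
iid null phenotypes the stage-1 rate and stage-2 false-locus counts are
calibrated (checked by simulation in the test suite).

## Allele evolution (`qtlallele.evolution`)

Group presence is literal (≥ 1 carrier; a configurable minimum count is
offered). Between an old and a new group, per locus: inherited =
old ∩ new, emerged = new \ old, excluded = old \ new; the set identities
are asserted on every call. Fractions use the denominators the
categories refer to: inherited and emerged over the new group's allele
total, excluded over the old group's. Sign splits classify an allele by
its estimated effect, with effect ≥ 0 counted positive (deterministic
zero-tie rule).

## Cross prediction (`qtlallele.cross`)

All n(n−1)/2 unordered pairs are enumerated, labelled within/between on
the collapsed grouping {I+II+III}, {0}, {00}, {000}. For each cross,
`n_progeny` (default 2,000) homozygous progenies are simulated at the
detected loci:

- **linkage** (default): crossover counts per chromosome are Poisson
  with the map length in Morgans as mean and uniform positions — i.e.
  Haldane's no-interference model. The implementation draws the
  equivalent independent Poisson counts in the inter-locus map intervals
  (the Poisson process restricted to the loci), which is exact and never
  evaluates the Haldane map function, so the closed-form recombinant
  fraction remains an independent oracle in the tests. A progeny is a
  doubled F1 gamete (doubled-haploid model). The `ril` option instead
  uses the Markov chain with per-interval recombination inflated to
  R = 2r/(1+2r), emulating repeated selfing from F2; doubled gametes are
  the default because the Poisson-per-gamete description maps to them
  directly.
- **independent**: every locus assorts freely.

Progeny value = model intercept + Σ allele main effects (QEI effects are
deliberately excluded from prediction). Percentiles use linear
interpolation of order statistics (position 1 + (n−1)p). Each cross
draws from an RNG stream keyed by (seed, sorted parent indices), so
results are independent of enumeration order and parallelism-safe.
Summaries per scope report mean/min/max of P95, superior-cross counts
(P95 above the scope's best observed accession), recombination potential
(mean P95 − population mean) and transgressive potential (max P95 − best
observed). Rankings sort by P95, ties by P99, then parent ids. The
intercept added to predictions is the grand mean, not an
environment-specific value.

## Candidate genes (`qtlallele.genes`)

QTL spans extend by `pad_bp` (default 200 kb, the LD-decay scale of
cultivated soybean) and clip to [1, chromosome length]. Gene overlap is
≥ 1 bp, 1-based inclusive. Gene-local haplotype classes are built from
SNPs within the gene span ± 5 kb, rare classes pooled below 0.01; a
per-SNP alternative is a matter of passing single-SNP windows. The
independence test is Pearson χ² with classes pooled until all expected
counts reach 5 (smallest-margin classes merge first); pooling below two
classes on a margin makes the test undefined and is signalled. α = 0.05
per gene with no multiple-testing correction, matching the pipeline's
convention; the per-test p-values are reported so any correction can be
applied downstream. Category tallies count each candidate gene once,
with unmapped genes reported as "unannotated".

## Pipeline (`qtlallele.pipeline`, CLI `qtlallele`)

Stages run in dependency order inside a run directory; each run writes a
manifest with the config, its hash, the per-stage seed fan-out (children
of the global seed via `SeedSequence`, kept below 2³¹) and a SHA-256 per
output file, so reruns are verifiably byte-identical. A stage failure
writes a machine-readable `error.json` and halts; a stage whose inputs
were toggled off fails with a missing-dependency error. The Markdown
reporter only re-reads stage outputs — every number in the report is
traceable to a file, none recomputed.

## Problem sizes used in the shipped checks

The test suite runs studies of 60–400 accessions on 2–5 chromosomes, and
the acceptance script runs the full default design (361 accessions, 20
chromosomes, 240 markers, 64,980 crosses at 2,000 progenies each); these
sizes keep the whole suite in the minutes range on one CPU while leaving
every statistical check at the sample sizes its tolerances were derived
for.

## Known limitations

- Stage-2 stepwise p-values are selection-biased, as in any stepwise
  procedure; the heritability cap bounds total contribution but is not a
  family-wise error control.
- The R² partition is sequential in selection order; other partitions
  (e.g. averaged-over-orderings) would give different per-locus shares.
- Unbalanced trials are handled by cell means only; severely unbalanced
  or missing-cell designs are rejected.
- The cross simulator models only the detected loci; background genetic
  variation and QEI do not enter progeny values.
- The generator's complete-LD blocks make SNPLDB assembly exactly
  recoverable; performance on real, decaying-LD data depends on the D′
  threshold and span cap in ways these tests do not measure.
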