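# Methods note

What germdiv computes, the assumptions behind each estimator, the defaults
we ship, and the numerical choices that affect results.

## Data model

Genotypes are diploid and biallelic. A call is stored as the dosage of
allele B (0, 1, 2) with −1 for missing; allele A is the alphabetically
first allele observed at the locus, so recoding is deterministic given the
data. The numeric interchange format maps dosage to 1/2/3 (homozygous A /
heterozygous / homozygous B). All per-locus statistics use
pairwise deletion: an individual missing at a locus contributes nothing to
that locus and everything elsewhere.

## Quality control

Markers are retained when call rate ≥ 0.90 **and** minor allele frequency
≥ 0.05, both thresholds inclusive. MAF is computed from genotype counts as
(Q + 2R)/(2(P+Q+R)) with Q the heterozygote and R the rarer-homozygote
count, folded to ≤ 0.5. Individuals are never dropped; the QC report
records the failing reason per marker (`call_rate` is checked first).

## Diversity statistics

Per locus, with p and q = 1 − p the two allele frequencies:

- gene diversity D = 1 − p² − q² = 2pq;
- PIC = D − 2p²q² (the two-allele case of the classic formula);
- observed heterozygosity = heterozygote count / called individuals.

Group summaries average over **all** retained loci, including loci
monomorphic within the group — dropping them would inflate small groups.
Private alleles are alleles observed (at any dosage) in exactly one group.
Group-pair allele-frequency correlations use Pearson r with the two-sided
t-test p-value (scipy); at least three markers with frequencies in both
groups are required, and zero variance in either group is an error rather
than a silent NaN.

## Nei distance and UPGMA

The distance is Nei's D_A, (1/r) Σ_loci (1 − Σ_alleles √(x·y)), computed on
unit allele frequencies: for single individuals a heterozygote contributes
0.5/0.5, so two identical homozygotes are at distance 0 and opposite
homozygotes at 1; a homozygote against a heterozygote gives the expected
1 − √0.5. A `literal` flag swaps in a variant that squares the summed
cross-products, matching a common typesetting of the formula; the default
is the √(xy) form because only it satisfies D(x,x) = 0.

UPGMA is hand-rolled (≈40 lines) rather than adapted from
`scipy.cluster.hierarchy` because we need a deterministic, documented
tie-break: among equal minimum distances, merge the pair whose smallest
leaf name is lexicographically first. Node height is half the merge
distance, so the tree is ultrametric and branch lengths follow from height
differences. scipy's implementation is still used in the test suite as an
independent oracle on tie-free inputs.

Bootstrap support resamples loci with replacement (default 2,000
replicates), rebuilds the tree, and reports for each internal node the
percentage of replicate trees containing the same leaf set as a clade.

## Kinship, Fst and effective size

G = WW′ / Σ 2p_i q_i, where W is the dosage matrix centered by 2q per locus
and missing entries are set to the locus mean (zero after centering) —
the standard genomic relationship matrix. The panel-level inbreeding
estimate is F_st = mean(diag G) − 1. Effective size:

- hybrids: N_e = N / (1 + F_st);
- parents of single crosses: N_e = N / (2 F_st).

The default mode (`n_scaled`) uses the panel size N in both formulas. An
`as_printed` mode computes the literal alternative forms
(1 + F)/ (2F)-style without the N scaling for comparison; the two coincide
in ratio but not in units, and `n_scaled` is the one with a census-size
interpretation, so it is the default.

## Admixture model and Gibbs sampler

The model is the standard admixture model: individual i has ancestry
vector q_i ~ Dirichlet(α,…,α); population k has allele-B frequency p_kl ~
Beta(λ, λ) at locus l; each of the 2 allele copies draws an origin z from
q_i and then the allele from p_zl. All conditionals are conjugate, so the
sampler is a plain Gibbs scan: z | q,p categorical per copy, p | z Beta
posterior, q | z Dirichlet posterior. Defaults α = 1, λ = 1.

The likelihood trace stores, per post-burn-in sweep, Σ log P(allele | q,p)
with z marginalized (a Rao-Blackwellized plug-in), and the model score is
the usual L(K) = mean − var/2 (sample variance, ddof = 1). ΔK follows
Evanno: |mean L(K+1) − 2 mean L(K) + mean L(K−1)| / sd(L(K)), undefined at
the endpoints and when sd = 0. Replicate chains are label-aligned by
maximizing the summed column correlation of Q matrices via the Hungarian
algorithm (`scipy.optimize.linear_sum_assignment`) — greedy matching can
fail on near-symmetric Q columns. An individual is assigned to a
population only when its aligned membership exceeds 0.60, otherwise it is
reported as `mixed`.

Performance/determinism: the per-sweep z-sampling and count accumulation
run in a numba kernel consuming uniforms pre-drawn from a numpy Generator,
so results are bit-reproducible for a given seed and independent of numba
threading. Each (K, replicate) chain gets its own `SeedSequence` child
keyed by (K, rep), so adding replicates or K values never perturbs
existing chains. Publication-scale settings (K 1–10, 10 replicates,
10,000 sweeps / 5,000 burn-in) are available via
`StructureConfig.publication_scale()`; the analysis scripts deliberately
use desk-scale sizes (2,000 sweeps, 5 replicates) that finish in minutes —
on these panel sizes the chains mix within a few hundred sweeps and the
desk-scale ΔK decision matched the truth in every seeded check we ran.

## Simulator

Balding–Nichols: ancestral frequency p ~ Uniform(0.1, 0.9) per locus;
population-specific frequency ~ Beta(p(1−F)/F, (1−p)(1−F)/F). Individuals
are either pure (one population each) or admixed with Dirichlet(α)
ancestries; inbred panels draw one allele and double it; F1 crosses are
deterministic from two inbred parents. Missingness is MCAR at a fixed
rate. The simulator records the full truth (ancestral and population
frequencies, Q, labels) for recovery tests. It does **not** emulate
linkage, ascertainment bias of SNP arrays, genotyping error beyond
missingness, selection, or pedigree depth greater than a single cross —
statistics sensitive to LD (e.g. effective-size estimators based on r²)
should not be validated against it.

## Known limitations

- Biallelic loci only; multi-allelic markers must be split upstream.
- The Gibbs sampler has no admixture-α update (α fixed), matching the
  simplest STRUCTURE variant.
- ΔK cannot choose K = k_min or k_max by construction; inspect L(K)
  directly when the optimum may sit on the boundary.
- Bootstrap support assumes exchangeable loci (no LD blocks).

## Tolerances used in tests

Closed-form identities are checked to 1e−12; Monte Carlo recoveries use
scale-appropriate bounds (Q-matrix RMSE ≤ 0.10 at 200 loci, |F̂ − F| < 0.05
at n = 200 × 500, K=1 likelihood vs. closed form within 1%) derived from
the estimators' standard errors, not tuned to specific seeds.
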