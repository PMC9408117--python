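# Methods

This note records the statistical models implemented in `msatpop`, the
conventions and defaults chosen where the field admits more than one, and
what the synthetic-data generator does and does not emulate.

## Data model and conventions

Genotypes are diploid, multi-allelic, and unordered; alleles are integer
codes — fragment sizes in bp for lab data, repeat counts for simulated
data. Missing genotypes are wholly missing (a half-missing genotype is a
validation error). Allele frequencies are computed over 2 × (observed
individuals); missing data are never imputed into frequencies. Population
order follows first appearance in the input file and allele order is
ascending by code, so every matrix the package writes is reproducible
bit-for-bit.

The GENEPOP writer places the population label after each `Pop`
separator (`Pop BAR`). Strict GENEPOP files with bare `Pop` lines are
read fine (populations are then named `Pop1`, `Pop2`, …); the labeled
variant exists so that write∘read is the identity.

## Marker diversity

* **TNA** — distinct alleles in the sample pooled over populations.
* **Allelic richness** — hypergeometric rarefaction,
  `AR(g) = Σ_a [1 − C(N−N_a, g)/C(N, g)]`, computed in log-gamma space.
  `AR(1) = 1` and `AR(N) = TNA` exactly. The default g is the smallest
  per-population gene-copy count at the locus, so that every population
  could have supplied a subsample of size g; g is logged because rarefied
  richness is not comparable across choices of g.
* **PIC** — Botstein's measure `1 − Σp² − Σ_{a<b} 2p_a²p_b²`, evaluated
  as `1 − S₂ − (S₂² − S₄)`.
* **Expected heterozygosity** — Nei's unbiased form
  `n/(n−1)·(1 − Σp²)` on gene copies.

Panel summaries (one row per locus, plus Average and SD rows using the
n−1 sample SD) are computed on the pooled sample, matching how marker
panels are conventionally characterized; per-population tables are also
exposed.

## Differentiation and gene flow

F_ST is the Weir–Cockerham (1984) θ: per (locus, allele) variance
components a (among populations), b (among individuals within
populations) and c (within individuals), combined as the ratio estimator
`θ = Σa / Σ(a+b+c)` over loci and alleles. The percent variation among
populations is 100·θ and within is 100·(1−θ). Pairwise values use the
same estimator at r = 2; negative pairwise estimates are reported as
computed (they are informative about the estimator's noise floor), but
are truncated to the +∞ gene-flow sentinel before the island-model
transform `Nm = (1−F_ST)/(4·F_ST)`, since negative migrant counts are
meaningless. Significance is assessed by permuting individuals among
populations (default 1000 permutations, seeded, +1-corrected p).

A leave-group-out recomputation (`fst_leave_group_out`) supports the
common robustness check of dropping a breed group and re-partitioning
the variance.

## Genetic distances

* **Molecular coancestry** `f_ij = (1/L) Σ_l Σ_a p_{l,i,a} p_{l,j,a}` —
  the probability that two random gene copies, one per population, are
  identical in state; the diagonal holds within-population expected
  homozygosity.
* **Nei's standard distance** uses the 1972 convention: gene identities
  J_X, J_Y, J_XY averaged arithmetically over loci before
  `Ds = −ln(J_XY/√(J_X J_Y))`, not per-locus Ds averaged. Disjoint allele
  sets give J_XY = 0 and a +∞ sentinel; for tree building infinities are
  replaced by a large finite sentinel (1e9) with a logged warning.
* **Goldstein's (δµ)²** `= (1/L) Σ_l (µ_{l,X} − µ_{l,Y})²` on mean allele
  sizes in repeat units. Fragment sizes in bp are converted through a
  per-locus offset and motif length. The unit choice rescales distances
  by a constant; all published-table reproductions here operate on the
  published distances themselves and are unit-independent.

Bootstrap resampling draws L loci with replacement per replicate and
recomputes the distance from per-locus ingredients (mean identities for
Ds, squared mean-size gaps for (δµ)², summed variance components for
F_ST), deterministic under a fixed seed.

## Neighbor joining

Saitou–Nei agglomeration with the Studier–Keppler criterion. Two
numerical choices make it deterministic and printable: ties in the Q
minimum break on the lowest (row, column) pair in the input label order,
and negative branch lengths are clamped to zero with the deficit moved
to the sister branch of the same join, preserving the joined pair's path
length (raw values are logged at debug level). On additive matrices the
tree reproduces the input metric to numerical precision; this is tested
against randomly generated trees. Bootstrap support of an internal edge
is the percentage of replicate trees containing the same leaf
bipartition. Newick output places integer supports as internal node
labels.

## Divergence dating

Under single-step stepwise mutation the expected (δµ)² between
populations diverged τ generations is 2βτ, so τ̂ = D/(2β) and years =
τ̂ × generation interval. Defaults: β = 1.2 × 10⁻³ per locus per gamete
per generation (the rate reported for highly polymorphic ovine
dinucleotide loci) and a 4.0-year generation interval. The 4.0-year
default was chosen because it is the constant that exactly regenerates
the packaged published divergence-time matrix from the packaged
published distances (every cell within the ±1.0-year residual of
3-decimal distance rounding); the 3.5-year interval often quoted for
Mediterranean sheep is available in `DatingConfig` and yields times
12.5% younger. The package does not attempt mutation-model corrections
beyond this linear calibration.

## Admixture clustering

The Gibbs sampler targets the admixture model: ancestry proportions Q_i
per individual, cluster allele profiles P_{k,l}, and latent per-copy
origins Z. All full conditionals are conjugate (Dirichlet); α (ancestry
concentration) and λ (profile prior) are fixed constants, default 1.0,
rather than Metropolis-updated — adequate for the well-separated
fixtures this package targets and simpler to verify. The data
log-likelihood is recorded on a thinned post-burn-in trace and
summarized as `L̂ = mean(lnL) − var(lnL)/2`, the usual estimate of
ln P(X|K). Default chain: 2000 burn-in, 10000 total sweeps, thinning 10
— deliberately far below STRUCTURE's defaults and sized for the
synthetic fixtures; real datasets warrant longer chains, and all
settings are logged. With K = 1 the allele counts are fixed, so each
recorded P is an iid draw from the exact Dirichlet posterior — the
correctness anchor used in the tests.

ΔK model selection follows Evanno: `ΔK = |L(K+1) − 2L(K) + L(K−1)| /
SD(L(K))` over ≥3 replicate runs per K (default 5), maximized over
interior K. Cross-run label alignment maximizes Σ Q_ref·Q_perm over
label permutations; because the objective separates over columns this is
solved exactly as a linear assignment rather than greedily.

Within-run label switching is not corrected; for the well-separated
fixtures the sampler does not switch in practice, and posterior-mean Q
would be diluted toward uniform if it did (the recovery tests would
catch this).

## DAPC

Individuals are coded as allele-dosage vectors (0/1/2 per allele
column), mean-imputed at missing genotypes, column-centered, reduced by
PCA (default: smallest PC count explaining ≥90% of variance), then
projected on linear discriminant axes of the group labels (at most
groups − 1 axes). PCA and LDA are delegated to scikit-learn.

## Synthetic-data generator

Forward-time Wright–Fisher: discrete non-overlapping generations, random
mating with selfing, constant diploid size N_e per branch, single-step
SMM mutation at rate β per copy per generation (no two-phase mutation,
no size bounds unless configured). Populations live on a rooted split
tree; a configurable pre-root burn-in (default 6·N_e generations) takes
the monomorphic founder population to mutation–drift equilibrium, which
matters because E[(δµ)²] = 2βτ holds only once the ancestral size
variance has equilibrated at 2N_eβ. Optional symmetric migration swaps
equal numbers of individuals (binomial counts at the configured rate)
between contemporaneous populations each generation, keeping sizes
constant.

The frequency-level admixture generator draws Q_i ~ Dirichlet(α), with
α = 0 as the exact no-admixture limit (pure individuals), and samples
each allele copy through its latent cluster; it returns the true Q for
recovery scoring.

The study-shaped preset emulates the published design — 975 individuals
in 11 breeds (n = 64, 41, 30, 28, 45, 41, 250, 186, 118, 141, 31), 17
loci with the published fragment-size windows — via a three-phase split
tree (deep split at 2750 generations, matching the deepest dated
divergence under the 4-year interval; intermediate splits 900–2400;
recent breed formations 120–420), N_e = 400, burn-in 1500 and a per-locus
mutation rate of 8 × 10⁻³. That rate was calibrated by simulation so
pooled per-locus allele counts land in the published 16–38 range
(seed 0: 17/17 loci, mean TNA 23.0 vs the published 22.53). Repeat
counts are mapped into each locus's bp window around its midpoint.

What the generator does **not** emulate: null alleles, genotyping error,
allele-size constraints and mutation-rate heterogeneity across loci,
overlapping generations, non-random mating, bottlenecks or expansions,
and real admixture histories. Passing recovery tests therefore
demonstrate estimator correctness under the stated model, not robustness
to these real-data complications.

## Pipeline determinism

Stage seeds derive from the master seed via
`numpy.random.SeedSequence(master).spawn` in a fixed stage order
(bootstrap, structure, permutation), and all stochastic operations take
explicit generators, so identical configs produce byte-identical
artifacts. Any stage failure aborts with the stage name; artifacts
already written are preserved.

## Problem sizes used in the test suite

The recovery checks run at desk scale, chosen to exercise each claim at
its stated tolerance: dating recovery uses 2 × N_e = 500 populations, 50
loci, τ = 500 and 20 replicate seeds; clustering recovery uses 100–120
individuals at 10–12 loci with 25 sampler runs for ΔK; the smoke test
runs the full pipeline twice on the 975-individual fixture with a
shortened chain and a reduced bootstrap count. Full-scale analyses
(B = 1000, STRUCTURE-scale chains) use the same code paths with the
default parameters.

## Known limitations

* The island-model Nm transform is a calibration, not an estimator;
  published Nm values computed by other tools from the same F_ST can
  differ (the transform here is the standard closed form).
* Per-locus β is assumed constant within a run; the dating calibration
  inherits any β misspecification linearly.
* The Gibbs sampler has no correlated-allele-frequency (F-model) prior,
  no linkage model, and no location prior.
* Ds is undefined for disjoint allele sets; the sentinel policy
  (∞ → 1e9 for trees) is logged but arbitrary.
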