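# msatpop

Microsatellite population genetics for structured diploid populations:
the full analysis chain used in breed phylogeography studies, as a
tested, scriptable Python package.

Given a table of diploid genotypes (individuals × loci, alleles coded as
fragment sizes or repeat counts, with population labels), `msatpop`
computes:

* **marker diversity** — allele counts (TNA), rarefied allelic richness
  AR(g), PIC, observed and unbiased expected heterozygosity;
* **differentiation** — Weir–Cockerham F_ST (global, pairwise,
  leave-group-out), the among/within variance partition, permutation
  significance, and island-model gene flow Nm = (1−F_ST)/(4F_ST);
* **genetic distances** — molecular coancestry f_ij, Nei's standard
  distance D_S, and Goldstein's (δµ)², with locus-bootstrap resampling;
* **trees** — neighbor-joining with bootstrap supports, written as
  Newick;
* **divergence dating** — τ = (δµ)²/(2β) generations under the stepwise
  mutation model (E[(δµ)²] = 2βτ), converted to years;
* **population structure** — an admixture-model Gibbs sampler
  (STRUCTURE-style Q and P matrices), Evanno ΔK model selection,
  cross-run label alignment, and DAPC;
* **simulation** — a forward-time Wright–Fisher engine with single-step
  stepwise mutation on a configurable population-split tree, plus an
  admixture-model generator, so every estimator can be validated against
  data with known truth.

It ships the published summary tables of a study of 11 western
Mediterranean sheep breeds (975 animals, 17 microsatellites) whose raw
genotypes were never deposited; the package re-derives that study's
marker-panel statistics and divergence-time matrix from those tables,
and its simulator generates study-shaped datasets for end-to-end
testing.

## Worked example

Simulate three populations related by a known split tree (ALP and BRO
split 100 generations ago, their ancestor and BAR 300 generations ago;
N_e = 200, β = 5×10⁻³ per locus), then summarize, measure
differentiation, and date the splits:

```python
from msatpop.simulate import SimConfig, SplitNode, simulate_smm
from msatpop.io import write_genotypes

cfg = SimConfig(split_tree=SplitNode(300, [SplitNode(100, ["ALP", "BRO"]), "BAR"]),
                n_e=200, beta=5e-3, L=10, sample_sizes=30, burn_in=1000, seed=42)
write_genotypes(simulate_smm(cfg), "demo.csv", "csv")
```

```text
$ msatpop summarize demo.csv -f csv
           TNA     AR   PIC    Ho    He
locus
L01       8.00   6.69  0.71  0.78  0.76
...
Average   8.30   7.41  0.77  0.72  0.80
SD        2.11   1.66  0.05  0.06  0.04

$ msatpop fst demo.csv -f csv
global theta = 0.1424 (14.2% among, 85.8% within)
    ALP	BRO
ALP
BRO 0.124
BAR 0.149	0.153

$ msatpop date demo.csv -f csv --beta 5e-3
    ALP	BRO
ALP
BRO 839.2
BAR 963.0	1289.2
```

Reading the output: about 14% of allele-frequency variance lies among
the three simulated populations. The dating step inverts (δµ)² through
τ = D/(2β) and a 4-year generation interval, so 839.2 years ≈ 210
generations for the ALP–BRO split whose true age is 100 — with only 10
loci the per-pair (δµ)² is noisy (its per-locus variance is of the order
of its squared mean); the package's tests show the estimator is unbiased
to within 30% once averaged over replicates at 50 loci. The BAR splits
(true age 300 generations = 1200 years at 4 yr/gen) date to 963–1289
years. `msatpop tree demo.csv -f csv --stat dmu2 -B 200` prints the
corresponding NJ tree with bootstrap supports as Newick.

The full chain (diversity → F_ST/Nm → f_ij → D_S/(δµ)² → NJ + bootstrap
→ dating → clustering + ΔK → DAPC) runs from one YAML config with
`msatpop run-all config.yaml`, writing a deterministic artifact bundle;
`msatpop simulate --out DIR` writes a study-shaped fixture in all three
supported formats (GENEPOP, STRUCTURE two-row, long CSV).

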