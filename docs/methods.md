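# Methods

This note documents the models implemented in `hapstep`, the choices made
where the design was genuinely open, and what the reduced-scale simulations
can and cannot show.

## The prediction problem

Single-step GBLUP (ssGBLUP) evaluates genotyped and non-genotyped animals
jointly under the animal model

    y = Xb + Zu + e,   u ~ N(0, H sigma_g^2),   e ~ N(0, I sigma_e^2)

where `b` holds fixed effects (generation class; the first class is absorbed
into the intercept) and `H` is the hybrid relationship matrix whose inverse
is the pedigree inverse plus a dense augmentation over the genotyped block:

    H^-1 = A^-1 + [0 0; 0 tau*(alpha*G + beta*A22)^-1 - omega*A22^-1]

with defaults alpha = 0.95, beta = 0.05, tau = omega = 1. `G` is VanRaden's
method-1 matrix `G = MM' / (2 sum p_i(1-p_i))` with dosages centered by `2p`
and missing dosages mean-imputed; frequencies come from the current
genotyped set.

Four model variants are supported: SNPs alone in one `G`; independent
(non-blocked) SNPs plus pseudo-SNPs in one `G`; pseudo-SNPs alone; and
independent SNPs and pseudo-SNPs as two uncorrelated genetic components,
each with its own `H`, the overall GEBV being `u1 + u2`.

### Base compatibility (tuning of G)

Before blending, `G` is rescaled so that its mean diagonal and mean
off-diagonal equal those of `A22` (two-parameter affine adjustment,
`ssgblup.tune_g`). When allele frequencies are estimated from a genotyped
subset that has been under selection, the genomic and pedigree relationship
matrices sit on different bases; without the adjustment the single-step
restricted likelihood degenerates and the genetic variance is driven to the
boundary. This is the standard compatibility treatment in single-step
software stacks and is applied by default in the scenario pipeline; the raw
matrix remains available through the library API.

### Solvers

The mixed-model equations are solved by Jacobi-preconditioned conjugate
gradients (relative residual 1e-12, at most 5,000 iterations). Variance
components are estimated by average-information REML with: damped Newton
steps (halving an update that would leave the parameter space), an EM step
as final fallback, a singularity guard on the AI matrix (condition number >
1e10 flags the fit as degenerate, as happens when two components carry
identical information), and a lower floor of 1e-6 * var(y) on every
component (hitting it flags the estimate as a boundary solution).
Convergence requires a maximum relative parameter change below 1e-8 for
library use; the scenario pipeline uses 1e-6 and at most 25 rounds and
reports non-convergence as a scenario status rather than an error. The
pipeline warm-starts every scenario's REML from a pedigree-only fit of the
same replicate, which typically halves the round count without changing the
optimum.

All per-round trace terms are computed exactly from a dense Cholesky
factorization of the coefficient matrix; this bounds the practical problem
size to a few thousand animals per evaluation, which the reduced preset
respects.

## Haploblocks and pseudo-SNPs

A haploblock is a run of two or more consecutive SNPs in mutual LD.
Candidate intervals within a 100-SNP sliding window qualify when every
member SNP has r^2 >= threshold with at least one other member and the mean
pairwise r^2 of the interval also clears the threshold; a non-overlapping
subset maximizing the number of SNPs covered is selected by
weighted-interval-scheduling dynamic programming with deterministic
tie-breaks (earlier start, then longer interval). This is a documented
approximation to clique-based LD blocking: published block finders in this
family do not specify a unique partition, so the stage is pluggable and its
contract (non-overlapping multi-SNP blocks from pairwise r^2 and a
threshold) is what downstream code relies on.

Each block's distinct haplotype alleles (enumerated over the genotyped sets,
training and validation jointly) become pseudo-SNPs; an individual's dosage
is its copy count of that allele, so dosages within a block sum to 2.
Missing phase inside a block contributes the block's allele frequencies
instead of hard counts (mean imputation, flagged). Pseudo-SNPs pass the same
QC as SNPs, treating each as bi-allelic (this allele vs all others): MAF >=
0.01 and |observed - expected heterozygote frequency| < 0.15.

## Diversity estimators

Pairwise r^2 is computed from phased gamete frequencies (squared dosage
correlation when phase is unavailable), restricted to MAF >= 0.05. Effective
population size comes from either the drift expectation E(r^2) =
1/(4*Ne*c + 2) inverted at a target distance (default c = 0.1 Morgan,
window +-5%, horizon t = 1/(2c) = 5 generations ago), or the realized
inbreeding rate Ne = 1/(2*dF), dF = (F_n - F_{n-1})/(1 - F_{n-1}).
Pedigree inbreeding uses the Meuwissen-Luo algorithm (a float32 tabular
sweep for pedigrees up to 8,000 animals, where it is faster). No sample-size
or mutation corrections are applied to E(r^2).

## The simulator

Meiosis draws crossovers as independent Bernoulli exchanges on inter-locus
intervals with Haldane recombination fractions, which is exactly a Poisson
crossover process without interference. Markers are bi-allelic (initial
frequency 0.5); QTLs carry 2-6 alleles (uniform initial frequencies) with
gamma(0.4) effect magnitudes and random signs, placed at positions disjoint
from markers. QTL effects are rescaled once, against the last historical
generation, so that the realized QTL variance equals `qtl_h2 * var_pheno`
(0.15*100 for the moderate trait, 0.01*100 for the low one); the remaining
genetic variance is an infinitesimal polygene: founders draw
N(0, var_polygenic), offspring receive the parent average plus a Mendelian
deviation with variance `0.5 * var_polygenic * (1 - mean parental F)`.
Inbreeding is tracked exactly through a relationship block maintained over
the active breeding stock. Phenotype = mean + TBV + N(0, (1-h2)*100).
Recurrent mutation (1e-4 per locus and generation; allele flip for markers,
re-draw for QTLs) acts in the historical phase only, the standard behavior
of forward breeding-program simulators.

Selection phases rank candidates on own phenotype, on pedigree-BLUP EBVs
(solved each generation on all records to date with the true variance
ratio), or at random. Breeding females are replaced at 20% per generation
plus exponential growth during the expansion phase; males at 40%; litter
sizes are 1/2/3 with odds 30/50/20. Ties are broken by a seeded random
jitter. Composites sample founders from their parent breeds at the
configured admixture proportions and mate at random for five generations
before EBV selection, with the founders' breed of origin recorded.

Genotyping observes dosages on a panel with 5% missing calls and a 1%
chance of replacing a call with a different valid code; SNP QC keeps loci
with MAF >= 0.01 and heterozygote deviation < 0.15. The HD panel is the set
of segregating markers (MAF >= 0.05) in the last historical generation; the
medium panel is a random within-chromosome subset of it.

## Reduced preset: what is scaled and why

The full study design (26 chromosomes, 2,656 cM, 576,595/46,827 markers,
historical census 80,000 and training sets of 60,000) is available as the
`full` preset but is cluster-scale. The default `reduced` preset keeps the
design's structure and its operative ratios while fitting a replicate into
roughly two minutes on one core:

- Genome: 4 chromosomes x 75 cM, 3,000 HD / 1,000 medium markers, 150
  QTLs. The genome is short; marker counts keep the design's operative
  ratio between panel spacing and the LD length scale 1/(4 Ne) so that
  haploblock formation behaves as in the full study.
- Historical population: census 500 for 80 generations, bottleneck to 300,
  recovery to 400 - enough drift to build baseline LD at the target Ne.
- Pure breeds: founder sizes 140/250/350, 10 (or 1) generations of
  phenotypic selection with 10% (15%) female growth, then 10 generations of
  EBV selection at ~130-175 dams. One sire serves five dams, giving a
  variance effective size near the design targets (Ne ~ 100 for the
  small-founder breed); the full-scale 1:25 ratio at thousands of dams
  yields the same Ne and ships in the `full` preset.
- Composites: 350 founders at 62.5/37.5 (or 37.5/37.5/25) admixture, five
  random-mating generations, then EBV selection with one sire per dam.
  The full design keeps composites at Ne 450-650 through census alone
  (>18,000 per generation at a 1/25 ratio); at ~250 animals per generation
  the high-diversity condition - the variable the study's conclusions turn
  on - survives only with maximal sire usage.
- Split: 1,600 phenotyped training animals (generations 1-8), 500
  genotyped (4-7), 300 validation animals (9-10), generation 8 a genotype
  gap - the full design's 60,000/8,000/2,000 kept in structure but with a
  larger genotyped and validation fraction so that accuracy and bias are
  estimable at this population size.

What reduced-scale runs do show: recovery of configured heritabilities by
pedigree REML under selection; the LD/Ne calibration; block counts falling
with the LD threshold and with diversity; pseudo-SNP-only models losing
accuracy and gaining negative dispersion bias; combined models matching
SNP-only models. What they cannot show: the absolute accuracies of the full
design (0.4-0.55 there) at their printed precision, convergence behavior of
the two-component model at 62,000+ animals, or block-statistic magnitudes,
all of which depend on the full training sizes and genome length.

## Realized heritability

`scenarios.pedigree_reml_heritability` estimates the realized h² the way a
routine evaluation would check it: phenotypes from the EBV-selection
generations, the relationship matrix from the breed's whole pedigree back
to its founders. The deep pedigree matters: it places the REML base in the
unselected founder cohort, so selection between founding and the recent
generations is accounted for and the estimate lands near the base h²
eroded only by drift (about 0.26 for the small-founder breed at reduced
scale against a base of 0.30). Truncating the pedigree at the recent
generations instead biases the estimate downward by several points.

## Equivalence margins in the acceptance tests

"Indistinguishable" scenario pairs (combined vs SNP-only models; medium
vs HD panels) are asserted as |mean paired accuracy difference| <= 0.02
across replicates. A paired t-test is the wrong tool at this scale: GEBVs
from near-identical marker sets correlate so strongly that differences of
under 0.01 become "statistically significant" while being practically
zero; the fixed margin expresses the scientific claim directly.

## Known limitations

- Dense-Cholesky REML bounds evaluations to a few thousand animals; the
  `full` preset requires external variance-component machinery.
- The blocking stage approximates clique-based partitioning; block
  boundaries can differ from other implementations even though counts and
  coverage behave the same way.
- Only additive QTL action is simulated; no sex chromosomes, no
  genotype-by-environment interaction, no epistasis.
- Validation animals whose parents sit in the genotype gap generation get
  no special treatment.
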