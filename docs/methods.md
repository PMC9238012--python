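# Methods

## The study design

The package reproduces, on synthetic data, a retrospective experiment on
genomic preselection (GPS).  A breeding program is simulated; its full
dataset is the *reference* scenario.  Two additional layers of GPS are
then imposed after the fact: *VGP* discards the genotypes and phenotypes
of every validation-generation animal without progeny, and *MGP*
additionally discards progeny-less animals in all training generations.
Because parents were chosen on GEBV, progeny-less animals are exactly
the preculled ones, so each layer deepens the preselection in the data.
Subsequent evaluations (ssGBLUP and PBLUP, with and without the
validation generation's own records, never with validation progeny) are
then scored against progeny yield deviations (PYD) of validation
animals — a forward-in-time validation, since the progeny records that
define PYD are withheld from every evaluation.

## Simulator

Discrete cohorts; cohort 0 is the founder population (unknown parents,
one unknown-parent group per founder cohort).  Genetics is additive:
per-SNP effect vectors are drawn with covariance G/(2Σp₀(1−p₀)) so that
founder true breeding values (TBV) have covariance G; offspring
genotypes are gene-dropped (unlinked biallelic loci); phenotype =
batch effect + litter effect + TBV + residual.  Trait variances are on
a phenotypic-variance-1 scale: additive h², litter `litter_var`,
residual the rest; the fixed batch effect (classes within cohort,
effects N(0, batch_sd²)) sits on top.

Defaults define the study conditions: 200 founders, 5 offspring
generations, 2 000 SNPs with founder allele frequencies U(0.05, 0.5),
4 traits named after pig production traits with h² = (0.25, 0.30, 0.50,
0.60), genetic and residual correlations 0.3 and 0.2, litter variance
0.10, 35 sires and 140 dams per generation, litter size 5, phenotyping
rate 0.95 (animal-level), genotyping rate 0.6 with parents always
genotyped, 1% missing calls.  This yields ≈2 900 animals, of which the
last cohort exists only to provide progeny phenotypes for PYD; the
training cut-off sits two cohorts before the end, making the
next-to-last cohort the validation generation.

**Two phases.**  The first `historic_generations` (default 2) cohorts
emulate the era before genomic preselection: replacement-sized litters
(size 2), random parent choice, no genotyping.  The modern phase uses
full litters, selective genotyping and truncation preselection.  The
genetic base used for rescaling (the first three training generations)
therefore consists of cohorts whose parents were not systematically
selected — as in the real data this design mirrors, where the base
generations long predate genomic selection and consist almost entirely
of breeding animals.  Without this structure, MGP's removal of
progeny-less base animals would delete a *selected* subset of the base
and shift the level-bias measure mechanically, an artefact of desk-scale
base cohorts rather than a property of preselection.

**Preselection is of young animals.**  The in-simulation selection index
is the sum of standardized per-trait GEBV (equal weights by default),
computed from all data *excluding the candidate cohort's own records* —
candidates are ranked on parent information plus their own genotypes,
which is what GPS means for animals preselected before performance
testing.  A consequence is that all information used by selection is
contained in the subsequent evaluations, the condition under which
ssGBLUP evaluations are expected to be unbiased.  The first modern
generation falls back to pedigree EBV (no informative genotypes yet);
the selection rule is configurable (`random`, `tbv`, `pblup`,
`ssgblup`).

Not emulated: overlapping generations, maternal effects, genotyping
errors, heterogeneous residual variance across environments, multi-line
structure.  Passing tests therefore demonstrate the statistical
machinery and the preselection logic, not robustness to those real-data
complications — in particular, the real-data driver of rising
heritability under preselection (culling of animals whose records are
poor for non-genetic reasons) is only partially mirrored by the
truncation mechanism here.

## Scenario semantics

"Discard" removes an animal's genotypes and phenotypes; the animal
survives as a bare pedigree node only if it is an ancestor of a kept
animal.  Because "has progeny in the data" refers to the data the
filter is applied to, a kept parent never loses its last progeny link
to pruning: its first progeny node is retained as evidence.  This makes
each scenario filter idempotent and keeps animal counts monotone
(reference ⊇ VGP ⊇ MGP).  Genotype QC (animal call rate → SNP call
rate → HWE exact test at p < 10⁻¹⁵ → MAF < 0.005, all strictly below;
thresholds configurable) is re-run per scenario, as the surviving
animal set changes.

## Evaluations

Henderson's mixed-model equations, assembled sparse with a per-animal
residual block R_S⁻¹ over each animal's observed traits, an
A⁻¹ ⊗ G⁻¹ (or H⁻¹ ⊗ G⁻¹) penalty, and independent non-genetic random
class effects per trait.  Unknown-parent groups use the Quaas–Pollak
augmented construction — group columns appended to A⁻¹ via Henderson's
rules with unknown parents replaced by their group — so animal
solutions are total breeding values including group means; the
equivalence with explicitly fitting genome-fraction covariates Q is
verified in the tests.  Rank deficiencies are resolved by zeroing the
first level of every fixed effect beyond the first and the first group
when any fixed effect is present; base-rescaled metrics are invariant
to this choice.  Systems are solved by dense Cholesky up to 6 500
equations and sparse LU above, with one step of iterative refinement;
the relative residual must reach 10⁻⁸ (target 10⁻¹⁰) or the solver
raises.

Precorrection fits the full model (batch fixed, litter random, animal
with A and groups, multi-trait) once on the full data and replaces each
record by y_c = y − Xb̂ − Wp̂.  Shrinkage of the litter solutions
absorbs a slice of each family's genetic mean, so var(y_c) sits
slightly below σ²_u + σ²_e at small litter sizes; the scenario-specific
REML step absorbs this scale into its estimates, which is why the
pipeline re-estimates variance components per scenario rather than
reusing the simulation truth.

The subsequent evaluations are mean-only models on precorrected
records.  The experiment grid evaluates trait by trait (single-trait
MME); genetic correlations enter through the multi-trait precorrection.
This keeps the largest solve at a few thousand equations; the
multi-trait solver itself is exercised against a dense GLS oracle in
the tests.

## Variance components

EM-REML for the single-trait model y = Xβ + a + e with
a ~ N(0, σ²_u A_rec), where A_rec is the recorded-animal block of A
(the restricted likelihood depends on the pedigree only through it) and
X holds the mean plus group fractions.  One symmetric
eigendecomposition of A_rec per record set turns each EM update into
O(n) work; updates are the standard monotone ones
(σ²⁺ = σ² + σ⁴(y'PMPy − tr(PM))/n with M = A_rec or I).  Convergence at
relative change < 10⁻⁶, up to 1 000 iterations; near a zero-variance
boundary EM approaches the floor slowly, which the boundary test
accounts for.  The EM fixed point is checked against a direct
Nelder–Mead maximisation of the dense-V restricted likelihood.

## Validation metrics

PYD per validation animal and trait averages y_c of phenotyped progeny
minus half the mate's EBV, mates taken from the mean-only full-data
pedigree model (the model that defines the PYD scale); progeny with
unknown mates are skipped and counted.  Weights are half-sib
reliabilities ¼nh²/(1+¼(n−1)h²) with the scenario-specific REML h² (a
full-sib variant is available).  PYD and (G)EBV are rescaled to the
base of the first three training generations before comparison.
Accuracy is the weighted Pearson correlation, its SE from the Fisher-z
interval at effective sample size (Σw)²/Σw²; level bias is the weighted
mean of PYD − GEBV/2 divided by the scenario's additive genetic SD,
with SE √(Σw²(x−x̄_w)²)/Σw; dispersion is the weighted least-squares
slope of PYD on GEBV with its WLS SE.  Scenario contrasts use a
one-tailed two-sample z comparison at the 5% level.

## Problem sizes and replication

The replicated checks use sizes chosen so a full study runs on a single
workstation core: the no-selection dispersion study uses the default
program (~2 900 animals, 2 000 SNPs, 4 traits) over 20 replicates; the
preselection grid uses a reduced program (150 founders, 25/100 parents,
litter 4, 1 000 SNPs, two traits with h² 0.3 and 0.5) over 20
replicates; REML recovery uses ~2 900 records per replicate.  Estimates
at these sizes carry sampling noise of a few hundredths on accuracy and
bias, which the acceptance bands account for by judging replicate means
against the typical reported SE of a single validation estimate — the
same standard used when declaring a bias "absent" in practice.

## Known limitations

- Single line per dataset; no shared-environment structure across lines.
- Litter-effect shrinkage leakage into y_c (above) grows as litters
  shrink; litter size 1 would make litter and residual inseparable.
- The exact inverse of A₂₂ and of the blended G are dense operations,
  capping comfortable genotyped-set sizes at a few thousand.
- EM-REML is single-trait; multi-trait covariances are taken from
  configuration where needed.
- PYD attenuates slightly when mates' EBV absorb part of a validation
  animal's merit through shared progeny records (small families); with
  the default family sizes the net effect on the dispersion slope is
  within sampling noise of 0.5.
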