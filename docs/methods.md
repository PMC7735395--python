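# Methods

`admixscan` analyses multi-population SNP genotype panels for population
structure and admixture, and ships a synthetic admixed-data generator so
that every stage of the pipeline can be validated end-to-end against
known truth.  This note records the models, the parameters that matter,
the numerical choices, and what the synthetic validation does and does
not demonstrate.

## Genotype model and QC

Genotypes are biallelic dosages (0/1/2 copies of the alphabetically
later allele; orientation is arbitrary and every downstream statistic is
invariant under flipping it, which the test suite asserts).  QC removes
individuals below a sample call-rate threshold (default 0.90) first,
then non-autosomal markers and markers outside an optional keep-list.  A
per-SNP call-rate filter exists behind a flag but is off by default: the
sample-level filter is the one that changes who enters the analysis,
and marker-level missingness is handled downstream by missing-aware
allele-frequency denominators (no imputation anywhere).

Weak-LD marker panels for the admixture grid are built by greedy
between-marker-distance (BMD) thinning: per chromosome, start at the
k-th marker and repeatedly take the first marker at least the target
spacing (default 550 kb) downstream.  Different start offsets give
near-disjoint panels of similar size.

## Synthetic data generator

Populations are mixtures of `K` ancestral components.  Component allele
frequencies follow the Balding–Nichols model around a shared ancestral
frequency drawn uniformly on [0.05, 0.95]:

    p_kl ~ Beta(p0_l (1-F_k)/F_k,  (1-p0_l)(1-F_k)/F_k)

so `E[p_kl] = p0_l` and `Var[p_kl] = F_k p0_l (1-p0_l)`.  The drift
coefficient `F_k` of a component is approximately the Weir–Cockerham
Fst between a pure population of that component and the ancestral pool,
and `F_i + F_j` approximates the Fst between pure populations of two
components — the scale on which the shipped scenario's values
(0.06–0.15) were chosen.

Each chromosome copy draws its ancestry from the individual's admixture
vector, either per SNP (independent-SNP mode: correct for the admixture
likelihood and for Fst calibration) or per genomic block (block-LD
mode).  Block-LD mode uses three nested scales, all tiling the
chromosome from coordinate 0:

* **founder blocks** (default 100 kb): each (component, block) carries a
  pool of founder haplotypes (default 6) drawn once per dataset from the
  component's frequencies — the pool belongs to the component, so
  populations mixing the same components share haplotypes;
* **founder tracts** (default 500 kb): a chromosome keeps copying the
  same founder index across consecutive blocks within a tract, so
  windows that straddle block boundaries still see contiguous founder
  haplotypes rather than an explosion of recombinant strings;
* **ancestry tracts** (default 5 Mb): ancestry switches only at tract
  boundaries, the scale of recent-admixture tracts.

Without the two longer scales, half-overlapping windows would combine
independent founder draws and show a large artificial excess of
population-private haplotypes — a property of the discretization, not
of admixture.

Marker maps use lognormal inter-marker spacings (mean 50 kb,
sigma = 1.4 on the log scale), emulating the clustered geometry of
gene-centric genotyping arrays; with this clustering, 550 kb BMD
thinning of a ~55k-marker map yields panels of roughly 3,700 markers,
matching the panel scale the pipeline's admixture grid is designed for.
Marker counts per chromosome are proportional to human autosome
lengths.

The bundled `table2` scenario has six components (an Austronesian
"Malay" component, Proto-Malay, Semang, Chinese, Indian, African) and
17 populations of 12–60 individuals (472 total) whose fixed design
admixture vectors have the published magnitudes for this kind of panel
(for example a northern-Malay-like population at ~0.21 of the
Indian-like component and ~0.53 of the Chinese-like component; rows are
normalized to sum to one on load).  Drift values were chosen once, at
human continental/regional magnitude, such that the six components are
mutually distinguishable at the ~3,700-marker panel size — the regime
the real study reports (stable clustering up to K = 6, unstable
above).

**What passing on synthetic data does not show.** The generator has no
mutation, no selection, no isolation-by-distance, no real recombination
map, and haplotype diversity bounded by the founder-pool size; real
panels have ascertainment bias and genotyping error.  Recovery results
therefore validate the estimators and the pipeline plumbing, not the
historical conclusions one would draw from real genotypes.

## Fst

Pairwise Fst is the two-population Weir–Cockerham theta computed from
per-population allele frequencies and haploid sample sizes (the
variance-components estimator in its haploid form), combined across
loci as a ratio of sums.  Loci with fewer than two sampled alleles on
either side, undefined frequencies, or zero total variance
(monomorphic across both samples) are skipped.  Negative estimates are
kept internally (they are informative about sampling noise) and floored
at zero only in reported distance matrices, which MDS and the tree
builders require to be nonnegative.  Whether a published matrix of this
kind used ratio-of-sums or per-locus averaging is generally ambiguous;
ratio-of-sums is the standard choice and the one implemented.

## MDS

The distance matrix is embedded by stress majorization: deterministic
classical (Torgerson) initialization followed by Guttman-transform
updates (SMACOF).  The majorized objective — normalized raw stress —
is guaranteed non-increasing and is the recorded stress sequence;
convergence is declared when the decrease in S-stress (formula 1,
computed on squared distances) falls below the tolerance (default
0.001) or after 30 iterations, and both S-stress and Kruskal stress-1
are reported.  Exact reproduction of ALSCAL's alternating least squares
is not attempted; for configurations realizable in the target dimension
both objectives reach zero and the embedding is exact up to rigid
motion.

## Admixture model

The likelihood is the standard admixture (frappe/ADMIXTURE) model: each
of the two allele copies of individual `i` at SNP `l` is allele B with
probability `sum_k q_ik p_kl`, so

    loglik = sum_{i,l} [ g_il log(sum_k q_ik p_kl)
                         + (2 - g_il) log(sum_k q_ik (1 - p_kl)) ]

maximized by EM with closed-form updates; missing genotypes contribute
nothing.  This is a deliberate replacement of Bayesian MCMC clustering
with maximum likelihood on the identical Q/P parameterization: it is
deterministic given a seed, desk-scale, and testable by parameter
recovery; the correlated-allele-frequencies prior is dropped (no
prior).  Consequences: the likelihood always increases with K, so model
choice cannot rely on the likelihood alone (see K selection), and the
likelihood surface has flatter ridges than the Bayesian posterior, so
run-to-run agreement depends on optimization quality.

Numerical choices, each load-bearing:

* **Acceleration.** Each recorded iteration is a SQUAREM extrapolation
  cycle built from two plain EM steps plus a stabilization step, with a
  fallback to the plain double step whenever extrapolation would lower
  the likelihood — the recorded log-likelihood path is therefore
  non-decreasing by construction, while convergence is roughly an order
  of magnitude faster than plain EM on admixed data.
* **Initialization.** Q rows from a seeded Dirichlet(1,...,1); cluster
  frequencies from k-means++-style archetypes — K individuals chosen by
  squared-distance-proportional sampling, pseudo-count smoothed.
  Starting the clusters apart this way avoids inferior symmetric modes
  far more reliably than perturbing the overall frequencies.
* **Multi-start.** Several burn-in phases (default 4 starts x 60 cycles)
  from independent initializations, continuing from the best.  The
  burn-in likelihood only becomes a reliable predictor of a start's
  final mode after a few dozen cycles — with 30-cycle burns the
  selection is close to random among starts — so one longer burn per
  start beats many short ones at equal cost.
* **Bounds.** P clipped to [1e-6, 1 - 1e-6]; Q renormalized each step.
  Because P is clipped and Q rows sum to one, the mixture probability
  is automatically bounded away from 0 and 1 and the likelihood is
  always finite.

## Run stability and K selection

Label switching between runs is resolved by the symmetric similarity
coefficient: `SSC(Q1, Q2) = 1 - ||Q1 - Q2 Pi||_F / sqrt(2N)` maximized
over column permutations Pi (exhaustive for K <= 8, optimal linear
assignment above — the assignment solution is exactly optimal, not
merely greedy).  `select_k` summarizes a grid of fits: per K, the mean
and SD of the final log-likelihood and the minimum pairwise SSC across
all runs and sub-panels.  The recommended K is the largest one whose
minimum SSC clears the stability floor (default 0.90) while still
improving the mean log-likelihood over K-1.  Under maximum likelihood
the second condition is nearly always satisfied, so the floor does the
work: above the true K the extra cluster's placement is arbitrary,
near-tied modes proliferate, and replicate runs disagree — the same
diagnostic practitioners apply to clustering output, made explicit.

## Haplotype sharing

Windows of 50/100/200 kb slide by half their size along each
chromosome; only complete windows inside the marker span are kept
(windows with no markers are dropped; a chromosome shorter than one
window contributes a single covering window).  Within a window every
chromosome's allele string is a haplotype; strings are compared for
exact identity.

Non-replacement sampling (NRS) removes sample-size bias: an equal
number of chromosomes (default twice the smallest group's individual
count) is drawn from every group, 100 times by default.  Within each
drawn group sample, strings observed fewer than twice (configurable)
are discarded — the rarity filter operates on the sampled set, after
resampling.  A focal group's surviving strings are then classified by
exact-match presence in the other two groups' surviving sets: private,
shared with one, shared with the other, shared with all.  Percentages
are over distinct strings (frequencies deliberately ignored), averaged
over windows with at least one surviving focal string within a
replicate, then over replicates.  A fourth (outgroup) group never
alters the categories; its sharing with each category is recorded.

For tree building, every window is treated as one multi-allelic locus
whose alleles are the surviving distinct haplotypes, and pairwise
multi-allelic Weir–Cockerham theta is combined across windows as a
ratio of sums and averaged over replicates.  What entity plays the role
of "population" is a genuine modelling choice, so both readings are
implemented behind a flag: the default taxa are the haplotype-category
pseudo-populations (chromosomes carrying private-A / private-B /
private-C / fully-shared haplotypes, plus outgroup chromosomes); the
alternative taxa are the drawn groups themselves.  Note the category
pseudo-populations have pairwise-disjoint allele sets by construction,
which inflates their mutual distances; the group reading is the one in
which an outlying outgroup is farthest from everything, and the test
suite checks each variant only for the properties that construction
actually implies.

## Phylogenies

Neighbor joining follows the canonical Saitou–Nei agglomeration with
the standard Q-criterion and branch-length formulas; ties in the
criterion are broken by the lexicographically smallest pair of
cluster labels (each cluster labelled by the smallest leaf beneath it),
making output identical across platforms and leaf orders.  Negative
branch lengths are clamped to zero with a counter recorded on the tree.
On additive matrices NJ recovers the generating topology and lengths
exactly, which the tests assert to 1e-10.

Cluster trees bootstrap SNP loci of the cluster-frequency matrix with
replacement (1,000 replicates by default), rebuild NJ per replicate
under Cavalli-Sforza chord or Nei's DA distance, and take the
majority-rule consensus (bipartitions in more than half the replicates;
support = percentage of replicates; branch lengths averaged over the
trees containing each bipartition).  Loci are the only exchangeable
unit once clusters are summarized as frequencies, hence the bootstrap
unit.  Rooting places the root at the midpoint of the outgroup's
pendant edge.

## Pipeline

One YAML config drives simulation/ingest, QC, Fst + MDS, the admixture
grid with K selection, HSA, and the trees; every output table and tree
is written with a SHA-256 hash into a manifest, and re-running with the
same config and seed reproduces identical hashes (timings go to the run
log, which is excluded from the manifest).  The bundled
`table2_pipeline` config runs the full-shape scenario (472 individuals,
~55k markers) with desk-scale stage settings — one thinned sub-panel,
K = 2..6 with two seeds each at 60 accelerated iterations, 10 NRS
replicates at the 100 kb window, 200 bootstrap replicates — sizes
chosen so a complete run takes a few minutes on one CPU; production
analyses would raise them (module defaults: 100 NRS replicates, 1,000
bootstraps, 2,000 EM iterations).

The validation experiments elsewhere in the repository use matched
problem sizes: Fst calibration at L = 5,000 and 50 individuals per
population; admixture recovery at K = 2, L = 2,000, 60 individuals;
K selection on a 472-individual, 3,700-marker independent-SNP panel
(the size and LD regime of one BMD-thinned sub-panel), with ten
replicate runs at the candidate K; haplotype-sharing checks on a
three-group, 120-individual block-LD simulation at the 100 kb window.

## Known limitations

* The admixture fit has no correlated-frequencies prior, so very
  recently diverged components need more markers to separate than a
  Bayesian fit with that prior would.
* Haplotype comparison is exact string identity; genotyping error or
  imperfect phasing would fragment sharing in real data (phasing is
  consumed as given and assumed complete).
* The haplotype-sharing distance is one defensible construction of an
  underdetermined quantity; trees built from it should be read as
  descriptive summaries, not estimates of a generative process.
* S-stress is reported but the update rule majorizes raw stress; the
  two disagree only away from convergence on non-realizable inputs.
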