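# admixscan

Population-structure and admixture analysis for multi-population SNP
genotype panels, built for studies of admixed human populations (the
motivating case: Peninsular Malaysia Malay sub-ethnic groups genotyped
on ~50k-SNP arrays alongside reference Asian and African populations).

The pipeline covers, as reusable library modules and a CLI:

* **QC and thinning** — PLINK PED/MAP text I/O, sample call-rate
  filtering, autosome restriction, greedy between-marker-distance
  thinning into weak-LD sub-panels (`admixscan.genotype_io`);
* **Genetic differentiation** — missing-aware allele frequencies,
  pairwise Weir–Cockerham Fst (two-population θ, ratio of sums over
  loci), Cavalli-Sforza chord and Nei's DA distances
  (`admixscan.popgen`), and stress-majorization MDS embedding in 2-D/3-D
  (`admixscan.mds`);
* **Admixture inference** — maximum-likelihood estimation of
  per-individual ancestry fractions Q and per-cluster allele
  frequencies P under the admixture model
  `loglik = Σ_{i,l} [g_il log Σ_k q_ik p_kl + (2−g_il) log Σ_k q_ik (1−p_kl)]`
  via accelerated EM, with CLUMPP-style symmetric-similarity (SSC)
  scoring of replicate runs and stability-based selection of the number
  of clusters K (`admixscan.admixture`);
* **Haplotype-sharing analysis (HSA)** — sliding 50/100/200 kb windows,
  four-category classification of a focal group's distinct window
  haplotypes (private, shared with one comparison group, with the
  other, with all), non-replacement resampling of equal chromosome
  numbers per group, and haplotype-based Weir–Cockerham distances
  (`admixscan.hsa`);
* **Phylogenies** — deterministic neighbor joining, locus-bootstrap
  cluster trees with majority-rule consensus supports, outgroup rooting,
  Newick I/O (`admixscan.phylo`);
* **Synthetic data** — a Balding–Nichols admixture generator with
  block-LD haplotype structure and recorded truth, so every stage is
  testable without access restrictions (`admixscan.simulate`).

The scientific background and all modelling choices are documented in
[docs/methods.md](docs/methods.md).

## Worked example

Simulate two drifted source populations and a 60/40 admixed one, then
measure differentiation and recover the ancestry fractions:

```python
import admixscan as ax

specs = [ax.PopulationSpec("EAST", 30, admixture=[1.0, 0.0]),
         ax.PopulationSpec("WEST", 30, admixture=[0.0, 1.0]),
         ax.PopulationSpec("ADMIX", 30, admixture=[0.6, 0.4])]
cfg = ax.SimulationConfig(component_names=["east", "west"],
                          drift=[0.08, 0.08], populations=specs,
                          n_snps=4000, n_chromosomes=4,
                          mode="independent", seed=1)
data = ax.simulate_dataset(cfg)

freqs = ax.allele_freqs(data.genotypes, data.labels)
print(ax.fst_matrix(freqs).to_frame().round(4))

fit = ax.fit_admixture(data.genotypes, K=2, seed=0, tol=1e-3, max_iter=300)
table = ax.cluster_mean_q(ax.align_to(data.truth.q, fit.q), data.labels,
                          data.genotypes.individual_ids)
print(table.round(3))
print(f"loglik {fit.loglik:.1f} after {fit.iterations} iterations")
```

Output:

```
        EAST    WEST   ADMIX
EAST   0.000  0.0800  0.0130
WEST   0.080  0.0000  0.0298
ADMIX  0.013  0.0298  0.0000
            cluster1  cluster2
population
EAST           0.987     0.013
WEST           0.007     0.993
ADMIX          0.597     0.403
loglik -362385.0 after 93 iterations
```

Reading the numbers: the two sources were each simulated with drift
F = 0.08 from their shared ancestor, and the estimated Fst between them
is 0.080; the admixed group sits asymmetrically between them (0.013 vs
0.030), closer to its 60% source — admixture shrinks differentiation
toward the majority donor.  The K = 2 fit recovers the design ancestry
fractions (1/0, 0/1, 0.6/0.4) to within about 0.01 from genotypes
alone.

## Command line

Each stage is exposed as a subcommand over the same library:

```bash
admixscan simulate --scenario table2 --seed 1 --out sim/
admixscan fst --ped sim/sim.ped --map sim/sim.map --labels sim/labels.tsv --out fst.tsv
admixscan mds --matrix fst.tsv --dims 2 --out mds.tsv
admixscan admix --ped sim/sim.ped --map sim/sim.map --k 6 --seed 0 --out admix/
admixscan run --config table2_pipeline --seed 5 --out results/
```

`admixscan run` executes the full pipeline from one YAML config
(bundled: `table2_pipeline`, a 472-individual, 17-population,
six-component scenario) and writes every table and tree with a SHA-256
manifest; re-running with the same seed reproduces identical hashes.

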