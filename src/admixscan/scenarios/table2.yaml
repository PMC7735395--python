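# Six-component admixed scenario emulating a 472-individual, 17-population
# SNP-array panel (five Peninsular Malaysia Malay sub-ethnic groups, Orang
# Asli, Thai, Indonesian, Chinese, Indian and Yoruba samples).  Each
# population has a fixed design admixture vector of the published magnitude
# over the six ancestral components; component allele frequencies drift from
# a shared ancestral frequency under Balding-Nichols with per-component F
# chosen at human continental/regional scale.  Block-LD mode gives each
# 100 kb block a small founder-haplotype pool per component so that sliding
# windows contain shared multi-SNP haplotypes.
components:
  - {name: malay, drift: 0.06}        # Austronesian-speaker component
  - {name: proto_malay, drift: 0.10}
  - {name: semang, drift: 0.14}       # strong drift: isolated forager groups
  - {name: chinese, drift: 0.06}
  - {name: indian, drift: 0.08}
  - {name: african, drift: 0.15}

# admixture rows are normalized to sum to 1 on load
populations:
  - {name: MY-JV, n: 19, admixture: [0.419, 0.004, 0.010, 0.665, 0.004, 0.001]}
  - {name: MY-BG, n: 14, admixture: [0.255, 0.027, 0.044, 0.561, 0.008, 0.001]}
  - {name: MY-MN, n: 20, admixture: [0.318, 0.011, 0.019, 0.525, 0.125, 0.002]}
  - {name: MY-KN, n: 18, admixture: [0.222, 0.018, 0.054, 0.542, 0.162, 0.002]}
  - {name: MY-KD, n: 24, admixture: [0.206, 0.028, 0.031, 0.527, 0.208, 0.001]}
  - {name: MY-TM, n: 49, admixture: [0.101, 0.361, 0.053, 0.478, 0.006, 0.001]}
  - {name: MY-JH, n: 50, admixture: [0.012, 0.010, 0.808, 0.168, 0.002, 0.000]}
  - {name: MY-KS, n: 30, admixture: [0.018, 0.006, 0.926, 0.035, 0.015, 0.001]}
  - {name: TH-PT, n: 14, admixture: [0.237, 0.013, 0.039, 0.570, 0.140, 0.001]}
  - {name: ID-JV, n: 19, admixture: [0.251, 0.029, 0.048, 0.663, 0.008, 0.001]}
  - {name: ID-ML, n: 12, admixture: [0.378, 0.005, 0.018, 0.586, 0.012, 0.001]}
  - {name: ID-TR, n: 20, admixture: [0.444, 0.004, 0.009, 0.540, 0.003, 0.001]}
  - {name: CN-JN, n: 29, admixture: [0.016, 0.005, 0.015, 0.959, 0.005, 0.001]}
  - {name: CN-WA, n: 56, admixture: [0.032, 0.005, 0.021, 0.936, 0.005, 0.001]}
  - {name: IN-WL, n: 14, admixture: [0.002, 0.003, 0.006, 0.006, 0.979, 0.004]}
  - {name: IN-DR, n: 24, admixture: [0.003, 0.003, 0.011, 0.006, 0.975, 0.002]}
  - {name: YRI,   n: 60, admixture: [0.001, 0.001, 0.003, 0.001, 0.002, 0.992]}

n_snps: 54794
n_chromosomes: 22
mean_spacing_bp: 50000
spacing_log_sd: 1.4      # clustered spacing typical of gene-centric arrays
ancestral_freq_range: [0.05, 0.95]
mode: block
block_length_bp: 100000
founders_per_block: 6
founder_tract_bp: 500000     # haplotype persistence across blocks
ancestry_tract_bp: 5000000   # recent-admixture ancestry tract scale
seed: 0
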