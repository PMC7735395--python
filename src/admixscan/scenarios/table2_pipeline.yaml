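# Full-pipeline demonstration config on the bundled six-component scenario.
# Stage sizes (admixture grid, NRS replicates, bootstrap replicates) are kept
# at desk scale so the whole pipeline runs in a few minutes on one CPU; every
# setting can be raised for production-scale runs.
scenario: table2
seed: 0

qc:
  min_call_rate: 0.9
  autosomes_only: true

mds:
  dims: [2, 3]
  tol: 0.001
  max_iter: 30

thinning:
  target_spacing_bp: 550000
  n_subsets: 5

admixture:
  k_min: 2
  k_max: 6
  seeds_per_k: 2
  n_datasets: 1
  tol: 0.001
  max_iter: 40
  n_starts: 2
  burn_iters: 10
  ssc_floor: 0.90

group_schemes:
  MY_CN_IN:
    MY: [MY-BG, MY-JV, MY-MN, MY-KN, MY-KD, TH-PT, ID-JV, ID-ML, ID-TR]
    CN: [CN-JN, CN-WA]
    IN: [IN-WL, IN-DR]
  NMY_CN_IN_YRI:
    NMY: [MY-KD, MY-KN, TH-PT]
    CN: [CN-JN, CN-WA]
    IN: [IN-WL, IN-DR]
    YRI: [YRI]

hsa:
  schemes: [MY_CN_IN]
  window_sizes: [100000]
  replicates: 10
  min_count: 2

hsa_distance:
  scheme: NMY_CN_IN_YRI
  window_size: 100000
  replicates: 5

phylogeny:
  bootstrap_reps: 200
  distances: [cavalli_chord, nei_da]
  outgroup_population: YRI
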