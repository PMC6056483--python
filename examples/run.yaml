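# Full-pipeline configuration: simulate the 25-population reference panel
# and run every stage. See `dipkit run --help`.
outdir: results/full_run
preset: kyrgyz_like
focal_population: Kyrgyz_study
alpha: 0.05
n_perm: 999
k_range: [1, 2, 3, 4, 5, 6]
n_seeds: 5
aim_threshold: 0.29
seed: 0
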