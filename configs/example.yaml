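# Full-pipeline configuration (see README).  Paths point at the fixture
# written by `python analysis/01_simulate_cohort.py`.
ped: scratch/cohort/genotypes.ped
map: scratch/cohort/genotypes.map
pedigree: scratch/cohort/pedigree.tsv
phenotypes: scratch/cohort/phenotypes.tsv
out_dir: results/run

# QC thresholds (strict inequalities)
maf_min: 0.01
call_rate_min: 0.90
hwe_p_min: 1.0e-6

# step 2
top_k: 500
a: 1.0e-6
b: 1.0e-6

# permutation threshold
n_perm: 200
alpha: 0.05

seed: 2024
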