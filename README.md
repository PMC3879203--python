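# lassogwas

Two-step multi-SNP GWAS for pedigreed populations — the analysis design
used for conformation traits in dairy cattle, where the phenotype is an
estimated breeding value (EBV), family structure is strong, and single-SNP
scans leave the joint architecture unresolved.

**Step 1.** A single-SNP mixed-model scan: for each SNP j,
`y = 1μ + x_j β_j + Zg + e` with a pedigree polygenic effect
`g ~ N(0, A σ_g²)` and `e ~ N(0, I σ_e²)`, genotypes coded AA/AB/BB →
−1/0/+1.  Variance components are REML-estimated once on the null model
and held fixed, so the scan is a linear solve per SNP; each β_j gets a
t-test against the Bonferroni threshold −log10(0.05/N).  The 500
smallest-P SNPs move on.

**Step 2.** Those SNPs are fit jointly, `y = 1μ + Xβ + Zg + e`, under an
adaptive Bayesian LASSO: a Laplace prior (λ_j/2)·exp(−λ_j|β_j|) per
effect with a gamma(a, b) hyperprior on λ_j²/2 (a = b = 10⁻⁶), maximized
by EM with g and the Laplace scale-mixture auxiliaries as missing data.
Each SNP is summarized by its heritability

    h_j² = σ_j² / (Σ_j σ_j² + σ_g² + σ_e²),   σ_j² = 2 p_j (1 − p_j) β_j²,

and declared genome-wise significant when h_j² exceeds the empirical 95th
percentile of the per-permutation maximum heritability over phenotype
permutations.  Hits are annotated with the nearest gene within 1 Mb.

Everything runs on synthetic cohorts with known truth — pedigree
simulation, gene-dropped genotypes, planted QTLs — so the whole pipeline
is testable without any external data.  See `docs/methods.md` for model
details, numerical choices, and what the simulation does and does not
emulate.

## Worked example

`analysis/` contains the numbered study scripts.  They simulate a
progeny-test cohort — 1000 phenotyped daughters of 50 sires in a paternal
half-sib pedigree — with 1500 SNPs on 5 chromosomes and five planted QTLs
each explaining ~3% of variance (polygenic 0.30, residual 0.50), then run
the two steps:

```bash
python analysis/01_simulate_cohort.py
python analysis/02_qc_and_kinship.py
python analysis/03_smma_scan.py
python analysis/04_multisnp_lasso.py
python analysis/05_permutation_threshold.py
python analysis/06_annotate_and_report.py
```

Output of the run shipped in `results/` (seed 2024):

```
null REML: sigma_g2 0.5556, sigma_e2 0.4326 (pedigree heritability 0.562)
scan over 1500 SNPs: Bonferroni -log10 threshold 4.48, 4 SNPs above it; min P at snp_5_74
top-500 selection carries 5/5 planted QTLs forward
EM converged in 129 iterations; 27/500 effects nonzero
planted QTL h2 ranks (1 = largest): {'snp_1_39': 4, 'snp_1_267': 3, 'snp_2_248': 5, 'snp_4_59': 2, 'snp_5_74': 1}
permutation null over 200 shuffles: median max-h2 0.00961, threshold (alpha=0.05) 0.01523
4 SNPs genome-wise significant: ['snp_5_74', 'snp_4_59', 'snp_1_267', 'snp_1_39']
planted QTLs among them: 4/5
```

Reading this: the null REML heritability (0.56) exceeds the simulated
polygenic share because the causal SNPs fold into the polygenic term in
the null model.  The scan's Bonferroni threshold clears only 4 SNPs, but
all five QTLs survive into the top-500 set, and in the joint fit they
occupy the top five heritability ranks while 473 of 500 effects are
zeroed exactly.  Four exceed the permutation threshold of 0.0152 on the
h² scale; the fifth sits just under it at this seed — across 50 seeded
replicates the validation suite finds a per-QTL significance rate of
roughly 85–90% at these effect sizes.  The same pipeline is available as
a CLI (`lassogwas run-all --config configs/example.yaml`) with
subcommands `simulate`, `qc`, `scan`, `lasso`, `permute`, `annotate`,
`correlations`.

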