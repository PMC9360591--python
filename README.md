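# mrkit — two-sample Mendelian randomization from GWAS summary statistics

`mrkit` implements the complete workflow for estimating the causal effect of
a genetically proxied exposure (here: liability to asthma) on disease
outcomes (here: eight cardiovascular diseases) from published GWAS summary
statistics, without individual-level data:

1. **Instrument validation** — genome-wide significance filtering
   (p < 5×10⁻⁸), greedy LD pruning at r² < 0.001 against a supplied
   pairwise-r² matrix, curated exclusion of confounder- and
   outcome-associated SNPs, and per-SNP strength via
   R² = 2β²q(1−q) / (2β²q(1−q) + 2Nq(1−q)·se²) and F = R²(N−2)/(1−R²).
2. **Harmonization** — expressing each SNP's exposure and outcome effects on
   a shared effect allele, resolving swaps and strand flips, and dropping
   palindromic SNPs whose allele frequency cannot resolve the strand.
3. **Estimation** — per-SNP Wald ratios β_Y/β_X; the inverse-variance
   weighted (IVW) estimator under a multiplicative random-effects model,

       β̂_IVW = Σ wⱼ β_Xⱼ β_Yⱼ / Σ wⱼ β_Xⱼ²,  wⱼ = 1/se_Yⱼ²,
       se = se_FE · max(1, √(Q/(J−1))),

   with Cochran's Q and I² heterogeneity diagnostics; the weighted-median
   estimator (consistent when >50 % of weight is valid) with a seeded
   parametric-bootstrap standard error; and MR-Egger regression, whose
   intercept tests for directional horizontal pleiotropy (t, J−2 df).
4. **Meta-analysis and classification** — fixed-effects pooling of
   per-source IVW estimates for each outcome and Bonferroni classification:
   p < α/k significant, α/k ≤ p < α suggestive (α = 0.05, k = 8 outcomes).
5. **Simulation** — a synthetic two-sample GWAS generator with known causal
   slope, instrument strengths and configurable horizontal pleiotropy, plus
   a scenario-grid harness for type-I error, power, bias and coverage.

Everything is driven by tab-delimited summary tables
(`snp_id chrom pos effect_allele other_allele eaf beta se pval n`) and
JSON-lines audit ledgers, so a full analysis is reproducible from flat files
and a YAML config.

## Worked example

The numbered scripts under `analysis/` run a complete synthetic study:

```bash
python analysis/01_simulate_cohorts.py     # simulate exposure + 2 outcome sources
python analysis/02_select_instruments.py   # 16 -> 9 instrument screen; R², F
python analysis/03_run_mr.py               # full MR + meta-analysis
python analysis/04_scenario_grid.py        # operating characteristics
```

Step 03 prints the forest table for a two-source analysis generated with a
true causal log-OR of 0.077 (odds ratio e^0.077 ≈ 1.08) per 1-log-unit
increase in exposure liability:

```
outcome      source          method  n_snps             or_ci      pval
     AF     primary         ivw_mre       9 1.08 (1.07, 1.09)  4.52e-63
     AF     primary weighted_median       9 1.08 (1.08, 1.09)  6.6e-108
     AF     primary  mr_egger_slope       9 1.09 (1.07, 1.10)  5.59e-06
     AF replication         ivw_mre       9 1.08 (1.07, 1.09)     2e-50
     AF replication weighted_median       9 1.08 (1.07, 1.09)  4.05e-41
     AF replication  mr_egger_slope       9 1.08 (1.07, 1.08)  2.77e-07
     AF        meta         ivw_mre       9 1.08 (1.07, 1.09) 1.27e-111
```

The meta-analyzed IVW odds ratio recovers the generating value (1.08), all
three estimators agree, and the MR-Egger intercept shows no pleiotropy — as
expected, since none was simulated.  Step 04 quantifies the estimators'
frequentist behaviour over 1,000 replicates per scenario: type-I error near
0.05 under the null, power ≈ 1 at log-OR 0.08 with nine strong instruments,
and under directional pleiotropy a biased IVW alongside an MR-Egger
intercept that flags the violation in ~84 % of replicates.

The same pipeline runs from the command line on real summary tables:

```bash
mrkit run --config run.yaml        # instruments -> harmonize -> MR -> meta
mrkit simulate --config sim.yaml --out simdir
mrkit grid --config grid.yaml
```

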