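# permforge

Permutation testing for quantitative-trait genome-wide association studies
(GWAS), on standard PLINK binary data. `permforge` implements the two
permutation procedures practitioners actually use at scale — **maxT**
family-wise error control and **adaptive (early-stopping) permutation** —
around a reproducible, block-partitionable dot-product kernel, with an
optional emulated fixed-point mode whose approximation error is explicit
and measurable. It is aimed at statistical geneticists who need exact,
replayable permutation p-values on continuous phenotypes, and at anyone
validating an accelerated permutation engine against a transparent
reference.

## The statistics

For each SNP, association with a continuous phenotype under the additive
model is scored by the simple-regression F statistic

```
F = ρ² / (1 − ρ²) · (n − 2),        ρ = Σᵢ(xᵢ − x̄)(yᵢ − ȳ) / √(Σ(xᵢ − x̄)² Σ(yᵢ − ȳ)²)
```

where `x` is the allele-count vector (0/1/2, missing entries mean-imputed)
and `y` the covariate-adjusted phenotype `y = b − C(CᵀC)⁻¹Cᵀb` (or plain
centring without covariates), computed once before permutation. Permuting
`y` leaves both sums of squares fixed, so each permutation costs one
matrix–vector product of the centred genotype matrix against the permuted
phenotype — the kernel everything else is built on.

Permutation p-values use the standard estimator `p = (x + 1)/(b + 1)` with
`x` the count of permuted statistics that tie or exceed the observed one.
Two drivers are provided:

- **maxT** builds the null from the per-permutation *maximum* F across all
  SNPs, giving family-wise adjusted p-values (`EMP2`) for which ~1000
  permutations suffice at the 0.05 level regardless of SNP count.
- **adaptive** permutation stops testing a SNP once `R` permuted
  statistics have tied-or-exceeded its observed F, reporting
  `p = (x+1)/(B+1)` after `B` permutations; dropping is evaluated at
  checkpoints that start at the minimum-permutations-per-SNP (M-P-S)
  parameter and grow by 20% every 5 checkpoints. Pointwise p-values at the
  genome-wide threshold 5×10⁻⁸ need ≥ 19 999 999 permutations per SNP,
  which is why early stopping matters.

## Worked example

Simulate a 200-SNP × 300-sample cohort with one planted effect at SNP
index 17 (`rs18`, β = 0.45 per allele copy), then test it:

```bash
permforge simulate --m 200 --n 300 --causal 17 --beta 0.45 \
    --missing-rate 0.02 --seed 42 --out sim
permforge maxt --bfile sim --mperm 999 --seed 7 --out gwas
```

The top of `gwas.maxt.tsv`, sorted by adjusted p-value:

```
  SNP     F_OBS  EMP1  EMP2
 rs18 16.319653 0.001 0.009
 rs94  9.140724 0.003 0.400
rs160  6.465858 0.011 0.905
```

The planted SNP reaches the minimum attainable pointwise p-value
1/(999+1) = 0.001 and a family-wise `EMP2` of 0.009 — significant at the
0.05 level after correction for all 200 SNPs — while the best null SNP's
`EMP2` of 0.400 shows the maxT null absorbing the multiplicity. The same
data under adaptive permutation with a 10 000-permutation budget:

```bash
permforge adaptive --bfile sim --aperm-max 10000 --aperm-mps 121 \
    --aperm-r 10 --seed 7 --out gwas
```

```
  SNP     F_OBS  X     B    EMP_P  DROPPED_AT
 rs18 16.319653  0 10000 0.000100          -1
 rs94  9.140724 10  4252 0.002586          23
rs160  6.465858 10  1041 0.010557           7
```

199 of 200 SNPs were dropped early (median after B = 121 permutations,
the first checkpoint); only the causal SNP ran its full budget and reached
the floor 1/(10000+1) ≈ 1.0×10⁻⁴. Identical command + seed reruns are
byte-identical, and every result file carries the seed, generator identity
and configuration needed to replay it.

The library API mirrors the CLI: `simulate_genotypes` /
`simulate_phenotype` → `adjust_phenotype` → `run_maxt` / `run_adaptive`,
with the kernel (`dot_products`, `dot_products_fixed`, `block_plan`)
exposed in `permforge.engine`.

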