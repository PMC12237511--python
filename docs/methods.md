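# Methods

## Model and procedure

`permforge` tests each biallelic SNP for association with a continuous
phenotype under the additive genotypic model. The phenotype is adjusted
once, before any permutation: with covariates, `y = b − C(CᵀC)⁻¹Cᵀb`
where `C` is the n×(c+1) design with a leading intercept column (solved by
least squares, not an explicit inverse); without covariates, `y = b − b̄`.
The residual `y` has mean zero, so its sum of squares `ss_y = yᵀy` is a
permutation invariant. Adjusting once is a deliberate modelling choice:
re-fitting covariates inside every permutation would couple covariates to
each permuted phenotype and multiply the cost by the covariate fit; the
one-shot adjustment is exact when genotypes and covariates are
independent and is the convention for streaming permutation engines.

Per SNP, the centred allele counts `x = a − ā` give the Pearson
correlation `ρ = xᵀy / √(ss_x · ss_y)` and the simple-regression statistic
`F = ρ²/(1 − ρ²)·(n_eff − 2)`, identical to the squared slope
t-statistic. Permuting `y` changes only the numerator `xᵀy`, so the whole
permutation inner loop is one matrix–vector product per permutation.

### Missing data

Missing genotypes are mean-imputed in the kernel: after centring, a
missing entry contributes exactly 0 to `xᵀy`. The denominator pieces use
the non-missing entries only — `ā` and `ss_x` over observed genotypes,
`n_eff` = the per-SNP non-missing count (the PLINK convention; the
alternative, total n, is indistinguishable without missingness). `ss_y`
is computed over all samples. This is the one missingness policy
compatible with a constant-denominator streaming design; a
pairwise-complete recomputation of `ss_y` per permutation would make the
denominator permutation-dependent. The two coincide exactly at zero
missingness, and the kernel's dot products equal the textbook
`Σ(xᵢ−x̄)(yᵢ−ȳ)` there (tested).

Degenerate SNPs — all-missing, monomorphic (`ss_x = 0`), or fewer than 3
observed genotypes — are excluded from testing: they are reported with
p = 1 and a flag, and never contribute to maxT maxima (a monomorphic SNP
can never be significant, and letting its F = 0 into the maxima would
only dilute the null).

### p-values and tie handling

All permutation p-values use `p = (x + 1)/(b + 1)` with inclusive
exceedance (`F_perm ≥ F_obs`), the conservative convention under which
the estimator is valid. Exceedance is evaluated through a relative
tolerance band of 1e−12: a permuted statistic that ties the observed one
in exact arithmetic can land a few ulps away in floating point (genotype
means like 4/7 are not binary fractions), and the band restores the
exact-arithmetic count. Genuinely distinct statistics on non-degenerate
data are separated by many orders of magnitude more; the exhaustive-
enumeration test verifies equality with a `fractions.Fraction` oracle.

Collinear genotype/phenotype pairs (`ρ² = 1` to within 1e−15) map to an
`F = +inf` sentinel that outranks every finite statistic. `|ρ|` may
exceed 1 by at most 1e−9 (rounding) before the library treats it as an
upstream bug; the fixed-point path widens this clip band to 1e−2 to
absorb quantization error in the numerator.

### maxT

For each of `n_perm` permutations the per-SNP F is recomputed and the
maximum over non-degenerate SNPs recorded; `EMP2_j` ranks `F_j` within
those maxima, `EMP1_j` within SNP j's own permuted statistics, so
`EMP2 ≥ EMP1` always. Around 1000 permutations give stable family-wise
p-values at the 0.05 level independent of SNP count (the default
`--mperm 1000`).

### Adaptive permutation

One shared permutation stream serves all SNPs. Exceedance counts update
every permutation, but dropping is evaluated at **checkpoints**: the
interval starts at the M-P-S parameter (default 121, a standard tested
setting; 36 is the common smaller choice) and multiplies by `growth`
(default 1.2) after every `drops_per_growth` (default 5) checkpoints,
with rounded-up cumulative positions capped so the final checkpoint is
exactly `b_max`. At a checkpoint, an active SNP with `x ≥ R` is dropped
with `B` = the checkpoint's permutation count and `p = (min(x,R)+1)/(B+1)`;
survivors report `(x+1)/(b_max+1)`. Checkpoint-resolution stopping
mirrors engines that rebuild per-SNP buffers periodically; the
literal sequential rule (stop at the exact permutation reaching `R`) is
available as `strict=True` and tested against a replay oracle. The
default exceedance limit `R = 10` follows the sequential permutation
literature; it is configurable and recorded in output metadata. With `R`
unreachable the adaptive p-values equal the pointwise full-permutation
p-values from the same stream exactly (tested bitwise).

This implementation evaluates the permuted statistic for all SNPs each
permutation and masks to the active set; physically shrinking the data
buffers is a throughput optimisation with no statistical content, and
results are independent of any block partition by construction.

## Reproducibility

The k-th permutation is produced by a Fisher–Yates shuffle driven by
PCG64 seeded from `SeedSequence(seed, spawn_key=(k,))` — random access to
any permutation without replaying the stream, identical across platforms.
The generator identity string (`pcg64-fisher-yates-v1`) is written into
result metadata. The synthetic-data generator routes every draw through
named SeedSequence children (maf/genotype/missing/covariate/noise), so a
`SimSpec` is a complete, portable description of a dataset. A `--threads`
option is accepted for interface compatibility but the computation is
single-process NumPy; results can never depend on it.

## Fixed-point kernel emulation

The optional integer kernel quantizes the phenotype and the per-SNP means
to `frac_bits` fractional bits (round-to-nearest-even, saturating with a
surfaced count) and accumulates exact 64-bit integer products,
dequantizing once by `2^(2·frac_bits)`. Allele counts are exact in the
format, so the only rounding is in `y` and `ā`; the numerator error is
bounded by `n · 2^(−frac_bits) · max(2, max|y|)` (asserted in tests). The
default format — 32 total bits, 16 fractional, 64-bit accumulator —
keeps the no-overflow guarantee `acc ≥ total + ⌈log₂ n⌉ + 2` up to
n = 262 144 samples. Kernel fidelity is measured as vector-relative error
(max absolute error over the largest numerator magnitude): element-wise
ratios are meaningless for the near-zero dot products of null SNPs, while
the quantities that decide p-values — comparisons among large statistics
— are captured by the vector norm and by the top-rank agreement check.
Fixed-point mode is off by default; floating point is the reference path,
and the emulation exists to make the cost of approximate numerators
measurable rather than assumed.

## Data blocking

SNP records are 2-bit packed and padded to 64-byte (512-bit = 256
genotypes) boundaries; a block plan holds
`floor(buffer_bytes / record_bytes)` records per block (default buffer
2²⁶ bytes). Each SNP's dot product is accumulated as an independent
one-row reduction, never a shape-dependent matrix product, so numerators
are bitwise identical across block plans (tested across four plans).

## Synthetic data

The generator emulates a simulated GWAS cohort: per-SNP MAFs uniform on a
configurable range (default 0.05–0.5), independent Binomial(2, MAF)
genotypes (Hardy–Weinberg), independent per-entry missingness, and a
phenotype of planted additive effects on mean-imputed dosages plus
standard-normal covariates and Gaussian noise (default SD 1). SNPs are
independent by default; a window-AR(1) Gaussian-copula mode adds local
LD (two independent haplotypes preserve HWE margins) because maxT's
advantage over Bonferroni appears only under dependence. What the
generator does **not** emulate: realistic LD structure beyond one window
shape, allele-frequency spectra, population stratification or
relatedness, genotyping-error patterns, or case-control ascertainment —
so passing calibration here demonstrates correctness of the permutation
machinery under the stated model, not robustness to confounding in real
cohorts.

## Problem sizes used in validation

The test and acceptance workloads are chosen to exercise every code path
at desk scale: exhaustive enumeration at n = 7/m = 4 (5040 permutations),
the F ≡ t² identity at n = 50 over 100 draws, family-wise error
calibration over 400 null cohorts of 50 SNPs × 100 samples at 200
permutations (the 95% binomial band for 400 replicates at α = 0.05 is
[0.028, 0.072]), adaptive consistency at 60 × 80 with a 300-permutation
budget, kernel fidelity on a 500 × 200 block, and planted-effect recovery
at 1000 × 500 with per-SNP R² ≈ 0.2. These sizes give tight oracles and
stable stochastic bands while keeping the full validation run in seconds.

## Known limitations

- Continuous phenotypes only; no logistic/case-control mode and no linear
  mixed models (kinship) — both are natural extensions.
- Covariates are residualized once, not per permutation (see above).
- Sample-major PLINK .bed files are rejected, not converted; no VCF/BGEN
  or dosage input.
- The adaptive driver's checkpoint semantics make `B` (and hence dropped
  SNPs' p-values) depend on the M-P-S schedule; `strict=True` removes
  that dependence at the cost of the literal per-permutation rule.
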