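"""Synthetic genotype/phenotype fixtures with known ground truth.

Generates desk-scale cohorts that structurally mimic a simulated GWAS
dataset: biallelic SNPs drawn independently under Hardy–Weinberg
equilibrium with per-SNP minor allele frequencies, optional genotype
missingness, and a continuous phenotype assembled from planted additive
SNP effects, covariate effects, and Gaussian noise.

SNPs are independent (no linkage disequilibrium) by default, which keeps
every test deterministic and every planted effect's ground-truth variance
contribution well-defined.  An optional window-correlated mode exists
because the family-wise advantage of maxT over Bonferroni only appears
under dependence.

All randomness flows from a single integer seed through named
``SeedSequence`` children, so a :class:`SimSpec` reproduces bit-identical
data on any platform.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import plink_io
from .plink_io import MISSING, GenotypeMatrix


@dataclass(frozen=True)
class SimSpec:
    """Recipe for one synthetic cohort.

    Attributes
    ----------
    m, n
        SNP and sample counts.
    maf_range
        Per-SNP minor allele frequencies are drawn uniformly from this
        interval within (0, 0.5].
    missing_rate
        Independent per-entry genotype missingness probability.
    causal_idx, betas
        SNP indices carrying planted additive effects, in phenotype units
        per allele copy.  Effects are added on mean-imputed dosages so the
        planted variance explained is well-defined under missingness.
    n_covariates, covariate_betas
        Standard-normal covariates and their effects on the phenotype.
    noise_sd
        Residual Gaussian noise standard deviation.
    ld_rho, ld_window
        Optional within-window genotype correlation (0 disables; see
        module docstring).
    """

    m: int
    n: int
    maf_range: tuple[float, float] = (0.05, 0.5)
    missing_rate: float = 0.0
    causal_idx: tuple[int, ...] = ()
    betas: tuple[float, ...] = ()
    n_covariates: int = 0
    covariate_betas: tuple[float, ...] = ()
    noise_sd: float = 1.0
    seed: int = 0
    ld_rho: float = 0.0
    ld_window: int = 10

    def __post_init__(self) -> None:
        if self.m < 1 or self.n < 1:
            raise ValueError("need m >= 1 SNPs and n >= 1 samples")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if any(not 0 <= j < self.m for j in self.causal_idx):
            raise ValueError("causal_idx outside [0, m)")
        if len(self.betas) != len(self.causal_idx):
            raise ValueError("betas and causal_idx lengths differ")
        if self.n_covariates and len(self.covariate_betas) != self.n_covariates:
            raise ValueError("covariate_betas length must equal n_covariates")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not 0 <= self.ld_rho < 1:
            raise ValueError("ld_rho must be in [0, 1)")


# stable stream labels, part of the reproducibility contract
_STREAMS = {"maf": 1, "genotype": 2, "missing": 3, "covariate": 4, "noise": 5}


def _stream_rng(spec: SimSpec, stream: str) -> np.random.Generator:
    ss = np.random.SeedSequence(spec.seed, spawn_key=(_STREAMS[stream],))
    return np.random.Generator(np.random.PCG64(ss))


def draw_mafs(spec: SimSpec) -> np.ndarray:
    """Per-SNP minor allele frequencies, uniform over ``maf_range``."""
    rng = _stream_rng(spec, "maf")
    lo, hi = spec.maf_range
    return rng.uniform(lo, hi, size=spec.m)


def simulate_genotypes(spec: SimSpec) -> tuple[GenotypeMatrix, np.ndarray]:
    """Draw genotypes under Hardy–Weinberg equilibrium.

    Each SNP j draws ``MAF_j`` uniformly from ``maf_range``; genotypes are
    independent Binomial(2, MAF_j) allele counts (so the A1 allele is the
    minor allele), masked missing at ``missing_rate``.

    Returns ``(G, mafs)``; the generator keeps its in-memory matrix as the
    ground truth that file round-trips are checked against.
    """
    mafs = draw_mafs(spec)
    rng = _stream_rng(spec, "genotype")
    if spec.ld_rho == 0.0:
        u = rng.random((2, spec.m, spec.n))
        codes = (u[0] < mafs[:, None]).astype(np.int8) + \
                (u[1] < mafs[:, None]).astype(np.int8)
    else:
        codes = _correlated_genotypes(spec, mafs, rng)
    if spec.missing_rate > 0:
        miss = _stream_rng(spec, "missing").random((spec.m, spec.n)) < spec.missing_rate
        codes[miss] = MISSING
    G = GenotypeMatrix(codes,
                       snp_ids=np.array([f"rs{j + 1}" for j in range(spec.m)]),
                       sample_ids=np.array([f"id{i + 1}" for i in range(spec.n)]))
    return G, mafs


def _correlated_genotypes(spec: SimSpec, mafs: np.ndarray,
                          rng: np.random.Generator) -> np.ndarray:
    """Window-wise AR(1) Gaussian copula, thresholded to HWE margins."""
    from scipy.stats import norm

    codes = np.empty((spec.m, spec.n), dtype=np.int8)
    for start in range(0, spec.m, spec.ld_window):
        stop = min(start + spec.ld_window, spec.m)
        w = stop - start
        for hap in range(2):  # two independent haplotypes keep HWE margins
            z = np.empty((w, spec.n))
            z[0] = rng.standard_normal(spec.n)
            for j in range(1, w):
                z[j] = spec.ld_rho * z[j - 1] + \
                    math.sqrt(1 - spec.ld_rho ** 2) * rng.standard_normal(spec.n)
            thresh = norm.ppf(mafs[start:stop])[:, None]
            alleles = (z < thresh).astype(np.int8)
            if hap == 0:
                codes[start:stop] = alleles
            else:
                codes[start:stop] += alleles
    return codes


def mean_imputed_dosage(codes_row: np.ndarray) -> np.ndarray:
    """Dosage vector with missing entries replaced by the row mean."""
    obs = codes_row != MISSING
    if not obs.any():
        return np.zeros(len(codes_row))
    d = codes_row.astype(np.float64)
    d[~obs] = d[obs].mean()
    return d


def simulate_phenotype(G: GenotypeMatrix,
                       spec: SimSpec) -> tuple[np.ndarray, np.ndarray | None]:
    """Continuous phenotype with planted effects; returns ``(b_raw, covariates)``.

    ``b_raw = sum_j beta_j * dosage_j + covariate effects + N(0, noise_sd)``
    with mean-imputed causal dosages.  Covariates (if any) are standard
    normal, n x c.
    """
    b = np.zeros(G.n_samples)
    for j, beta in zip(spec.causal_idx, spec.betas):
        b += beta * mean_imputed_dosage(G.codes[j])
    covariates = None
    if spec.n_covariates:
        covariates = _stream_rng(spec, "covariate").standard_normal(
            (G.n_samples, spec.n_covariates))
        b += covariates @ np.asarray(spec.covariate_betas)
    b += spec.noise_sd * _stream_rng(spec, "noise").standard_normal(G.n_samples)
    return b, covariates


def beta_for_r2(r2: float, maf: float, noise_sd: float = 1.0) -> float:
    """Effect size giving a planted per-SNP variance explained of ``r2``.

    Under HWE the dosage variance is ``2 * maf * (1 - maf)``; solving
    ``r2 = beta^2 v / (beta^2 v + noise_sd^2)`` for beta.
    """
    if not 0 < r2 < 1:
        raise ValueError("r2 must be in (0, 1)")
    v = 2 * maf * (1 - maf)
    return noise_sd * math.sqrt(r2 / ((1 - r2) * v))


def make_fixture(spec: SimSpec, path_prefix: str) -> dict:
    """Write a complete PLINK trio plus covariate and ground-truth files.

    Emits ``prefix.bed/.bim/.fam`` (phenotype in the .fam), and, when the
    spec includes covariates, ``prefix.covar``.  ``prefix.truth.tsv``
    records the causal indices, betas, realized MAFs and the seed as a
    commented TSV.  Returns the in-memory pieces for callers that want the
    ground truth without re-reading files.
    """
    G, mafs = simulate_genotypes(spec)
    b_raw, covariates = simulate_phenotype(G, spec)

    vt = plink_io.default_variant_table(G)
    st = plink_io.default_sample_table(G, phenotype=b_raw)
    plink_io.write_plink(G, vt, st, path_prefix)

    if covariates is not None:
        cov = pd.DataFrame(covariates,
                           columns=[f"cov{k + 1}" for k in range(covariates.shape[1])])
        cov.insert(0, "IID", G.sample_ids)
        cov.insert(0, "FID", G.sample_ids)
        cov.to_csv(path_prefix + ".covar", sep="\t", index=False,
                   float_format="%.17g")

    truth = pd.DataFrame({
        "snp": [G.snp_ids[j] for j in spec.causal_idx],
        "index": list(spec.causal_idx),
        "beta": list(spec.betas),
        "maf": [mafs[j] for j in spec.causal_idx],
    })
    with open(path_prefix + ".truth.tsv", "w") as fh:
        fh.write(f"# seed: {spec.seed}\n# m: {spec.m}\n# n: {spec.n}\n")
        fh.write(f"# noise_sd: {spec.noise_sd}\n")
        truth.to_csv(fh, sep="\t", index=False, float_format="%.17g")

    return {"genotypes": G, "mafs": mafs, "b_raw": b_raw,
            "covariates": covariates, "truth": truth}
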