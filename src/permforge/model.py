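"""Core association statistics for quantitative-trait GWAS.

Each SNP is tested for association with a continuous phenotype under the
additive genotypic model via simple linear regression.  With genotype
allele counts ``a`` (centred to ``x = a - mean(a)``) and adjusted phenotype
``y``, the test statistic is

    F = rho^2 / (1 - rho^2) * (n - 2),

where ``rho`` is the Pearson correlation of ``x`` and ``y``.  For a single
regressor F equals the squared t-statistic of the fitted slope.

Permuting ``y`` leaves the denominator of ``rho`` fixed: the genotype sum
of squares does not depend on the permutation, and the phenotype sum of
squares is permutation-invariant.  Only the numerator ``sum(x_i * y_i)``
changes, which is what makes a dot-product kernel (see
:mod:`permforge.engine`) the whole inner loop of permutation testing.

Covariates are regressed out of the phenotype once, before permutation:
``y = b - C (C'C)^{-1} C' b`` with ``C`` carrying an intercept column, so
``y`` is a zero-mean residual vector.  This single up-front adjustment is a
deliberate approximation to refitting covariates inside every permutation;
it is exact when genotypes and covariates are independent.

Missing genotypes are mean-imputed in the kernel (a missing entry
contributes exactly zero to the centred dot product), while the genotype
sum of squares and the effective sample size use the non-missing count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .plink_io import MISSING

#: Excursion of rho beyond [-1, 1] tolerated as rounding noise.
RHO_CLIP_TOL = 1e-9


@dataclass
class PhenotypeSet:
    """Raw phenotype, optional covariate design, and the adjusted residual.

    Attributes
    ----------
    b_raw
        Raw phenotype vector, length n.
    C
        Design matrix used for adjustment (intercept column first), or
        None when plain mean-centring was applied.
    y
        Zero-mean adjusted phenotype (residuals of ``b_raw`` on ``C``).
    ss_y
        Sum of squares of ``y`` (its mean is zero), strictly positive.
    """

    b_raw: np.ndarray
    C: np.ndarray | None
    y: np.ndarray
    ss_y: float

    @property
    def n(self) -> int:
        return len(self.y)


@dataclass
class SnpSummary:
    """Per-SNP moments over non-missing genotypes."""

    mean: float
    ss_x: float
    n_obs: int
    sd: float


@dataclass
class TestStatistic:
    """Pearson correlation and the derived F statistic for one SNP."""

    rho: float
    F: float
    n_eff: int
    degenerate: bool = False


def adjust_phenotype(b_raw: np.ndarray,
                     covariates: np.ndarray | None = None) -> PhenotypeSet:
    """Residualize the phenotype on an intercept and optional covariates.

    Parameters
    ----------
    b_raw
        Raw phenotype values, length n.
    covariates
        Optional ``n x c`` numeric matrix (no intercept column; one is
        prepended internally).  ``None`` or zero columns reduces to plain
        mean-centring.

    Raises
    ------
    ValueError
        Constant phenotype ("zero phenotype variance"), or a rank-deficient
        design (the message names the collinear column indices).
    """
    b = np.asarray(b_raw, dtype=np.float64)
    if b.ndim != 1 or len(b) < 3:
        raise ValueError("phenotype must be a vector of length >= 3")
    if np.ptp(b) == 0:
        raise ValueError("zero phenotype variance: phenotype is constant")

    n = len(b)
    if covariates is None or (hasattr(covariates, "shape") and
                              np.size(covariates) == 0):
        y = b - b.mean()
        C = None
    else:
        X = np.asarray(covariates, dtype=np.float64)
        if X.ndim == 1:
            X = X[:, None]
        if X.shape[0] != n:
            raise ValueError("covariate rows do not match phenotype length")
        C = np.column_stack([np.ones(n), X])
        rank = np.linalg.matrix_rank(C)
        if rank < C.shape[1]:
            bad = _collinear_columns(C)
            raise ValueError(
                f"rank-deficient covariate design: collinear columns {bad} "
                "(0 is the intercept)")
        coef, *_ = np.linalg.lstsq(C, b, rcond=None)
        y = b - C @ coef

    ss_y = float(y @ y)
    if ss_y <= 0:
        raise ValueError("zero phenotype variance after adjustment")
    return PhenotypeSet(b_raw=b, C=C, y=y, ss_y=ss_y)


def _collinear_columns(C: np.ndarray) -> list[int]:
    """Indices of columns that add no rank to their predecessors."""
    bad, rank = [], 0
    for j in range(C.shape[1]):
        r = np.linalg.matrix_rank(C[:, :j + 1])
        if r == rank:
            bad.append(j)
        rank = r
    return bad


def snp_summary(a: np.ndarray) -> SnpSummary:
    """Mean, centred sum of squares, count and SD over non-missing entries.

    All-missing SNPs raise; callers flag them degenerate instead of
    testing them.
    """
    a = np.asarray(a)
    obs = a[a != MISSING].astype(np.float64)
    if obs.size == 0:
        raise ValueError("all genotypes missing for SNP")
    mean = float(obs.mean())
    ss_x = float(((obs - mean) ** 2).sum())
    sd = math.sqrt(ss_x / obs.size)
    return SnpSummary(mean=mean, ss_x=ss_x, n_obs=int(obs.size), sd=sd)


def snp_summaries(codes: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized per-row summaries for a genotype matrix.

    Returns
    -------
    (mean, ss_x, n_obs)
        Arrays of length m.  Rows with no observed genotypes get
        ``mean = 0, ss_x = 0, n_obs = 0``; callers must treat them as
        degenerate.
    """
    miss = codes == MISSING
    vals = codes.astype(np.float64)
    vals[miss] = 0.0
    n_obs = (~miss).sum(axis=1)
    safe = np.maximum(n_obs, 1)
    mean = vals.sum(axis=1) / safe
    ss_x = (vals ** 2).sum(axis=1) - safe * mean ** 2
    ss_x = np.maximum(ss_x, 0.0)  # guard tiny negative rounding
    mean[n_obs == 0] = 0.0
    return mean, ss_x, n_obs


def f_from_numerator(num: float, ss_x: float, ss_y: float,
                     n_eff: int) -> TestStatistic:
    """Build the F statistic from the centred dot product and fixed sums.

    ``rho = num / sqrt(ss_x * ss_y)``; values outside [-1, 1] by at most
    :data:`RHO_CLIP_TOL` are clipped (rounding), larger excursions raise.
    ``rho^2 = 1`` maps to ``F = +inf`` (compares greater than any finite F);
    a monomorphic SNP (``ss_x = 0``) is flagged degenerate with ``F = 0``.
    """
    if ss_y <= 0:
        raise ValueError("ss_y must be positive")
    if n_eff < 3:
        raise ValueError("need n_eff >= 3")
    if ss_x == 0:
        return TestStatistic(rho=0.0, F=0.0, n_eff=n_eff, degenerate=True)
    rho = num / math.sqrt(ss_x * ss_y)
    if abs(rho) > 1.0 + RHO_CLIP_TOL:
        raise ValueError(f"correlation {rho} outside [-1, 1] beyond rounding tolerance")
    rho = min(1.0, max(-1.0, rho))
    # collinear data lands within a few ulps of |rho| = 1; snap to the sentinel
    if 1.0 - rho * rho < 1e-15:
        return TestStatistic(rho=rho, F=math.inf, n_eff=n_eff)
    F = rho * rho / (1.0 - rho * rho) * (n_eff - 2)
    return TestStatistic(rho=rho, F=F, n_eff=n_eff)


def f_from_numerators(num: np.ndarray, ss_x: np.ndarray, ss_y: float,
                      n_obs: np.ndarray,
                      clip_tol: float = RHO_CLIP_TOL) -> np.ndarray:
    """Vectorized F over SNPs; degenerate rows (ss_x == 0) get F = 0.

    Used in the permutation inner loop where the denominators are constant
    across permutations.  ``clip_tol`` widens the |rho| <= 1 clipping band;
    the fixed-point kernel needs a looser band because its numerator
    carries quantization error.
    """
    if ss_y <= 0:
        raise ValueError("ss_y must be positive")
    ok = ss_x > 0
    denom = np.sqrt(np.where(ok, ss_x, 1.0) * ss_y)
    rho = np.where(ok, num / denom, 0.0)
    excess = np.abs(rho) - 1.0
    if np.any(excess > clip_tol):
        raise ValueError("correlation outside [-1, 1] beyond rounding tolerance")
    rho = np.clip(rho, -1.0, 1.0)
    rho2 = rho * rho
    with np.errstate(divide="ignore"):
        F = np.where(1.0 - rho2 < 1e-15, np.inf,
                     rho2 / np.maximum(1.0 - rho2, np.finfo(float).tiny)
                     * (n_obs - 2))
    F[~ok] = 0.0
    return F


def perm_pvalue(x: int, n_perm: int) -> float:
    """Permutation p-value ``(x + 1) / (n_perm + 1)``.

    ``x`` is the number of permuted statistics that tie or exceed the
    observed one.  The +1 terms count the observed statistic itself among
    the permutations, keeping the estimate valid (never zero).
    """
    if n_perm < 1:
        raise ValueError("need n_perm >= 1")
    if not 0 <= x <= n_perm:
        raise ValueError("exceedance count x must be in [0, n_perm]")
    return (x + 1) / (n_perm + 1)


def adaptive_pvalue(x: int, R: int, B: int, b_max: int) -> float:
    """Early-stopping permutation p-value.

    A SNP either survives all ``b_max`` permutations with ``x < R``
    exceedances (p = (x+1)/(b_max+1)) or is stopped after ``B``
    permutations once ``x`` reaches the limit ``R`` (p = (x+1)/(B+1)).
    """
    if x > R:
        raise ValueError("exceedance count x cannot exceed the limit R")
    if B > b_max:
        raise ValueError("permutations performed cannot exceed b_max")
    if x < R:
        if B != b_max:
            raise ValueError("a SNP with x < R must have run all b_max permutations")
        return (x + 1) / (b_max + 1)
    return (x + 1) / (B + 1)


def min_permutations(alpha: float) -> int:
    """Smallest permutation count whose p-value resolution reaches ``alpha``.

    The minimum attainable permuted p-value after b permutations is
    ``1 / (b + 1)``; this returns the smallest b with ``1/(b+1) <= alpha``.
    At the genome-wide threshold 5e-8 that is 19 999 999 permutations per
    SNP — the resolution wall that motivates maxT and adaptive testing.
    """
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    k = math.ceil(1.0 / alpha)  # candidate b + 1
    while k > 1 and 1.0 / (k - 1) <= alpha:
        k -= 1
    return k - 1
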