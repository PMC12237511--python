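"""The two permutation-testing drivers: maxT and adaptive early stopping.

maxT
----
The maxT procedure strongly controls the family-wise error rate.  For each
of ``n_perm`` phenotype permutations the F statistic is recomputed for
every SNP and the maximum over SNPs is recorded; the adjusted p-value of
SNP j (EMP2) is the rank of its observed F within that null distribution
of maxima, ``(#{max_t >= F_j} + 1) / (n_perm + 1)``.  The pointwise
p-value (EMP1) ranks F_j within its own permuted statistics.  Because one
family of maxima serves all SNPs, about a thousand permutations suffice at
the 0.05 level regardless of how many SNPs are tested.

Adaptive permutation
--------------------
For per-SNP p-values at genome-wide resolution the permutation count is
enormous (about 2e7 per SNP at 5e-8), but most SNPs reveal themselves as
unremarkable almost immediately.  The adaptive procedure counts, per SNP,
the permuted statistics that tie or exceed the observed one; once that
exceedance count reaches a limit R the SNP's p-value is already
well-estimated and the SNP is dropped from further permutation.  Dropping
is evaluated at checkpoints rather than per permutation, mirroring an
implementation whose per-SNP data buffers are rebuilt only periodically:
the checkpoint interval starts at the minimum-permutations-per-SNP
parameter (M-P-S) and grows by 20% every 5 checkpoints, so the sweeps
become sparser as the surviving set shrinks.  An optional strict mode
instead stops a SNP at the exact permutation where its count reaches R.

Both drivers share the engine's reproducible permutation stream and report
p-values via the ``(x + 1) / (b + 1)`` estimator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np

from . import engine, model
from .plink_io import GenotypeMatrix

#: Relative tolerance of the exceedance comparison.  A permuted statistic
#: that ties the observed one in exact arithmetic can land a few ulps away
#: in floating point (genotype means are rarely exact binary fractions);
#: counting "ties or exceeds" through a small relative band keeps the
#: exceedance count equal to the exact-arithmetic one, since genuinely
#: distinct statistics on non-degenerate data differ by far more.
EXCEED_REL_TOL = 1e-12


def _exceed_threshold(f_obs: np.ndarray) -> np.ndarray:
    """Per-SNP threshold: a permuted F at or above it counts as exceedance."""
    finite = np.isfinite(f_obs)
    slack = EXCEED_REL_TOL * np.maximum(np.abs(f_obs, where=finite,
                                               out=np.ones_like(f_obs)), 1.0)
    return np.where(finite, f_obs - slack, np.inf)


@dataclass
class MaxTResult:
    """Output of :func:`run_maxt`.

    ``emp2`` is the family-wise adjusted p-value, ``emp1`` the pointwise
    one; ``emp2 >= emp1`` always.  Degenerate SNPs (all-missing or
    monomorphic) carry ``p = 1`` and never contribute to the null maxima.
    """

    snp_ids: np.ndarray
    f_obs: np.ndarray
    null_maxima: np.ndarray
    emp1: np.ndarray
    emp2: np.ndarray
    degenerate: np.ndarray
    plan: engine.PermutationPlan | None
    n_perm: int
    fixed_point: engine.FixedPointFormat | None = None
    n_saturated: int = 0


@dataclass(frozen=True)
class AdaptiveConfig:
    """Parameters of the adaptive driver.

    Attributes
    ----------
    R
        Exceedance limit; a SNP is dropped once R permuted statistics tie
        or exceed its observed one.  Default 10, the usual choice in the
        sequential permutation literature.
    b_max
        Permutation budget per SNP.
    mps
        Minimum permutations per SNP; also the initial checkpoint interval.
        Default 121.
    growth, drops_per_growth
        The checkpoint interval is multiplied by ``growth`` after every
        ``drops_per_growth`` checkpoints (default: +20% every 5).
    """

    b_max: int
    R: int = 10
    mps: int = 121
    growth: float = 1.2
    drops_per_growth: int = 5

    def __post_init__(self) -> None:
        if self.R < 1:
            raise ValueError("exceedance limit R must be >= 1")
        if self.b_max < 1:
            raise ValueError("b_max must be >= 1")
        if self.mps < 1:
            raise ValueError("mps must be >= 1")
        if self.mps > self.b_max:
            raise ValueError("minimum permutations per SNP cannot exceed b_max")
        if self.growth <= 1:
            raise ValueError("interval growth factor must exceed 1")
        if self.drops_per_growth < 1:
            raise ValueError("drops_per_growth must be >= 1")


@dataclass
class AdaptiveResult:
    """Output of :func:`run_adaptive`.

    ``x`` is capped at ``cfg.R`` for dropped SNPs; ``B`` is b_max for
    survivors and the dropping checkpoint's permutation count otherwise.
    ``dropped_at`` is the 0-based checkpoint index, or -1.
    """

    snp_ids: np.ndarray
    f_obs: np.ndarray
    x: np.ndarray
    B: np.ndarray
    pvalue: np.ndarray
    dropped: np.ndarray
    dropped_at: np.ndarray
    degenerate: np.ndarray
    checkpoints: list[int]
    cfg: AdaptiveConfig
    plan: engine.PermutationPlan | None
    fixed_point: engine.FixedPointFormat | None = None
    n_saturated: int = 0


def dropping_schedule(cfg: AdaptiveConfig) -> list[int]:
    """Checkpoint permutation counts for the adaptive driver.

    The interval starts at ``mps`` and is tracked as a real number; after
    every ``drops_per_growth`` checkpoints it grows by ``growth``.
    Checkpoints are the rounded-up cumulative sums, strictly increasing and
    capped so the final checkpoint is exactly ``b_max``.

    >>> dropping_schedule(AdaptiveConfig(b_max=10**6, mps=121))[:6]
    [121, 242, 363, 484, 605, 751]
    """
    points: list[int] = []
    pos = 0.0
    interval = float(cfg.mps)
    while True:
        pos += interval
        cp = math.ceil(pos)
        if points:
            cp = max(cp, points[-1] + 1)
        if cp >= cfg.b_max:
            points.append(cfg.b_max)
            return points
        points.append(cp)
        if len(points) % cfg.drops_per_growth == 0:
            interval *= cfg.growth


def _prepare(G: GenotypeMatrix, pheno: model.PhenotypeSet,
             fixed_point: engine.FixedPointFormat | None):
    """Shared observed-statistic setup for both drivers.

    Returns centred data (or quantized data in fixed-point mode), per-SNP
    denominators, observed F, and the degenerate mask.
    """
    if G.n_samples != pheno.n:
        raise ValueError("genotype sample count does not match phenotype length")
    means, ss_x, n_obs = model.snp_summaries(G.codes)
    degenerate = (n_obs == 0) | (ss_x == 0.0) | (n_obs < 3)

    n_sat = 0
    if fixed_point is None:
        Xc = engine.centered_matrix(G.codes, means)
        clip_tol = model.RHO_CLIP_TOL

        def raw_numerators(y_vec: np.ndarray) -> np.ndarray:
            return Xc @ y_vec
    else:
        codes, fmt = G.codes, fixed_point
        # quantization error in the numerator can nudge |rho| past 1
        clip_tol = 1e-2

        def raw_numerators(y_vec: np.ndarray) -> np.ndarray:
            y_q, _ = engine.quantize_with_stats(y_vec, fmt)
            return engine.dot_products_fixed(codes, means, y_q, fmt)

        _, n_sat = engine.quantize_with_stats(pheno.y, fixed_point)

    def f_for(y_vec: np.ndarray) -> np.ndarray:
        return model.f_from_numerators(raw_numerators(y_vec), ss_x,
                                       pheno.ss_y, np.maximum(n_obs, 3),
                                       clip_tol=clip_tol)

    f_obs = f_for(pheno.y)
    f_obs[degenerate] = 0.0
    return f_for, ss_x, n_obs, f_obs, degenerate, n_sat


def run_maxt(G: GenotypeMatrix, pheno: model.PhenotypeSet, n_perm: int,
             seed: int = 0,
             fixed_point: engine.FixedPointFormat | None = None,
             permutations: Iterable[np.ndarray] | None = None) -> MaxTResult:
    """maxT permutation testing over all SNPs.

    Parameters
    ----------
    G, pheno
        Genotypes and the covariate-adjusted phenotype.
    n_perm
        Number of permutations (around 1000 is the conventional choice at
        the 0.05 family-wise level).
    seed
        Seed of the reproducible permutation stream.
    fixed_point
        Optional fixed-point format; when given, all numerators (observed
        and permuted) go through the integer kernel.
    permutations
        Explicit index permutations replacing the seeded stream — used for
        exhaustive enumeration at tiny n, where the permutation null can be
        computed exactly.
    """
    if n_perm < 1 and permutations is None:
        raise ValueError("need n_perm >= 1")
    f_for, ss_x, n_obs, f_obs, degenerate, n_sat = _prepare(G, pheno, fixed_point)
    if not np.any(~degenerate):
        raise ValueError("no testable SNPs: all rows are degenerate")

    if permutations is None:
        plan = engine.PermutationPlan(seed=seed, n_perm=n_perm, n=pheno.n)
        perm_iter: Iterable[np.ndarray] = engine.permutation_stream(plan)
    else:
        plan = None
        perm_iter = permutations

    y = pheno.y
    valid = ~degenerate
    thresh = _exceed_threshold(f_obs)
    exceed1 = np.zeros(G.n_snps, dtype=np.int64)
    maxima = []
    count = 0
    for perm in perm_iter:
        f_perm = f_for(y[perm])
        exceed1 += f_perm >= thresh
        maxima.append(f_perm[valid].max())
        count += 1
    if count == 0:
        raise ValueError("empty permutation sequence")
    null_maxima = np.array(maxima)

    emp1 = (exceed1 + 1) / (count + 1)
    exceed2 = (null_maxima[None, :] >= thresh[:, None]).sum(axis=1)
    emp2 = (exceed2 + 1) / (count + 1)
    emp1[degenerate] = 1.0
    emp2[degenerate] = 1.0
    return MaxTResult(snp_ids=G.snp_ids, f_obs=f_obs, null_maxima=null_maxima,
                      emp1=emp1, emp2=emp2, degenerate=degenerate, plan=plan,
                      n_perm=count, fixed_point=fixed_point, n_saturated=n_sat)


def run_adaptive(G: GenotypeMatrix, pheno: model.PhenotypeSet,
                 cfg: AdaptiveConfig, seed: int = 0,
                 fixed_point: engine.FixedPointFormat | None = None,
                 strict: bool = False) -> AdaptiveResult:
    """Adaptive permutation testing with checkpointed SNP dropping.

    All SNPs start active and share one permutation stream.  Each SNP's
    exceedance count ``x`` is updated every permutation; at each checkpoint
    of :func:`dropping_schedule`, active SNPs with ``x >= cfg.R`` are
    dropped with ``B`` equal to the checkpoint's permutation count.
    Survivors after ``cfg.b_max`` permutations report
    ``p = (x + 1) / (b_max + 1)``.

    With ``strict=True`` a SNP instead stops at the exact permutation where
    its count reaches R (``B`` = that permutation's index), the literal
    sequential-stopping rule.

    Degenerate SNPs never enter the procedure: ``p = 1``, ``B = 0``.
    """
    f_for, ss_x, n_obs, f_obs, degenerate, n_sat = _prepare(G, pheno, fixed_point)
    m = G.n_snps
    plan = engine.PermutationPlan(seed=seed, n_perm=cfg.b_max, n=pheno.n)
    checkpoints = dropping_schedule(cfg)

    thresh = _exceed_threshold(f_obs)
    x = np.zeros(m, dtype=np.int64)
    B = np.full(m, cfg.b_max, dtype=np.int64)
    dropped = np.zeros(m, dtype=bool)
    dropped_at = np.full(m, -1, dtype=np.int64)
    active = ~degenerate

    y = pheno.y
    prev = 0
    for ci, cp in enumerate(checkpoints):
        idx = np.flatnonzero(active)
        if idx.size == 0:
            break
        seg = cp - prev
        # permuted F for active SNPs over this segment, one column per permutation
        exceed = np.zeros((idx.size, seg), dtype=bool)
        for t in range(seg):
            perm = engine.kth_permutation(plan, prev + t)
            f_perm = f_for(y[perm])
            exceed[:, t] = f_perm[idx] >= thresh[idx]
        if strict:
            cum = x[idx, None] + np.cumsum(exceed, axis=1)
            hit = cum >= cfg.R
            hits_now = hit[:, -1]
            first = np.argmax(hit, axis=1)  # first column where the limit is reached
            stop_rows = idx[hits_now]
            B[stop_rows] = prev + first[hits_now] + 1
            x[stop_rows] = cfg.R
            dropped[stop_rows] = True
            dropped_at[stop_rows] = ci
            active[stop_rows] = False
            keep = idx[~hits_now]
            x[keep] += exceed[~hits_now].sum(axis=1)
        else:
            x[idx] += exceed.sum(axis=1)
            over = idx[x[idx] >= cfg.R]
            B[over] = cp
            x[over] = np.minimum(x[over], cfg.R)
            dropped[over] = True
            dropped_at[over] = ci
            active[over] = False
        prev = cp

    pvalue = np.ones(m)
    testable = ~degenerate
    for j in np.flatnonzero(testable):
        if dropped[j]:
            pvalue[j] = model.adaptive_pvalue(int(min(x[j], cfg.R)), cfg.R,
                                             int(B[j]), cfg.b_max)
        else:
            pvalue[j] = model.perm_pvalue(int(x[j]), cfg.b_max)
    B[degenerate] = 0
    return AdaptiveResult(snp_ids=G.snp_ids, f_obs=f_obs, x=x, B=B,
                          pvalue=pvalue, dropped=dropped,
                          dropped_at=dropped_at, degenerate=degenerate,
                          checkpoints=checkpoints, cfg=cfg, plan=plan,
                          fixed_point=fixed_point, n_saturated=n_sat)
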