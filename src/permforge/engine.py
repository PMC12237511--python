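"""Permutation streams, data blocking, and the dot-product kernels.

This module is the software stand-in for a streaming matrix–vector
hardware accelerator.  The permutation inner loop of quantitative-trait
permutation testing reduces to one matrix–vector product per permutation:
the m x n centred genotype matrix against the permuted adjusted phenotype.
Everything here is organised around making that product reproducible,
block-partitionable, and optionally computable in emulated fixed-point
integer arithmetic.

Reproducibility contract
------------------------
Permutations are defined by ``(seed, n, k)`` alone: the k-th permutation is
generated by a PCG64 generator seeded from ``SeedSequence(seed,
spawn_key=(k,))`` and a Fisher–Yates shuffle.  Random access to the k-th
permutation therefore costs O(n), which lets an oracle replay any single
permutation without iterating the stream.  The generator identity string
:data:`RNG_ID` is recorded in result metadata.

Blocking
--------
SNP records are processed in blocks sized to a byte buffer, mirroring how
a streaming accelerator partitions its input: each 2-bit-packed SNP record
is padded to a 64-byte (512-bit, 256-genotype) boundary and the buffer
holds ``floor(buffer_bytes / record_bytes)`` records.  Partitioning must
never change results — each SNP's dot product is computed independently,
so numerators are bitwise identical across block plans.

Fixed-point emulation
---------------------
The optional fixed-point path quantizes the phenotype and the per-SNP
genotype means to ``frac_bits`` fractional bits and accumulates exact
integer products in a wide accumulator, dequantizing once at the end.
Genotype codes are small integers, so their scaled representation is
exact; the only rounding is in the phenotype and the means, giving a per-
entry error of at most ``2^-frac_bits`` and a numerator error that grows
linearly in n.  Permutation p-values depend only on comparisons between
statistics, so modest numerator error rarely disturbs them — the emulation
makes that approximation explicit and measurable.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterator

import numpy as np

from .plink_io import MISSING

#: Identity of the permutation generator, recorded in output metadata.
RNG_ID = "pcg64-fisher-yates-v1"

#: 512-bit alignment of one SNP record, in bytes.
SNP_RECORD_ALIGN = 64


@dataclass(frozen=True)
class PermutationPlan:
    """A reproducible stream of ``n_perm`` permutations of ``0..n-1``."""

    seed: int
    n_perm: int
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("need at least 2 samples to permute")
        if self.n_perm < 0:
            raise ValueError("n_perm must be non-negative")


def kth_permutation(plan: PermutationPlan, k: int) -> np.ndarray:
    """The k-th permutation of the plan's stream (0-based), random access."""
    if not 0 <= k < max(plan.n_perm, 1):
        raise IndexError(f"permutation index {k} outside stream of {plan.n_perm}")
    ss = np.random.SeedSequence(plan.seed, spawn_key=(k,))
    rng = np.random.Generator(np.random.PCG64(ss))
    return rng.permutation(plan.n)


def permutation_stream(plan: PermutationPlan) -> Iterator[np.ndarray]:
    """Yield the plan's ``n_perm`` index permutations in order."""
    for k in range(plan.n_perm):
        yield kth_permutation(plan, k)


def snp_record_bytes(n_samples: int) -> int:
    """Bytes of one 2-bit-packed SNP record, padded to a 512-bit boundary."""
    raw = -(-n_samples // 4)
    return -(-raw // SNP_RECORD_ALIGN) * SNP_RECORD_ALIGN


@dataclass(frozen=True)
class BlockPlan:
    """Partition of m SNP records into buffer-sized blocks."""

    n_snps: int
    n_snps_per_block: int
    n_blocks: int
    snp_block_bytes: int
    buffer_bytes: int

    def slices(self) -> list[slice]:
        """Row slices of the genotype matrix, one per block (last may be partial)."""
        return [slice(b * self.n_snps_per_block,
                      min((b + 1) * self.n_snps_per_block, self.n_snps))
                for b in range(self.n_blocks)]


def block_plan(n_snps: int, n_samples: int, buffer_bytes: int) -> BlockPlan:
    """Compute the block partition for a buffer of ``buffer_bytes``.

    ``n_snps_per_block = floor(buffer_bytes / record_bytes)`` and
    ``n_blocks = ceil(n_snps / n_snps_per_block)``.
    """
    rec = snp_record_bytes(n_samples)
    per_block = buffer_bytes // rec
    if per_block < 1:
        raise ValueError(
            f"buffer of {buffer_bytes} bytes cannot hold one {rec}-byte SNP record")
    n_blocks = -(-n_snps // per_block)
    return BlockPlan(n_snps=n_snps, n_snps_per_block=per_block,
                     n_blocks=n_blocks, snp_block_bytes=rec,
                     buffer_bytes=buffer_bytes)


def centered_matrix(codes: np.ndarray, means: np.ndarray) -> np.ndarray:
    """Float centred genotypes ``a - mean`` with missing entries set to 0.

    Setting a missing entry to zero after centring is mean imputation: it
    contributes nothing to any dot product.
    """
    X = codes.astype(np.float64)
    X -= means[:, None]
    X[codes == MISSING] = 0.0
    return X


def dot_products(codes: np.ndarray, means: np.ndarray, y_perm: np.ndarray,
                 plan: BlockPlan | None = None) -> np.ndarray:
    """Per-SNP centred dot products against a (permuted) phenotype.

    For SNP j the numerator is ``sum over non-missing i of
    (a_ji - mean_j) * y_perm[i]``.  When a :class:`BlockPlan` is given the
    rows are processed block by block; the result is bitwise identical for
    any plan because each row's product is accumulated independently of the
    partition (a one-row reduction per SNP, never a shape-dependent matrix
    product whose summation order could vary).
    """
    if codes.shape[1] != len(y_perm):
        raise ValueError("phenotype length does not match sample count")
    slices = [slice(0, codes.shape[0])] if plan is None else plan.slices()
    out = np.empty(codes.shape[0], dtype=np.float64)
    for sl in slices:
        Xc = centered_matrix(codes[sl], means[sl])
        for i in range(Xc.shape[0]):
            out[sl.start + i] = np.dot(Xc[i], y_perm)
    return out


@dataclass(frozen=True)
class FixedPointFormat:
    """Signed fixed-point format: ``total_bits`` wide, ``frac_bits`` fractional.

    The accumulator must be wide enough that an n-term dot product of
    full-scale values cannot overflow: ``accumulator_bits >= total_bits +
    ceil(log2(n)) + 2``.  The default (32/16/64) satisfies this for any
    n up to 262 144 samples.
    """

    total_bits: int = 32
    frac_bits: int = 16
    accumulator_bits: int = 64

    def __post_init__(self) -> None:
        if not 0 < self.frac_bits < self.total_bits <= 64:
            raise ValueError("need 0 < frac_bits < total_bits <= 64")
        if self.accumulator_bits > 64:
            raise ValueError("accumulators wider than 64 bits are not emulated")

    @property
    def scale(self) -> int:
        return 1 << self.frac_bits

    @property
    def max_mantissa(self) -> int:
        return (1 << (self.total_bits - 1)) - 1

    @property
    def min_mantissa(self) -> int:
        return -(1 << (self.total_bits - 1))

    def supports_n(self, n: int) -> bool:
        """Whether an n-term dot product is overflow-safe in the accumulator."""
        return self.accumulator_bits >= self.total_bits + math.ceil(math.log2(max(n, 2))) + 2


def quantize(v, fmt: FixedPointFormat) -> np.ndarray:
    """Round-to-nearest-even quantization to integer mantissas.

    Values outside the representable range saturate; a warning reports the
    saturation count (also retrievable via :func:`quantize_with_stats`).
    """
    q, n_sat = quantize_with_stats(v, fmt)
    if n_sat:
        warnings.warn(f"fixed-point saturation on {n_sat} value(s)",
                      RuntimeWarning, stacklevel=2)
    return q


def quantize_with_stats(v, fmt: FixedPointFormat) -> tuple[np.ndarray, int]:
    """As :func:`quantize`, returning ``(mantissas, saturation_count)``."""
    scaled = np.rint(np.asarray(v, dtype=np.float64) * fmt.scale)
    n_sat = int(np.count_nonzero((scaled > fmt.max_mantissa) |
                                 (scaled < fmt.min_mantissa)))
    q = np.clip(scaled, fmt.min_mantissa, fmt.max_mantissa).astype(np.int64)
    return q, n_sat


def dequantize(q, fmt: FixedPointFormat) -> np.ndarray:
    """Map integer mantissas back to floats."""
    return np.asarray(q, dtype=np.float64) / fmt.scale


def dot_products_fixed(codes: np.ndarray, means: np.ndarray,
                       y_q: np.ndarray, fmt: FixedPointFormat,
                       plan: BlockPlan | None = None) -> np.ndarray:
    """Fixed-point emulation of :func:`dot_products`.

    ``y_q`` holds the phenotype mantissas from :func:`quantize`.  Genotype
    codes are exact in the format (integers scaled by ``2^frac_bits``); the
    per-SNP means are quantized here.  Products and sums are exact 64-bit
    integer arithmetic — the only rounding is the quantization of the
    phenotype and the means — and the result is dequantized by
    ``2^(2 * frac_bits)``.
    """
    n = codes.shape[1]
    if n != len(y_q):
        raise ValueError("phenotype length does not match sample count")
    if not fmt.supports_n(n):
        raise ValueError(
            f"accumulator of {fmt.accumulator_bits} bits cannot guarantee an "
            f"overflow-free dot product over n={n}")
    if plan is None:
        return _fixed_block(codes, means, y_q, fmt)
    out = np.empty(codes.shape[0], dtype=np.float64)
    for sl in plan.slices():
        out[sl] = _fixed_block(codes[sl], means[sl], y_q, fmt)
    return out


def _fixed_block(codes: np.ndarray, means: np.ndarray, y_q: np.ndarray,
                 fmt: FixedPointFormat) -> np.ndarray:
    mean_q, _ = quantize_with_stats(means, fmt)
    x_q = codes.astype(np.int64) * fmt.scale - mean_q[:, None]
    x_q[codes == MISSING] = 0
    acc = x_q @ y_q.astype(np.int64)
    return acc / float(fmt.scale) ** 2
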