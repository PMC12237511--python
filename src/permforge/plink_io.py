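"""PLINK 1 binary genotype I/O and tabular result output.

The PLINK binary trio (``prefix.bed`` / ``prefix.bim`` / ``prefix.fam``) is
the de-facto interchange format for genotyped cohorts.  The ``.bed`` file
stores additive allele counts two bits per genotype in SNP-major order: all
samples for one variant are packed contiguously, four genotypes per byte,
lowest-order bit pair first.  The bit-pair encoding is

====  =======================================
bits  meaning (additive count of allele A1)
====  =======================================
00    homozygous A1 -> code 2
01    missing genotype
10    heterozygous  -> code 1
11    homozygous A2 -> code 0
====  =======================================

Only SNP-major files (magic bytes ``0x6C 0x1B``, mode byte ``0x01``) are
accepted; the obsolete sample-major layout is rejected rather than
converted.  Missing genotypes are represented in memory by :data:`MISSING`
(-1) in an ``int8`` matrix.

The additive code counts copies of allele A1 (the first ``.bim`` allele
column).  Association statistics are invariant to flipping which allele is
counted (the correlation changes sign, its square does not), so this
orientation choice cannot change any reported p-value.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: In-memory marker for a missing genotype.
MISSING: int = -1

#: Column names for the six-column .bim variant table.
BIM_COLUMNS = ["chrom", "snp", "cm", "pos", "a1", "a2"]

#: Column names for the six-column .fam sample table.
FAM_COLUMNS = ["fid", "iid", "father", "mother", "sex", "phenotype"]

_BED_MAGIC = bytes([0x6C, 0x1B])
_SNP_MAJOR = 0x01
_SAMPLE_MAJOR = 0x00

# code for each 2-bit value 0b00, 0b01, 0b10, 0b11
_PAIR_TO_CODE = np.array([2, MISSING, 1, 0], dtype=np.int8)
# bit pair for each code, indexed by code + 1 (missing first)
_CODE_TO_PAIR = np.array([0b01, 0b11, 0b10, 0b00], dtype=np.uint8)

# 256 x 4 table: byte value -> four codes, lowest-order bit pair first
_BYTE_DECODE = np.empty((256, 4), dtype=np.int8)
for _b in range(256):
    for _k in range(4):
        _BYTE_DECODE[_b, _k] = _PAIR_TO_CODE[(_b >> (2 * _k)) & 0b11]


class PlinkFormatError(ValueError):
    """Raised when a .bed/.bim/.fam trio violates the PLINK 1 binary format."""


@dataclass
class GenotypeMatrix:
    """Additive allele-count matrix with variant and sample identifiers.

    Parameters
    ----------
    codes
        ``m x n`` ``int8`` matrix; entries are 0, 1, 2 or :data:`MISSING`.
    snp_ids
        Length-``m`` variant identifiers (unique).
    sample_ids
        Length-``n`` sample identifiers.
    """

    codes: np.ndarray
    snp_ids: np.ndarray = field(default=None)  # type: ignore[assignment]
    sample_ids: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.ndim != 2 or self.codes.shape[0] < 1 or self.codes.shape[1] < 1:
            raise ValueError("codes must be a non-empty 2-D matrix")
        valid = np.isin(self.codes, (0, 1, 2, MISSING))
        if not valid.all():
            bad = self.codes[~valid][0]
            raise ValueError(f"invalid genotype code {bad}; expected 0, 1, 2 or {MISSING}")
        m, n = self.codes.shape
        if self.snp_ids is None:
            self.snp_ids = np.array([f"snp{j}" for j in range(m)])
        if self.sample_ids is None:
            self.sample_ids = np.array([f"sample{i}" for i in range(n)])
        self.snp_ids = np.asarray(self.snp_ids)
        self.sample_ids = np.asarray(self.sample_ids)
        if len(self.snp_ids) != m:
            raise ValueError("snp_ids length does not match row count")
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length does not match column count")

    @property
    def n_snps(self) -> int:
        return self.codes.shape[0]

    @property
    def n_samples(self) -> int:
        return self.codes.shape[1]


def decode_bed_byte(byte: int) -> tuple[int, int, int, int]:
    """Decode one SNP-major .bed byte into its four genotype codes.

    The lowest-order bit pair is the first sample.  Every byte value is
    decodable; trailing padding pairs in a real file are the caller's
    concern.

    >>> decode_bed_byte(0x1B)
    (0, 1, -1, 2)
    """
    if not 0 <= byte <= 0xFF:
        raise ValueError("byte must be in 0..255")
    return tuple(int(c) for c in _BYTE_DECODE[byte])


def encode_bed_byte(codes: tuple[int, int, int, int]) -> int:
    """Pack four genotype codes (0/1/2/missing) into one .bed byte."""
    byte = 0
    for k, c in enumerate(codes):
        byte |= int(_CODE_TO_PAIR[c + 1]) << (2 * k)
    return byte


def _read_bim(path: str) -> pd.DataFrame:
    bim = pd.read_csv(path, sep=r"\s+", header=None, names=BIM_COLUMNS,
                      dtype={"chrom": str, "snp": str, "a1": str, "a2": str})
    if bim["snp"].duplicated().any():
        dup = bim.loc[bim["snp"].duplicated(), "snp"].iloc[0]
        raise PlinkFormatError(f"duplicate variant identifier {dup!r} in {path}")
    return bim


def _read_fam(path: str) -> pd.DataFrame:
    fam = pd.read_csv(path, sep=r"\s+", header=None, names=FAM_COLUMNS,
                      dtype={"fid": str, "iid": str, "father": str,
                             "mother": str, "phenotype": str})
    if fam.duplicated(subset=["fid", "iid"]).any():
        raise PlinkFormatError(f"duplicate (FID, IID) pair in {path}")
    return fam


def read_plink(path_prefix: str) -> tuple[GenotypeMatrix, pd.DataFrame, pd.DataFrame]:
    """Read a PLINK binary trio ``prefix.bed/.bim/.fam``.

    Returns
    -------
    (GenotypeMatrix, variant table, sample table)
        The variant and sample tables are DataFrames with columns
        :data:`BIM_COLUMNS` and :data:`FAM_COLUMNS`; their row order matches
        the genotype matrix rows and columns respectively.  The ``.fam``
        phenotype column is returned as text; interpreting ``-9``/``NA`` as
        missing is an analysis-level decision (see :mod:`permforge.cli`).

    Raises
    ------
    PlinkFormatError
        Wrong magic bytes, sample-major mode byte, or a .bed payload whose
        size is inconsistent with ``m * ceil(n / 4)``.
    """
    bed_path = path_prefix + ".bed"
    bim = _read_bim(path_prefix + ".bim")
    fam = _read_fam(path_prefix + ".fam")
    m, n = len(bim), len(fam)

    raw = np.fromfile(bed_path, dtype=np.uint8)
    if raw.size < 3 or bytes(raw[:2]) != _BED_MAGIC:
        got = raw[:2].tobytes().hex() if raw.size >= 2 else raw.tobytes().hex()
        raise PlinkFormatError(
            f"{bed_path}: bad magic bytes 0x{got or '??'} (expected 0x6c1b)")
    mode = int(raw[2])
    if mode == _SAMPLE_MAJOR:
        raise PlinkFormatError(
            f"{bed_path}: unsupported layout (sample-major mode byte 0x00)")
    if mode != _SNP_MAJOR:
        raise PlinkFormatError(
            f"{bed_path}: unrecognized mode byte 0x{mode:02x} (expected 0x01)")

    bytes_per_snp = -(-n // 4)
    payload = raw[3:]
    if payload.size != m * bytes_per_snp:
        raise PlinkFormatError(
            f"{bed_path}: truncated or oversized payload: {payload.size} bytes, "
            f"expected {m} x {bytes_per_snp} = {m * bytes_per_snp}")

    # decode all bytes at once, then trim padding columns
    codes = _BYTE_DECODE[payload.reshape(m, bytes_per_snp)].reshape(m, 4 * bytes_per_snp)
    codes = np.ascontiguousarray(codes[:, :n])

    G = GenotypeMatrix(codes, snp_ids=bim["snp"].to_numpy(),
                       sample_ids=fam["iid"].to_numpy())
    return G, bim, fam


def write_plink(G: GenotypeMatrix, variants: pd.DataFrame, samples: pd.DataFrame,
                path_prefix: str) -> None:
    """Write a PLINK binary trio such that :func:`read_plink` inverts it.

    ``variants`` and ``samples`` must have the .bim/.fam columns and row
    counts matching ``G``.  Padding bit pairs in the final byte of each SNP
    record are written as zero bit pairs.
    """
    m, n = G.codes.shape
    if len(variants) != m:
        raise ValueError("variant table row count does not match genotype rows")
    if len(samples) != n:
        raise ValueError("sample table row count does not match genotype columns")

    bytes_per_snp = -(-n // 4)
    padded = np.zeros((m, 4 * bytes_per_snp), dtype=np.int8)
    padded[:, :n] = G.codes
    padded[:, n:] = 2  # code 2 encodes to bit pair 00
    pairs = _CODE_TO_PAIR[padded.astype(np.int16) + 1].reshape(m, bytes_per_snp, 4)
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    payload = (pairs.astype(np.uint8) << shifts).sum(axis=2, dtype=np.uint8)

    with open(path_prefix + ".bed", "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(bytes([_SNP_MAJOR]))
        fh.write(payload.tobytes())
    variants[BIM_COLUMNS].to_csv(path_prefix + ".bim", sep="\t",
                                 header=False, index=False)
    samples[FAM_COLUMNS].to_csv(path_prefix + ".fam", sep="\t",
                                header=False, index=False)


def default_variant_table(G: GenotypeMatrix) -> pd.DataFrame:
    """Minimal .bim table for a bare genotype matrix (chromosome 1, unit spacing)."""
    m = G.n_snps
    return pd.DataFrame({
        "chrom": ["1"] * m, "snp": G.snp_ids, "cm": [0.0] * m,
        "pos": np.arange(1, m + 1), "a1": ["A"] * m, "a2": ["B"] * m,
    })


def default_sample_table(G: GenotypeMatrix,
                         phenotype: np.ndarray | None = None) -> pd.DataFrame:
    """Minimal .fam table; phenotype defaults to the missing sentinel -9."""
    n = G.n_samples
    pheno = ["-9"] * n if phenotype is None else [repr(float(v)) for v in phenotype]
    return pd.DataFrame({
        "fid": G.sample_ids, "iid": G.sample_ids, "father": ["0"] * n,
        "mother": ["0"] * n, "sex": [0] * n, "phenotype": pheno,
    })


def read_covariates(path: str) -> pd.DataFrame:
    """Read a whitespace-delimited covariate table (PLINK ``--covar`` dialect).

    First two columns are FID and IID (a header line is accepted and
    detected by non-numeric values in the third column); remaining columns
    are numeric covariates.
    """
    df = pd.read_csv(path, sep=r"\s+", header=None, dtype=str)
    if df.shape[1] < 3:
        raise PlinkFormatError(f"{path}: covariate file needs FID, IID and >=1 covariate column")
    first_val = df.iloc[0, 2]
    try:
        float(first_val)
        header = None
    except (TypeError, ValueError):
        header = df.iloc[0].tolist()
        df = df.iloc[1:].reset_index(drop=True)
    names = ["fid", "iid"] + (
        [str(h) for h in header[2:]] if header is not None
        else [f"cov{k}" for k in range(1, df.shape[1] - 1)])
    df.columns = names
    for c in names[2:]:
        df[c] = pd.to_numeric(df[c])
    return df


def write_results(rows: pd.DataFrame, path: str,
                  metadata: dict | None = None) -> None:
    """Write per-SNP results as tab-delimited text.

    Floating-point columns are rendered with 17 significant digits so every
    p-value parses back to the identical float.  ``metadata`` entries are
    written as ``# key: value`` comment lines above the header.
    """
    with open(path, "w") as fh:
        for key, val in (metadata or {}).items():
            fh.write(f"# {key}: {val}\n")
        fh.write("\t".join(rows.columns) + "\n")
        for _, row in rows.iterrows():
            cells = []
            for v in row:
                if isinstance(v, (float, np.floating)):
                    cells.append(format(float(v), ".17g"))
                else:
                    cells.append(str(v))
            fh.write("\t".join(cells) + "\n")


def read_results(path: str) -> pd.DataFrame:
    """Read a results file written by :func:`write_results`."""
    return pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip")
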