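"""Tabular input/output: summary statistics, allele-frequency tables, LD blocks.

Conventions
-----------
* Summary-statistic and frequency tables are tab-separated with a header.
  Positions are 1-based (GWAS convention).
* LD blocks are BED3: 0-based, half-open intervals.  A SNP at 1-based
  position ``P`` lies in block ``(start, end)`` iff ``start <= P - 1 < end``.
* Rows violating basic invariants (non-positive standard errors,
  frequencies outside (0, 1), ...) are dropped with a logged count rather
  than raising: real summary-statistic files routinely contain a handful of
  malformed rows.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SUMSTATS_COLUMNS",
    "FREQ_COLUMNS",
    "DEFAULT_SUMSTATS_DIALECT",
    "DEFAULT_FREQ_DIALECT",
    "FormatError",
    "EmptyTableError",
    "BlockPartition",
    "read_sumstats",
    "write_sumstats",
    "read_freqs",
    "write_freqs",
    "read_ld_blocks",
    "harmonize_freqs",
    "validate_sumstats",
]

#: canonical column order for summary-statistic tables
SUMSTATS_COLUMNS = [
    "snp_id", "chrom", "pos", "effect_allele", "other_allele", "p",
    "beta_m", "se_m", "n_m", "beta_f", "se_f", "n_f",
]

#: canonical column order for sex-stratified allele-frequency tables
FREQ_COLUMNS = ["snp_id", "counted_allele", "p_m_hat", "p_f_hat", "an_m", "an_f"]

#: default file-header names (canonical name -> file column name)
DEFAULT_SUMSTATS_DIALECT = {
    "snp_id": "SNP", "chrom": "CHR", "pos": "BP",
    "effect_allele": "A1", "other_allele": "A2", "p": "FRQ",
    "beta_m": "BETA_M", "se_m": "SE_M", "n_m": "N_M",
    "beta_f": "BETA_F", "se_f": "SE_F", "n_f": "N_F",
}

DEFAULT_FREQ_DIALECT = {
    "snp_id": "SNP", "counted_allele": "A1",
    "p_m_hat": "FRQ_M", "p_f_hat": "FRQ_F", "an_m": "AN_M", "an_f": "AN_F",
}


class FormatError(ValueError):
    """A required column is missing or a file cannot be interpreted."""


class EmptyTableError(ValueError):
    """A table contains no (valid) rows."""


def _read_tsv(path, dialect, columns, kind):
    try:
        raw = pd.read_csv(path, sep="\t", dtype={dialect.get("snp_id", "SNP"): str},
                          float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise EmptyTableError(f"{kind} file {path!r} is empty") from None
    missing = [dialect[c] for c in columns if dialect[c] not in raw.columns]
    if missing:
        raise FormatError(f"{kind} file {path!r} lacks required column(s): {missing}")
    df = raw[[dialect[c] for c in columns]].copy()
    df.columns = columns
    if len(df) == 0:
        raise EmptyTableError(f"{kind} file {path!r} has a header but no rows")
    return df


def validate_sumstats(df: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Enforce per-record invariants; return (valid rows, number dropped)."""
    num = df[["p", "beta_m", "se_m", "n_m", "beta_f", "se_f", "n_f", "pos"]]
    ok = (
        np.isfinite(num.to_numpy(dtype=float)).all(axis=1)
        & (df["se_m"] > 0) & (df["se_f"] > 0)
        & (df["p"] > 0) & (df["p"] < 1)
        & (df["n_m"] >= 1) & (df["n_f"] >= 1)
        & (df["pos"] >= 1)
        & ~df["snp_id"].duplicated(keep=False)
    )
    dropped = int((~ok).sum())
    return df.loc[ok].reset_index(drop=True), dropped


def read_sumstats(path, dialect: dict | None = None) -> pd.DataFrame:
    """Read a sex-stratified GWAS summary-statistics TSV.

    Parameters
    ----------
    path : str or Path
        Tab-separated file with a header.
    dialect : dict, optional
        Mapping from canonical column names (:data:`SUMSTATS_COLUMNS`) to the
        header names used in the file.  Defaults to
        :data:`DEFAULT_SUMSTATS_DIALECT`, so deposited files with other
        headers can be adapted through configuration rather than code.

    Returns
    -------
    pandas.DataFrame
        One validated record per row, canonical columns and dtypes.  Rows
        failing the record invariants are dropped with a logged count.
    """
    dialect = {**DEFAULT_SUMSTATS_DIALECT, **(dialect or {})}
    df = _read_tsv(path, dialect, SUMSTATS_COLUMNS, "summary-statistics")
    df = df.astype({
        "snp_id": str, "chrom": str, "pos": np.int64,
        "effect_allele": str, "other_allele": str,
        "p": float, "beta_m": float, "se_m": float, "n_m": np.int64,
        "beta_f": float, "se_f": float, "n_f": np.int64,
    })
    df, dropped = validate_sumstats(df)
    if dropped:
        logger.warning("read_sumstats: dropped %d invalid row(s) from %s", dropped, path)
    if len(df) == 0:
        raise EmptyTableError(f"no valid rows in {path!r}")
    return df


def write_sumstats(df: pd.DataFrame, path, dialect: dict | None = None) -> None:
    """Write a summary-statistics table in canonical form (round-trips losslessly)."""
    dialect = {**DEFAULT_SUMSTATS_DIALECT, **(dialect or {})}
    out = df[SUMSTATS_COLUMNS].rename(columns=dialect)
    out.to_csv(path, sep="\t", index=False)


def read_freqs(path, dialect: dict | None = None) -> pd.DataFrame:
    """Read a sex-stratified allele-frequency TSV (sample frequency and
    allele number per sex)."""
    dialect = {**DEFAULT_FREQ_DIALECT, **(dialect or {})}
    df = _read_tsv(path, dialect, FREQ_COLUMNS, "frequency")
    df = df.astype({
        "snp_id": str, "counted_allele": str,
        "p_m_hat": float, "p_f_hat": float, "an_m": np.int64, "an_f": np.int64,
    })
    ok = (
        (df["p_m_hat"] >= 0) & (df["p_m_hat"] <= 1)
        & (df["p_f_hat"] >= 0) & (df["p_f_hat"] <= 1)
        & (df["an_m"] > 0) & (df["an_f"] > 0)
        & ~df["snp_id"].duplicated(keep=False)
    )
    dropped = int((~ok).sum())
    if dropped:
        logger.warning("read_freqs: dropped %d invalid row(s) from %s", dropped, path)
    df = df.loc[ok].reset_index(drop=True)
    if len(df) == 0:
        raise EmptyTableError(f"no valid rows in {path!r}")
    return df


def write_freqs(df: pd.DataFrame, path, dialect: dict | None = None) -> None:
    dialect = {**DEFAULT_FREQ_DIALECT, **(dialect or {})}
    out = df[FREQ_COLUMNS].rename(columns=dialect)
    out.to_csv(path, sep="\t", index=False)


class BlockPartition:
    """An ordered set of non-overlapping genomic intervals (BED convention).

    Blocks are 0-based, half-open; block ids are row numbers in the input
    order.  Used as the approximate-independence unit for subsampling and
    resampling.
    """

    def __init__(self, blocks: pd.DataFrame):
        blocks = blocks.reset_index(drop=True)
        if not {"chrom", "start", "end"}.issubset(blocks.columns):
            raise FormatError("block table needs columns chrom/start/end")
        if (blocks["end"] <= blocks["start"]).any():
            raise FormatError("blocks must satisfy start < end")
        for chrom, grp in blocks.groupby("chrom", sort=False):
            g = grp.sort_values("start")
            if (g["start"].to_numpy()[1:] < g["end"].to_numpy()[:-1]).any():
                raise FormatError(f"overlapping blocks on chromosome {chrom}")
        self.blocks = blocks
        self._by_chrom = {}
        for chrom, grp in blocks.groupby("chrom", sort=False):
            g = grp.sort_values("start")
            self._by_chrom[str(chrom)] = (
                g["start"].to_numpy(np.int64),
                g["end"].to_numpy(np.int64),
                g.index.to_numpy(np.int64),
            )

    def __len__(self) -> int:
        return len(self.blocks)

    def assign(self, chrom, pos) -> np.ndarray:
        """Block id for each SNP given 1-based positions; -1 if unassigned."""
        chrom = np.asarray(chrom, dtype=str)
        pos0 = np.asarray(pos, dtype=np.int64) - 1  # to 0-based
        out = np.full(len(pos0), -1, dtype=np.int64)
        for c in np.unique(chrom):
            if c not in self._by_chrom:
                continue
            starts, ends, ids = self._by_chrom[c]
            mask = chrom == c
            k = np.searchsorted(starts, pos0[mask], side="right") - 1
            inside = (k >= 0) & (pos0[mask] < ends[np.clip(k, 0, None)])
            res = np.where(inside, ids[np.clip(k, 0, None)], -1)
            out[mask] = res
        n_un = int((out < 0).sum())
        if n_un:
            logger.info("BlockPartition.assign: %d SNP(s) fall in no block", n_un)
        return out


def read_ld_blocks(path) -> BlockPartition:
    """Read LD blocks from a BED3 file (no header required)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "start", "end"],
                     dtype={0: str, 1: np.int64, 2: np.int64})
    if len(df) == 0:
        raise EmptyTableError(f"no blocks in {path!r}")
    return BlockPartition(df)


def harmonize_freqs(sumstats: pd.DataFrame, freqs: pd.DataFrame) -> pd.DataFrame:
    """Join frequency records onto summary statistics on ``snp_id``,
    re-orienting frequencies to count the effect allele.

    When ``counted_allele`` equals the summary-statistics other allele, the
    sex-specific frequencies are replaced by ``1 - p_hat``.  Records whose
    counted allele matches neither allele are excluded with a logged count.
    All downstream statistics of the selection test depend only on squared
    frequency differences and on ``p(1-p)``, so they are exactly invariant
    to which allele was counted.
    """
    merged = sumstats.merge(freqs, on="snp_id", how="inner")
    flip = merged["counted_allele"] == merged["other_allele"]
    keep = flip | (merged["counted_allele"] == merged["effect_allele"])
    n_bad = int((~keep).sum())
    if n_bad:
        logger.warning("harmonize_freqs: excluded %d record(s) with mismatching alleles", n_bad)
    merged = merged.loc[keep].reset_index(drop=True)
    flip = (merged["counted_allele"] == merged["other_allele"]).to_numpy()
    merged.loc[flip, "p_m_hat"] = 1.0 - merged.loc[flip, "p_m_hat"]
    merged.loc[flip, "p_f_hat"] = 1.0 - merged.loc[flip, "p_f_hat"]
    merged.loc[flip, "counted_allele"] = merged.loc[flip, "effect_allele"]
    return merged
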