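"""Readers, quality control and LD computation for the tabular inputs.

All tables are delimited text.  Summary statistics are held as a pandas
DataFrame with canonical column names (``snp_id, chrom, pos, effect_allele,
other_allele, beta, se, pvalue, maf, info``); published files with other
layouts are mapped through a *dialect* — a ``{canonical: file column}``
dictionary.  The reference panel is a plain individuals-by-SNPs dosage
matrix used only to estimate genotype correlations (LD).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "SUMSTAT_COLUMNS",
    "FUNCTIONAL_CLASSES",
    "ReferencePanel",
    "LDMatrix",
    "read_summary_stats",
    "write_summary_stats",
    "read_gene_definitions",
    "gene_definitions_from_bed",
    "read_annotations",
    "apply_qc_filters",
    "harmonize_alleles",
    "compute_ld",
]

SUMSTAT_COLUMNS = [
    "snp_id", "chrom", "pos", "effect_allele", "other_allele",
    "beta", "se", "pvalue", "maf", "info",
]
_NUMERIC = ["pos", "beta", "se", "pvalue", "maf", "info"]
_STRING = ["snp_id", "chrom", "effect_allele", "other_allele"]

FUNCTIONAL_CLASSES = (
    "nonsynonymous", "exonic_other", "utr5", "utr3", "intron",
    "other_within_gene",
)


def read_summary_stats(path, dialect=None, sep="\t") -> pd.DataFrame:
    """Read GWAS summary statistics into the canonical layout.

    Parameters
    ----------
    path : str or file-like
        Delimited text file with a header row.
    dialect : dict, optional
        Mapping from canonical names to the file's column names for any
        columns that differ.
    sep : str
        Field separator.

    Returns
    -------
    DataFrame
        Canonical columns; rows whose numeric fields failed to parse are
        dropped (count logged and stored in ``.attrs['n_dropped']``).

    Raises
    ------
    KeyError
        If a required column cannot be resolved through the dialect.
    """
    dialect = dialect or {}
    raw = pd.read_csv(path, sep=sep, dtype=str, comment="#")
    colmap = {canon: dialect.get(canon, canon) for canon in SUMSTAT_COLUMNS}
    missing = [c for c in colmap.values() if c not in raw.columns]
    if missing:
        raise KeyError(
            f"summary-statistic file is missing required columns: {missing}"
        )
    df = pd.DataFrame({canon: raw[col] for canon, col in colmap.items()})
    for c in _NUMERIC:
        df[c] = pd.to_numeric(df[c], errors="coerce")
    n0 = len(df)
    df = df.dropna(subset=_NUMERIC).reset_index(drop=True)
    n_dropped = n0 - len(df)
    if n_dropped:
        logger.warning("dropped %d rows with unparseable numeric fields", n_dropped)
    df["pos"] = df["pos"].astype(np.int64)
    _validate_sumstats(df)
    df.attrs["n_dropped"] = n_dropped
    return df


def _validate_sumstats(df: pd.DataFrame) -> None:
    if (df["se"] <= 0).any():
        raise ValueError("standard errors must be positive")
    if ((df["pvalue"] <= 0) | (df["pvalue"] > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    if ((df["maf"] <= 0) | (df["maf"] > 0.5)).any():
        raise ValueError("MAF must lie in (0, 0.5]")
    if ((df["info"] < 0) | (df["info"] > 1)).any():
        raise ValueError("INFO must lie in [0, 1]")
    # published files round beta/se/p: inconsistency warns, never fails
    z = (df["beta"] / df["se"]).to_numpy()
    p_expect = 2.0 * stats.norm.sf(np.abs(z))
    p_given = df["pvalue"].to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.abs(p_expect - p_given) / np.maximum(p_given, 1e-300)
    bad = (rel > 1e-3) & (p_given > 1e-280)
    if bad.any():
        logger.warning(
            "%d records have p-values inconsistent with beta/se beyond "
            "relative tolerance 1e-3 (rounding in the source file?)",
            int(bad.sum()),
        )


def write_summary_stats(df: pd.DataFrame, path, sep="\t") -> None:
    """Write canonical summary statistics (full float precision)."""
    df.to_csv(path, sep=sep, index=False, columns=SUMSTAT_COLUMNS,
              float_format="%.17g")


def read_gene_definitions(path, sep="\t") -> pd.DataFrame:
    """Gene table: gene_id, name, chrom, tx_start, tx_end (1-based inclusive)."""
    df = pd.read_csv(path, sep=sep, dtype={"gene_id": str, "name": str,
                                           "chrom": str}, comment="#")
    required = ["gene_id", "name", "chrom", "tx_start", "tx_end"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise KeyError(f"gene-definition file is missing columns: {missing}")
    df = df[required].copy()
    df["tx_start"] = df["tx_start"].astype(np.int64)
    df["tx_end"] = df["tx_end"].astype(np.int64)
    if (df["tx_start"] > df["tx_end"]).any():
        raise ValueError("tx_start must not exceed tx_end")
    return df


def gene_definitions_from_bed(path) -> pd.DataFrame:
    """Import genes from BED (0-based half-open -> 1-based inclusive)."""
    bed = pd.read_csv(path, sep="\t", header=None, comment="#")
    if bed.shape[1] < 4:
        raise ValueError("BED gene import needs chrom, start, end, name")
    df = pd.DataFrame({
        "gene_id": bed[3].astype(str),
        "name": bed[3].astype(str),
        "chrom": bed[0].astype(str),
        "tx_start": bed[1].astype(np.int64) + 1,
        "tx_end": bed[2].astype(np.int64),
    })
    if (df["tx_start"] > df["tx_end"]).any():
        raise ValueError("invalid BED interval")
    return df


def read_annotations(path, sep="\t") -> pd.DataFrame:
    """Per-SNP functional classes: snp_id, functional_class."""
    df = pd.read_csv(path, sep=sep, dtype=str, comment="#")
    if not {"snp_id", "functional_class"} <= set(df.columns):
        raise KeyError("annotation file needs snp_id and functional_class")
    bad = ~df["functional_class"].isin(FUNCTIONAL_CLASSES)
    if bad.any():
        raise ValueError(
            f"unknown functional classes: {sorted(df['functional_class'][bad].unique())}"
        )
    if df["snp_id"].duplicated().any():
        raise ValueError("a SNP may carry only one functional class")
    return df[["snp_id", "functional_class"]].copy()


def apply_qc_filters(records: pd.DataFrame, maf_min: float = 0.001,
                     info_min: float = 0.8) -> pd.DataFrame:
    """Retain SNPs with maf >= maf_min and info >= info_min.

    Exact-boundary values are retained: the exclusion rule is the strict
    inequality MAF < maf_min or INFO < info_min.
    """
    keep = (records["maf"] >= maf_min) & (records["info"] >= info_min)
    n_excl = int((~keep).sum())
    if n_excl:
        logger.info("QC excluded %d of %d SNPs", n_excl, len(records))
    out = records.loc[keep].reset_index(drop=True)
    out.attrs["n_qc_excluded"] = n_excl
    return out


@dataclass
class ReferencePanel:
    """Dosage matrix (individuals x SNPs, values in [0, 2]) for LD estimation.

    ``counted_allele`` optionally records, per SNP, which allele the dosage
    counts; it is only needed for allele harmonization against summary
    statistics from another source.
    """

    snp_ids: list[str]
    dosages: np.ndarray
    counted_allele: list[str] | None = None
    _index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=np.float64)
        if self.dosages.ndim != 2 or self.dosages.shape[1] != len(self.snp_ids):
            raise ValueError("dosages must be individuals x SNPs")
        with np.errstate(invalid="ignore"):
            if np.nanmin(self.dosages, initial=0.0) < 0 or \
               np.nanmax(self.dosages, initial=0.0) > 2:
                raise ValueError("dosages must lie in [0, 2]")
        self._index = {s: j for j, s in enumerate(self.snp_ids)}

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    def columns(self, snp_ids) -> np.ndarray:
        try:
            idx = [self._index[s] for s in snp_ids]
        except KeyError as e:
            raise KeyError(f"SNP {e.args[0]!r} not in reference panel") from None
        return self.dosages[:, idx]

    def allele_freqs(self, snp_ids=None) -> np.ndarray:
        cols = self.dosages if snp_ids is None else self.columns(snp_ids)
        return np.nanmean(cols, axis=0) / 2.0

    def save(self, path) -> None:
        """Plain TSV: header row of SNP ids, one row per individual."""
        pd.DataFrame(self.dosages, columns=self.snp_ids).to_csv(
            path, sep="\t", index=False, float_format="%.17g")

    @classmethod
    def load(cls, path) -> "ReferencePanel":
        df = pd.read_csv(path, sep="\t")
        return cls(snp_ids=list(df.columns), dosages=df.to_numpy(float))


@dataclass
class LDMatrix:
    """Pearson genotype-correlation matrix over an ordered SNP list."""

    snp_ids: list[str]
    r: np.ndarray
    _index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        self.r = np.asarray(self.r, dtype=float)
        m = len(self.snp_ids)
        if self.r.shape != (m, m):
            raise ValueError("LD matrix shape does not match SNP list")
        if not np.allclose(self.r, self.r.T, atol=1e-12):
            raise ValueError("LD matrix must be symmetric")
        if np.any(np.abs(self.r) > 1 + 1e-10):
            raise ValueError("correlations must lie in [-1, 1]")
        self._index = {s: j for j, s in enumerate(self.snp_ids)}

    def submatrix(self, snp_ids) -> np.ndarray:
        idx = [self._index[s] for s in snp_ids]
        return self.r[np.ix_(idx, idx)]

    def r2(self, snp_a: str, snp_b: str) -> float:
        return float(self.r[self._index[snp_a], self._index[snp_b]] ** 2)


def harmonize_alleles(records: pd.DataFrame, panel: ReferencePanel) -> pd.DataFrame:
    """Flip beta where the effect allele is the panel's non-counted allele.

    SNPs absent from the panel are returned unchanged.  Strand-ambiguous
    (A/T, C/G) SNPs are retained as-is; the source of truth here is the SNP
    identifier, and no frequency-based guessing is attempted.
    """
    if panel.counted_allele is None:
        return records
    counted = dict(zip(panel.snp_ids, panel.counted_allele))
    out = records.copy()
    flip = out.apply(
        lambda row: counted.get(row["snp_id"]) == row["other_allele"], axis=1
    )
    n = int(flip.sum())
    if n:
        logger.info("flipped effect direction of %d SNPs to match the panel", n)
        out.loc[flip, "beta"] = -out.loc[flip, "beta"]
        out.loc[flip, ["effect_allele", "other_allele"]] = (
            out.loc[flip, ["other_allele", "effect_allele"]].to_numpy()
        )
    return out


def compute_ld(panel: ReferencePanel, snp_subset) -> LDMatrix:
    """Pearson correlation of dosage columns over a SNP subset.

    Missing dosages are mean-imputed per SNP before the correlation.  A
    constant column is a hard error: it should have been removed at QC.
    """
    snp_subset = list(snp_subset)
    if panel.n_individuals < 2:
        raise ValueError("LD estimation needs at least two individuals")
    g = panel.columns(snp_subset).copy()
    if np.isnan(g).any():
        means = np.nanmean(g, axis=0)
        nan_r, nan_c = np.where(np.isnan(g))
        g[nan_r, nan_c] = means[nan_c]
    sd = g.std(axis=0)
    if np.any(sd == 0):
        const = [s for s, x in zip(snp_subset, sd) if x == 0]
        raise ValueError(f"constant dosage columns in panel: {const}")
    r = np.corrcoef(g, rowvar=False)
    r = np.atleast_2d(r)
    np.fill_diagonal(r, 1.0)
    return LDMatrix(snp_ids=snp_subset, r=0.5 * (r + r.T))
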