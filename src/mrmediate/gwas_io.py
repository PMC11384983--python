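"""Reading, writing and validation of GWAS summary-statistic tables.

The whole pipeline trades in one currency: a per-SNP association table with
canonical columns ``snp, chr, pos, ea, oa, eaf, beta, se, pval, n``.
Consortium files use different headers, so :func:`read_sumstats` accepts a
column map; everything downstream sees only the canonical names.

Validation is row-wise and destructive-but-audited: rows violating the record
invariants (non-ACGT or identical alleles, se <= 0, p outside (0, 1],
position < 1, allele frequency outside [0, 1]) are dropped and counted, never
silently repaired.  Missing ``eaf``, ``chr``, ``pos`` or ``n`` are tolerated
(some microbiome consortia omit them); missing ``beta`` or ``se`` are not.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._utils import VALID_BASES
from .errors import ConfigurationError, EmptyInputError

logger = logging.getLogger(__name__)

#: canonical column order of the on-disk dialect
CANONICAL_COLUMNS = ["snp", "chr", "pos", "ea", "oa", "eaf", "beta", "se", "pval", "n"]

#: columns that must be present (directly or via column_map) in any input
REQUIRED_COLUMNS = ["snp", "ea", "oa", "beta", "se", "pval"]

_STRING_COLS = ["snp", "chr", "ea", "oa"]
_FLOAT_COLS = ["eaf", "beta", "se", "pval"]
_INT_COLS = ["pos", "n"]


@dataclass
class SummaryStatTable:
    """Validated per-SNP summary statistics for one trait.

    ``df`` holds the canonical columns in canonical order, unique by ``snp``.
    ``trait_type`` records whether ``beta`` is on a continuous or log-odds
    scale; it is carried for presentation, not branching logic.
    """

    trait_id: str
    df: pd.DataFrame
    trait_type: str = "continuous"
    n_dropped: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.trait_id:
            raise ValueError("trait_id must be non-empty")
        if self.trait_type not in ("continuous", "binary"):
            raise ValueError(f"unknown trait_type {self.trait_type!r}")
        missing = [c for c in CANONICAL_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"table missing canonical columns {missing}")
        self.df = self.df[CANONICAL_COLUMNS].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def snp_ids(self) -> pd.Series:
        return self.df["snp"]

    def subset(self, mask_or_ids) -> "SummaryStatTable":
        """New table restricted to a boolean mask or iterable of SNP ids."""
        if isinstance(mask_or_ids, (pd.Series, np.ndarray, list)) and len(
            mask_or_ids
        ) == len(self.df) and pd.api.types.is_bool_dtype(np.asarray(mask_or_ids)):
            sub = self.df.loc[np.asarray(mask_or_ids)]
        else:
            sub = self.df[self.df["snp"].isin(set(mask_or_ids))]
        return SummaryStatTable(self.trait_id, sub.copy(), self.trait_type)

    def equals(self, other: "SummaryStatTable", sig_digits: int = 10) -> bool:
        """Field-for-field equality, floats compared to ``sig_digits``."""
        if self.trait_id != other.trait_id or len(self) != len(other):
            return False
        a, b = self.df, other.df
        for col in _STRING_COLS + _INT_COLS:
            if not a[col].fillna("NA").astype(str).equals(
                b[col].fillna("NA").astype(str)
            ):
                return False
        for col in _FLOAT_COLS:
            x, y = a[col].to_numpy(float), b[col].to_numpy(float)
            both_nan = np.isnan(x) & np.isnan(y)
            # half an ulp at sig_digits significant decimal digits
            tol = 0.5 * 10.0 ** (1 - sig_digits)
            with np.errstate(divide="ignore", invalid="ignore"):
                rel = np.abs(x - y) <= tol * np.maximum(np.abs(x), np.abs(y))
            if not np.all(both_nan | rel):
                return False
        return True


def _coerce_dtypes(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    for col in _STRING_COLS:
        df[col] = df[col].astype("string")
    df["ea"] = df["ea"].str.upper()
    df["oa"] = df["oa"].str.upper()
    for col in _FLOAT_COLS:
        df[col] = pd.to_numeric(df[col], errors="coerce")
    for col in _INT_COLS:
        df[col] = pd.to_numeric(df[col], errors="coerce").astype("Int64")
    return df


def validate_records(df: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Drop rows violating the record invariants; return (clean, drop counts).

    Never mutates passing rows.  Duplicate SNP ids keep the first occurrence.
    """
    df = _coerce_dtypes(df)
    bases = list(VALID_BASES)
    reasons = {}
    ok = pd.Series(True, index=df.index)

    def drop(name: str, bad: pd.Series) -> None:
        bad = bad & ok
        reasons[name] = int(bad.sum())
        ok[bad] = False

    drop("missing_core", df[["snp", "ea", "oa", "beta", "se", "pval"]].isna().any(axis=1))
    drop("bad_allele", ~(df["ea"].isin(bases) & df["oa"].isin(bases)) | (df["ea"] == df["oa"]))
    drop("nonpositive_se", ~(df["se"] > 0) | ~np.isfinite(df["se"].to_numpy(float)))
    drop("bad_beta", ~np.isfinite(df["beta"].to_numpy(float)))
    drop("bad_pval", ~((df["pval"] > 0) & (df["pval"] <= 1)))
    drop("bad_pos", df["pos"].notna() & (df["pos"] < 1))
    drop("bad_eaf", df["eaf"].notna() & ~((df["eaf"] >= 0) & (df["eaf"] <= 1)))
    drop("duplicate_snp", df["snp"].duplicated(keep="first"))

    clean = df.loc[ok].reset_index(drop=True)
    reasons = {k: v for k, v in reasons.items() if v}
    if reasons:
        logger.warning("validation dropped rows: %s", reasons)
    return clean, reasons


def read_sumstats(
    path: str | Path,
    column_map: dict[str, str] | None = None,
    trait_id: str | None = None,
    trait_type: str = "continuous",
    sep: str = "\t",
) -> SummaryStatTable:
    """Read a delimited summary-statistics file into a validated table.

    Parameters
    ----------
    column_map
        Maps canonical names to the file's headers, e.g.
        ``{"snp": "rsid", "ea": "ALLELE1"}``.  Canonical-named columns need no
        entry.  Must cover ``snp, ea, oa, beta, se, pval``.
    trait_id
        Defaults to the file stem.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep=sep, na_values=["NA", "nan", ""], dtype="object")
    if column_map:
        missing_src = [v for v in column_map.values() if v not in raw.columns]
        if missing_src:
            raise ConfigurationError(
                f"column_map names absent from {path.name}: {missing_src}"
            )
        raw = raw.rename(columns={v: k for k, v in column_map.items()})
    missing = [c for c in REQUIRED_COLUMNS if c not in raw.columns]
    if missing:
        raise ConfigurationError(f"{path.name} lacks mandatory columns {missing}")
    for col in CANONICAL_COLUMNS:
        if col not in raw.columns:
            raw[col] = pd.NA
    clean, reasons = validate_records(raw[CANONICAL_COLUMNS])
    if clean.empty:
        raise EmptyInputError(f"{path.name}: zero valid rows after validation")
    return SummaryStatTable(
        trait_id or path.stem, clean, trait_type, n_dropped=reasons
    )


def write_sumstats(table: SummaryStatTable, path: str | Path) -> Path:
    """Write the canonical tab-delimited dialect; ``read_sumstats`` inverts it.

    Floats are rendered with %.10g so write -> read -> write is byte-stable.
    """
    if len(table) == 0:
        raise EmptyInputError("refusing to write an empty table")
    path = Path(path)
    table.df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.10g")
    return path


def table_from_records(
    trait_id: str, records: list[dict], trait_type: str = "continuous"
) -> SummaryStatTable:
    """Build a validated table from in-memory record dicts (testing/synthesis)."""
    df = pd.DataFrame.from_records(records)
    for col in CANONICAL_COLUMNS:
        if col not in df.columns:
            df[col] = pd.NA
    clean, reasons = validate_records(df[CANONICAL_COLUMNS])
    if clean.empty:
        raise EmptyInputError(f"{trait_id}: zero valid records")
    return SummaryStatTable(trait_id, clean, trait_type, n_dropped=reasons)
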