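"""Instrumental-variable selection for summary-data MR.

Four-stage filter, applied in fixed order:

1. significance threshold (p < p_threshold, strict);
2. greedy LD clumping (lowest-p index SNP claims every SNP on the same
   chromosome within the window whose r² with it exceeds ``clump_r2``);
3. removal of SNPs on a user-supplied confounder exclusion list;
4. weak-instrument filter F = (beta/se)² > f_min, strict.

Palindromic SNPs are *not* handled here — they fall out during allele
harmonization, matching the order of operations of the conventional
two-sample MR toolchain.

LD is abstracted behind a pairwise r² provider, because which reference panel
(if any) backs the r² estimates is an input to the analysis, not a property
of the algorithm: a dense table for toys, a block-diagonal synthetic model
for simulations, anything callable for real panels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Protocol

import numpy as np
import pandas as pd

from .errors import EmptyInstrumentSetError
from .gwas_io import SummaryStatTable

logger = logging.getLogger(__name__)

#: default reverse-direction threshold (binary outcome used as the exposure)
REVERSE_P_THRESHOLD = 5e-6


@dataclass(frozen=True)
class SelectionParams:
    """Tunables of the IV selection pipeline.

    Defaults follow common practice for under-powered exposure GWAS:
    suggestive threshold 1e-5, aggressive clumping (r² 0.001 within
    10,000 kb), F > 10.
    """

    p_threshold: float = 1e-5
    clump_r2: float = 0.001
    clump_window_kb: float = 10_000.0
    f_min: float = 10.0
    exclusion_ids: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self):
        if not 0.0 < self.p_threshold <= 1.0:
            raise ValueError("p_threshold must lie in (0, 1]")
        if not 0.0 <= self.clump_r2 <= 1.0:
            raise ValueError("clump_r2 must lie in [0, 1]")
        if self.clump_window_kb <= 0:
            raise ValueError("clump_window_kb must be > 0")
        if self.f_min < 0:
            raise ValueError("f_min must be >= 0")


class LDProvider(Protocol):
    """Anything that answers pairwise r² queries."""

    def r2(self, snp_a: str, snp_b: str) -> float: ...


class ZeroLD:
    """All SNPs independent (r² = 0 off-diagonal)."""

    def r2(self, snp_a: str, snp_b: str) -> float:
        return 1.0 if snp_a == snp_b else 0.0


class TableLD:
    """r² looked up from an explicit symmetric pair table; 0 when absent."""

    def __init__(self, pairs: Mapping[tuple[str, str], float]):
        self._r2 = {}
        for (a, b), v in pairs.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"r2 out of [0,1] for pair ({a},{b}): {v}")
            self._r2[(a, b)] = v
            self._r2[(b, a)] = v

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TableLD":
        """3-column TSV: snp_a, snp_b, r2 (header required)."""
        df = pd.read_csv(path, sep="\t")
        return cls(
            {(r.snp_a, r.snp_b): float(r.r2) for r in df.itertuples(index=False)}
        )

    def r2(self, snp_a: str, snp_b: str) -> float:
        if snp_a == snp_b:
            return 1.0
        return self._r2.get((snp_a, snp_b), 0.0)


class BlockLD:
    """Block-diagonal toy LD: constant r² within a block, 0 between."""

    def __init__(self, blocks: Mapping[str, object], within_r2: float = 0.9):
        if not 0.0 <= within_r2 <= 1.0:
            raise ValueError("within_r2 must lie in [0, 1]")
        self._block = dict(blocks)
        self._within = within_r2

    def r2(self, snp_a: str, snp_b: str) -> float:
        if snp_a == snp_b:
            return 1.0
        ba, bb = self._block.get(snp_a), self._block.get(snp_b)
        if ba is not None and ba == bb:
            return self._within
        return 0.0


@dataclass
class InstrumentSet:
    """SNPs surviving selection for one exposure, with audit trail."""

    trait_id: str
    table: SummaryStatTable
    f_stats: pd.Series  # indexed by snp id
    audit: dict[str, int]
    params: SelectionParams

    @property
    def n_snp(self) -> int:
        return len(self.table)

    @property
    def mean_f(self) -> float:
        return float(self.f_stats.mean())


def f_statistic(beta, se):
    """Instrument-strength F = (beta/se)²; accepts scalars or arrays."""
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise ValueError("se must be > 0 for an F-statistic")
    out = (beta / se) ** 2
    return float(out) if out.ndim == 0 else out


def threshold_select(table: SummaryStatTable, p_threshold: float) -> SummaryStatTable:
    """Keep exactly the records with p < p_threshold (strict), order kept."""
    keep = table.df["pval"] < p_threshold
    if not keep.any():
        logger.warning(
            "trait %s: no SNP passes p < %g", table.trait_id, p_threshold
        )
    return SummaryStatTable(table.trait_id, table.df.loc[keep].copy(), table.trait_type)


def exclude_confounder_snps(
    table: SummaryStatTable, exclusion_ids
) -> SummaryStatTable:
    """Drop SNPs on the confounder exclusion list; removals logged per id."""
    excl = set(exclusion_ids)
    hit = table.df["snp"].isin(excl)
    for sid in table.df.loc[hit, "snp"]:
        logger.info("trait %s: SNP %s removed (confounder list)", table.trait_id, sid)
    return SummaryStatTable(table.trait_id, table.df.loc[~hit].copy(), table.trait_type)


def ld_clump(
    table: SummaryStatTable, ld: LDProvider, params: SelectionParams
) -> SummaryStatTable:
    """Greedy p-value clumping; output is the index SNPs, position-sorted.

    Ties on p broken by (chr, pos, snp) lexicographic order so the result is
    independent of input record order.  Records without a position form their
    own clump (they can neither claim nor be claimed over a distance).
    """
    df = table.df
    order = df.assign(
        _pos=df["pos"].astype("float"), _chr=df["chr"].astype(str)
    ).sort_values(["pval", "_chr", "_pos", "snp"], kind="mergesort")
    claimed: set[str] = set()
    index_snps: list[str] = []
    window_bp = params.clump_window_kb * 1000.0
    rows = list(order.itertuples(index=False))
    for row in rows:
        if row.snp in claimed:
            continue
        index_snps.append(row.snp)
        claimed.add(row.snp)
        if pd.isna(row.pos):
            logger.warning("SNP %s lacks a position; treated as its own clump", row.snp)
            continue
        for other in rows:
            if other.snp in claimed or pd.isna(other.pos):
                continue
            if str(other.chr) != str(row.chr):
                continue
            if abs(float(other.pos) - float(row.pos)) > window_bp:
                continue
            if ld.r2(row.snp, other.snp) > params.clump_r2:
                claimed.add(other.snp)
    keep = df["snp"].isin(index_snps)
    out = df.loc[keep].copy()
    out = out.sort_values(
        ["chr", "pos", "snp"], key=lambda s: s.astype(str) if s.name == "chr" else s
    )
    return SummaryStatTable(table.trait_id, out, table.trait_type)


def build_instrument_set(
    table: SummaryStatTable,
    ld: LDProvider | None = None,
    params: SelectionParams | None = None,
) -> InstrumentSet:
    """Run the full selection pipeline and return survivors with audit."""
    ld = ld or ZeroLD()
    params = params or SelectionParams()
    audit: dict[str, int] = {}

    stages = [
        ("threshold", lambda t: threshold_select(t, params.p_threshold)),
        ("clump", lambda t: ld_clump(t, ld, params)),
        ("confounder", lambda t: exclude_confounder_snps(t, params.exclusion_ids)),
    ]
    current = table
    for name, fn in stages:
        nxt = fn(current)
        audit[name] = len(current) - len(nxt)
        if len(nxt) == 0:
            raise EmptyInstrumentSetError(table.trait_id, name)
        current = nxt

    f = f_statistic(current.df["beta"].to_numpy(), current.df["se"].to_numpy())
    strong = f > params.f_min
    audit["weak"] = int((~strong).sum())
    if not strong.any():
        raise EmptyInstrumentSetError(table.trait_id, "weak")
    survivors = SummaryStatTable(
        table.trait_id, current.df.loc[strong].copy(), table.trait_type
    )
    f_stats = pd.Series(f[strong], index=survivors.df["snp"].to_numpy(), name="F")
    logger.info(
        "trait %s: %d instruments (mean F %.1f), audit %s",
        table.trait_id, len(survivors), float(f_stats.mean()), audit,
    )
    return InstrumentSet(table.trait_id, survivors, f_stats, audit, params)


def read_exclusion_list(path: str | Path) -> frozenset[str]:
    """One SNP id per line; blank lines and '#' comments ignored."""
    ids = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            ids.append(line)
    return frozenset(ids)
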