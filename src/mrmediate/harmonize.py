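"""Allele harmonization of exposure and outcome summary statistics.

Two GWAS report each SNP against an arbitrary choice of effect allele and
strand.  Before any Wald ratio is meaningful the outcome effect must be
expressed per copy of the *exposure's* effect allele:

* same alleles, same order          -> kept as-is;
* same alleles, swapped             -> outcome beta negated, eaf complemented;
* same only after strand complement -> complement, then align as above;
* palindromic (A/T or C/G)          -> dropped (strand is unresolvable from
  alleles alone; no frequency-based rescue is attempted, by design);
* anything else                     -> dropped as incompatible.

Matching is by SNP identifier only — consortium tables are merged on rsID,
not position.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._utils import COMPLEMENT, is_palindromic
from .errors import HarmonizationError
from .gwas_io import SummaryStatTable
from .instruments import InstrumentSet

ACTION_KEPT = "kept-as-is"
ACTION_FLIPPED = "outcome-flipped"
ACTION_STRAND = "strand-corrected"
DROP_PALINDROMIC = "dropped-palindromic"
DROP_INCOMPATIBLE = "dropped-incompatible"
DROP_UNMATCHED = "dropped-unmatched"

PAIR_COLUMNS = ["snp", "beta_exp", "se_exp", "beta_out", "se_out", "action"]


@dataclass
class HarmonizedSet:
    """Per-SNP (beta_exp, beta_out) pairs on a common effect-allele
    orientation — the input of every causal estimator."""

    exposure_id: str
    outcome_id: str
    pairs: pd.DataFrame  # PAIR_COLUMNS
    dropped: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["snp", "reason"])
    )

    def __post_init__(self):
        if len(self.pairs) == 0:
            raise HarmonizationError(
                f"no SNP pair survived harmonization of "
                f"{self.exposure_id!r} vs {self.outcome_id!r}"
            )
        if self.pairs["snp"].duplicated().any():
            raise HarmonizationError("duplicate SNP ids in harmonized pairs")
        bad = (self.pairs["se_exp"] <= 0) | (self.pairs["se_out"] <= 0)
        if bad.any():
            raise HarmonizationError("non-positive SE in harmonized pairs")
        self.pairs = self.pairs.reset_index(drop=True)

    @property
    def n_snp(self) -> int:
        return len(self.pairs)

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        p = self.pairs
        return (
            p["beta_exp"].to_numpy(float),
            p["se_exp"].to_numpy(float),
            p["beta_out"].to_numpy(float),
            p["se_out"].to_numpy(float),
        )

    @classmethod
    def from_arrays(
        cls,
        beta_exp,
        se_exp,
        beta_out,
        se_out,
        snp_ids=None,
        exposure_id: str = "exposure",
        outcome_id: str = "outcome",
    ) -> "HarmonizedSet":
        """Build directly from aligned effect arrays (tests, toy examples)."""
        beta_exp = np.asarray(beta_exp, float)
        if snp_ids is None:
            snp_ids = [f"snp{i + 1}" for i in range(len(beta_exp))]
        pairs = pd.DataFrame(
            {
                "snp": snp_ids,
                "beta_exp": beta_exp,
                "se_exp": np.asarray(se_exp, float),
                "beta_out": np.asarray(beta_out, float),
                "se_out": np.asarray(se_out, float),
                "action": ACTION_KEPT,
            }
        )
        return cls(exposure_id, outcome_id, pairs)

    def to_frame(self) -> pd.DataFrame:
        return self.pairs.copy()


def _complement_series(s: pd.Series) -> pd.Series:
    return s.map(COMPLEMENT)


def harmonize(
    exposure: InstrumentSet | SummaryStatTable,
    outcome: SummaryStatTable,
    drop_palindromic: bool = True,
) -> HarmonizedSet:
    """Pair exposure instruments with outcome records on a common orientation.

    The audit (``HarmonizedSet.dropped``) itemizes every exposure SNP that
    did not survive, with its reason, so attrition between merging and
    estimation is inspectable.
    """
    exp_table = exposure.table if isinstance(exposure, InstrumentSet) else exposure
    e = exp_table.df
    o = outcome.df.set_index("snp")

    kept_rows: list[dict] = []
    dropped_rows: list[dict] = []
    for row in e.itertuples(index=False):
        if row.snp not in o.index:
            dropped_rows.append({"snp": row.snp, "reason": DROP_UNMATCHED})
            continue
        orow = o.loc[row.snp]
        if drop_palindromic and is_palindromic(row.ea, row.oa):
            dropped_rows.append({"snp": row.snp, "reason": DROP_PALINDROMIC})
            continue
        ea_o, oa_o = orow["ea"], orow["oa"]
        beta_out = float(orow["beta"])
        if (ea_o, oa_o) == (row.ea, row.oa):
            action = ACTION_KEPT
        elif (ea_o, oa_o) == (row.oa, row.ea):
            action = ACTION_FLIPPED
            beta_out = -beta_out
        else:
            cea, coa = COMPLEMENT.get(ea_o), COMPLEMENT.get(oa_o)
            if (cea, coa) == (row.ea, row.oa):
                action = ACTION_STRAND
            elif (cea, coa) == (row.oa, row.ea):
                action = ACTION_STRAND
                beta_out = -beta_out
            else:
                dropped_rows.append({"snp": row.snp, "reason": DROP_INCOMPATIBLE})
                continue
        kept_rows.append(
            {
                "snp": row.snp,
                "beta_exp": float(row.beta),
                "se_exp": float(row.se),
                "beta_out": beta_out,
                "se_out": float(orow["se"]),
                "action": action,
            }
        )

    pairs = pd.DataFrame(kept_rows, columns=PAIR_COLUMNS)
    dropped = pd.DataFrame(dropped_rows, columns=["snp", "reason"])
    return HarmonizedSet(exp_table.trait_id, outcome.trait_id, pairs, dropped)
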