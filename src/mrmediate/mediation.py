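"""Bidirectional screening, two-step MR and product-method mediation.

The question the pipeline answers: does an exposure (a gut-microbiome genus
analogue) influence a binary outcome *through* a measurable mediator (a
serum-metabolite analogue)?  Three IVW estimates feed one line:

    beta0  total exposure→outcome effect   (exposure instruments)
    beta1  exposure→mediator effect        (exposure instruments)
    beta2  mediator→outcome effect         (mediator's own instruments)

Product method:  indirect = beta1 * beta2, and the mediation proportion

    P(%) = 100 * (beta1 * beta2) / beta0,

with beta0 the *total* effect.  A delta-method SE for the indirect effect,
sqrt(beta1² se2² + beta2² se1²), and an approximate propagated CI for P are
reported as extensions — the proportion itself is exactly the ratio above.

Directionality is established first: an exposure enters mediation analysis
only if the forward IVW is significant while the reverse direction
(outcome used as the exposure, with its own instruments at a laxer
threshold suitable for an under-powered case-control GWAS) is not.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import pandas as pd

from ._utils import Z95
from .errors import MRError
from .estimators import MREstimate, ivw
from .gwas_io import SummaryStatTable
from .harmonize import harmonize
from .instruments import (
    REVERSE_P_THRESHOLD,
    LDProvider,
    SelectionParams,
    build_instrument_set,
)

logger = logging.getLogger(__name__)


def mediation_proportion(beta0: float, beta1: float, beta2: float) -> float:
    """Product-method mediation proportion, in percent: 100·(β1·β2)/β0.

    The sign is preserved; a negative value means the indirect and total
    effects point in opposite directions (inconsistent mediation).
    """
    if beta0 == 0.0:
        raise ValueError("mediation proportion undefined for beta0 = 0")
    return 100.0 * (beta1 * beta2) / beta0


@dataclass
class MediationLine:
    """One exposure→mediator→outcome chain with its product-method summary."""

    exposure_id: str
    mediator_id: str
    outcome_id: str
    total: MREstimate  # beta0
    step1: MREstimate  # beta1
    step2: MREstimate  # beta2

    @property
    def beta0(self) -> float:
        return self.total.beta

    @property
    def beta1(self) -> float:
        return self.step1.beta

    @property
    def beta2(self) -> float:
        return self.step2.beta

    @property
    def indirect(self) -> float:
        return self.beta1 * self.beta2

    @property
    def se_indirect(self) -> float:
        """Delta-method SE of the indirect effect (independent samples)."""
        return math.sqrt(
            self.beta1**2 * self.step2.se**2 + self.beta2**2 * self.step1.se**2
        )

    @property
    def proportion(self) -> float:
        return mediation_proportion(self.beta0, self.beta1, self.beta2)

    @property
    def proportion_se(self) -> float:
        """Approximate SE of P by delta method on the ratio indirect/beta0."""
        ind = self.indirect
        if ind == 0.0:
            return 100.0 * self.se_indirect / abs(self.beta0)
        rel = (self.se_indirect / ind) ** 2 + (self.total.se / self.beta0) ** 2
        return abs(self.proportion) * math.sqrt(rel)

    @property
    def proportion_ci(self) -> tuple[float, float]:
        p, s = self.proportion, self.proportion_se
        return (p - Z95 * s, p + Z95 * s)

    @property
    def consistent(self) -> bool:
        """True when the indirect effect shares the total effect's sign."""
        return math.copysign(1.0, self.indirect) == math.copysign(1.0, self.beta0)

    def to_row(self) -> dict:
        return {
            "exposure": self.exposure_id,
            "mediator": self.mediator_id,
            "outcome": self.outcome_id,
            "beta0": self.beta0, "se0": self.total.se, "p0": self.total.pval,
            "beta1": self.beta1, "se1": self.step1.se, "p1": self.step1.pval,
            "beta2": self.beta2, "se2": self.step2.se, "p2": self.step2.pval,
            "or0": self.total.or_, "or1": self.step1.or_, "or2": self.step2.or_,
            "indirect": self.indirect,
            "se_indirect": self.se_indirect,
            "proportion_pct": self.proportion,
            "proportion_se_pct": self.proportion_se,
            "consistent": self.consistent,
        }


@dataclass
class ScreenResult:
    """Forward and reverse IVW for one exposure/outcome pair."""

    forward: MREstimate | None
    reverse: MREstimate | None
    passes: bool
    reason: str = ""


def _ivw_edge(
    exp_table: SummaryStatTable,
    out_table: SummaryStatTable,
    ld: LDProvider | None,
    params: SelectionParams,
    ivw_variant: str = "random",
) -> MREstimate:
    iv = build_instrument_set(exp_table, ld, params)
    h = harmonize(iv, out_table)
    return ivw(h, variant=ivw_variant)


def bidirectional_screen(
    exp_table: SummaryStatTable,
    out_table: SummaryStatTable,
    ld: LDProvider | None = None,
    fwd_params: SelectionParams | None = None,
    rev_params: SelectionParams | None = None,
    alpha_fwd: float = 0.05,
    alpha_rev: float = 0.05,
) -> ScreenResult:
    """Directionality screen: forward IVW significant, reverse IVW not.

    The reverse direction treats the outcome as the exposure, selecting its
    instruments at a laxer default threshold (5e-6) appropriate to a small
    case-control GWAS.
    """
    fwd_params = fwd_params or SelectionParams()
    rev_params = rev_params or SelectionParams(p_threshold=REVERSE_P_THRESHOLD)
    forward = reverse = None
    try:
        forward = _ivw_edge(exp_table, out_table, ld, fwd_params)
    except MRError as err:
        return ScreenResult(None, None, False, f"forward inestimable: {err}")
    try:
        reverse = _ivw_edge(out_table, exp_table, ld, rev_params)
    except MRError as err:
        return ScreenResult(forward, None, False, f"reverse inestimable: {err}")
    passes = forward.pval < alpha_fwd and reverse.pval >= alpha_rev
    reason = "" if passes else (
        "forward not significant" if forward.pval >= alpha_fwd
        else "reverse direction significant"
    )
    return ScreenResult(forward, reverse, passes, reason)


def two_step(
    exp_table: SummaryStatTable,
    med_table: SummaryStatTable,
    out_table: SummaryStatTable,
    ld: LDProvider | None = None,
    exp_params: SelectionParams | None = None,
    med_params: SelectionParams | None = None,
    ivw_variant: str = "random",
) -> MediationLine:
    """Estimate one full mediation line by two-step MR.

    Exposure instruments give the total effect (beta0) and the step-1
    exposure→mediator effect (beta1); the mediator's own instruments give
    the step-2 mediator→outcome effect (beta2).  Instrument sets are not
    de-overlapped.
    """
    exp_params = exp_params or SelectionParams()
    med_params = med_params or SelectionParams()
    exp_iv = build_instrument_set(exp_table, ld, exp_params)
    total = ivw(harmonize(exp_iv, out_table), variant=ivw_variant)
    step1 = ivw(harmonize(exp_iv, med_table), variant=ivw_variant)
    med_iv = build_instrument_set(med_table, ld, med_params)
    step2 = ivw(harmonize(med_iv, out_table), variant=ivw_variant)
    return MediationLine(
        exp_table.trait_id, med_table.trait_id, out_table.trait_id,
        total, step1, step2,
    )


def screen_mediators(
    candidate_mediators: dict[str, SummaryStatTable],
    exp_table: SummaryStatTable,
    out_table: SummaryStatTable,
    ld: LDProvider | None = None,
    exp_params: SelectionParams | None = None,
    med_params: SelectionParams | None = None,
    alpha: float = 0.05,
) -> tuple[list[MediationLine], pd.DataFrame]:
    """Keep mediators with significant exposure→mediator AND mediator→outcome
    edges (nominal alpha, no multiplicity correction by default).

    Returns the kept lines and an audit frame covering every candidate,
    including those that failed or were inestimable.
    """
    kept: list[MediationLine] = []
    audit_rows = []
    for med_id, med_table in candidate_mediators.items():
        try:
            line = two_step(
                exp_table, med_table, out_table, ld, exp_params, med_params
            )
        except MRError as err:
            audit_rows.append(
                {"mediator": med_id, "kept": False, "reason": str(err)}
            )
            continue
        ok = line.step1.pval < alpha and line.step2.pval < alpha
        audit_rows.append(
            {
                "mediator": med_id,
                "kept": ok,
                "reason": "" if ok else "edge not significant",
                "p1": line.step1.pval,
                "p2": line.step2.pval,
                "proportion_pct": line.proportion,
            }
        )
        if ok:
            kept.append(line)
    audit = pd.DataFrame(audit_rows)
    return kept, audit


def lines_to_frame(lines: list[MediationLine]) -> pd.DataFrame:
    cols = list(MediationLine.to_row(lines[0]).keys()) if lines else [
        "exposure", "mediator", "outcome", "proportion_pct",
    ]
    return pd.DataFrame([ln.to_row() for ln in lines], columns=cols)
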