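"""Causal-effect estimators for two-sample summary-data MR.

All five methods consume a :class:`~mrmediate.harmonize.HarmonizedSet` of
per-SNP (beta_exp, beta_out) pairs and return an :class:`MREstimate` whose
odds-ratio presentation (exp(beta), 95% CI) is filled automatically.

* Wald ratio      r_j = beta_out,j / beta_exp,j, first-order
                  se(r_j) = se_out,j / |beta_exp,j|.
* IVW             weighted regression of beta_out on beta_exp through the
                  origin, weights 1/se_out²; the default multiplicative
                  random-effects variant scales the fixed SE by
                  max(1, sqrt(Q/(J-1))).
* MR-Egger        same regression with a free intercept; a non-zero
                  intercept estimates the average directional pleiotropy.
                  Inference uses t with J-2 df and SEs scaled by
                  max(1, sqrt(RSS_w/(J-2))).
* Weighted median consistent when >50% of the weight comes from valid
                  instruments; SE by seeded parametric bootstrap.
* Mode (simple /  kernel-density argmax of the Wald ratios (ZEMPA-style
  weighted)       plurality-valid assumption); SE by seeded bootstrap.

Different methods lean on different identifying assumptions, which is
exactly why all of them are computed: agreement across them is the
sensitivity argument.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from ._utils import Z95
from .errors import DegenerateInstrumentError, InsufficientInstrumentsError
from .harmonize import HarmonizedSet

logger = logging.getLogger(__name__)

METHOD_MIN_SNPS = {
    "wald": 1,
    "ivw": 1,
    "egger": 3,
    "weighted_median": 3,
    "simple_mode": 3,
    "weighted_mode": 3,
}


@dataclass
class MREstimate:
    """One method's causal estimate on the log scale, with OR presentation."""

    method: str
    beta: float
    se: float
    pval: float
    n_snp: int
    or_: float = float("nan")
    ci_low: float = float("nan")
    ci_high: float = float("nan")

    def __post_init__(self):
        if math.isnan(self.or_):
            self.or_ = math.exp(self.beta)
            self.ci_low = math.exp(self.beta - Z95 * self.se)
            self.ci_high = math.exp(self.beta + Z95 * self.se)


def to_odds_scale(e: MREstimate) -> MREstimate:
    """Copy with OR and 95% CI refreshed from (beta, se); beta/se unchanged."""
    return replace(
        e,
        or_=math.exp(e.beta),
        ci_low=math.exp(e.beta - Z95 * e.se),
        ci_high=math.exp(e.beta + Z95 * e.se),
    )


@dataclass
class WaldRatios:
    """Per-SNP causal ratios with first-order SEs and inverse-variance
    weights; the shared building block of median and mode methods."""

    snp: np.ndarray
    ratio: np.ndarray
    se: np.ndarray
    weight: np.ndarray


def wald_ratios(h: HarmonizedSet) -> WaldRatios:
    bx, _, by, sy = h.arrays()
    zero = bx == 0.0
    if zero.any():
        bad = h.pairs.loc[zero, "snp"].iloc[0]
        raise DegenerateInstrumentError(
            f"SNP {bad} has beta_exp = 0; Wald ratio undefined"
        )
    ratio = by / bx
    se = sy / np.abs(bx)
    return WaldRatios(h.pairs["snp"].to_numpy(), ratio, se, 1.0 / se**2)


def _require(h: HarmonizedSet, method: str, minimum: int) -> None:
    if h.n_snp < minimum:
        raise InsufficientInstrumentsError(method, minimum, h.n_snp)


def _norm_p(beta: float, se: float) -> float:
    return float(2.0 * stats.norm.sf(abs(beta) / se)) if se > 0 else 0.0


def ivw_fixed_components(h: HarmonizedSet) -> tuple[float, float, float]:
    """(slope, fixed SE, Cochran Q) of the origin-constrained weighted fit."""
    bx, _, by, sy = h.arrays()
    w = 1.0 / sy**2
    sxx = float(np.sum(w * bx * bx))
    if sxx == 0.0:
        raise DegenerateInstrumentError("all beta_exp are zero")
    beta = float(np.sum(w * bx * by)) / sxx
    se_fixed = sxx**-0.5
    q = float(np.sum(w * (by - beta * bx) ** 2))
    return beta, se_fixed, q


def ivw(h: HarmonizedSet, variant: str = "random") -> MREstimate:
    """Inverse-variance-weighted estimate; the pipeline's primary method.

    ``variant='random'`` (default) is the multiplicative random-effects
    model: under-dispersion never shrinks the SE below the fixed-effect one.
    With a single SNP the estimate reduces to that SNP's Wald ratio and the
    random variant falls back to fixed.
    """
    if variant not in ("fixed", "random"):
        raise ValueError(f"unknown IVW variant {variant!r}")
    _require(h, "ivw", 1)
    beta, se, q = ivw_fixed_components(h)
    j = h.n_snp
    if variant == "random":
        if j == 1:
            logger.warning("IVW random-effects with J = 1; falling back to fixed")
        else:
            se *= max(1.0, math.sqrt(q / (j - 1)))
    return MREstimate("ivw", beta, se, _norm_p(beta, se), j)


@dataclass
class EggerResult:
    slope: MREstimate
    intercept: MREstimate


def mr_egger(h: HarmonizedSet) -> EggerResult:
    """Weighted regression with a free intercept (directional pleiotropy).

    Orientation convention: exposure effects are made non-negative first
    (flipping the paired outcome effects), so the intercept's sign is
    interpretable as the average pleiotropic effect per instrument.
    """
    _require(h, "egger", 3)
    bx, _, by, sy = h.arrays()
    flip = np.sign(bx)
    flip[flip == 0] = 1.0
    x = bx * flip
    y = by * flip
    w = 1.0 / sy**2

    # weighted least squares via the normal equations on the 2-column design
    sw = w.sum()
    swx = float(np.sum(w * x))
    swy = float(np.sum(w * y))
    swxx = float(np.sum(w * x * x))
    swxy = float(np.sum(w * x * y))
    det = sw * swxx - swx * swx
    if det <= 0:
        raise DegenerateInstrumentError("exposure effects are collinear/constant")
    slope = (sw * swxy - swx * swy) / det
    intercept = (swxx * swy - swx * swxy) / det

    j = h.n_snp
    resid = y - intercept - slope * x
    rss = float(np.sum(w * resid**2))
    scale = max(1.0, math.sqrt(rss / (j - 2)))
    se_slope = math.sqrt(sw / det) * scale
    se_int = math.sqrt(swxx / det) * scale
    p_slope = float(2.0 * stats.t.sf(abs(slope) / se_slope, df=j - 2))
    p_int = float(2.0 * stats.t.sf(abs(intercept) / se_int, df=j - 2))
    return EggerResult(
        slope=MREstimate("egger", slope, se_slope, p_slope, j),
        intercept=MREstimate("egger_intercept", intercept, se_int, p_int, j),
    )


def _weighted_median_point(ratio: np.ndarray, weight: np.ndarray) -> float:
    order = np.argsort(ratio, kind="mergesort")
    r = ratio[order]
    w = weight[order]
    p = (np.cumsum(w) - 0.5 * w) / w.sum()
    return float(np.interp(0.5, p, r))


def _boot_draws(h: HarmonizedSet, n_boot: int, rng: np.random.Generator):
    bx, sx, by, sy = h.arrays()
    bx_d = bx + sx * rng.standard_normal((n_boot, h.n_snp))
    by_d = by + sy * rng.standard_normal((n_boot, h.n_snp))
    # a resampled exposure effect of exactly 0 has probability 0; guard anyway
    bx_d[bx_d == 0.0] = 1e-300
    return bx_d, by_d, sy


def weighted_median(
    h: HarmonizedSet, n_boot: int = 1000, seed: int = 0
) -> MREstimate:
    """Penalised-free weighted median of the Wald ratios.

    The point estimate interpolates the inverse-variance-weighted empirical
    CDF of the ordered ratios to probability 0.5; the SE is the standard
    deviation of the estimate under a parametric bootstrap that redraws
    (beta_exp, beta_out) from their sampling normals.
    """
    _require(h, "weighted_median", 3)
    wr = wald_ratios(h)
    est = _weighted_median_point(wr.ratio, wr.weight)

    rng = np.random.default_rng(seed)
    bx_d, by_d, sy = _boot_draws(h, n_boot, rng)
    ratios = by_d / bx_d
    weights = (bx_d / sy) ** 2
    boots = np.empty(n_boot)
    for b in range(n_boot):
        boots[b] = _weighted_median_point(ratios[b], weights[b])
    se = float(boots.std(ddof=1))
    return MREstimate("weighted_median", est, se, _norm_p(est, se), h.n_snp)


def _mode_bandwidth(ratio: np.ndarray, factor: float) -> float:
    j = len(ratio)
    sd = float(np.std(ratio, ddof=1))
    iqr = float(np.subtract(*np.percentile(ratio, [75, 25])))
    spread = min(sd, iqr / 1.349) if iqr > 0 else sd
    return factor * 0.9 * spread * j ** (-1 / 5)


def _mode_point(
    ratio: np.ndarray, weight: np.ndarray, bandwidth: float, grid_size: int = 512
) -> float:
    if bandwidth <= 0 or np.ptp(ratio) == 0.0:
        return float(ratio[0]) if np.ptp(ratio) == 0.0 else float(np.median(ratio))
    lo = ratio.min() - 3.0 * bandwidth
    hi = ratio.max() + 3.0 * bandwidth
    grid = np.linspace(lo, hi, grid_size)
    z = (grid[:, None] - ratio[None, :]) / bandwidth
    dens = (np.exp(-0.5 * z**2) * weight[None, :]).sum(axis=1)
    return float(grid[np.argmax(dens)])


def mode_estimate(
    h: HarmonizedSet,
    weighted: bool = False,
    bandwidth_factor: float = 1.0,
    n_boot: int = 1000,
    seed: int = 0,
) -> MREstimate:
    """Mode-based estimate: argmax of a normal-kernel density of the ratios.

    Bandwidth follows the modified Silverman rule
    ``factor * 0.9 * min(SD, IQR/1.349) * J^(-1/5)`` over the ratios.  The
    simple mode weighs every SNP equally; the weighted mode uses
    inverse-variance weights.  When every ratio coincides the estimate is
    that common ratio.
    """
    _require(h, "weighted_mode" if weighted else "simple_mode", 3)
    wr = wald_ratios(h)
    j = h.n_snp
    weight = wr.weight if weighted else np.ones(j)
    bw = _mode_bandwidth(wr.ratio, bandwidth_factor)
    est = _mode_point(wr.ratio, weight, bw)

    rng = np.random.default_rng(seed)
    bx_d, by_d, sy = _boot_draws(h, n_boot, rng)
    ratios = by_d / bx_d
    weights = (bx_d / sy) ** 2 if weighted else np.ones_like(ratios)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        bw_b = _mode_bandwidth(ratios[b], bandwidth_factor)
        boots[b] = _mode_point(ratios[b], weights[b], bw_b)
    se = float(boots.std(ddof=1))
    return MREstimate(
        "weighted_mode" if weighted else "simple_mode",
        est, se, _norm_p(est, se), j,
    )


def all_estimates(
    h: HarmonizedSet,
    ivw_variant: str = "random",
    n_boot: int = 1000,
    seed: int = 0,
) -> list[MREstimate]:
    """Every method the SNP count supports; warns about the ones it cannot.

    With a single harmonized SNP only the Wald ratio (reported under the IVW
    umbrella, to which it is identical at J = 1) is available.
    """
    out = [ivw(h, variant=ivw_variant)]
    if h.n_snp >= 3:
        out.append(mr_egger(h).slope)
        out.append(weighted_median(h, n_boot=n_boot, seed=seed))
        out.append(mode_estimate(h, weighted=False, n_boot=n_boot, seed=seed))
        out.append(mode_estimate(h, weighted=True, n_boot=n_boot, seed=seed))
    else:
        logger.warning(
            "%s vs %s: only %d SNP(s); Egger/median/mode need >= 3",
            h.exposure_id, h.outcome_id, h.n_snp,
        )
    return out


def estimates_to_frame(
    estimates: list[MREstimate], exposure_id: str = "", outcome_id: str = ""
) -> pd.DataFrame:
    """Tidy one-row-per-method table (the forest-plot shape)."""
    return pd.DataFrame(
        [
            {
                "exposure": exposure_id,
                "outcome": outcome_id,
                "method": e.method,
                "nsnp": e.n_snp,
                "beta": e.beta,
                "se": e.se,
                "pval": e.pval,
                "or": e.or_,
                "ci_low": e.ci_low,
                "ci_high": e.ci_high,
            }
            for e in estimates
        ]
    )
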