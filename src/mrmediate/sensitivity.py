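"""Heterogeneity, pleiotropy, outlier and influence diagnostics.

These are the checks that decide whether an IVW estimate can be trusted:

* Cochran's Q — do the per-SNP Wald ratios scatter more than their SEs
  allow?  (p < 0.05 flags heterogeneity.)
* MR-Egger intercept — is there *directional* pleiotropy on average?
* MR-PRESSO — residual-sum-of-squares simulation test: a global test for
  horizontal pleiotropy, per-SNP outlier flags (Bonferroni-corrected), a
  distortion test for whether removing the outliers moves the estimate, and
  an outlier-corrected IVW.
* leave-one-out — is any single SNP driving the result?
* plot tables — scatter / funnel / forest data, optionally rendered to SVG.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    DegenerateCorrectionError,
    InsufficientInstrumentsError,
    MRError,
)
from .estimators import (
    MREstimate,
    estimates_to_frame,
    ivw,
    ivw_fixed_components,
    mr_egger,
    wald_ratios,
)
from .harmonize import HarmonizedSet


@dataclass
class HeterogeneityResult:
    Q: float
    df: int
    pval: float

    @property
    def heterogeneous(self) -> bool:
        return self.pval < 0.05


def cochran_q(h: HarmonizedSet) -> HeterogeneityResult:
    """Cochran's Q of the Wald ratios about the fixed-effect IVW estimate."""
    if h.n_snp < 2:
        raise InsufficientInstrumentsError("cochran_q", 2, h.n_snp)
    _, _, q = ivw_fixed_components(h)
    df = h.n_snp - 1
    return HeterogeneityResult(q, df, float(stats.chi2.sf(q, df)))


@dataclass
class EggerInterceptResult:
    estimate: MREstimate  # the intercept, with its t-test p
    pleiotropy_detected: bool


def egger_intercept_test(h: HarmonizedSet) -> EggerInterceptResult:
    """Directional-pleiotropy test: Egger intercept with p < 0.05 flag."""
    intercept = mr_egger(h).intercept
    return EggerInterceptResult(intercept, intercept.pval < 0.05)


@dataclass
class PressoResult:
    rss_obs: float
    global_pval: float
    outlier_pvals: pd.Series  # per SNP, Monte-Carlo with +1 correction
    outliers: list[str]
    distortion_pval: float  # NaN when no outlier flagged
    corrected: MREstimate | None  # IVW after outlier removal
    n_sim: int
    seed: int


def _loo_slopes(x, y, w):
    """Leave-one-out origin-constrained WLS slopes, vectorized over j."""
    sxy = np.sum(w * x * y, axis=-1, keepdims=True)
    sxx = np.sum(w * x * x, axis=-1, keepdims=True)
    return (sxy - w * x * y) / (sxx - w * x * x)


def mr_presso(
    h: HarmonizedSet,
    n_sim: int = 1000,
    outlier_alpha: float = 0.05,
    seed: int = 0,
) -> PressoResult:
    """Residual-sum-of-squares simulation test for pleiotropic outliers.

    For each SNP j the expected outcome effect is beta(-j) * beta_exp,j,
    with beta(-j) the IVW slope fitted without SNP j; the observed weighted
    RSS of these residuals is compared against ``n_sim`` parametric
    replicates drawn under the no-pleiotropy model.  All Monte-Carlo
    p-values carry the +1 correction, so 1/(n_sim+1) is their floor.  The
    per-SNP outlier test is Bonferroni-corrected by J; the distortion test
    compares the observed shift from removing the flagged SNPs against the
    shift from removing 1000 random same-sized subsets.
    """
    j = h.n_snp
    if j < 4:
        raise InsufficientInstrumentsError("mr_presso", 4, j)
    rng = np.random.default_rng(seed)
    bx, sx, by, sy = h.arrays()
    w = 1.0 / sy**2
    snps = h.pairs["snp"].to_numpy()

    beta_loo = _loo_slopes(bx, by, w)[0]
    resid_obs = by - beta_loo * bx
    wres_obs = w * resid_obs**2
    rss_obs = float(wres_obs.sum())

    # parametric replicates under the per-SNP no-pleiotropy expectation
    x_sim = bx + sx * rng.standard_normal((n_sim, j))
    y_sim = beta_loo * bx + sy * rng.standard_normal((n_sim, j))
    beta_loo_sim = _loo_slopes(x_sim, y_sim, w)
    resid_sim = y_sim - beta_loo_sim * x_sim
    wres_sim = w * resid_sim**2
    rss_sim = wres_sim.sum(axis=1)

    global_pval = (1.0 + float((rss_sim >= rss_obs).sum())) / (n_sim + 1.0)
    outlier_p = (1.0 + (wres_sim >= wres_obs).sum(axis=0)) / (n_sim + 1.0)
    outlier_pvals = pd.Series(outlier_p, index=snps, name="presso_p")
    flagged = outlier_p < outlier_alpha / j
    outliers = list(snps[flagged])

    distortion_pval = float("nan")
    corrected = None
    if outliers:
        if flagged.all():
            raise DegenerateCorrectionError("every instrument flagged as outlier")
        keep = ~flagged
        sub = HarmonizedSet(
            h.exposure_id,
            h.outcome_id,
            h.pairs.loc[keep].reset_index(drop=True),
        )
        corrected = ivw(sub, variant="random")
        beta_full, _, _ = ivw_fixed_components(h)
        beta_corr, _, _ = ivw_fixed_components(sub)
        obs_d = abs(beta_full - beta_corr)
        k = int(flagged.sum())
        n_draw = 1000
        d_null = np.empty(n_draw)
        for b in range(n_draw):
            drop = rng.choice(j, size=k, replace=False)
            m = np.ones(j, bool)
            m[drop] = False
            sxy = float(np.sum(w[m] * bx[m] * by[m]))
            sxx = float(np.sum(w[m] * bx[m] * bx[m]))
            d_null[b] = abs(beta_full - sxy / sxx)
        distortion_pval = (1.0 + float((d_null >= obs_d).sum())) / (n_draw + 1.0)

    return PressoResult(
        rss_obs=rss_obs,
        global_pval=global_pval,
        outlier_pvals=outlier_pvals,
        outliers=outliers,
        distortion_pval=distortion_pval,
        corrected=corrected,
        n_sim=n_sim,
        seed=seed,
    )


@dataclass
class LeaveOneOutResult:
    rows: pd.DataFrame  # snp, beta, se, pval (IVW without that SNP)
    full: MREstimate
    influential: bool  # any sign change or loss/gain of nominal significance


def leave_one_out(h: HarmonizedSet, variant: str = "random") -> LeaveOneOutResult:
    """IVW re-fitted J times, each omitting one SNP."""
    j = h.n_snp
    if j < 2:
        raise InsufficientInstrumentsError("leave_one_out", 2, j)
    full = ivw(h, variant=variant)
    rows = []
    for i in range(j):
        sub = HarmonizedSet(
            h.exposure_id,
            h.outcome_id,
            h.pairs.drop(index=i).reset_index(drop=True),
        )
        e = ivw(sub, variant=variant)
        rows.append(
            {"snp": h.pairs.loc[i, "snp"], "beta": e.beta, "se": e.se, "pval": e.pval}
        )
    df = pd.DataFrame(rows)
    sign_change = bool((np.sign(df["beta"]) != np.sign(full.beta)).any())
    sig_full = full.pval < 0.05
    sig_change = bool(((df["pval"] < 0.05) != sig_full).any())
    return LeaveOneOutResult(df, full, sign_change or sig_change)


@dataclass
class PlotData:
    scatter: pd.DataFrame  # per-SNP effects with SEs
    fits: pd.DataFrame  # per-method slope (+ Egger intercept)
    funnel: pd.DataFrame  # ratio vs precision, with the IVW vertical
    forest: pd.DataFrame  # per-SNP Wald CIs plus summary rows


def plot_data(h: HarmonizedSet, estimates: list[MREstimate] | None = None) -> PlotData:
    """Assemble the scatter/funnel/forest tables behind the standard plots."""
    bx, sx, by, sy = h.arrays()
    wr = wald_ratios(h)
    if estimates is None:
        from .estimators import all_estimates

        estimates = all_estimates(h)
    scatter = pd.DataFrame(
        {"snp": wr.snp, "beta_exp": bx, "se_exp": sx, "beta_out": by, "se_out": sy}
    )
    fit_rows = []
    for e in estimates:
        intercept = 0.0
        if e.method == "egger":
            intercept = mr_egger(h).intercept.beta
        fit_rows.append({"method": e.method, "slope": e.beta, "intercept": intercept})
    fits = pd.DataFrame(fit_rows)
    ivw_beta = next(e.beta for e in estimates if e.method == "ivw")
    funnel = pd.DataFrame(
        {"snp": wr.snp, "ratio": wr.ratio, "precision": 1.0 / wr.se,
         "ivw_beta": ivw_beta}
    )
    from ._utils import Z95

    forest = pd.DataFrame(
        {
            "label": wr.snp,
            "beta": wr.ratio,
            "ci_low": wr.ratio - Z95 * wr.se,
            "ci_high": wr.ratio + Z95 * wr.se,
            "kind": "snp",
        }
    )
    summary = pd.DataFrame(
        {
            "label": [e.method for e in estimates],
            "beta": [e.beta for e in estimates],
            "ci_low": [e.beta - Z95 * e.se for e in estimates],
            "ci_high": [e.beta + Z95 * e.se for e in estimates],
            "kind": "summary",
        }
    )
    forest = pd.concat([forest, summary], ignore_index=True)
    return PlotData(scatter, fits, funnel, forest)


def render_figures(pdata: PlotData, outdir, prefix: str = "mr") -> list:
    """Write scatter, funnel and forest SVGs; returns the paths."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []

    fig, ax = plt.subplots(figsize=(5, 4))
    s = pdata.scatter
    ax.errorbar(
        s["beta_exp"], s["beta_out"], xerr=s["se_exp"], yerr=s["se_out"],
        fmt="o", ms=3, lw=0.7, color="0.3",
    )
    xs = np.linspace(0, s["beta_exp"].abs().max() * 1.05, 50)
    for row in pdata.fits.itertuples(index=False):
        ax.plot(xs, row.intercept + row.slope * xs, label=row.method, lw=1)
    ax.set_xlabel("SNP effect on exposure")
    ax.set_ylabel("SNP effect on outcome")
    ax.legend(fontsize=7)
    p = outdir / f"{prefix}_scatter.svg"
    fig.savefig(p, bbox_inches="tight")
    plt.close(fig)
    paths.append(p)

    fig, ax = plt.subplots(figsize=(4.5, 4))
    f = pdata.funnel
    ax.plot(f["ratio"], f["precision"], "o", ms=3, color="0.3")
    ax.axvline(float(f["ivw_beta"].iloc[0]), color="C0", lw=1)
    ax.set_xlabel("Wald ratio")
    ax.set_ylabel("1 / SE")
    p = outdir / f"{prefix}_funnel.svg"
    fig.savefig(p, bbox_inches="tight")
    plt.close(fig)
    paths.append(p)

    fr = pdata.forest
    fig, ax = plt.subplots(figsize=(5, 0.25 * len(fr) + 1))
    ypos = np.arange(len(fr))[::-1]
    colors = np.where(fr["kind"] == "summary", "C3", "0.3")
    for yv, row, c in zip(ypos, fr.itertuples(index=False), colors):
        ax.plot([row.ci_low, row.ci_high], [yv, yv], "-", color=c, lw=1)
        ax.plot(row.beta, yv, "s", color=c, ms=3)
    ax.axvline(0, color="0.7", lw=0.8)
    ax.set_yticks(ypos)
    ax.set_yticklabels(fr["label"], fontsize=6)
    ax.set_xlabel("causal estimate (log scale)")
    p = outdir / f"{prefix}_forest.svg"
    fig.savefig(p, bbox_inches="tight")
    plt.close(fig)
    paths.append(p)
    return paths


def sensitivity_suite(
    h: HarmonizedSet, n_sim: int = 1000, seed: int = 0
) -> pd.DataFrame:
    """One tidy row per diagnostic, skipping those the SNP count forbids."""
    rows = []
    try:
        q = cochran_q(h)
        rows.append({"diagnostic": "cochran_q", "statistic": q.Q, "pval": q.pval,
                     "flag": q.heterogeneous})
    except MRError:
        pass
    try:
        eg = egger_intercept_test(h)
        rows.append({"diagnostic": "egger_intercept", "statistic": eg.estimate.beta,
                     "pval": eg.estimate.pval, "flag": eg.pleiotropy_detected})
    except MRError:
        pass
    try:
        pr = mr_presso(h, n_sim=n_sim, seed=seed)
        rows.append({"diagnostic": "mr_presso_global", "statistic": pr.rss_obs,
                     "pval": pr.global_pval, "flag": bool(pr.outliers)})
    except MRError:
        pass
    try:
        loo = leave_one_out(h)
        rows.append({"diagnostic": "leave_one_out", "statistic": float("nan"),
                     "pval": float("nan"), "flag": loo.influential})
    except MRError:
        pass
    return pd.DataFrame(rows, columns=["diagnostic", "statistic", "pval", "flag"])
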