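"""Summary-level GWAS simulation with a known exposure→mediator→outcome chain.

Two-sample MR consumes only per-SNP summary statistics, so no genotypes are
simulated: each observed effect is drawn around its true value with the
analytic standard error of a single-SNP regression,

    se_j = 1 / sqrt(2 p_j (1 - p_j) n)          (continuous trait)

inflated by 1/sqrt(phi (1 - phi)) for a binary outcome with case fraction
phi.  Default sample sizes echo the cohorts the pipeline is aimed at: a large
16S microbiome GWAS (n = 18,340) for exposures, a metabolite GWAS (n = 8,299)
for mediators, and a rare-disease case-control GWAS (170 cases / 4,717
controls) for the outcome.

The causal chain: instrument j has effect gamma_j on the exposure, hence
theta_em * gamma_j on the mediator and (theta_direct + theta_em * theta_mo) *
gamma_j (+ any pleiotropic alpha_j) on the outcome.  A second block of SNPs
carries direct mediator effects delta_j (outcome effect theta_mo * delta_j,
zero exposure effect) so the mediator has valid instruments of its own —
without them the step-2 Wald ratio on chain SNPs identifies
theta_total/theta_em, not theta_mo.  A third block of outcome-specific loci
(effects eta_j on the outcome only) plays the role of the disease's own GWAS
hits: they are what make the *reverse* direction of a bidirectional screen
estimable, exactly as a real case-control GWAS contributes its own
suggestive SNPs.  Null SNPs have true effect 0 everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._utils import COMPLEMENT, VALID_BASES
from .gwas_io import CANONICAL_COLUMNS, SummaryStatTable

#: ordered non-palindromic allele pairs
_NONPAL_PAIRS = [
    (a, b) for a in VALID_BASES for b in VALID_BASES if b not in (a, COMPLEMENT[a])
]
_PAL_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]

#: default case fraction of the outcome GWAS (170 cases / 4,887 total)
DEFAULT_CASE_FRACTION = 170 / 4887


@dataclass
class SimulationConfig:
    """Study conditions for one exposure→mediator→outcome chain.

    Defaults give strong exposure instruments (median instrument p ≈ 1e-8 at
    the exposure sample size) and a true mediation proportion of
    theta_em*theta_mo / (theta_direct + theta_em*theta_mo) = 0.2/0.8 = 25%.
    """

    n_instruments: int = 30
    n_med_instruments: int = 30
    n_out_instruments: int = 10
    n_null_snps: int = 0
    n_exp: int = 18340
    n_med: int = 8299
    n_out: int = 4887
    case_fraction: float = DEFAULT_CASE_FRACTION
    theta_em: float = 0.4
    theta_mo: float = 0.5
    theta_direct: float = 0.6
    gamma_sd: float = 0.1
    delta_sd: float = 0.15
    eta_sd: float = 1.0
    pleiotropy_frac: float = 0.0
    pleiotropy_sd: float = 0.1
    pleiotropy_mean: float = 0.0
    outlier_idx: Sequence[int] = field(default_factory=tuple)
    outlier_scale: float = 10.0
    maf_range: tuple[float, float] = (0.05, 0.5)
    palindrome_frac: float = 0.0
    flip_frac: float = 0.0
    seed: int = 0

    @property
    def theta_total(self) -> float:
        return self.theta_direct + self.theta_em * self.theta_mo

    def validate(self) -> None:
        for name in ("pleiotropy_frac", "palindrome_frac", "flip_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in ("n_exp", "n_med", "n_out"):
            if getattr(self, name) < 2:
                raise ValueError(f"{name} must be >= 2")
        if self.n_instruments < 1:
            raise ValueError("n_instruments must be >= 1")
        if self.gamma_sd <= 0:
            raise ValueError("gamma_sd must be > 0")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must sit inside (0, 0.5]")
        if not 0.0 < self.case_fraction < 1.0:
            raise ValueError("case_fraction must lie in (0, 1)")


@dataclass
class TruthRecord:
    """Ground truth of a simulated chain, for recovery checks."""

    snp_ids: list[str]
    gamma: np.ndarray  # true SNP→exposure effects (0 off the exposure block)
    delta: np.ndarray  # true direct SNP→mediator effects
    eta: np.ndarray  # true outcome-locus effects (the disease's own hits)
    alpha: np.ndarray  # pleiotropic SNP→outcome effects
    theta_em: float
    theta_mo: float
    theta_direct: float
    theta_total: float
    true_proportion: float | None  # percent; None when theta_total == 0
    proportion_undefined: bool


def _analytic_se(maf: np.ndarray, n: int, case_fraction: float | None = None):
    se = 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * n)
    if case_fraction is not None:
        se = se / np.sqrt(case_fraction * (1.0 - case_fraction))
    return se


def _pvals(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    p = 2.0 * stats.norm.sf(np.abs(beta) / se)
    # keep p inside (0, 1] so record validation never drops an extreme hit
    return np.clip(p, 5e-324, 1.0)


def _make_table(
    trait_id, snp, chrom, pos, ea, oa, maf, true_beta, se, n, rng, trait_type
) -> SummaryStatTable:
    beta = true_beta + rng.normal(0.0, 1.0, size=se.shape) * se
    df = pd.DataFrame(
        {
            "snp": snp,
            "chr": chrom,
            "pos": pos,
            "ea": ea,
            "oa": oa,
            "eaf": maf,
            "beta": beta,
            "se": se,
            "pval": _pvals(beta, se),
            "n": n,
        }
    )
    df = df[CANONICAL_COLUMNS]
    df["pos"] = df["pos"].astype("Int64")
    df["n"] = df["n"].astype("Int64")
    for c in ("snp", "chr", "ea", "oa"):
        df[c] = df[c].astype("string")
    return SummaryStatTable(trait_id, df, trait_type)


def _layout(m: int, rng: np.random.Generator, palindrome_frac: float):
    """SNP ids, positions spaced beyond any clumping window, allele pairs."""
    snp = [f"rs{i + 1:06d}" for i in range(m)]
    chrom = np.array([str((i % 22) + 1) for i in range(m)])
    pos = np.array([1_000_000 + (i // 22) * 25_000_000 for i in range(m)])
    pair_idx = rng.integers(0, len(_NONPAL_PAIRS), size=m)
    ea = np.array([_NONPAL_PAIRS[i][0] for i in pair_idx])
    oa = np.array([_NONPAL_PAIRS[i][1] for i in pair_idx])
    n_pal = int(round(palindrome_frac * m))
    if n_pal:
        pal_rows = rng.choice(m, size=n_pal, replace=False)
        pal_pick = rng.integers(0, len(_PAL_PAIRS), size=n_pal)
        for r, k in zip(pal_rows, pal_pick):
            ea[r], oa[r] = _PAL_PAIRS[k]
    return snp, chrom, pos, ea, oa


def simulate_chain(
    config: SimulationConfig,
) -> tuple[SummaryStatTable, SummaryStatTable, SummaryStatTable, TruthRecord]:
    """Simulate exposure, mediator and outcome GWAS sharing one SNP panel.

    Reproducible given ``config.seed``; identical SNP id sets across the
    three tables.  When ``flip_frac > 0`` the outcome table is emitted with
    that fraction of rows allele-swapped (beta negated, eaf complemented), as
    a cross-consortium orientation mismatch would present.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    ni, nm = config.n_instruments, config.n_med_instruments
    no, nn = config.n_out_instruments, config.n_null_snps
    m = ni + nm + no + nn
    snp, chrom, pos, ea, oa = _layout(m, rng, config.palindrome_frac)
    maf = rng.uniform(*config.maf_range, size=m)

    gamma = np.zeros(m)
    gamma[:ni] = rng.normal(0.0, config.gamma_sd, size=ni)
    delta = np.zeros(m)
    delta[ni : ni + nm] = rng.normal(0.0, config.delta_sd, size=nm)
    eta = np.zeros(m)
    eta[ni + nm : ni + nm + no] = rng.normal(0.0, config.eta_sd, size=no)

    alpha = np.zeros(m)
    n_pleio = int(round(config.pleiotropy_frac * ni))
    if n_pleio:
        pleio_rows = rng.choice(ni, size=n_pleio, replace=False)
        alpha[pleio_rows] += rng.normal(
            config.pleiotropy_mean, config.pleiotropy_sd, size=n_pleio
        )
    theta_total = config.theta_total
    if config.outlier_idx:
        # deterministic gross effect: outlier_scale x the typical per-SNP
        # causal signal, not the SNP's own (possibly tiny) random gamma
        base = abs(theta_total) if theta_total != 0 else 1.0
        alpha[list(config.outlier_idx)] += config.outlier_scale * base * config.gamma_sd

    true_exp = gamma
    true_med = config.theta_em * gamma + delta
    true_out = theta_total * gamma + config.theta_mo * delta + eta + alpha

    se_exp = _analytic_se(maf, config.n_exp)
    se_med = _analytic_se(maf, config.n_med)
    se_out = _analytic_se(maf, config.n_out, config.case_fraction)

    exp_t = _make_table(
        "exposure", snp, chrom, pos, ea, oa, maf, true_exp, se_exp,
        config.n_exp, rng, "continuous",
    )
    med_t = _make_table(
        "mediator", snp, chrom, pos, ea, oa, maf, true_med, se_med,
        config.n_med, rng, "continuous",
    )
    out_t = _make_table(
        "outcome", snp, chrom, pos, ea, oa, maf, true_out, se_out,
        config.n_out, rng, "binary",
    )
    if config.flip_frac > 0:
        out_t = corrupt_alleles(
            out_t, flip_frac=config.flip_frac, palindrome_frac=0.0,
            seed=int(rng.integers(2**31)),
        )

    undefined = theta_total == 0.0
    truth = TruthRecord(
        snp_ids=snp,
        gamma=gamma,
        delta=delta,
        eta=eta,
        alpha=alpha,
        theta_em=config.theta_em,
        theta_mo=config.theta_mo,
        theta_direct=config.theta_direct,
        theta_total=theta_total,
        true_proportion=None
        if undefined
        else 100.0 * config.theta_em * config.theta_mo / theta_total,
        proportion_undefined=undefined,
    )
    return exp_t, med_t, out_t, truth


def corrupt_alleles(
    table: SummaryStatTable,
    flip_frac: float = 0.0,
    palindrome_frac: float = 0.0,
    seed: int = 0,
) -> SummaryStatTable:
    """Return a copy with allele-orientation corruption applied.

    Flipped rows swap effect/other alleles, negate beta and complement eaf —
    harmonization must undo this exactly.  Palindromized rows get allele
    pairs drawn from {A/T, T/A, C/G, G/C}.  Row count and order unchanged.
    """
    rng = np.random.default_rng(seed)
    df = table.df.copy()
    m = len(df)
    n_pal = int(round(palindrome_frac * m))
    if n_pal:
        rows = rng.choice(m, size=n_pal, replace=False)
        picks = rng.integers(0, len(_PAL_PAIRS), size=n_pal)
        df.loc[rows, "ea"] = [_PAL_PAIRS[k][0] for k in picks]
        df.loc[rows, "oa"] = [_PAL_PAIRS[k][1] for k in picks]
    n_flip = int(round(flip_frac * m))
    if n_flip:
        rows = rng.choice(m, size=n_flip, replace=False)
        ea = df.loc[rows, "ea"].copy()
        df.loc[rows, "ea"] = df.loc[rows, "oa"].to_numpy()
        df.loc[rows, "oa"] = ea.to_numpy()
        df.loc[rows, "beta"] = -df.loc[rows, "beta"]
        df.loc[rows, "eaf"] = 1.0 - df.loc[rows, "eaf"]
    return SummaryStatTable(table.trait_id, df, table.trait_type)


@dataclass
class ScenarioConfig:
    """Many-trait screening scenario: several exposures and mediators, one
    outcome, with a single true chain (or none) planted among them."""

    n_exposures: int = 5
    n_mediators: int = 4
    causal_exposure: int | None = 0  # None => fully null scenario
    causal_mediator: int | None = 0
    base: SimulationConfig = field(default_factory=SimulationConfig)
    seed: int = 0


@dataclass
class ScenarioTruth:
    causal_exposure: str | None
    causal_mediator: str | None
    chain: TruthRecord | None


def simulate_scenario(
    scenario: ScenarioConfig,
) -> tuple[dict[str, SummaryStatTable], dict[str, SummaryStatTable], SummaryStatTable, ScenarioTruth]:
    """Emit exposure/mediator/outcome tables over a shared SNP panel.

    Each trait owns a disjoint instrument block; only the designated causal
    exposure→mediator pair propagates effects to the outcome.
    """
    cfg = scenario.base
    cfg.validate()
    rng = np.random.default_rng(scenario.seed)
    ne, nm = scenario.n_exposures, scenario.n_mediators
    ni = cfg.n_instruments
    nmed_i = cfg.n_med_instruments
    no = cfg.n_out_instruments
    m = ne * ni + nm * nmed_i + no + cfg.n_null_snps
    snp, chrom, pos, ea, oa = _layout(m, rng, cfg.palindrome_frac)
    maf = rng.uniform(*cfg.maf_range, size=m)
    se_exp = _analytic_se(maf, cfg.n_exp)
    se_med = _analytic_se(maf, cfg.n_med)
    se_out = _analytic_se(maf, cfg.n_out, cfg.case_fraction)

    exp_block = {e: slice(e * ni, (e + 1) * ni) for e in range(ne)}
    med_block = {
        k: slice(ne * ni + k * nmed_i, ne * ni + (k + 1) * nmed_i) for k in range(nm)
    }
    gammas = {e: rng.normal(0.0, cfg.gamma_sd, size=ni) for e in range(ne)}
    deltas = {k: rng.normal(0.0, cfg.delta_sd, size=nmed_i) for k in range(nm)}
    out_block = slice(ne * ni + nm * nmed_i, ne * ni + nm * nmed_i + no)
    eta_full = np.zeros(m)
    eta_full[out_block] = rng.normal(0.0, cfg.eta_sd, size=no)

    ce, cm = scenario.causal_exposure, scenario.causal_mediator
    causal = ce is not None and cm is not None

    true_out = eta_full.copy()
    if causal:
        true_out[exp_block[ce]] += cfg.theta_total * gammas[ce]
        true_out[med_block[cm]] += cfg.theta_mo * deltas[cm]

    exposures: dict[str, SummaryStatTable] = {}
    for e in range(ne):
        true = np.zeros(m)
        true[exp_block[e]] = gammas[e]
        tid = f"exposure_{e:02d}"
        exposures[tid] = _make_table(
            tid, snp, chrom, pos, ea, oa, maf, true, se_exp, cfg.n_exp, rng,
            "continuous",
        )
    mediators: dict[str, SummaryStatTable] = {}
    for k in range(nm):
        true = np.zeros(m)
        true[med_block[k]] = deltas[k]
        if causal and k == cm:
            true[exp_block[ce]] += cfg.theta_em * gammas[ce]
        tid = f"mediator_{k:02d}"
        mediators[tid] = _make_table(
            tid, snp, chrom, pos, ea, oa, maf, true, se_med, cfg.n_med, rng,
            "continuous",
        )
    outcome = _make_table(
        "outcome", snp, chrom, pos, ea, oa, maf, true_out, se_out, cfg.n_out,
        rng, "binary",
    )
    if cfg.flip_frac > 0:
        outcome = corrupt_alleles(
            outcome, flip_frac=cfg.flip_frac, seed=int(rng.integers(2**31))
        )

    chain_truth = None
    if causal:
        gamma_full = np.zeros(m)
        gamma_full[exp_block[ce]] = gammas[ce]
        delta_full = np.zeros(m)
        delta_full[med_block[cm]] = deltas[cm]
        chain_truth = TruthRecord(
            snp_ids=snp,
            gamma=gamma_full,
            delta=delta_full,
            eta=eta_full,
            alpha=np.zeros(m),
            theta_em=cfg.theta_em,
            theta_mo=cfg.theta_mo,
            theta_direct=cfg.theta_direct,
            theta_total=cfg.theta_total,
            true_proportion=None
            if cfg.theta_total == 0
            else 100.0 * cfg.theta_em * cfg.theta_mo / cfg.theta_total,
            proportion_undefined=cfg.theta_total == 0,
        )
    truth = ScenarioTruth(
        causal_exposure=f"exposure_{ce:02d}" if causal else None,
        causal_mediator=f"mediator_{cm:02d}" if causal else None,
        chain=chain_truth,
    )
    return exposures, mediators, outcome, truth


def null_config(**overrides) -> SimulationConfig:
    """A chain with every causal path switched off (type-I-error studies)."""
    cfg = SimulationConfig(theta_em=0.0, theta_mo=0.0, theta_direct=0.0)
    return replace(cfg, **overrides)
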