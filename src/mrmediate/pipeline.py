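"""Orchestration of the full bidirectional two-step analysis.

One declarative config (YAML or an in-memory :class:`PipelineConfig`) drives,
for every exposure: instrument selection → harmonization → all estimators →
sensitivity suite → bidirectional screen; and, for screen-passing exposures,
mediator screening and product-method mediation.  A per-exposure failure is
recorded and skipped, never fatal to the run.

Reproducibility: one global seed fans out to per-stage seeds via
``derive_seed(global_seed, label)`` (SHA-256 based), so any stage can be
rerun in isolation with the seed it had inside the full run.  The manifest
records the config hash, seed and package version.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from ._utils import derive_seed
from .errors import ConfigurationError, MRError
from .estimators import all_estimates, estimates_to_frame
from .gwas_io import SummaryStatTable, read_sumstats, write_sumstats
from .harmonize import harmonize
from .instruments import (
    REVERSE_P_THRESHOLD,
    SelectionParams,
    TableLD,
    ZeroLD,
    build_instrument_set,
    read_exclusion_list,
)
from .mediation import bidirectional_screen, lines_to_frame, screen_mediators
from .sensitivity import sensitivity_suite
from .synthetic import ScenarioConfig, SimulationConfig, simulate_scenario

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything a full run needs.

    Either ``scenario`` (simulate in memory) or explicit sumstats paths
    (``exposure_paths``/``mediator_paths``/``outcome_path``) must be given.
    """

    scenario: ScenarioConfig | None = None
    exposure_paths: dict[str, str] = field(default_factory=dict)
    mediator_paths: dict[str, str] = field(default_factory=dict)
    outcome_path: str | None = None
    ld_path: str | None = None
    exclusion_path: str | None = None
    fwd_params: SelectionParams = field(default_factory=SelectionParams)
    rev_params: SelectionParams = field(
        default_factory=lambda: SelectionParams(p_threshold=REVERSE_P_THRESHOLD)
    )
    med_params: SelectionParams = field(default_factory=SelectionParams)
    ivw_variant: str = "random"
    alpha: float = 0.05
    n_boot: int = 1000
    n_sim: int = 1000
    seed: int = 0
    outdir: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs: dict = {}
        if "scenario" in raw:
            sc = dict(raw["scenario"])
            base = SimulationConfig(**sc.pop("base", {}))
            kwargs["scenario"] = ScenarioConfig(base=base, **sc)
        for key in (
            "exposure_paths", "mediator_paths", "outcome_path", "ld_path",
            "exclusion_path", "ivw_variant", "alpha", "n_boot", "n_sim",
            "seed", "outdir",
        ):
            if key in raw:
                kwargs[key] = raw[key]
        for pkey in ("fwd_params", "rev_params", "med_params"):
            if pkey in raw:
                p = dict(raw[pkey])
                if "exclusion_ids" in p:
                    p["exclusion_ids"] = frozenset(p["exclusion_ids"])
                kwargs[pkey] = SelectionParams(**p)
        return cls(**kwargs)

    def validate(self) -> None:
        """Fail fast: every referenced input must resolve before any work."""
        if self.scenario is None:
            if not self.exposure_paths or self.outcome_path is None:
                raise ConfigurationError(
                    "config needs either a scenario or exposure_paths + outcome_path"
                )
            missing = [
                p
                for p in [
                    *self.exposure_paths.values(),
                    *self.mediator_paths.values(),
                    self.outcome_path,
                    self.ld_path,
                    self.exclusion_path,
                ]
                if p is not None and not Path(p).exists()
            ]
            if missing:
                raise ConfigurationError(f"missing input files: {missing}")
        if self.ivw_variant not in ("fixed", "random"):
            raise ConfigurationError(f"unknown ivw_variant {self.ivw_variant!r}")

    def config_hash(self) -> str:
        """Stable digest over every setting (changes iff a setting changes)."""

        def enc(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {
                    f.name: enc(getattr(obj, f.name))
                    for f in dataclasses.fields(obj)
                }
            if isinstance(obj, frozenset):
                return sorted(obj)
            if isinstance(obj, dict):
                return {k: enc(v) for k, v in sorted(obj.items())}
            if isinstance(obj, (list, tuple)):
                return [enc(v) for v in obj]
            return obj

        blob = json.dumps(enc(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class ReportBundle:
    forward_mr: pd.DataFrame
    reverse_mr: pd.DataFrame
    sensitivity: pd.DataFrame
    screen: pd.DataFrame
    mediator_screen: pd.DataFrame
    mediation_lines: pd.DataFrame
    errors: pd.DataFrame
    manifest: dict

    def write(self, outdir: str | Path) -> Path:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name in (
            "forward_mr", "reverse_mr", "sensitivity", "screen",
            "mediator_screen", "mediation_lines", "errors",
        ):
            getattr(self, name).to_csv(outdir / f"{name}.tsv", sep="\t", index=False)
        (outdir / "manifest.json").write_text(json.dumps(self.manifest, indent=2))
        return outdir


def _load_inputs(config: PipelineConfig):
    if config.scenario is not None:
        exposures, mediators, outcome, _ = simulate_scenario(config.scenario)
        return exposures, mediators, outcome, ZeroLD()
    exposures = {
        tid: read_sumstats(p, trait_id=tid)
        for tid, p in config.exposure_paths.items()
    }
    mediators = {
        tid: read_sumstats(p, trait_id=tid)
        for tid, p in config.mediator_paths.items()
    }
    outcome = read_sumstats(
        config.outcome_path, trait_id=Path(config.outcome_path).stem,
        trait_type="binary",
    )
    ld = TableLD.from_tsv(config.ld_path) if config.ld_path else ZeroLD()
    return exposures, mediators, outcome, ld


def run_full_analysis(config: PipelineConfig) -> ReportBundle:
    """Execute the whole analysis; deterministic given ``config.seed``."""
    config.validate()
    if config.exclusion_path:
        excl = read_exclusion_list(config.exclusion_path)
        config = dataclasses.replace(
            config,
            fwd_params=dataclasses.replace(config.fwd_params, exclusion_ids=excl),
            med_params=dataclasses.replace(config.med_params, exclusion_ids=excl),
        )
    exposures, mediators, outcome, ld = _load_inputs(config)

    fwd_rows, rev_rows, sens_rows, screen_rows, err_rows = [], [], [], [], []
    med_screen_frames, lines = [], []
    for tid, exp_table in exposures.items():
        stage_seed = derive_seed(config.seed, f"estimate:{tid}")
        try:
            iv = build_instrument_set(exp_table, ld, config.fwd_params)
            h = harmonize(iv, outcome)
            ests = all_estimates(
                h, ivw_variant=config.ivw_variant, n_boot=config.n_boot,
                seed=stage_seed,
            )
            fwd_rows.append(estimates_to_frame(ests, tid, outcome.trait_id))
            sens = sensitivity_suite(
                h, n_sim=config.n_sim, seed=derive_seed(config.seed, f"sens:{tid}")
            )
            sens.insert(0, "exposure", tid)
            sens_rows.append(sens)
            screen = bidirectional_screen(
                exp_table, outcome, ld, config.fwd_params, config.rev_params,
                alpha_fwd=config.alpha, alpha_rev=config.alpha,
            )
            if screen.reverse is not None:
                rev_rows.append(
                    estimates_to_frame([screen.reverse], outcome.trait_id, tid)
                )
            screen_rows.append(
                {
                    "exposure": tid,
                    "forward_p": screen.forward.pval if screen.forward else None,
                    "reverse_p": screen.reverse.pval if screen.reverse else None,
                    "passes": screen.passes,
                    "reason": screen.reason,
                }
            )
            if screen.passes and mediators:
                kept, audit = screen_mediators(
                    mediators, exp_table, outcome, ld,
                    config.fwd_params, config.med_params, alpha=config.alpha,
                )
                audit.insert(0, "exposure", tid)
                med_screen_frames.append(audit)
                lines.extend(kept)
        except MRError as err:
            logger.warning("exposure %s skipped: %s", tid, err)
            err_rows.append({"exposure": tid, "error": str(err)})

    def cat(frames, cols):
        return (
            pd.concat(frames, ignore_index=True)
            if frames
            else pd.DataFrame(columns=cols)
        )

    from . import __version__

    bundle = ReportBundle(
        forward_mr=cat(fwd_rows, ["exposure", "outcome", "method"]),
        reverse_mr=cat(rev_rows, ["exposure", "outcome", "method"]),
        sensitivity=cat(sens_rows, ["exposure", "diagnostic"]),
        screen=pd.DataFrame(
            screen_rows,
            columns=["exposure", "forward_p", "reverse_p", "passes", "reason"],
        ),
        mediator_screen=cat(med_screen_frames, ["exposure", "mediator", "kept"]),
        mediation_lines=lines_to_frame(lines),
        errors=pd.DataFrame(err_rows, columns=["exposure", "error"]),
        manifest={
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "version": __version__,
            "n_exposures": len(exposures),
            "n_mediators": len(mediators),
        },
    )
    if config.outdir:
        bundle.write(config.outdir)
    return bundle


def simulate_to_dir(scenario: ScenarioConfig, outdir: str | Path) -> Path:
    """Materialize a scenario as canonical TSVs plus a truth ledger."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    exposures, mediators, outcome, truth = simulate_scenario(scenario)
    for tid, t in {**exposures, **mediators, "outcome": outcome}.items():
        write_sumstats(t, outdir / f"{tid}.tsv")
    ledger = {
        "causal_exposure": truth.causal_exposure,
        "causal_mediator": truth.causal_mediator,
        "true_proportion_pct": truth.chain.true_proportion if truth.chain else None,
    }
    (outdir / "truth.json").write_text(json.dumps(ledger, indent=2))
    return outdir
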