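"""Stage orchestration: simulate -> fit -> summarize -> compare -> report.

A :class:`PipelineConfig` (built programmatically or from a YAML file)
names either an input CSV or a synthetic-trial configuration, the sampler
settings, priors and reporting thresholds. :func:`run_pipeline` runs every
stage, writes all artifacts under the output directory, and records a
manifest (seed, config hash, package versions) sufficient to reproduce
them bit-exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .data import OUTCOMES, encode, read_trial_csv
from .errors import ConfigError
from .frequentist import MixedLogisticML, compare
from .hmc import SamplerConfig
from .models import TrialOutcomeModel
from .simulate import SimConfig, simulate_trial, write_trial_csv
from .summary import DEFAULT_THRESHOLDS, report

log = logging.getLogger("bintrial")

SCALE_BY_OUTCOME = {"risk": "risk_or", "audit_total": "audit_total_md",
                    "audit_c": "audit_c_md"}


@dataclass(frozen=True)
class PipelineConfig:
    """Full run configuration; exactly one of input_path / sim_config."""

    output_dir: str = "bintrial_run"
    input_path: str | None = None
    sim_config: SimConfig | None = None
    sampler: SamplerConfig = field(default_factory=SamplerConfig)
    prior_sd_beta: float = 1.0
    prior_sd_scales: float = 1.0
    parameterization: str = "noncentered"
    thresholds: dict = field(default_factory=lambda: dict(DEFAULT_THRESHOLDS))
    mapping: str | None = None
    seed: int = 0
    allow_warnings: bool = False
    verbosity: str = "info"

    def __post_init__(self):
        if (self.input_path is None) == (self.sim_config is None):
            raise ConfigError(
                "input_path/sim_config",
                "provide exactly one of an input CSV or a simulation config",
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        if "sim_config" in raw and raw["sim_config"] is not None:
            sim = raw["sim_config"]
            if isinstance(sim, dict):
                sim = {k: tuple(v) if isinstance(v, list) else v
                       for k, v in sim.items()}
                raw["sim_config"] = SimConfig(**sim)
        if "sampler" in raw and isinstance(raw["sampler"], dict):
            sampler = dict(raw["sampler"])
            preset = sampler.pop("preset", None)
            raw["sampler"] = (SamplerConfig.preset(preset, **sampler)
                              if preset else SamplerConfig(**sampler))
        if "thresholds" in raw and isinstance(raw["thresholds"], dict):
            raw["thresholds"] = {k: tuple(v) for k, v in raw["thresholds"].items()}
        return cls(**raw)

    def to_canonical_dict(self) -> dict:
        out = dataclasses.asdict(self)
        return json.loads(json.dumps(out, default=list, sort_keys=True))


def config_hash(config: PipelineConfig) -> str:
    payload = json.dumps(config.to_canonical_dict(), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()


def run_pipeline(config: PipelineConfig) -> int:
    """Run all stages; returns the process exit status (0 = clean).

    A non-zero status signals flagged convergence diagnostics unless
    ``allow_warnings`` is set; artifacts are written either way.
    """
    logging.basicConfig(level=getattr(logging, config.verbosity.upper(), 20))
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.sim_config is not None:
        sim = config.sim_config
        if sim.seed != config.seed:
            sim = dataclasses.replace(sim, seed=config.seed)
        log.info("simulating trial (%d + %d participants)", *sim.n_per_arm)
        trial = simulate_trial(sim)
        data_path = write_trial_csv(trial, out / "trial.csv")
        table = read_trial_csv(data_path)
    else:
        table = read_trial_csv(config.input_path, mapping=config.mapping)

    tables, flagged = [], []
    diag_frames = {}
    for outcome in OUTCOMES:
        design = encode(table, outcome)
        log.info("fitting %s model (n=%d completers, k=%d centers)",
                 outcome, design.n, design.k)
        model = TrialOutcomeModel(
            design,
            prior_sd_beta=config.prior_sd_beta,
            prior_sd_scales=config.prior_sd_scales,
            parameterization=config.parameterization,
        )
        res = model.fit(config.sampler, seed=config.seed)
        res.to_csv(out / f"draws_{outcome}.csv")
        res.summary().to_csv(out / f"summary_{outcome}.csv")
        scale = SCALE_BY_OUTCOME[outcome]
        tab = res.effect_table(config.thresholds.get(scale))
        tab.to_dataframe().to_csv(out / f"effect_table_{outcome}.csv", index=False)
        res.plot_posterior(out / f"density_{outcome}.png")
        tables.append(tab)
        diag_frames[outcome] = res.diagnostics
        if res.diagnostics["flagged"].any():
            flagged.extend(f"{outcome}:{p}" for p in
                           res.diagnostics.index[res.diagnostics["flagged"]])
        if outcome == "risk":
            risk_design, risk_table = design, tab

    # design summary (completers, centers, arms)
    pd.DataFrame(
        {
            "n_completers": [risk_design.n],
            "n_centers": [risk_design.k],
            "n_bi": [int(risk_design.X[:, 1].sum())],
            "n_control": [int(risk_design.n - risk_design.X[:, 1].sum())],
            "risky_rate_fu": [float(risk_design.y_binary.mean())],
        }
    ).to_csv(out / "design_summary.csv", index=False)

    freq = MixedLogisticML(risk_design).fit()
    pd.DataFrame(
        {"term": freq.colnames, "coef": freq.beta_hat, "se": freq.se}
    ).to_csv(out / "frequentist_coefficients.csv", index=False)
    (out / "comparison.md").write_text(compare(freq, risk_table))

    diag_all = pd.concat(diag_frames, names=["outcome", "parameter"])
    (out / "report.md").write_text(
        report(
            tables,
            diagnostics=diag_frames["risk"],
            meta={
                "n completers": risk_design.n,
                "chains": config.sampler.n_chains,
                "kept iterations per chain": config.sampler.n_iter,
                "warmup per chain": config.sampler.warmup,
                "seed": config.seed,
            },
        )
    )
    diag_all.to_csv(out / "diagnostics.csv")

    manifest = {
        "package": "bintrial",
        "version": __version__,
        "numpy": np.__version__,
        "seed": config.seed,
        "config_hash": config_hash(config),
        "config": config.to_canonical_dict(),
        "flagged_parameters": flagged,
        "frequentist_converged": freq.converged,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))

    if flagged and not config.allow_warnings:
        log.warning("convergence flags raised: %s", ", ".join(flagged))
        return 1
    return 0
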