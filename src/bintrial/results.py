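"""Results object tying posterior draws to reporting and diagnostics."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .hmc import PosteriorDraws, diagnose
from .summary import (
    DEFAULT_THRESHOLDS,
    EffectSummaryTable,
    cumulative_table,
    density_export,
    or_samples,
    reduction_samples,
)


class TrialPosterior:
    """Posterior of one outcome model, with summaries and exports.

    Returned by :meth:`bintrial.models.TrialOutcomeModel.fit`. Offers the
    effect draws on the reporting scale (:meth:`effect_samples`), the
    cumulative effect-probability table (:meth:`effect_table`), a
    parameter summary with convergence diagnostics (:meth:`summary`) and
    density/CSV exports.
    """

    def __init__(self, model, draws: PosteriorDraws):
        self.model = model
        self.draws = draws

    @property
    def kind(self) -> str:
        return self.model.spec.kind

    @property
    def outcome_scale(self) -> str:
        if self.kind == "bernoulli_logit":
            return "risk_or"
        return ("audit_total_md"
                if self.model.design.outcome == "audit_total" else "audit_c_md")

    @property
    def diagnostics(self) -> pd.DataFrame:
        if self.draws.diagnostics is None:
            self.draws.diagnostics = diagnose(self.draws)
        return self.draws.diagnostics

    def effect_samples(self) -> np.ndarray:
        """Group-effect draws on the reporting scale (OR or reduction)."""
        if self.kind == "bernoulli_logit":
            return or_samples(self.draws)
        return reduction_samples(self.draws)

    def effect_table(self, thresholds=None) -> EffectSummaryTable:
        scale = self.outcome_scale
        if thresholds is None:
            thresholds = DEFAULT_THRESHOLDS[scale]
        orientation = "less_than" if scale == "risk_or" else "reduction_at_least"
        return cumulative_table(
            self.effect_samples(), thresholds, orientation,
            outcome=scale, n_chains=self.draws.n_chains,
        )

    def summary(self) -> pd.DataFrame:
        """Per-parameter posterior mean, SD, 95% CrI, R-hat and bulk ESS."""
        d = self.draws
        q = np.percentile(d.draws, [2.5, 97.5], axis=0)
        out = pd.DataFrame(
            {
                "mean": d.draws.mean(axis=0),
                "sd": d.draws.std(axis=0, ddof=1),
                "ci2.5": q[0],
                "ci97.5": q[1],
            },
            index=d.columns,
        )
        diag = self.diagnostics
        out["rhat"] = diag["rhat"]
        out["ess_bulk"] = diag["ess_bulk"]
        return out

    def plot_posterior(self, path: str | Path, title: str = ""):
        null = 1.0 if self.kind == "bernoulli_logit" else 0.0
        return density_export(self.effect_samples(), path, null_value=null,
                              title=title)

    def to_csv(self, path: str | Path) -> Path:
        return self.draws.to_csv(path)
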