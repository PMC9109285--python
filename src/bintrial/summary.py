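"""Decision-oriented posterior summaries.

Transforms group-effect draws to the reporting scales (odds ratio for the
binary outcome, score reduction for AUDIT totals) and tabulates cumulative
probabilities of effect sizes — the probability that the odds ratio falls
below 1, 0.8, 0.6, or that the score reduction exceeds 0, 0.5, 1 point —
together with posterior means, 95% credible intervals and Monte-Carlo
standard errors.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import arviz as az
import matplotlib
import numpy as np
import pandas as pd

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .errors import UsageError
from .hmc import PosteriorDraws

#: Table-style default thresholds per outcome (user-overridable).
DEFAULT_THRESHOLDS = {
    "risk_or": (1.0, 0.8, 0.6),
    "audit_total_md": (0.0, 0.5, 1.0),
    "audit_c_md": (0.0, 0.25, 0.5),
}

OUTCOME_LABELS = {
    "risk_or": "Risk of risky drinking (odds ratio)",
    "audit_total_md": "AUDIT total score (reduction, points)",
    "audit_c_md": "AUDIT-C score (reduction, points)",
}


@dataclass(frozen=True)
class EffectSummaryTable:
    """Cumulative effect-size probabilities for one outcome."""

    outcome: str
    orientation: str               # "less_than" | "reduction_at_least"
    thresholds: np.ndarray
    cum_prob: np.ndarray
    posterior_mean: float
    ci95: tuple[float, float]
    mc_se: np.ndarray
    n_draws: int

    def to_dataframe(self) -> pd.DataFrame:
        label = "OR < {:g}" if self.orientation == "less_than" \
            else "reduction >= {:g}"
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "label": [label.format(t) for t in self.thresholds],
                "posterior_probability": self.cum_prob,
                "mc_se": self.mc_se,
            }
        )


def _effective_sample_size(samples: np.ndarray, n_chains: int) -> float:
    """Bulk ESS; falls back to the draw count for degenerate inputs."""
    arr = np.asarray(samples, float).reshape(n_chains, -1)
    if np.allclose(arr, arr.flat[0]):
        return float(arr.size)
    try:
        return float(az.ess(az.convert_to_dataset(arr), method="bulk")["x"].values)
    except Exception:
        return float(arr.size)


def or_samples(draws: PosteriorDraws) -> np.ndarray:
    """Odds-ratio draws exp(beta_group) from the risk-model posterior."""
    if draws.kind != "bernoulli_logit":
        raise UsageError(
            "odds-ratio samples require draws from the Bernoulli-logit "
            f"risk model, got kind={draws.kind!r}"
        )
    return np.exp(draws.column("beta_group"))


def reduction_samples(draws: PosteriorDraws) -> np.ndarray:
    """Score-reduction draws (control minus intervention mean) = -beta_group."""
    if draws.kind != "gaussian":
        raise UsageError(
            "score reductions require draws from a Gaussian score model, "
            f"got kind={draws.kind!r}"
        )
    return -draws.column("beta_group")


def cumulative_table(
    effect_samples: np.ndarray,
    thresholds,
    orientation: str = "less_than",
    outcome: str = "effect",
    n_chains: int = 1,
) -> EffectSummaryTable:
    """Tabulate P(effect < t) or P(reduction >= t) with Monte-Carlo SEs.

    ``less_than`` expects effect samples on the reported scale (e.g. odds
    ratios); ``reduction_at_least`` expects reduction samples (positive =
    intervention lowers the score).
    """
    samples = np.asarray(effect_samples, float)
    if samples.size == 0:
        raise ValueError("empty effect-sample vector")
    if orientation not in ("less_than", "reduction_at_least"):
        raise ValueError(f"unknown orientation {orientation!r}")
    thresholds = np.asarray(thresholds, float)

    if orientation == "less_than":
        probs = np.array([(samples < t).mean() for t in thresholds])
    else:
        probs = np.array([(samples >= t).mean() for t in thresholds])

    ess = _effective_sample_size(samples, n_chains)
    mc_se = np.sqrt(probs * (1.0 - probs) / ess)
    lo, hi = np.percentile(samples, [2.5, 97.5])
    return EffectSummaryTable(
        outcome=outcome,
        orientation=orientation,
        thresholds=thresholds,
        cum_prob=probs,
        posterior_mean=float(samples.mean()),
        ci95=(float(lo), float(hi)),
        mc_se=mc_se,
        n_draws=samples.size,
    )


def density_export(effect_samples: np.ndarray, path: str | Path,
                   null_value: float = 1.0, title: str = "") -> pd.DataFrame:
    """Write a posterior density figure (PNG) and its binned CSV.

    Bins follow the Freedman-Diaconis rule; the CSV holds bin edges and
    normalized density heights. Returns the binned density frame.
    """
    samples = np.asarray(effect_samples, float)
    if samples.size < 100:
        raise ValueError("density export needs at least 100 samples")
    path = Path(path)
    if np.ptp(samples) == 0.0:
        edges = np.array([samples[0] - 0.5, samples[0] + 0.5])
        heights = np.array([1.0])
    else:
        heights, edges = np.histogram(samples, bins="fd", density=True)
    binned = pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "density": heights}
    )
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.stairs(heights, edges, fill=True, alpha=0.5)
    ax.axvline(null_value, color="black", linestyle="--", linewidth=1,
               label=f"null = {null_value:g}")
    ax.set_xlabel("effect size")
    ax.set_ylabel("posterior density")
    if title:
        ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    binned.to_csv(path.with_suffix(".csv"), index=False)
    return binned


def report(tables: list[EffectSummaryTable],
           diagnostics: pd.DataFrame | None = None,
           meta: dict | None = None) -> str:
    """Render the effect-probability tables as a markdown report.

    One block per outcome (risk odds ratio, AUDIT-total, AUDIT-C), plus a
    diagnostics appendix; a warning section appears only when a parameter
    is flagged for poor convergence.
    """
    lines = ["# Cumulative probabilities of intervention effects", ""]
    if meta:
        for key, value in meta.items():
            lines.append(f"- {key}: {value}")
        lines.append("")
    for tab in tables:
        label = OUTCOME_LABELS.get(tab.outcome, tab.outcome)
        lines += [f"## {label}", ""]
        lines.append(
            f"Posterior mean {tab.posterior_mean:.2f} "
            f"(95% CrI {tab.ci95[0]:.2f} to {tab.ci95[1]:.2f}; "
            f"{tab.n_draws} draws)"
        )
        lines.append("")
        lines.append("| effect size | posterior probability | MC SE |")
        lines.append("|---|---|---|")
        for _, row in tab.to_dataframe().iterrows():
            lines.append(
                f"| {row['label']} | {row['posterior_probability']:.2f} "
                f"| {row['mc_se']:.4f} |"
            )
        lines.append("")
    if diagnostics is not None:
        lines += ["## Convergence diagnostics", ""]
        flagged = diagnostics[diagnostics["flagged"]]
        if len(flagged):
            lines += [
                "**Warning: convergence flags raised**", "",
                f"Parameters with split-R-hat above threshold: "
                f"{', '.join(flagged.index)}", "",
            ]
        lines.append("| parameter | R-hat | bulk ESS |")
        lines.append("|---|---|---|")
        for name, row in diagnostics.iterrows():
            lines.append(f"| {name} | {row['rhat']:.4f} | {row['ess_bulk']:.0f} |")
        div = diagnostics.attrs.get("divergences")
        if div is not None:
            lines += ["", f"Divergent transitions (kept phase): {div}"]
        lines.append("")
    return "\n".join(lines)
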