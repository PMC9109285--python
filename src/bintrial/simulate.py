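"""Synthetic two-arm brief-intervention trial generator.

Emulates the design of a cluster-structured randomized trial of a brief
alcohol intervention in primary care: participants with a baseline AUDIT
total score in the risky band are randomized between a pamphlet control and
a brief-intervention arm across a handful of health centers, and the
AUDIT is re-administered at follow-up with some attrition.

Two outcome modes are supported:

``coherent`` (default)
    Follow-up AUDIT-total is simulated from a Gaussian regression on the
    baseline score with an arm effect and center intercepts; the binary
    risky-drinking status is then *derived* as ``audit_total_fu >= 8``, so
    score and status can never disagree.
``independent``
    Risky status is drawn directly from a Bernoulli-logit model with a
    specified true log odds ratio and center random intercepts, and the
    follow-up score is generated conditional on that status (>= 8 iff
    risky). This makes the logistic model exactly true, which parameter
    recovery tests require.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError

CSV_COLUMNS = [
    "id", "center", "arm", "sex", "education", "age",
    "audit_total_baseline", "audit_c_baseline",
    "audit_total_fu", "audit_c_fu", "completed",
]

ARM_LEVELS = ("control", "bi")
SEX_LEVELS = ("male", "female")
EDUCATION_LEVELS = ("incomplete", "complete", "superior")

#: AUDIT-C is roughly this fraction of the AUDIT total in the risky band
#: (the three consumption items dominate totals between 8 and 15).
AUDITC_FRACTION = 0.55


@dataclass(frozen=True)
class SimConfig:
    """True data-generating parameters for a synthetic trial.

    ``n_per_arm`` is (intervention, control). ``fixed_effects`` are the
    logit-scale coefficients (intercept, sex=female, education=complete,
    education=superior, age per year) of the follow-up risk model used in
    ``independent`` mode. ``audit_effect`` / ``auditc_effect`` are the true
    mean shifts of the follow-up scores under the intervention (negative
    means the intervention lowers drinking scores).
    """

    n_per_arm: tuple[int, int] = (174, 168)
    n_centers: int = 5
    true_log_or: float = math.log(0.6)
    fixed_effects: tuple[float, ...] = (1.1, -0.25, -0.15, -0.35, -0.01)
    sigma_c_true: float = 0.3
    audit_effect: float = -0.74
    auditc_effect: float = -0.4
    residual_sd: float = 2.5
    baseline_range: tuple[int, int] = (8, 15)
    attrition_rate: float = 0.14
    seed: int = 0
    outcome_mode: str = "coherent"
    education_probs: tuple[float, float, float] = (0.3, 0.5, 0.2)
    age_range: tuple[int, int] = (18, 65)
    # follow-up score regression on baseline (regression to the mean)
    fu_intercept: float = 2.1
    fu_slope: float = 0.6

    def __post_init__(self):
        if len(self.n_per_arm) != 2 or any(int(n) < 1 for n in self.n_per_arm):
            raise ConfigError("n_per_arm", "both arm sizes must be >= 1")
        if self.n_centers < 1:
            raise ConfigError("n_centers", "must be >= 1")
        lo, hi = self.baseline_range
        if not (0 <= lo <= hi <= 40):
            raise ConfigError("baseline_range", "need 0 <= low <= high <= 40")
        if not 0.0 <= self.attrition_rate <= 1.0:
            raise ConfigError("attrition_rate", "must lie in [0, 1]")
        if self.residual_sd <= 0:
            raise ConfigError("residual_sd", "must be > 0")
        if self.sigma_c_true < 0:
            raise ConfigError("sigma_c_true", "must be >= 0")
        if len(self.fixed_effects) != 5:
            raise ConfigError(
                "fixed_effects",
                "need 5 values: intercept, sex, edu_complete, edu_superior, age",
            )
        if self.outcome_mode not in ("coherent", "independent"):
            raise ConfigError("outcome_mode", "must be 'coherent' or 'independent'")
        if abs(sum(self.education_probs) - 1.0) > 1e-9:
            raise ConfigError("education_probs", "must sum to 1")


@dataclass(frozen=True)
class SyntheticTrial:
    """A simulated trial table together with its generating truth."""

    table: pd.DataFrame
    config: SimConfig
    center_effects: np.ndarray  # realized center intercepts, length n_centers

    def __post_init__(self):
        assert len(self.table) == sum(self.config.n_per_arm)
        assert len(self.center_effects) == self.config.n_centers


def _derive_audit_c(total: np.ndarray, shift: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """AUDIT-C as a noisy bounded fraction of the AUDIT total."""
    noisy = AUDITC_FRACTION * total + shift + rng.normal(0.0, 0.8, size=total.shape)
    c = np.clip(np.rint(noisy), 0, 12).astype(int)
    return np.minimum(c, total.astype(int))


def simulate_trial(config: SimConfig) -> SyntheticTrial:
    """Draw one synthetic trial. Deterministic given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    n_bi, n_control = config.n_per_arm
    n = n_bi + n_control

    group = np.zeros(n, dtype=int)
    group[:n_bi] = 1
    rng.shuffle(group)  # randomization order

    center = rng.integers(0, config.n_centers, size=n)
    u = rng.normal(0.0, config.sigma_c_true, size=config.n_centers) \
        if config.sigma_c_true > 0 else np.zeros(config.n_centers)

    female = rng.binomial(1, 0.5, size=n)
    education = rng.choice(3, size=n, p=config.education_probs)
    age = rng.integers(config.age_range[0], config.age_range[1] + 1, size=n)
    lo, hi = config.baseline_range
    base_total = rng.integers(lo, hi + 1, size=n)
    base_c = _derive_audit_c(base_total, np.zeros(n), rng)

    b1, b_sex, b_ec, b_es, b_age = config.fixed_effects
    if config.outcome_mode == "independent":
        eta = (
            b1
            + config.true_log_or * group
            + b_sex * female
            + b_ec * (education == 1)
            + b_es * (education == 2)
            + b_age * age
            + u[center]
        )
        risky = rng.binomial(1, 1.0 / (1.0 + np.exp(-eta)))
        # score consistent with status so the >=8 threshold inverts exactly
        fu_total = np.where(
            risky == 1, rng.integers(8, 16, size=n), rng.integers(0, 8, size=n)
        ).astype(int)
    else:
        mu = (
            config.fu_intercept
            + config.fu_slope * base_total
            + config.audit_effect * group
            + u[center]
        )
        fu_total = np.clip(
            np.rint(rng.normal(mu, config.residual_sd)), 0, 40
        ).astype(int)

    # arm shift on AUDIT-C beyond what the total already induces
    extra_c = (config.auditc_effect - AUDITC_FRACTION * config.audit_effect) * group
    fu_c = _derive_audit_c(fu_total, extra_c, rng)

    completed = rng.binomial(1, 1.0 - config.attrition_rate, size=n)

    table = pd.DataFrame(
        {
            "id": np.arange(1, n + 1),
            "center": center + 1,
            "arm": np.where(group == 1, "bi", "control"),
            "sex": np.where(female == 1, "female", "male"),
            "education": np.asarray(EDUCATION_LEVELS)[education],
            "age": age,
            "audit_total_baseline": base_total,
            "audit_c_baseline": base_c,
            "audit_total_fu": pd.array(fu_total, dtype="Int64"),
            "audit_c_fu": pd.array(fu_c, dtype="Int64"),
            "completed": completed,
        }
    )
    incomplete = table["completed"] == 0
    table.loc[incomplete, ["audit_total_fu", "audit_c_fu"]] = pd.NA
    return SyntheticTrial(table=table, config=config, center_effects=u)


def write_trial_csv(trial: SyntheticTrial | pd.DataFrame, path: str | Path) -> Path:
    """Write the canonical trial CSV (empty follow-up fields for dropouts)."""
    table = trial.table if isinstance(trial, SyntheticTrial) else trial
    path = Path(path)
    table.to_csv(path, index=False, columns=CSV_COLUMNS, na_rep="")
    return path
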