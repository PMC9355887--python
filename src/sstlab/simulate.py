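"""Independent horse-race simulator for stop-signal task cohorts.

Each trial is a race between a go process and (on stop trials) a stop
process.  Go finish times are ex-Gaussian, the standard positively
skewed model for human reaction times.  On a stop trial the stop
process finishes at ``SSD + ssrt_true + jitter``; the response is
emitted if and only if the go process wins, so responses on stop trials
are a censored (fast) sample of the go distribution.  The SSD is
assigned by the per-condition staircase from :mod:`sstlab.protocol`,
carried across blocks (practice included) within a session.

Cohorts mirror the study design this package models: three groups of 30
subjects, two stop-stimulus conditions per subject, an ~8 ms true
stopping advantage for the emotional condition, and questionnaire
covariates (STAI trait anxiety, HADS, BIS-11 impulsivity subscales)
whose non-planning subscale linearly moderates the per-subject
emotional-minus-neutral SSRT index.

By default cohorts are drawn with *empirical* moments: the realised
between-subject means/SDs equal the specified population values exactly
and the index-noise vector is exactly orthogonal to the regression
covariates (in the spirit of ``MASS::mvrnorm(empirical = TRUE)``).  A
simulated cohort thereby realises the stated study conditions rather
than a random draw from them, which is what parameter-recovery checks
need; pass ``empirical=False`` for fully random cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError
from .protocol import SessionConfig, StaircaseState, build_session, staircase_update

__all__ = [
    "SubjectParams",
    "CohortSpec",
    "TRIAL_COLUMNS",
    "simulate_subject",
    "simulate_cohort",
    "draw_exgaussian",
]

#: Canonical trial-log column order.
TRIAL_COLUMNS = [
    "subject",
    "group",
    "block",
    "trial",
    "trial_type",
    "condition",
    "arrow",
    "ssd",
    "response",
    "rt",
    "premature",
    "correct",
    "practice",
]

#: Questionnaire score ranges (min, max) used to clip generated covariates.
COVARIATE_RANGES = {
    "STAI-Y2": (20, 80),
    "HADS-anxiety": (0, 21),
    "HADS-depression": (0, 21),
    "BIS-motor": (11, 44),
    "BIS-attentional": (8, 32),
    "BIS-nonplanning": (11, 44),
}

#: Per-group covariate (mean, SD) pairs matching the modelled cohort.
COVARIATE_NORMS = {
    "SARS-CoV-2": {
        "STAI-Y2": (45.17, 9.11),
        "HADS-anxiety": (8.00, 4.13),
        "HADS-depression": (4.70, 3.72),
        "BIS-motor": (16.67, 3.24),
        "BIS-attentional": (21.23, 3.96),
        "BIS-nonplanning": (26.47, 4.17),
    },
    "Fear-Face": {
        "STAI-Y2": (46.77, 8.15),
        "HADS-anxiety": (7.00, 3.27),
        "HADS-depression": (5.97, 3.20),
        "BIS-motor": (16.60, 3.09),
        "BIS-attentional": (19.57, 3.44),
        "BIS-nonplanning": (26.50, 3.66),
    },
    "Fear-Body": {
        "STAI-Y2": (47.43, 9.55),
        "HADS-anxiety": (6.97, 2.95),
        "HADS-depression": (5.00, 3.13),
        "BIS-motor": (18.10, 2.72),
        "BIS-attentional": (20.90, 4.38),
        "BIS-nonplanning": (25.70, 3.62),
    },
}

#: Per-group neutral-condition true-SSRT (mean, between-subject SD), ms.
NEUTRAL_SSRT_NORMS = {
    "SARS-CoV-2": (242.46, 35.12),
    "Fear-Face": (235.07, 52.68),
    "Fear-Body": (242.41, 46.06),
}


def draw_exgaussian(
    rng: np.random.Generator, mu: float, sigma: float, tau: float, size: int
) -> np.ndarray:
    """Ex-Gaussian sample: Normal(mu, sigma) + Exponential(tau)."""
    return rng.normal(mu, sigma, size) + rng.exponential(tau, size)


@dataclass
class SubjectParams:
    """Generative race-model parameters for one simulated subject.

    ``ssrt_true`` maps each stop condition to that subject's mean stop
    latency (ms); ``ssrt_noise_sd`` is trial-level Gaussian jitter on
    the stop latency.  ``p_trigger_failure`` (stop process not starting
    at all) exists as a hook and defaults to 0.
    """

    subject: str
    group: str
    ssrt_true: dict[str, float]
    go_mu: float = 430.0
    go_sigma: float = 60.0
    go_tau: float = 115.0
    ssrt_noise_sd: float = 20.0
    p_go_omission: float = 0.005
    p_choice_error: float = 0.015
    p_trigger_failure: float = 0.0
    covariates: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        for name in ("go_mu", "go_sigma", "go_tau"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        for name in ("p_go_omission", "p_choice_error", "p_trigger_failure"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ConfigError(f"{name} must be a probability")
        if self.ssrt_noise_sd < 0:
            raise ConfigError("ssrt_noise_sd must be >= 0")
        for cond, v in self.ssrt_true.items():
            if v < 0:
                raise ConfigError(f"ssrt_true[{cond!r}] must be >= 0")


@dataclass
class CohortSpec:
    """Population-level description of a simulated cohort.

    ``emotional_advantage_ms`` is the true reduction in stop latency for
    the emotional condition; ``nonplanning_slope`` (ms per BIS point)
    links the BIS-11 non-planning score, centred on the cohort mean, to
    the per-subject SSRT index (emotional minus neutral).
    """

    n_per_group: int = 30
    groups: tuple[str, ...] = ("SARS-CoV-2", "Fear-Face", "Fear-Body")
    conditions: tuple[str, ...] = ("emotional", "neutral")
    emotional_advantage_ms: float = 8.3
    nonplanning_slope: float = 1.192
    index_noise_sd: float = 15.0
    neutral_ssrt_mean: dict[str, float] | float | None = None
    neutral_ssrt_sd: dict[str, float] | float | None = None
    go_mu_mean: float = 430.0
    go_mu_between_sd: float = 120.0
    go_sigma: float = 60.0
    go_tau: float = 115.0
    ssrt_noise_sd: float = 20.0
    p_go_omission: float = 0.005
    p_choice_error: float = 0.015
    empirical: bool = True
    rng_seed: int | None = None

    def __post_init__(self):
        if self.n_per_group <= 0:
            raise ConfigError("n_per_group must be positive")
        if len(set(self.groups)) != len(self.groups):
            raise ConfigError("groups must be distinct")
        if len(self.conditions) != 2:
            raise ConfigError("exactly two stop conditions (emotional, neutral) are modelled")

    def _per_group(self, value, fallback_index: int) -> dict[str, float]:
        """Resolve a scalar / mapping / None field to a per-group dict."""
        if value is None:
            return {
                g: NEUTRAL_SSRT_NORMS.get(g, NEUTRAL_SSRT_NORMS["SARS-CoV-2"])[fallback_index]
                for g in self.groups
            }
        if isinstance(value, dict):
            return {g: float(value[g]) for g in self.groups}
        return {g: float(value) for g in self.groups}

    def neutral_means(self) -> dict[str, float]:
        return self._per_group(self.neutral_ssrt_mean, 0)

    def neutral_sds(self) -> dict[str, float]:
        return self._per_group(self.neutral_ssrt_sd, 1)


def simulate_subject(
    params: SubjectParams,
    config: SessionConfig,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Simulate one subject playing a full session; returns a trial log.

    The schedule comes from :func:`sstlab.protocol.build_session`; the
    staircase state persists across all blocks of the session, practice
    included.  Stop-trial responses with ``rt < ssd`` are flagged
    premature (the response beat the stop-signal onset).  ``correct``
    means "pressed the arrow's key" on go trials and "successfully
    inhibited" on stop trials.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng if rng is not None else config.rng_seed)
    plans = build_session(config, rng)
    n = len(plans)
    cols: dict[str, list] = {c: [None] * n for c in TRIAL_COLUMNS}
    stair = StaircaseState.from_config(config)
    for i, plan in enumerate(plans):
        ssd = np.nan
        premature = False
        if plan.trial_type == "go":
            if rng.random() < params.p_go_omission:
                response, rt, correct = "none", np.nan, False
            else:
                rt = rng.normal(params.go_mu, params.go_sigma) + rng.exponential(params.go_tau)
                if rng.random() < params.p_choice_error:
                    response = "left" if plan.arrow == "right" else "right"
                    correct = False
                else:
                    response, correct = plan.arrow, True
        else:
            ssd = stair.ssd[plan.condition]
            go_finish = rng.normal(params.go_mu, params.go_sigma) + rng.exponential(
                params.go_tau
            )
            if params.p_trigger_failure and rng.random() < params.p_trigger_failure:
                stop_finish = np.inf
            else:
                stop_finish = (
                    ssd + params.ssrt_true[plan.condition] + rng.normal(0.0, params.ssrt_noise_sd)
                )
            if go_finish < stop_finish:  # go wins: response escapes
                rt = go_finish
                premature = rt < ssd
                if rng.random() < params.p_choice_error:
                    response = "left" if plan.arrow == "right" else "right"
                else:
                    response = plan.arrow
                correct = False
                inhibited = False
            else:
                response, rt, correct, inhibited = "none", np.nan, True, True
            stair = staircase_update(stair, plan.condition, inhibited)
        row = (
            params.subject,
            params.group,
            plan.block,
            plan.trial,
            plan.trial_type,
            plan.condition,
            plan.arrow,
            ssd,
            response,
            rt,
            premature,
            correct,
            plan.practice,
        )
        for c, v in zip(TRIAL_COLUMNS, row):
            cols[c][i] = v
    df = pd.DataFrame(cols)
    df["ssd"] = df["ssd"].astype(float)
    df["rt"] = df["rt"].astype(float)
    df["premature"] = df["premature"].astype(bool)
    df["correct"] = df["correct"].astype(bool)
    df["practice"] = df["practice"].astype(bool)
    return df


def _empirical_columns(draws: np.ndarray) -> np.ndarray:
    """Rescale each column of ``draws`` to sample mean 0 and sample SD 1
    (ddof=1) exactly."""
    z = draws - draws.mean(axis=0)
    sd = z.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    return z / sd


def _orthogonal_noise(
    rng: np.random.Generator, design: np.ndarray, sd: float
) -> np.ndarray:
    """Gaussian noise vector with sample SD exactly ``sd`` and exactly
    zero sample correlation with every column of ``design``."""
    n = design.shape[0]
    x = np.column_stack([np.ones(n), design])
    raw = rng.normal(size=n)
    beta, *_ = np.linalg.lstsq(x, raw, rcond=None)
    resid = raw - x @ beta
    s = resid.std(ddof=1)
    if s == 0:  # pragma: no cover - degenerate tiny-n corner
        return np.zeros(n)
    return resid / s * sd


def _draw_covariates(
    rng: np.random.Generator, group: str, n: int, empirical: bool
) -> pd.DataFrame:
    """Integer questionnaire scores for one group, clipped to instrument
    ranges; BIS total is the sum of the three subscales."""
    norms = COVARIATE_NORMS.get(group, COVARIATE_NORMS["SARS-CoV-2"])
    out = {}
    for name, (mean, sd) in norms.items():
        z = rng.normal(size=n)
        if empirical and n > 1:
            z = _empirical_columns(z[:, None])[:, 0]
        lo, hi = COVARIATE_RANGES[name]
        out[name] = np.clip(np.rint(mean + sd * z), lo, hi).astype(int)
    df = pd.DataFrame(out)
    df["BIS-total"] = df["BIS-motor"] + df["BIS-attentional"] + df["BIS-nonplanning"]
    return df


def draw_cohort_params(
    spec: CohortSpec, rng: np.random.Generator | int | None = None
) -> list[SubjectParams]:
    """Draw the generative parameter set for every subject of a cohort.

    Subject ids are ``s001 ...`` in group order.  The emotional-condition
    true SSRT follows the linear moderation rule
    ``neutral - advantage + slope * (nonplanning - cohort mean) + noise``.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng if rng is not None else spec.rng_seed)
    n_mean = spec.neutral_means()
    n_sd = spec.neutral_sds()
    frames = []
    for group in spec.groups:
        cov = _draw_covariates(rng, group, spec.n_per_group, spec.empirical)
        latent = rng.normal(size=(spec.n_per_group, 2))
        if spec.empirical and spec.n_per_group > 1:
            latent = _empirical_columns(latent)
        cov["group"] = group
        cov["ssrt_neutral"] = n_mean[group] + n_sd[group] * latent[:, 0]
        cov["go_mu"] = np.maximum(150.0, spec.go_mu_mean + spec.go_mu_between_sd * latent[:, 1])
        frames.append(cov)
    table = pd.concat(frames, ignore_index=True)
    np_scores = table["BIS-nonplanning"].to_numpy(float)
    predictors = table[["STAI-Y2", "BIS-motor", "BIS-attentional", "BIS-nonplanning"]].to_numpy(
        float
    )
    if spec.empirical and len(table) > predictors.shape[1] + 2:
        noise = _orthogonal_noise(rng, predictors, spec.index_noise_sd)
    else:
        noise = rng.normal(0.0, spec.index_noise_sd, len(table))
    index_true = (
        -spec.emotional_advantage_ms
        + spec.nonplanning_slope * (np_scores - np_scores.mean())
        + noise
    )
    table["ssrt_emotional"] = np.maximum(1.0, table["ssrt_neutral"] + index_true)
    params = []
    for i, row in table.iterrows():
        params.append(
            SubjectParams(
                subject=f"s{i + 1:03d}",
                group=row["group"],
                ssrt_true={"emotional": row["ssrt_emotional"], "neutral": row["ssrt_neutral"]},
                go_mu=row["go_mu"],
                go_sigma=spec.go_sigma,
                go_tau=spec.go_tau,
                ssrt_noise_sd=spec.ssrt_noise_sd,
                p_go_omission=spec.p_go_omission,
                p_choice_error=spec.p_choice_error,
                covariates={
                    k: row[k]
                    for k in (
                        "STAI-Y2",
                        "HADS-anxiety",
                        "HADS-depression",
                        "BIS-total",
                        "BIS-motor",
                        "BIS-attentional",
                        "BIS-nonplanning",
                    )
                },
            )
        )
    return params


def params_to_frame(params: list[SubjectParams]) -> pd.DataFrame:
    """Generative-truth table: one row per subject with race parameters,
    per-condition true SSRT, the true index, and covariates."""
    rows = []
    for p in params:
        row = {
            "subject": p.subject,
            "group": p.group,
            "go_mu": p.go_mu,
            "go_sigma": p.go_sigma,
            "go_tau": p.go_tau,
            "ssrt_noise_sd": p.ssrt_noise_sd,
            "p_go_omission": p.p_go_omission,
            "p_choice_error": p.p_choice_error,
        }
        for cond, v in p.ssrt_true.items():
            row[f"ssrt_true_{cond}"] = v
        if {"emotional", "neutral"} <= set(p.ssrt_true):
            row["ssrt_index_true"] = p.ssrt_true["emotional"] - p.ssrt_true["neutral"]
        row.update(p.covariates)
        rows.append(row)
    return pd.DataFrame(rows)


def simulate_cohort(
    spec: CohortSpec,
    config: SessionConfig | None = None,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a full cohort; returns (trial log, generative truth).

    One master seed drives everything: cohort-level parameters come from
    the master stream and each subject's session from a child stream
    spawned deterministically from it, so cohorts are reproducible
    subject by subject.
    """
    if config is None:
        config = SessionConfig()
    if seed is None:
        seed = spec.rng_seed
    master = np.random.SeedSequence(seed)
    param_stream, session_stream = master.spawn(2)
    params = draw_cohort_params(spec, np.random.default_rng(param_stream))
    children = session_stream.spawn(len(params))
    logs = [
        simulate_subject(p, config, np.random.default_rng(child))
        for p, child in zip(params, children)
    ]
    return pd.concat(logs, ignore_index=True), params_to_frame(params)
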