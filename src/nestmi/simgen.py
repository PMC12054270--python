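"""Synthetic longitudinal cohort generator.

Emulates a cohort-study design: six measured variables (smoking, BMI, systolic
and diastolic blood pressure, total cholesterol, fasting glucose) observed at
evenly spaced exams, drawn jointly from a multivariate normal with
moderate-to-high within-variable correlation across exams and low
between-variable correlation; binary variables are dichotomised latent draws.
Missingness is imposed in two halves of the cohort: logistic-model MAR
(item-level and whole-wave) in one half, percentile-rule MNAR non-attendance
in the other.  Death times follow a piecewise-exponential model driven by the
true composite score, and exams after death are flagged as a third mechanism.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .panel import ComponentPanel, Mechanism, MissingnessMask, col
from .rng import stream

__all__ = [
    "CohortSpec",
    "MarModel",
    "MarSpec",
    "MnarScenario",
    "SurvivalSpec",
    "EventTable",
    "default_cohort_spec",
    "default_mar_spec",
    "default_survival_spec",
    "dichotomize_at_quantile",
    "generate_full_panel",
    "generate_mar_missingness",
    "generate_mnar_nonattendance",
    "generate_event_times",
    "truncate_after_event",
]

log = logging.getLogger(__name__)

_CHUNK = 100_000  # subjects per MVN draw when generating very large populations


# --------------------------------------------------------------------------- spec
@dataclass
class CohortSpec:
    """Parameters of the full-data generator.

    ``means``/``sds`` map each variable to one value per time point; for binary
    variables the latent scale is standard normal and ``binary_targets`` gives
    the target prevalence per time.  ``within_corr`` is the exchangeable
    correlation of one variable across time points, ``between_corr`` the
    correlation between any two distinct variables (all time-pairs), and
    ``covariate_corr`` the correlation of each variable with the baseline
    covariates, which enter the joint draw.
    """

    n_subjects: int
    n_times: int = 5
    time_step: float = 5.0
    variables: tuple = ("SMK", "BMI", "SBP", "DBP", "TC", "BG")
    binary_variables: frozenset = field(default_factory=lambda: frozenset({"SMK"}))
    means: Mapping[str, tuple] = field(default_factory=dict)
    sds: Mapping[str, tuple] = field(default_factory=dict)
    within_corr: Mapping[str, float] = field(default_factory=dict)
    between_corr: float = 0.15
    covariate_corr: float = 0.10
    binary_targets: Mapping[str, tuple] = field(default_factory=dict)
    age_mean: float = 55.0
    age_sd: float = 9.0
    sex_prevalence: float = 0.45

    def validate(self) -> None:
        T = self.n_times
        for v in self.variables:
            if v in self.binary_variables:
                targets = self.binary_targets.get(v)
                if targets is None or len(targets) != T:
                    raise ValueError(f"binary_targets missing or wrong length for {v}")
                if not all(0 < p < 1 for p in targets):
                    raise ValueError(f"prevalences for {v} must lie in (0,1)")
            else:
                mu, sd = self.means.get(v), self.sds.get(v)
                if mu is None or sd is None or len(mu) != T or len(sd) != T:
                    raise ValueError(f"means/sds missing or wrong length for {v}")
                if any(np.diff(mu) < 0):
                    raise ValueError(f"means for {v} must be non-decreasing over time")
                if any(s <= 0 for s in sd):
                    raise ValueError(f"sds for {v} must be positive")
            rho = self.within_corr.get(v, 0.0)
            if not 0 <= rho < 1:
                raise ValueError(f"within_corr for {v} must lie in [0,1)")
        if not 0 < self.sex_prevalence < 1:
            raise ValueError("sex_prevalence must lie in (0,1)")
        self.correlation_matrix()  # raises on non-PD assembly

    # ---------------------------------------------------------------- structure
    def latent_columns(self) -> list:
        cols = [col(v, t) for v in self.variables for t in range(1, self.n_times + 1)]
        return cols + ["age", "sex"]

    def correlation_matrix(self) -> np.ndarray:
        """Assemble the joint correlation over (variable x time) + covariates.

        Raises a ``ValueError`` naming the offending blocks if the result is
        not positive definite.
        """
        V, T = len(self.variables), self.n_times
        K = V * T + 2
        R = np.full((K, K), self.between_corr)
        for i, v in enumerate(self.variables):
            sl = slice(i * T, (i + 1) * T)
            rho = self.within_corr.get(v, 0.0)
            block = np.full((T, T), rho)
            np.fill_diagonal(block, 1.0)
            R[sl, sl] = block
        R[:, -2:] = self.covariate_corr
        R[-2:, :] = self.covariate_corr
        R[-2, -1] = R[-1, -2] = 0.0
        np.fill_diagonal(R, 1.0)
        try:
            np.linalg.cholesky(R)
        except np.linalg.LinAlgError:
            raise ValueError(
                "assembled joint correlation matrix is not positive definite; "
                f"check within_corr blocks {dict(self.within_corr)} against "
                f"between_corr={self.between_corr}, covariate_corr={self.covariate_corr}"
            ) from None
        return R


def default_cohort_spec(n_subjects: int = 3700) -> CohortSpec:
    """Default cohort: an ageing population with slowly worsening risk factors.

    Means drift upward over the 20-year window (worse cardiovascular health),
    SDs are typical of mid-to-late-life cohorts, within-variable correlation is
    0.7 and between-variable correlation 0.15.
    """
    return CohortSpec(
        n_subjects=n_subjects,
        means={
            "BMI": (27.0, 27.4, 27.8, 28.1, 28.3),
            "SBP": (125.0, 128.0, 131.0, 134.0, 137.0),
            "DBP": (78.0, 79.0, 79.5, 80.0, 80.0),
            "TC": (205.0, 208.0, 210.0, 212.0, 213.0),
            "BG": (98.0, 100.0, 102.0, 105.0, 108.0),
        },
        sds={
            "BMI": (4.8,) * 5,
            "SBP": (17.0,) * 5,
            "DBP": (10.0,) * 5,
            "TC": (38.0,) * 5,
            "BG": (22.0,) * 5,
        },
        within_corr={v: 0.70 for v in ("SMK", "BMI", "SBP", "DBP", "TC", "BG")},
        between_corr=0.15,
        covariate_corr=0.10,
        binary_targets={"SMK": (0.22,) * 5},
    )


# ----------------------------------------------------------------- full panel
def dichotomize_at_quantile(latent: np.ndarray, target_rate: float) -> np.ndarray:
    """1 for values above the (1 - target_rate) empirical quantile, else 0.

    The proportion of ones equals ``target_rate`` up to rank granularity.
    """
    if not 0 < target_rate < 1:
        raise ValueError("target_rate must lie in (0,1)")
    latent = np.asarray(latent, dtype=float)
    if np.ptp(latent) == 0:
        raise ValueError("quantile threshold undefined for a constant latent vector")
    threshold = np.quantile(latent, 1.0 - target_rate)
    return (latent > threshold).astype(float)


def generate_full_panel(spec: CohortSpec, seed: int) -> ComponentPanel:
    """Draw a complete panel from the joint multivariate-normal model."""
    spec.validate()
    R = spec.correlation_matrix()
    L = np.linalg.cholesky(R)
    rng = stream(seed, "panel")
    n, T = spec.n_subjects, spec.n_times
    parts = []
    done = 0
    while done < n:
        m = min(_CHUNK, n - done)
        parts.append(rng.standard_normal((m, R.shape[0])) @ L.T)
        done += m
    Z = parts[0] if len(parts) == 1 else np.vstack(parts)

    data = {}
    for i, v in enumerate(spec.variables):
        for j, t in enumerate(range(1, T + 1)):
            z = Z[:, i * T + j]
            if v in spec.binary_variables:
                data[col(v, t)] = dichotomize_at_quantile(z, spec.binary_targets[v][j])
            else:
                data[col(v, t)] = spec.means[v][j] + spec.sds[v][j] * z
    covs = pd.DataFrame(
        {
            "age": spec.age_mean + spec.age_sd * Z[:, -2],
            "sex": dichotomize_at_quantile(Z[:, -1], spec.sex_prevalence),
        }
    )
    frame = pd.DataFrame(data)
    return ComponentPanel(
        data=frame,
        covariates=covs,
        variables=spec.variables,
        n_times=T,
        time_step=spec.time_step,
        binary_variables=spec.binary_variables,
    )


# ------------------------------------------------------------------- MAR side
@dataclass
class MarModel:
    """One logistic missingness model, applied at each time point t = 2..T.

    logit P(missing at t) = intercept_t + b_value * z(baseline value)
                            + b_comp * z(baseline composite)
                            + b_age * z(age) + b_sex * sex
    Predictors are standardised against their sample distribution, so the
    intercepts are approximately the logits of the marginal rates.
    """

    intercepts: tuple
    b_value: float = 0.0
    b_comp: float = 0.0
    b_age: float = 0.0
    b_sex: float = 0.0


@dataclass
class MarSpec:
    """Item-level models for two designated components plus a wave model."""

    item_models: Mapping[str, MarModel]
    wave_model: MarModel

    def validate(self, panel: ComponentPanel) -> None:
        for v in self.item_models:
            if v not in panel.variables:
                raise ValueError(f"MAR item model references unknown variable {v!r}")


def default_mar_spec(n_times: int = 5) -> MarSpec:
    """Item missingness for BMI and TC plus whole-wave non-attendance.

    Intercepts are calibrated so that, applied to half of the cohort, the
    realized rates match the documented study conditions: per-component item
    rates of 5/3/8/9% and wave non-attendance of 5/4/8/11% of the full cohort
    at t = 2..5 (hence twice that within the affected half).
    """
    if n_times != 5:
        raise ValueError("default MAR spec is calibrated for five time points")
    item_rates = (0.10, 0.06, 0.16, 0.18)   # within the MAR half
    wave_rates = (0.10, 0.08, 0.16, 0.22)
    item = lambda: MarModel(  # noqa: E731
        intercepts=tuple(float(logit(r)) for r in item_rates),
        b_value=0.3, b_age=0.1, b_sex=0.1,
    )
    wave = MarModel(
        intercepts=tuple(float(logit(r)) for r in wave_rates),
        b_comp=-0.3, b_age=0.1, b_sex=0.1,
    )
    return MarSpec(item_models={"BMI": item(), "TC": item()}, wave_model=wave)


def _mar_probabilities(panel, model, variable, baseline_composite):
    """Per-subject, per-time (t=2..T) missingness probabilities."""
    z = lambda x: (x - np.mean(x)) / (np.std(x) or 1.0)  # noqa: E731
    eta0 = np.zeros(panel.n_subjects)
    if model.b_value:
        eta0 = eta0 + model.b_value * z(panel.data[col(variable, 1)].to_numpy())
    if model.b_comp:
        eta0 = eta0 + model.b_comp * z(baseline_composite)
    eta0 = eta0 + model.b_age * z(panel.covariates["age"].to_numpy())
    eta0 = eta0 + model.b_sex * panel.covariates["sex"].to_numpy()
    return np.stack([expit(a + eta0) for a in model.intercepts], axis=1)


def generate_mar_missingness(
    panel: ComponentPanel,
    mar: MarSpec,
    seed: int,
    subjects: np.ndarray | None = None,
    criteria=None,
) -> MissingnessMask:
    """Bernoulli MAR missingness (items + waves) in the MAR half of the cohort.

    ``subjects`` is a boolean membership vector for the MAR group; by default
    the first half of the cohort.  Missingness is drawn only at t = 2..T.
    """
    from .composite import build_composite, default_criteria

    mar.validate(panel)
    if len(mar.wave_model.intercepts) != panel.n_times - 1:
        raise ValueError("wave model must supply one intercept per time point t=2..T")
    if subjects is None:
        subjects = np.arange(panel.n_subjects) < panel.n_subjects // 2
    criteria = criteria or default_criteria()
    comp1 = build_composite(panel, criteria).iloc[:, 0].to_numpy()

    rng = stream(seed, "mar")
    mask = MissingnessMask.all_observed(panel)
    codes = mask.codes.to_numpy()
    colnames = list(mask.codes.columns)
    cidx = {c: i for i, c in enumerate(colnames)}

    # whole-wave non-attendance
    p_wave = _mar_probabilities(panel, mar.wave_model, None, comp1)
    draw = rng.random(p_wave.shape) < p_wave
    draw &= subjects[:, None]
    for j, t in enumerate(range(2, panel.n_times + 1)):
        rows = np.flatnonzero(draw[:, j])
        for v in panel.variables:
            codes[rows, cidx[col(v, t)]] = int(Mechanism.MAR)

    # item-level missingness for the designated components
    for v, model in mar.item_models.items():
        p_item = _mar_probabilities(panel, model, v, comp1)
        d = (rng.random(p_item.shape) < p_item) & subjects[:, None]
        for j, t in enumerate(range(2, panel.n_times + 1)):
            rows = np.flatnonzero(d[:, j])
            codes[rows, cidx[col(v, t)]] = int(Mechanism.MAR)

    mask.codes = pd.DataFrame(codes, index=panel.data.index, columns=colnames)
    return mask


# ------------------------------------------------------------------ MNAR side
@dataclass
class MnarScenario:
    """Percentile-rule MNAR non-attendance.

    Scenario 1 targets the lower tail of the composite distribution (declining
    health), scenario 2 the upper tail, scenario 3 both tails.  In ``rule``
    mode the scheduled tail fraction is flagged and then dropped with
    probability ``nonattend_prob``; in ``rates`` mode the tail fraction is
    back-calculated so that the realized non-attendance matches ``rates``
    (fractions of the *whole* cohort when ``rate_denominator='cohort'``).
    """

    scenario_id: int = 1
    percentile_schedule: tuple = (0.10, 0.15, 0.20, 0.25)
    nonattend_prob: float = 0.8
    mode: str = "rule"  # "rule" | "rates"
    rates: tuple = (0.10, 0.125, 0.15, 0.175)
    rate_denominator: str = "cohort"  # "cohort" | "group"

    @property
    def tail(self) -> str:
        return {1: "lower", 2: "upper", 3: "both"}[self.scenario_id]

    def validate(self, n_times: int) -> None:
        if self.scenario_id not in (1, 2, 3):
            raise ValueError("scenario_id must be 1, 2 or 3")
        sched = self.rates if self.mode == "rates" else self.percentile_schedule
        if len(sched) != n_times - 1:
            raise ValueError("schedule length must equal n_times - 1")
        if not 0 <= self.nonattend_prob <= 1:
            raise ValueError("nonattend_prob must lie in [0,1]")
        if self.mode not in ("rule", "rates"):
            raise ValueError("mode must be 'rule' or 'rates'")


def generate_mnar_nonattendance(
    panel: ComponentPanel,
    scenario: MnarScenario,
    seed: int,
    subjects: np.ndarray | None = None,
    criteria=None,
) -> MissingnessMask:
    """Composite-percentile non-attendance in the MNAR half of the cohort.

    At each t = 2..T, group members whose composite at t ranks in the
    scheduled tail (ties broken by uniform jitter so the selected fraction is
    exact) lose all components with probability ``nonattend_prob``.
    """
    from .composite import build_composite, default_criteria

    scenario.validate(panel.n_times)
    if subjects is None:
        subjects = np.arange(panel.n_subjects) >= panel.n_subjects // 2
    criteria = criteria or default_criteria()
    comp = build_composite(panel, criteria)
    rng = stream(seed, "mnar")

    group = np.flatnonzero(subjects)
    n_group = len(group)
    mask = MissingnessMask.all_observed(panel)
    codes = mask.codes.to_numpy()
    cidx = {c: i for i, c in enumerate(mask.codes.columns)}

    for j, t in enumerate(range(2, panel.n_times + 1)):
        if scenario.mode == "rates":
            target = scenario.rates[j]
            if scenario.rate_denominator == "cohort":
                target = target * panel.n_subjects / n_group
            frac = target / scenario.nonattend_prob if scenario.nonattend_prob else 0.0
            if frac > 1:
                raise ValueError("rate-calibrated tail fraction exceeds 1")
        else:
            frac = scenario.percentile_schedule[j]
        scores = comp.iloc[group, t - 1].to_numpy()
        key = scores + rng.uniform(0, 0.5, n_group)  # break integer ties, keep order
        order = np.argsort(key, kind="stable")
        if scenario.tail == "both":
            k = int(round(frac / 2 * n_group))
            flagged = np.concatenate([order[:k], order[n_group - k:]])
        else:
            k = int(round(frac * n_group))
            flagged = order[:k] if scenario.tail == "lower" else order[n_group - k:]
        chosen = group[flagged[rng.random(len(flagged)) < scenario.nonattend_prob]]
        for v in panel.variables:
            codes[chosen, cidx[col(v, t)]] = int(Mechanism.MNAR)

    mask.codes = pd.DataFrame(codes, index=panel.data.index, columns=mask.codes.columns)
    return mask


# ------------------------------------------------------------------- survival
@dataclass
class SurvivalSpec:
    """Piecewise-exponential death model driven by the true composite score.

    Interval t covers [(t-1)*interval_length, t*interval_length) and carries
    baseline hazard ``interval_hazards[t-1]`` per year, multiplied by
    exp(log_hr_truth * C_it + covariate_log_hrs . (age - age_center, sex)).
    """

    interval_hazards: tuple = (0.012, 0.017, 0.022, 0.027, 0.032)
    log_hr_truth: float = float(np.log(0.85))
    covariate_log_hrs: tuple = (float(np.log(1.06)), float(np.log(1.4)))
    interval_length: float = 5.0
    age_center: float = 55.0

    @property
    def admin_censor_time(self) -> float:
        return self.interval_length * len(self.interval_hazards)

    def validate(self) -> None:
        if any(h <= 0 for h in self.interval_hazards):
            raise ValueError("interval hazards must be positive")


def default_survival_spec() -> SurvivalSpec:
    """Defaults calibrated to roughly 40% cumulative mortality by end of follow-up."""
    return SurvivalSpec()


@dataclass
class EventTable:
    """Per-subject event/censor time (years) and indicator."""

    table: pd.DataFrame  # columns: event_time, event_indicator

    @property
    def event_time(self) -> np.ndarray:
        return self.table["event_time"].to_numpy()

    @property
    def event_indicator(self) -> np.ndarray:
        return self.table["event_indicator"].to_numpy()


def generate_event_times(
    panel: ComponentPanel, surv: SurvivalSpec, seed: int, criteria=None
) -> EventTable:
    """Simulate piecewise-exponential death times from the true composite.

    The hazard in interval t uses the (pre-missingness) composite at the exam
    opening the interval; a subject dies in the first interval whose
    exponential draw falls inside it, otherwise is administratively censored.
    """
    from .composite import build_composite, default_criteria

    surv.validate()
    criteria = criteria or default_criteria()
    comp = build_composite(panel, criteria).to_numpy()
    if np.isnan(comp).any():
        raise ValueError("event generation requires a complete panel")
    n = panel.n_subjects
    rng = stream(seed, "events")
    age = panel.covariates["age"].to_numpy() - surv.age_center
    sex = panel.covariates["sex"].to_numpy()
    g2 = np.asarray(surv.covariate_log_hrs)
    cov_eta = g2[0] * age + g2[1] * sex

    time = np.full(n, surv.admin_censor_time)
    dead = np.zeros(n, dtype=bool)
    for t, lam0 in enumerate(surv.interval_hazards, start=1):
        ct = comp[:, min(t, panel.n_times) - 1]
        rate = lam0 * np.exp(surv.log_hr_truth * ct + cov_eta)
        draw = rng.exponential(1.0, n) / rate
        hit = (~dead) & (draw < surv.interval_length)
        time[hit] = (t - 1) * surv.interval_length + draw[hit]
        dead |= hit
    return EventTable(
        table=pd.DataFrame(
            {"event_time": time, "event_indicator": dead.astype(int)},
            index=panel.data.index,
        )
    )


def truncate_after_event(
    mask: MissingnessMask, events: EventTable, panel: ComponentPanel
) -> MissingnessMask:
    """Label every cell at exams strictly after a subject's death as post-death.

    Overrides prior labels; idempotent.
    """
    if not mask.codes.index.equals(events.table.index):
        raise ValueError("mask and event table refer to different subjects")
    out = mask.copy()
    codes = out.codes.to_numpy()
    cidx = {c: i for i, c in enumerate(out.codes.columns)}
    dead = events.event_indicator == 1
    for t in panel.times():
        after = dead & (panel.exam_time(t) > events.event_time)
        rows = np.flatnonzero(after)
        for v in panel.variables:
            codes[rows, cidx[col(v, t)]] = int(Mechanism.DEATH)
    out.codes = pd.DataFrame(codes, index=mask.codes.index, columns=mask.codes.columns)
    return out
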