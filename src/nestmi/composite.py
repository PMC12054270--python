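"""Composite health score: dichotomisation, scoring and comparator transforms.

The composite C_it sums P ideal-level indicators, one per component.  The
blood-pressure component pools two measured variables (SBP and DBP) with a
conjunctive rule; dichotomisation happens after imputation, never before.
Default thresholds follow the ideal levels of the Life's Simple 7 metrics and
every threshold is configurable.
"""

from __future__ import annotations

import operator
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import ComponentPanel, Mechanism, MissingnessMask, col

__all__ = [
    "ComponentRule",
    "IdealCriteria",
    "default_criteria",
    "build_composite",
    "locf_fill",
    "cc_restrict",
]

_OPS = {"<": operator.lt, "<=": operator.le, "==": operator.eq, ">": operator.gt, ">=": operator.ge}


@dataclass(frozen=True)
class ComponentRule:
    """One component's ideal-level rule: the AND of (variable, op, threshold) terms."""

    component: str
    terms: tuple  # of (variable, op, threshold)


@dataclass
class IdealCriteria:
    """Exactly P component rules mapping measured variables to indicators."""

    rules: tuple = ()
    metadata: dict = field(default_factory=dict)

    def validate(self, panel: ComponentPanel) -> None:
        for rule in self.rules:
            for var, op, thr in rule.terms:
                if var not in panel.variables:
                    raise KeyError(f"criteria reference unknown component {var!r}")
                if op not in _OPS:
                    raise ValueError(f"unknown comparison {op!r}")
                if not np.isfinite(thr):
                    raise ValueError("thresholds must be finite")

    @property
    def n_components(self) -> int:
        return len(self.rules)


def default_criteria() -> IdealCriteria:
    """Composite-5 ideal levels (Life's Simple 7 conventions).

    Smoking ideal = non-smoker; BMI < 25 kg/m^2; blood pressure ideal requires
    SBP < 120 mmHg AND DBP < 80 mmHg; total cholesterol < 200 mg/dL; fasting
    glucose < 100 mg/dL.
    """
    return IdealCriteria(
        rules=(
            ComponentRule("SMK", (("SMK", "<=", 0.5),)),
            ComponentRule("BMI", (("BMI", "<", 25.0),)),
            ComponentRule("BP", (("SBP", "<", 120.0), ("DBP", "<", 80.0))),
            ComponentRule("TC", (("TC", "<", 200.0),)),
            ComponentRule("BG", (("BG", "<", 100.0),)),
        ),
        metadata={"thresholds": "Life's Simple 7 ideal-level defaults"},
    )


def build_composite(panel: ComponentPanel, criteria: IdealCriteria | None = None) -> pd.DataFrame:
    """Sum the component indicators at each subject-time.

    The score is defined only where every component indicator is determinable;
    any missing contributing variable makes the cell NaN.  Higher scores mean
    better health.
    """
    criteria = criteria or default_criteria()
    criteria.validate(panel)
    T = panel.n_times
    out = np.zeros((panel.n_subjects, T))
    for rule in criteria.rules:
        ind = np.ones((panel.n_subjects, T))
        for var, op, thr in rule.terms:
            vals = panel.data[[col(var, t) for t in panel.times()]].to_numpy(dtype=float)
            term = np.where(np.isnan(vals), np.nan, _OPS[op](vals, thr).astype(float))
            ind = ind * term
        out = out + ind
    return pd.DataFrame(out, index=panel.data.index, columns=list(panel.times()))


def locf_fill(panel: ComponentPanel, mask: MissingnessMask) -> ComponentPanel:
    """Fill each missing cell with the last prior observation of that component.

    Requires time point 1 fully observed, so every monotone chain has a source.
    """
    from .panel import apply_mask

    blanked = apply_mask(panel, mask)
    out = blanked.copy()
    for v in panel.variables:
        cols = [col(v, t) for t in panel.times()]
        out.data[cols] = blanked.data[cols].ffill(axis=1)
    return out


def cc_restrict(panel: ComponentPanel, mask: MissingnessMask) -> ComponentPanel:
    """Complete-case restriction per subject-time.

    Any subject-time with at least one missing component contributes no data
    at that time (all its variables are blanked); other times are kept.
    """
    from .panel import apply_mask

    blanked = apply_mask(panel, mask)
    out = blanked.copy()
    vals = out.data.to_numpy(dtype=float, copy=True)
    T = panel.n_times
    for ti, t in enumerate(panel.times()):
        cols = [panel.columns().index(col(v, t)) for v in panel.variables]
        any_missing = np.isnan(vals[:, cols]).any(axis=1)
        vals[np.ix_(any_missing, cols)] = np.nan
    out.data = pd.DataFrame(vals, index=panel.data.index, columns=panel.data.columns)
    return out
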