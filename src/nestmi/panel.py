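"""Containers for longitudinal component panels and mechanism-labelled masks.

A :class:`ComponentPanel` holds the subject x time x variable grid of raw
component values (one wide column per variable-time pair, e.g. ``BMI_3``)
together with the baseline covariates.  A :class:`MissingnessMask` is an
aligned grid of mechanism codes: observed, MNAR non-attendance (type A),
MAR (type B) or post-death.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import IntEnum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = ["Mechanism", "ComponentPanel", "MissingnessMask", "col", "apply_mask"]


class Mechanism(IntEnum):
    """Per-cell missingness mechanism label."""

    OBS = 0
    MNAR = 1  # type A: non-attendance driven by the current (unobserved) value
    MAR = 2   # type B: missingness explained by observed data
    DEATH = 3  # cell falls after the subject's death


def col(variable: str, t: int) -> str:
    """Wide-format column name for ``variable`` at time point ``t`` (1-based)."""
    return f"{variable}_{t}"


@dataclass
class ComponentPanel:
    """Subject x time x variable grid plus baseline covariates.

    Attributes
    ----------
    data : DataFrame indexed by subject id with columns ``<VAR>_<t>`` in
        variable-major order; binary variables are coded 0/1.
    covariates : DataFrame with columns ``age`` (years) and ``sex`` (0/1),
        aligned to ``data``.
    variables : ordered variable names.
    n_times : number of evenly spaced time points (t = 1..n_times).
    time_step : calendar spacing of time points in years.
    binary_variables : subset of ``variables`` coded 0/1.
    """

    data: pd.DataFrame
    covariates: pd.DataFrame
    variables: tuple
    n_times: int
    time_step: float = 5.0
    binary_variables: frozenset = field(default_factory=lambda: frozenset({"SMK"}))

    def __post_init__(self):
        self.variables = tuple(self.variables)
        expected = self.columns()
        if list(self.data.columns) != expected:
            self.data = self.data.loc[:, expected]
        if not self.data.index.equals(self.covariates.index):
            raise ValueError("data and covariates must share a subject index")

    def columns(self) -> list:
        return [col(v, t) for v in self.variables for t in self.times()]

    def times(self) -> range:
        return range(1, self.n_times + 1)

    @property
    def n_subjects(self) -> int:
        return len(self.data)

    @property
    def time_grid(self) -> np.ndarray:
        """Calendar offset in years of each time point (t=1 is 0.0)."""
        return np.arange(self.n_times) * self.time_step

    def exam_time(self, t: int) -> float:
        return (t - 1) * self.time_step

    def values_of(self, variable: str) -> pd.DataFrame:
        """Subject x time block for one variable."""
        return self.data[[col(variable, t) for t in self.times()]]

    def copy(self) -> "ComponentPanel":
        return replace(self, data=self.data.copy(), covariates=self.covariates)

    # ------------------------------------------------------------------ io
    def to_long(self, mask: "MissingnessMask | None" = None) -> pd.DataFrame:
        """Long-format export (subject_id, time, variable, value, mechanism).

        Covariates are encoded as pseudo-variables at time 0.
        """
        rows = []
        mech = mask.codes if mask is not None else None
        for v in self.variables:
            for t in self.times():
                c = col(v, t)
                frame = pd.DataFrame(
                    {
                        "subject_id": self.data.index,
                        "time": t,
                        "variable": v,
                        "value": self.data[c].to_numpy(),
                        "mechanism": (
                            [Mechanism(m).name for m in mech[c]] if mech is not None else "OBS"
                        ),
                    }
                )
                rows.append(frame)
        for cv in self.covariates.columns:
            rows.append(
                pd.DataFrame(
                    {
                        "subject_id": self.covariates.index,
                        "time": 0,
                        "variable": cv,
                        "value": self.covariates[cv].to_numpy(),
                        "mechanism": "OBS",
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)

    @classmethod
    def from_long(
        cls,
        long: pd.DataFrame,
        variables: Sequence[str] | None = None,
        time_step: float = 5.0,
        binary_variables: Iterable[str] = ("SMK",),
    ) -> tuple["ComponentPanel", "MissingnessMask"]:
        """Rebuild a panel (and mask) from :meth:`to_long` output."""
        body = long[long["time"] > 0]
        if variables is None:
            variables = list(dict.fromkeys(body["variable"]))
        n_times = int(body["time"].max())
        wide = body.pivot_table(
            index="subject_id", columns=["variable", "time"], values="value", aggfunc="first"
        )
        data = pd.DataFrame(index=wide.index)
        for v in variables:
            for t in range(1, n_times + 1):
                data[col(v, t)] = wide[(v, t)]
        covs = long[long["time"] == 0].pivot_table(
            index="subject_id", columns="variable", values="value", aggfunc="first"
        )
        covs = covs.loc[data.index]
        panel = cls(
            data=data,
            covariates=covs,
            variables=tuple(variables),
            n_times=n_times,
            time_step=time_step,
            binary_variables=frozenset(binary_variables),
        )
        mech_codes = {m.name: int(m) for m in Mechanism}
        mech_wide = body.assign(code=body["mechanism"].map(mech_codes)).pivot_table(
            index="subject_id", columns=["variable", "time"], values="code", aggfunc="first"
        )
        codes = pd.DataFrame(index=data.index)
        for v in variables:
            for t in range(1, n_times + 1):
                codes[col(v, t)] = mech_wide[(v, t)].astype(np.int8)
        return panel, MissingnessMask(codes=codes)


@dataclass
class MissingnessMask:
    """Mechanism codes aligned cell-for-cell with a panel's wide data frame."""

    codes: pd.DataFrame

    @classmethod
    def all_observed(cls, panel: ComponentPanel) -> "MissingnessMask":
        codes = pd.DataFrame(
            np.zeros(panel.data.shape, dtype=np.int8),
            index=panel.data.index,
            columns=panel.data.columns,
        )
        return cls(codes=codes)

    def copy(self) -> "MissingnessMask":
        return MissingnessMask(codes=self.codes.copy())

    def counts(self) -> pd.Series:
        flat = self.codes.to_numpy().ravel()
        return pd.Series(
            {m.name: int((flat == m).sum()) for m in Mechanism}, name="cells"
        )

    def is_missing(self, mechanisms=(Mechanism.MNAR, Mechanism.MAR, Mechanism.DEATH)) -> np.ndarray:
        arr = self.codes.to_numpy()
        out = np.zeros(arr.shape, dtype=bool)
        for m in mechanisms:
            out |= arr == int(m)
        return out

    def merge(self, other: "MissingnessMask") -> "MissingnessMask":
        """Overlay two masks; a cell may carry at most one non-OBS label."""
        a = self.codes.to_numpy()
        b = other.codes.to_numpy()
        if ((a != 0) & (b != 0) & (a != b)).any():
            raise ValueError("conflicting mechanism labels in merged masks")
        return MissingnessMask(
            codes=pd.DataFrame(
                np.where(a != 0, a, b).astype(np.int8),
                index=self.codes.index,
                columns=self.codes.columns,
            )
        )


def apply_mask(
    panel: ComponentPanel,
    mask: MissingnessMask,
    mechanisms=(Mechanism.MNAR, Mechanism.MAR, Mechanism.DEATH),
) -> ComponentPanel:
    """Blank out masked cells (set to NaN), leaving the panel itself intact."""
    out = panel.copy()
    miss = mask.is_missing(mechanisms)
    vals = out.data.to_numpy(dtype=float, copy=True)
    vals[miss] = np.nan
    out.data = pd.DataFrame(vals, index=panel.data.index, columns=panel.data.columns)
    return out
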