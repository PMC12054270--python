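"""Two-stage (nested) multiple imputation.

Stage 1 imputes the MNAR non-attendance cells m times under a working MAR
model and transforms each draw to its nonignorable counterpart with a scaling
factor k (a multiplier for continuous components, an odds ratio on the
imputation probability for the binary component).  Stage 2 then imputes the
MAR cells n times within each Stage-1 block, treating the Stage-1 values as
fixed and known, which yields m x n non-independent completed datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .fcs import FcsConfig, _design, _irls_logistic, fcs_predictors, impute_chained, nelson_aalen_cumhaz
from .panel import ComponentPanel, Mechanism, MissingnessMask, col
from .rng import stream
from .simgen import EventTable

__all__ = [
    "IgnorabilityAssumption",
    "ImputedStack",
    "DEFAULT_K_GRID",
    "transform_continuous",
    "transform_binary",
    "run_stage1",
    "run_stage2",
    "run_two_stage",
]

# Default sensitivity grid: continuous multiplier -> binary odds ratio.
DEFAULT_K_GRID = {0.8: 0.5, 0.9: 0.5, 1.0: 1.0, 1.1: 2.0, 1.2: 2.0}


@dataclass(frozen=True)
class IgnorabilityAssumption:
    """The scaling linking ignorable imputations to nonignorable ones.

    ``k_cont`` multiplies continuous draws at MNAR cells; ``k_bin`` shifts the
    imputation odds of the binary component.  When ``k_bin`` is omitted it is
    looked up in the default grid (1 <-> 1; 1.1, 1.2 <-> 2; 0.8, 0.9 <-> 0.5).
    """

    k_cont: float = 1.0
    k_bin: float | None = None

    def __post_init__(self):
        if self.k_cont <= 0:
            raise ValueError("k_cont must be positive")
        if self.k_bin is None:
            if self.k_cont not in DEFAULT_K_GRID:
                raise ValueError(
                    f"k_cont={self.k_cont} is not on the default grid; supply k_bin explicitly"
                )
            object.__setattr__(self, "k_bin", DEFAULT_K_GRID[self.k_cont])
        if self.k_bin <= 0:
            raise ValueError("k_bin must be positive")

    @property
    def label(self) -> str:
        return f"k={self.k_cont:g}"


@dataclass
class ImputedStack:
    """m x n completed panels from the nested procedure, block structure kept.

    ``panels[j][k]`` is the k-th Stage-2 completion within Stage-1 block j.
    Within a block all n panels share identical values at MNAR (and post-death)
    cells; all m x n panels agree at observed cells.
    """

    panels: list
    m: int
    n: int
    mask: MissingnessMask
    assumption: IgnorabilityAssumption
    config: FcsConfig
    seed: int | None = None

    def __iter__(self):
        for block in self.panels:
            yield from block

    def flat(self) -> list:
        return [p for block in self.panels for p in block]

    def validate(self) -> None:
        codes = self.mask.codes.to_numpy()
        obs = codes == int(Mechanism.OBS)
        fixed = (codes == int(Mechanism.MNAR)) | (codes == int(Mechanism.DEATH))
        ref = self.panels[0][0].data.to_numpy()
        for j, block in enumerate(self.panels):
            block_ref = block[0].data.to_numpy()
            for p in block:
                arr = p.data.to_numpy()
                if not np.array_equal(arr[obs], ref[obs]):
                    raise AssertionError("observed cells differ across panels")
                if not np.array_equal(arr[fixed], block_ref[fixed]):
                    raise AssertionError(f"Stage-1 cells differ within block {j}")


# ---------------------------------------------------------------- transforms
def transform_continuous(values, k_cont: float) -> np.ndarray:
    """Nonignorable continuous draws: elementwise multiplication by k."""
    return np.asarray(values, dtype=float) * float(k_cont)


def transform_binary(values, fit_y, fit_X, miss_X, k_bin: float, seed) -> np.ndarray:
    """Nonignorable binary draws via an odds-ratio shift on the logit scale.

    A logistic regression of the Stage-1 completed binary column (``fit_y`` on
    ``fit_X``) supplies per-cell logit(pi_ignr); log(k) is added and each MNAR
    cell is redrawn Bernoulli(pi_nonignr).
    """
    values = np.asarray(values, dtype=float)
    if k_bin == 1.0:
        return values
    classes = np.unique(np.asarray(fit_y))
    if len(classes) < 2:
        raise ValueError("odds-ratio transform undefined for a single-class column")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    A = _design(fit_X)
    beta, fac, converged = _irls_logistic(A, np.asarray(fit_y, dtype=float), ridge=1e-8 * A.shape[0])
    if not converged or np.max(np.abs(beta)) > 15:
        beta, fac, _ = _irls_logistic(A, np.asarray(fit_y, dtype=float), ridge=0.5)
    eta = np.clip(_design(miss_X) @ beta, -30, 30)
    p_non = expit(np.log(k_bin) + eta)
    return (rng.random(len(p_non)) < p_non).astype(float)


# ------------------------------------------------------------------- stage 1
@dataclass
class Stage1Values:
    """Per-block fixed values for the Stage-1 (MNAR + post-death) cells.

    ``blocks[j]`` maps wide column name -> (row positions, values).
    """

    blocks: list
    m: int


def _stage1_raw(panel, mask, config, m, seed, events=None):
    """m independent chained completions over the full missingness pattern."""
    return [
        impute_chained(panel, mask, config, stream(seed, "stage1", j), events=events)
        for j in range(m)
    ]


def apply_ignorability(
    completed: list,
    panel: ComponentPanel,
    mask: MissingnessMask,
    config: FcsConfig,
    assumption: IgnorabilityAssumption,
    seed,
    transform_death: bool = False,
) -> Stage1Values:
    """k-transform the MNAR cells of each Stage-1 completion and fix them.

    Post-death cells are retained untransformed (the k-adjustment models the
    dropout group; set ``transform_death=True`` to extend it to post-death
    imputations).  Binary columns are redrawn through the odds-ratio shift
    using the column's own FCS predictor row as regressors.
    """
    codes = mask.codes.to_numpy()
    blocks = []
    for j, comp in enumerate(completed):
        rng = stream(seed, "ktrans", j)
        data = comp.data.to_numpy()
        covs = [panel.covariates["age"].to_numpy(), panel.covariates["sex"].to_numpy()]
        wide = np.column_stack([data] + covs)
        names = panel.columns() + ["age", "sex"]
        index = {c: i for i, c in enumerate(names)}
        block = {}
        for vi, v in enumerate(panel.variables):
            for t in panel.times():
                c = col(v, t)
                ci = index[c]
                code_col = codes[:, ci]
                a_rows = np.flatnonzero(code_col == int(Mechanism.MNAR))
                d_rows = np.flatnonzero(code_col == int(Mechanism.DEATH))
                rows = np.concatenate([a_rows, d_rows])
                if rows.size == 0:
                    continue
                vals = data[:, ci].copy()
                transform_rows = (
                    np.concatenate([a_rows, d_rows]) if transform_death else a_rows
                )
                if transform_rows.size:
                    if v in panel.binary_variables:
                        preds = fcs_predictors(
                            config.structure, v, t, panel.variables, panel.n_times, False
                        )
                        pidx = np.array([index[p] for p in preds if p in index], dtype=np.intp)
                        vals[transform_rows] = transform_binary(
                            vals[transform_rows],
                            fit_y=data[:, ci],
                            fit_X=wide[:, pidx],
                            miss_X=wide[transform_rows][:, pidx],
                            k_bin=assumption.k_bin,
                            seed=rng,
                        )
                    else:
                        vals[transform_rows] = transform_continuous(
                            vals[transform_rows], assumption.k_cont
                        )
                block[c] = (rows, vals[rows])
        blocks.append(block)
    return Stage1Values(blocks=blocks, m=len(blocks))


def run_stage1(
    panel: ComponentPanel,
    mask: MissingnessMask,
    config: FcsConfig,
    assumption: IgnorabilityAssumption,
    m: int,
    seed,
    events: EventTable | None = None,
    transform_death: bool = False,
) -> Stage1Values:
    """Stage 1: impute the MNAR cells m times and k-transform the draws.

    Chained equations run over the full missingness pattern (complete
    predictors are required), but only the MNAR and post-death cell values are
    retained; the Stage-1 MAR imputations are discarded.
    """
    if m < 1:
        raise ValueError("m must be at least 1")
    raw = _stage1_raw(panel, mask, config, m, seed, events)
    return apply_ignorability(
        raw, panel, mask, config, assumption, seed, transform_death=transform_death
    )


# ------------------------------------------------------------------- stage 2
def _with_fixed(panel: ComponentPanel, block: dict) -> ComponentPanel:
    out = panel.copy()
    arr = out.data.to_numpy(dtype=float, copy=True)
    cidx = {c: i for i, c in enumerate(out.data.columns)}
    for c, (rows, vals) in block.items():
        arr[rows, cidx[c]] = vals
    out.data = pd.DataFrame(arr, index=panel.data.index, columns=panel.data.columns)
    return out


def run_stage2(
    panel: ComponentPanel,
    mask: MissingnessMask,
    stage1_values: Stage1Values,
    config: FcsConfig,
    n: int,
    seed,
    events: EventTable | None = None,
    assumption: IgnorabilityAssumption | None = None,
) -> ImputedStack:
    """Stage 2: impute the MAR cells n times within each Stage-1 block.

    The MNAR and post-death values of block j are written into the working
    panel and treated as observed; only MAR cells are re-imputed.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    panels = []
    for j, block in enumerate(stage1_values.blocks):
        base = _with_fixed(panel, block)
        row = [
            impute_chained(
                base,
                mask,
                config,
                stream(seed, "stage2", j, k),
                events=events,
                mechanisms=(Mechanism.MAR,),
            )
            for k in range(n)
        ]
        panels.append(row)
    return ImputedStack(
        panels=panels,
        m=stage1_values.m,
        n=n,
        mask=mask,
        assumption=assumption or IgnorabilityAssumption(1.0),
        config=config,
        seed=seed if isinstance(seed, int) else None,
    )


def run_two_stage(
    panel: ComponentPanel,
    mask: MissingnessMask,
    config: FcsConfig,
    assumption: IgnorabilityAssumption,
    m: int = 5,
    n: int = 5,
    seed=0,
    events: EventTable | None = None,
    transform_death: bool = False,
) -> ImputedStack:
    """Full nested procedure: Stage 1 then Stage 2 (default m = n = 5)."""
    stage1 = run_stage1(
        panel, mask, config, assumption, m, seed, events=events, transform_death=transform_death
    )
    return run_stage2(
        panel, mask, stage1, config, n, seed, events=events, assumption=assumption
    )
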