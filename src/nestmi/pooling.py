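"""Combining rules for nested (two-stage) multiple imputation.

With m Stage-1 blocks of n Stage-2 completions each, the m x n estimates are
not independent; the combining rules mirror a one-way analysis of variance
with the Stage-1 block as the factor:

    Q_bar = mean of all Q_hat
    U_bar = mean of all within-dataset variances
    B     = variance of the block means of Q_hat          (between-block)
    W     = mean within-block variance of Q_hat           (within-block)
    T     = U_bar + (1 + 1/m) B + (1 - 1/n) W
    1/nu* = [ (1+1/m)B / T ]^2 / (m-1)  +  [ (1-1/n)W / T ]^2 / (m(n-1))

and (Q - Q_bar)/sqrt(T) is referred to a t distribution on nu* degrees of
freedom (normal reference when both variance-ratio terms vanish).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["EstimateGrid", "PooledEstimate", "pool_two_stage", "pool_replicate"]


@dataclass
class EstimateGrid:
    """(j,k)-indexed point estimates and within-dataset variances."""

    q_hat: np.ndarray  # shape (m, n)
    u_hat: np.ndarray  # shape (m, n), non-negative

    def __post_init__(self):
        self.q_hat = np.asarray(self.q_hat, dtype=float)
        self.u_hat = np.asarray(self.u_hat, dtype=float)
        if self.q_hat.shape != self.u_hat.shape or self.q_hat.ndim != 2:
            raise ValueError("q_hat and u_hat must be equal-shaped (m, n) grids")
        if np.isnan(self.q_hat).any() or np.isnan(self.u_hat).any():
            raise ValueError("estimate grid must be complete (no missing cells)")
        if (self.u_hat < 0).any():
            raise ValueError("within-dataset variances must be non-negative")
        m, n = self.q_hat.shape
        if m < 2 or n < 2:
            raise ValueError("need m >= 2 blocks and n >= 2 completions per block")

    @property
    def m(self) -> int:
        return self.q_hat.shape[0]

    @property
    def n(self) -> int:
        return self.q_hat.shape[1]


@dataclass
class PooledEstimate:
    """Pooled point estimate with its three-component variance and interval."""

    q_bar: float
    u_bar: float
    b_between: float
    w_within: float
    t_total: float
    df: float
    ci_low: float
    ci_high: float
    level: float = 0.95
    m: int = 0
    n: int = 0

    @property
    def se(self) -> float:
        return float(np.sqrt(self.t_total))

    def covers(self, truth: float) -> bool:
        return self.ci_low <= truth <= self.ci_high


def pool_two_stage(grid: EstimateGrid, level: float = 0.95) -> PooledEstimate:
    """Apply the nested combining rules to a complete (m, n) estimate grid."""
    q, u = grid.q_hat, grid.u_hat
    m, n = grid.m, grid.n
    q_bar = float(q.mean())
    u_bar = float(u.mean())
    block_means = q.mean(axis=1)
    b = float(((block_means - q_bar) ** 2).sum() / (m - 1))
    w = float(((q - block_means[:, None]) ** 2).sum() / (m * (n - 1)))
    t_total = u_bar + (1 + 1 / m) * b + (1 - 1 / n) * w

    if t_total == 0.0:
        # fully degenerate grid: zero-width interval, normal reference
        return PooledEstimate(q_bar, u_bar, b, w, t_total, np.inf, q_bar, q_bar, level, m, n)

    term_b = ((1 + 1 / m) * b / t_total) ** 2 / (m - 1)
    term_w = ((1 - 1 / n) * w / t_total) ** 2 / (m * (n - 1))
    inv_df = term_b + term_w
    df = np.inf if inv_df == 0.0 else 1.0 / inv_df
    quantile = (
        stats.norm.ppf((1 + level) / 2)
        if np.isinf(df)
        else stats.t.ppf((1 + level) / 2, df)
    )
    half = float(quantile * np.sqrt(t_total))
    return PooledEstimate(
        q_bar, u_bar, b, w, float(t_total), float(df), q_bar - half, q_bar + half, level, m, n
    )


def pool_replicate(estimator_fn, stack, level: float = 0.95) -> dict:
    """Apply an estimator to every panel of a stack and pool each parameter.

    ``estimator_fn(panel) -> {parameter: (estimate, variance)}``.  An
    estimator failure on any panel is raised (flagged, never silently
    dropped).  Returns ``{parameter: PooledEstimate}``.
    """
    m, n = stack.m, stack.n
    per_param: dict = {}
    for j, block in enumerate(stack.panels):
        for k, panel in enumerate(block):
            try:
                results = estimator_fn(panel)
            except Exception as exc:  # noqa: BLE001 - annotate the failing replicate
                raise RuntimeError(f"estimator failed on imputed dataset (j={j}, k={k})") from exc
            for param, (est, var) in results.items():
                grid = per_param.setdefault(
                    param, (np.full((m, n), np.nan), np.full((m, n), np.nan))
                )
                grid[0][j, k] = est
                grid[1][j, k] = var
    return {
        param: pool_two_stage(EstimateGrid(qh, uh), level=level)
        for param, (qh, uh) in per_param.items()
    }
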