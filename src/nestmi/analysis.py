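"""Analysis models for the (imputed or comparator) composite score.

Three estimators: per-time means, the random-intercept mixed-model slope of
the composite over calendar time, and the log hazard ratio of death per unit
composite from a Cox model with the composite as a time-varying covariate in
counting-process form (the value at an exam is carried across the following
interval).

The Cox fit defaults to an in-package Breslow partial-likelihood Newton
solver built on vectorised risk-set suffix sums; the simulation study needs
thousands of fits and a generic fitter is orders of magnitude slower.
lifelines remains available as ``backend='lifelines'`` and is the independent
cross-check in the test suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "AnalysisResult",
    "LmmFit",
    "mean_by_time",
    "fit_slope_lmm",
    "build_episodes",
    "fit_cox_tv",
]


@dataclass
class AnalysisResult:
    parameter: str
    estimate: float
    variance: float


@dataclass
class LmmFit:
    """Random-intercept linear mixed model fit (maximum likelihood)."""

    beta0: float
    beta1: float
    beta2: np.ndarray
    sigma_b2: float
    sigma2: float
    se_beta1: float
    converged: bool = True


# -------------------------------------------------------------------- means
def mean_by_time(composite: pd.DataFrame) -> dict:
    """Per-time mean of the composite over non-missing scores.

    Returns ``{"mean_t<t>": (estimate, variance)}`` with the simple
    complete-data variance s^2 / N.
    """
    out = {}
    for t in composite.columns:
        vals = composite[t].to_numpy(dtype=float)
        vals = vals[~np.isnan(vals)]
        if len(vals) < 2:
            raise ValueError(f"need at least two non-missing scores at time {t}")
        out[f"mean_t{t}"] = (float(vals.mean()), float(vals.var(ddof=1) / len(vals)))
    return out


# -------------------------------------------------------------------- slope
def _long_frame(composite, covariates, time_grid):
    n, T = composite.shape
    time_grid = np.asarray(time_grid, dtype=float)
    frame = pd.DataFrame(
        {
            "subject": np.repeat(np.arange(n), T),
            "time": np.tile(time_grid, n),
            "score": composite.to_numpy(dtype=float).ravel(),
            "age": np.repeat(covariates["age"].to_numpy(), T),
            "sex": np.repeat(covariates["sex"].to_numpy(), T),
        }
    )
    return frame.dropna(subset=["score"])


def fit_slope_lmm(composite: pd.DataFrame, covariates: pd.DataFrame, time_grid) -> LmmFit:
    """ML fit of C_it = b0 + b1*time + b2'X_i + u_i + e_it.

    ``time_grid`` gives the calendar offset (years) of each column of
    ``composite``; rows with missing scores are dropped.
    """
    import statsmodels.api as sm

    long = _long_frame(composite, covariates, time_grid)
    exog = sm.add_constant(long[["time", "age", "sex"]])
    model = sm.MixedLM(long["score"], exog, groups=long["subject"])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = model.fit(reml=False, method="lbfgs")
    if not fit.converged:
        raise RuntimeError(f"mixed model did not converge: {fit.summary()}")
    params = fit.params
    return LmmFit(
        beta0=float(params["const"]),
        beta1=float(params["time"]),
        beta2=np.array([params["age"], params["sex"]]),
        sigma_b2=float(fit.cov_re.iloc[0, 0]),
        sigma2=float(fit.scale),
        se_beta1=float(fit.bse["time"]),
        converged=bool(fit.converged),
    )


def slope_estimator(composite, covariates, time_grid) -> dict:
    fit = fit_slope_lmm(composite, covariates, time_grid)
    return {"slope": (fit.beta1, fit.se_beta1**2)}


# ---------------------------------------------------------------------- cox
def build_episodes(composite: pd.DataFrame, events, covariates: pd.DataFrame, time_grid) -> pd.DataFrame:
    """Counting-process episodes (start, stop, event, score, age, sex).

    Episode t runs from exam t to the next exam (or the event/censor time if
    earlier) with the composite at exam t constant across the episode.
    Episodes with a missing composite are dropped (complete-case behaviour);
    episodes after death never exist because follow-up ends at the event.
    """
    time_grid = np.asarray(time_grid, dtype=float)
    T = len(time_grid)
    n = len(composite)
    etime = events.event_time
    eind = events.event_indicator
    rows = []
    scores = composite.to_numpy(dtype=float)
    age = covariates["age"].to_numpy()
    sex = covariates["sex"].to_numpy()
    horizon = np.inf
    for t in range(T):
        start = time_grid[t]
        nominal_stop = time_grid[t + 1] if t + 1 < T else horizon
        stop = np.minimum(nominal_stop, etime)
        alive = etime > start
        keep = alive & ~np.isnan(scores[:, t])
        ev = (eind == 1) & (etime <= nominal_stop) & keep
        rows.append(
            pd.DataFrame(
                {
                    "start": start,
                    "stop": stop[keep],
                    "event": ev[keep].astype(int),
                    "score": scores[keep, t],
                    "age": age[keep],
                    "sex": sex[keep],
                    "subject": np.flatnonzero(keep),
                }
            )
        )
    out = pd.concat(rows, ignore_index=True)
    return out[out["stop"] > out["start"]].reset_index(drop=True)


def _cox_breslow_newton(start, stop, event, Z, max_iter=50, tol=1e-9):
    """Breslow partial-likelihood Newton solver for (start, stop] episodes.

    Risk-set sums at each event time are computed as suffix cumulative sums
    over episodes sorted by stop and by start: an episode is at risk at tau
    iff start < tau <= stop.
    """
    start = np.asarray(start, float)
    stop = np.asarray(stop, float)
    event = np.asarray(event, bool)
    Z = np.atleast_2d(np.asarray(Z, float))
    n, p = Z.shape
    taus, d_tau = np.unique(stop[event], return_counts=True)
    if len(taus) == 0:
        raise ValueError("no events: Cox model undefined")
    # per-event-time sums of covariates over deaths
    zsum_tau = np.zeros((len(taus), p))
    pos = np.searchsorted(taus, stop[event])
    np.add.at(zsum_tau, pos, Z[event])

    order_stop = np.argsort(stop, kind="stable")
    order_start = np.argsort(start, kind="stable")
    stop_sorted = stop[order_stop]
    start_sorted = start[order_start]
    # indices: episodes with stop >= tau / start >= tau
    i_stop = np.searchsorted(stop_sorted, taus, side="left")
    i_start = np.searchsorted(start_sorted, taus, side="left")

    iu = np.triu_indices(p)
    nq = 1 + p + len(iu[0])

    def _moments(Zs):
        # per-episode [1, z, z_i z_j] rows, fixed across Newton iterations
        return np.column_stack([np.ones(len(Zs)), Zs, Zs[:, iu[0]] * Zs[:, iu[1]]])

    P_stop = _moments(Z[order_stop])
    P_start = _moments(Z[order_start])
    pad = np.zeros((1, nq))

    def _suffix(P, w_sorted, idx):
        acc = np.cumsum((P * w_sorted[:, None])[::-1], axis=0)[::-1]
        return np.concatenate([acc, pad])[idx]

    def at_risk_sums(beta):
        eta = Z @ beta
        eta -= eta.max()  # guard overflow; Breslow terms are scale-invariant up to loglik shift
        w = np.exp(eta)
        S = _suffix(P_stop, w[order_stop], i_stop) - _suffix(P_start, w[order_start], i_start)
        return S[:, 0], S[:, 1 : 1 + p], S[:, 1 + p :], eta

    def loglik(s0, eta):
        return float(eta[event].sum() - (d_tau * np.log(s0)).sum())

    def information(s0, s1, s2):
        zbar = s1 / s0[:, None]
        grad = zsum_tau.sum(axis=0) - (d_tau[:, None] * zbar).sum(axis=0)
        S2 = np.zeros((len(taus), p, p))
        S2[:, iu[0], iu[1]] = s2
        S2[:, iu[1], iu[0]] = s2
        info = np.einsum(
            "t,tij->ij", d_tau, S2 / s0[:, None, None] - zbar[:, :, None] * zbar[:, None, :]
        )
        return grad, info

    beta = np.zeros(p)
    s0, s1, s2, eta = at_risk_sums(beta)
    if (s0 <= 0).any():
        raise RuntimeError("empty risk set encountered in Cox fit")
    ll = loglik(s0, eta)
    for _ in range(max_iter):
        grad, info = information(s0, s1, s2)
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError as exc:
            raise RuntimeError("singular information matrix (monotone likelihood?)") from exc
        # damped Newton: halve until the likelihood does not decrease, keeping
        # the accepted evaluation for the next iteration
        scale = 1.0
        for _ in range(30):
            cand = beta + scale * step
            s0n, s1n, s2n, etan = at_risk_sums(cand)
            lln = loglik(s0n, etan)
            if lln >= ll - 1e-12:
                break
            scale /= 2
        beta, s0, s1, s2 = cand, s0n, s1n, s2n
        converged = np.max(np.abs(scale * step)) < tol
        done = converged or abs(lln - ll) < 1e-12 and np.max(np.abs(grad)) < 1e-6
        ll = lln
        if done:
            break
    if np.max(np.abs(beta)) > 50:
        raise RuntimeError("monotone likelihood: coefficient diverged")
    _, info = information(s0, s1, s2)
    cov = np.linalg.inv(info)
    return beta, cov


def fit_cox_tv(
    composite: pd.DataFrame,
    events,
    covariates: pd.DataFrame,
    time_grid,
    backend: str = "fast",
) -> AnalysisResult:
    """Time-varying Cox log hazard ratio per unit composite.

    ``backend='fast'`` uses the in-package Breslow Newton solver;
    ``backend='lifelines'`` routes through CoxTimeVaryingFitter.
    """
    episodes = build_episodes(composite, events, covariates, time_grid)
    if episodes["event"].sum() == 0:
        raise ValueError("no events: Cox model undefined")
    if backend == "fast":
        Z = episodes[["score", "age", "sex"]].to_numpy()
        beta, cov = _cox_breslow_newton(
            episodes["start"].to_numpy(), episodes["stop"].to_numpy(),
            episodes["event"].to_numpy(), Z,
        )
        return AnalysisResult("log_hr", float(beta[0]), float(cov[0, 0]))
    if backend == "lifelines":
        from lifelines import CoxTimeVaryingFitter

        ctv = CoxTimeVaryingFitter(penalizer=0.0)
        df = episodes.rename(columns={"subject": "id"})
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ctv.fit(
                df[["id", "start", "stop", "event", "score", "age", "sex"]],
                id_col="id", start_col="start", stop_col="stop", event_col="event",
            )
        return AnalysisResult(
            "log_hr",
            float(ctv.params_["score"]),
            float(ctv.standard_errors_["score"] ** 2),
        )
    raise ValueError(f"unknown backend {backend!r}")


def cox_estimator(composite, events, covariates, time_grid, backend="fast") -> dict:
    res = fit_cox_tv(composite, events, covariates, time_grid, backend=backend)
    return {"log_hr": (res.estimate, res.variance)}
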