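"""Fully conditional specification (chained equations) imputation.

Each component at each time point is a distinct variable.  Three predictor
structures are supported:

* ``AFCS`` — the same variable at all other times plus all other variables at
  all times (longitudinal + cross-sectional information);
* ``LFCS`` — only the same variable at all other times (longitudinal only);
* ``XFCS`` — only the other variables at the same time (cross-sectional only).

Every imputation model additionally includes baseline age and sex and, when
the downstream analysis is a Cox model, the death indicator and the
Nelson-Aalen cumulative null hazard evaluated at each subject's event or
censoring time.

The elementary draws (bootstrap linear, Bayesian linear, approximate-Bayesian
logistic) are implemented directly on numpy via normal equations / IRLS: the
simulation study performs on the order of a million elementary fits, so the
inner loop must stay allocation-light.  statsmodels serves as the independent
cross-check for these fits in the test suite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.linalg import cho_solve
from scipy.linalg.lapack import dposv
from scipy.special import expit

from .panel import ComponentPanel, Mechanism, MissingnessMask, col
from .rng import stream
from .simgen import EventTable

__all__ = [
    "FcsConfig",
    "NullHazard",
    "fcs_predictors",
    "build_predictor_matrix",
    "draw_linear_boot",
    "draw_linear_bayes",
    "draw_logistic_abayes",
    "impute_chained",
    "nelson_aalen_cumhaz",
]

log = logging.getLogger(__name__)

STRUCTURES = ("AFCS", "LFCS", "XFCS")


@dataclass
class FcsConfig:
    """Configuration of one chained-equations pass.

    ``structure`` selects the predictor layout; ``n_iterations`` is the number
    of full sweeps after the random initial fill (0 means the output is the
    initial fill); ``cox_mode`` appends the survival predictors.  Binary
    variables always use the approximate-Bayesian logistic draw; continuous
    variables use ``continuous_method`` (bootstrap by default for speed,
    Bayesian retained for the distributional-equivalence check).
    """

    structure: str = "LFCS"
    n_iterations: int = 5
    cox_mode: bool = False
    continuous_method: str = "linear_boot"  # or "linear_bayes"

    def validate(self) -> None:
        if self.structure not in STRUCTURES:
            raise ValueError(f"unknown FCS structure {self.structure!r}")
        if self.continuous_method not in ("linear_boot", "linear_bayes"):
            raise ValueError(f"unknown continuous method {self.continuous_method!r}")
        if self.n_iterations < 0:
            raise ValueError("n_iterations must be non-negative")


@dataclass
class NullHazard:
    """Cumulative null hazard H0 evaluated at each subject's event/censor time."""

    h0: pd.Series


# ----------------------------------------------------------------- predictors
def fcs_predictors(structure, variable, t, variables, n_times, cox_mode=False):
    """Predictor column names for imputing ``variable`` at time ``t``.

    The target itself is never in its own predictor list (zero diagonal).
    """
    if structure not in STRUCTURES:
        raise ValueError(f"unknown FCS structure {structure!r}")
    times = range(1, n_times + 1)
    preds = []
    if structure in ("AFCS", "LFCS"):
        preds += [col(variable, s) for s in times if s != t]
    if structure in ("AFCS", "XFCS"):
        preds += [col(v, t) for v in variables if v != variable]
    if structure == "AFCS":
        preds += [col(v, s) for v in variables if v != variable for s in times if s != t]
        # keep variable-major ordering: same variable's other times, then other
        # variables at all times
        preds = [col(variable, s) for s in times if s != t] + [
            col(v, s) for v in variables if v != variable for s in times
        ]
    preds += ["age", "sex"]
    if cox_mode:
        preds += ["death", "H0"]
    return preds


def build_predictor_matrix(structure, variables, n_times, cox_mode=False) -> pd.DataFrame:
    """0/1 predictor matrix over the flattened layout, for audit and export."""
    targets = [col(v, t) for v in variables for t in range(1, n_times + 1)]
    extras = ["age", "sex"] + (["death", "H0"] if cox_mode else [])
    mat = pd.DataFrame(0, index=targets, columns=targets + extras, dtype=np.int8)
    for v in variables:
        for t in range(1, n_times + 1):
            for p in fcs_predictors(structure, v, t, variables, n_times, cox_mode):
                mat.loc[col(v, t), p] = 1
    return mat


# ------------------------------------------------------------ elementary draws
def _as_rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def _design(X):
    X = np.atleast_2d(np.asarray(X, dtype=float))
    A = np.empty((X.shape[0], X.shape[1] + 1))
    A[:, 0] = 1.0
    A[:, 1:] = X
    return A


def _posv(G, rhs):
    """Solve the SPD system G x = rhs via one LAPACK call; raises if not PD."""
    c, x, info = dposv(G, rhs, lower=1)
    if info != 0:
        raise np.linalg.LinAlgError(f"normal equations not positive definite (info={info})")
    return x, (c, True)


def _solve_wls(A, y, weights=None, ridge=0.0):
    """Normal-equation (weighted) least squares; returns (beta, chol factor)."""
    if weights is None:
        G = A.T @ A
        rhs = A.T @ y
    else:
        Aw = A * weights[:, None]
        G = Aw.T @ A
        rhs = Aw.T @ y
    if ridge:
        G = G + ridge * np.eye(G.shape[0])
    return _posv(G, rhs)


def draw_linear_boot(y_obs, X_obs, X_miss, seed, max_attempts=10):
    """Bootstrap linear-regression imputation draw.

    Resamples the observed cases with replacement, fits least squares on the
    resample, and imputes X_miss @ beta* + N(0, sigma*^2) with sigma*^2 the
    resample residual variance.  The resample enters as multinomial case
    weights, so no row gather is needed.  Singular resampled designs are
    redrawn up to ``max_attempts`` times before a ridge fallback.
    """
    rng = _as_rng(seed)
    y = np.asarray(y_obs, dtype=float)
    A = _design(X_obs)
    Am = _design(X_miss)
    n, q = A.shape
    if n < q + 2:
        raise ValueError(f"need at least rank(X)+2 = {q + 2} observed cases, got {n}")
    beta = counts = None
    for _ in range(max_attempts):
        counts = np.bincount(rng.integers(0, n, n), minlength=n).astype(float)
        try:
            beta, _ = _solve_wls(A, y, weights=counts)
            break
        except np.linalg.LinAlgError:
            beta = None
            continue
    if beta is None:  # ridge fallback after repeated singular resamples
        beta, _ = _solve_wls(A, y, weights=counts, ridge=1e-6 * n)
    resid = y - A @ beta
    sigma2 = float(counts @ (resid * resid)) / max(n - q, 1)
    return Am @ beta + rng.normal(0.0, np.sqrt(max(sigma2, 0.0)), Am.shape[0])


def draw_linear_bayes(y_obs, X_obs, X_miss, seed):
    """Bayesian linear-regression imputation draw.

    sigma*^2 is drawn from the scaled inverse-chi-square posterior
    (nu = n - q, scale = RSS/nu), beta* ~ N(beta_hat, sigma*^2 (X'X)^-1), and
    the imputations are X_miss @ beta* + N(0, sigma*^2).
    """
    rng = _as_rng(seed)
    y = np.asarray(y_obs, dtype=float)
    A = _design(X_obs)
    Am = _design(X_miss)
    n, q = A.shape
    if n < q + 2:
        raise ValueError(f"need at least rank(X)+2 = {q + 2} observed cases, got {n}")
    try:
        beta_hat, fac = _solve_wls(A, y)
    except np.linalg.LinAlgError:
        beta_hat, fac = _solve_wls(A, y, ridge=1e-6 * np.trace(A.T @ A) / q)
    resid = y - A @ beta_hat
    rss = float(resid @ resid)
    nu = max(n - q, 1)
    sigma2 = rss / rng.chisquare(nu) if rss > 0 else 0.0
    Ginv = cho_solve(fac, np.eye(q), check_finite=False)
    # chol of sigma2 * Ginv; Ginv is PD by construction
    Lcov = np.linalg.cholesky(sigma2 * Ginv + 1e-300 * np.eye(q))
    beta_star = beta_hat + Lcov @ rng.standard_normal(q)
    return Am @ beta_star + rng.normal(0.0, np.sqrt(sigma2), Am.shape[0])


def _irls_logistic(A, y, ridge, max_iter=25, tol=1e-6, beta0=None):
    """Ridge-stabilised Newton fit; returns (beta, chol factor of the information).

    ``beta0`` warm-starts the iteration (e.g. the previous sweep's fit for the
    same column); by default the intercept starts at the marginal logit.
    """
    q = A.shape[1]
    if beta0 is not None and len(beta0) == q:
        beta = beta0.copy()
    else:
        beta = np.zeros(q)
        ybar = float(np.mean(y))
        if 0 < ybar < 1:
            beta[0] = np.log(ybar / (1 - ybar))  # warm-start the intercept
    eye = np.eye(q)
    for _ in range(max_iter):
        eta = np.clip(A @ beta, -30, 30)
        p = expit(eta)
        w = p * (1 - p) + 1e-12
        G = (A * w[:, None]).T @ A + ridge * eye
        grad = A.T @ (y - p) - ridge * beta
        step, fac = _posv(G, grad)
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            return beta, fac, True
    return beta, fac, False


def _logistic_fit(A, y, beta0=None):
    """ML logistic fit with the separation fallback; returns (beta, chol factor)."""
    beta, fac, converged = _irls_logistic(A, y, ridge=1e-8 * A.shape[0], beta0=beta0)
    if not converged or np.max(np.abs(beta)) > 15:
        beta, fac, _ = _irls_logistic(A, y, ridge=0.5)  # weak penalty beats separation
    return beta, fac


def _logistic_perturbed_draw(beta, fac, Am, rng):
    q = len(beta)
    V = cho_solve(fac, np.eye(q), check_finite=False)
    beta_star = beta + np.linalg.cholesky((V + V.T) / 2) @ rng.standard_normal(q)
    p = expit(np.clip(Am @ beta_star, -30, 30))
    return (rng.random(Am.shape[0]) < p).astype(float)


def draw_logistic_abayes(y_obs, X_obs, X_miss, seed, beta0=None):
    """Approximate-Bayesian logistic imputation draw for a binary variable.

    Fits ML logistic regression, perturbs the coefficients with a draw from
    their asymptotic normal distribution, and imputes Bernoulli outcomes.
    Separation triggers a weakly penalised refit; a single observed class
    yields the constant class (with a logged warning).
    """
    rng = _as_rng(seed)
    y = np.asarray(y_obs, dtype=float)
    classes = np.unique(y)
    Am = _design(X_miss)
    if len(classes) < 2:
        log.warning("logistic imputation saw a single observed class; imputing the constant")
        return np.full(Am.shape[0], classes[0] if len(classes) else 0.0)
    beta, fac = _logistic_fit(_design(X_obs), y, beta0=beta0)
    return _logistic_perturbed_draw(beta, fac, Am, rng)


# --------------------------------------------------------------------- chains
def nelson_aalen_cumhaz(events: EventTable) -> NullHazard:
    """Nelson-Aalen cumulative null hazard at each subject's event/censor time.

    Standard increment-sum estimator (d_i / n_i, no tie smoothing), so exact
    hand computations and replication invariance hold.  The result is cached
    on the event table (it is re-evaluated many times per imputation stack).
    """
    from lifelines import NelsonAalenFitter

    cached = getattr(events, "_h0_cache", None)
    if cached is not None:
        return cached

    times = events.event_time
    if len(times) == 0:
        raise ValueError("need at least one subject")
    if (times < 0).any():
        raise ValueError("negative event times")
    naf = NelsonAalenFitter(nelson_aalen_smoothing=False)
    naf.fit(times, event_observed=events.event_indicator)
    h0 = naf.cumulative_hazard_at_times(times).to_numpy()
    out = NullHazard(h0=pd.Series(h0, index=events.table.index, name="H0"))
    events._h0_cache = out
    return out


def _chain_layout(panel: ComponentPanel, config: FcsConfig, events):
    """Column metadata shared by every chained run on the same layout."""
    names = panel.columns() + ["age", "sex"]
    if config.cox_mode:
        names += ["death", "H0"]
    index = {c: i for i, c in enumerate(names)}
    meta = []
    for v in panel.variables:
        for t in panel.times():
            preds = fcs_predictors(
                config.structure, v, t, panel.variables, panel.n_times, config.cox_mode
            )
            meta.append(
                (
                    index[col(v, t)],
                    np.array([index[p] for p in preds], dtype=np.intp),
                    v in panel.binary_variables,
                )
            )
    return names, index, meta


def impute_chained(
    panel: ComponentPanel,
    mask: MissingnessMask,
    config: FcsConfig,
    seed,
    events: EventTable | None = None,
    mechanisms=(Mechanism.MNAR, Mechanism.MAR, Mechanism.DEATH),
    trace: list | None = None,
) -> ComponentPanel:
    """One completed copy of the panel from a full chained-equations pass.

    Cells whose mechanism is in ``mechanisms`` are (re-)imputed; all other
    cells — including previously imputed values carried in ``panel.data`` —
    are treated as fixed and known.  Missing cells are initialised by sampling
    observed values of the same variable, then ``config.n_iterations`` sweeps
    re-impute each variable from its predictor row.  Repeated calls with
    distinct seeds give independent imputations.
    """
    config.validate()
    if config.cox_mode and events is None:
        raise ValueError("cox_mode imputation requires an event table")
    rng = _as_rng(seed) if isinstance(seed, np.random.Generator) else stream(seed, "chain")

    X = panel.data.to_numpy(dtype=float, copy=True)
    X[mask.is_missing(mechanisms)] = np.nan
    n = X.shape[0]
    extra = [panel.covariates["age"].to_numpy(), panel.covariates["sex"].to_numpy()]
    if config.cox_mode:
        extra += [events.event_indicator.astype(float), nelson_aalen_cumhaz(events).h0.to_numpy()]
    W = np.column_stack([X] + extra)

    _, _, meta = _chain_layout(panel, config, events)
    jobs = []
    for ci, pred_idx, is_binary in meta:
        miss_rows = np.flatnonzero(np.isnan(W[:, ci]))
        if miss_rows.size == 0:
            continue
        obs_rows = np.flatnonzero(~np.isnan(W[:, ci]))
        if obs_rows.size == 0:
            raise ValueError(f"variable column {ci} has no observed cells to learn from")
        jobs.append((ci, pred_idx, is_binary, obs_rows, miss_rows))

    if not jobs:
        return panel.copy()

    # initial fill: sample observed values of the same variable
    for ci, _, _, obs_rows, miss_rows in jobs:
        W[miss_rows, ci] = rng.choice(W[obs_rows, ci], size=miss_rows.size, replace=True)

    names = panel.data.columns
    draw_cont = draw_linear_boot if config.continuous_method == "linear_boot" else draw_linear_bayes
    warm: dict = {}  # per-column logistic warm starts across sweeps
    for it in range(config.n_iterations):
        for ci, pred_idx, is_binary, obs_rows, miss_rows in jobs:
            Xp = W[:, pred_idx]
            if is_binary:
                y_col = W[obs_rows, ci]
                if len(np.unique(y_col)) < 2:
                    W[miss_rows, ci] = draw_logistic_abayes(
                        y_col, Xp[obs_rows], Xp[miss_rows], rng
                    )
                else:
                    beta, fac = _logistic_fit(_design(Xp[obs_rows]), y_col, beta0=warm.get(ci))
                    warm[ci] = beta
                    W[miss_rows, ci] = _logistic_perturbed_draw(
                        beta, fac, _design(Xp[miss_rows]), rng
                    )
            else:
                W[miss_rows, ci] = draw_cont(W[obs_rows, ci], Xp[obs_rows], Xp[miss_rows], rng)
        if trace is not None:  # convergence diagnostics: imputed-cell moments
            for ci, _, _, _, miss_rows in jobs:
                vals = W[miss_rows, ci]
                trace.append(
                    {
                        "iteration": it + 1,
                        "column": names[ci],
                        "mean": float(vals.mean()),
                        "sd": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
                    }
                )

    out = panel.copy()
    k = len(panel.columns())
    out.data = pd.DataFrame(W[:, :k], index=panel.data.index, columns=panel.data.columns)
    return out
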