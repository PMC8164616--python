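"""Conditional Poisson regression for the time-stratified case-crossover design.

Daily counts grouped into 'year : month : day-of-week' strata are modelled as

    y_t ~ Poisson(mu_t),   log mu_t = alpha_{s(t)} + beta * x_t + gamma' w_t

where x_t is the lagged pollutant concentration and w_t holds natural-spline
bases of lagged temperature and relative humidity.  Conditioning on the
stratum totals Y_s eliminates the stratum intercepts alpha_s, leaving the
conditional log-likelihood

    l(beta, gamma) = sum_s [ sum_{t in s} y_t eta_t  -  Y_s log sum_{t in s} e^{eta_t} ]

which coincides with a multinomial likelihood within strata and yields the
same beta and standard error as an unconditional Poisson fit with one
indicator per stratum.  The maximiser is found by Newton iteration with
step-halving; the standard error comes from the inverse observed information.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exposure import ExposureSeries
from .strata import build_time_strata

logger = logging.getLogger(__name__)

Z_975 = 1.959964  # two-sided 95% normal quantile


class DataError(ValueError):
    """Raised when a model-ready dataset cannot be assembled."""


class NotIdentifiedError(RuntimeError):
    """Raised when the exposure is constant within every time stratum."""


# ---------------------------------------------------------------------------
# Natural cubic spline basis

def natural_spline_basis(x, df: int, *, interior_knots=None,
                         boundary_knots=None) -> np.ndarray:
    """Natural cubic spline basis with ``df`` columns evaluated at ``x``.

    Boundary knots default to min/max of ``x`` and the ``df - 1`` interior
    knots to equally spaced quantiles.  The basis spans exactly the natural
    cubic splines on those knots (linear beyond the boundary), excludes the
    intercept, and for df=1 degenerates to the identity column x.

    Built from the truncated-power natural-spline construction:
    with knots xi_1 < ... < xi_K (K = df + 1), the non-intercept basis is
    x together with d_k(x) - d_{K-1}(x), k = 1..K-2, where
    d_k(x) = [(x - xi_k)_+^3 - (x - xi_K)_+^3] / (xi_K - xi_k).
    """
    x = np.asarray(x, dtype=float)
    if df < 1:
        raise ValueError("df must be >= 1")
    finite = x[np.isfinite(x)]
    if len(np.unique(finite)) < df + 2:
        raise DataError(
            f"natural spline with df={df} needs >= {df + 2} distinct values")
    if boundary_knots is None:
        boundary_knots = (finite.min(), finite.max())
    lo, hi = map(float, boundary_knots)
    if interior_knots is None:
        probs = np.linspace(0, 1, df + 1)[1:-1]
        interior_knots = np.quantile(finite, probs) if df > 1 else np.array([])
    knots = np.sort(np.r_[lo, np.asarray(interior_knots, float), hi])
    K = len(knots)

    basis = np.empty((len(x), df))
    basis[:, 0] = x
    if K > 2:
        def d(k):
            num = (np.clip(x - knots[k], 0, None) ** 3
                   - np.clip(x - knots[-1], 0, None) ** 3)
            return num / (knots[-1] - knots[k])

        d_last = d(K - 2)
        for j in range(K - 2):
            basis[:, j + 1] = d(j) - d_last
    return basis


# ---------------------------------------------------------------------------
# Dataset assembly

@dataclass
class CaseCrossoverDataset:
    """Model-ready rows for one (chapter, stratum, pollutant, lag) cell.

    Complete-case: no retained row has a missing exposure or weather value;
    every retained time stratum has positive total count and >= 2 rows.
    """

    dates: pd.DatetimeIndex
    y: np.ndarray                 # daily counts
    exposure: np.ndarray          # lagged concentration
    temp_basis: np.ndarray        # natural-spline basis of lagged temperature
    rh_basis: np.ndarray          # natural-spline basis of lagged RH
    stratum_codes: np.ndarray     # 0..n_strata-1, rows sorted by stratum
    stratum_keys: list = field(default_factory=list)
    n_dropped_missing: int = 0
    n_dropped_strata: int = 0

    @property
    def n_rows(self) -> int:
        return len(self.y)

    @property
    def n_strata(self) -> int:
        return len(self.stratum_keys)

    def design(self) -> np.ndarray:
        """Design matrix [exposure | temp basis | rh basis]; exposure first."""
        return np.column_stack([self.exposure, self.temp_basis, self.rh_basis])


def build_dataset(counts, exposure: ExposureSeries, weather: pd.DataFrame,
                  lag: int, spline_df: int = 3) -> CaseCrossoverDataset:
    """Assemble a case-crossover dataset at a given lag.

    ``counts`` is a date-indexed integer Series (or CountSeries-like with a
    ``.data`` attribute); ``weather`` has columns ``temp`` and ``rh``.
    Exposure, temperature and RH are all lagged by the same number of days.
    Rows with any missing value are dropped (complete-case) and strata with
    zero total count or fewer than 2 days are removed: they carry no
    information under conditioning.
    """
    cdata = counts.data if hasattr(counts, "data") else counts
    df = pd.DataFrame({"y": cdata})
    df["x"] = exposure.data.shift(lag).reindex(df.index)
    df["temp"] = weather["temp"].shift(lag).reindex(df.index)
    df["rh"] = weather["rh"].shift(lag).reindex(df.index)

    n0 = len(df)
    df = df.dropna()
    n_missing = n0 - len(df)
    if n_missing:
        logger.debug("dropped %d rows with missing exposure/weather", n_missing)
    if df.empty:
        raise DataError("no complete-case rows remain")

    keys = build_time_strata(df.index)
    df["stratum"] = keys.to_numpy()
    grp = df.groupby("stratum", sort=False)
    totals = grp["y"].transform("sum")
    sizes = grp["y"].transform("size")
    keep = (totals > 0) & (sizes >= 2)
    n_strata_dropped = df.loc[~keep, "stratum"].nunique()
    df = df.loc[keep]
    if df.empty:
        raise DataError("all time strata empty after filtering")

    # Sort rows by stratum so per-stratum reductions are contiguous.
    codes, uniques = pd.factorize(df["stratum"], sort=True)
    order = np.argsort(codes, kind="stable")
    df = df.iloc[order]
    codes = codes[order]

    if spline_df >= 1:
        temp_basis = natural_spline_basis(df["temp"].to_numpy(), spline_df)
        rh_basis = natural_spline_basis(df["rh"].to_numpy(), spline_df)
    else:
        temp_basis = np.empty((len(df), 0))
        rh_basis = np.empty((len(df), 0))

    return CaseCrossoverDataset(
        dates=df.index,
        y=df["y"].to_numpy(dtype=float),
        exposure=df["x"].to_numpy(dtype=float),
        temp_basis=temp_basis,
        rh_basis=rh_basis,
        stratum_codes=codes,
        stratum_keys=list(uniques),
        n_dropped_missing=n_missing,
        n_dropped_strata=int(n_strata_dropped),
    )


# ---------------------------------------------------------------------------
# Conditional Poisson fit

@dataclass
class ModelResult:
    beta: float
    se: float
    p_value: float
    n_rows: int
    n_strata: int
    converged: bool
    iterations: int
    log_likelihood: float
    coef: np.ndarray | None = None


def _cond_loglik(eta, y, codes, Y, n_strata):
    """Conditional log-likelihood and softmax probabilities per stratum."""
    m = np.full(n_strata, -np.inf)
    np.maximum.at(m, codes, eta)
    z = np.exp(eta - m[codes])
    denom = np.bincount(codes, weights=z, minlength=n_strata)
    ll = float(y @ eta - Y @ (np.log(denom) + m))
    p = z / denom[codes]
    return ll, p


def fit_conditional_poisson(data: CaseCrossoverDataset, *, tol: float = 1e-8,
                            max_iter: int = 100) -> ModelResult:
    """Maximise the conditional log-likelihood by Newton iteration.

    Returns the slope on the exposure column (per unit of its declared
    concentration scale), its standard error from the inverse observed
    information, and a two-sided Wald p-value.  Convergence is a relative
    conditional-log-likelihood change below ``tol``, with step-halving
    whenever a Newton step would decrease the likelihood.
    """
    X = data.design()
    y = data.y
    codes = data.stratum_codes
    S = data.n_strata
    Y = np.bincount(codes, weights=y, minlength=S)

    # Identifiability: the exposure must vary within at least one stratum.
    x = data.exposure
    xbar = np.bincount(codes, weights=x, minlength=S) / np.bincount(
        codes, minlength=S)
    within_var = np.bincount(codes, weights=(x - xbar[codes]) ** 2,
                             minlength=S)
    if np.all(within_var < 1e-12 * max(1.0, float(np.var(x)))):
        raise NotIdentifiedError(
            "exposure is constant within every time stratum")

    # Scale columns for numerical conditioning; rescale at the end.
    scales = X.std(axis=0)
    scales[scales == 0] = 1.0
    Xs = X / scales

    p_dim = Xs.shape[1]
    theta = np.zeros(p_dim)
    ll, probs = _cond_loglik(Xs @ theta, y, codes, Y, S)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        mu = Y[codes] * probs                      # conditional fitted counts
        grad = Xs.T @ (y - mu)
        # Observed information: X' diag(mu) X - sum_s Y_s g_s g_s'
        G = np.empty((S, p_dim))
        for j in range(p_dim):
            G[:, j] = np.bincount(codes, weights=probs * Xs[:, j], minlength=S)
        info = (Xs * mu[:, None]).T @ Xs - (G * Y[:, None]).T @ G

        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(info, grad, rcond=None)[0]

        new_ll, new_probs = _cond_loglik(Xs @ (theta + step), y, codes, Y, S)
        halvings = 0
        while new_ll < ll and halvings < 30:
            step *= 0.5
            halvings += 1
            new_ll, new_probs = _cond_loglik(Xs @ (theta + step), y, codes, Y, S)
        theta = theta + step
        rel = abs(new_ll - ll) / (abs(ll) + 1.0)
        ll, probs = new_ll, new_probs
        if rel < tol:
            converged = True
            break

    # Final observed information for the covariance.
    mu = Y[codes] * probs
    G = np.empty((S, p_dim))
    for j in range(p_dim):
        G[:, j] = np.bincount(codes, weights=probs * Xs[:, j], minlength=S)
    info = (Xs * mu[:, None]).T @ Xs - (G * Y[:, None]).T @ G
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(info)

    beta = float(theta[0] / scales[0])
    se = float(np.sqrt(max(cov[0, 0], 0.0)) / scales[0])
    p = wald_p(beta, se) if se > 0 else np.nan
    return ModelResult(
        beta=beta, se=se, p_value=p, n_rows=data.n_rows,
        n_strata=S, converged=converged, iterations=it,
        log_likelihood=ll, coef=theta / scales,
    )


def wald_p(beta: float, se: float) -> float:
    """Two-sided normal-approximation p-value, p = 2 (1 - Phi(|beta/se|))."""
    if se <= 0:
        raise ValueError("standard error must be positive")
    return float(2.0 * stats.norm.sf(abs(beta / se)))


def relative_risk(result: ModelResult, increment: float) -> dict:
    """Relative risk and 95% CI for a given concentration increment.

    RR = exp(beta * increment); the CI exponentiates the symmetric Wald
    interval, so it always contains the point estimate.
    """
    if not result.converged:
        raise ValueError("relative risk requires a converged model")
    if increment <= 0:
        raise ValueError("increment must be positive")
    with np.errstate(over="ignore"):  # huge SEs in sparse strata -> inf bound
        rr = float(np.exp(result.beta * increment))
        lo = float(np.exp((result.beta - Z_975 * result.se) * increment))
        hi = float(np.exp((result.beta + Z_975 * result.se) * increment))
    return {"rr": rr, "ci_low": lo, "ci_high": hi, "increment": increment}
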