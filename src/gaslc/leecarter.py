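"""Classic three-stage Lee-Carter baseline.

Stage 1 estimates (alpha_x, beta_x, kappa_t) by SVD of the centred log-rate
matrix under the identification constraints sum(beta) = 1, sum(kappa) = 0.
Stage 2 re-fits each year's kappa so the fitted total death count matches
the observed total (a one-dimensional root-find per year), weighting the
trend toward high-mortality ages.  Stage 3 projects kappa with an
ARIMA(0,1,1)-with-drift model, falling back to a random walk with drift
when the MA term cannot be estimated.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .surface import MortalitySurface

__all__ = ["LeeCarter", "LeeCarterResults"]

logger = logging.getLogger("gaslc")


@dataclass
class LeeCarterResults:
    """Stage-1/2 estimates and the fitted trend model."""

    ages: list[str]
    years: list[int]
    alpha: np.ndarray
    beta: np.ndarray
    kappa: np.ndarray          # stage-1 SVD trend, sums to zero
    kappa_adjusted: np.ndarray # stage-2 death-matched trend
    drift: float
    sigma2: float              # innovation variance of the trend model
    ma_theta: float            # MA(1) coefficient (0 under the random-walk fallback)
    trend_model: str           # "arima011" or "rwd"
    arima_result: object | None = None   # fitted statsmodels results, when available

    def forecast_kappa(self, horizon: int) -> np.ndarray:
        """Mean trend forecast over the horizon."""
        if horizon < 1:
            raise ValueError("horizon must be at least 1")
        if self.trend_model == "arima011" and self.arima_result is not None:
            return np.asarray(self.arima_result.forecast(horizon), dtype=float)
        h = np.arange(1, horizon + 1, dtype=float)
        return self.kappa_adjusted[-1] + h * self.drift

    def forecast(self, horizon: int) -> pd.DataFrame:
        """Project rates ``horizon`` years ahead from the adjusted trend.

        Under ARIMA(0,1,1) with drift the multi-step mean path is linear in
        the horizon after the first step; with theta = 0 this is the random
        walk with drift.  Returns a long table (age, year, rate).
        """
        if horizon < 1:
            raise ValueError("horizon must be at least 1")
        h = np.arange(1, horizon + 1, dtype=float)
        kappa_f = self.forecast_kappa(horizon)
        rates = np.exp(self.alpha[:, None] + self.beta[:, None] * kappa_f[None, :])
        years = [self.years[-1] + int(i) for i in h]
        n = len(self.ages)
        return pd.DataFrame(
            {
                "age": np.repeat(self.ages, horizon),
                "year": np.tile(years, n),
                "rate": rates.ravel(),
            }
        )

    def forecast_rates(self, horizon: int) -> np.ndarray:
        """(N, H) matrix of forecast central rates."""
        df = self.forecast(horizon)
        return df["rate"].to_numpy().reshape(len(self.ages), horizon)


class LeeCarter:
    """Classic Lee-Carter model on a mortality surface."""

    def __init__(self, surface: MortalitySurface):
        self.surface = surface

    def fit(self) -> LeeCarterResults:
        surf = self.surface
        d, exp_ = surf.deaths, surf.exposures
        m = (d + 0.5 * (d == 0)) / exp_
        logm = np.log(m)
        alpha = logm.mean(axis=1)
        centred = logm - alpha[:, None]
        u, s, vt = np.linalg.svd(centred, full_matrices=False)
        if s[0] <= 0:
            raise ValueError("degenerate log-rate matrix: no leading singular value")
        beta_raw, kappa_raw = u[:, 0], s[0] * vt[0]
        scale = float(beta_raw.sum())
        if abs(scale) < 1e-12:
            raise ValueError("degenerate loadings: leading singular vector sums to zero")
        beta = beta_raw / scale
        kappa = kappa_raw * scale
        # re-centre kappa to sum zero, absorbing the shift into alpha
        shift = float(kappa.mean())
        kappa = kappa - shift
        alpha = alpha + beta * shift

        kappa_adj = np.array(
            [_match_deaths(d[:, t], exp_[:, t], alpha, beta, kappa[t]) for t in range(surf.n_years)]
        )

        diffs = np.diff(kappa_adj)
        drift = float(diffs.mean())
        theta, sigma2, model, arima_res = _fit_trend(kappa_adj)
        return LeeCarterResults(
            ages=list(surf.ages),
            years=list(surf.years),
            alpha=alpha,
            beta=beta,
            kappa=kappa,
            kappa_adjusted=kappa_adj,
            drift=drift,
            sigma2=sigma2,
            ma_theta=theta,
            trend_model=model,
            arima_result=arima_res,
        )


def _match_deaths(d_col, exp_col, alpha, beta, k0) -> float:
    """Stage 2: choose kappa so total fitted deaths equal total observed deaths."""
    total = float(d_col.sum())

    def gap(k):
        return float(np.sum(exp_col * np.exp(alpha + beta * k))) - total

    lo, hi = k0 - 1.0, k0 + 1.0
    for _ in range(60):
        if gap(lo) * gap(hi) <= 0:
            return float(brentq(gap, lo, hi, xtol=1e-12))
        lo -= 2.0
        hi += 2.0
    raise RuntimeError("stage-2 death-matching root-find failed to bracket")


def _fit_trend(kappa_adj: np.ndarray):
    """ARIMA(0,1,1)-with-drift fit to the trend; random-walk fallback."""
    diffs = np.diff(kappa_adj)
    sigma2_rwd = float(np.var(diffs, ddof=1)) if diffs.size > 1 else 0.0
    if kappa_adj.size < 5 or float(np.var(diffs)) < 1e-12:
        return 0.0, sigma2_rwd, "rwd", None
    try:
        from statsmodels.tsa.arima.model import ARIMA

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = ARIMA(kappa_adj, order=(0, 1, 1), trend="t").fit()
        theta = float(res.params[res.param_names.index("ma.L1")])
        sigma2 = float(res.params[res.param_names.index("sigma2")])
        if not np.isfinite(theta) or abs(theta) >= 1.0:
            raise ValueError("non-invertible MA estimate")
        return theta, sigma2, "arima011", res
    except Exception as err:  # noqa: BLE001 - any estimation failure falls back
        logger.warning("ARIMA(0,1,1) trend fit failed (%s); using random walk with drift", err)
        return 0.0, sigma2_rwd, "rwd", None
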