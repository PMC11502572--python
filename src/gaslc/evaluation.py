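"""Model selection and forecast-accuracy metrics.

AIC/BIC on the maximised likelihood with the effective parameter count,
MAPE of predicted against observed mortality rates (stored in percent),
five-number MAPE summaries across populations, the Diebold-Mariano test of
equal predictive accuracy, and the winner-per-cell comparison map.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

__all__ = [
    "aic_bic",
    "mape",
    "MapeSummary",
    "mape_summary",
    "DMResult",
    "diebold_mariano",
    "winner_map",
    "MODEL_CODES",
]

logger = logging.getLogger("gaslc")

#: integer codes used in comparison maps
MODEL_CODES = {
    "com_poisson": 1,
    "poisson": 2,
    "binomial": 3,
    "negative_binomial": 4,
    "lee_carter": 5,
}


def aic_bic(loglik: float, n_params: int, n_obs: int) -> tuple[float, float]:
    """AIC = -2 LL + 2 n_p and BIC = -2 LL + n_p ln(n_d)."""
    if n_obs < 1:
        raise ValueError("n_obs must be at least 1")
    aic = -2.0 * loglik + 2.0 * n_params
    bic = -2.0 * loglik + n_params * np.log(n_obs)
    return float(aic), float(bic)


def mape(actual, predicted) -> float:
    """Mean absolute percentage error, in percent.

    Both inputs must be positive and of equal shape; zero observed rates
    must be masked or regrouped by the caller before scoring.
    """
    a = np.asarray(actual, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if a.shape != p.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {p.shape}")
    if np.any(a <= 0):
        raise ValueError(
            "observed rates must be positive for MAPE; mask zero cells or regroup ages"
        )
    return float(np.mean(np.abs(p - a) / a) * 100.0)


@dataclass
class MapeSummary:
    """Five-number summary of per-population MAPE values (percent)."""

    values: np.ndarray
    min: float
    q1: float
    mean: float
    q3: float
    max: float


def mape_summary(values) -> MapeSummary:
    """Min / Q1 / mean / Q3 / max across populations.

    Quartiles use the inclusive linear-interpolation convention (the default
    quantile definition of numpy).
    """
    v = np.asarray(list(np.atleast_1d(values)), dtype=float)
    if v.size == 0:
        raise ValueError("need at least one MAPE value")
    return MapeSummary(
        values=v,
        min=float(v.min()),
        q1=float(np.quantile(v, 0.25)),
        mean=float(v.mean()),
        q3=float(np.quantile(v, 0.75)),
        max=float(v.max()),
    )


@dataclass
class DMResult:
    statistic: float
    pvalue: float


def diebold_mariano(loss_a, loss_b, horizon: int = 1) -> DMResult:
    """Diebold-Mariano test of equal predictive accuracy.

    The statistic is the mean loss differential d_t = loss_a - loss_b over
    its long-run-variance standard error, with the long-run variance built
    from rectangular (uniform) weights up to lag ``horizon - 1``; the
    p-value is two-sided standard normal.  A positive statistic favours the
    second forecast.
    """
    a = np.asarray(loss_a, dtype=float)
    b = np.asarray(loss_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("loss series must be 1-d and of equal length")
    t = a.size
    if t < 5:
        raise ValueError("need at least 5 loss observations")
    if horizon < 1:
        raise ValueError("horizon must be at least 1")
    d = a - b
    dbar = float(d.mean())
    dc = d - dbar
    gamma0 = float(dc @ dc) / t
    lrv = gamma0
    for lag in range(1, min(horizon, t)):
        lrv += 2.0 * float(dc[lag:] @ dc[:-lag]) / t
    if lrv <= 1e-14:
        if abs(dbar) < 1e-14:
            warnings.warn("identical losses: DM statistic undefined, returning 0", stacklevel=2)
            return DMResult(0.0, 1.0)
        warnings.warn(
            "constant loss differential: no variance, DM statistic diverges", stacklevel=2
        )
        return DMResult(float(np.sign(dbar) * np.inf), 0.0)
    stat = dbar / np.sqrt(lrv / t)
    pval = 2.0 * float(norm.sf(abs(stat)))
    return DMResult(float(stat), pval)


def winner_map(mape_tensor, model_names=None):
    """Argmin model code per cell of a (model, population, age) MAPE tensor.

    Ties break toward the lower model code; tied cells are reported in the
    returned ``ties`` list of (population index, age index, tied codes).

    Returns
    -------
    codes : (P, G) integer array of winning model codes (1-based by input
        order unless ``model_names`` maps into ``MODEL_CODES``)
    ties : list of tie records
    """
    arr = np.asarray(mape_tensor, dtype=float)
    if arr.ndim != 3 or arr.shape[0] < 2:
        raise ValueError("need a (model, population, age) tensor with at least 2 models")
    if np.any(~np.isfinite(arr)):
        raise ValueError("missing cells in the MAPE tensor")
    if model_names is not None:
        if len(model_names) != arr.shape[0]:
            raise ValueError("one name per model required")
        codes_by_model = np.asarray([MODEL_CODES.get(m, i + 1) for i, m in enumerate(model_names)])
        order = np.argsort(codes_by_model, kind="stable")
        arr = arr[order]
        codes_by_model = codes_by_model[order]
    else:
        codes_by_model = np.arange(1, arr.shape[0] + 1)
    winners_idx = np.argmin(arr, axis=0)  # ties -> first (lowest code after sorting)
    codes = codes_by_model[winners_idx]
    ties = []
    best = arr.min(axis=0)
    tied_mask = (arr == best[None, :, :]).sum(axis=0) > 1
    for pi, gi in zip(*np.nonzero(tied_mask)):
        tied_codes = codes_by_model[arr[:, pi, gi] == best[pi, gi]]
        ties.append((int(pi), int(gi), [int(c) for c in tied_codes]))
    return codes, ties
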