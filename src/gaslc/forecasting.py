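"""Monte-Carlo projection of the trend and of age-specific mortality rates.

Forecasting uses the same recursion as the filter.  The first out-of-sample
trend value is deterministic (it only needs the last observed score); from
then on each simulated path draws synthetic deaths from the family's
conditional distribution at the current trend, recomputes the scaled score
from those draws, and advances the recursion.  A ``mean_path`` mode sets all
future scores to zero (the deterministic recursion) for diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass

import logging

import numpy as np
import pandas as pd

from .distributions import CellParams, Family, compoisson_rvs
from .estimation import FittedModel
from .gas import filter_kappa
from .surface import MortalitySurface

__all__ = ["ForecastResult", "simulate_paths", "point_and_interval_rates"]


@dataclass
class ForecastResult:
    """Simulated trend paths and per-cell mortality-rate forecasts."""

    ages: list[str]
    years: list[int]              # forecast years T+1 .. T+H
    horizon: int
    n_sims: int
    seed: int | None
    kappa_paths: np.ndarray       # (n_sims, H)
    rates_point: np.ndarray       # (N, H) across-path mean of conditional expected rates
    rate_paths: np.ndarray        # (n_sims, N, H) per-path conditional expected rates

    def rate_quantiles(self, levels) -> dict[float, np.ndarray]:
        """Empirical across-path quantiles of the conditional expected rate."""
        out = {}
        for lv in np.atleast_1d(levels):
            lv = float(lv)
            if not 0.0 < lv < 1.0:
                raise ValueError(f"quantile level must lie in (0, 1), got {lv}")
            out[lv] = np.quantile(self.rate_paths, lv, axis=0)
        return out


_MAX_COMPOISSON_MEAN = 5e5
_warned_sat = False


def _clip_compoisson_rate(lam, nu):
    """Cap lambda so the implied death mean lambda**(1/nu) stays summable.

    Simulated trend paths can wander far enough that the COM-Poisson series
    mean exceeds any plausible death count (and the truncated-summation
    budget); such paths are saturated at a huge ceiling rather than aborting
    the whole forecast.  Logged once.
    """
    global _warned_sat
    cap = _MAX_COMPOISSON_MEAN**nu
    if np.any(lam > cap):
        if not _warned_sat:
            logging.getLogger("gaslc").warning(
                "COM-Poisson forecast paths saturated at a mean of %g deaths",
                _MAX_COMPOISSON_MEAN,
            )
            _warned_sat = True
        lam = np.minimum(lam, cap)
    return lam


def _conditional_rates(spec, alpha, beta, kappa, exposures, start_pops):
    """Conditional expected mortality rate per age for a vector of kappas.

    kappa: (n_sims,) -> returns (n_sims, N).
    """
    eta = alpha[None, :] + beta[None, :] * kappa[:, None]
    mu = np.exp(np.clip(eta, -50.0, 50.0))
    fam = spec.family
    if fam is Family.POISSON:
        return mu
    if fam is Family.COM_POISSON:
        lam = _clip_compoisson_rate(exposures[None, :] * mu, spec.nu)
        mean = lam ** (1.0 / spec.nu) - (spec.nu - 1.0) / (2.0 * spec.nu)
        return np.maximum(mean, 0.0) / exposures[None, :]
    if fam is Family.NEGATIVE_BINOMIAL:
        return mu  # mean d = r(1-h)/h = L mu
    if fam is Family.BINOMIAL:
        q = 1.0 / (1.0 + np.exp(-np.clip(eta, -50.0, 50.0)))
        return start_pops[None, :] * q / exposures[None, :]
    raise ValueError(f"unknown family {fam}")


def _draw_deaths(spec, lam_or_eta, exposures, start_pops, rng):
    """One death draw per (path, age) cell; input is the rate-scale mu matrix."""
    mu = lam_or_eta
    fam = spec.family
    if fam is Family.POISSON:
        return rng.poisson(exposures[None, :] * mu)
    if fam is Family.COM_POISSON:
        lam = _clip_compoisson_rate(exposures[None, :] * mu, spec.nu)
        flat = compoisson_rvs(lam.ravel(), spec.nu, rng=rng)
        return flat.reshape(lam.shape)
    if fam is Family.NEGATIVE_BINOMIAL:
        lam = exposures[None, :] * mu
        h = spec.r[None, :] / (spec.r[None, :] + lam)
        return rng.negative_binomial(np.broadcast_to(spec.r[None, :], h.shape), h)
    if fam is Family.BINOMIAL:
        q = mu / (1.0 + mu)  # logistic(eta) written in terms of mu = e^eta
        l_int = np.round(start_pops).astype(np.int64)
        return rng.binomial(l_int[None, :], q)
    raise ValueError(f"unknown family {fam}")


def simulate_paths(
    fitted: FittedModel,
    surface: MortalitySurface,
    horizon: int,
    n_sims: int = 1000,
    seed: int | None = None,
    mode: str = "simulate",
    exposures: np.ndarray | None = None,
) -> ForecastResult:
    """Project the trend and rates ``horizon`` years past the sample end.

    Exposures (and, for the binomial family, start-of-year populations) are
    held at their last observed values unless projected values are supplied.
    ``mode="mean_path"`` freezes future scores at zero.
    """
    if horizon < 1:
        raise ValueError("horizon must be at least 1")
    if n_sims < 2:
        raise ValueError("at least 2 simulation paths are required for quantiles")
    if mode not in ("simulate", "mean_path"):
        raise ValueError(f"unknown mode {mode!r}")
    p, spec = fitted.params, fitted.spec
    fr = filter_kappa(surface, p, spec, fitted.config.score_form)
    # the last observed year delivers the first out-of-sample trend value
    kappa_next = p.omega + p.A * fr.scores[-1] + p.B * fr.kappa[-1]

    n = surface.n_ages
    exp_last = surface.exposures[:, -1] if exposures is None else np.asarray(exposures, float)
    pop_last = (
        surface.start_populations[:, -1] if surface.start_populations is not None else None
    )
    rng = np.random.default_rng(seed)
    from .distributions import partial_information, partial_score  # local: avoids cycle noise

    kappa_paths = np.empty((n_sims, horizon))
    rate_paths = np.empty((n_sims, n, horizon))
    kappa_cur = np.full(n_sims, kappa_next)
    for h in range(horizon):
        kappa_paths[:, h] = kappa_cur
        rate_paths[:, :, h] = _conditional_rates(spec, p.alpha, p.beta, kappa_cur, exp_last, pop_last)
        if h == horizon - 1:
            break
        if mode == "mean_path":
            kappa_cur = p.omega + p.B * kappa_cur
            continue
        eta = p.alpha[None, :] + p.beta[None, :] * kappa_cur[:, None]
        mu = np.exp(np.clip(eta, -50.0, 50.0))
        d_sim = _draw_deaths(spec, mu, exp_last, pop_last, rng)
        # per-path scaled score from the simulated deaths
        if spec.family in (Family.POISSON, Family.COM_POISSON):
            cell = CellParams(lam=exp_last[None, :] * mu)
        elif spec.family is Family.BINOMIAL:
            cell = CellParams(l=np.broadcast_to(pop_last[None, :], mu.shape), q=mu / (1.0 + mu))
        else:
            lam = exp_last[None, :] * mu
            h_nb = spec.r[None, :] / (spec.r[None, :] + lam)
            cell = CellParams(r=np.broadcast_to(spec.r[None, :], mu.shape), h=h_nb)
        grad = partial_score(spec, p.beta[None, :], d_sim, cell, fitted.config.score_form)
        info = partial_information(spec, p.beta[None, :], cell)
        s = grad.sum(axis=1) / np.sqrt(np.maximum(info.sum(axis=1), 1e-12))
        kappa_cur = p.omega + p.A * s + p.B * kappa_cur

    years = [surface.years[-1] + h for h in range(1, horizon + 1)]
    return ForecastResult(
        ages=list(surface.ages),
        years=years,
        horizon=horizon,
        n_sims=n_sims,
        seed=seed,
        kappa_paths=kappa_paths,
        rates_point=rate_paths.mean(axis=0),
        rate_paths=rate_paths,
    )


def point_and_interval_rates(result: ForecastResult, levels=(0.05, 0.5, 0.95)) -> pd.DataFrame:
    """Long table of point forecasts and empirical quantile bands.

    One row per (age, year); one column per requested quantile level.
    """
    qs = result.rate_quantiles(levels)
    n, h = result.rates_point.shape
    out = pd.DataFrame(
        {
            "age": np.repeat(result.ages, h),
            "year": np.tile(result.years, n),
            "point": result.rates_point.ravel(),
        }
    )
    for lv in sorted(qs):
        out[f"q{lv:g}"] = qs[lv].ravel()
    return out
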