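"""Model / Results facade for the score-driven Lee-Carter model.

``GasLeeCarter`` is built from a :class:`~gaslc.surface.MortalitySurface`
(or a long DataFrame) and an observation family; ``fit`` returns a
``GasLeeCarterResults`` carrying the estimates, information criteria,
filtered trend and convergence diagnostics, with ``summary()``,
``forecast()`` and plotting attached.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

from .distributions import Family, FamilySpec
from .estimation import FitConfig, FittedModel, fit, initialize
from .evaluation import aic_bic
from .forecasting import ForecastResult, simulate_paths
from .gas import FilterResult, GasParams, filter_kappa
from .surface import MortalitySurface

__all__ = ["GasLeeCarter", "GasLeeCarterResults"]


class GasLeeCarter:
    """Score-driven Lee-Carter mortality model.

    Parameters
    ----------
    surface : MortalitySurface
        Deaths and exposures (plus start-of-year populations for the
        binomial family) on an age x year grid.
    family : str or Family
        One of ``com_poisson``, ``poisson``, ``binomial``,
        ``negative_binomial``.

    Examples
    --------
    >>> model = GasLeeCarter(surface, family="com_poisson")
    >>> res = model.fit()
    >>> res.summary()
    >>> fc = res.forecast(horizon=10, n_sims=1000, seed=0)
    """

    def __init__(self, surface: MortalitySurface, family: str | Family = Family.POISSON):
        self.surface = surface
        fam = Family(family)
        if fam is Family.NEGATIVE_BINOMIAL:
            # placeholder r; replaced by the method-of-moments start inside fit
            self.family_spec = FamilySpec(fam, r=np.full(surface.n_ages, 50.0))
        elif fam is Family.COM_POISSON:
            self.family_spec = FamilySpec(fam, nu=1.0)
        else:
            self.family_spec = FamilySpec(fam)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, family: str | Family = Family.POISSON):
        """Build from a long table with columns year, age, deaths, exposure
        (and optionally population)."""
        return cls(MortalitySurface.from_dataframe(df), family)

    def start_params(self) -> tuple[GasParams, FamilySpec]:
        """SVD-based starting values (see :func:`gaslc.estimation.initialize`)."""
        return initialize(self.surface, self.family_spec)

    def loglike(self, params: GasParams, spec: FamilySpec | None = None,
                score_form: str = "offset") -> float:
        """Observation log-likelihood at given parameters."""
        return filter_kappa(self.surface, params, spec or self.family_spec, score_form).loglik

    def filter(self, params: GasParams, spec: FamilySpec | None = None,
               score_form: str = "offset") -> FilterResult:
        """Run the score-driven filter at given parameters."""
        return filter_kappa(self.surface, params, spec or self.family_spec, score_form)

    def fit(self, config: FitConfig | None = None, **kwargs) -> "GasLeeCarterResults":
        """Maximum-likelihood fit; keyword arguments build a FitConfig."""
        if config is None:
            config = FitConfig(**kwargs)
        elif kwargs:
            raise TypeError("pass either a FitConfig or keyword options, not both")
        fitted = fit(self.surface, self.family_spec, config)
        return GasLeeCarterResults(self, fitted)


class GasLeeCarterResults:
    """Estimation results for :class:`GasLeeCarter`."""

    def __init__(self, model: GasLeeCarter, fitted: FittedModel):
        self.model = model
        self.fitted = fitted
        self.params = fitted.params
        self.family_spec = fitted.spec
        self.llf = fitted.loglik
        self.nobs = fitted.n_obs
        self.df_model = fitted.n_params
        self.aic, self.bic = aic_bic(self.llf, self.df_model, self.nobs)
        self.filter_result = filter_kappa(
            model.surface, fitted.params, fitted.spec, fitted.config.score_form
        )

    # -- accessors ---------------------------------------------------------

    @property
    def kappa(self) -> np.ndarray:
        """Filtered common trend over the sample years."""
        return self.filter_result.kappa

    @property
    def linpred_rates(self) -> np.ndarray:
        """exp(alpha + beta kappa), the linear-predictor rate scale, (N, T)."""
        p = self.params
        return np.exp(p.alpha[:, None] + p.beta[:, None] * self.kappa[None, :])

    @property
    def fittedvalues(self) -> np.ndarray:
        """Model-implied expected central mortality rates, (N, T).

        Equal to exp(alpha + beta kappa) for the Poisson and negative
        binomial; l q / L for the binomial; for the COM-Poisson the death
        mean is the asymptotic lambda**(1/nu) - (nu-1)/(2 nu), divided by
        exposure (floored at a tiny positive rate).
        """
        mean = self.conditional_rate_moments()["mean"]
        return np.maximum(mean, 1e-300)

    def conditional_rate_moments(self) -> dict[str, np.ndarray]:
        """Mean and variance of the mortality rate implied by the family.

        Diagnostics accessor; forecasting and inference go through the pmf.
        For the COM-Poisson family these are the asymptotic approximations
        on the death-count scale divided by exposure.
        """
        surf = self.model.surface
        p, spec = self.params, self.family_spec
        mu = self.linpred_rates
        if spec.family is Family.POISSON:
            return {"mean": mu, "variance": mu / surf.exposures}
        if spec.family is Family.COM_POISSON:
            lam = surf.exposures * mu
            mean = lam ** (1.0 / spec.nu) - (spec.nu - 1.0) / (2.0 * spec.nu)
            var = lam ** (1.0 / spec.nu) / spec.nu
            return {"mean": mean / surf.exposures, "variance": var / surf.exposures}
        if spec.family is Family.NEGATIVE_BINOMIAL:
            lam = surf.exposures * mu
            h = spec.r[:, None] / (spec.r[:, None] + lam)
            return {"mean": mu, "variance": mu / (surf.exposures * h)}
        l = surf.start_populations
        q = self.filter_result.cell_params.q
        return {
            "mean": l * q / surf.exposures,
            "variance": l * q * (1 - q) / surf.exposures**2,
        }

    # -- reporting ---------------------------------------------------------

    def summary(self):
        """statsmodels-style summary tables."""
        from statsmodels.iolib.summary2 import Summary

        smry = Summary()
        spec = self.family_spec
        info = {
            "Family:": spec.family.value,
            "No. cells:": f"{self.nobs}",
            "Ages x Years:": f"{self.model.surface.n_ages} x {self.model.surface.n_years}",
            "Log-likelihood:": f"{self.llf:.2f}",
            "AIC:": f"{self.aic:.2f}",
            "BIC:": f"{self.bic:.2f}",
            "Eff. parameters:": f"{self.df_model}",
            "Converged:": str(self.fitted.converged),
            "Iterations:": f"{self.fitted.n_iter}",
        }
        smry.add_dict(info)
        p = self.params
        trend = {
            "omega": f"{p.omega:.5f}",
            "A": f"{p.A:.5f}",
            "B": f"{p.B:.5f}",
            "kappa_init": f"{p.kappa_init:.4f}",
        }
        if spec.family is Family.COM_POISSON:
            trend["nu"] = f"{spec.nu:.5f}"
        smry.add_dict(trend)
        age_tbl = pd.DataFrame(
            {"age": self.model.surface.ages, "alpha": p.alpha, "beta": p.beta}
        )
        if spec.family is Family.NEGATIVE_BINOMIAL:
            age_tbl["r"] = spec.r
        smry.add_df(age_tbl.round(5), index=False)
        smry.add_title("Score-driven Lee-Carter results")
        return smry

    # -- forecasting / plotting --------------------------------------------

    def forecast(self, horizon: int, n_sims: int = 1000, seed: int | None = None,
                 mode: str = "simulate", exposures=None) -> ForecastResult:
        """Monte-Carlo projection of trend and rates (see
        :func:`gaslc.forecasting.simulate_paths`)."""
        return simulate_paths(self.fitted, self.model.surface, horizon, n_sims, seed,
                              mode=mode, exposures=exposures)

    def plot_kappa(self, ax=None):
        """Plot the filtered common trend."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.model.surface.years, self.kappa, marker="o", ms=3)
        ax.set_xlabel("year")
        ax.set_ylabel(r"common trend $\kappa_t$")
        return ax

    # -- serialisation -----------------------------------------------------

    def to_json(self) -> str:
        """Documented JSON layout: family, parameter vectors, fit block."""
        surf = self.model.surface
        spec = self.family_spec
        payload = {
            "family": spec.family.value,
            "dispersion": {
                "nu": spec.nu,
                "r": None if spec.r is None else list(map(float, spec.r)),
            },
            "parameters": {
                "alpha": list(map(float, self.params.alpha)),
                "beta": list(map(float, self.params.beta)),
                "omega": self.params.omega,
                "A": self.params.A,
                "B": self.params.B,
                "kappa_init": self.params.kappa_init,
            },
            "data": {
                "ages": surf.ages,
                "years": surf.years,
                "last_exposures": list(map(float, surf.exposures[:, -1])),
            },
            "fit": {
                "loglik": self.llf,
                "aic": self.aic,
                "bic": self.bic,
                "n_params": self.df_model,
                "n_obs": self.nobs,
                "converged": self.fitted.converged,
                "iterations": self.fitted.n_iter,
                "grad_norm": self.fitted.grad_norm,
                "message": self.fitted.message,
                "score_form": self.fitted.config.score_form,
                "b_mode": self.fitted.config.b_mode,
            },
            "filtered": {
                "kappa": list(map(float, self.kappa)),
                "last_score": float(self.filter_result.scores[-1]),
            },
        }
        return json.dumps(payload, indent=2)
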