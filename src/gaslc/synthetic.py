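"""Synthetic mortality surfaces with known score-driven Lee-Carter structure.

The generator is the package's test bed: it draws death counts from any of
the four observation families on an age x year grid whose common trend
follows the same score recursion the filter assumes, so the fitted model is
correctly specified by construction.  A misspecification switch (generate
negative binomial, fit something else) supports the model-selection
experiments.

Defaults emulate grouped national mortality surfaces: 20 age groups spanning
0 to 90+, log rates between -9 (childhood minimum, ~1e-4) and -1 (oldest
ages, ~0.37), exposures of 1e3-1e6 person-years, and a downward-drifting
trend (random-walk form B = 1, drift omega = -0.5, score weight A = 0.08).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .distributions import (
    Family,
    FamilySpec,
    partial_information,
    partial_score,
    sample,
)
from .gas import GasParams, link_cell
from .surface import MortalitySurface

__all__ = ["ScenarioConfig", "make_params", "simulate_surface", "default_age_labels"]


def default_age_labels(n_ages: int) -> list[str]:
    """Age-group labels 0, 1-4, 5-9, ..., 85-89, 90+ (20 standard groups),
    truncated/extended to n_ages."""
    labels = ["0", "1-4"] + [f"{a}-{a + 4}" for a in range(5, 90, 5)] + ["90+"]
    if n_ages <= len(labels):
        return labels[:n_ages]
    return labels + [f"g{i}" for i in range(len(labels), n_ages)]


def _age_midpoints(n_ages: int) -> np.ndarray:
    """Nominal mid-ages for the default grouping, rescaled for other N."""
    if n_ages == 20:
        return np.array([0.5, 3.0] + [a + 2.5 for a in range(5, 90, 5)] + [92.5])
    return np.linspace(0.5, 92.5, n_ages)


def make_params(n_ages: int, seed: int | None = None, a: float = 0.08,
                b: float = 1.0, omega: float = -0.5) -> GasParams:
    """Realistic true parameters for a synthetic population.

    The age intercepts trace the canonical log-mortality profile: elevated
    infant mortality, a childhood minimum near -9, then a log-linear
    (Gompertz-like) rise to about -1 at the oldest ages.  Loadings are
    positive with a mild childhood tilt and sum to one.  The trend drifts
    downward (improving mortality).

    The score weight defaults to A = 0.08: with exposures around 1e5 the
    summed information I_t is a few hundred, and the filter's error-feedback
    gain B - A * sqrt(I_t) must stay inside the unit circle for the
    score-driven recursion to be a contraction; larger A makes the filter
    explosive at these exposure scales.
    """
    if n_ages < 2:
        raise ValueError("need at least 2 age groups")
    rng = np.random.default_rng(seed)
    mid = _age_midpoints(n_ages)
    # piecewise-linear canonical profile through (0, -5.2), (10, -9), (92.5, -1.2)
    alpha = np.where(
        mid <= 10.0,
        -5.2 + (mid / 10.0) * (-9.0 + 5.2),
        -9.0 + (mid - 10.0) / (92.5 - 10.0) * (-1.2 + 9.0),
    )
    alpha = np.clip(alpha + rng.normal(0.0, 0.1, n_ages), -9.0, -1.0)
    w = 1.0 + 0.8 * np.exp(-((mid - 15.0) / 30.0) ** 2) + rng.uniform(0.0, 0.3, n_ages)
    beta = w / w.sum()
    return GasParams(alpha=alpha, beta=beta, omega=omega, A=a, B=b, kappa_init=0.0)


@dataclass
class ScenarioConfig:
    """Data-generating scenario: grid size, exposures, truth and family."""

    n_ages: int = 20
    n_years: int = 30
    params: GasParams | None = None
    family: FamilySpec = field(default_factory=lambda: FamilySpec(Family.POISSON))
    exposure: float | np.ndarray = 1e5   # scalar or per-age profile
    first_year: int = 1990
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.params is None:
            self.params = make_params(self.n_ages, seed=self.seed)
        if self.params.n_ages != self.n_ages:
            raise ValueError("params dimension does not match n_ages")
        exp_profile = np.broadcast_to(np.asarray(self.exposure, dtype=float), (self.n_ages,))
        if np.any(exp_profile <= 0):
            raise ValueError("exposures must be positive")
        self.exposure_profile = np.round(exp_profile.copy())


def simulate_surface(config: ScenarioConfig) -> tuple[MortalitySurface, np.ndarray]:
    """Draw a mortality surface and return it with the true trend path.

    The trend evolves by the same score recursion the filter uses, with the
    scores computed from the freshly drawn deaths (self-consistent data
    generation).  For the binomial family the start-of-year population is
    set to l = L / (1 - q/2), the self-consistent version of the
    ``l = L + d/2`` convention at the expected death count.
    """
    rng = np.random.default_rng(config.seed)
    p = config.params
    spec = config.family
    n, t_len = config.n_ages, config.n_years
    exp_col = config.exposure_profile

    deaths = np.empty((n, t_len))
    pops = np.empty((n, t_len)) if spec.family is Family.BINOMIAL else None
    kappa = np.empty(t_len)
    kappa[0] = p.kappa_init
    for t in range(t_len):
        if spec.family is Family.BINOMIAL:
            eta = np.clip(p.alpha + p.beta * kappa[t], -50, 50)
            q = 1.0 / (1.0 + np.exp(-eta))
            if np.any(q / (1.0 - 0.5 * q) > 1.0):
                raise ValueError("scenario implies mortality rates above 1 for the binomial family")
            l_col = np.round(exp_col / (1.0 - 0.5 * q))
            pops[:, t] = l_col
            cp = link_cell(spec, p.alpha, p.beta, kappa[t], exp_col, l_col)
        else:
            cp = link_cell(spec, p.alpha, p.beta, kappa[t], exp_col)
        d_col = sample(spec, cp, rng=rng)
        deaths[:, t] = d_col
        grad = partial_score(spec, p.beta, d_col, cp)
        info = partial_information(spec, p.beta, cp)
        s_t = float(grad.sum()) / np.sqrt(max(float(info.sum()), 1e-12))
        if t < t_len - 1:
            kappa[t + 1] = p.omega + p.A * s_t + p.B * kappa[t]

    surface = MortalitySurface(
        ages=default_age_labels(n),
        years=list(range(config.first_year, config.first_year + t_len)),
        deaths=deaths,
        exposures=np.tile(exp_col[:, None], (1, t_len)),
        start_populations=pops,
    )
    return surface, kappa
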