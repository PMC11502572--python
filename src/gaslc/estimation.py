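"""Single-step maximum-likelihood estimation of the score-driven model.

All static parameters -- age intercepts alpha_x, loadings beta_x, trend
recursion coefficients (omega, A, B), the initial trend value and the
family's dispersion parameters -- are estimated jointly by maximising the
observation log-likelihood of the filtered model.

Identification: the loadings are constrained to sum to one (beta_N is
eliminated), and one location constraint is needed because shifting the
trend by c while moving alpha_x by -beta_x * c (and omega by c(1-B)) leaves
the fit unchanged; here alpha_1 is pinned to its initialisation value and
the initial trend value is estimated freely.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import minimize

from .distributions import Family, FamilySpec, SummationLimitError
from .gas import GasParams, filter_kappa, loglik_and_grad
from .surface import MortalitySurface

__all__ = [
    "FitConfig",
    "FittedModel",
    "initialize",
    "fit",
    "count_effective_params",
]

logger = logging.getLogger("gaslc")

_PENALTY = 1e8


@dataclass(frozen=True)
class FitConfig:
    """Optimisation settings for :func:`fit`.

    ``b_mode`` chooses between a freely estimated autoregressive coefficient
    constrained to |B| < 1 ("free") and the random-walk form B = 1
    ("fixed_one").  ``score_form`` selects the COM-Poisson score variant
    (see :func:`gaslc.distributions.partial_score`).
    """

    maxiter: int = 500
    gtol: float = 1e-5
    b_mode: str = "free"          # "free" (|B| < 1) or "fixed_one" (B = 1)
    score_form: str = "offset"    # "offset" or "plain"
    seed: int | None = None       # jitter seed for multi-start
    n_starts: int = 1
    jitter: float = 0.05
    warm_start_poisson: bool = True   # COM-Poisson fits start from the Poisson MLE

    def __post_init__(self) -> None:
        if self.gtol <= 0 or self.maxiter <= 0:
            raise ValueError("tolerances and iteration budgets must be positive")
        if self.b_mode not in ("free", "fixed_one"):
            raise ValueError(f"unknown b_mode {self.b_mode!r}")


@dataclass
class FittedModel:
    """Maximum-likelihood estimates plus a convergence report."""

    params: GasParams
    spec: FamilySpec
    config: FitConfig
    loglik: float
    loglik_init: float
    n_params: int          # effective free-parameter count
    n_obs: int             # N x T
    converged: bool
    n_iter: int
    grad_norm: float
    message: str


def count_effective_params(spec: FamilySpec, n_ages: int, b_mode: str = "free") -> int:
    """Effective number of free parameters for the given configuration.

    With B free: (N-1) intercepts + (N-1) loadings + omega, A, B, kappa_init
    + dispersion, i.e. 2N+2 for Poisson and binomial, 2N+3 for COM-Poisson
    and 3N+2 for the negative binomial.  Fixing B = 1 removes one.
    """
    base = 2 * n_ages + 2 + spec.n_dispersion
    return base - (1 if b_mode == "fixed_one" else 0)


# --------------------------------------------------------------------------
# initialisation
# --------------------------------------------------------------------------


def initialize(surface: MortalitySurface, spec: FamilySpec) -> tuple[GasParams, FamilySpec]:
    """Starting values from the classic SVD decomposition of log rates.

    alpha_x is the mean log rate per age (zero deaths patched by a +0.5
    continuity correction inside the log only); (beta_x, kappa_t) come from
    the leading singular pair of the centred log-rate matrix, rescaled so
    the loadings sum to one; (omega, B) from an AR(1) regression on the SVD
    trend (B clipped inside the unit interval), A starts at 0.1.  Dispersion
    starts at nu = 1 (COM-Poisson) or a per-age method-of-moments r
    (negative binomial).
    """
    d, exp_ = surface.deaths, surface.exposures
    if np.any(d.sum(axis=1) == 0):
        bad = [surface.ages[i] for i in np.where(d.sum(axis=1) == 0)[0]]
        raise ValueError(
            f"age rows with no deaths at all ({bad}); regroup into wider age bands"
        )
    m = (d + 0.5 * (d == 0)) / exp_
    logm = np.log(m)
    alpha = logm.mean(axis=1)
    centred = logm - alpha[:, None]
    u, s, vt = np.linalg.svd(centred, full_matrices=False)
    beta_raw = u[:, 0]
    kappa_raw = s[0] * vt[0]
    scale = float(beta_raw.sum())
    if abs(scale) < 1e-10:
        beta = np.full(surface.n_ages, 1.0 / surface.n_ages)
        kappa = centred.mean(axis=0) * surface.n_ages
    else:
        beta = beta_raw / scale
        kappa = kappa_raw * scale
    # AR(1) regression kappa_{t+1} = omega + B kappa_t on the SVD trend
    x, y = kappa[:-1], kappa[1:]
    varx = float(np.var(x))
    if varx > 1e-12:
        b = float(np.cov(x, y, bias=True)[0, 1] / varx)
    else:
        b = 0.95
    b = float(np.clip(b, -0.995, 0.995))
    omega = float(np.mean(y - b * x))
    params = GasParams(
        alpha=alpha, beta=beta, omega=omega, A=0.1, B=b, kappa_init=float(kappa[0])
    )
    if spec.family is Family.COM_POISSON:
        spec0 = FamilySpec(Family.COM_POISSON, nu=spec.nu if spec.nu else 1.0)
    elif spec.family is Family.NEGATIVE_BINOMIAL:
        lam0 = exp_ * np.exp(alpha[:, None] + beta[:, None] * kappa[None, :])
        excess = np.mean((d - lam0) ** 2 - lam0, axis=1)
        r0 = np.where(excess > 0, np.mean(lam0, axis=1) ** 2 / np.maximum(excess, 1e-12), 50.0)
        spec0 = FamilySpec(Family.NEGATIVE_BINOMIAL, r=np.clip(r0, 0.1, 1e6))
    else:
        spec0 = spec
    # the start likelihood is very sensitive to the score weight (too large
    # makes the filter's feedback loop explosive): grid-pick the best A
    best, best_ll = (params.A, params.B, params.omega), -np.inf
    for b_try in (params.B, 0.98):
        om_try = float(np.mean(y - b_try * x))
        for a_try in (0.01, 0.02, 0.04, 0.06, 0.08, 0.1, 0.12, 0.15):
            cand = replace(params, A=a_try, B=b_try, omega=om_try)
            try:
                ll = filter_kappa(surface, cand, spec0).loglik
            except (ValueError, FloatingPointError, SummationLimitError):
                continue
            if np.isfinite(ll) and ll > best_ll:
                best, best_ll = (a_try, b_try, om_try), ll
    params = replace(params, A=best[0], B=best[1], omega=best[2])
    return params, spec0


# --------------------------------------------------------------------------
# parameter packing
# --------------------------------------------------------------------------


class _Packer:
    """Bijective map between model parameters and the optimiser's vector.

    Shared transforms: A on the log scale (A > 0), B through tanh when free
    (|B| < 1), nu and r on the log scale.  For the COM-Poisson family the
    intercepts, trend coefficients and initial trend are carried divided by
    nu (with the log-exposure folded into the intercept coordinate), so
    moving nu holds the implied death-count mean lambda**(1/nu) roughly
    fixed; without this the optimiser crawls along a curved (nu, alpha)
    likelihood valley.
    """

    def __init__(self, surface: MortalitySurface, family: Family, config: FitConfig,
                 alpha0: float):
        self.family = family
        self.config = config
        self.n_ages = surface.n_ages
        self.log_exp = np.log(surface.exposures).mean(axis=1)
        self.alpha0 = alpha0
        # fixed location anchor for the first intercept, in internal units
        self.m1 = (self.log_exp[0] + alpha0) if family is Family.COM_POISSON else alpha0

    def pack(self, params: GasParams, spec: FamilySpec) -> np.ndarray:
        cp = self.family is Family.COM_POISSON
        nu = spec.nu if cp else 1.0
        if cp:
            a_int = (params.alpha + self.log_exp) / nu - self.log_exp
            alpha_part = (a_int + self.log_exp)[1:]  # m_x coordinates
        else:
            alpha_part = params.alpha[1:]
        parts = [
            alpha_part,
            params.beta[:-1],
            [params.omega / nu],
            [np.log(max(params.A / nu, 1e-12))],
        ]
        if self.config.b_mode == "free":
            parts.append([np.arctanh(np.clip(params.B, -0.999999, 0.999999))])
        parts.append([params.kappa_init / nu])
        if cp:
            parts.append([np.log(nu)])
        elif self.family is Family.NEGATIVE_BINOMIAL:
            parts.append(np.log(spec.r))
        return np.concatenate([np.atleast_1d(np.asarray(p, dtype=float)) for p in parts])

    def unpack(self, x: np.ndarray) -> tuple[GasParams, FamilySpec]:
        n = self.n_ages
        cp = self.family is Family.COM_POISSON
        i = 0
        alpha_part = x[i : i + n - 1]
        i += n - 1
        beta_free = x[i : i + n - 1]
        i += n - 1
        beta = np.concatenate([beta_free, [1.0 - beta_free.sum()]])
        omega_int = float(x[i]); i += 1
        a_int = float(np.exp(x[i])); i += 1
        if self.config.b_mode == "free":
            b_coef = float(np.tanh(x[i])); i += 1
        else:
            b_coef = 1.0
        kappa_int = float(x[i]); i += 1
        if cp:
            nu = float(np.exp(x[i]))
            spec = FamilySpec(Family.COM_POISSON, nu=nu)
            m = np.concatenate([[self.m1], alpha_part])
            alpha = nu * m - self.log_exp
        else:
            nu = 1.0
            alpha = np.concatenate([[self.alpha0], alpha_part])
            if self.family is Family.NEGATIVE_BINOMIAL:
                spec = FamilySpec(Family.NEGATIVE_BINOMIAL, r=np.exp(x[i : i + n]))
            else:
                spec = FamilySpec(self.family)
        params = GasParams(alpha, beta, nu * omega_int, nu * a_int, b_coef, nu * kappa_int)
        return params, spec

    def grad_to_packed(self, grads: dict, params: GasParams, spec: FamilySpec) -> np.ndarray:
        """Chain rule from raw-parameter gradients to the packed coordinates."""
        cp = self.family is Family.COM_POISSON
        nu = spec.nu if cp else 1.0
        g_alpha = np.asarray(grads["alpha"])
        g_beta = np.asarray(grads["beta"])
        parts = [
            nu * g_alpha[1:],
            g_beta[:-1] - g_beta[-1],
            [nu * grads["omega"]],
            [params.A * grads["A"]],
        ]
        if self.config.b_mode == "free":
            parts.append([(1.0 - params.B**2) * grads["B"]])
        parts.append([nu * grads["kappa_init"]])
        if cp:
            gu = (
                float((g_alpha * (params.alpha + self.log_exp)).sum())
                + grads["omega"] * params.omega
                + grads["A"] * params.A
                + grads["kappa_init"] * params.kappa_init
                + grads["nu"] * nu
            )
            parts.append([gu])
        elif self.family is Family.NEGATIVE_BINOMIAL:
            parts.append(np.asarray(grads["r"]) * spec.r)
        return np.concatenate([np.atleast_1d(np.asarray(p, dtype=float)) for p in parts])


# --------------------------------------------------------------------------
# fitting
# --------------------------------------------------------------------------


def _curvature_scales(objective, x0: np.ndarray, step: float = 1e-4) -> np.ndarray:
    """Per-coordinate 1/sqrt(curvature) scaling from finite differences."""
    f0 = objective(x0)
    scales = np.ones_like(x0)
    for i in range(x0.size):
        e = np.zeros_like(x0)
        e[i] = step
        h = (objective(x0 + e) - 2.0 * f0 + objective(x0 - e)) / step**2
        if np.isfinite(h) and h > 1e-8:
            scales[i] = 1.0 / np.sqrt(h)
    return np.clip(scales, 1e-4, 1e3)


def _preconditioned_bfgs(objective, objective_grad, x_start: np.ndarray, config: FitConfig):
    """Quasi-Newton (BFGS) with analytic gradients in curvature-rescaled
    coordinates, with restarts.

    The likelihood is far stiffer in the age loadings than in the recursion
    coefficients; rescaling each coordinate by the inverse square root of
    its diagonal curvature keeps the quasi-Newton steps inside the curved
    valley.  BFGS is restarted (scales re-estimated) until the objective
    stops improving or the restart budget is exhausted.
    """
    x_cur = np.asarray(x_start, dtype=float)
    best = None
    prev_fun = np.inf
    for _ in range(4):
        scales = _curvature_scales(objective, x_cur)

        def objective_scaled(z, _s=scales, _x=x_cur):
            f, g = objective_grad(_x + _s * z)
            return f, g * _s

        res = minimize(
            objective_scaled,
            np.zeros_like(x_cur),
            jac=True,
            method="BFGS",
            options={"maxiter": config.maxiter, "gtol": config.gtol},
        )
        res.x = x_cur + scales * res.x
        # gradient norm is reported in the optimiser's (rescaled) metric
        res.grad_scaled = float(np.max(np.abs(res.jac)))
        res.jac = res.jac / scales  # chain rule back to the raw coordinates
        if best is None or res.fun < best.fun:
            best = res
        if res.success or res.fun > prev_fun - 1e-9:
            break
        prev_fun = res.fun
        x_cur = res.x
    return best


def fit(
    surface: MortalitySurface,
    spec: FamilySpec,
    config: FitConfig | None = None,
    start: tuple[GasParams, FamilySpec] | None = None,
) -> FittedModel:
    """Maximise the observation log-likelihood with a quasi-Newton optimiser.

    COM-Poisson fits are warm-started from the Poisson maximum (nu = 1 nests
    Poisson exactly) unless disabled in the config.  The returned model never
    has a log-likelihood below its initialisation.
    """
    config = config or FitConfig()
    if start is None:
        params0, spec0 = initialize(surface, spec)
        if spec.family is Family.COM_POISSON and config.warm_start_poisson:
            pois = fit(surface, FamilySpec(Family.POISSON), config, start=(params0, FamilySpec(Family.POISSON)))
            params0 = pois.params
            spec0 = FamilySpec(Family.COM_POISSON, nu=spec.nu if spec.nu else 1.0)
    else:
        params0, spec0 = start

    n, t = surface.shape
    n_obs = n * t
    alpha0 = float(params0.alpha[0])
    family = spec.family
    packer = _Packer(surface, family, config, alpha0)

    def objective(x: np.ndarray) -> float:
        try:
            p, s = packer.unpack(x)
        except (ValueError, FloatingPointError):
            return _PENALTY
        try:
            ll = filter_kappa(surface, p, s, config.score_form).loglik
        except (SummationLimitError, FloatingPointError, ValueError):
            return _PENALTY
        if not np.isfinite(ll):
            return _PENALTY
        return -ll / n_obs

    def objective_grad(x: np.ndarray) -> tuple[float, np.ndarray]:
        try:
            p, s = packer.unpack(x)
            ll, grads = loglik_and_grad(surface, p, s, config.score_form)
        except (SummationLimitError, FloatingPointError, ValueError):
            return _PENALTY, np.zeros_like(x)
        if not np.isfinite(ll):
            return _PENALTY, np.zeros_like(x)
        g = packer.grad_to_packed(grads, p, s)
        if not np.all(np.isfinite(g)):
            return _PENALTY, np.zeros_like(x)
        return -ll / n_obs, -g / n_obs

    x0 = packer.pack(params0, spec0)
    ll_init = -objective(x0) * n_obs
    if not np.isfinite(ll_init):
        raise ValueError("initialisation has non-finite log-likelihood")

    starts = [x0]
    if config.n_starts > 1:
        rng = np.random.default_rng(config.seed)
        starts += [
            x0 + rng.normal(0.0, config.jitter, size=x0.size)
            for _ in range(config.n_starts - 1)
        ]

    best = None
    for x_start in starts:
        res = _preconditioned_bfgs(objective, objective_grad, x_start, config)
        if best is None or res.fun < best.fun:
            best = res

    ll_fit = -float(best.fun) * n_obs
    converged = bool(best.success)
    message = str(best.message)
    if ll_fit < ll_init:
        # ascent guarantee: never return a point below the start
        logger.warning("optimiser ended below the initial log-likelihood; keeping the start")
        params_hat, spec_hat = params0, spec0
        ll_fit = ll_init
        converged = False
        message += " [reverted to initialisation]"
    else:
        params_hat, spec_hat = packer.unpack(best.x)
    grad_norm = getattr(best, "grad_scaled", np.nan)
    if not converged:
        logger.warning("fit did not fully converge: %s", message)
    return FittedModel(
        params=params_hat,
        spec=spec_hat,
        config=config,
        loglik=ll_fit,
        loglik_init=ll_init,
        n_params=count_effective_params(spec_hat, n, config.b_mode),
        n_obs=n_obs,
        converged=converged,
        n_iter=int(best.nit),
        grad_norm=grad_norm,
        message=message,
    )
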