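"""Score-driven (GAS) filter for the common mortality trend.

The Lee-Carter decomposition log m_xt = alpha_x + beta_x * kappa_t is made
dynamic by treating kappa_t as the time-varying parameter of a GAS(1,1)
recursion driven by the scaled score of the observation density:

    kappa_{t+1} = omega + A * s_t + B * kappa_t
    s_t  = I_t^{-1/2} * sum_x grad_xt,      I_t = sum_x I_xt

where grad_xt and I_xt are the per-age partial score and partial Fisher
information of the chosen count family (see :mod:`gaslc.distributions`).
The filter is strictly causal: the last observed year updates nothing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .distributions import CellParams, Family, FamilySpec, log_pmf
from .surface import MortalitySurface

__all__ = ["GasParams", "FilterResult", "link_cell", "filter_kappa", "log_likelihood"]

logger = logging.getLogger("gaslc")

#: floor applied to the summed information before the inverse square root
INFO_FLOOR = 1e-12

#: clamp on the linear predictor alpha + beta * kappa before exponentiation
ETA_CLAMP = 50.0

_warned_clamp = False
_warned_floor = False


@dataclass
class GasParams:
    """Static parameters of the score-driven Lee-Carter model.

    ``alpha`` are age intercepts, ``beta`` age loadings constrained to sum to
    one, ``(omega, A, B)`` the trend recursion coefficients (A >= 0) and
    ``kappa_init`` the trend value in the first observed year.
    """

    alpha: np.ndarray
    beta: np.ndarray
    omega: float
    A: float
    B: float
    kappa_init: float

    def __post_init__(self) -> None:
        self.alpha = np.asarray(self.alpha, dtype=float)
        self.beta = np.asarray(self.beta, dtype=float)
        if self.alpha.shape != self.beta.shape or self.alpha.ndim != 1:
            raise ValueError("alpha and beta must be 1-d arrays of equal length")
        if abs(float(self.beta.sum()) - 1.0) > 1e-8:
            raise ValueError(f"beta must sum to 1 (got {self.beta.sum():.12g})")
        if self.A < 0:
            raise ValueError("A must be non-negative")

    @property
    def n_ages(self) -> int:
        return int(self.alpha.size)


@dataclass
class FilterResult:
    """Filtered trend path, scaled scores and the observation log-likelihood."""

    kappa: np.ndarray          # (T,) filtered trend, kappa[0] = kappa_init
    scores: np.ndarray         # (T,) scaled scores s_t (the last one updates nothing)
    cell_params: CellParams    # per-cell conditional parameters, (N, T) arrays
    cell_loglik: np.ndarray    # (N, T) per-cell log densities
    loglik: float              # total log-likelihood


def link_cell(
    spec: FamilySpec,
    alpha,
    beta,
    kappa: float,
    exposure,
    start_population=None,
) -> CellParams:
    """Map (alpha_x, beta_x, kappa_t, exposure) to the family's cell parameters.

    Poisson / COM-Poisson:  lam = L * exp(alpha + beta * kappa)
    binomial:               q = 1 / (1 + exp(-(alpha + beta * kappa))), with l
    negative binomial:      h = r / (r + L * exp(alpha + beta * kappa))

    The binomial link is the plain logistic in the linear predictor: it is
    the unique choice under which the family's partial score beta*(d - l q)
    and information beta**2 l q (1 - q) are the exact derivative and Fisher
    information of the binomial log mass in the trend.

    The linear predictor is clamped to +-ETA_CLAMP before exponentiation so
    the output is always finite (a warning is logged the first time).
    """
    global _warned_clamp
    alpha = np.asarray(alpha, dtype=float)
    beta = np.asarray(beta, dtype=float)
    eta = alpha + beta * kappa
    if np.any(np.abs(eta) > ETA_CLAMP):
        if not _warned_clamp:
            logger.warning("linear predictor clamped to +-%.0f to avoid overflow", ETA_CLAMP)
            _warned_clamp = True
        eta = np.clip(eta, -ETA_CLAMP, ETA_CLAMP)
    mu = np.exp(eta)  # central-rate scale exp(alpha + beta kappa)
    fam = spec.family
    if fam in (Family.POISSON, Family.COM_POISSON):
        return CellParams(lam=np.asarray(exposure, dtype=float) * mu)
    if fam is Family.BINOMIAL:
        if start_population is None:
            raise ValueError("binomial family requires start-of-year populations")
        q = 1.0 / (1.0 + np.exp(-eta))
        return CellParams(l=np.asarray(start_population, dtype=float), q=q)
    if fam is Family.NEGATIVE_BINOMIAL:
        r = spec.r
        h = r / (r + np.asarray(exposure, dtype=float) * mu)
        return CellParams(r=np.broadcast_to(r, mu.shape).astype(float), h=h)
    raise ValueError(f"unknown family {fam}")


def filter_kappa(
    surface: MortalitySurface,
    params: GasParams,
    spec: FamilySpec,
    score_form: str = "offset",
) -> FilterResult:
    """Run the GAS(1,1) filter over the surface and score the likelihood.

    For each year t the per-age scores and informations are summed,
    scaled by I_t^{-1/2} (floored at ``INFO_FLOOR``), and the trend advanced
    by ``kappa_{t+1} = omega + A s_t + B kappa_t``.  The total log-likelihood
    sums the per-cell log densities over all N x T cells.
    """
    global _warned_floor
    n, t_len = surface.shape
    if params.n_ages != n:
        raise ValueError("parameter dimension does not match the surface")
    if spec.family is Family.BINOMIAL and surface.start_populations is None:
        raise ValueError("binomial family requires start-of-year populations")
    if spec.family is Family.NEGATIVE_BINOMIAL and spec.r.size != n:
        raise ValueError("negative binomial r vector must have one entry per age")

    kappa = np.empty(t_len)
    scores = np.empty(t_len)
    kappa[0] = params.kappa_init

    fam = spec.family
    alpha, beta = params.alpha, params.beta
    omega, a_coef, b_coef = params.omega, params.A, params.B
    deaths, expos = surface.deaths, surface.exposures
    beta_sq = beta**2
    if fam is Family.COM_POISSON:
        score_off = 0.0 if score_form == "plain" else (spec.nu - 1.0) / (2.0 * spec.nu)
        if spec.nu == 0:
            raise ValueError("COM-Poisson filter undefined at nu = 0")
        if score_form not in ("offset", "plain"):
            raise ValueError(f"unknown score_form {score_form!r}")
    else:
        score_off = 0.0
    store_a = np.empty((n, t_len))
    store_b = np.empty((n, t_len))
    floored = False
    for t in range(t_len):
        k = kappa[t]
        eta = alpha + beta * k
        np.clip(eta, -ETA_CLAMP, ETA_CLAMP, out=eta)
        mu = np.exp(eta)
        d_col = deaths[:, t]
        if fam in (Family.POISSON, Family.COM_POISSON):
            lam = expos[:, t] * mu
            store_a[:, t] = lam
            grad_sum = float((beta * (d_col - lam)).sum()) + score_off * float(beta.sum())
            info_sum = float((beta_sq * lam).sum())
        elif fam is Family.BINOMIAL:
            l_col = surface.start_populations[:, t]
            q = 1.0 / (1.0 + np.exp(-eta))
            store_a[:, t] = l_col
            store_b[:, t] = q
            grad_sum = float((beta * (d_col - l_col * q)).sum())
            info_sum = float((beta_sq * l_col * q * (1.0 - q)).sum())
        else:
            r = spec.r
            h = r / (r + expos[:, t] * mu)
            np.clip(h, 1e-12, 1.0 - 1e-12, out=h)
            store_a[:, t] = r
            store_b[:, t] = h
            grad_sum = float((beta * (d_col * h - (1.0 - h) * r)).sum())
            info_sum = float((beta_sq * (1.0 - h) * r).sum())
        if info_sum < INFO_FLOOR:
            info_sum = INFO_FLOOR
            floored = True
        scores[t] = grad_sum / np.sqrt(info_sum)
        if t < t_len - 1:
            kappa[t + 1] = omega + a_coef * scores[t] + b_coef * kappa[t]
    if floored and not _warned_floor:
        logger.warning(
            "summed information floored at %.0e (degenerate beta or vanishing rates)",
            INFO_FLOOR,
        )
        _warned_floor = True
    store = {"a": store_a, "b": store_b}

    if fam in (Family.POISSON, Family.COM_POISSON):
        cell = CellParams(lam=store["a"])
    elif fam is Family.BINOMIAL:
        cell = CellParams(l=store["a"], q=store["b"])
    else:
        cell = CellParams(r=store["a"], h=store["b"])
    cell_ll = log_pmf(spec, cell, surface.deaths)
    return FilterResult(
        kappa=kappa,
        scores=scores,
        cell_params=cell,
        cell_loglik=cell_ll,
        loglik=float(cell_ll.sum()),
    )


def log_likelihood(
    surface: MortalitySurface,
    params: GasParams,
    spec: FamilySpec,
    score_form: str = "offset",
) -> float:
    """Total observation log-likelihood at the filtered trend path."""
    return filter_kappa(surface, params, spec, score_form).loglik


def loglik_and_grad(
    surface: MortalitySurface,
    params: GasParams,
    spec: FamilySpec,
    score_form: str = "offset",
) -> tuple[float, dict[str, np.ndarray | float]]:
    """Log-likelihood and its exact gradient in the static parameters.

    The gradient is propagated forward through the score recursion: the
    tangent of kappa_t with respect to every static parameter is carried
    along with the filter, so each evaluation costs a small multiple of the
    filter itself.  Gradient keys: ``alpha`` (N,), ``beta`` (N,), ``omega``,
    ``A``, ``B``, ``kappa_init`` and, family-permitting, ``nu`` or ``r`` (N,).
    The COM-Poisson pieces use E[Y] and E[log Y!] from the truncated series
    (the derivatives of the log normalizing constant).
    """
    from scipy.special import digamma, gammaln as _gammaln

    from .distributions import compoisson_logz_stats

    n, t_len = surface.shape
    fam = spec.family
    if fam is Family.BINOMIAL and surface.start_populations is None:
        raise ValueError("binomial family requires start-of-year populations")
    alpha, beta = params.alpha, params.beta
    omega, a_coef, b_coef = params.omega, params.A, params.B
    deaths, expos = surface.deaths, surface.exposures
    beta_sq = beta**2
    n_disp = spec.n_dispersion
    # tangent layout: [alpha (N), beta (N), omega, A, B, kappa_init, disp...]
    p_dim = 2 * n + 4 + n_disp
    i_om, i_a, i_b, i_ki = 2 * n, 2 * n + 1, 2 * n + 2, 2 * n + 3
    i_disp = 2 * n + 4
    dk = np.zeros(p_dim)
    dk[i_ki] = 1.0
    dll = np.zeros(p_dim)
    ll = 0.0

    if fam is Family.COM_POISSON:
        nu = spec.nu
        if nu == 0:
            raise ValueError("COM-Poisson filter undefined at nu = 0")
        off = 0.0 if score_form == "plain" else (nu - 1.0) / (2.0 * nu)
        doff_dnu = 0.0 if score_form == "plain" else 1.0 / (2.0 * nu**2)
        lfact_d = _gammaln(deaths + 1.0)
    elif fam is Family.NEGATIVE_BINOMIAL:
        r_vec = spec.r

    kappa = params.kappa_init
    for t in range(t_len):
        eta = alpha + beta * kappa
        act = (np.abs(eta) < ETA_CLAMP).astype(float)  # clamp kills the local slope
        eta = np.clip(eta, -ETA_CLAMP, ETA_CLAMP)
        mu = np.exp(eta)
        d_col = deaths[:, t]

        if fam in (Family.POISSON, Family.COM_POISSON):
            lam = expos[:, t] * mu
            if fam is Family.COM_POISSON:
                logz, ey, elogf = compoisson_logz_stats(lam, nu)
                grad_c = beta * (d_col - lam + off)
                dgrad_dbeta = d_col - lam + off
                ll_t = float((d_col * np.log(lam) - nu * lfact_d[:, t] - logz).sum())
                dll_deta = d_col - ey
                dll_ddisp = float((-lfact_d[:, t] + elogf).sum())
                dgrad_ddisp = float((beta * doff_dnu).sum())
                dinfo_ddisp = 0.0
            else:
                grad_c = beta * (d_col - lam)
                dgrad_dbeta = d_col - lam
                ll_t = float(
                    (d_col * np.log(lam) - lam - _gammaln(d_col + 1.0)).sum()
                )
                dll_deta = d_col - lam
            dgrad_deta = -beta * lam
            info_c = beta_sq * lam
            dinfo_deta = beta_sq * lam
            dinfo_dbeta = 2.0 * beta * lam
        elif fam is Family.BINOMIAL:
            l_col = surface.start_populations[:, t]
            q = 1.0 / (1.0 + np.exp(-eta))
            dq_deta = q * (1.0 - q)
            grad_c = beta * (d_col - l_col * q)
            dgrad_deta = -beta * l_col * dq_deta
            dgrad_dbeta = d_col - l_col * q
            info_c = beta_sq * l_col * q * (1.0 - q)
            dinfo_deta = beta_sq * l_col * (1.0 - 2.0 * q) * dq_deta
            dinfo_dbeta = 2.0 * beta * l_col * q * (1.0 - q)
            ll_t = float(
                (
                    _gammaln(l_col + 1.0)
                    - _gammaln(d_col + 1.0)
                    - _gammaln(l_col - d_col + 1.0)
                    + d_col * np.log(q)
                    + (l_col - d_col) * np.log1p(-q)
                ).sum()
            )
            dll_deta = (d_col / q - (l_col - d_col) / (1.0 - q)) * dq_deta
        else:  # negative binomial
            lam = expos[:, t] * mu
            h = r_vec / (r_vec + lam)
            np.clip(h, 1e-12, 1.0 - 1e-12, out=h)
            dh_deta = -h * (1.0 - h)
            dh_dr = h * (1.0 - h) / r_vec
            grad_c = beta * (d_col * h - (1.0 - h) * r_vec)
            dgrad_dh = beta * (d_col + r_vec)
            dgrad_deta = dgrad_dh * dh_deta
            dgrad_dbeta = d_col * h - (1.0 - h) * r_vec
            dgrad_dr = dgrad_dh * dh_dr - beta * (1.0 - h)
            info_c = beta_sq * (1.0 - h) * r_vec
            dinfo_deta = beta_sq * r_vec * h * (1.0 - h)
            dinfo_dbeta = 2.0 * beta * (1.0 - h) * r_vec
            dinfo_dr = beta_sq * (1.0 - h) ** 2
            ll_t = float(
                (
                    _gammaln(d_col + r_vec)
                    - _gammaln(r_vec)
                    - _gammaln(d_col + 1.0)
                    + d_col * np.log1p(-h)
                    + r_vec * np.log(h)
                ).sum()
            )
            dll_dh = -d_col / (1.0 - h) + r_vec / h
            dll_deta = dll_dh * dh_deta
            dll_dr = digamma(d_col + r_vec) - digamma(r_vec) + np.log(h) + dll_dh * dh_dr

        dgrad_deta = dgrad_deta * act
        dinfo_deta = dinfo_deta * act
        dll_deta = dll_deta * act

        ll += ll_t
        # log-likelihood accumulation: direct partials plus the kappa tangent
        dll[:n] += dll_deta
        dll[n : 2 * n] += dll_deta * kappa
        dll_dkappa = float((dll_deta * beta).sum())
        dll += dll_dkappa * dk
        if fam is Family.COM_POISSON:
            dll[i_disp] += dll_ddisp
        elif fam is Family.NEGATIVE_BINOMIAL:
            dll[i_disp:] += dll_dr

        if t == t_len - 1:
            break

        g_sum = float(grad_c.sum())
        i_sum = float(info_c.sum())
        floored = i_sum < INFO_FLOOR
        i_eff = max(i_sum, INFO_FLOOR)
        sqrt_i = np.sqrt(i_eff)
        s_t = g_sum / sqrt_i

        # total derivatives of the summed score and information
        dG = np.zeros(p_dim)
        dG[:n] = dgrad_deta
        dG[n : 2 * n] = dgrad_deta * kappa + dgrad_dbeta
        dG_dkappa = float((dgrad_deta * beta).sum())
        dI = np.zeros(p_dim)
        dI[:n] = dinfo_deta
        dI[n : 2 * n] = dinfo_deta * kappa + dinfo_dbeta
        dI_dkappa = float((dinfo_deta * beta).sum())
        if fam is Family.COM_POISSON:
            dG[i_disp] = dgrad_ddisp
            dI[i_disp] = dinfo_ddisp
        elif fam is Family.NEGATIVE_BINOMIAL:
            dG[i_disp:] = dgrad_dr
            dI[i_disp:] = dinfo_dr
        dG += dG_dkappa * dk
        dI += dI_dkappa * dk
        if floored:
            dI[:] = 0.0
        ds = dG / sqrt_i - (g_sum / (2.0 * i_eff * sqrt_i)) * dI

        dk_new = a_coef * ds + b_coef * dk
        dk_new[i_om] += 1.0
        dk_new[i_a] += s_t
        dk_new[i_b] += kappa
        dk = dk_new
        kappa = omega + a_coef * s_t + b_coef * kappa

    grads: dict[str, np.ndarray | float] = {
        "alpha": dll[:n],
        "beta": dll[n : 2 * n],
        "omega": float(dll[i_om]),
        "A": float(dll[i_a]),
        "B": float(dll[i_b]),
        "kappa_init": float(dll[i_ki]),
    }
    if fam is Family.COM_POISSON:
        grads["nu"] = float(dll[i_disp])
    elif fam is Family.NEGATIVE_BINOMIAL:
        grads["r"] = dll[i_disp:]
    return float(ll), grads
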