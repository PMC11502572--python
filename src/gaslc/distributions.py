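"""Count distributions for death counts.

The Conway-Maxwell-Poisson (COM-Poisson) distribution is the centrepiece: a
two-parameter count family with rate ``lambda`` and dispersion ``nu`` whose
pmf is

    P(Y = y) = lambda**y / ((y!)**nu * Z(lambda, nu)),     y = 0, 1, 2, ...

with normalizing constant ``Z(lambda, nu) = sum_s lambda**s / (s!)**nu``.
It bridges the geometric (nu = 0, lambda < 1), Poisson (nu = 1) and
Bernoulli (nu -> infinity, success probability lambda / (1 + lambda))
distributions; ``nu < 1`` gives overdispersion, ``nu > 1`` underdispersion.

Alongside it live the Poisson, binomial and negative-binomial observation
families used by the score-driven mortality model, each with its per-cell
partial score (derivative of the log density with respect to the common
trend) and partial Fisher information:

=================  ===============================================  ==================
family             partial score (per age x)                        partial information
=================  ===============================================  ==================
COM-Poisson        beta * (d - lambda + (nu - 1) / (2 nu))          beta**2 * lambda
Poisson            beta * (d - lambda)                              beta**2 * lambda
binomial           beta * (d - l * q)                               beta**2 * l q (1 - q)
negative binomial  beta * (d * h - (1 - h) * r)                     beta**2 * (1 - h) * r
=================  ===============================================  ==================

The COM-Poisson score is also available in its simplified form
``beta * (d - lambda)`` via ``score_form="plain"`` (the two coincide at
nu = 1, where the family is exactly Poisson).

All normalizing-constant work happens in log space.  ``Z`` is evaluated by a
truncated summation of the series centred on its largest term (index near
``lambda**(1/nu)``), with the truncation window sized from the local
curvature of the log terms and the endpoints verified; summation is capped
at ``MAX_TERMS`` terms and fails loudly beyond that.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import NamedTuple

import numpy as np
from scipy.special import gammaln

__all__ = [
    "Family",
    "FamilySpec",
    "CellParams",
    "ComPoissonParams",
    "ComPoissonDivergenceError",
    "SummationLimitError",
    "log_normalizer",
    "compoisson_logpmf",
    "compoisson_rvs",
    "exact_moment",
    "approx_mean_var",
    "log_pmf",
    "partial_score",
    "partial_information",
    "sample",
]

#: hard cap on the number of series terms for any single cell
MAX_TERMS = 1_000_000


class ComPoissonDivergenceError(ValueError):
    """The COM-Poisson series diverges (nu = 0 with lambda >= 1)."""


class SummationLimitError(RuntimeError):
    """The truncated series would need more than ``MAX_TERMS`` terms."""


# --------------------------------------------------------------------------
# log-factorial lookup table (grown lazily); integer arguments only
# --------------------------------------------------------------------------

_LFACT = np.zeros(2)


def _log_factorial(n: np.ndarray) -> np.ndarray:
    """log(n!) for non-negative integer arrays, via a cached cumulative table."""
    global _LFACT
    n = np.asarray(n, dtype=np.int64)
    top = int(n.max(initial=0))
    if top >= _LFACT.size:
        new_size = max(top + 1, 2 * _LFACT.size)
        ext = np.log(np.arange(_LFACT.size, new_size, dtype=float))
        _LFACT = np.concatenate([_LFACT, _LFACT[-1] + np.cumsum(ext)])
    return _LFACT[n]


# --------------------------------------------------------------------------
# parameter containers
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ComPoissonParams:
    """Admissible (lambda, nu) pair.

    lambda must be positive; nu non-negative; the boundary case nu = 0
    requires lambda < 1, otherwise the normalizing series diverges and the
    distribution is undefined.
    """

    lam: float
    nu: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.lam) and np.isfinite(self.nu)):
            raise ValueError("lambda and nu must be finite")
        if self.lam <= 0:
            raise ValueError(f"lambda must be positive, got {self.lam}")
        if self.nu < 0:
            raise ValueError(f"nu must be non-negative, got {self.nu}")
        if self.nu == 0 and self.lam >= 1:
            raise ComPoissonDivergenceError(
                f"COM-Poisson with nu=0 requires lambda < 1 (got lambda={self.lam}); "
                "the normalizing series diverges"
            )


class Family(str, Enum):
    """Observation family for the death-count model."""

    COM_POISSON = "com_poisson"
    POISSON = "poisson"
    BINOMIAL = "binomial"
    NEGATIVE_BINOMIAL = "negative_binomial"


@dataclass(frozen=True)
class FamilySpec:
    """Family tag plus its dispersion parameters.

    ``nu`` applies to the COM-Poisson family only; ``r`` (one positive value
    per age) to the negative binomial only.
    """

    family: Family
    nu: float | None = None
    r: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        fam = Family(self.family)
        object.__setattr__(self, "family", fam)
        if fam is Family.COM_POISSON:
            if self.nu is None:
                object.__setattr__(self, "nu", 1.0)
            if self.nu < 0 or not np.isfinite(self.nu):
                raise ValueError(f"nu must be a non-negative real, got {self.nu}")
            if self.r is not None:
                raise ValueError("r applies to the negative binomial family only")
        elif fam is Family.NEGATIVE_BINOMIAL:
            if self.r is None:
                raise ValueError("negative binomial requires an r vector (one per age)")
            r = np.atleast_1d(np.asarray(self.r, dtype=float))
            if np.any(r <= 0) or not np.all(np.isfinite(r)):
                raise ValueError("all r must be positive finite reals")
            object.__setattr__(self, "r", r)
            if self.nu is not None:
                raise ValueError("nu applies to the COM-Poisson family only")
        else:
            if self.nu is not None or self.r is not None:
                raise ValueError(f"{fam.value} carries no dispersion parameter")

    @property
    def n_dispersion(self) -> int:
        if self.family is Family.COM_POISSON:
            return 1
        if self.family is Family.NEGATIVE_BINOMIAL:
            return int(self.r.size)
        return 0


@dataclass
class CellParams:
    """Per-cell conditional distribution parameters produced by the link.

    Poisson / COM-Poisson carry ``lam``; binomial carries ``(l, q)``;
    negative binomial carries ``(r, h)``.  Arrays are aligned with ages.
    """

    lam: np.ndarray | None = None
    l: np.ndarray | None = None
    q: np.ndarray | None = None
    r: np.ndarray | None = None
    h: np.ndarray | None = None


# --------------------------------------------------------------------------
# COM-Poisson normalizing constant
# --------------------------------------------------------------------------


def _window_logsum(lam: np.ndarray, nu: float, drop: np.ndarray):
    """Truncated log-series sum centred on the largest term.

    Returns (logz, lo, logterms) where ``logterms`` covers indices
    ``lo[i] + j`` for cell i, column j.  ``drop`` is the required log-distance
    between the peak term and the truncation endpoints.
    """
    lam = np.atleast_1d(np.asarray(lam, dtype=float))
    mode = lam ** (1.0 / nu)
    if np.any(mode + 10 > MAX_TERMS):
        raise SummationLimitError(
            f"COM-Poisson series mode lambda**(1/nu) ~ {float(mode.max()):.3g} "
            f"exceeds the {MAX_TERMS}-term summation cap"
        )
    # half-width from local curvature of the log term, d2/ds2 ~ -nu/s
    half = np.sqrt(2.0 * np.maximum(mode, 1.0) * drop / nu) + 20.0
    for _ in range(6):
        k = int(np.ceil(half.max()))
        if 2 * k + 1 > MAX_TERMS or mode.max() + k > MAX_TERMS:
            raise SummationLimitError(
                "COM-Poisson truncation window exceeds the summation cap "
                f"(lambda up to {float(lam.max()):.3g}, nu={nu:.4g})"
            )
        lo = np.maximum(np.floor(mode).astype(np.int64) - k, 0)
        s = lo[:, None] + np.arange(2 * k + 1, dtype=np.int64)[None, :]
        logterms = s * np.log(lam)[:, None] - nu * _log_factorial(s)
        peak = logterms.max(axis=1)
        # endpoints must sit `drop` below the peak (left endpoint only when > 0)
        right_ok = logterms[:, -1] < peak - drop
        left_ok = (lo == 0) | (logterms[:, 0] < peak - drop)
        if bool(np.all(right_ok & left_ok)):
            shifted = np.exp(logterms - peak[:, None])
            return peak + np.log(shifted.sum(axis=1)), lo, logterms
        half = half * 2.0
    raise SummationLimitError("COM-Poisson truncation window failed to close")


def _logz_ragged(
    lam: np.ndarray, nu: float, drop: np.ndarray, half: np.ndarray, stats: bool = False
):
    """Per-cell truncated log-series sums (ragged windows, one flat pass).

    With ``stats=True`` also returns the implied mean E[Y] and E[log Y!]
    (the derivatives of log Z with respect to log lambda and -nu).
    """
    with np.errstate(over="ignore"):
        mode = lam ** (1.0 / nu)
    if np.any(~np.isfinite(mode) | (mode + half > MAX_TERMS)):
        raise SummationLimitError(
            f"COM-Poisson series needs indices beyond the {MAX_TERMS}-term cap "
            f"(lambda up to {float(lam.max()):.3g}, nu={nu:.4g})"
        )
    mode_floor = np.floor(np.maximum(mode, 0.0)).astype(np.int64)
    lo = np.maximum(mode_floor - half.astype(np.int64), 0)
    hi = mode_floor + half.astype(np.int64)
    widths = hi - lo + 1
    total = int(widths.sum())
    if total > 50_000_000:
        raise SummationLimitError("COM-Poisson truncation windows too large in aggregate")
    starts = np.concatenate([[0], np.cumsum(widths)[:-1]])
    idx = np.arange(total, dtype=np.int64) - np.repeat(starts, widths) + np.repeat(lo, widths)
    lfact = _log_factorial(idx)
    logterms = idx * np.repeat(np.log(lam), widths) - nu * lfact
    seg_max = np.maximum.reduceat(logterms, starts)
    w = np.exp(logterms - np.repeat(seg_max, widths))
    sums = np.add.reduceat(w, starts)
    logz = seg_max + np.log(sums)
    # verify the endpoints sit far enough below each segment's peak
    right_bad = logterms[starts + widths - 1] >= seg_max - drop
    left_bad = (lo > 0) & (logterms[starts] >= seg_max - drop)
    bad = right_bad | left_bad
    if not stats:
        if np.any(bad):
            logz = logz.copy()
            logz[bad] = _logz_ragged(lam[bad], nu, drop[bad], half[bad] * 2.0)
        return logz
    mean = np.add.reduceat(idx * w, starts) / sums
    elogf = np.add.reduceat(lfact * w, starts) / sums
    if np.any(bad):
        logz, mean, elogf = logz.copy(), mean.copy(), elogf.copy()
        logz[bad], mean[bad], elogf[bad] = _logz_ragged(
            lam[bad], nu, drop[bad], half[bad] * 2.0, stats=True
        )
    return logz, mean, elogf


def compoisson_logz_stats(lam, nu: float, rel_tol: float = 1e-10):
    """(log Z, E[Y], E[log Y!]) per cell; closed forms at nu = 0 and nu = 1."""
    lam = np.atleast_1d(np.asarray(lam, dtype=float))
    if nu == 0:
        if np.any(lam >= 1):
            raise ComPoissonDivergenceError("nu=0 requires lambda < 1")
        mean = lam / (1.0 - lam)
        # E[log Y!] for the geometric case, by direct summation per cell
        elogf = np.array([exact_logfact_mean_geometric(l) for l in lam])
        return -np.log1p(-lam), mean, elogf
    with np.errstate(over="ignore"):  # inf modes are rejected downstream
        mode = np.maximum(lam ** (1.0 / nu), 1.0)
        drop = -np.log(rel_tol) + 0.5 * np.log(mode / nu + 1.0) + 10.0 + np.log(mode + 10.0)
        half = np.sqrt(2.0 * mode * drop / nu) + 20.0
    logz, mean, elogf = _logz_ragged(lam, nu, drop, half, stats=True)
    if nu == 1:  # the sum is exact there anyway; pin the closed forms
        logz, mean = lam.copy(), lam.copy()
    return logz, mean, elogf


def exact_logfact_mean_geometric(lam: float) -> float:
    s_max = int(np.ceil(np.log(1e-16) / np.log(lam))) + 10 if 0 < lam < 1 else 10
    s = np.arange(s_max + 1)
    w = np.exp(s * np.log(lam) + np.log1p(-lam))
    return float((_log_factorial(s) * w).sum())


def _logz(lam, nu: float, rel_tol: float = 1e-10) -> np.ndarray:
    """Vectorised log Z(lambda, nu); closed forms at nu = 0 and nu = 1."""
    lam = np.atleast_1d(np.asarray(lam, dtype=float))
    if not np.all(np.isfinite(lam)) or np.any(lam <= 0):
        raise ValueError("lambda must be positive and finite")
    if not np.isfinite(nu) or nu < 0:
        raise ValueError(f"nu must be a non-negative real, got {nu}")
    if nu == 0:
        if np.any(lam >= 1):
            raise ComPoissonDivergenceError(
                "nu=0 requires lambda < 1; the normalizing series diverges"
            )
        return -np.log1p(-lam)
    if nu == 1:
        return lam.copy()
    with np.errstate(over="ignore"):  # inf modes are rejected downstream
        mode = np.maximum(lam ** (1.0 / nu), 1.0)
        drop = -np.log(rel_tol) + 0.5 * np.log(mode / nu + 1.0) + 10.0
        half = np.sqrt(2.0 * mode * drop / nu) + 20.0
    return _logz_ragged(lam, nu, drop, half)


def log_normalizer(lam: float, nu: float, rel_tol: float = 1e-10) -> float:
    """log Z(lambda, nu) = log sum_s lambda**s / (s!)**nu.

    Computed in log space with the series truncated once successive terms
    are negligible at ``rel_tol`` relative to the running sum.  Exact closed
    forms are used at nu = 1 (Z = e**lambda) and nu = 0 with lambda < 1
    (geometric sum 1 / (1 - lambda)).

    Raises
    ------
    ComPoissonDivergenceError
        if nu = 0 and lambda >= 1 (the series diverges).
    SummationLimitError
        if the truncation would need more than ``MAX_TERMS`` terms.
    """
    if rel_tol <= 0:
        raise ValueError("rel_tol must be positive")
    return float(_logz(lam, nu, rel_tol)[0])


def compoisson_logpmf(y, lam, nu: float) -> np.ndarray:
    """COM-Poisson log pmf; -inf outside the support (negative or non-integer y)."""
    y = np.atleast_1d(np.asarray(y, dtype=float))
    lam_arr = np.atleast_1d(np.asarray(lam, dtype=float))
    y_b, lam_b = np.broadcast_arrays(y, lam_arr)
    logz = _logz(lam_b.ravel(), nu).reshape(lam_b.shape)
    ok = (y_b >= 0) & (y_b == np.floor(y_b)) & np.isfinite(y_b)
    yy = np.where(ok, y_b, 0.0)
    out = yy * np.log(lam_b) - nu * gammaln(yy + 1.0) - logz
    return np.where(ok, out, -np.inf)


def exact_moment(lam: float, nu: float, order: int = 1) -> float:
    """E(Y**order) by direct truncated summation of y**order * pmf(y).

    The truncation tail is held below 1e-10 of the accumulated sum.  Serves
    as the moment oracle for the whole package (the closed-form moment
    recursion for this family is numerically treacherous near nu = 1, so
    summation is the authoritative route).
    """
    if order < 1 or order != int(order):
        raise ValueError("order must be a positive integer")
    ComPoissonParams(lam, nu)  # validates, incl. divergence at nu=0, lam>=1
    if nu == 0:
        # geometric on {0,1,...} with success prob 1-lam
        s_max = int(np.ceil((np.log(1e-16) / np.log(lam)))) + 10
        s = np.arange(s_max + 1, dtype=float)
        w = np.exp(s * np.log(lam) + np.log1p(-lam))
        return float(np.sum(s**order * w))
    mode = max(lam ** (1.0 / nu), 1.0)
    drop = 23.0 + 0.5 * np.log(mode / nu + 1.0) + order * np.log(mode + 10.0) + 10.0
    logz, lo, logterms = _window_logsum(np.asarray([lam]), nu, np.asarray([drop]))
    s = lo[0] + np.arange(logterms.shape[1], dtype=float)
    pmf = np.exp(logterms[0] - logz[0])
    return float(np.sum(s**order * pmf))


class ApproxMoments(NamedTuple):
    mean: float
    variance: float
    within_region: bool


def approx_mean_var(lam: float, nu: float) -> ApproxMoments:
    """Asymptotic mean / variance approximation for the COM-Poisson family.

        E(Y)  ~  lambda**(1/nu) - (nu - 1) / (2 nu)
        Var(Y) ~ lambda**(1/nu) / nu

    Stated to be reliable for nu <= 1 or lambda > 10**nu; outside that region
    the value is still returned but flagged via ``within_region=False``.
    """
    if nu == 0:
        raise ValueError("approximation undefined at nu = 0")
    ComPoissonParams(lam, nu)
    mean = lam ** (1.0 / nu) - (nu - 1.0) / (2.0 * nu)
    var = lam ** (1.0 / nu) / nu
    return ApproxMoments(float(mean), float(var), bool(nu <= 1 or lam > 10.0**nu))


def compoisson_rvs(lam, nu: float, size: int | None = None, rng=None) -> np.ndarray:
    """Draw COM-Poisson variates by inversion of the truncated cmf.

    ``lam`` may be a scalar (with ``size`` draws) or an array (one draw per
    element).  Deterministic given the generator state.
    """
    rng = np.random.default_rng(rng)
    lam_arr = np.atleast_1d(np.asarray(lam, dtype=float))
    if size is not None:
        if lam_arr.size != 1:
            raise ValueError("size is only valid with scalar lambda")
        lam_arr = np.full(size, float(lam_arr[0]))
    if np.any(lam_arr <= 0) or not np.all(np.isfinite(lam_arr)):
        raise ValueError("lambda must be positive and finite")
    if nu == 0:
        if np.any(lam_arr >= 1):
            raise ComPoissonDivergenceError("nu=0 requires lambda < 1")
        return rng.geometric(1.0 - lam_arr) - 1
    if nu == 1:
        return rng.poisson(lam_arr)
    mode = np.maximum(lam_arr ** (1.0 / nu), 1.0)
    drop = 23.0 + 0.5 * np.log(mode / nu + 1.0) + 14.0
    logz, lo, logterms = _window_logsum(lam_arr, nu, drop)
    pmf = np.exp(logterms - logz[:, None])
    cmf = np.cumsum(pmf, axis=1)
    u = rng.random(lam_arr.size)
    idx = (cmf < u[:, None]).sum(axis=1)
    return lo + np.minimum(idx, pmf.shape[1] - 1)


# --------------------------------------------------------------------------
# family dispatch: log pmf, partial score, partial information, sampling
# --------------------------------------------------------------------------


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValueError(msg)


def log_pmf(spec: FamilySpec, params: CellParams, y) -> np.ndarray:
    """Log probability mass of counts ``y`` under the family's cell parameters.

    Out-of-support counts return -inf; inadmissible parameters raise.
    """
    y = np.asarray(y, dtype=float)
    fam = spec.family
    if fam is Family.COM_POISSON:
        _require(params.lam is not None, "COM-Poisson cells need lam")
        return compoisson_logpmf(y, params.lam, spec.nu)
    if fam is Family.POISSON:
        _require(params.lam is not None, "Poisson cells need lam")
        lam = np.asarray(params.lam, dtype=float)
        _require(bool(np.all(lam > 0)), "lambda must be positive")
        ok = (y >= 0) & (y == np.floor(y))
        yy = np.where(ok, y, 0.0)
        out = yy * np.log(lam) - lam - gammaln(yy + 1.0)
        return np.where(ok, out, -np.inf)
    if fam is Family.BINOMIAL:
        _require(params.l is not None and params.q is not None, "binomial cells need (l, q)")
        l = np.asarray(params.l, dtype=float)
        q = np.asarray(params.q, dtype=float)
        _require(bool(np.all((q > 0) & (q <= 1))), "q must lie in (0, 1]")
        _require(bool(np.all(l > 0)), "l must be positive")
        ok = (y >= 0) & (y <= l) & (y == np.floor(y))
        yy = np.where(ok, y, 0.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            out = (
                gammaln(l + 1.0)
                - gammaln(yy + 1.0)
                - gammaln(l - yy + 1.0)
                + yy * np.log(q)
                + np.where(l - yy > 0, (l - yy) * np.log1p(-q), 0.0)
            )
        return np.where(ok, out, -np.inf)
    if fam is Family.NEGATIVE_BINOMIAL:
        _require(params.r is not None and params.h is not None, "negative binomial cells need (r, h)")
        r = np.asarray(params.r, dtype=float)
        h = np.asarray(params.h, dtype=float)
        _require(bool(np.all(r > 0)), "r must be positive")
        _require(bool(np.all((h > 0) & (h < 1))), "h must lie in (0, 1)")
        ok = (y >= 0) & (y == np.floor(y))
        yy = np.where(ok, y, 0.0)
        out = (
            gammaln(yy + r)
            - gammaln(r)
            - gammaln(yy + 1.0)
            + yy * np.log1p(-h)
            + r * np.log(h)
        )
        return np.where(ok, out, -np.inf)
    raise ValueError(f"unknown family {fam}")


def partial_score(
    spec: FamilySpec,
    beta,
    d,
    params: CellParams,
    score_form: str = "offset",
) -> np.ndarray:
    """Per-age partial score: derivative of the cell log density in the trend.

    ``score_form`` selects the COM-Poisson variant: ``"offset"`` includes the
    dispersion offset (nu - 1) / (2 nu); ``"plain"`` drops it.  The two
    agree exactly at nu = 1.
    """
    beta = np.asarray(beta, dtype=float)
    d = np.asarray(d, dtype=float)
    fam = spec.family
    if fam is Family.COM_POISSON:
        if spec.nu == 0:
            raise ValueError("COM-Poisson score undefined at nu = 0")
        if score_form == "offset":
            offset = (spec.nu - 1.0) / (2.0 * spec.nu)
        elif score_form == "plain":
            offset = 0.0
        else:
            raise ValueError(f"unknown score_form {score_form!r}")
        return beta * (d - np.asarray(params.lam, dtype=float) + offset)
    if fam is Family.POISSON:
        return beta * (d - np.asarray(params.lam, dtype=float))
    if fam is Family.BINOMIAL:
        return beta * (d - np.asarray(params.l, dtype=float) * np.asarray(params.q, dtype=float))
    if fam is Family.NEGATIVE_BINOMIAL:
        h = np.asarray(params.h, dtype=float)
        r = np.asarray(params.r, dtype=float)
        return beta * (d * h - (1.0 - h) * r)
    raise ValueError(f"unknown family {fam}")


def partial_information(spec: FamilySpec, beta, params: CellParams) -> np.ndarray:
    """Per-age partial Fisher information of the trend; always non-negative."""
    beta = np.asarray(beta, dtype=float)
    fam = spec.family
    if fam in (Family.COM_POISSON, Family.POISSON):
        if fam is Family.COM_POISSON and spec.nu == 0:
            raise ValueError("COM-Poisson information undefined at nu = 0")
        return beta**2 * np.asarray(params.lam, dtype=float)
    if fam is Family.BINOMIAL:
        l = np.asarray(params.l, dtype=float)
        q = np.asarray(params.q, dtype=float)
        return beta**2 * l * q * (1.0 - q)
    if fam is Family.NEGATIVE_BINOMIAL:
        h = np.asarray(params.h, dtype=float)
        r = np.asarray(params.r, dtype=float)
        return beta**2 * (1.0 - h) * r
    raise ValueError(f"unknown family {fam}")


def sample(spec: FamilySpec, params: CellParams, n: int | None = None, rng=None) -> np.ndarray:
    """Draw counts from the family at the given cell parameters.

    With ``n`` given, the cell parameters must be scalar and ``n`` i.i.d.
    draws are returned; otherwise one draw per cell.
    """
    rng = np.random.default_rng(rng)
    fam = spec.family

    def _expand(a):
        a = np.asarray(a, dtype=float)
        if n is not None:
            if a.size != 1:
                raise ValueError("n draws require scalar cell parameters")
            return np.full(n, float(a.ravel()[0]))
        return a

    if fam is Family.COM_POISSON:
        return compoisson_rvs(_expand(params.lam), spec.nu, rng=rng)
    if fam is Family.POISSON:
        lam = _expand(params.lam)
        _require(bool(np.all(lam > 0)), "lambda must be positive")
        return rng.poisson(lam)
    if fam is Family.BINOMIAL:
        l = _expand(params.l)
        q = _expand(params.q)
        _require(bool(np.all((q > 0) & (q <= 1))), "q must lie in (0, 1]")
        return rng.binomial(np.round(l).astype(np.int64), q)
    if fam is Family.NEGATIVE_BINOMIAL:
        r = _expand(params.r)
        h = _expand(params.h)
        _require(bool(np.all((h > 0) & (h < 1))), "h must lie in (0, 1)")
        # numpy's nbinom counts failures before n successes with success prob p:
        # pmf C(y+n-1, y) p**n (1-p)**y, matching NB(r, h) with p = h.
        return rng.negative_binomial(r, h)
    raise ValueError(f"unknown family {fam}")
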