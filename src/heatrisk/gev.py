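"""Extreme-value analysis of decadal heatwave-magnitude maxima.

Decadal block maxima of the annual HWMId (or TX5x) series are fitted with a
Generalized Extreme Value distribution by the method of L-moments, with the
shape constrained to the Gumbel/Frechet branch (Coles-convention shape
``xi >= 0``): when the unconstrained L-moment solution lands in the Weibull
branch the sample is re-fitted as Gumbel. Return levels, exceedance
probabilities, profile-likelihood confidence intervals and a
parametric-bootstrap Anderson-Darling goodness-of-fit test are built on top.

Return periods are counted in blocks (decades): the "500-year" event is the
level with per-decade exceedance probability 1/500 = 0.2%.

Conventions: we write the GEV CDF as ``F(z) = exp(-(1 + xi*(z-mu)/sigma)**(-1/xi))``
for ``xi > 0`` (support ``z > mu - sigma/xi``) and the Gumbel limit
``F(z) = exp(-exp(-(z-mu)/sigma))`` at ``xi = 0``. SciPy's ``genextreme``
uses the opposite sign (``c = -xi``); the tests cross-check against it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, special, stats

EULER_GAMMA = 0.5772156649015329
_XI_TINY = 1e-9  # below this the fit is treated as Gumbel


class DegenerateFitError(ValueError):
    """All block maxima identical: the GEV fit is undefined."""


@dataclass(frozen=True)
class BlockMaximaSeries:
    """Ordered decadal maxima of an annual index series for one cell."""

    values: np.ndarray
    block_length: int = 10

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.values.ndim != 1:
            raise ValueError("block maxima must be a 1-D series")

    @property
    def n_blocks(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class GEVParams:
    """Location/scale/shape triple (Coles convention, shape >= 0)."""

    loc: float
    scale: float
    shape: float
    method: str = "lmoments"
    n_blocks: int = 0

    def __post_init__(self) -> None:
        if not self.scale > 0:
            raise ValueError(f"scale must be positive, got {self.scale}")
        if self.shape < 0:
            raise ValueError(f"shape must be >= 0, got {self.shape}")


def block_maxima(annual: np.ndarray, block_length: int = 10) -> np.ndarray:
    """Maxima of consecutive ``block_length``-year blocks.

    ``annual`` has years on the leading axis; the result has
    ``years // block_length`` blocks on the leading axis. Partial blocks are
    an error.
    """
    annual = np.asarray(annual, dtype=float)
    nyears = annual.shape[0]
    if block_length < 1 or nyears % block_length != 0:
        raise ValueError(
            f"{nyears} years do not divide into blocks of {block_length}"
        )
    nblocks = nyears // block_length
    return annual.reshape((nblocks, block_length) + annual.shape[1:]).max(axis=1)


# ---------------------------------------------------------------------------
# L-moments
# ---------------------------------------------------------------------------


def sample_lmoments(x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Unbiased sample L-moments (lambda1, lambda2, tau3).

    Computed from unbiased probability-weighted moments b0, b1, b2 of the
    sorted sample. Works on the trailing axis for batched input.
    """
    x = np.sort(np.asarray(x, dtype=float), axis=-1)
    n = x.shape[-1]
    if n < 3:
        raise ValueError("need at least 3 values for lambda1, lambda2, tau3")
    j = np.arange(1, n + 1, dtype=float)
    b0 = x.mean(axis=-1)
    b1 = (x * ((j - 1) / (n - 1))).mean(axis=-1)
    b2 = (x * ((j - 1) * (j - 2) / ((n - 1) * (n - 2)))).mean(axis=-1)
    l1 = b0
    l2 = 2 * b1 - b0
    l3 = 6 * b2 - 6 * b1 + b0
    with np.errstate(divide="ignore", invalid="ignore"):
        tau3 = np.where(l2 != 0, l3 / np.where(l2 != 0, l2, 1.0), np.nan)
    return l1, l2, tau3


def _gev_from_lmoments(
    l1: np.ndarray, l2: np.ndarray, tau3: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised GEV L-moment solution with the shape floored at 0.

    Uses Hosking's rational approximation for the shape. Hosking's ``k`` is
    the negative of the Coles shape; the non-negativity constraint therefore
    maps to ``k <= 0``, with ``k > 0`` solutions re-fitted as Gumbel.
    """
    c = 2.0 / (3.0 + tau3) - np.log(2.0) / np.log(3.0)
    k = 7.8590 * c + 2.9554 * c**2  # Hosking sign convention
    xi = -k
    gumbel = xi <= _XI_TINY
    k_safe = np.where(gumbel, -0.1, k)
    gam = special.gamma(1.0 + k_safe)
    sigma_f = l2 * k_safe / ((1.0 - 2.0 ** (-k_safe)) * gam)
    mu_f = l1 - sigma_f * (1.0 - gam) / k_safe
    sigma_g = l2 / np.log(2.0)
    mu_g = l1 - EULER_GAMMA * sigma_g
    sigma = np.where(gumbel, sigma_g, sigma_f)
    mu = np.where(gumbel, mu_g, mu_f)
    xi = np.where(gumbel, 0.0, xi)
    return mu, sigma, xi


def fit_gev_lmoments(
    values: np.ndarray | BlockMaximaSeries, min_blocks: int = 20
) -> GEVParams:
    """L-moment GEV fit of one block-maxima sample, shape constrained >= 0."""
    if isinstance(values, BlockMaximaSeries):
        values = values.values
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a 1-D block-maxima sample")
    if x.size < min_blocks:
        raise ValueError(f"need at least {min_blocks} blocks, got {x.size}")
    l1, l2, tau3 = sample_lmoments(x)
    if not l2 > 0:
        raise DegenerateFitError("zero second L-moment: all block maxima identical")
    mu, sigma, xi = _gev_from_lmoments(l1, l2, tau3)
    return GEVParams(
        loc=float(mu), scale=float(sigma), shape=float(xi), n_blocks=x.size
    )


def fit_gev_lmoments_batch(
    maxima: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Batched L-moment GEV fit; samples on the trailing axis.

    Degenerate samples (zero second L-moment) yield NaN parameters rather
    than raising, so grids with masked cells fit in one call.
    """
    x = np.asarray(maxima, dtype=float)
    l1, l2, tau3 = sample_lmoments(x)
    ok = l2 > 0
    mu, sigma, xi = _gev_from_lmoments(
        l1, np.where(ok, l2, 1.0), np.where(ok, tau3, 0.0)
    )
    nan = np.nan
    return (
        np.where(ok, mu, nan),
        np.where(ok, sigma, nan),
        np.where(ok, xi, nan),
    )


# ---------------------------------------------------------------------------
# Distribution functions (vectorised over parameters and levels)
# ---------------------------------------------------------------------------


def gev_cdf(z, mu, sigma, xi):
    z, mu, sigma, xi = np.broadcast_arrays(*map(np.asarray, (z, mu, sigma, xi)))
    s = (np.asarray(z, float) - mu) / sigma
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        t = 1.0 + xi * s
        frechet = np.exp(-np.power(np.clip(t, 1e-300, None), -1.0 / np.where(xi > 0, xi, 1.0)))
        frechet = np.where(t > 0, frechet, 0.0)
        gumbel = np.exp(-np.exp(-s))
    out = np.where(xi > _XI_TINY, frechet, gumbel)
    return np.where(np.isnan(mu) | np.isnan(sigma) | np.isnan(xi), np.nan, out)


def return_level(params, T: float):
    """Level with per-block exceedance probability 1/T.

    ``params`` is a :class:`GEVParams` or a (mu, sigma, xi) triple of arrays.
    """
    if T <= 1:
        raise ValueError(f"return period must exceed 1 block, got {T}")
    mu, sigma, xi = _unpack(params)
    yp = -np.log1p(-1.0 / T)  # -ln(1 - 1/T)
    with np.errstate(divide="ignore", invalid="ignore"):
        frechet = mu + sigma / np.where(xi > 0, xi, 1.0) * (
            np.power(yp, -xi) - 1.0
        )
        gumbel = mu - sigma * np.log(yp)
    return np.where(xi > _XI_TINY, frechet, gumbel)


def exceedance_probability(params, level):
    """Per-block probability of exceeding ``level`` under the fitted GEV."""
    mu, sigma, xi = _unpack(params)
    return 1.0 - gev_cdf(level, mu, sigma, xi)


def gev_rvs(params, size, rng: np.random.Generator):
    """Inverse-transform sampling from the fitted GEV."""
    mu, sigma, xi = _unpack(params)
    u = rng.uniform(size=size)
    y = -np.log(u)
    with np.errstate(divide="ignore", invalid="ignore"):
        frechet = mu + sigma / np.where(xi > 0, xi, 1.0) * (np.power(y, -xi) - 1.0)
        gumbel = mu - sigma * np.log(y)
    return np.where(xi > _XI_TINY, frechet, gumbel)


def _unpack(params):
    if isinstance(params, GEVParams):
        return params.loc, params.scale, params.shape
    mu, sigma, xi = params
    return np.asarray(mu, float), np.asarray(sigma, float), np.asarray(xi, float)


def hazard_under_state(present: tuple | GEVParams, future: tuple | GEVParams, T: float = 500):
    """Exceedance probability, under a warmed fit, of the present T-block level.

    Under ``future = present`` this returns exactly 1/T.
    """
    level = return_level(present, T)
    return exceedance_probability(future, level)


# ---------------------------------------------------------------------------
# Likelihood machinery: profile-likelihood CI for return levels
# ---------------------------------------------------------------------------


def gev_negloglik(theta: np.ndarray, x: np.ndarray) -> float:
    """Negative log-likelihood at theta = (mu, log sigma, xi), xi >= 0."""
    mu, log_sigma, xi = theta
    sigma = np.exp(log_sigma)
    s = (x - mu) / sigma
    if xi < 0:
        return 1e12
    if xi <= _XI_TINY:
        return x.size * log_sigma + np.sum(s + np.exp(-s))
    t = 1.0 + xi * s
    if np.any(t <= 0):
        return 1e12
    return x.size * log_sigma + np.sum(
        (1.0 + 1.0 / xi) * np.log(t) + np.power(t, -1.0 / xi)
    )


def fit_gev_mle(x: np.ndarray, start: GEVParams | None = None) -> GEVParams:
    """Constrained (shape >= 0) maximum-likelihood GEV fit."""
    x = np.asarray(x, dtype=float)
    if start is None:
        start = fit_gev_lmoments(x, min_blocks=3)
    theta0 = np.array([start.loc, np.log(start.scale), max(start.shape, 0.0)])
    res = optimize.minimize(
        gev_negloglik,
        theta0,
        args=(x,),
        method="Nelder-Mead",
        options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 2000},
    )
    mu, log_sigma, xi = res.x
    return GEVParams(
        loc=float(mu),
        scale=float(np.exp(log_sigma)),
        shape=float(max(xi, 0.0)),
        method="mle",
        n_blocks=x.size,
    )


def _negloglik_given_z(psi: np.ndarray, z: float, yp: float, x: np.ndarray) -> float:
    """NLL in (log sigma, xi) with the location eliminated via the level z."""
    log_sigma, xi = psi
    sigma = np.exp(log_sigma)
    if xi < 0:
        return 1e12
    if xi <= _XI_TINY:
        mu = z + sigma * np.log(yp)
    else:
        mu = z - sigma / xi * (np.power(yp, -xi) - 1.0)
    return gev_negloglik(np.array([mu, log_sigma, xi]), x)


def confidence_interval(
    values: np.ndarray | BlockMaximaSeries,
    T: float = 500,
    alpha: float = 0.05,
    min_blocks: int = 20,
) -> tuple[float, float]:
    """Profile-likelihood interval for the T-block return level (xi >= 0).

    The likelihood is re-parametrised in (z_T, sigma, xi); the profile
    deviance 2*(lhat - l(z)) is compared against the chi-squared(1) quantile.
    Returns (nan, nan) when the profile cannot be bracketed.
    """
    if isinstance(values, BlockMaximaSeries):
        values = values.values
    x = np.asarray(values, dtype=float)
    if x.size < min_blocks:
        raise ValueError(f"need at least {min_blocks} blocks, got {x.size}")
    mle = fit_gev_mle(x)
    z_hat = float(return_level(mle, T))
    if alpha >= 1.0:
        return z_hat, z_hat
    yp = float(-np.log1p(-1.0 / T))
    nll_hat = gev_negloglik(
        np.array([mle.loc, np.log(mle.scale), mle.shape]), x
    )
    crit = stats.chi2.ppf(1.0 - alpha, df=1) / 2.0

    psi_hat = np.array([np.log(mle.scale), mle.shape])
    warm: dict[str, np.ndarray] = {"psi": psi_hat.copy()}

    def pdev(z: float) -> float:
        starts = [warm["psi"], psi_hat, np.array([psi_hat[0], 0.0])]
        best = None
        for s in starts:
            res = optimize.minimize(
                _negloglik_given_z,
                s,
                args=(z, yp, x),
                method="Nelder-Mead",
                options={"xatol": 1e-7, "fatol": 1e-9, "maxiter": 1000},
            )
            if best is None or res.fun < best.fun:
                best = res
        if best.fun < 1e11:
            warm["psi"] = best.x
        return best.fun - nll_hat - crit

    bounds = []
    for direction in (-1.0, 1.0):
        step = 0.25 * mle.scale
        z_prev, f_prev = z_hat, -crit
        bound = np.nan
        warm["psi"] = psi_hat.copy()
        for _ in range(200):
            z_next = z_prev + direction * step
            f_next = pdev(z_next)
            if f_next >= 0:
                bound = optimize.brentq(pdev, min(z_prev, z_next), max(z_prev, z_next), xtol=1e-6 * max(1.0, abs(z_hat)))
                break
            z_prev, f_prev = z_next, f_next
            step *= 1.5
        bounds.append(bound)
    lower, upper = bounds
    return float(lower), float(upper)


# ---------------------------------------------------------------------------
# Anderson-Darling goodness of fit with parametric bootstrap
# ---------------------------------------------------------------------------


def anderson_darling_statistic(x: np.ndarray, mu, sigma, xi) -> np.ndarray:
    """A^2 of sample(s) against the given GEV; samples on the trailing axis."""
    x = np.sort(np.asarray(x, dtype=float), axis=-1)
    n = x.shape[-1]
    u = gev_cdf(x, np.asarray(mu)[..., None] if np.ndim(mu) else mu,
                np.asarray(sigma)[..., None] if np.ndim(sigma) else sigma,
                np.asarray(xi)[..., None] if np.ndim(xi) else xi)
    eps = 1e-12
    u = np.clip(u, eps, 1 - eps)
    i = np.arange(1, n + 1, dtype=float)
    s = ((2 * i - 1) * (np.log(u) + np.log(1 - u[..., ::-1]))).sum(axis=-1)
    return -n - s / n


def ad_test_gev(
    values: np.ndarray | BlockMaximaSeries,
    n_boot: int = 200,
    rng: np.random.Generator | None = None,
    min_blocks: int = 20,
) -> tuple[float, float]:
    """Parametric-bootstrap Anderson-Darling GEV test.

    Parameters are estimated by L-moments from the sample; each bootstrap
    replicate re-fits its own simulated sample, so the null distribution of
    A^2 accounts for parameter estimation. Returns ``(statistic, p_value)``;
    degenerate samples give ``(nan, nan)``.
    """
    if isinstance(values, BlockMaximaSeries):
        values = values.values
    x = np.asarray(values, dtype=float)
    rng = rng or np.random.default_rng()
    try:
        fit = fit_gev_lmoments(x, min_blocks=min_blocks)
    except DegenerateFitError:
        return float("nan"), float("nan")
    a2 = float(anderson_darling_statistic(x, fit.loc, fit.scale, fit.shape))
    sims = gev_rvs(fit, size=(n_boot, x.size), rng=rng)
    mu_b, sigma_b, xi_b = fit_gev_lmoments_batch(sims)
    a2_boot = anderson_darling_statistic(sims, mu_b, sigma_b, xi_b)
    a2_boot = a2_boot[np.isfinite(a2_boot)]
    p = (1.0 + np.sum(a2_boot >= a2)) / (a2_boot.size + 1.0)
    return a2, float(p)
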