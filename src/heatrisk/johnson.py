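"""Johnson-system normalization of exposure and vulnerability fields.

Population density and the vulnerability proxy (1 - HDI) enter the risk index
on very different scales, so both are mapped to (0, 1) through the CDF of a
Johnson-family distribution fitted to the *present-period* field:

* population density uses the log-normal branch (S_L) with its lower bound
  pinned at zero — support [0, +inf), matching a density that is exactly zero
  in uninhabited cells;
* 1 - HDI uses the bounded branch (S_B) with support pinned to (0, 1), the
  full definitional range of the index, so projected values can never fall
  outside the fitted support.

Ties are removed from the fitting sample only; the fitted CDF is then applied
to the complete present and projected fields, so equal raw values always get
equal scores. Goodness of fit is assessed with a Kolmogorov-Smirnov test; a
rejection flags the fit but does not fail it.

With the bounds pinned, both branches reduce to a Gaussian model on the
log / logit scale, where the maximum-likelihood estimates of (gamma, delta)
are closed-form.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

SUPPORT_NONNEGATIVE = "nonnegative"  # S_L, lower bound 0
SUPPORT_UNIT_INTERVAL = "unit_interval"  # S_B on (0, 1)


class DegenerateSampleError(ValueError):
    """Fit sample has too little variation to identify a Johnson curve."""


def dedup_for_fit(values: np.ndarray) -> np.ndarray:
    """Sorted unique finite values — the tie-free fitting sample."""
    values = np.asarray(values, dtype=float).ravel()
    values = values[np.isfinite(values)]
    if values.size == 0:
        raise ValueError("no finite values to fit")
    return np.unique(values)


@dataclass(frozen=True)
class JohnsonFit:
    """A fitted Johnson CDF used as the normalizing transform.

    The transform is ``z = gamma + delta * g((x - xi) / lam)`` with
    ``g = log`` for the S_L family and ``g = logit`` for S_B; scores are
    ``Phi(z)``.
    """

    family: str  # "SL" | "SB"
    gamma: float
    delta: float
    xi: float
    lam: float
    n_fit: int
    ks_stat: float
    ks_pvalue: float

    def __post_init__(self) -> None:
        if self.delta <= 0:
            raise ValueError("delta must be positive")
        if self.family not in ("SL", "SB"):
            raise ValueError(f"unknown Johnson family {self.family!r}")

    def cdf(self, x: np.ndarray) -> np.ndarray:
        """Fitted CDF; values at/below the lower bound map to 0, above the
        upper bound (S_B only) to 1; NaN passes through."""
        x = np.asarray(x, dtype=float)
        u = (x - self.xi) / self.lam
        with np.errstate(divide="ignore", invalid="ignore"):
            if self.family == "SL":
                z = self.gamma + self.delta * np.log(u)
                out = stats.norm.cdf(z)
                out = np.where(u <= 0, 0.0, out)
            else:
                z = self.gamma + self.delta * (np.log(u) - np.log1p(-u))
                out = stats.norm.cdf(z)
                out = np.where(u <= 0, 0.0, out)
                out = np.where(u >= 1, 1.0, out)
        return np.where(np.isnan(x), np.nan, out)


def fit_johnson(
    values: np.ndarray,
    support: str = SUPPORT_NONNEGATIVE,
    min_unique: int = 30,
) -> JohnsonFit:
    """Fit a bound-pinned Johnson curve to the present-period sample.

    ``values`` is the raw present field; ties and non-finite entries are
    dropped for fitting (zeros as well for the S_L branch, whose CDF is 0
    there by construction). Maximum likelihood on the transformed scale;
    KS test of the deduplicated sample against the fitted CDF.
    """
    unique = dedup_for_fit(values)
    if support == SUPPORT_NONNEGATIVE:
        family = "SL"
        sample = unique[unique > 0]
        if np.any(unique < 0):
            raise ValueError("negative values in a nonnegative-support sample")
        transformed = np.log(sample)
        xi, lam = 0.0, 1.0
    elif support == SUPPORT_UNIT_INTERVAL:
        family = "SB"
        sample = unique
        if np.any((sample <= 0) | (sample >= 1)):
            raise ValueError("unit-interval support requires values inside (0, 1)")
        transformed = np.log(sample) - np.log1p(-sample)
        xi, lam = 0.0, 1.0
    else:
        raise ValueError(f"unknown support constraint {support!r}")
    if sample.size < min_unique:
        raise DegenerateSampleError(
            f"need at least {min_unique} unique values, got {sample.size}"
        )
    m = float(transformed.mean())
    s = float(transformed.std(ddof=0))
    if s <= 0:
        raise DegenerateSampleError("zero spread on the transformed scale")
    delta = 1.0 / s
    gamma = -m / s

    fit = JohnsonFit(
        family=family, gamma=gamma, delta=delta, xi=xi, lam=lam,
        n_fit=int(sample.size), ks_stat=float("nan"), ks_pvalue=float("nan"),
    )
    ks = stats.kstest(sample, fit.cdf)
    return JohnsonFit(
        family=family, gamma=gamma, delta=delta, xi=xi, lam=lam,
        n_fit=int(sample.size), ks_stat=float(ks.statistic), ks_pvalue=float(ks.pvalue),
    )


def normalize_field(raw: np.ndarray, fit: JohnsonFit) -> np.ndarray:
    """Transform a raw field to (0, 1) scores through the fitted present CDF.

    Monotone non-decreasing in the raw value; zero raw value maps to score 0;
    projected values beyond the fitted support saturate at the CDF limits.
    Missing cells (NaN) stay missing.
    """
    return fit.cdf(np.asarray(raw, dtype=float))
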