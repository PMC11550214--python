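"""Goodness-of-fit and information-theoretic model comparison.

Implements the statistics used to arbitrate between the OC and OC-SF models:

* coefficient of determination ``R^2 = 1 - RSS/TSS``,
* adjusted ``R^2 = 1 - (n-1)/(n-p) * (1 - R^2)`` — note the ``n - p``
  denominator, chosen deliberately over the more common ``n - p - 1``,
* profile Gaussian maximum log-likelihood
  ``ln L = 0.5 * (-n * (ln 2*pi + 1 - ln n + ln sum(x_i^2)))``,
* ``AIC = 2p - 2 ln L`` and its small-sample correction
  ``AICc = AIC + 2p(p+1)/(n-p-1)`` (recommended whenever ``n/p < 40``),
* Akaike weights ``w_i = exp(-delta_i/2) / sum_k exp(-delta_k/2)`` with
  ``delta_i`` the AICc difference to the best model.

``p`` counts only the fitted kinetic parameters (2 for OC, 3 for OC-SF); the
Gaussian error variance is profiled out of the likelihood and not counted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .fitting import FitResult
from .models import ConcentrationSeries

__all__ = [
    "PerfectFitError",
    "FitStatistics",
    "ModelComparison",
    "r_squared",
    "adjusted_r_squared",
    "gaussian_loglik",
    "aic",
    "aicc",
    "akaike_weights",
    "compare_models",
]


class PerfectFitError(ValueError):
    """Raised when a zero residual sum of squares makes the Gaussian
    log-likelihood unbounded; callers must handle the degeneracy."""


def r_squared(observed: Sequence[float], fitted: Sequence[float]) -> float:
    """Coefficient of determination ``1 - RSS/TSS``.

    May be negative for fits worse than the observed mean.  Raises on
    degenerate data whose total sum of squares is zero.
    """
    obs = np.asarray(observed, dtype=float)
    fit = np.asarray(fitted, dtype=float)
    if obs.shape != fit.shape:
        raise ValueError("observed and fitted must be aligned")
    if obs.size < 2:
        raise ValueError("need at least two observations")
    tss = float(np.sum((obs - obs.mean()) ** 2))
    if tss == 0.0:
        raise ValueError("all observations identical: TSS is zero, R^2 undefined")
    rss = float(np.sum((obs - fit) ** 2))
    return 1.0 - rss / tss


def adjusted_r_squared(r2: float, n: int, p: int) -> float:
    """``1 - (n-1)/(n-p) * (1 - r2)`` — parameter-count-corrected R^2."""
    if n <= p:
        raise ValueError(f"adjusted R^2 requires n > p, got n={n}, p={p}")
    return 1.0 - (n - 1) / (n - p) * (1.0 - r2)


def gaussian_loglik(residuals: Sequence[float], n: int | None = None) -> float:
    """Profile maximum log-likelihood of i.i.d. Gaussian residuals.

    The error variance is replaced by its maximum-likelihood estimate
    ``sum(x_i^2)/n``, giving
    ``ln L = 0.5 * (-n * (ln 2*pi + 1 - ln n + ln sum(x_i^2)))``.
    """
    x = np.asarray(residuals, dtype=float)
    if n is None:
        n = x.size
    if n < 1:
        raise ValueError("need at least one residual")
    ss = float(np.sum(x**2))
    if ss <= 0.0:
        raise PerfectFitError("zero RSS: Gaussian log-likelihood is unbounded")
    return 0.5 * (-n * (math.log(2 * math.pi) + 1.0 - math.log(n) + math.log(ss)))


def aic(p: int, loglik: float) -> float:
    """Akaike Information Criterion ``2p - 2 ln L``; lower is better."""
    if p < 1:
        raise ValueError("p must be >= 1")
    return 2.0 * p - 2.0 * loglik


def aicc(aic_value: float, n: int, p: int) -> float:
    """Small-sample bias-corrected AIC: ``AIC + 2p(p+1)/(n-p-1)``."""
    if n <= p + 1:
        raise ValueError(f"AICc requires n > p + 1, got n={n}, p={p}")
    return aic_value + 2.0 * p * (p + 1) / (n - p - 1)


def akaike_weights(aicc_values: Sequence[float]) -> np.ndarray:
    """Evidence weights ``exp(-delta_i/2) / sum exp(-delta_k/2)``.

    The minimum AICc is subtracted before exponentiation for numerical
    stability; this is algebraically the identity transformation.
    """
    vals = np.asarray(aicc_values, dtype=float)
    if vals.size == 0:
        raise ValueError("need at least one AICc value")
    if not np.all(np.isfinite(vals)):
        raise ValueError("AICc values must be finite")
    deltas = vals - vals.min()
    raw = np.exp(-deltas / 2.0)
    return raw / raw.sum()


@dataclass(frozen=True)
class FitStatistics:
    """Per-model goodness-of-fit summary."""

    n: int
    p: int
    rss: float
    tss: float
    r2: float
    adj_r2: float
    loglik: float
    aic: float
    aicc: float

    @classmethod
    def from_residuals(
        cls, observed: np.ndarray, fitted: np.ndarray, p: int
    ) -> "FitStatistics":
        obs = np.asarray(observed, dtype=float)
        fit = np.asarray(fitted, dtype=float)
        n = obs.size
        residuals = obs - fit
        rss = float(np.sum(residuals**2))
        tss = float(np.sum((obs - obs.mean()) ** 2))
        r2 = r_squared(obs, fit)
        ll = gaussian_loglik(residuals, n)
        a = aic(p, ll)
        return cls(
            n=n, p=p, rss=rss, tss=tss, r2=r2,
            adj_r2=adjusted_r_squared(r2, n, p),
            loglik=ll, aic=a, aicc=aicc(a, n, p),
        )

    def to_dict(self) -> dict:
        return {
            "n": self.n, "p": self.p, "rss": self.rss, "tss": self.tss,
            "r2": self.r2, "adj_r2": self.adj_r2, "loglik": self.loglik,
            "aic": self.aic, "aicc": self.aicc,
        }


@dataclass
class ModelComparison:
    """Akaike-weight comparison across candidate model fits.

    When a candidate fits the data perfectly (zero RSS) the Gaussian
    likelihood is unbounded and AICc is undefined; the comparison then
    reports the perfect fit(s) as decisively best (``degenerate=True``,
    weight split among them) instead of emitting non-finite statistics.
    """

    labels: list[str]
    aicc_values: list[float] | None
    deltas: list[float] | None
    weights: list[float]
    best_index: int
    statistics: list[FitStatistics | None]
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {
            "labels": self.labels,
            "aicc_values": self.aicc_values,
            "deltas": self.deltas,
            "weights": self.weights,
            "best_index": self.best_index,
            "degenerate": self.degenerate,
            "statistics": [s.to_dict() if s else None for s in self.statistics],
        }


def compare_models(
    data: ConcentrationSeries, fits: Sequence[FitResult]
) -> ModelComparison:
    """Rank fits of the same data by AICc and compute Akaike weights.

    ``p`` is taken from each fit's model kind (2 for OC, 3 for OC-SF).
    """
    if len(fits) == 0:
        raise ValueError("need at least one fit to compare")
    obs = np.asarray(data.values, dtype=float)
    labels = [f.model.value for f in fits]
    perfect = [float(np.sum((obs - f.fitted_values) ** 2)) == 0.0 for f in fits]

    if any(perfect):
        k = sum(perfect)
        weights = [1.0 / k if flag else 0.0 for flag in perfect]
        stats: list[FitStatistics | None] = [
            None if flag else FitStatistics.from_residuals(obs, f.fitted_values, f.model.n_params)
            for flag, f in zip(perfect, fits)
        ]
        # among perfect fits, prefer the more parsimonious model
        best = min(
            (i for i, flag in enumerate(perfect) if flag),
            key=lambda i: fits[i].model.n_params,
        )
        return ModelComparison(
            labels=labels, aicc_values=None, deltas=None,
            weights=weights, best_index=best, statistics=stats, degenerate=True,
        )

    stats = [
        FitStatistics.from_residuals(obs, f.fitted_values, f.model.n_params)
        for f in fits
    ]
    aicc_vals = np.array([s.aicc for s in stats])
    weights = akaike_weights(aicc_vals)
    deltas = aicc_vals - aicc_vals.min()
    best = int(np.argmin(aicc_vals))
    return ModelComparison(
        labels=labels,
        aicc_values=aicc_vals.tolist(),
        deltas=deltas.tolist(),
        weights=weights.tolist(),
        best_index=best,
        statistics=list(stats),
    )
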