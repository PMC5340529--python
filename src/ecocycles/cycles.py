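"""Cycle documentation: burn-in removal, detrending, ACF, and a classifier.

Multigenerational cycles show up as stationary periodic dynamics whose
sample autocorrelation function decays to zero while oscillating: a
significantly negative trough at some lag followed by a significantly
positive peak at a larger lag.  The classifier below formalizes that
visual criterion with the usual +/- 1.96/sqrt(n) white-noise band.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from statsmodels.tsa.stattools import acf as _sm_acf

__all__ = ["ACFResult", "detrend_series", "autocorrelation", "classify_cycling"]

#: Generations discarded before any cycle analysis, to drop transients
#: caused by the initial population size.
DEFAULT_BURN_IN = 3

#: Cap on the number of lags examined by the classifier.
MAX_LAG_CAP = 20


@dataclass
class ACFResult:
    """Sample autocorrelation with its white-noise band and classification."""

    lags: np.ndarray
    rho: np.ndarray
    conf: float
    n: int
    cycling: bool | None = None
    period_estimate: int | None = None


def detrend_series(
    values,
    burn_in: int = DEFAULT_BURN_IN,
    steps_per_generation: int = 1,
):
    """Drop the burn-in and remove a fitted linear trend.

    ``burn_in`` is in generations; for interleaved two-season series pass
    ``steps_per_generation=2``.  Returns the residuals of an ordinary
    least-squares regression of the remaining values on their time index,
    so the output has mean zero and zero linear trend.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1:
        raise ValueError("series must be one-dimensional")
    if np.any(~np.isfinite(values)):
        raise ValueError("series contains missing values")
    drop = burn_in * steps_per_generation
    if len(values) <= drop + 2:
        raise ValueError(
            f"series of length {len(values)} too short for burn-in of {drop} steps"
        )
    kept = values[drop:]
    t = np.arange(len(kept), dtype=float)
    slope, intercept = np.polyfit(t, kept, 1)
    return kept - (intercept + slope * t)


def autocorrelation(values, max_lag: int | None = None) -> ACFResult:
    """Biased-normalized sample ACF with a two-sided 1.96/sqrt(n) band.

    The series should already be detrended.  ``max_lag`` defaults to
    ``min(n // 2, 20)``.
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n < 8:
        raise ValueError("need at least 8 steps for ACF estimation")
    if np.allclose(values, values[0]):
        raise ValueError("zero-variance series has no autocorrelation")
    if max_lag is None:
        max_lag = min(n // 2, MAX_LAG_CAP)
    if not 0 < max_lag < n:
        raise ValueError("max_lag must be in (0, n)")
    rho = _sm_acf(values, nlags=max_lag, adjusted=False, fft=False)
    conf = 1.96 / np.sqrt(n)
    return ACFResult(
        lags=np.arange(max_lag + 1), rho=rho, conf=float(conf), n=n
    )


def classify_cycling(acf: ACFResult) -> ACFResult:
    """Flag oscillatory decay: a significant trough then a significant peak.

    ``cycling`` is True iff some lag has rho below ``-conf`` and a larger
    lag has rho above ``+conf``; ``period_estimate`` is the lag of the first
    significant positive peak after the first significant trough (ties
    resolved toward the smaller lag by the first-hit rule).  The result is
    returned with the classification fields filled in.
    """
    lags, rho = acf.lags[1:], acf.rho[1:]  # lag 0 is trivially 1
    below = lags[rho < -acf.conf]
    cycling = False
    period = None
    if below.size:
        trough = int(below[0])
        after = lags > trough
        above = lags[after & (rho > acf.conf)]
        if above.size:
            cycling = True
            period = int(above[0])
    acf.cycling = cycling
    acf.period_estimate = period
    return acf
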