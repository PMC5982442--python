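"""Rectangular-hyperbola light response and the light-saturation filter.

The saturating response of gross primary productivity (GPP) to photon flux
density (PFD) is modelled with the Michaelis-Menten-equivalent rectangular
hyperbola parameterized by the initial slope ``alpha`` and the asymptote
``p_max``::

    GPP(PFD) = alpha * PFD * p_max / (alpha * PFD + p_max)

Fluxes measured above a saturating PFD threshold (default 1000
umol m^-2 s^-1) are labelled GPP_sat and carried forward to the resilience
analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "LightResponseError",
    "LightResponseFit",
    "rectangular_hyperbola",
    "fit_light_response",
    "saturation_filter",
    "saturation_fraction",
]

DEFAULT_PFD_THRESHOLD = 1000.0


class LightResponseError(RuntimeError):
    def __init__(self, reason: str, message: str | None = None):
        self.reason = reason
        super().__init__(message or reason)


@dataclass(frozen=True)
class LightResponseFit:
    alpha: float  # umol CO2 (umol photons)^-1
    p_max: float  # umol m^-2 s^-1
    r_squared: float
    group: str
    n_obs: int

    def predict(self, pfd):
        return rectangular_hyperbola(np.asarray(pfd, dtype=float), self.alpha, self.p_max)


def rectangular_hyperbola(pfd, alpha, p_max):
    pfd = np.asarray(pfd, dtype=float)
    return alpha * pfd * p_max / (alpha * pfd + p_max)


def fit_light_response(gpp, pfd, group: str = "") -> LightResponseFit:
    """Nonlinear least squares of the rectangular hyperbola.

    Initialization: alpha from a straight line through the three lowest-PFD
    points, p_max at 1.2x the largest observed GPP; both bounded positive.
    Non-convergence raises, it is never silently defaulted.
    """
    gpp = np.asarray(gpp, dtype=float)
    pfd = np.asarray(pfd, dtype=float)
    if gpp.size != pfd.size:
        raise ValueError("gpp and pfd must have equal length")
    if gpp.size < 4:
        raise LightResponseError("too_few_points", f"need >= 4 observations, got {gpp.size}")
    if np.ptp(pfd) == 0:
        raise LightResponseError("ill_conditioned", "pfd has no spread")
    if not np.any(gpp > 0):
        raise LightResponseError("no_signal", "all GPP observations are <= 0")

    order = np.argsort(pfd)
    lo = order[:3]
    with np.errstate(all="ignore"):
        alpha0 = float(np.polyfit(pfd[lo], gpp[lo], 1)[0]) if np.ptp(pfd[lo]) > 0 else 0.01
    if not np.isfinite(alpha0) or alpha0 <= 0:
        alpha0 = 0.01
    pmax0 = 1.2 * float(np.max(gpp))

    try:
        popt, _ = curve_fit(
            rectangular_hyperbola,
            pfd,
            gpp,
            p0=(alpha0, pmax0),
            bounds=((1e-9, 1e-9), (np.inf, np.inf)),
            maxfev=10000,
        )
    except RuntimeError as exc:  # pragma: no cover - scipy message passthrough
        raise LightResponseError("no_convergence", str(exc)) from exc
    alpha, p_max = (float(v) for v in popt)
    if not (np.isfinite(alpha) and np.isfinite(p_max) and alpha > 0 and p_max > 0):
        raise LightResponseError("no_convergence", "fit returned non-finite parameters")

    resid = gpp - rectangular_hyperbola(pfd, alpha, p_max)
    ss_tot = float(np.sum((gpp - gpp.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    return LightResponseFit(alpha=alpha, p_max=p_max, r_squared=r2, group=group, n_obs=gpp.size)


def saturation_filter(records, pfd_threshold: float = DEFAULT_PFD_THRESHOLD):
    """Retain sunlit-derived flux records measured at PFD >= threshold.

    The retained ``gpp`` values are light-saturated (GPP_sat). ``records``
    is a DataFrame with a ``par`` column; rows without PAR are dropped.
    """
    out = records[records["par"].notna() & (records["par"] >= pfd_threshold)]
    return out.copy()


def saturation_fraction(fit: LightResponseFit, pfd_threshold: float = DEFAULT_PFD_THRESHOLD) -> float:
    """Fraction of the asymptotic maximum reached at the threshold PFD.

    Reported so the levelling-off of a light-response curve at the chosen
    threshold can be assessed on any dataset.
    """
    return float(rectangular_hyperbola(pfd_threshold, fit.alpha, fit.p_max) / fit.p_max)
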