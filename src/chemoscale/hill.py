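"""Hill-function summaries of dose-response curves.

Fits the four-parameter Hill function

    A(L) = A_inf + (A_0 - A_inf) / (1 + (L/K)^nH)

to a tabulated dose-response, in log-concentration space with free plateaus
(curves need not span [0, 1]).  ``A_0`` is the plateau at L -> 0 and
``A_inf`` at L -> inf; decreasing and increasing curves are both handled.
The Hill coefficient nH is the standard descriptive measure of
cooperativity: ~1 for a single effective binding site, 2-3 for a single
trimer of dimers, and well above 3 for strongly coupled clusters of trimers.

Initialisation is deterministic (no random restarts): K starts at the grid
point nearest half-range, nH at the local log-log slope there, and the fit
is repeated from nH/2 and 2*nH, keeping the best of the three.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
from scipy.optimize import least_squares

from .mwc_cluster import DoseResponse

__all__ = ["HillFit", "fit_hill", "cooperativity_class"]

# class boundaries partitioning the "~1" / "~2-3" / ">>3" cooperativity
# regimes; exposed so callers can override
LOW_MODERATE_BOUNDARY = 1.5
MODERATE_HIGH_BOUNDARY = 3.0


@dataclass(frozen=True)
class HillFit:
    """Result of a Hill fit: coefficient, midpoint, plateaus, RMS residual."""

    n_H: float
    K_half: float
    A_high: float
    A_low: float
    residual: float

    def __post_init__(self) -> None:
        if not (self.n_H > 0 and self.K_half > 0):
            raise ValueError("n_H and K_half must be positive")
        if self.A_high < self.A_low:
            raise ValueError("A_high must be >= A_low")
        if self.residual < 0:
            raise ValueError("residual must be >= 0")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


def _hill(logL: np.ndarray, a0: float, a_inf: float, logK: float, n: float) -> np.ndarray:
    # evaluated in log-L space: (L/K)^n = exp(n*(logL - logK)); clip the
    # exponent so the optimizer can roam without overflow
    z = np.clip(n * (logL - logK), -500, 500)
    return a_inf + (a0 - a_inf) / (1.0 + np.exp(z))


def fit_hill(curve: DoseResponse) -> HillFit:
    """Least-squares Hill fit of a dose-response curve.

    Requires >= 20 points and a curve that actually spans its transition
    (flat curves raise).  Deterministic: the same curve always yields the
    same fit.
    """
    L = np.asarray(curve.L, float)
    y = np.asarray(curve.p_on, float)
    if L.size < 20:
        raise ValueError("need at least 20 points to fit")
    if np.any(L <= 0):
        raise ValueError("ligand levels must be positive for a log-space fit")
    rng_y = y.max() - y.min()
    if rng_y < 1e-6:
        raise ValueError("no transition: curve range below 1e-6")

    logL = np.log(L)
    a0_init, a_inf_init = y[0], y[-1]
    # K: grid point nearest half-range
    half = 0.5 * (a0_init + a_inf_init)
    i_half = int(np.argmin(np.abs(y - half)))
    i_half = min(max(i_half, 1), L.size - 2)
    logK_init = logL[i_half]
    # n: local log-log slope of the logistic argument at half-range.
    # d y/d logL at midpoint = -(a0 - a_inf) * n / 4  for the Hill form.
    slope = (y[i_half + 1] - y[i_half - 1]) / (logL[i_half + 1] - logL[i_half - 1])
    n_init = abs(4.0 * slope / (a0_init - a_inf_init)) if a0_init != a_inf_init else 1.0
    n_init = float(np.clip(n_init, 0.1, 50.0))

    def resid(p: np.ndarray) -> np.ndarray:
        return _hill(logL, p[0], p[1], p[2], p[3]) - y

    best = None
    for n_start in (n_init, 0.5 * n_init, 2.0 * n_init):
        sol = least_squares(
            resid,
            x0=[a0_init, a_inf_init, logK_init, n_start],
            bounds=([-np.inf, -np.inf, logL[0] - 30, 1e-3], [np.inf, np.inf, logL[-1] + 30, 1e3]),
            xtol=1e-14,
            ftol=1e-14,
            gtol=1e-14,
        )
        if best is None or sol.cost < best.cost:
            best = sol
    a0, a_inf, logK, n = best.x
    rms = float(np.sqrt(np.mean(resid(best.x) ** 2)))
    return HillFit(
        n_H=float(n),
        K_half=float(np.exp(logK)),
        A_high=float(max(a0, a_inf)),
        A_low=float(min(a0, a_inf)),
        residual=rms,
    )


def cooperativity_class(
    fit: HillFit,
    low_moderate: float = LOW_MODERATE_BOUNDARY,
    moderate_high: float = MODERATE_HIGH_BOUNDARY,
) -> str:
    """Classify a fitted Hill coefficient as 'low', 'moderate' or 'high'.

    low: nH < 1.5 (single effective site); moderate: 1.5 <= nH <= 3 (single
    trimer of dimers); high: nH > 3 (coupled cluster of trimers).
    """
    if fit.n_H < low_moderate:
        return "low"
    if fit.n_H <= moderate_high:
        return "moderate"
    return "high"
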