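"""Threshold Monod model for population growth along a calcium gradient.

The growth rate of a Ca-limited population is described by a Monod
(saturating) curve shifted so that growth is zero at a threshold
concentration Ca_ZPG:

    r(Ca) = r_max * (Ca - Ca_ZPG) / (Ca - Ca_ZPG + K_s)

with r_max the asymptotic maximal growth rate (day^-1), Ca_ZPG the
zero-population-growth threshold (mg Ca L^-1) and K_s the half-saturation
constant (mg Ca L^-1).  The three parameters are estimated by
Levenberg-Marquardt nonlinear least squares on (Ca, r) points, typically the
per-treatment mean r values along a 4-level gradient at one food x
temperature combination.  Asymptotic standard errors come from the Jacobian
at the optimum and 95% confidence intervals from the t distribution with
n - 3 degrees of freedom (the interval may legitimately cross zero when the
gradient barely constrains the threshold).

A fit is refused - not force-converged - when no point has positive growth:
with every mean r negative the zero crossing is unidentified, the situation
reported for low-food treatments in chronic Ca-limitation assays.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from scipy.optimize import least_squares

__all__ = ["MonodFitResult", "monod_threshold_model", "fit_monod_threshold"]


@dataclass(frozen=True)
class MonodFitResult:
    """Parameters and uncertainty of a threshold-Monod fit."""

    r_max: float
    ca_zpg: float
    k_s: float
    se_r_max: float
    se_ca_zpg: float
    se_k_s: float
    ci_ca_zpg: tuple[float, float]
    p_ca_zpg: float          # Wald t p-value for Ca_ZPG != 0
    rss: float
    n_points: int
    converged: bool
    refused: Optional[str] = None   # reason string when the fit was declined


def monod_threshold_model(ca, r_max: float, ca_zpg: float, k_s: float):
    """Evaluate r(Ca); vectorised over ``ca``."""
    ca = np.asarray(ca, dtype=float)
    denom = ca - ca_zpg + k_s
    if np.any(denom == 0):
        raise ZeroDivisionError(
            "singular denominator: ca - ca_zpg + k_s = 0")
    out = r_max * (ca - ca_zpg) / denom
    return float(out) if out.ndim == 0 else out


def _default_init(ca: np.ndarray, r: np.ndarray) -> tuple[float, float, float]:
    r_max0 = float(np.max(r))
    nonpos = ca[r <= 0]
    ca_zpg0 = float(np.max(nonpos)) if nonpos.size else float(np.min(ca)) / 2.0
    k_s0 = max(float(np.median(ca)) - ca_zpg0, 0.01)
    return r_max0, ca_zpg0, k_s0


def fit_monod_threshold(
        ca: Sequence[float],
        r: Sequence[float],
        weights: Optional[Sequence[float]] = None,
        init: Optional[tuple[float, float, float]] = None,
        conf_level: float = 0.95) -> MonodFitResult:
    """Least-squares fit of the threshold Monod model to (Ca, r) points.

    Parameters
    ----------
    ca, r : sequences
        Calcium levels (mg Ca L^-1) and growth rates (day^-1); >= 4 points.
    weights : sequence, optional
        Per-point weights multiplying the residuals (e.g. inverse jackknife
        SEs); unweighted by default.
    init : (r_max, ca_zpg, k_s), optional
        Starting values; a robust data-driven default is used otherwise.
    """
    ca = np.asarray(ca, dtype=float)
    r = np.asarray(r, dtype=float)
    if ca.shape != r.shape or ca.ndim != 1:
        raise ValueError("ca and r must be 1-d arrays of equal length")
    n = ca.size
    if n < 4:
        raise ValueError("need at least 4 points to fit 3 parameters")
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)

    nan = float("nan")
    if np.all(r <= 0):
        return MonodFitResult(
            r_max=nan, ca_zpg=nan, k_s=nan, se_r_max=nan, se_ca_zpg=nan,
            se_k_s=nan, ci_ca_zpg=(nan, nan), p_ca_zpg=nan, rss=nan,
            n_points=n, converged=False,
            refused="all growth rates are non-positive; the zero-growth "
                    "threshold is not identified")

    theta0 = np.asarray(init if init is not None else _default_init(ca, r))

    def resid(theta: np.ndarray) -> np.ndarray:
        r_max, ca_zpg, k_s = theta
        denom = ca - ca_zpg + k_s
        denom = np.where(np.abs(denom) < 1e-12, 1e-12, denom)
        return w * (r - r_max * (ca - ca_zpg) / denom)

    sol = least_squares(resid, theta0, method="lm", xtol=1e-14, ftol=1e-14,
                        gtol=1e-14, max_nfev=20000)
    r_max, ca_zpg, k_s = (float(v) for v in sol.x)
    rss = float(np.sum(sol.fun ** 2))
    converged = bool(sol.success) and math.isfinite(rss)
    if k_s <= 0:
        converged = False
        warnings.warn("threshold-Monod fit converged to non-positive K_s",
                      stacklevel=2)

    dof = n - 3
    ses = (nan, nan, nan)
    ci = (nan, nan)
    p_zpg = nan
    if converged and dof > 0:
        J = sol.jac
        try:
            cov = np.linalg.inv(J.T @ J) * (rss / dof)
            ses = tuple(float(math.sqrt(max(v, 0.0))) for v in np.diag(cov))
            tcrit = float(stats.t.ppf(0.5 + conf_level / 2.0, dof))
            ci = (ca_zpg - tcrit * ses[1], ca_zpg + tcrit * ses[1])
            if ses[1] > 0:
                tval = ca_zpg / ses[1]
                p_zpg = float(2.0 * stats.t.sf(abs(tval), dof))
        except np.linalg.LinAlgError:
            warnings.warn("singular Jacobian at the optimum; SEs unavailable",
                          stacklevel=2)

    return MonodFitResult(
        r_max=r_max, ca_zpg=ca_zpg, k_s=k_s,
        se_r_max=ses[0], se_ca_zpg=ses[1], se_k_s=ses[2],
        ci_ca_zpg=ci, p_ca_zpg=p_zpg, rss=rss, n_points=n,
        converged=converged)
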