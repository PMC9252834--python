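"""Four-parameter log-logistic (Hill) dose-response fitting.

The single-agent model is

    y(d) = l + (u - l) / (1 + (EC50 / d)^h)

with lower asymptote ``l`` (the response at dose 0), upper asymptote ``u``,
midpoint ``EC50`` and slope ``h > 0``.  Inhibition is assumed non-decreasing
with dose, so fits enforce ``l <= u``.  The zero dose is handled by the
closed-form limit y(0) = l, never by evaluating log(0).

Fits are deterministic: bounded nonlinear least squares started from a fixed
3x3 grid of (EC50, h) initial values; the start with the best residual sum
of squares wins, ties broken by smaller h then smaller EC50.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .errors import (
    DataError,
    InsufficientDataError,
    ResponseAboveRange,
    ResponseBelowRange,
)

# Parameter bounds for the fit, in %inhibition / dose units.
L_BOUNDS = (-50.0, 150.0)
SPAN_MAX = 250.0  # upper bound on u - l
H_BOUNDS = (0.05, 20.0)
RSS_WARN_PER_DF = 100.0  # %inh^2 per residual degree of freedom


@dataclass(frozen=True)
class DoseResponseCurve:
    """Fitted monotone sigmoidal single-agent dose-response curve."""

    drug: str
    l: float  # lower asymptote, %inh (response at zero dose)
    u: float  # upper asymptote, %inh
    ec50: float  # midpoint dose, > 0
    h: float  # Hill slope, > 0
    fit_rss: float = 0.0

    def __post_init__(self):
        if not (self.l <= self.u + 1e-12):
            raise DataError("curve requires l <= u")
        if self.ec50 <= 0 or self.h <= 0:
            raise DataError("curve requires EC50 > 0 and h > 0")

    def predict(self, dose) -> np.ndarray | float:
        return predict_response(self, dose)

    def inverse(self, response: float) -> float:
        return inverse_dose(self, response)

    def as_dict(self) -> dict:
        return {
            "drug": self.drug,
            "l": self.l,
            "u": self.u,
            "ec50": self.ec50,
            "h": self.h,
            "rss": self.fit_rss,
        }


def hill(dose, l: float, u: float, ec50: float, h: float):
    """Evaluate the four-parameter log-logistic model; vectorized in dose."""
    d = np.asarray(dose, dtype=float)
    scalar = d.ndim == 0
    d = np.atleast_1d(d)
    out = np.full(d.shape, float(l))
    pos = d > 0
    # (EC50/d)^h computed in log space for numerical stability
    with np.errstate(over="ignore"):
        ratio = np.exp(h * (np.log(ec50) - np.log(d[pos])))
    out[pos] = l + (u - l) / (1.0 + ratio)
    return float(out[0]) if scalar else out


def predict_response(curve: DoseResponseCurve, dose):
    """Predicted % inhibition at ``dose`` (scalar or array, all >= 0)."""
    d = np.asarray(dose, dtype=float)
    if np.any(d < 0):
        raise DataError("dose must be non-negative")
    return hill(dose, curve.l, curve.u, curve.ec50, curve.h)


def inverse_dose(curve: DoseResponseCurve, response: float) -> float:
    """Dose producing ``response``, by closed-form inversion.

    Raises :class:`ResponseBelowRange` for responses at/below ``l`` (the
    equivalent dose is 0) and :class:`ResponseAboveRange` for responses
    at/above ``u`` (no finite dose reaches them) so the Loewe solver can
    treat both saturation directions explicitly.
    """
    y = float(response)
    if y <= curve.l:
        raise ResponseBelowRange(
            f"response {y} at/below lower asymptote {curve.l}"
        )
    if y >= curve.u:
        raise ResponseAboveRange(
            f"response {y} at/above upper asymptote {curve.u}"
        )
    return curve.ec50 * ((y - curve.l) / (curve.u - y)) ** (1.0 / curve.h)


def _fit_starts(doses_pos: np.ndarray) -> list[tuple[float, float]]:
    """Fixed 3x3 multi-start grid over (EC50, h)."""
    dmin, dmax = float(doses_pos.min()), float(doses_pos.max())
    gmid = float(np.sqrt(dmin * dmax))
    return [(c, s) for c in (dmin, gmid, dmax) for s in (0.5, 1.0, 3.0)]


def fit_hill(
    doses,
    responses,
    drug: str = "",
    fixed_l: float | None = None,
    warn_poor_fit: bool = True,
) -> DoseResponseCurve:
    """Least-squares fit of the four-parameter log-logistic curve.

    Parameters
    ----------
    doses, responses
        Paired observations; doses non-negative, at least 3 distinct doses
        (including 0 is allowed and recommended).  NaN responses are dropped.
    fixed_l
        If given, the lower asymptote is pinned to this value (used by the
        conditional fits of the ZIP model) and only (u, EC50, h) are free.
    """
    d = np.asarray(doses, dtype=float).ravel()
    y = np.asarray(responses, dtype=float).ravel()
    if d.shape != y.shape:
        raise DataError("doses and responses must have equal length")
    keep = ~np.isnan(y)
    d, y = d[keep], y[keep]
    if not np.all(np.isfinite(y)):
        raise DataError("non-finite response value")
    if np.any(d < 0):
        raise DataError("negative dose")
    if np.unique(d).size < 3:
        raise InsufficientDataError(
            f"need >= 3 distinct doses to fit a curve (got {np.unique(d).size})"
        )
    pos = d > 0
    if pos.sum() < 2:
        raise InsufficientDataError("need >= 2 positive doses")

    ymin, ymax = float(y.min()), float(y.max())
    l0 = float(y[d == 0].mean()) if np.any(d == 0) else ymin
    l0 = float(np.clip(l0, *L_BOUNDS))
    span0 = float(np.clip(ymax - l0, 1e-3, SPAN_MAX))
    log_dmin = np.log10(d[pos].min())
    log_dmax = np.log10(d[pos].max())

    def residual(p):
        if fixed_l is None:
            l, span, logc, h = p
        else:
            l = fixed_l
            span, logc, h = p
        return hill(d, l, l + span, 10.0**logc, h) - y

    if fixed_l is None:
        lb = [L_BOUNDS[0], 0.0, log_dmin - 3.0, H_BOUNDS[0]]
        ub = [L_BOUNDS[1], SPAN_MAX, log_dmax + 3.0, H_BOUNDS[1]]
    else:
        lb = [0.0, log_dmin - 3.0, H_BOUNDS[0]]
        ub = [SPAN_MAX, log_dmax + 3.0, H_BOUNDS[1]]

    # degenerate candidate: a flat curve (span 0); wins on constant data
    if fixed_l is None:
        flat_l = float(np.clip(y.mean(), *L_BOUNDS))
        flat_rss = float(np.sum((y - flat_l) ** 2))
        gmid = float(np.sqrt(d[pos].min() * d[pos].max()))
        flat = ([flat_l, 0.0, np.log10(gmid), 1.0], flat_rss)
    else:
        flat = None

    best = None
    for c0, h0 in _fit_starts(d[pos]):
        if fixed_l is None:
            x0 = [l0, span0, np.log10(c0), h0]
        else:
            x0 = [max(span0 + l0 - fixed_l, 1e-3), np.log10(c0), h0]
        x0 = np.clip(x0, lb, ub)
        sol = least_squares(residual, x0, bounds=(lb, ub), method="trf")
        rss = float(np.sum(sol.fun**2))
        key = (rss, sol.x[-1], sol.x[-2])  # RSS, then smaller h, smaller EC50
        if best is None or key < best[0]:
            best = (key, sol.x, rss)

    _, x, rss = best
    if flat is not None and flat[1] <= rss + 1e-12:
        x, rss = np.asarray(flat[0]), flat[1]
    if fixed_l is None:
        l, span, logc, h = x
    else:
        l = fixed_l
        span, logc, h = x
    df = max(d.size - (3 if fixed_l is not None else 4), 1)
    if warn_poor_fit and rss / df > RSS_WARN_PER_DF:
        warnings.warn(
            f"poor dose-response fit for {drug or 'drug'} "
            f"(RSS/df = {rss / df:.1f} %inh^2); data may be non-sigmoidal",
            stacklevel=2,
        )
    return DoseResponseCurve(
        drug=drug,
        l=float(l),
        u=float(l + span),
        ec50=float(10.0**logc),
        h=float(x[-1]),
        fit_rss=rss,
    )


def fit_block_curves(block, warn_poor_fit: bool = True) -> dict:
    """Fit one curve per drug from a block's single-agent axes.

    Returns a dict mapping drug name -> DoseResponseCurve.  NaN axis cells
    (permitted missing single-agent measurements) are dropped before
    fitting.
    """
    curves = {}
    for axis, drug in enumerate(block.drugs):
        doses = block.dose_grid[axis]
        resp = block.single_agent_responses(axis)
        curves[drug] = fit_hill(
            doses, resp, drug=drug, warn_poor_fit=warn_poor_fit
        )
    return curves
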