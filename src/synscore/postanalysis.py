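"""Post-analysis of scored surfaces.

Two tools for interpreting an identified synergy:

* **Concentration weighting** — synergy at each dose combination is
  down-weighted by how far the single agents already are up their
  dose-response curves,

      w = sqrt( prod_n (100 - y_n) / (100 - l_n) ),

  where y_n is the measured %inhibition of drug n at its dose in the cell
  and l_n the lower asymptote of its fitted curve.  Cells where the single
  agents barely respond keep weight ~1; cells where any single agent is
  saturated get weight 0.  This favours synergy found at low effective
  doses without using the (unit-dependent) absolute concentrations.

* **MuSyC decomposition** — a two-drug mass-action surface model whose
  parameters separate *potency* synergy (alpha_12, alpha_21: fold-changes
  of each drug's potency induced by the other) from *efficacy* synergy
  (beta: gain of the combination's maximal effect over the stronger single
  agent, on the normalized 0-1 effect scale).
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import least_squares

from .blocks import CombinationBlock
from .doseresponse import fit_block_curves
from .errors import DataError, DegenerateCurveError, InsufficientDataError
from .models import SynergySurface

# ---------------------------------------------------------------------------
# concentration weighting


def dose_weight(
    y_singles: Sequence[float], l_asymptotes: Sequence[float]
) -> float:
    """Concentration weight for one cell; always in [0, 1].

    Each factor (100 - y)/(100 - l) is clamped to [0, 1] before the
    product, so stimulation (y < l) and super-inhibition (y > 100) do not
    push the weight over 1 or below 0.
    """
    if len(y_singles) != len(l_asymptotes) or len(y_singles) == 0:
        raise DataError("y_singles and l_asymptotes must have equal length >= 1")
    prod = 1.0
    for y, l in zip(y_singles, l_asymptotes):
        if l >= 100.0 - 1e-9:
            raise DegenerateCurveError(
                f"lower asymptote {l} too close to 100 %inh for weighting"
            )
        factor = (100.0 - float(y)) / (100.0 - float(l))
        prod *= min(max(factor, 0.0), 1.0)
    return float(np.sqrt(prod))


def weighted_surface(
    surface: SynergySurface,
    curves: dict,
    block: CombinationBlock,
) -> SynergySurface:
    """Fill the surface's weight tensor from the block's single-agent
    measurements and the curves' lower asymptotes.

    Returns a new surface; `summarize_surface` then reports
    weighted_mean_delta = mean(weight * delta) over the positive subgrid
    (no renormalization by the mean weight).
    """
    from .models import _axis_observations

    axes = _axis_observations(block, curves)
    ls = [curves[d].l for d in block.drugs]
    for l, d in zip(ls, block.drugs):
        if l >= 100.0 - 1e-9:
            raise DegenerateCurveError(
                f"lower asymptote of {d!r} too close to 100 %inh"
            )
    factors = [
        np.clip((100.0 - a) / (100.0 - l), 0.0, 1.0)
        for a, l in zip(axes, ls)
    ]
    grids = np.meshgrid(*factors, indexing="ij")
    weight = np.sqrt(np.prod(grids, axis=0))
    return dc_replace(surface, weight=weight)


# ---------------------------------------------------------------------------
# MuSyC


@dataclass
class MuSyCFit:
    """Fitted two-drug MuSyC surface (effects on the 0-1 inhibition scale).

    E0 is the baseline (zero-dose) effect, E1/E2 the single-drug maximal
    effects, E3 the combination maximal effect; C and h are per-drug
    midpoints and slopes.  alpha_12 is the fold-change in drug 1's potency
    caused by drug 2 being bound (alpha_21 vice versa); beta is the gain
    of E3 over max(E1, E2).  Cooperativity-interaction (gamma) terms are
    fixed at 1.
    """

    drugs: tuple[str, str]
    E0: float
    E1: float
    E2: float
    E3: float
    C1: float
    C2: float
    h1: float
    h2: float
    alpha_12: float
    alpha_21: float
    beta: float
    fit_rss: float
    quality_warning: bool = False

    def as_dict(self) -> dict:
        return {
            "drug1": self.drugs[0],
            "drug2": self.drugs[1],
            "E0": self.E0,
            "E1": self.E1,
            "E2": self.E2,
            "E3": self.E3,
            "C1": self.C1,
            "C2": self.C2,
            "h1": self.h1,
            "h2": self.h2,
            "alpha_12": self.alpha_12,
            "alpha_21": self.alpha_21,
            "beta": self.beta,
            "rss": self.fit_rss,
            "quality_warning": self.quality_warning,
        }


def musyc_response(
    d1,
    d2,
    E0: float,
    E1: float,
    E2: float,
    E3: float,
    C1: float,
    C2: float,
    h1: float,
    h2: float,
    alpha_12: float = 1.0,
    alpha_21: float = 1.0,
):
    """Two-drug MuSyC surface: steady state of the four-state mass-action
    model (unaffected U, drug-1-affected A1, drug-2-affected A2, doubly
    affected A12) with gamma = 1.

    Transition weights: U->A1 at (d1/C1)^h1, U->A2 at (d2/C2)^h2,
    A2->A12 at (alpha_12 d1/C1)^h1 (drug 1 acting on drug-2-bound cells),
    A1->A12 at (alpha_21 d2/C2)^h2; all reverse rates 1.  At
    alpha_12 = alpha_21 = 1 the two processes decouple and the surface is
    the MuSyC no-interaction null.  Effects on the normalized scale are
    mixed by state occupancy.  Vectorized over broadcastable d1, d2.
    """
    d1 = np.asarray(d1, dtype=float)
    d2 = np.asarray(d2, dtype=float)
    d1, d2 = np.broadcast_arrays(d1, d2)
    shape = d1.shape
    f1 = (d1 / C1) ** h1
    f2 = (d2 / C2) ** h2
    g1 = (alpha_12 * d1 / C1) ** h1  # drug 1 potency modified by drug 2
    g2 = (alpha_21 * d2 / C2) ** h2

    n = d1.size
    M = np.zeros((n, 4, 4))
    a = f1.ravel()
    b = f2.ravel()
    c = g2.ravel()  # A1 -> A12
    e = g1.ravel()  # A2 -> A12
    # steady state: dU = -(a+b)U + A1 + A2 = 0 ; dA1 = aU - (1+c)A1 + A12 = 0
    # dA2 = bU - (1+e)A2 + A12 = 0 ; conservation replaces the 4th equation
    M[:, 0, 0] = -(a + b)
    M[:, 0, 1] = 1.0
    M[:, 0, 2] = 1.0
    M[:, 1, 0] = a
    M[:, 1, 1] = -(1.0 + c)
    M[:, 1, 3] = 1.0
    M[:, 2, 0] = b
    M[:, 2, 2] = -(1.0 + e)
    M[:, 2, 3] = 1.0
    M[:, 3, :] = 1.0
    rhs = np.zeros((n, 4))
    rhs[:, 3] = 1.0
    p = np.linalg.solve(M, rhs[..., None])[..., 0]
    eff = p @ np.array([E0, E1, E2, E3])
    out = eff.reshape(shape)
    return float(out) if out.ndim == 0 else out


def _musyc_null_E3(E1: float, E2: float) -> float:
    return max(E1, E2)


def fit_musyc(
    block: CombinationBlock,
    alpha_starts: Sequence[float] = (0.1, 1.0, 10.0),
) -> MuSyCFit:
    """Bounded least-squares fit of the two-drug MuSyC surface.

    Responses are normalized to the 0-1 effect scale (%inh / 100).  The
    single-agent Hill fits seed E1/E2, C and h; a deterministic multi-start
    over the (alpha_12, alpha_21) grid picks the best residual sum of
    squares.  Non-sigmoidal monotherapies trigger a quality warning on the
    returned fit (the model assumes monotone sigmoidal single agents) but
    the fit still proceeds.
    """
    if block.n_drugs != 2:
        raise DataError("MuSyC decomposition is defined for 2-drug blocks")
    if any(s < 4 for s in block.shape):
        raise InsufficientDataError(
            "MuSyC needs >= 4 doses per drug including 0"
        )
    import warnings as _w

    quality_warning = False
    with _w.catch_warnings(record=True) as caught:
        _w.simplefilter("always")
        curves = fit_block_curves(block)
        quality_warning = any("poor dose-response fit" in str(c.message)
                              for c in caught)

    c1, c2 = (curves[d] for d in block.drugs)
    d1 = block.dose_grid[0]
    d2 = block.dose_grid[1]
    D1, D2 = np.meshgrid(d1, d2, indexing="ij")
    Y = block.response / 100.0
    valid = ~np.isnan(Y)

    log_c1_bounds = (np.log10(d1[1]) - 2.0, np.log10(d1[-1]) + 2.0)
    log_c2_bounds = (np.log10(d2[1]) - 2.0, np.log10(d2[-1]) + 2.0)

    # params: E0, E1, E2, beta, logC1, logC2, h1, h2, log_a12, log_a21
    lb = [-0.3, -0.2, -0.2, -1.0, log_c1_bounds[0], log_c2_bounds[0],
          0.1, 0.1, -2.0, -2.0]
    ub = [0.3, 1.5, 1.5, 1.0, log_c1_bounds[1], log_c2_bounds[1],
          10.0, 10.0, 2.0, 2.0]

    def unpack(p):
        E0, E1, E2, beta, lc1, lc2, h1, h2, la12, la21 = p
        E3 = max(E1, E2) + beta
        return (E0, E1, E2, E3, 10.0**lc1, 10.0**lc2, h1, h2,
                10.0**la12, 10.0**la21)

    def residual(p):
        pred = musyc_response(D1, D2, *unpack(p))
        return (pred - Y)[valid].ravel()

    e1_0 = float(np.clip(c1.u / 100.0, lb[1], ub[1]))
    e2_0 = float(np.clip(c2.u / 100.0, lb[2], ub[2]))
    e0_0 = float(np.clip((c1.l + c2.l) / 200.0, lb[0], ub[0]))
    y_corner = float(Y[-1, -1]) if valid[-1, -1] else max(e1_0, e2_0)
    beta_0 = float(np.clip(y_corner - max(e1_0, e2_0), -0.9, 0.9))
    base = [
        e0_0, e1_0, e2_0, beta_0,
        float(np.clip(np.log10(c1.ec50), *log_c1_bounds)),
        float(np.clip(np.log10(c2.ec50), *log_c2_bounds)),
        float(np.clip(c1.h, 0.1, 10.0)),
        float(np.clip(c2.h, 0.1, 10.0)),
    ]

    best = None
    for a12 in alpha_starts:
        for a21 in alpha_starts:
            x0 = np.array(base + [np.log10(a12), np.log10(a21)])
            x0 = np.clip(x0, lb, ub)
            sol = least_squares(
                residual, x0, bounds=(lb, ub), method="trf",
                xtol=1e-10, ftol=1e-10,
            )
            rss = float(np.sum(sol.fun**2))
            if best is None or rss < best[0] - 1e-12:
                best = (rss, sol.x)

    rss, x = best
    E0, E1, E2, E3, C1, C2, h1, h2, a12, a21 = unpack(x)
    return MuSyCFit(
        drugs=(block.drugs[0], block.drugs[1]),
        E0=E0, E1=E1, E2=E2, E3=E3, C1=C1, C2=C2, h1=h1, h2=h2,
        alpha_12=a12, alpha_21=a21, beta=float(x[3]), fit_rss=rss,
        quality_warning=quality_warning,
    )


SYNERGY_MODES = (
    "potency_synergy",
    "efficacy_synergy",
    "both",
    "antagonism_potency",
    "antagonism_efficacy",
    "mixed",
    "none",
)


def classify_synergy_mode(
    fit: MuSyCFit, alpha_tol: float = 0.1, beta_tol: float = 0.05
) -> str:
    """Label the mode of interaction from a MuSyC fit.

    The potency axis uses the geometric mean of the two alphas on the
    log10 scale against the tolerance; the efficacy axis uses beta against
    its tolerance.  Same-direction synergy on both axes is "both";
    opposite directions (or antagonism on both) is "mixed".
    """
    log_alpha_gm = 0.5 * (np.log10(fit.alpha_12) + np.log10(fit.alpha_21))
    potency = 0
    if log_alpha_gm > alpha_tol:
        potency = 1
    elif log_alpha_gm < -alpha_tol:
        potency = -1
    efficacy = 0
    if fit.beta > beta_tol:
        efficacy = 1
    elif fit.beta < -beta_tol:
        efficacy = -1

    if potency == 0 and efficacy == 0:
        return "none"
    if potency == 1 and efficacy == 1:
        return "both"
    if potency == 1 and efficacy == 0:
        return "potency_synergy"
    if potency == 0 and efficacy == 1:
        return "efficacy_synergy"
    if potency == -1 and efficacy == 0:
        return "antagonism_potency"
    if potency == 0 and efficacy == -1:
        return "antagonism_efficacy"
    return "mixed"
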