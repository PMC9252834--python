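"""Reference-model synergy scoring: Bliss, Loewe, HSA, ZIP and consensus.

For every all-positive-dose cell of a combination block the expected
response under a no-interaction null is computed and the synergy delta is

    delta = observed - expected   (%inh)

Positive deltas indicate synergy, negative antagonism.  The Bliss/Loewe
consensus takes the *maximum* expected effect over Bliss, Loewe and HSA at
each dose combination, making its delta the most conservative (elementwise
minimum) of the three.  ZIP is kept out of the consensus because it rests on
the same multiplicative-survival principle as Bliss and would bias the
combined score toward that family.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .blocks import CombinationBlock
from .doseresponse import (
    DoseResponseCurve,
    fit_hill,
    inverse_dose,
    predict_response,
)
from .errors import (
    DataError,
    DegenerateCurveError,
    InsufficientDataError,
    ResponseAboveRange,
    ResponseBelowRange,
)

CONSENSUS_MODELS = ("bliss", "loewe", "hsa")
ALL_MODELS = ("bliss", "loewe", "hsa", "zip", "consensus")

LOEWE_TOL = 1e-6  # tolerance on the dose-fraction sum


@dataclass
class SynergySurface:
    """Expected effect and synergy delta over the all-positive-dose grid."""

    block_id: str
    sample_id: Optional[str]
    model: str
    drugs: tuple[str, ...]
    doses: tuple[np.ndarray, ...]  # positive doses per drug
    observed: np.ndarray
    expected: np.ndarray
    delta: np.ndarray
    weight: Optional[np.ndarray] = None


@dataclass
class SynergySummary:
    """Summary synergy scores for one (block, sample, model)."""

    block_id: str
    sample_id: Optional[str]
    model: str
    mean_delta: float
    msa_delta: float
    weighted_mean_delta: Optional[float] = None


# ---------------------------------------------------------------------------
# expected-effect primitives


def expected_bliss(y: Sequence[float]) -> float | np.ndarray:
    """Bliss independence: survival fractions multiply.

    ``100 * (1 - prod_i(1 - y_i/100))`` with each y_i clamped to [0, 100]
    inside the product (survival fractions outside [0, 1] are unphysical).
    Accepts a list of scalars or of broadcastable arrays.
    """
    if len(y) == 0:
        raise DataError("expected_bliss requires at least one response")
    arrs = [np.clip(np.asarray(v, dtype=float), 0.0, 100.0) for v in y]
    if any(not np.all(np.isfinite(a)) for a in arrs):
        raise DataError("non-finite single-agent response")
    surv = arrs[0] * 0 + 1.0
    for a in arrs:
        surv = surv * (1.0 - a / 100.0)
    out = 100.0 * (1.0 - surv)
    return float(out) if np.ndim(out) == 0 else out


def expected_hsa(y: Sequence[float]) -> float | np.ndarray:
    """Highest single agent: the best monotherapy effect at these doses."""
    if len(y) == 0:
        raise DataError("expected_hsa requires at least one response")
    arrs = [np.asarray(v, dtype=float) for v in y]
    if any(not np.all(np.isfinite(a)) for a in arrs):
        raise DataError("non-finite single-agent response")
    out = arrs[0]
    for a in arrs[1:]:
        out = np.maximum(out, a)
    return float(out) if np.ndim(out) == 0 else out


def expected_loewe(
    curves: Sequence[DoseResponseCurve], doses: Sequence[float]
) -> float:
    """Loewe additivity: solve sum_i d_i / D_i(y) = 1 for y by bisection.

    D_i(y) is the dose of drug i alone producing response y.  The solution
    is searched on (max_i l_i, min_i u_i); if even the upper end leaves the
    dose-fraction sum above 1 the combination saturates every curve and the
    expected effect is min_i u_i.
    """
    if len(curves) != len(doses) or len(curves) == 0:
        raise DataError("one curve per dose is required")
    d = np.asarray(doses, dtype=float)
    if np.any(d <= 0):
        raise DataError("Loewe expects strictly positive doses")
    lo = max(c.l for c in curves)
    hi = min(c.u for c in curves)
    if lo >= hi:
        raise DegenerateCurveError(
            "non-overlapping response ranges (max l >= min u)"
        )

    def frac_sum(y: float) -> float:
        total = 0.0
        for ci, di in zip(curves, d):
            try:
                total += di / inverse_dose(ci, y)
            except ResponseBelowRange:
                return np.inf  # equivalent dose -> 0: unbounded ratio
            except ResponseAboveRange:
                return 0.0 - 1.0  # unreachable by construction of (lo, hi)
        return total

    span = hi - lo
    y_hi = hi - 1e-9 * span
    if frac_sum(y_hi) - 1.0 > 0:
        return hi  # saturation: every curve maxed out
    a, b = lo + 1e-12 * span, y_hi
    for _ in range(80):  # 2^-80 of the span: well past the sum tolerance
        mid = 0.5 * (a + b)
        if frac_sum(mid) - 1.0 > 0:
            a = mid
        else:
            b = mid
        if b - a < 1e-12 * span:
            break
    return 0.5 * (a + b)


# ---------------------------------------------------------------------------
# surfaces


def _axis_observations(
    block: CombinationBlock, curves: dict | None
) -> list[np.ndarray]:
    """Measured single-agent responses over positive doses, one array per
    drug; NaN axis cells fall back to the curve prediction."""
    out = []
    for axis, drug in enumerate(block.drugs):
        vals = block.single_agent_responses(axis)[1:]
        if np.any(np.isnan(vals)):
            if curves is None or drug not in curves:
                raise DataError(
                    f"missing single-agent measurements for {drug!r} and no "
                    "fitted curve to fall back on"
                )
            pred = predict_response(curves[drug], block.dose_grid[axis][1:])
            vals = np.where(np.isnan(vals), pred, vals)
        out.append(vals)
    return out


def _surface_from_expected(
    block: CombinationBlock, model: str, expected: np.ndarray
) -> SynergySurface:
    observed = block.response[block.interior_index]
    return SynergySurface(
        block_id=block.block_id,
        sample_id=block.sample_id,
        model=model,
        drugs=block.drugs,
        doses=block.interior_doses,
        observed=observed.copy(),
        expected=expected,
        delta=observed - expected,
    )


def synergy_surface(
    block: CombinationBlock,
    model: str,
    curves: dict | None = None,
) -> SynergySurface:
    """Expected-effect surface and delta for one reference model.

    Bliss and HSA combine the *measured* single-agent axis responses
    (after any outlier correction applied upstream); Loewe necessarily uses
    the fitted curves.
    """
    model = model.lower()
    if model == "zip":
        return zip_surface(block, curves)
    if model == "consensus":
        return consensus_surface(block, curves)
    if model not in CONSENSUS_MODELS:
        raise DataError(f"unknown synergy model {model!r}")

    shape = tuple(s - 1 for s in block.shape)
    if model in ("bliss", "hsa"):
        axes = _axis_observations(block, curves)
        grids = np.meshgrid(*axes, indexing="ij")
        fn = expected_bliss if model == "bliss" else expected_hsa
        expected = np.asarray(fn(grids), dtype=float)
    else:  # loewe
        if curves is None:
            raise DataError("Loewe requires fitted curves")
        curve_list = [curves[d] for d in block.drugs]
        expected = np.empty(shape)
        for idx, doses in block.iter_interior_cells():
            pos_idx = tuple(i - 1 for i in idx)
            expected[pos_idx] = expected_loewe(curve_list, doses)
    return _surface_from_expected(block, model, expected)


def consensus_surface(
    block: CombinationBlock, curves: dict | None = None
) -> SynergySurface:
    """Bliss/Loewe consensus: pointwise maximum expected effect over the
    Bliss, Loewe and HSA nulls; delta is the elementwise minimum of the
    three per-model deltas (the most conservative call)."""
    expecteds = [
        synergy_surface(block, m, curves).expected for m in CONSENSUS_MODELS
    ]
    expected = np.maximum.reduce(expecteds)
    return _surface_from_expected(block, "consensus", expected)


def zip_surface(
    block: CombinationBlock, curves: dict | None = None
) -> SynergySurface:
    """Zero-interaction-potency surface for a two-drug block.

    For each dose pair, dose-response curves are re-fitted along the row
    and the column through that cell with the zero-dose anchor pinned to
    the partner drug's fitted single-agent response.  The ZIP expectation
    is the Bliss (multiplicative-survival) combination of the two fitted
    single-agent values; the ZIP delta averages the two directional
    fitted-minus-expected differences, so a surface exactly obeying the
    multiplicative null scores 0 everywhere.
    """
    if block.n_drugs != 2:
        raise DataError("ZIP is defined for 2-drug blocks only")
    if any(s < 3 for s in block.shape):
        raise InsufficientDataError(
            "ZIP conditional fits need >= 3 doses (incl. 0) per drug"
        )
    if curves is None:
        from .doseresponse import fit_block_curves

        curves = fit_block_curves(block)
    c1, c2 = (curves[d] for d in block.drugs)
    d1 = block.dose_grid[0]
    d2 = block.dose_grid[1]
    y1_fit = predict_response(c1, d1[1:])  # fitted monotherapy, drug 1
    y2_fit = predict_response(c2, d2[1:])

    n1, n2 = d1.size - 1, d2.size - 1
    fit_along_1 = np.empty((n1, n2))  # curves in the drug-1 direction
    fit_along_2 = np.empty((n1, n2))

    for j in range(n2):  # fix drug-2 dose, fit along drug 1
        row = block.response[:, j + 1].copy()
        row[0] = y2_fit[j]  # zero-dose anchor = partner's fitted response
        cond = fit_hill(
            d1, row, drug=f"{block.drugs[0]}|{block.drugs[1]}",
            fixed_l=float(y2_fit[j]), warn_poor_fit=False,
        )
        fit_along_1[:, j] = predict_response(cond, d1[1:])
    for i in range(n1):
        col = block.response[i + 1, :].copy()
        col[0] = y1_fit[i]
        cond = fit_hill(
            d2, col, drug=f"{block.drugs[1]}|{block.drugs[0]}",
            fixed_l=float(y1_fit[i]), warn_poor_fit=False,
        )
        fit_along_2[i, :] = predict_response(cond, d2[1:])

    expected = np.asarray(
        expected_bliss(np.meshgrid(y1_fit, y2_fit, indexing="ij"))
    )
    delta = 0.5 * ((fit_along_1 - expected) + (fit_along_2 - expected))
    surf = _surface_from_expected(block, "zip", expected)
    surf.delta = delta  # ZIP delta is fit-based, not observed - expected
    return surf


# ---------------------------------------------------------------------------
# summaries


def summarize_surface(
    surface: SynergySurface, msa_window: int = 3
) -> SynergySummary:
    """Mean synergy score and most-synergistic-area (MSA) score.

    mean_delta averages delta over all-positive-dose cells; msa_delta is
    the maximum mean over axis-aligned windows of edge length
    ``msa_window`` (clipped per axis to the grid size).
    """
    delta = surface.delta
    if delta.size == 0:
        raise DataError("empty delta tensor")
    if msa_window < 1:
        raise DataError("msa_window must be >= 1")
    window = tuple(min(msa_window, s) for s in delta.shape)
    if any(w != msa_window for w in window):
        warnings.warn(
            f"MSA window {msa_window} clipped to {window} for grid "
            f"{delta.shape}",
            stacklevel=2,
        )
    view = np.lib.stride_tricks.sliding_window_view(delta, window)
    win_means = view.mean(axis=tuple(range(delta.ndim, 2 * delta.ndim)))
    mean_delta = float(delta.mean())
    weighted = None
    if surface.weight is not None:
        weighted = float((surface.weight * delta).mean())
    return SynergySummary(
        block_id=surface.block_id,
        sample_id=surface.sample_id,
        model=surface.model,
        mean_delta=mean_delta,
        msa_delta=float(win_means.max()),
        weighted_mean_delta=weighted,
    )
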